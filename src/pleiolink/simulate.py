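"""Synthetic data generation with planted ground truth.

Emulates every input class the pipeline consumes — a PDB structure ensemble
with controlled mutation-to-partner minimum distances, a per-structure ΔΔG
table, a negative-binomial count matrix with genotype-specific
temperature-response DEG sets, a GMT gene-set collection with planted
enrichment, logistic growth curves with known AUC, and scalar trait tables —
so every downstream stage can be tested against known truth without any
external download.

Geometry is deliberately minimal: partner chains are poly-alanine or
idealized poly-nucleotide segments whose contact atom is placed analytically
at the planted distance (only inter-chain minimum distances matter
downstream, not stereochemistry). The default scenario mirrors the study
design this package targets: six rpoB mutants plus the wild type, two
temperatures (37/42 °C), two experiment batches, three RNA-seq replicates
per cell, twelve growth replicates, OD600 every 10 minutes for 24 h.

Ground-truth tables are generated before any pipeline stage runs and no
stage reads them; fixing the seed fixes every byte of output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import stage_seed, write_table
from .organismal import GrowthCurveMatrix, logistic_auc_closed_form
from .structures import MutationSite, StructureModel

AA3 = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
       "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
       "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
       "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR"}

#: x-spacing between mutation sites; planted distances must stay well below
#: this so each site's nearest partner atom is its own contact segment.
SITE_SPACING = 150.0

ROLE_CHAIN_IDS = {"beta": "B", "beta_prime": "C", "sigma": "D",
                  "dna_template": "E", "dna_nontemplate": "F", "rna": "G"}
PROTEIN_ROLES = ("beta", "beta_prime", "sigma")
DNA_ROLES = ("dna_template", "dna_nontemplate")

DEFAULT_GENOTYPES = ("WT", "V146F", "Q513L", "Q513R", "S522F", "H526Y",
                     "S531F")
DEFAULT_ROLES = ("beta_prime", "sigma", "dna_template", "dna_nontemplate",
                 "rna")


def parse_mutation(genotype: str) -> MutationSite | None:
    """``V146F`` -> MutationSite; labels without digits (wild type) -> None."""
    digits = "".join(c for c in genotype if c.isdigit())
    if not digits:
        return None
    wt, mut = genotype[0], genotype[-1]
    return MutationSite(genotype=genotype, residue_seq=int(digits),
                        wt_aa=wt, mut_aa=mut)


@dataclass
class SetSpec:
    name: str
    size: int
    fraction: float          # planted-member fraction; 0 = pure random set
    genotype: str | None = None
    direction: str = "up"    # up | down


@dataclass
class SimScenario:
    """All knobs of the synthetic study, with defaults matching its design."""

    seed: int = 0
    genotypes: tuple = DEFAULT_GENOTYPES
    roles: tuple = DEFAULT_ROLES
    planted_min_dist: dict = field(default_factory=dict)   # (genotype, role) -> Å
    n_structures: int = 7
    coord_jitter_sd: float = 0.3
    ddg_mean: dict = field(default_factory=dict)           # genotype -> kcal/mol
    ddg_sd: float = 0.4
    n_genes: int = 2000
    planted_degs: dict = field(default_factory=dict)       # genotype -> (n_up, n_down, lfc)
    nb_dispersion: float = 0.05
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    size_factor_range: tuple = (0.7, 1.4)
    batch_effect_sd: float = 0.1
    n_count_replicates: int = 3
    set_specs: list = field(default_factory=list)
    growth_params: dict = field(default_factory=dict)      # (genotype, temp) -> (K, r, N0)
    growth_noise_sd: float = 0.01
    n_growth_replicates: int = 12
    trait_specs: dict = field(default_factory=dict)        # (assay, genotype, temp) -> (mean, sd, n)

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_count_replicates < 2:
            raise ValueError("need >=2 replicates per (genotype, temperature): "
                             "dispersion unidentifiable otherwise")
        if any(d <= 0 for d in self.planted_min_dist.values()):
            raise ValueError("planted distances must be > 0")
        total_planted = sum(u + d for u, d, _ in self.planted_degs.values())
        if total_planted > self.n_genes:
            raise ValueError("planted DEGs exceed the gene universe")

    @property
    def mutants(self) -> tuple:
        return tuple(g for g in self.genotypes if parse_mutation(g))

    @property
    def sites(self) -> list[MutationSite]:
        return [s for g in self.genotypes if (s := parse_mutation(g))]


def default_scenario(seed: int = 0) -> SimScenario:
    """The study-design scenario: 6 mutants + WT, planted effects everywhere."""
    genotypes = DEFAULT_GENOTYPES
    dist = {}
    base = {"beta_prime": 14.0, "sigma": 22.0, "dna_template": 18.0,
            "dna_nontemplate": 20.0, "rna": 12.0}
    offsets = {"V146F": 6.0, "Q513L": -4.0, "Q513R": -4.0, "S522F": 10.0,
               "H526Y": 0.0, "S531F": 3.0}
    for g, off in offsets.items():
        for role, b in base.items():
            dist[(g, role)] = b + off
    ddg = {"V146F": 1.5, "Q513L": -1.0, "Q513R": 0.05, "S522F": 2.0,
           "H526Y": -0.8, "S531F": 1.2}
    degs = {"WT": (30, 15, 2.0), "V146F": (120, 60, 2.0),
            "Q513L": (40, 53, 2.0), "Q513R": (150, 80, 2.0),
            "S522F": (240, 138, 2.0), "H526Y": (90, 45, 2.0),
            "S531F": (160, 70, 2.0)}
    sets = [SetSpec("metabolic_pathways", 50, 0.6, "Q513R", "up"),
            SetSpec("biofilm_formation", 40, 0.5, "S531F", "down"),
            SetSpec("abc_transporters", 30, 0.5, "S522F", "up"),
            SetSpec("random_set_a", 40, 0.0),
            SetSpec("random_set_b", 60, 0.0)]
    growth = {}
    for g in genotypes:
        k37 = 0.8 if g == "Q513R" else 1.2
        bump = {"Q513R": 0.25, "S531F": 0.20}.get(g, 0.05)
        growth[(g, 37)] = (k37, 0.7, 0.001)
        growth[(g, 42)] = (k37 + bump, 0.7, 0.001)
    traits = {}
    for g in genotypes:
        bio42 = {"V146F": -0.10, "Q513L": -0.10, "S531F": -0.10,
                 "S522F": 0.05}.get(g, 0.0)
        ni42 = {"Q513R": 20.0, "S522F": 15.0}.get(g, 0.0)
        traits[("biofilm_od550", g, 37)] = (0.35, 0.05, 6)
        traits[("biofilm_od550", g, 42)] = (0.35 + bio42, 0.05, 6)
        traits[("nickel_ppb", g, 37)] = (50.0, 8.0, 3)
        traits[("nickel_ppb", g, 42)] = (50.0 + ni42, 8.0, 3)
    return SimScenario(seed=seed, genotypes=genotypes, planted_min_dist=dist,
                       ddg_mean=ddg, planted_degs=degs, set_specs=sets,
                       growth_params=growth, trait_specs=traits)


# ---------------------------------------------------------------------------
# structures

def _site_positions(sites: list[MutationSite]) -> dict[int, np.ndarray]:
    """One shared position per unique residue number, spaced along x."""
    residues = sorted({s.residue_seq for s in sites})
    return {res: np.array([SITE_SPACING * i, 0.0, 0.0])
            for i, res in enumerate(residues)}


def _validate_geometry(scenario: SimScenario) -> None:
    """Reject contradictory planted distances before building any atoms."""
    by_residue: dict[tuple[int, str], float] = {}
    for site in scenario.sites:
        for role in scenario.roles:
            d = scenario.planted_min_dist.get((site.genotype, role))
            if d is None:
                continue
            if d < 2.0:
                raise ValueError(
                    f"planted distance {d} Å for ({site.genotype}, {role}) "
                    "below the 2 Å physical floor")
            if d > SITE_SPACING / 3:
                raise ValueError(
                    f"planted distance {d} Å for ({site.genotype}, {role}) "
                    f"infeasible: exceeds site spacing / 3 ({SITE_SPACING / 3:.0f} Å)")
            key = (site.residue_seq, role)
            if key in by_residue and by_residue[key] != d:
                raise ValueError(
                    f"contradictory planted distances for residue "
                    f"{site.residue_seq}, role {role}: two genotypes at the "
                    f"same residue require {by_residue[key]} and {d} Å")
            by_residue[key] = d


@dataclass
class EnsembleBundle:
    structures: list
    role_map: dict
    sites: list
    truth: pd.DataFrame   # genotype, role, structure_id, planted, realized
    ddg: pd.DataFrame     # genotype, structure_id, ddG


def _protein_segment(chain: str, first_res: int, resname: str,
                     origin: np.ndarray, direction: np.ndarray,
                     n_res: int = 5, spacing: float = 3.8) -> list[tuple]:
    """Cα-only segment whose first residue sits at *origin*, receding along
    *direction* so every later atom is strictly farther from the site."""
    rows = []
    for k in range(n_res):
        pos = origin + direction * (spacing * k)
        rows.append((chain, first_res + k, resname, "CA", "C", pos))
    return rows


def _dna_segment(chain: str, first_res: int, resname: str,
                 origin: np.ndarray, direction: np.ndarray,
                 n_res: int = 4, spacing: float = 6.0) -> list[tuple]:
    """C1'/P nucleotide segment; C1' of the first residue at *origin*, its P
    and all later residues strictly farther along *direction*."""
    rows = []
    for k in range(n_res):
        pos = origin + direction * (spacing * k)
        rows.append((chain, first_res + k, resname, "C1'", "C", pos))
        rows.append((chain, first_res + k, resname, "P", "P",
                     pos + direction * 1.5))
    return rows


def gen_structure_ensemble(scenario: SimScenario,
                           out_dir: Path | None = None) -> EnsembleBundle:
    """Build the PDB structure ensemble with planted minimum distances.

    Each structure has one β chain carrying a Cα at every mutated residue,
    and one chain per partner role whose nearest representative atom to each
    mutation site sits at the planted distance plus N(0, coord_jitter_sd)
    radial jitter; all other atoms of the chain are strictly farther. Also
    draws the per-structure ΔΔG table around the scenario's genotype means.
    """
    sites = scenario.sites
    if not sites or not scenario.roles:
        raise ValueError("need >=1 mutant genotype and >=1 role")
    _validate_geometry(scenario)
    rng = np.random.default_rng(stage_seed(scenario.seed, "structures"))
    positions = _site_positions(sites)
    resname_of = {s.residue_seq: AA3[s.wt_aa] for s in sites}
    unique_residues = sorted(positions)

    structures, role_map = [], {}
    truth_rows, ddg_rows = [], []
    for s_idx in range(scenario.n_structures):
        sid = f"synth_{s_idx:02d}"
        rows: list[tuple] = []
        # beta chain: one Cα per mutated residue + far filler helix
        for res in unique_residues:
            rows.append(("B", res, resname_of[res], "CA", "C", positions[res]))
        rows += _protein_segment("B", 9001, "ALA",
                                 np.array([-80.0, -80.0, 0.0]),
                                 np.array([0.0, -1.0, 0.0]), n_res=8)
        chain_roles = {"B": "beta"}
        realized: dict[tuple[int, str], float] = {}
        for role in scenario.roles:
            chain = ROLE_CHAIN_IDS[role]
            chain_roles[chain] = role
            planted_any = False
            for seg_idx, res in enumerate(unique_residues):
                genos = [s.genotype for s in sites if s.residue_seq == res]
                d = scenario.planted_min_dist.get((genos[0], role))
                if d is None:
                    continue
                planted_any = True
                eps = rng.normal(0.0, scenario.coord_jitter_sd)
                dist = max(d + eps, 2.0)
                origin = positions[res] + np.array([0.0, dist, 0.0])
                first = seg_idx * 10 + 1
                if role in PROTEIN_ROLES:
                    rows += _protein_segment(chain, first, "ALA", origin,
                                             np.array([0.0, 1.0, 0.0]))
                elif role in DNA_ROLES:
                    rows += _dna_segment(chain, first, "DA", origin,
                                         np.array([0.0, 1.0, 0.0]))
                else:  # rna
                    rows += _dna_segment(chain, first, "A", origin,
                                         np.array([0.0, 1.0, 0.0]))
                realized[(res, role)] = dist
            if not planted_any:
                del chain_roles[chain]
        atoms = pd.DataFrame(
            [(c, r, rn, an, float(p[0]), float(p[1]), float(p[2]))
             for c, r, rn, an, _el, p in rows],
            columns=["chain_id", "residue_seq", "residue_name", "atom_name",
                     "x", "y", "z"])
        atoms["icode"] = ""
        atoms["altloc"] = ""
        model = StructureModel(structure_id=sid, atoms=atoms[
            ["chain_id", "residue_seq", "icode", "residue_name", "atom_name",
             "altloc", "x", "y", "z"]])
        structures.append(model)
        role_map[sid] = chain_roles
        for site in sites:
            for role in scenario.roles:
                key = (site.residue_seq, role)
                if key in realized:
                    truth_rows.append(
                        (site.genotype, role, sid,
                         scenario.planted_min_dist[(site.genotype, role)],
                         realized[key]))
            mean_ddg = scenario.ddg_mean.get(site.genotype)
            if mean_ddg is not None:
                ddg_rows.append((site.genotype, sid,
                                 mean_ddg + rng.normal(0.0, scenario.ddg_sd)))

    truth = pd.DataFrame(truth_rows, columns=["genotype", "role",
                                              "structure_id", "planted",
                                              "realized"])
    ddg = pd.DataFrame(ddg_rows, columns=["genotype", "structure_id", "ddG"])
    bundle = EnsembleBundle(structures=structures, role_map=role_map,
                            sites=sites, truth=truth, ddg=ddg)
    if out_dir is not None:
        _write_ensemble(bundle, Path(out_dir))
    return bundle


def _write_ensemble(bundle: EnsembleBundle, out_dir: Path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as biotite_pdb

    out_dir.mkdir(parents=True, exist_ok=True)
    for model in bundle.structures:
        n = len(model.atoms)
        arr = struc.AtomArray(n)
        arr.chain_id[:] = model.atoms["chain_id"].to_numpy()
        arr.res_id[:] = model.atoms["residue_seq"].to_numpy()
        arr.res_name[:] = model.atoms["residue_name"].to_numpy()
        arr.atom_name[:] = model.atoms["atom_name"].to_numpy()
        arr.element[:] = [a[0] for a in model.atoms["atom_name"]]
        arr.hetero[:] = False
        arr.coord = model.atoms[["x", "y", "z"]].to_numpy(dtype=np.float32)
        pdb_file = biotite_pdb.PDBFile()
        pdb_file.set_structure(arr)
        pdb_file.write(str(out_dir / f"{model.structure_id}.pdb"))
    role_rows = [(sid, chain, role)
                 for sid, chains in sorted(bundle.role_map.items())
                 for chain, role in sorted(chains.items())]
    write_table(pd.DataFrame(role_rows,
                             columns=["structure_id", "chain_id", "role"]),
                out_dir / "roles.tsv")
    write_table(pd.DataFrame(
        [(s.genotype, s.residue_seq, s.wt_aa, s.mut_aa) for s in bundle.sites],
        columns=["genotype", "residue_seq", "wt_aa", "mut_aa"]),
        out_dir / "mutations.tsv")
    write_table(bundle.truth, out_dir / "truth_distances.tsv")
    write_table(bundle.ddg, out_dir / "ddg.tsv")


# ---------------------------------------------------------------------------
# counts

@dataclass
class CountsBundle:
    counts: pd.DataFrame    # genes x samples, integers
    design: pd.DataFrame    # index sample: genotype, temperature, experiment, replicate
    truth_de: pd.DataFrame  # gene, genotype, lfc
    size_factors_true: pd.Series


def gen_counts(scenario: SimScenario,
               out_dir: Path | None = None) -> CountsBundle:
    """Negative-binomial count matrix with planted temperature-response DEGs.

    count ~ NB(mean = baseline × size_factor × batch × 2^LFC, dispersion),
    where the LFC applies only to (gene, genotype) pairs planted for that
    genotype's temperature response and only at 42 °C. Batch ("experiment")
    enters as a per-(gene, experiment) multiplicative log-normal factor so
    the PERMANOVA experiment term has signal to detect. Planted gene sets
    are disjoint across genotypes.
    """
    rng = np.random.default_rng(stage_seed(scenario.seed, "counts"))
    genes = [f"gene_{i:04d}" for i in range(scenario.n_genes)]
    samples, meta = [], []
    for g in scenario.genotypes:
        for t in (37, 42):
            for i in range(1, scenario.n_count_replicates + 1):
                samples.append(f"{g}_{t}_r{i}")
                meta.append((g, t, f"exp{(i - 1) % 2 + 1}", f"r{i}"))
    design = pd.DataFrame(meta, columns=["genotype", "temperature",
                                         "experiment", "replicate"],
                          index=pd.Index(samples, name="sample"))

    baseline = rng.lognormal(scenario.baseline_log_mean,
                             scenario.baseline_log_sd, scenario.n_genes)
    lo, hi = scenario.size_factor_range
    sf = pd.Series(rng.uniform(lo, hi, len(samples)), index=design.index)
    experiments = sorted(design["experiment"].unique())
    batch = {e: np.exp(rng.normal(0.0, scenario.batch_effect_sd,
                                  scenario.n_genes))
             for e in experiments}

    # disjoint planted DEG sets per genotype, drawn from a shuffled pool
    pool = rng.permutation(scenario.n_genes)
    cursor = 0
    lfc = np.zeros((scenario.n_genes, len(scenario.genotypes)))
    truth_rows = []
    geno_index = {g: j for j, g in enumerate(scenario.genotypes)}
    for g, (n_up, n_down, mag) in scenario.planted_degs.items():
        take = pool[cursor:cursor + n_up + n_down]
        cursor += n_up + n_down
        lfc[take[:n_up], geno_index[g]] = mag
        lfc[take[n_up:], geno_index[g]] = -mag
        truth_rows += [(genes[i], g, mag) for i in take[:n_up]]
        truth_rows += [(genes[i], g, -mag) for i in take[n_up:]]

    counts = np.empty((scenario.n_genes, len(samples)), dtype=np.int64)
    alpha = scenario.nb_dispersion
    for j, s in enumerate(samples):
        g, t, e, _ = meta[j]
        mu = baseline * sf.iloc[j] * batch[e]
        if t == 42:
            mu = mu * np.exp2(lfc[:, geno_index[g]])
        lam = rng.gamma(1.0 / alpha, alpha * mu)
        counts[:, j] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=samples)
    truth_de = pd.DataFrame(truth_rows, columns=["gene", "genotype", "lfc"])
    bundle = CountsBundle(counts=counts_df, design=design, truth_de=truth_de,
                          size_factors_true=sf.rename("size_factor"))
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_table(counts_df, out_dir / "counts.tsv", index=True)
        write_table(design.reset_index(), out_dir / "design.tsv")
        write_table(truth_de, out_dir / "truth_de.tsv")
    return bundle


# ---------------------------------------------------------------------------
# gene sets

def gen_gene_sets(scenario: SimScenario, truth_de: pd.DataFrame,
                  out_path: Path | None = None
                  ) -> tuple[dict[str, set], pd.DataFrame]:
    """Gene-set collection with planted enrichment.

    Each enriched set draws fraction×size members from the named genotype's
    planted up- (or down-) genes and the remainder uniformly from genes with
    no planted effect for any genotype.
    """
    rng = np.random.default_rng(stage_seed(scenario.seed, "gene_sets"))
    genes = [f"gene_{i:04d}" for i in range(scenario.n_genes)]
    planted_any = set(truth_de["gene"])
    unplanted = [g for g in genes if g not in planted_any]
    collection: dict[str, set] = {}
    truth_rows = []
    for spec in scenario.set_specs:
        if spec.size > scenario.n_genes:
            raise ValueError(f"set {spec.name}: size exceeds gene universe")
        n_planted = int(round(spec.fraction * spec.size))
        members: list = []
        if n_planted > 0:
            sign = 1 if spec.direction == "up" else -1
            pool = truth_de[(truth_de["genotype"] == spec.genotype)
                            & (np.sign(truth_de["lfc"]) == sign)]["gene"]
            if n_planted > len(pool):
                raise ValueError(
                    f"set {spec.name}: wants {n_planted} planted genes but "
                    f"{spec.genotype} {spec.direction} has only {len(pool)}")
            members += list(rng.choice(pool.to_numpy(), n_planted,
                                       replace=False))
        members += list(rng.choice(unplanted, spec.size - n_planted,
                                   replace=False))
        collection[spec.name] = set(members)
        truth_rows.append((spec.name, spec.size, spec.fraction,
                           spec.genotype or "", spec.direction, n_planted))
    truth = pd.DataFrame(truth_rows, columns=["set", "size", "fraction",
                                              "genotype", "direction",
                                              "n_planted"])
    if out_path is not None:
        from .gsea import write_gmt
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        write_gmt(collection, out_path)
        write_table(truth, Path(out_path).with_suffix(".truth.tsv"))
    return collection, truth


# ---------------------------------------------------------------------------
# growth curves and traits

def gen_growth_curves(scenario: SimScenario,
                      out_dir: Path | None = None
                      ) -> tuple[GrowthCurveMatrix, pd.DataFrame]:
    """Logistic growth curves (OD600 every 10 min, 0–24 h) with known AUC.

    OD(t) = K / (1 + ((K−N0)/N0) e^(−rt)) + N(0, noise), clipped at zero;
    the truth table holds the closed-form integral per (genotype, temperature).
    """
    for (g, t), (K, r, N0) in scenario.growth_params.items():
        if min(K, r, N0) <= 0:
            raise ValueError(f"non-positive logistic parameters for ({g}, {t})")
    rng = np.random.default_rng(stage_seed(scenario.seed, "growth"))
    time_min = np.arange(0, 24 * 60 + 1, 10)
    t_h = time_min / 60.0
    wells, well_meta, truth_rows = {}, [], []
    for (g, t), (K, r, N0) in sorted(scenario.growth_params.items()):
        A = (K - N0) / N0
        clean = K / (1.0 + A * np.exp(-r * t_h))
        truth_rows.append((g, t, logistic_auc_closed_form(K, r, N0, 24.0)))
        for i in range(1, scenario.n_growth_replicates + 1):
            well = f"{g}_{t}_w{i:02d}"
            noisy = clean + rng.normal(0.0, scenario.growth_noise_sd,
                                       len(t_h))
            wells[well] = np.clip(noisy, 0.0, None)
            well_meta.append((well, g, t, i))
    od = pd.DataFrame(wells)
    well_map = pd.DataFrame(well_meta, columns=["well", "genotype",
                                                "temperature", "replicate"]
                            ).set_index("well")
    curves = GrowthCurveMatrix(time_min=time_min, od=od, well_map=well_map)
    truth = pd.DataFrame(truth_rows, columns=["genotype", "temperature",
                                              "true_auc"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        wide = od.copy()
        wide.insert(0, "time_min", time_min)
        wide.to_csv(out_dir / "plates.csv", index=False, float_format="%.6g")
        write_table(well_map.reset_index(), out_dir / "well_map.tsv")
        write_table(truth, out_dir / "truth_auc.tsv")
    return curves, truth


def gen_traits(scenario: SimScenario,
               out_path: Path | None = None) -> pd.DataFrame:
    """Scalar phenotype draws (Gaussian) per (assay, genotype, temperature)."""
    rng = np.random.default_rng(stage_seed(scenario.seed, "traits"))
    rows = []
    for (assay, g, t), (mean, sd, n) in sorted(scenario.trait_specs.items()):
        for i, v in enumerate(rng.normal(mean, sd, n), start=1):
            rows.append((assay, g, t, i, v))
    traits = pd.DataFrame(rows, columns=["assay", "genotype", "temperature",
                                         "replicate", "value"])
    if out_path is not None:
        write_table(traits, out_path)
    return traits


def scenario_to_jsonable(scenario: SimScenario) -> dict:
    """Provenance record of a scenario: tuple keys flattened to strings."""
    def flatten(value):
        if isinstance(value, dict):
            return {"|".join(map(str, k)) if isinstance(k, tuple) else str(k):
                    flatten(v) for k, v in value.items()}
        if isinstance(value, (list, tuple)):
            return [flatten(v) for v in value]
        if isinstance(value, SetSpec):
            return vars(value)
        if isinstance(value, (np.integer, np.floating)):
            return value.item()
        return value

    return {key: flatten(val) for key, val in vars(scenario).items()}


# ---------------------------------------------------------------------------
# linked scenario

@dataclass
class LinkedBundle:
    scenario: SimScenario
    ensemble: EnsembleBundle
    counts: CountsBundle
    gene_sets: dict
    gene_set_truth: pd.DataFrame
    curves: GrowthCurveMatrix
    growth_truth: pd.DataFrame
    traits: pd.DataFrame
    link_truth: dict  # intercept, slope, per-genotype (distance, n_deg)


def gen_linked_scenario(seed: int, slope: float = 8.0, intercept: float = 50.0,
                        r2_true: float = 0.9,
                        out_dir: Path | None = None) -> LinkedBundle:
    """Full synthetic bundle with a planted structural→transcriptomic link.

    Per mutant genotype, the planted minimum distance d to the nontemplate
    DNA strand and the planted temperature-response DEG count n satisfy
    n = intercept + slope·d + ε, with ε scaled so the truth-level R² equals
    ``r2_true`` (slope 0 gives the null calibration scenario). Mutants at the
    same residue share d, as they must structurally. ΔΔG means are drawn
    independently of the DEG counts, planting the stability↔DEG
    non-correlation. Counts driven non-positive by noise are resampled.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    scenario = default_scenario(seed)
    rng = np.random.default_rng(stage_seed(seed, "link"))
    mutants = scenario.mutants
    residues = {g: parse_mutation(g).residue_seq for g in mutants}
    unique_res = sorted(set(residues.values()))
    d_res = {res: d for res, d in
             zip(unique_res, np.linspace(10.0, 35.0, len(unique_res)))}
    d = np.array([d_res[residues[g]] for g in mutants])

    if slope != 0.0 and not 0 < r2_true < 1:
        raise ValueError("r2_true must be in (0, 1)")
    signal_sd = abs(slope) * np.std(d)
    noise_sd = (signal_sd * np.sqrt((1 - r2_true) / r2_true)
                if slope != 0.0 else 25.0)
    # floor keeps every genotype's planted up/down pools large enough to
    # feed the enriched gene-set specs (largest request: 30 up, 20 down);
    # infeasible draws have their noise term resampled element-wise
    n_deg = intercept + slope * d + rng.normal(0.0, noise_sd, len(d))
    for _ in range(1000):
        low = n_deg < 55
        if not low.any():
            break
        n_deg[low] = (intercept + slope * d[low]
                      + rng.normal(0.0, noise_sd, int(low.sum())))
    else:
        raise ValueError("could not draw feasible DEG counts; raise intercept")
    n_deg = np.round(n_deg).astype(int)

    planted = dict(scenario.planted_degs)
    for g, n in zip(mutants, n_deg):
        n_up = int(round(0.6 * n))
        planted[g] = (n_up, int(n) - n_up, 2.0)
    dist = dict(scenario.planted_min_dist)
    for g in mutants:
        dist[(g, "dna_nontemplate")] = float(d_res[residues[g]])
    scenario = SimScenario(
        **{**vars(default_scenario(seed)), "planted_degs": planted,
           "planted_min_dist": dist})

    ensemble = gen_structure_ensemble(
        scenario, out_dir / "structures" if out_dir else None)
    counts = gen_counts(scenario, out_dir / "counts" if out_dir else None)
    sets, set_truth = gen_gene_sets(
        scenario, counts.truth_de,
        out_dir / "gene_sets.gmt" if out_dir else None)
    curves, growth_truth = gen_growth_curves(
        scenario, out_dir / "growth" if out_dir else None)
    traits = gen_traits(scenario,
                        out_dir / "traits.tsv" if out_dir else None)
    link_truth = {
        "intercept": float(intercept), "slope": float(slope),
        "r2_true": float(r2_true) if slope != 0 else 0.0,
        "genotypes": list(mutants),
        "distance_nontemplate": [float(v) for v in d],
        "n_deg_planted": [int(v) for v in n_deg],
    }
    bundle = LinkedBundle(scenario=scenario, ensemble=ensemble, counts=counts,
                          gene_sets=sets, gene_set_truth=set_truth,
                          curves=curves, growth_truth=growth_truth,
                          traits=traits, link_truth=link_truth)
    if out_dir is not None:
        with open(Path(out_dir) / "truth_link.json", "w") as fh:
            json.dump(link_truth, fh, indent=1, sort_keys=True)
        with open(Path(out_dir) / "scenario.json", "w") as fh:
            json.dump(scenario_to_jsonable(scenario), fh, indent=1,
                      sort_keys=True)
    return bundle
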