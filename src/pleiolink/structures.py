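"""Structure-level metrics for multi-chain RNA polymerase complexes.

Parses PDB coordinate files, computes per-mutation minimum Euclidean distances
from the mutated residue's Cα to annotated partner chains (β′ subunit, σ
factor, template/nontemplate DNA, nascent RNA), aggregates distances over a
structure ensemble, runs the per-role one-way ANOVA across mutants, and
ingests/classifies per-structure ΔΔG stability tables.

Distances follow the per-residue representative-atom convention: amino acids
contribute their Cα; nucleotides (which have no Cα) contribute a configurable
representative atom, C1′ by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import read_table, write_table

ROLES = ("beta", "beta_prime", "sigma", "dna_template", "dna_nontemplate",
         "rna", "other")

#: Residue names treated as nucleotides (DNA + RNA, standard PDB naming).
NUCLEOTIDE_RESNAMES = frozenset(
    {"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "I"}
)

ATOM_COLUMNS = ["chain_id", "residue_seq", "icode", "residue_name",
                "atom_name", "altloc", "x", "y", "z"]


@dataclass
class StructureModel:
    """Atomic coordinates of one multi-chain complex (model 1 only)."""

    structure_id: str
    atoms: pd.DataFrame  # columns ATOM_COLUMNS

    def __post_init__(self) -> None:
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(xyz).all():
            raise ValueError(
                f"{self.structure_id}: non-finite coordinates present")

    def chain_atoms(self, chain_id: str) -> pd.DataFrame:
        return self.atoms[self.atoms["chain_id"] == chain_id]


@dataclass
class MutationSite:
    """One point mutation in β-chain numbering."""

    genotype: str
    residue_seq: int
    wt_aa: str
    mut_aa: str


@dataclass
class DistanceProfile:
    """Per (genotype, role, structure) minimum distances plus ensemble aggregates."""

    records: pd.DataFrame    # genotype, role, structure_id, min_distance, nearest_partner_residue
    aggregates: pd.DataFrame  # genotype, role, mean, sd, n_structures


@dataclass
class StabilityTable:
    """Per-structure ΔΔG records and per-genotype stability classification."""

    records: pd.DataFrame    # genotype, structure_id, ddG
    aggregates: pd.DataFrame  # genotype, mean, sd, n, stability_class
    negligible_band: float


def _check_pdb_lines(path: Path) -> int:
    """Validate fixed-column coordinate fields; return count of coordinate records."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n += 1
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fragment = line[lo:hi]
                    try:
                        float(fragment)
                    except ValueError:
                        raise ValueError(
                            f"{path}: malformed coordinate field "
                            f"{fragment!r} on line {lineno}"
                        ) from None
            elif line.startswith("ENDMDL"):
                break  # model 1 only
    return n


def read_pdb(path) -> StructureModel:
    """Read a PDB coordinate file into a :class:`StructureModel`.

    All ATOM records and nucleic-acid HETATM records of model 1 are kept;
    alternate locations are retained (selection happens at distance time).
    Raises ``ValueError`` naming the offending line for malformed coordinate
    fields and for files without coordinate records.
    """
    import biotite.structure.io.pdb as biotite_pdb

    path = Path(path)
    if _check_pdb_lines(path) == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    pdb_file = biotite_pdb.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1, altloc="all")
    keep = ~arr.hetero | np.isin(arr.res_name, list(NUCLEOTIDE_RESNAMES))
    arr = arr[keep]
    atoms = pd.DataFrame({
        "chain_id": arr.chain_id,
        "residue_seq": arr.res_id.astype(int),
        "icode": [c.strip() for c in arr.ins_code],
        "residue_name": arr.res_name,
        "atom_name": arr.atom_name,
        "altloc": [c.strip() for c in arr.altloc_id],
        "x": arr.coord[:, 0].astype(float),
        "y": arr.coord[:, 1].astype(float),
        "z": arr.coord[:, 2].astype(float),
    })
    return StructureModel(structure_id=path.stem, atoms=atoms)


def load_role_map(path) -> dict[str, dict[str, str]]:
    """Read a chain-role TSV (structure_id, chain_id, role) into a nested map."""
    df = read_table(path, dtype=str)
    role_map: dict[str, dict[str, str]] = {}
    for row in df.itertuples(index=False):
        if row.role not in ROLES:
            raise ValueError(f"unknown role {row.role!r} for "
                             f"{row.structure_id}/{row.chain_id}")
        role_map.setdefault(row.structure_id, {})[row.chain_id] = row.role
    for sid, chains in role_map.items():
        n_beta = sum(1 for r in chains.values() if r == "beta")
        if n_beta != 1:
            raise ValueError(f"{sid}: expected exactly one beta chain, got {n_beta}")
    return role_map


def load_mutations(path) -> list[MutationSite]:
    df = read_table(path, dtype={"residue_seq": int})
    return [MutationSite(r.genotype, int(r.residue_seq), r.wt_aa, r.mut_aa)
            for r in df.itertuples(index=False)]


class RoleMissing(Exception):
    """A partner role is absent from a structure (caller decides skip vs fail)."""


def _select_altloc(atoms: pd.DataFrame) -> pd.DataFrame:
    """Keep altloc 'A' or blank; deterministic and matches common practice."""
    return atoms[atoms["altloc"].isin(["", "A"])]


def representative_points(structure: StructureModel, role: str,
                          role_map: dict[str, dict[str, str]],
                          na_rep_atom: str = "C1'") -> pd.DataFrame:
    """One representative point per residue of every chain playing *role*.

    Amino acids contribute Cα; nucleotides contribute ``na_rep_atom``
    (default C1′, may be ``"P"`` or ``"heavy"`` for all heavy atoms).
    Returns a DataFrame (chain_id, residue_seq, icode, x, y, z) sorted for
    deterministic downstream tie-breaking; raises :class:`RoleMissing` if no
    chain carries the role.
    """
    chains = [c for c, r in role_map.get(structure.structure_id, {}).items()
              if r == role]
    if not chains:
        raise RoleMissing(f"{structure.structure_id}: no chain with role {role!r}")
    atoms = _select_altloc(structure.atoms)
    atoms = atoms[atoms["chain_id"].isin(chains)]
    is_nuc = atoms["residue_name"].isin(NUCLEOTIDE_RESNAMES)
    if na_rep_atom == "heavy":
        nuc = atoms[is_nuc & ~atoms["atom_name"].str.startswith("H")]
    else:
        nuc = atoms[is_nuc & (atoms["atom_name"] == na_rep_atom)]
    prot = atoms[~is_nuc & (atoms["atom_name"] == "CA")]
    pts = pd.concat([prot, nuc])
    pts = pts.sort_values(["chain_id", "residue_seq", "icode", "atom_name"],
                          kind="mergesort")
    return pts[["chain_id", "residue_seq", "icode", "x", "y", "z"]]


def site_calpha(structure: StructureModel, site: MutationSite,
                role_map: dict[str, dict[str, str]]) -> np.ndarray:
    """Cα coordinate of the mutated residue on the β chain."""
    beta_chain = next(c for c, r in role_map[structure.structure_id].items()
                      if r == "beta")
    atoms = _select_altloc(structure.atoms)
    hit = atoms[(atoms["chain_id"] == beta_chain)
                & (atoms["residue_seq"] == site.residue_seq)
                & (atoms["atom_name"] == "CA")]
    if hit.empty:
        raise ValueError(
            f"{structure.structure_id}: residue {site.residue_seq} "
            f"({site.genotype}) has no Cα on beta chain {beta_chain!r}")
    return hit[["x", "y", "z"]].to_numpy(dtype=float)[0]


def min_distance(structure: StructureModel,
                 role_map: dict[str, dict[str, str]],
                 site: MutationSite, role: str,
                 na_rep_atom: str = "C1'") -> tuple[float, str]:
    """Shortest Euclidean distance (Å) from the site's Cα to the partner role.

    Minimum over all per-residue representative points of every chain with the
    given role; ties broken by (chain_id, residue_seq) ascending. Returns the
    distance and the nearest partner residue identifier ``chain:resseq``.
    """
    ca = site_calpha(structure, site, role_map)
    pts = representative_points(structure, role, role_map, na_rep_atom)
    if pts.empty:
        raise RoleMissing(
            f"{structure.structure_id}: role {role!r} has no representative atoms")
    xyz = pts[["x", "y", "z"]].to_numpy(dtype=float)
    d = np.sqrt(((xyz - ca) ** 2).sum(axis=1))
    best = int(np.argmin(d))  # pts pre-sorted: first minimum is the tie-break winner
    row = pts.iloc[best]
    label = f"{row['chain_id']}:{int(row['residue_seq'])}{row['icode']}"
    return float(d[best]), label


def distance_profile(structures: list[StructureModel],
                     role_map: dict[str, dict[str, str]],
                     sites: list[MutationSite],
                     roles: list[str],
                     na_rep_atom: str = "C1'") -> DistanceProfile:
    """Minimum distances for every (site, role, structure), with ensemble aggregates.

    Structures lacking a role are skipped for that role (reducing the
    aggregate n, never imputing); a role absent from all structures is an
    error. Output is independent of the input order of structures.
    """
    if not structures:
        raise ValueError("need at least one structure")
    rows = []
    seen_roles: set[str] = set()
    for structure in sorted(structures, key=lambda s: s.structure_id):
        for site in sites:
            for role in roles:
                try:
                    dist, nearest = min_distance(structure, role_map, site,
                                                 role, na_rep_atom)
                except RoleMissing:
                    continue
                seen_roles.add(role)
                rows.append((site.genotype, role, structure.structure_id,
                             dist, nearest))
    missing_everywhere = [r for r in roles if r not in seen_roles]
    if missing_everywhere:
        raise ValueError(f"roles absent from every structure: {missing_everywhere}")
    records = pd.DataFrame(
        rows, columns=["genotype", "role", "structure_id", "min_distance",
                       "nearest_partner_residue"])
    agg = (records.groupby(["genotype", "role"], sort=True)["min_distance"]
           .agg(mean="mean", sd="std", n_structures="count").reset_index())
    agg.loc[agg["n_structures"] < 2, "sd"] = np.nan
    return DistanceProfile(records=records, aggregates=agg)


def anova_by_mutant(profile: DistanceProfile, role: str,
                    exclude_genotypes: tuple[str, ...] = ()
                    ) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA of per-structure distances across mutants.

    Each structure's minimum distance is one observation. Returns
    (F, df_between, df_within, p); degenerate data (zero within-group
    variance everywhere) yields (inf, df1, df2, 0.0) flagged by the caller.
    """
    sub = profile.records[profile.records["role"] == role]
    sub = sub[~sub["genotype"].isin(exclude_genotypes)]
    groups = [g["min_distance"].to_numpy() for _, g in sub.groupby("genotype")]
    if len(groups) < 2:
        raise ValueError(f"role {role!r}: need >=2 genotypes for ANOVA")
    if any(len(g) < 2 for g in groups):
        raise ValueError(
            f"role {role!r}: a genotype has a single observation "
            "(within-group variance undefined)")
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    if all(np.ptp(g) == 0 for g in groups):
        between = np.ptp([g[0] for g in groups])
        return (np.inf if between > 0 else np.nan, df_between, df_within,
                0.0 if between > 0 else np.nan)
    F, p = stats.f_oneway(*groups)
    return float(F), df_between, df_within, float(p)


def load_and_classify_ddg(path, negligible_band: float = 0.5) -> StabilityTable:
    """Ingest a per-structure ΔΔG table (kcal/mol) and classify genotypes.

    Positive ΔΔG destabilizes. Mean ΔΔG above ``+negligible_band`` is
    destabilizing, below ``−negligible_band`` stabilizing, else negligible.
    """
    df = read_table(path)
    for col in ("genotype", "structure_id", "ddG"):
        if col not in df.columns:
            raise ValueError(f"ΔΔG table missing column {col!r}")
    bad = df[pd.to_numeric(df["ddG"], errors="coerce").isna()]
    if not bad.empty:
        raise ValueError(f"non-numeric ddG at rows {list(bad.index)}")
    df["ddG"] = df["ddG"].astype(float)
    agg = (df.groupby("genotype", sort=True)["ddG"]
           .agg(mean="mean", sd="std", n="count").reset_index())

    def classify(mean: float) -> str:
        if mean > negligible_band:
            return "destabilizing"
        if mean < -negligible_band:
            return "stabilizing"
        return "negligible"

    agg["stability_class"] = agg["mean"].map(classify)
    return StabilityTable(records=df, aggregates=agg,
                          negligible_band=negligible_band)


def write_profile(profile: DistanceProfile, out_dir,
                  metadata: dict | None = None) -> None:
    out_dir = Path(out_dir)
    write_table(profile.records, out_dir / "distance_records.tsv", metadata)
    write_table(profile.aggregates, out_dir / "distance_aggregates.tsv", metadata)
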