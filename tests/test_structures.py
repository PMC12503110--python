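"""Structure parsing, minimum-distance computation, ANOVA, ΔΔG classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleiolink.structures import (MutationSite, RoleMissing, anova_by_mutant,
                                  distance_profile, load_and_classify_ddg,
                                  min_distance, read_pdb,
                                  representative_points)
from pleiolink.simulate import default_scenario, gen_structure_ensemble

from conftest import make_structure, random_structure


# ---------------------------------------------------------------------------
# parsing

PDB_ONE_ATOM = (
    "ATOM      1  CA  VAL B 146       1.000   2.000   3.000  1.00  0.00"
    "           C  \n"
)


def test_read_pdb_exact_coordinates(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(PDB_ONE_ATOM)
    model = read_pdb(path)
    assert len(model.atoms) == 1
    row = model.atoms.iloc[0]
    assert (row["x"], row["y"], row["z"]) == (1.0, 2.0, 3.0)
    assert row["chain_id"] == "B" and row["residue_seq"] == 146


def test_read_pdb_malformed_coordinate_names_line(tmp_path):
    bad = PDB_ONE_ATOM + PDB_ONE_ATOM.replace("   2.000", "  x2.000")
    path = tmp_path / "bad.pdb"
    path.write_text(bad)
    with pytest.raises(ValueError, match="line 2"):
        read_pdb(path)


def test_read_pdb_empty_file_rejected(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("HEADER    NOTHING\n")
    with pytest.raises(ValueError, match="no ATOM"):
        read_pdb(path)


def test_read_pdb_retains_both_altlocs(tmp_path):
    lines = (
        "ATOM      1  CA AVAL B 146       1.000   2.000   3.000  0.50  0.00"
        "           C  \n"
        "ATOM      2  CA BVAL B 146       1.100   2.000   3.000  0.50  0.00"
        "           C  \n"
    )
    path = tmp_path / "alt.pdb"
    path.write_text(lines)
    model = read_pdb(path)
    assert sorted(model.atoms["altloc"]) == ["A", "B"]


def test_generator_roundtrip_atom_count(tmp_path):
    scenario = default_scenario(seed=7)
    bundle = gen_structure_ensemble(scenario, tmp_path)
    for model in bundle.structures:
        reread = read_pdb(tmp_path / f"{model.structure_id}.pdb")
        assert len(reread.atoms) == len(model.atoms)


# ---------------------------------------------------------------------------
# representative points and distances

def test_representative_points_protein_and_dna():
    pts = [("B", 1, "VAL", "CA", (0, 0, 0))]
    pts += [("C", i, "ALA", "CA", (i, 0, 0)) for i in range(1, 11)]
    pts += [("D", i, "DA", "C1'", (0, i, 0)) for i in range(1, 9)]
    pts += [("D", i, "DA", "P", (0, i, 1)) for i in range(1, 9)]
    model = make_structure(pts)
    role_map = {"toy": {"B": "beta", "C": "sigma", "D": "dna_template"}}
    assert len(representative_points(model, "sigma", role_map)) == 10
    assert len(representative_points(model, "dna_template", role_map)) == 8
    p_pts = representative_points(model, "dna_template", role_map,
                                  na_rep_atom="P")
    assert len(p_pts) == 8 and (p_pts["z"] == 1).all()
    with pytest.raises(RoleMissing):
        representative_points(model, "rna", role_map)


def test_min_distance_three_four_five(toy_structure, toy_role_map, toy_site):
    dist, nearest = min_distance(toy_structure, toy_role_map, toy_site, "sigma")
    assert dist == 5.0
    assert nearest == "C:1"


def test_min_distance_site_absent_errors(toy_structure, toy_role_map):
    site = MutationSite("Q999X", 999, "Q", "X")
    with pytest.raises(ValueError, match="999"):
        min_distance(toy_structure, toy_role_map, site, "sigma")


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_min_distance_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    model, role_map = random_structure(rng, n_partner_atoms=200)
    site = MutationSite("V10F", 10, "V", "F")
    ca = model.atoms.query("chain_id == 'B'")[["x", "y", "z"]].to_numpy()[0]
    for role, chain in [("sigma", "C"), ("dna_nontemplate", "D")]:
        dist, _ = min_distance(model, role_map, site, role)
        partner = model.atoms.query(f"chain_id == '{chain}'")
        brute = min(np.linalg.norm(ca - p) for p in
                    partner[["x", "y", "z"]].to_numpy())
        assert dist == pytest.approx(brute, abs=1e-9)


def test_min_distance_rigid_transform_invariant():
    rng = np.random.default_rng(3)
    model, role_map = random_structure(rng)
    site = MutationSite("V10F", 10, "V", "F")
    d0, _ = min_distance(model, role_map, site, "sigma")
    # random rotation (QR of a Gaussian matrix) + translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    shift = rng.normal(0, 50, 3)
    moved = model.atoms.copy()
    moved[["x", "y", "z"]] = moved[["x", "y", "z"]].to_numpy() @ q.T + shift
    model2 = make_structure([], "rand")
    model2.atoms = moved
    d1, _ = min_distance(model2, role_map, site, "sigma")
    assert d1 == pytest.approx(d0, abs=1e-6)


def test_removing_nearest_residue_never_decreases_minimum():
    rng = np.random.default_rng(4)
    model, role_map = random_structure(rng)
    site = MutationSite("V10F", 10, "V", "F")
    d0, nearest = min_distance(model, role_map, site, "sigma")
    chain, resseq = nearest.split(":")
    keep = ~((model.atoms["chain_id"] == chain)
             & (model.atoms["residue_seq"] == int(resseq)))
    model2 = make_structure([], "rand")
    model2.atoms = model.atoms[keep]
    d1, _ = min_distance(model2, role_map, site, "sigma")
    assert d1 >= d0


# ---------------------------------------------------------------------------
# profile aggregation

def test_profile_order_invariance_and_single_structure_sd():
    scenario = default_scenario(seed=5)
    bundle = gen_structure_ensemble(scenario)
    roles = list(scenario.roles)
    prof_fwd = distance_profile(bundle.structures, bundle.role_map,
                                bundle.sites, roles)
    prof_rev = distance_profile(bundle.structures[::-1], bundle.role_map,
                                bundle.sites, roles)
    pd.testing.assert_frame_equal(prof_fwd.records, prof_rev.records)
    one = distance_profile(bundle.structures[:1], bundle.role_map,
                           bundle.sites, roles)
    assert one.aggregates["sd"].isna().all()
    assert (one.aggregates["n_structures"] == 1).all()


def test_profile_missing_role_everywhere_errors():
    scenario = default_scenario(seed=5)
    bundle = gen_structure_ensemble(scenario)
    with pytest.raises(ValueError, match="other"):
        distance_profile(bundle.structures, bundle.role_map, bundle.sites,
                         ["sigma", "other"])


# ---------------------------------------------------------------------------
# ANOVA

def _anova_oracle(groups):
    """Textbook one-way ANOVA from sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = len(groups) - 1, len(allv) - len(groups)
    F = (ss_between / df1) / (ss_within / df2)
    return F, df1, df2, stats.f.sf(F, df1, df2)


def _profile_from_values(values_by_genotype, role="sigma"):
    rows = [(g, role, f"s{i}", v, "C:1")
            for g, vals in values_by_genotype.items()
            for i, v in enumerate(vals)]
    records = pd.DataFrame(rows, columns=["genotype", "role", "structure_id",
                                          "min_distance",
                                          "nearest_partner_residue"])
    from pleiolink.structures import DistanceProfile
    return DistanceProfile(records=records, aggregates=pd.DataFrame())


def test_anova_matches_textbook_oracle():
    rng = np.random.default_rng(6)
    values = {f"g{i}": rng.normal(20 + i, 2, 7) for i in range(5)}
    prof = _profile_from_values(values)
    F, df1, df2, p = anova_by_mutant(prof, "sigma")
    Fo, d1o, d2o, po = _anova_oracle(list(values.values()))
    assert F == pytest.approx(Fo, abs=1e-10)
    assert (df1, df2) == (d1o, d2o)
    assert p == pytest.approx(po, abs=1e-10)


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(7)
    a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
    prof = _profile_from_values({"a": a, "b": b})
    F, *_ = anova_by_mutant(prof, "sigma")
    t = stats.ttest_ind(a, b, equal_var=True).statistic
    assert F == pytest.approx(t**2, rel=1e-10)


def test_anova_degenerate_and_error_cases():
    prof = _profile_from_values({"a": np.ones(3), "b": np.ones(3)})
    F, df1, df2, p = anova_by_mutant(prof, "sigma")
    assert np.isnan(F) and np.isnan(p)
    prof2 = _profile_from_values({"a": np.ones(3), "b": 2 * np.ones(3)})
    F2, *_ , p2 = anova_by_mutant(prof2, "sigma")
    assert np.isinf(F2) and p2 == 0.0
    prof3 = _profile_from_values({"a": np.ones(1), "b": np.ones(3)})
    with pytest.raises(ValueError, match="single observation"):
        anova_by_mutant(prof3, "sigma")


# ---------------------------------------------------------------------------
# ΔΔG

def _ddg_tsv(tmp_path, rows):
    path = tmp_path / "ddg.tsv"
    pd.DataFrame(rows, columns=["genotype", "structure_id", "ddG"]).to_csv(
        path, sep="\t", index=False)
    return path


def test_ddg_sign_classification(tmp_path):
    rows = [("a", "s1", -1.0), ("b", "s1", 0.0), ("c", "s1", 1.0),
            ("a", "s2", -1.0), ("b", "s2", 0.0), ("c", "s2", 1.0)]
    table = load_and_classify_ddg(_ddg_tsv(tmp_path, rows),
                                  negligible_band=0.3)
    classes = dict(zip(table.aggregates["genotype"],
                       table.aggregates["stability_class"]))
    assert classes == {"a": "stabilizing", "b": "negligible",
                       "c": "destabilizing"}


def test_ddg_positive_mean_is_destabilizing(tmp_path):
    table = load_and_classify_ddg(_ddg_tsv(tmp_path, [("a", "s1", 1.2)]),
                                  negligible_band=0.3)
    assert table.aggregates["stability_class"].iloc[0] == "destabilizing"


def test_ddg_non_numeric_cell_errors(tmp_path):
    path = tmp_path / "ddg.tsv"
    path.write_text("genotype\tstructure_id\tddG\na\ts1\toops\n")
    with pytest.raises(ValueError, match="non-numeric"):
        load_and_classify_ddg(path)
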