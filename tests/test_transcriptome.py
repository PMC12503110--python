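"""Filtering, normalization, NB Wald contrasts, DEG sets, Bray–Curtis,
PERMANOVA, and the BH procedure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleiolink._util import bh_adjust
from pleiolink.simulate import gen_counts
from pleiolink.transcriptome import (Contrast, bray_curtis, call_degs,
                                     exclusive_intersections, filter_genes,
                                     nb_wald_contrast, normalize, permanova,
                                     size_factors, updown_paired_t)


# ---------------------------------------------------------------------------
# filtering

def test_filter_genes_thresholds(counts_bundle):
    counts = counts_bundle.counts
    kept = filter_genes(counts, 10)
    oracle = [g for g in counts.index if counts.loc[g].sum() >= 10]
    assert list(kept.index) == oracle
    assert filter_genes(counts, 0).equals(counts)
    toy = pd.DataFrame({"s1": [4, 10], "s2": [5, 10]},
                       index=["below", "above"])
    assert list(filter_genes(toy, 10).index) == ["above"]  # rowsum 9 dropped


def test_filter_empty_result_errors():
    toy = pd.DataFrame({"s1": [1], "s2": [1]}, index=["g"])
    with pytest.raises(ValueError, match="filter"):
        filter_genes(toy, 100)


# ---------------------------------------------------------------------------
# size factors

def test_size_factor_symmetry_and_scaling():
    rng = np.random.default_rng(0)
    base = rng.poisson(50, 200)
    counts = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
    sf = size_factors(counts)
    assert sf["a"] == pytest.approx(sf["b"])
    assert sf["c"] / sf["a"] == pytest.approx(2.0)


def test_size_factors_recover_planted(counts_bundle):
    from scipy.stats import spearmanr
    sf = size_factors(filter_genes(counts_bundle.counts, 10))
    rho = spearmanr(sf, counts_bundle.size_factors_true[sf.index]).statistic
    assert rho >= 0.95


def test_size_factors_require_all_positive_gene():
    counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="pseudo-reference"):
        size_factors(counts)


# ---------------------------------------------------------------------------
# NB Wald

def test_swapping_groups_negates_lfc_keeps_p(counts_bundle):
    counts = filter_genes(counts_bundle.counts, 10)
    design = counts_bundle.design
    sf = size_factors(counts)
    fwd = nb_wald_contrast(counts, design, Contrast(
        "genotype_within_temp", "V146F", 42, "WT"), sf)
    rev = nb_wald_contrast(counts, design, Contrast(
        "genotype_within_temp", "WT", 42, "V146F"), sf)
    np.testing.assert_allclose(fwd.table["log2FC"], -rev.table["log2FC"],
                               atol=1e-12)
    np.testing.assert_allclose(fwd.table["pvalue"], rev.table["pvalue"],
                               atol=1e-12)


def test_planted_lfc_recovered(counts_bundle, scenario):
    counts = filter_genes(counts_bundle.counts, 10)
    res = nb_wald_contrast(counts, counts_bundle.design,
                           Contrast("temp_within_genotype", "S522F"))
    truth = counts_bundle.truth_de.query("genotype == 'S522F'")
    up = truth[truth["lfc"] > 0]["gene"]
    est = res.table.loc[res.table.index.intersection(up), "log2FC"]
    assert abs(est.median() - 2.0) < 0.3


def test_group_below_two_samples_rejected(counts_bundle):
    design = counts_bundle.design
    drop = design.query("genotype == 'WT' and temperature == 42").index[1:]
    small = design.drop(drop)
    counts = counts_bundle.counts[small.index]
    with pytest.raises(ValueError):
        nb_wald_contrast(filter_genes(counts, 10), small,
                         Contrast("temp_within_genotype", "WT"))


def test_padj_dominates_p_and_is_monotone(counts_bundle):
    counts = filter_genes(counts_bundle.counts, 10)
    res = nb_wald_contrast(counts, counts_bundle.design,
                           Contrast("temp_within_genotype", "WT"))
    t = res.table.sort_values("pvalue")
    assert (t["padj"] >= t["pvalue"] - 1e-15).all()
    assert (np.diff(t["padj"]) >= -1e-15).all()


def test_deg_calls_invariant_to_orderings_and_one_sample_scaling(counts_bundle):
    counts = filter_genes(counts_bundle.counts, 10)
    design = counts_bundle.design
    contrast = Contrast("temp_within_genotype", "Q513R")
    ref = call_degs(nb_wald_contrast(counts, design, contrast))
    rng = np.random.default_rng(1)
    shuffled = counts.iloc[rng.permutation(len(counts))]
    shuffled = shuffled[list(rng.permutation(counts.columns))]
    assert call_degs(nb_wald_contrast(shuffled, design, contrast)).up == ref.up
    doubled = counts.copy()
    doubled[counts.columns[0]] = 2 * doubled[counts.columns[0]]
    got = call_degs(nb_wald_contrast(doubled, design, contrast))
    assert got.up == ref.up and got.down == ref.down


# ---------------------------------------------------------------------------
# DEG thresholding

def test_call_deg_rule_boundaries():
    contrast = Contrast("temp_within_genotype", "WT")
    table = pd.DataFrame({
        "log2FC": [1.5, 0.9, -2.0, 1.5, 1.0],
        "padj": [0.01, 1e-6, 0.04, 0.2, 0.01],
    }, index=["up_hit", "small_fc", "down_hit", "weak_p", "at_thresh"])
    from pleiolink.transcriptome import DEResult
    summary = call_degs(DEResult(contrast, table))
    assert summary.up == {"up_hit"}
    assert summary.down == {"down_hit"}
    assert summary.n_total == 2  # |LFC| strictly > 1; padj strictly < 0.05


# ---------------------------------------------------------------------------
# intersections

def test_exclusive_intersections_small_cases():
    excl, _ = exclusive_intersections(
        {"A": {1, 2, 3}, "B": {4, 5, 6, 7}}, min_size=0)
    as_dict = dict(zip(excl["combination"], excl["count"]))
    assert as_dict == {"A": 3, "B": 4}
    excl2, pair2 = exclusive_intersections(
        {"A": set(range(7)), "B": set(range(7))}, min_size=0)
    assert dict(zip(excl2["combination"], excl2["count"])) == {"A+B": 7}
    assert pair2["shared"].iloc[0] == 7


def test_exclusive_intersections_match_bruteforce_enumeration():
    rng = np.random.default_rng(2)
    names = list("ABCDEF")
    sets = {n: set(rng.choice(500, rng.integers(20, 120), replace=False))
            for n in names}
    excl, _ = exclusive_intersections(sets, min_size=1)
    got = dict(zip(excl["combination"], excl["count"]))
    oracle = {}
    for gene in range(500):
        combo = "+".join(sorted(n for n in names if gene in sets[n]))
        if combo:
            oracle[combo] = oracle.get(combo, 0) + 1
    assert got == oracle


def test_min_size_filter_drops_small_rows():
    excl, _ = exclusive_intersections(
        {"A": {1, 2, 3}, "B": set(range(1, 10))}, min_size=5)
    # B-exclusive has 6 genes; A-exclusive (0) and A+B (3) fall below 5
    assert list(excl["combination"]) == ["B"]
    assert excl["count"].iloc[0] == 6


# ---------------------------------------------------------------------------
# up/down paired t

def test_updown_t_df_and_oracle():
    rng = np.random.default_rng(3)
    ups = rng.integers(50, 300, 7)
    downs = rng.integers(30, 200, 7)
    summaries = {f"g{i}": (int(u), int(d))
                 for i, (u, d) in enumerate(zip(ups, downs))}
    t, df, p = updown_paired_t(summaries)
    assert df == 6
    diffs = ups - downs
    t_oracle = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(7))
    from scipy import stats
    assert t == pytest.approx(t_oracle, abs=1e-10)
    assert p == pytest.approx(2 * stats.t.sf(abs(t_oracle), 6), abs=1e-10)


def test_updown_t_degenerate_and_minimum_size():
    t, df, p = updown_paired_t({"a": (5, 5), "b": (7, 7), "c": (9, 9)})
    assert np.isnan(t) and np.isnan(p)
    with pytest.raises(ValueError):
        updown_paired_t({"a": (1, 0), "b": (2, 0)})


# ---------------------------------------------------------------------------
# Bray–Curtis

def test_bray_curtis_identical_and_disjoint():
    x = pd.DataFrame({"a": [1.0, 2.0, 0.0], "b": [1.0, 2.0, 0.0],
                      "c": [0.0, 0.0, 5.0]})
    d = bray_curtis(x)
    assert d.loc["a", "b"] == 0.0
    assert d.loc["a", "c"] == 1.0
    assert np.allclose(d, d.T) and (np.diag(d) == 0).all()


def test_bray_curtis_matches_reference_library():
    from scipy.spatial.distance import braycurtis as scipy_bc
    import skbio
    rng = np.random.default_rng(4)
    x = pd.DataFrame(rng.uniform(0, 10, (40, 8)),
                     columns=[f"s{i}" for i in range(8)])
    d = bray_curtis(x)
    dm = skbio.diversity.beta_diversity(
        "braycurtis", x.T.to_numpy(), ids=list(x.columns))
    np.testing.assert_allclose(d.to_numpy(), dm.data, atol=1e-12)
    assert d.iloc[0, 1] == pytest.approx(
        scipy_bc(x.iloc[:, 0], x.iloc[:, 1]), abs=1e-12)


def test_bray_curtis_two_empty_samples_error():
    x = pd.DataFrame({"a": [0.0], "b": [0.0]})
    with pytest.raises(ValueError, match="all-zero"):
        bray_curtis(x)


# ---------------------------------------------------------------------------
# PERMANOVA

def _noise_design(n_per=3):
    geno = np.repeat(["a", "b", "c", "d"], 2 * n_per)
    temp = np.tile(np.repeat([37, 42], n_per), 4)
    reps = np.tile([f"r{i}" for i in range(1, n_per + 1)], 8)
    exp = np.tile(["e1", "e2", "e1"], 8)
    return pd.DataFrame({"genotype": geno, "temperature": temp,
                         "experiment": exp, "replicate": reps},
                        index=[f"s{i}" for i in range(8 * n_per)])


def test_permanova_r2_decomposition_sums_to_one():
    rng = np.random.default_rng(5)
    design = _noise_design()
    x = pd.DataFrame(rng.uniform(0, 10, (30, len(design))),
                     columns=design.index)
    res = permanova(bray_curtis(x), design, n_perm=99, seed=0)
    assert res.table["r2"].sum() == pytest.approx(1.0, abs=1e-10)
    assert res.table["sum_sq"].sum() == pytest.approx(res.total_ss, abs=1e-10)


def test_permanova_matches_vegan_adonis2_frozen_fixture():
    """SS/R²/F frozen from vegan::adonis2 (by='terms', same Bray–Curtis
    matrix built from uniform draws with this seed)."""
    rng = np.random.default_rng(0)
    design = _noise_design()
    x = pd.DataFrame(rng.uniform(0, 10, (30, len(design))),
                     columns=design.index)
    res = permanova(bray_curtis(x), design, n_perm=99, seed=1)
    table = res.table.set_index("term")
    expected = {  # vegan 2.7-1 adonis2 output for this fixture
        "temperature": (0.045005, 0.038022, 0.778399),
        "genotype": (0.119314, 0.100801, 0.687872),
        "temperature:genotype": (0.142203, 0.120139, 0.819833),
        "experiment": (0.041354, 0.034938, 0.715254),
        "replicate": (0.026331, 0.022246, 0.455421),
    }
    for term, (ss, r2, f) in expected.items():
        assert table.loc[term, "sum_sq"] == pytest.approx(ss, abs=5e-6)
        assert table.loc[term, "r2"] == pytest.approx(r2, abs=5e-6)
        assert table.loc[term, "pseudo_F"] == pytest.approx(f, abs=5e-6)


def test_permanova_detects_planted_genotype_separation(counts_bundle):
    counts = filter_genes(counts_bundle.counts, 10)
    d = bray_curtis(normalize(counts))
    res = permanova(d, counts_bundle.design, n_perm=199, seed=2)
    p_geno = res.table.set_index("term").loc["genotype", "p"]
    assert p_geno <= 0.01


def test_permanova_drops_aliased_term():
    rng = np.random.default_rng(6)
    design = _noise_design()
    design["replicate"] = design["experiment"]  # fully aliased
    x = pd.DataFrame(rng.uniform(0, 10, (20, len(design))),
                     columns=design.index)
    res = permanova(bray_curtis(x), design, n_perm=49, seed=0)
    assert res.dropped_terms == ["replicate"]
    assert "replicate" not in set(res.table["term"])


# ---------------------------------------------------------------------------
# BH procedure

def _bh_oracle(p):
    """Sort, cumulative-min of p*m/rank from the right, clip at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=60))
@settings(max_examples=60, deadline=None)
def test_bh_matches_sort_cummin_clip_oracle(pvals):
    np.testing.assert_allclose(bh_adjust(pvals), _bh_oracle(pvals),
                               atol=1e-12)


def test_null_scenario_padj_rate_below_one_percent(null_scenario):
    bundle = gen_counts(null_scenario)
    counts = filter_genes(bundle.counts, 10)
    res = nb_wald_contrast(counts, bundle.design,
                           Contrast("temp_within_genotype", "WT"))
    assert (res.table["padj"] < 0.05).mean() <= 0.01
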