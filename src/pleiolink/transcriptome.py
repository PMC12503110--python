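"""Transcriptome-level analysis: filtering, normalization, differential
expression, DEG set arithmetic, and multivariate dissimilarity testing.

The differential-expression procedure is an explicit negative-binomial Wald
test per contrast (a mutant's 42 vs 37 °C samples, or mutant vs wild type
within one temperature). It is DESeq2-like — median-of-ratios size factors,
NB error model, BH adjustment — but deliberately simpler and fully explicit:
per-contrast method-of-moments dispersion, no dispersion or fold-change
shrinkage, no independent filtering. With a full factorial design this
per-contrast estimator reads out the same quantity as the releveled
interaction coefficient of a joint genotype×temperature GLM.

PERMANOVA partitions a Bray–Curtis distance matrix by sequential (Type-I)
sums of squares over an ordered term list (McArdle–Anderson projection form),
with free permutation of sample labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5  # on the normalized scale, for fold-change stability

DEFAULT_PERMANOVA_TERMS = ("temperature", "genotype", "temperature:genotype",
                           "experiment", "replicate")


# ---------------------------------------------------------------------------
# design / contrasts

def validate_design(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    """Counts columns and design rows must match exactly; >=2 replicates per cell."""
    if set(counts.columns) != set(design.index) or counts.isna().any().any():
        missing = set(counts.columns) ^ set(design.index)
        raise ValueError(f"counts/design sample mismatch: {sorted(missing)}")
    cell_sizes = design.groupby(["genotype", "temperature"]).size()
    if (cell_sizes < 2).any():
        bad = cell_sizes[cell_sizes < 2].index.tolist()
        raise ValueError(f"<2 replicates for design cells: {bad}")


@dataclass(frozen=True)
class Contrast:
    """Two-group contrast descriptor.

    ``temp_within_genotype``: 42 vs 37 °C inside one genotype (the
    genotype-specific temperature response). ``genotype_within_temp``: mutant
    vs wild type inside one temperature. Fold changes are log2(group_b/group_a)
    with group_a the reference (37 °C, or the wild type).
    """

    kind: str  # temp_within_genotype | genotype_within_temp
    genotype: str
    temperature: int | None = None  # genotype_within_temp only
    reference_genotype: str | None = None

    def label(self) -> str:
        if self.kind == "temp_within_genotype":
            return f"{self.genotype}_42v37"
        return f"{self.genotype}_vs_{self.reference_genotype}_at_{self.temperature}"

    def groups(self, design: pd.DataFrame) -> tuple[list[str], list[str]]:
        if self.kind == "temp_within_genotype":
            sub = design[design["genotype"] == self.genotype]
            a = sub[sub["temperature"] == 37].index.tolist()
            b = sub[sub["temperature"] == 42].index.tolist()
        elif self.kind == "genotype_within_temp":
            sub = design[design["temperature"] == self.temperature]
            a = sub[sub["genotype"] == self.reference_genotype].index.tolist()
            b = sub[sub["genotype"] == self.genotype].index.tolist()
        else:
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        return a, b


@dataclass
class DEResult:
    contrast: Contrast
    table: pd.DataFrame  # index gene; baseMean, log2FC, lfcSE, stat, pvalue, padj
    n_excluded_allzero: int = 0


@dataclass
class DEGSummary:
    contrast_label: str
    up: frozenset
    down: frozenset

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down


# ---------------------------------------------------------------------------
# filtering / normalization

def filter_genes(counts: pd.DataFrame, min_rowsum: int = 10) -> pd.DataFrame:
    """Keep genes whose total count across all samples is >= ``min_rowsum``."""
    if min_rowsum < 0:
        raise ValueError("min_rowsum must be >= 0")
    kept = counts[counts.sum(axis=1) >= min_rowsum]
    if kept.empty:
        raise ValueError("no genes pass the row-sum filter")
    return kept


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with positive counts in every sample; each
    sample's factor is the median over reference genes of count / geometric
    mean. Factors are reported unnormalized.
    """
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no gene has positive counts in every sample; consider a "
            "pseudo-reference")
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geomean, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def normalize(counts: pd.DataFrame,
              factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts.div(factors, axis=1)


# ---------------------------------------------------------------------------
# NB Wald contrast

def nb_wald_contrast(counts: pd.DataFrame, design: pd.DataFrame,
                     contrast: Contrast,
                     factors: pd.Series | None = None) -> DEResult:
    """Per-gene negative-binomial Wald test between two sample groups.

    Group means are computed on size-factor-normalized counts with a ½
    pseudocount for the fold change; the per-gene dispersion α is a
    method-of-moments estimate pooled across the two groups, with an
    adaptive floor at the across-gene median (per-gene MoM is too noisy at
    2-4 replicates to stand alone); the standard error of log2FC follows
    from the delta method on the NB group means (variance μ + αμ² on the
    normalized scale); the Wald statistic is referred to a standard normal,
    and BH adjustment runs over all tested genes of the contrast.
    """
    validate_design(counts, design)
    group_a, group_b = contrast.groups(design)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(
            f"contrast {contrast.label()}: both groups need >=2 samples "
            f"(got {len(group_a)}, {len(group_b)})")
    if factors is None:
        factors = size_factors(counts)

    sub = counts[group_a + group_b]
    allzero = (sub.sum(axis=1) == 0)
    sub = sub[~allzero]
    norm = sub.div(factors[sub.columns], axis=1)
    xa = norm[group_a].to_numpy()
    xb = norm[group_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)

    # method-of-moments dispersion pooled over the two groups; the NB
    # mean-variance relation mu + alpha*mu^2 is evaluated on the normalized
    # scale, so the statistic is a function of normalized counts only and
    # rescaling any one sample is absorbed entirely by its size factor
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    alpha_a = (va - mu_a) / np.where(mu_a > 0, mu_a**2, 1.0)
    alpha_b = (vb - mu_b) / np.where(mu_b > 0, mu_b**2, 1.0)
    alpha = ((na - 1) * alpha_a + (nb - 1) * alpha_b) / (na + nb - 2)
    # adaptive floor at the across-gene median: per-gene MoM dispersion is
    # extremely noisy at 2-4 replicates, and letting it collapse toward zero
    # understates the SE and inflates the Wald statistic without bound
    alpha = np.maximum(alpha, max(float(np.median(alpha)), DISPERSION_FLOOR))

    mu_a_p = mu_a + PSEUDOCOUNT
    mu_b_p = mu_b + PSEUDOCOUNT
    log2fc = np.log2(mu_b_p / mu_a_p)
    var_mean_a = (mu_a_p + alpha * mu_a_p**2) / na
    var_mean_b = (mu_b_p + alpha * mu_b_p**2) / nb
    se = np.sqrt(var_mean_a / mu_a_p**2 + var_mean_b / mu_b_p**2) / np.log(2)
    stat = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    table = pd.DataFrame({
        "baseMean": norm.mean(axis=1).to_numpy(),
        "log2FC": log2fc,
        "lfcSE": se,
        "stat": stat,
        "pvalue": pvalue,
        "padj": bh_adjust(pvalue),
        "dispersion": alpha,
    }, index=sub.index)
    return DEResult(contrast=contrast, table=table,
                    n_excluded_allzero=int(allzero.sum()))


def call_degs(de_result: DEResult, lfc_thresh: float = 1.0,
              alpha: float = 0.05) -> DEGSummary:
    """Threshold a contrast into up/down DEG sets: |log2FC| > thresh and padj < alpha."""
    t = de_result.table
    if "padj" not in t.columns:
        raise ValueError("DE table lacks padj")
    sig = t["padj"] < alpha
    up = frozenset(t.index[sig & (t["log2FC"] > lfc_thresh)])
    down = frozenset(t.index[sig & (t["log2FC"] < -lfc_thresh)])
    return DEGSummary(contrast_label=de_result.contrast.label(), up=up, down=down)


# ---------------------------------------------------------------------------
# set arithmetic / paired test

def exclusive_intersections(deg_sets: dict[str, set], min_size: int = 5
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """UpSet-style exclusive intersection counts plus pairwise shared counts.

    The exclusive table counts, for every nonempty combination of set names,
    the genes present in all named sets and in none of the others; rows below
    ``min_size`` are dropped. The pairwise table is plain (non-exclusive)
    overlap sizes.
    """
    if not deg_sets:
        raise ValueError("need at least one set")
    names = sorted(deg_sets)
    universe = sorted(set().union(*deg_sets.values()))
    membership = {g: frozenset(n for n in names if g in deg_sets[n])
                  for g in universe}
    combo_counts: dict[frozenset, int] = {}
    for combo in membership.values():
        combo_counts[combo] = combo_counts.get(combo, 0) + 1
    rows = [("+".join(sorted(combo)), len(combo), count)
            for combo, count in combo_counts.items() if count >= min_size]
    exclusive = (pd.DataFrame(rows, columns=["combination", "degree", "count"])
                 .sort_values(["count", "combination"],
                              ascending=[False, True], kind="mergesort")
                 .reset_index(drop=True))
    pair_rows = [(a, b, len(set(deg_sets[a]) & set(deg_sets[b])))
                 for i, a in enumerate(names) for b in names[i + 1:]]
    pairwise = pd.DataFrame(pair_rows, columns=["set_a", "set_b", "shared"])
    return exclusive, pairwise


def updown_paired_t(summaries: dict[str, tuple[int, int]]
                    ) -> tuple[float, int, float]:
    """One-sample t of per-genotype (n_up − n_down) differences against zero.

    Numerically identical to a paired t between up- and down-counts.
    Returns (t, df, p); zero variance of the differences is degenerate and
    reported as (nan, df, nan).
    """
    if len(summaries) < 3:
        raise ValueError("need >=3 genotypes for the paired test")
    diffs = np.array([up - down for up, down in summaries.values()], dtype=float)
    df = len(diffs) - 1
    if np.ptp(diffs) == 0:
        return np.nan, df, np.nan
    res = stats.ttest_1samp(diffs, 0.0)
    return float(res.statistic), df, float(res.pvalue)


# ---------------------------------------------------------------------------
# Bray–Curtis / PERMANOVA

def bray_curtis(profiles: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis dissimilarity between sample columns.

    d(i,j) = Σ_g |x_gi − x_gj| / Σ_g (x_gi + x_gj) on non-negative values.
    """
    x = profiles.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray–Curtis requires non-negative values")
    totals = x.sum(axis=0)
    if (totals == 0).sum() >= 2:
        raise ValueError("two all-zero samples: Bray–Curtis undefined")
    diff = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=0)
    summ = (x[:, :, None] + x[:, None, :]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(summ > 0, diff / summ, 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.columns, columns=profiles.columns)


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, df, sum_sq, r2, pseudo_F, p
    total_ss: float
    n_permutations: int
    seed: int
    dropped_terms: list = field(default_factory=list)


def _dummy(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series.astype("category")).to_numpy(dtype=float)


def _term_matrix(design: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":", 1)
        da, db = _dummy(design[a]), _dummy(design[b])
        return np.einsum("ni,nj->nij", da, db).reshape(len(design), -1)
    return _dummy(design[term])


def permanova(dist: pd.DataFrame, design: pd.DataFrame,
              terms: tuple[str, ...] = DEFAULT_PERMANOVA_TERMS,
              n_perm: int = 9999, seed: int = 0) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA on a distance matrix.

    Gower-centers −½D² and partitions its trace over the ordered term list by
    successive projections onto cumulative design subspaces; each term's
    pseudo-F is tested against the residual by free permutation of sample
    labels, p = (1 + #{F_perm >= F_obs}) / (1 + n_perm). Rank-deficient terms
    (adding no dimension beyond the preceding ones, e.g. an aliased replicate
    factor) are dropped and recorded.
    """
    samples = list(dist.index)
    if list(dist.columns) != samples:
        raise ValueError("distance matrix index/columns mismatch")
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    design = design.loc[samples]
    n = len(samples)
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    total_ss = float(np.trace(g))

    # cumulative hat matrices
    ones = np.ones((n, 1))
    hats: list[np.ndarray] = []
    kept_terms: list[str] = []
    dfs: list[int] = []
    dropped: list[str] = []
    x = ones
    rank_prev = 1
    h_prev = np.full((n, n), 1.0 / n)
    for term in terms:
        cols = [c for c in ([term.split(":", 1)[0], term.split(":", 1)[1]]
                            if ":" in term else [term])]
        for c in cols:
            if c not in design.columns:
                raise ValueError(f"term {term!r}: no design column {c!r}")
        x_new = np.hstack([x, _term_matrix(design, term)])
        rank_new = np.linalg.matrix_rank(x_new)
        df_term = rank_new - rank_prev
        if df_term == 0:
            dropped.append(term)
            continue
        h_new = x_new @ np.linalg.pinv(x_new)
        hats.append(h_new - h_prev)  # projector increment for this term
        kept_terms.append(term)
        dfs.append(df_term)
        x, rank_prev, h_prev = x_new, rank_new, h_new
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("model saturates the samples: no residual df")
    resid_proj = np.eye(n) - h_prev

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(h * gmat)) for h in hats])
        ss_res = float(np.sum(resid_proj * gmat))
        return ss, ss_res

    ss_obs, ss_res_obs = term_stats(g)
    f_obs = (ss_obs / np.array(dfs)) / (ss_res_obs / df_resid)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(kept_terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = term_stats(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_resid)
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = list(zip(kept_terms, dfs, ss_obs, ss_obs / total_ss, f_obs, pvals))
    rows.append(("Residual", df_resid, ss_res_obs, ss_res_obs / total_ss,
                 np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "sum_sq", "r2",
                                        "pseudo_F", "p"])
    return PermanovaResult(table=table, total_ss=total_ss,
                           n_permutations=n_perm, seed=seed,
                           dropped_terms=dropped)
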