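"""Organismal-level analysis: growth-curve fitness and scalar phenotypes.

Fitness is the empirical area under an OD600 growth curve over 0–24 h
(trapezoid on the observed grid, OD·hour units). Between-temperature deltas
carry propagated uncertainty σ_f = sqrt(SEM_37² + SEM_42²). Scalar
phenotypes (biofilm OD550, intracellular nickel ppb) get the same delta
treatment plus a one-way ANOVA across genotypes and per-genotype Welch
t-tests between temperatures with BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust


@dataclass
class GrowthCurveMatrix:
    """Plate reads: time grid (minutes) x wells, with per-well metadata."""

    time_min: np.ndarray
    od: pd.DataFrame          # index aligned with time_min, columns wells
    well_map: pd.DataFrame    # index well; genotype, temperature, replicate

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.time_min) > 0):
            raise ValueError("time grid must be strictly increasing")


def auc_empirical(time_min: np.ndarray, od: np.ndarray,
                  t_max_h: float = 24.0) -> float:
    """Trapezoidal AUC (OD·hour) over observed points within [0, t_max].

    No extrapolation: integration stops at the last observed point inside
    the window.
    """
    t = np.asarray(time_min, dtype=float) / 60.0
    y = np.asarray(od, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    mask = (t >= 0) & (t <= t_max_h)
    if mask.sum() < 2:
        raise ValueError("need >=2 timepoints within the integration window")
    return float(np.trapezoid(y[mask], t[mask]))


def summarize_fitness(curves: GrowthCurveMatrix,
                      t_max_h: float = 24.0) -> pd.DataFrame:
    """Per (genotype, temperature): mean AUC, SEM (= sd/sqrt(n)), and n."""
    aucs = {well: auc_empirical(curves.time_min, curves.od[well].to_numpy(),
                                t_max_h)
            for well in curves.od.columns}
    df = curves.well_map.copy()
    df["auc"] = df.index.map(aucs)
    grouped = df.groupby(["genotype", "temperature"], sort=True)["auc"]
    out = grouped.agg(mean_auc="mean", sd="std", n="count").reset_index()
    if (out["n"] < 2).any():
        raise ValueError("every (genotype, temperature) cell needs >=2 replicates")
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


def delta_with_error(summary: pd.DataFrame, value_col: str = "mean_auc"
                     ) -> pd.DataFrame:
    """Per-genotype delta (42 − 37 °C) with propagated error.

    σ_f = sqrt(SEM_37² + SEM_42²). Genotypes missing a temperature are
    skipped and listed in the ``skipped`` attribute of the result.
    """
    rows, skipped = [], []
    for genotype, sub in summary.groupby("genotype", sort=True):
        by_temp = sub.set_index("temperature")
        if not {37, 42}.issubset(by_temp.index):
            skipped.append(genotype)
            continue
        m37, m42 = by_temp.loc[37, value_col], by_temp.loc[42, value_col]
        s37, s42 = by_temp.loc[37, "sem"], by_temp.loc[42, "sem"]
        rows.append((genotype, m37, s37, m42, s42, m42 - m37,
                     float(np.hypot(s37, s42))))
    out = pd.DataFrame(rows, columns=["genotype", "mean_37", "sem_37",
                                      "mean_42", "sem_42", "delta", "sigma_f"])
    out.attrs["skipped"] = skipped
    return out


def summarize_traits(traits: pd.DataFrame, assay: str) -> pd.DataFrame:
    """Mean/SEM/n per (genotype, temperature) for one scalar assay."""
    sub = traits[traits["assay"] == assay]
    if sub.empty:
        raise ValueError(f"no rows for assay {assay!r}")
    out = (sub.groupby(["genotype", "temperature"], sort=True)["value"]
           .agg(mean_value="mean", sd="std", n="count").reset_index())
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


def anova_phenotype(values: pd.DataFrame, response: str = "value",
                    group: str = "genotype") -> tuple[float, int, int, float]:
    """One-way ANOVA of a response across genotypes. Returns (F, df1, df2, p)."""
    groups = [g[response].to_numpy() for _, g in values.groupby(group)]
    if len(groups) < 2:
        raise ValueError("need >=2 genotypes")
    if any(len(g) < 2 for g in groups):
        raise ValueError("a genotype has <2 observations")
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    if all(np.ptp(g) == 0 for g in groups):
        between = np.ptp([g[0] for g in groups])
        return (np.inf if between > 0 else np.nan, df1, df2,
                0.0 if between > 0 else np.nan)
    F, p = stats.f_oneway(*groups)
    return float(F), df1, df2, float(p)


def per_genotype_temp_test(traits: pd.DataFrame) -> pd.DataFrame:
    """Welch two-sample t per genotype (42 vs 37 °C), BH across genotypes.

    Degenerate genotypes (zero variance in both groups) get NaN statistics
    and a flag but stay in the BH family as p = NaN (excluded from BH).
    """
    rows = []
    for genotype, sub in traits.groupby("genotype", sort=True):
        x37 = sub.loc[sub["temperature"] == 37, "value"].to_numpy()
        x42 = sub.loc[sub["temperature"] == 42, "value"].to_numpy()
        if len(x37) < 2 or len(x42) < 2:
            raise ValueError(f"{genotype}: need >=2 replicates per temperature")
        if np.ptp(x37) == 0 and np.ptp(x42) == 0:
            rows.append((genotype, np.nan, np.nan, np.nan, True))
            continue
        res = stats.ttest_ind(x42, x37, equal_var=False)
        rows.append((genotype, float(res.statistic), float(res.df),
                     float(res.pvalue), False))
    out = pd.DataFrame(rows, columns=["genotype", "t", "df", "pvalue",
                                      "degenerate"])
    out["padj"] = bh_adjust(out["pvalue"])
    return out


def logistic_auc_closed_form(K: float, r: float, N0: float,
                             t_max_h: float = 24.0) -> float:
    """Analytic integral of K / (1 + ((K−N0)/N0) e^(−rt)) over [0, t_max] hours."""
    A = (K - N0) / N0
    return (K / r) * np.log((A + np.exp(r * t_max_h)) / (A + 1.0))
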