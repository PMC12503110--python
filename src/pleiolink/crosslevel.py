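"""Cross-level correlation screen.

Links per-genotype metrics across levels of biological organization
(structural distances and ΔΔG; DEG counts; fitness deltas) by ordinary least
squares, one pair at a time. A link is significant when its adjusted r²
exceeds 0.3 and its BH FDR — computed over all pairs tested in one screen
invocation — is below 0.05. Significant links are emitted as a level-to-level
edge table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust

GATE_ADJ_R2 = 0.3
GATE_FDR = 0.05


@dataclass
class CorrelationRecord:
    var1: str
    var2: str
    n: int
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    pvalue: float
    fdr: float = np.nan
    significant: bool = False


@dataclass
class MetricTable:
    """One row per genotype; each metric column tagged with a level."""

    values: pd.DataFrame               # index genotype
    levels: dict[str, str]             # metric -> structural|transcriptomic|organismal

    def __post_init__(self) -> None:
        unknown = set(self.levels) - set(self.values.columns)
        if unknown:
            raise ValueError(f"level tags for absent metrics: {sorted(unknown)}")


def ols_fit(x: pd.Series, y: pd.Series, var1: str, var2: str
            ) -> CorrelationRecord:
    """OLS of y on x with intercept; p from the model F-test.

    With a single predictor the model F-test and the slope t-test coincide.
    Adjusted r² = 1 − (1 − r²)(n − 1)/(n − 2).
    """
    aligned = pd.concat([x, y], axis=1, keys=["x", "y"]).dropna()
    n = len(aligned)
    if n < 4:
        raise ValueError(f"{var1}~{var2}: need >=4 genotypes, got {n}")
    xv, yv = aligned["x"].to_numpy(float), aligned["y"].to_numpy(float)
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError(f"{var1}~{var2}: non-finite values")
    if np.ptp(xv) == 0:
        raise ValueError(f"{var1}~{var2}: degenerate predictor (zero variance)")
    if n < 6:
        warnings.warn(f"{var1}~{var2}: n={n} < 6; the adjusted-r² gate is "
                      "unstable at this size", stacklevel=2)
    res = stats.linregress(xv, yv)
    r2 = res.rvalue**2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CorrelationRecord(var1=var1, var2=var2, n=n,
                             slope=float(res.slope),
                             intercept=float(res.intercept),
                             r2=float(r2), adj_r2=float(adj_r2),
                             pvalue=float(res.pvalue))


def default_pairs(metrics: MetricTable) -> list[tuple[str, str]]:
    """The standard screen family: DEG counts against every structural
    metric, plus fitness delta against the total DEG count."""
    cols = list(metrics.values.columns)
    deg_metrics = [c for c in cols
                   if metrics.levels.get(c) == "transcriptomic"]
    structural = [c for c in cols if metrics.levels.get(c) == "structural"]
    pairs = [(d, s) for d in deg_metrics for s in structural]
    if "delta_auc" in cols:
        total = [c for c in deg_metrics if c.startswith("n_deg_total")]
        pairs += [("delta_auc", t) for t in total]
    return pairs


def correlation_screen(metrics: MetricTable,
                       pairs: list[tuple[str, str]] | None = None,
                       gate_r2: float = GATE_ADJ_R2,
                       gate_fdr: float = GATE_FDR) -> list[CorrelationRecord]:
    """Run OLS for every metric pair and gate by adjusted r² and BH FDR.

    The FDR family is all pairs tested in this invocation. Records are
    returned sorted by FDR then pair name.
    """
    if pairs is None:
        pairs = default_pairs(metrics)
    missing = {m for pair in pairs for m in pair
               if m not in metrics.values.columns}
    if missing:
        raise ValueError(f"pairs reference unknown metrics: {sorted(missing)}")
    records = [ols_fit(metrics.values[v2], metrics.values[v1], v1, v2)
               for v1, v2 in pairs]
    fdrs = bh_adjust([r.pvalue for r in records])
    for rec, fdr in zip(records, fdrs):
        rec.fdr = float(fdr)
        rec.significant = bool(rec.adj_r2 > gate_r2 and rec.fdr < gate_fdr)
    return sorted(records, key=lambda r: (r.fdr, r.var1, r.var2))


def screen_table(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def link_report(records: list[CorrelationRecord],
                levels: dict[str, str]) -> pd.DataFrame:
    """Edge table of significant links: (level_from, metric, level_to, metric,
    sign of slope), deterministically ordered."""
    rows = []
    for rec in records:
        if not rec.significant:
            continue
        lvl1 = levels.get(rec.var1, "unknown")
        lvl2 = levels.get(rec.var2, "unknown")
        sign = "+" if rec.slope > 0 else ("-" if rec.slope < 0 else "0")
        rows.append((lvl2, rec.var2, lvl1, rec.var1, sign, rec.adj_r2, rec.fdr))
    out = pd.DataFrame(rows, columns=["level_from", "metric_from", "level_to",
                                      "metric_to", "slope_sign", "adj_r2",
                                      "fdr"])
    return out.sort_values(["level_from", "metric_from", "metric_to"],
                           kind="mergesort").reset_index(drop=True)
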