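"""Shared helpers: FDR adjustment, seed derivation, TSV with metadata headers."""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "stage_seed", "write_table", "read_table"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up FDR).

    NaN entries are left NaN and excluded from the family.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a master seed, keyed by stage name.

    Deterministic across runs and platforms; result is a valid 31-bit seed so
    stages can be rerun in isolation with the printed value.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key])
    return int(ss.generate_state(1)[0] % (2**31))


def write_table(df: pd.DataFrame, path, metadata: dict | None = None,
                index: bool = False) -> None:
    """Write a TSV with a commented ``# key: value`` metadata header block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping the header block."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
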