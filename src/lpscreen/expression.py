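"""Present/absent expression calls from processed microarray tables.

Consumes a processed table with one row per probe and, per condition, a
log2 signal intensity and a detection p-value (the per-probe probability
that the signal is indistinguishable from background).  A probe is
*detected* in a condition when its detection p-value is strictly below
0.1; a gene is *expressed in macrophages* when any of its probes is
detected in at least one of the four conditions (with/without LPS in the
reporter line and in primary macrophages).  Missing detection p-values
are treated as 1 (not detected), a conservative choice.

The expressed-gene set gates the secondary screen: non-expressed genes
are removed before consensus calling; scores of retained genes are never
altered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DETECTION_ALPHA = 0.1
#: the four profiled conditions: reporter line and primary macrophages, +/- LPS
CONDITIONS = ("RAWG9_LPS", "RAWG9_ctrl", "BMDM_LPS", "BMDM_ctrl")


def detection_call(detection_p, alpha: float = DETECTION_ALPHA):
    """Detected iff detection p-value < alpha (strict).

    Accepts scalars or arrays; NaN (missing) is never detected.
    """
    p = np.asarray(detection_p, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("detection p-values must lie in [0, 1]")
    out = np.where(np.isnan(p), False, p < alpha)
    return bool(out) if np.isscalar(detection_p) else out


def detection_p_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("DetectionP_")]
    if not cols:
        raise ValueError("table has no DetectionP_<condition> columns")
    return cols


def expressed_in_macrophages(
    table: pd.DataFrame, alpha: float = DETECTION_ALPHA
) -> pd.Series:
    """Per-probe call: detected in at least one condition.

    Missing conditions count as not detected.
    """
    cols = detection_p_columns(table)
    p = table[cols].to_numpy(dtype=float)
    return pd.Series(
        np.nansum(np.where(np.isnan(p), False, p < alpha), axis=1) > 0,
        index=table.index,
        name="Expressed",
    )


def gene_expression_calls(
    table: pd.DataFrame, alpha: float = DETECTION_ALPHA
) -> pd.Series:
    """Collapse probe calls to genes: expressed iff ANY probe is expressed.

    The any-probe rule matches the permissive at-least-one-condition rule
    at the probe level.  Returns a boolean Series indexed by GeneSymbol.
    """
    if "GeneSymbol" not in table.columns:
        raise ValueError("table needs a GeneSymbol column")
    probe = expressed_in_macrophages(table, alpha)
    return probe.groupby(table["GeneSymbol"]).any().rename("Expressed")


def read_expression_table(path) -> pd.DataFrame:
    """Read a processed expression table (CSV; ProbeID, GeneSymbol,
    Log2Signal_* and DetectionP_* columns)."""
    df = pd.read_csv(path)
    for col in ("ProbeID", "GeneSymbol"):
        if col not in df.columns:
            raise ValueError(f"expression table missing column {col}")
    detection_p_columns(df)
    return df
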