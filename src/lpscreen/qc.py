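"""Screen-level quality gates.

Implements the four reported QC statistics: per-plate replicate Spearman
correlation against a reproducibility gate, intra-plate coefficient of
variation for uniformity plates, inter-plate fold shift of the mid-level
signal across days, and siGFP knockdown efficiency.  All statistics are
pure functions of the data; re-running QC on the same dataset yields an
identical report.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from . import io
from .errors import QcError

SPEARMAN_GATE = 0.55
MIN_COMMON_WELLS = 20


@dataclasses.dataclass(frozen=True)
class ReplicateQc:
    rho: float
    passed: bool
    reason: str = ""


def replicate_correlation(
    rep1, rep2, gate: float = SPEARMAN_GATE
) -> ReplicateQc:
    """Spearman rank correlation of two replicate vectors against a gate.

    Ties receive average ranks.  Constant vectors make the correlation
    undefined; the plate then fails with an explanatory reason.
    """
    x = np.asarray(rep1, dtype=float)
    y = np.asarray(rep2, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < MIN_COMMON_WELLS:
        raise ValueError(
            f"need >= {MIN_COMMON_WELLS} common sample wells, got {x.size}"
        )
    if np.all(x == x[0]) or np.all(y == y[0]):
        return ReplicateQc(float("nan"), False, "constant replicate vector")
    rho = float(stats.spearmanr(x, y).statistic)
    return ReplicateQc(rho, rho >= gate, "" if rho >= gate else "below gate")


def replicate_qc_table(
    ds: io.ScreenDataset, gate: float = SPEARMAN_GATE
) -> pd.DataFrame:
    """Per (plate, readout) replicate correlation over sample wells.

    Controls are excluded so that designed extremes do not inflate the
    correlation; the gate measures reproducibility of the unknowns.
    """
    rows = []
    samples = ds.sample_wells()
    for (plate, readout), sub in samples.groupby(["PlateID", "Readout"], sort=True):
        try:
            r = replicate_correlation(sub["Rep1Value"], sub["Rep2Value"], gate)
        except ValueError as exc:
            r = ReplicateQc(float("nan"), False, str(exc))
        rows.append(
            {
                "PlateID": plate,
                "Readout": readout,
                "SpearmanRho": r.rho,
                "Pass": r.passed,
                "Reason": r.reason,
            }
        )
    return pd.DataFrame(rows)


def plate_uniformity_cv(values) -> float:
    """Coefficient of variation (percent) over like wells at one dose.

    Uses the sample standard deviation (n-1 denominator).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise ValueError(f"need >= 8 wells, got {x.size}")
    mean = float(np.mean(x))
    if mean <= 0:
        raise QcError("CV undefined for non-positive mean")
    return 100.0 * float(np.std(x, ddof=1)) / mean


@dataclasses.dataclass(frozen=True)
class FoldShift:
    """Inter-plate shift of the normalized mid-level signal across days.

    Reported on the log2 scale (a dimensionless shift; 1.0 means a
    two-fold change) with the raw day2/day1 ratio alongside.
    """

    log2_shift: float
    ratio: float


def interplate_fold_shift(mid_signal_day1: float, mid_signal_day2: float) -> FoldShift:
    if mid_signal_day1 <= 0 or mid_signal_day2 <= 0:
        raise ValueError("mid-level signals must be positive")
    ratio = mid_signal_day2 / mid_signal_day1
    return FoldShift(abs(float(np.log2(ratio))), float(ratio))


def gfp_knockdown(sigfp_values, ntc_values) -> float:
    """Percent reduction of GFP signal in siGFP wells relative to NTC.

    Both inputs must come from unstimulated (no-LPS) wells imaged in the
    GFP channel; at least 3 wells each.
    """
    s = np.asarray(sigfp_values, dtype=float)
    n = np.asarray(ntc_values, dtype=float)
    s, n = s[np.isfinite(s)], n[np.isfinite(n)]
    if s.size < 3 or n.size < 3:
        raise ValueError("need >= 3 siGFP and >= 3 NTC wells")
    ref = float(np.mean(n))
    if ref <= 0:
        raise QcError("knockdown undefined for non-positive NTC mean")
    return 100.0 * (1.0 - float(np.mean(s)) / ref)


def gfp_knockdown_report(ds: io.ScreenDataset) -> float:
    """Screen-wide siGFP knockdown from the unstimulated control wells.

    Pools both replicate values of all siGFP wells against the no-LPS
    NTC wells across plates and readout plate sets.
    """
    sigfp = ds.wells_for_role("siGFP")
    nolps = ds.wells_for_role("noLPS")
    s = np.concatenate([sigfp["Rep1Value"], sigfp["Rep2Value"]])
    n = np.concatenate([nolps["Rep1Value"], nolps["Rep2Value"]])
    return gfp_knockdown(s, n)


def control_summary(ds: io.ScreenDataset) -> pd.DataFrame:
    """Median final z-score per control role and readout."""
    if "Zscore" not in ds.wells.columns:
        raise ValueError("dataset has no Zscore column; normalize first")
    ctrl = ds.wells_for_role(*io.CONTROL_ROLES)
    out = (
        ctrl.groupby(["Readout", "WellAnno"], sort=True, observed=True)["Zscore"]
        .median()
        .rename("MedianZscore")
        .reset_index()
    )
    return out


@dataclasses.dataclass
class QcReport:
    replicate: pd.DataFrame
    controls: pd.DataFrame | None
    gfp_knockdown_percent: float | None

    @property
    def all_replicates_pass(self) -> bool:
        return bool(self.replicate["Pass"].all())

    def to_text(self) -> str:
        lines = ["Replicate correlation (Spearman, sample wells):"]
        for _, r in self.replicate.iterrows():
            flag = "pass" if r["Pass"] else f"FAIL ({r['Reason']})"
            lines.append(
                f"  {r['PlateID']:>8s} {r['Readout']:>4s}  rho={r['SpearmanRho']:.3f}  {flag}"
            )
        if self.gfp_knockdown_percent is not None:
            lines.append(f"siGFP knockdown: {self.gfp_knockdown_percent:.1f}%")
        if self.controls is not None and len(self.controls):
            lines.append("Control medians (final z):")
            for _, r in self.controls.iterrows():
                lines.append(
                    f"  {r['Readout']:>4s} {r['WellAnno']:>6s}  {r['MedianZscore']:+.2f}"
                )
        return "\n".join(lines)


def qc_report(ds: io.ScreenDataset, gate: float = SPEARMAN_GATE) -> QcReport:
    """Assemble the screen QC report (replicates, controls, knockdown)."""
    rep = replicate_qc_table(ds, gate)
    controls = control_summary(ds) if "Zscore" in ds.wells.columns else None
    try:
        kd = gfp_knockdown_report(ds)
    except (ValueError, QcError):
        kd = None
    return QcReport(rep, controls, kd)
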