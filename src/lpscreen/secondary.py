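"""Secondary-screen consensus hit calling.

Each candidate gene is retested with six independent siRNA sequences,
three from each of two vendors, so that seed-driven off-target phenotypes
(which follow individual sequences, not the gene) are voted out.  Per
gene, readout and vendor the median of six z-scores (3 siRNAs x 2
replicates) is taken, giving four scores per gene: Ambion/Qiagen x
NFKB/TNF.  A vendor-specific hit threshold (the Ambion phenotypes being
consistently stronger than the Qiagen ones) flags each score, the flags
are summed (``SumAllhit``), and the consensus class follows:

* ``all4`` — hit in all four vendor x readout groups,
* ``three_of_four`` — hit in exactly three (any three),
* ``both_tnf`` — hit in both TNF groups only,
* ``none`` — anything weaker.

The validated hit list is the union of the first three classes.  Only
genes with siRNAs from both vendors and a positive expression call enter
consensus calling.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from . import io

VENDORS = ("Ambion", "Qiagen")
MIN_VENDOR_VALUES = 4
HIT_CLASSES = ("all4", "three_of_four", "both_tnf")


@dataclasses.dataclass(frozen=True)
class SecondaryThresholds:
    """Vendor-specific positive-regulator hit thresholds (inclusive)."""

    ambion_threshold: float = -2.0
    qiagen_threshold: float = -1.0

    def __post_init__(self) -> None:
        if not (self.ambion_threshold < 0 and self.qiagen_threshold < 0):
            raise ValueError("hit thresholds must be negative")

    def for_vendor(self, vendor: str) -> float:
        return self.ambion_threshold if vendor == "Ambion" else self.qiagen_threshold


def vendor_of_index(sirna_index: int) -> str:
    """siRNAs 1-3 are Ambion, 4-6 Qiagen (plating convention)."""
    if not 1 <= sirna_index <= 6:
        raise ValueError(f"siRNA index out of range: {sirna_index}")
    return "Ambion" if sirna_index <= 3 else "Qiagen"


def vendor_median(z_values, min_values: int = MIN_VENDOR_VALUES) -> float:
    """Median of the six per-replicate z-scores of one vendor's siRNAs.

    Accepts 4 or 5 values with a warning (an siRNA that failed QC);
    returns NaN below ``min_values``.  Even counts use the mean of the
    central pair.
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < min_values:
        return float("nan")
    if z.size < 6:
        warnings.warn(f"vendor median from only {z.size} values")
    return float(np.median(z))


def vendor_scores(ds: io.ScreenDataset) -> pd.DataFrame:
    """Per-gene table of the four vendor x readout median z-scores.

    Pools ``ZscoreRep1`` and ``ZscoreRep2`` of the (up to) three wells per
    vendor.  Columns ``MedianZ_<vendor>_<readout>`` match the
    ``ZscoreGeneMedian`` fields of the deposited records; ``BothVendors``
    marks genes with at least one scored siRNA from each vendor.
    """
    df = ds.sample_wells()
    for col in ("ZscoreRep1", "ZscoreRep2", "siRNAIndex"):
        if col not in df.columns or df[col].isna().all():
            raise ValueError(f"secondary dataset needs column {col}; normalize first")
    work = df[
        ["GeneSymbol", "EntrezID", "Readout", "siRNAIndex", "ZscoreRep1", "ZscoreRep2"]
    ].copy()
    work["Vendor"] = [vendor_of_index(int(i)) for i in work["siRNAIndex"]]
    rows: dict[tuple, dict] = {}
    grouped = work.groupby(["GeneSymbol", "Readout", "Vendor"], sort=False)
    for (gene, readout, vendor), sub in grouped:
        z = np.concatenate(
            [sub["ZscoreRep1"].to_numpy(float), sub["ZscoreRep2"].to_numpy(float)]
        )
        key = gene
        row = rows.setdefault(
            key, {"GeneSymbol": gene, "EntrezID": sub["EntrezID"].iloc[0]}
        )
        row[f"MedianZ_{vendor}_{readout}"] = vendor_median(z)
        row[f"N_{vendor}"] = max(row.get(f"N_{vendor}", 0), sub["siRNAIndex"].nunique())
    out = pd.DataFrame(list(rows.values()))
    for vendor in VENDORS:
        for readout in io.READOUTS:
            col = f"MedianZ_{vendor}_{readout}"
            if col not in out.columns:
                out[col] = np.nan
        if f"N_{vendor}" not in out.columns:
            out[f"N_{vendor}"] = 0
        out[f"N_{vendor}"] = out[f"N_{vendor}"].fillna(0).astype(int)
    out["BothVendors"] = (out["N_Ambion"] > 0) & (out["N_Qiagen"] > 0)
    return out.reset_index(drop=True)


_FLAG_COLUMNS = {
    "Hit_Ambion_TNF": ("Ambion", "TNF"),
    "Hit_Ambion_NFKB": ("Ambion", "NFKB"),
    "Hit_Qiagen_TNF": ("Qiagen", "TNF"),
    "Hit_Qiagen_NFKB": ("Qiagen", "NFKB"),
}


def call_secondary(
    scores: pd.DataFrame,
    thresholds: SecondaryThresholds | None = None,
    expressed: Mapping[str, bool] | pd.Series | None = None,
) -> pd.DataFrame:
    """Flag vendor medians against thresholds and assign consensus classes.

    Genes not expressed in macrophages (per ``expressed``) or lacking
    siRNAs from both vendors are excluded from consensus calling and kept
    with an ``Excluded`` reason.  Flag comparisons are inclusive (median
    z less than or equal to the vendor threshold).
    """
    th = thresholds or SecondaryThresholds()
    out = scores.copy()
    if expressed is not None:
        expr = pd.Series(expressed)
        out["Expressed"] = out["GeneSymbol"].map(expr).fillna(False).astype(bool)
    elif "Expressed" not in out.columns:
        out["Expressed"] = True
    out["Excluded"] = ""
    out.loc[~out["Expressed"].astype(bool), "Excluded"] = "not expressed"
    out.loc[~out["BothVendors"], "Excluded"] = "single vendor"
    callable_mask = out["Excluded"] == ""

    for col, (vendor, readout) in _FLAG_COLUMNS.items():
        med = out[f"MedianZ_{vendor}_{readout}"]
        out[col] = callable_mask & (med <= th.for_vendor(vendor))
    flags = out[list(_FLAG_COLUMNS)].to_numpy(dtype=bool)
    out["SumAllhit"] = flags.sum(axis=1)

    cls = np.full(len(out), "none", dtype=object)
    both_tnf = out["Hit_Ambion_TNF"].to_numpy() & out["Hit_Qiagen_TNF"].to_numpy()
    cls[both_tnf & (out["SumAllhit"] < 3)] = "both_tnf"
    cls[out["SumAllhit"] == 3] = "three_of_four"
    cls[out["SumAllhit"] == 4] = "all4"
    cls[~callable_mask.to_numpy()] = "none"
    out["ConsensusClass"] = cls
    return out


@dataclasses.dataclass(frozen=True)
class ConsensusCounts:
    """Per-class hit counts; the validated list is their union."""

    all4: int
    three_of_four: int
    both_tnf: int

    @property
    def final_total(self) -> int:
        return self.all4 + self.three_of_four + self.both_tnf


@dataclasses.dataclass(frozen=True)
class SecondaryGeneSet:
    """Composition of the secondary screen gene set by vendor coverage."""

    common: int
    ambion_only: int
    qiagen_only: int

    @property
    def total(self) -> int:
        return self.common + self.ambion_only + self.qiagen_only


@dataclasses.dataclass
class ConsensusReport:
    counts: ConsensusCounts
    per_flag_counts: dict[str, int]
    final_hits: pd.DataFrame
    negative_candidate_count: int

    def to_text(self) -> str:
        c = self.counts
        lines = [
            f"hits in all 4 groups:    {c.all4}",
            f"hits in 3 of 4 groups:   {c.three_of_four}",
            f"hits in both TNF groups: {c.both_tnf}",
            f"validated positive regulators: {c.final_total}",
            "per-group hit counts: "
            + ", ".join(f"{k.removeprefix('Hit_')}={v}" for k, v in self.per_flag_counts.items()),
            f"consistent negative-regulator candidates: {self.negative_candidate_count}",
        ]
        return "\n".join(lines)


def consensus_report(called: pd.DataFrame) -> ConsensusReport:
    """Summarize consensus calls into the final validated hit list.

    The final list is the union of the ``all4``, ``three_of_four`` and
    ``both_tnf`` classes, ranked by ``SumAllhit`` then by the strongest
    Ambion TNF median.  Genes above the mirrored positive thresholds with
    both vendors on either readout are counted as negative-regulator
    candidates but no class thresholds are applied to them.
    """
    counts = ConsensusCounts(
        all4=int((called["ConsensusClass"] == "all4").sum()),
        three_of_four=int((called["ConsensusClass"] == "three_of_four").sum()),
        both_tnf=int((called["ConsensusClass"] == "both_tnf").sum()),
    )
    per_flag = {col: int(called[col].sum()) for col in _FLAG_COLUMNS}
    hits = called[called["ConsensusClass"].isin(HIT_CLASSES)].copy()
    hits = hits.sort_values(
        ["SumAllhit", "MedianZ_Ambion_TNF"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    neg = (called["Excluded"] == "").to_numpy()
    neg_any = np.zeros(len(called), dtype=bool)
    for readout in io.READOUTS:
        neg_any |= (
            (called[f"MedianZ_Ambion_{readout}"] >= 2.0)
            & (called[f"MedianZ_Qiagen_{readout}"] >= 1.0)
        ).to_numpy()
    n_neg = int((neg & neg_any).sum())
    return ConsensusReport(counts, per_flag, hits, n_neg)
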