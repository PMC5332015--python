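"""Primary-screen hit calling.

The primary screen scores one SMARTpool well per gene and readout.  Hit
thresholds for putative positive regulators are anchored to the on-plate
Tlr4 control (its median final z-score per readout); thresholds for
negative regulators are fixed configuration values.  Genes killing the
cells (both replicate wells below the viability floor) are excluded from
classification.  Classified genes fall into four groups:

====== ======= ==========================================
group  readout meaning
====== ======= ==========================================
G1     NFKB    positive regulator (knockdown lowers N:C)
G2     NFKB    negative regulator
G3     TNF     positive regulator
G4     TNF     negative regulator
====== ======= ==========================================

Hit thresholds are inclusive; the activity-score bins of the deposited
records use strict inequalities.  Both conventions are kept exactly as
deposited, so a well at exactly the positive-regulator threshold is
classified a hit yet carries activity score 25 — a real asymmetry of the
record schema, preserved deliberately.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Collection, Mapping

import numpy as np
import pandas as pd

from . import io

DEFAULT_MIN_CELLS = 50
DEFAULT_P_CUTOFF = 0.05


@dataclasses.dataclass(frozen=True)
class PrimaryThresholds:
    """Hit thresholds for the primary screen.

    Positive-regulator thresholds default to the deposited Tlr4-control
    medians; negative-regulator thresholds to the fixed values chosen for
    the deposited records.
    """

    pos_reg_threshold_nfkb: float = -1.56
    pos_reg_threshold_tnf: float = -1.3
    neg_reg_threshold_nfkb: float = 3.3
    neg_reg_threshold_tnf: float = 3.0
    min_cells: int = DEFAULT_MIN_CELLS
    p_cutoff: float = DEFAULT_P_CUTOFF

    def __post_init__(self) -> None:
        if not (
            self.pos_reg_threshold_nfkb < 0 < self.neg_reg_threshold_nfkb
            and self.pos_reg_threshold_tnf < 0 < self.neg_reg_threshold_tnf
        ):
            raise ValueError("positive thresholds must be < 0 < negative thresholds")


def viability_filter(ds: io.ScreenDataset, min_cells: int = DEFAULT_MIN_CELLS) -> io.ScreenDataset:
    """Flag wells whose cell count is below ``min_cells`` in BOTH replicates.

    The comparison is strict (a count of exactly ``min_cells`` passes).
    Wells with missing counts are flagged indeterminate (``NA``) with a
    warning and are excluded from classification downstream.
    """
    out = ds.copy()
    df = out.wells
    if "Rep1CellCount" not in df.columns or "Rep2CellCount" not in df.columns:
        raise ValueError("dataset has no cell-count columns")
    c1, c2 = df["Rep1CellCount"], df["Rep2CellCount"]
    flag = (c1 < min_cells) & (c2 < min_cells)
    missing = (c1.isna() | c2.isna()) & (df["WellAnno"] != io.EMPTY)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} non-empty well(s) have missing cell counts; "
            "viability flag indeterminate"
        )
        flag = flag.mask(missing)
    df["LowCellCount"] = flag.astype("boolean")
    return out


def derive_thresholds(
    ds: io.ScreenDataset,
    *,
    neg_reg_threshold_nfkb: float = 3.3,
    neg_reg_threshold_tnf: float = 3.0,
    min_cells: int = DEFAULT_MIN_CELLS,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> PrimaryThresholds:
    """Anchor positive-regulator thresholds to the Tlr4 control medians.

    Takes the median final z-score of the Tlr4 wells per readout.  Falls
    back to the configured defaults, with a warning, when fewer than 3
    scored Tlr4 wells exist for a readout.
    """
    if "Zscore" not in ds.wells.columns:
        raise ValueError("dataset has no Zscore column; normalize first")
    tlr4 = ds.wells_for_role("Tlr4")
    defaults = PrimaryThresholds()
    pos = {}
    for readout, default in (
        ("NFKB", defaults.pos_reg_threshold_nfkb),
        ("TNF", defaults.pos_reg_threshold_tnf),
    ):
        z = tlr4.loc[tlr4["Readout"] == readout, "Zscore"].dropna()
        if len(z) < 3:
            warnings.warn(
                f"{readout}: {len(z)} Tlr4 wells; using default threshold {default}"
            )
            pos[readout] = default
        else:
            pos[readout] = float(z.median())
    return PrimaryThresholds(
        pos_reg_threshold_nfkb=pos["NFKB"],
        pos_reg_threshold_tnf=pos["TNF"],
        neg_reg_threshold_nfkb=neg_reg_threshold_nfkb,
        neg_reg_threshold_tnf=neg_reg_threshold_tnf,
        min_cells=min_cells,
        p_cutoff=p_cutoff,
    )


def gene_scores(ds: io.ScreenDataset) -> pd.DataFrame:
    """Per-gene, per-readout score table from the scored sample wells.

    The primary design has one SMARTpool well per gene, so this is a
    column selection, not an aggregation.
    """
    cols = ["GeneSymbol", "EntrezID", "Readout", "PlateID", "Well", "Zscore", "Pvalue"]
    if "LowCellCount" in ds.wells.columns:
        cols.append("LowCellCount")
    out = ds.sample_wells()[cols].copy()
    return out.reset_index(drop=True)


def classify_primary(scores: pd.DataFrame, th: PrimaryThresholds) -> pd.DataFrame:
    """Assign G1-G4 group labels (inclusive thresholds, as deposited).

    Wells flagged for low cell count (or with an indeterminate flag) get
    group ``none``.
    """
    out = scores.copy()
    z = out["Zscore"].to_numpy(dtype=float)
    nfkb = (out["Readout"] == "NFKB").to_numpy()
    tnf = (out["Readout"] == "TNF").to_numpy()
    group = np.full(len(out), "none", dtype=object)
    group[nfkb & (z <= th.pos_reg_threshold_nfkb)] = "G1"
    group[nfkb & (z >= th.neg_reg_threshold_nfkb)] = "G2"
    group[tnf & (z <= th.pos_reg_threshold_tnf)] = "G3"
    group[tnf & (z >= th.neg_reg_threshold_tnf)] = "G4"
    if "LowCellCount" in out.columns:
        low = out["LowCellCount"].fillna(True).to_numpy(dtype=bool)
        group[low] = "none"
    out["Group"] = group
    return out


@dataclasses.dataclass(frozen=True)
class SelectionSummary:
    """Bookkeeping of the genes carried into the secondary screen."""

    nfkb_only: int
    tnf_only: int
    both: int

    @property
    def total(self) -> int:
        return self.nfkb_only + self.tnf_only + self.both


def prioritize(
    scores: pd.DataFrame,
    annotation_list: Collection[str] = (),
    canonical_pathway: Collection[str] | None = None,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> tuple[pd.DataFrame, SelectionSummary]:
    """Select classified genes for secondary screening.

    A grouped gene is selected iff it is statistically supported
    (replicate p-value <= ``p_cutoff``) or carried by the user-supplied
    pathway-annotation list, AND it is not a canonical-pathway member
    (known canonical regulators are deliberately excluded; the goal is
    novel regulators).  This rule is a declared surrogate for the
    knowledge-base triage used on the deposited data, which is not
    reproducible from the records alone; both gene lists are inputs.
    """
    if canonical_pathway is None:
        canonical_pathway = CANONICAL_TLR4_PATHWAY
    annotation = set(annotation_list)
    canonical = set(canonical_pathway)
    out = scores.copy()
    grouped = out["Group"].isin(["G1", "G2", "G3", "G4"])
    supported = (out["Pvalue"] <= p_cutoff) | out["GeneSymbol"].isin(annotation)
    out["Selected"] = (
        (grouped & supported & ~out["GeneSymbol"].isin(canonical))
        .astype("boolean")
    )
    per_gene = out.groupby("GeneSymbol", sort=False)
    sel_nfkb = set()
    sel_tnf = set()
    for gene, sub in per_gene:
        sel = sub[sub["Selected"].fillna(False).astype(bool)]
        if (sel["Readout"] == "NFKB").any():
            sel_nfkb.add(gene)
        if (sel["Readout"] == "TNF").any():
            sel_tnf.add(gene)
    both = sel_nfkb & sel_tnf
    summary = SelectionSummary(
        nfkb_only=len(sel_nfkb - both),
        tnf_only=len(sel_tnf - both),
        both=len(both),
    )
    return out, summary


# ---------------------------------------------------------------------------
# deposited activity-score binning

#: (upper, lower, score) bins per scheme; score = highest bin whose strict
#: condition z > upper or z < lower holds.
ACTIVITY_BINS: Mapping[str, tuple[tuple[float, float, int], ...]] = {
    "primary_nfkb": (
        (1.0, -1.0, 25),
        (3.3, -1.56, 50),
        (4.0, -2.0, 75),
        (5.0, -2.5, 100),
    ),
    "primary_tnf": (
        (1.0, -1.0, 25),
        (3.0, -1.3, 50),
        (3.5, -1.5, 75),
        (4.0, -2.0, 100),
    ),
    "secondary": (
        (1.0, -1.0, 25),
        (2.0, -2.0, 50),
        (3.0, -3.0, 75),
        (4.0, -4.0, 100),
    ),
}

ACTIVE_OUTCOME = 2
INACTIVE_OUTCOME = 1
CONTROL_OUTCOME = 4


def activity_annotation(z_mean: float, scheme: str) -> tuple[int, int]:
    """Activity score and outcome of a final z-score under a record scheme.

    The score is the highest bin whose strict inequality (z greater than
    the upper bound or less than the lower bound) holds; 0 when the
    z-score lies within [-1, 1].  The outcome is 2 ('active') for scores
    of at least 50 and 1 ('inactive') otherwise.  Control wells are
    annotated separately (score 0, outcome 4); see
    :func:`annotate_activity`.
    """
    if scheme not in ACTIVITY_BINS:
        raise ValueError(f"unknown activity scheme {scheme!r}")
    if not np.isfinite(z_mean):
        raise ValueError("z-score must be finite")
    score = 0
    for upper, lower, s in ACTIVITY_BINS[scheme]:
        if z_mean > upper or z_mean < lower:
            score = s
    outcome = ACTIVE_OUTCOME if score >= 50 else INACTIVE_OUTCOME
    return score, outcome


def scheme_for(design: str, readout: str) -> str:
    if design == "secondary":
        return "secondary"
    return "primary_nfkb" if readout == "NFKB" else "primary_tnf"


def annotate_activity(ds: io.ScreenDataset) -> io.ScreenDataset:
    """Add ``ActivityScore``/``ActivityOutcome`` columns to a scored dataset.

    Sample wells are binned under the scheme matching the design and
    readout; control wells always get (0, 4); empty wells are left
    unannotated.
    """
    out = ds.copy()
    df = out.wells
    if "Zscore" not in df.columns:
        raise ValueError("dataset has no Zscore column; normalize first")
    score = np.full(len(df), pd.NA, dtype=object)
    outcome = np.full(len(df), pd.NA, dtype=object)
    anno = df["WellAnno"].to_numpy()
    z = df["Zscore"].to_numpy(dtype=float)
    readout = df["Readout"].to_numpy()
    for i in range(len(df)):
        if anno[i] == io.EMPTY:
            continue
        if anno[i] != io.SAMPLE:
            score[i], outcome[i] = 0, CONTROL_OUTCOME
        elif np.isfinite(z[i]):
            score[i], outcome[i] = activity_annotation(
                z[i], scheme_for(ds.design, readout[i])
            )
    df["ActivityScore"] = pd.array(score, dtype="Int64")
    df["ActivityOutcome"] = pd.array(outcome, dtype="Int64")
    return out


#: canonical TLR4/NF-kB pathway members bundled as the default exclusion
#: list for :func:`prioritize` (48 mouse gene symbols; replaceable by the
#: caller with any knowledge-base export).
CANONICAL_TLR4_PATHWAY = frozenset(
    {
        "Tlr4", "Myd88", "Irak1", "Irak2", "Irak4", "Ikbkg", "Chuk", "Ikbkb",
        "Nfkb1", "Nfkb2", "Rela", "Relb", "Rel", "Nfkbia", "Nfkbib", "Traf6",
        "Traf3", "Tab1", "Tab2", "Tab3", "Map3k7", "Ticam1", "Ticam2", "Tirap",
        "Cd14", "Ly96", "Lbp", "Tollip", "Peli1", "Peli2", "Peli3", "Ube2n",
        "Ube2v1", "Ecsit", "Irf3", "Irf7", "Tbk1", "Ikbke", "Ripk1", "Tnip1",
        "Tnip2", "Tnfaip3", "Cyld", "Sharpin", "Rbck1", "Rnf31", "Sqstm1",
        "Unc93b1",
    }
)
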