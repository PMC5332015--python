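"""End-to-end orchestration: normalize -> QC -> hit calling.

Thin composition of the stage modules, so a whole screen can be processed
with one call (and so the command-line interface stays trivial).
"""

from __future__ import annotations

import dataclasses
from typing import Collection, Mapping

import pandas as pd

from . import io, normalize, primary, qc, secondary


@dataclasses.dataclass
class PrimaryResult:
    dataset: io.ScreenDataset
    gene_scores: pd.DataFrame
    thresholds: primary.PrimaryThresholds
    qc: qc.QcReport
    selection: primary.SelectionSummary

    def group_counts(self) -> dict[str, int]:
        counts = self.gene_scores["Group"].value_counts().to_dict()
        return {g: int(counts.get(g, 0)) for g in ("G1", "G2", "G3", "G4", "none")}


def run_primary(
    ds: io.ScreenDataset,
    *,
    thresholds: primary.PrimaryThresholds | None = None,
    derive: bool = True,
    annotation_list: Collection[str] = (),
    canonical_pathway: Collection[str] | None = None,
    p_cutoff: float = primary.DEFAULT_P_CUTOFF,
    min_cells: int = primary.DEFAULT_MIN_CELLS,
    qc_gate: float = qc.SPEARMAN_GATE,
) -> PrimaryResult:
    """Process a primary screen from raw well values to selected genes.

    Median-normalizes per plate, computes sample-anchored robust
    z-scores, averages replicates with the replicate t-test, applies the
    viability floor, anchors positive-regulator thresholds to the Tlr4
    control medians (unless ``thresholds`` is given and ``derive`` is
    False), classifies genes into G1-G4, runs the prioritization rule,
    and annotates deposited-record activity scores.
    """
    scored = normalize.normalize_dataset(ds, method="sample")
    scored = primary.viability_filter(scored, min_cells)
    if thresholds is not None and not derive:
        th = thresholds
    else:
        th = primary.derive_thresholds(scored, min_cells=min_cells, p_cutoff=p_cutoff)
    genes = primary.classify_primary(primary.gene_scores(scored), th)
    genes, selection = primary.prioritize(
        genes, annotation_list, canonical_pathway, p_cutoff
    )
    scored = primary.annotate_activity(scored)
    report = qc.qc_report(scored, qc_gate)
    return PrimaryResult(scored, genes, th, report, selection)


@dataclasses.dataclass
class SecondaryResult:
    dataset: io.ScreenDataset
    scores: pd.DataFrame
    thresholds: secondary.SecondaryThresholds
    qc: qc.QcReport
    report: secondary.ConsensusReport


def run_secondary(
    ds: io.ScreenDataset,
    expressed: Mapping[str, bool] | pd.Series | None = None,
    *,
    thresholds: secondary.SecondaryThresholds | None = None,
    qc_gate: float = qc.SPEARMAN_GATE,
) -> SecondaryResult:
    """Process a secondary screen: NTC z-scores to consensus classes.

    ``expressed`` is the per-gene macrophage expression gate (from
    :func:`lpscreen.expression.gene_expression_calls`); omit it to treat
    all genes as expressed.
    """
    th = thresholds or secondary.SecondaryThresholds()
    scored = normalize.normalize_dataset(ds, method="ntc")
    scored = primary.annotate_activity(scored)
    scores = secondary.vendor_scores(scored)
    called = secondary.call_secondary(scores, th, expressed)
    report = secondary.consensus_report(called)
    return SecondaryResult(scored, called, th, qc.qc_report(scored, qc_gate), report)
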