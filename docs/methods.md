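# Methods

This note documents the models, conventions and design choices behind
`lpscreen`, in the order data flows through the pipeline.

## Well-table dialect and plate layouts

Well tables are UTF-8 CSV with a mandatory header, one row per
(plate, well, readout). The six minimal identity fields (`PlateID`,
`Well`, `GeneSymbol`, `EntrezID`, `siRNAID`, `WellAnno`) follow the
public RNAi-record convention; raw data are `Rep1Value`/`Rep2Value`
(N:C ratio for the NF-κB readout, mean fluorescence for TNF-α) plus
per-replicate cell counts in the primary design. Well addresses are
canonically zero-padded (`A01`); the parser also accepts unpadded forms.
Row order is never meaningful, and empty wells carry no values and enter
no statistic.

The primary layout places samples in columns 3–22 (320 wells) and ten
control roles — lipid-only, NTC2, NTC5, Ppib, siGFP, no-LPS, Tlr4,
Myd88, Irak1, Ikbkg — in columns 1, 2, 23, 24, at least 3 wells each, in
a fixed documented order. The secondary layout leaves outer rows A, C, O,
P and columns 1, 2, 22–24 empty and reserves the central columns 11–13
for controls. The A/C asymmetry is kept exactly as deposited; a
symmetric A/B/O/P variant is selectable (`empty_rows=`). In the
secondary design the two NTC roles receive twice the per-role well count
(12 NTC wells per plate at the default of 3), because the NTC pool
anchors the secondary z-scores and the MAD of a small pool is noisy.

## Normalization

Raw values are divided by the per-plate, per-replicate, per-readout
median of the *sample* wells (percent-of-median), then standardized with
the robust z-score `z = (x − median)/(1.4826·MAD)` over the same sample
population. Controls are excluded from the reference population — they
are intentionally shifted and would bias both location and scale — but
receive z-scores like every non-empty well. Because the z-score is
invariant to any positive affine map of a plate, computing it on raw or
median-normalized values gives identical results; the median division is
kept as an explicitly inspectable intermediate (`NormRep*`).

Secondary plates are dominated by pre-selected hits, so the sample
median/MAD are not a null reference. There the z-score anchors to the
pooled NTC2+NTC5 wells ("fraction of negative control" normalization,
realized as an NTC-anchored robust z). The literal ratio
`x / median(NTC)` is stored alongside (`FractionNTCRep*`) for audit,
since a pure ratio is not a z-score and cannot be thresholded on the
same scale. A zero MAD falls back to the reference standard deviation
(n−1); a zero spread is a degenerate-plate error. Medians of even counts
are the mean of the central order statistics throughout.

Replicates are combined as the plain mean of the two z-scores. The
replicate p-value is a two-sided one-sample t-test of the two z-scores
against zero (1 degree of freedom) — minimal power, but kept exactly as
defined, with the degenerate cases pinned: equal replicates with nonzero
mean give p = 0, mean zero gives p = 1, a missing replicate gives no
p-value and a warning.

## QC gates

* **Replicate correlation**: Spearman rank correlation (average ranks on
  ties) over the common sample wells of a plate/readout, gated at 0.55;
  controls are excluded so designed extremes cannot inflate
  reproducibility. Constant vectors fail with an explicit reason.
* **Plate uniformity**: CV% = 100·sd/mean over like wells at one dose,
  with the sample (n−1) standard deviation — stated here because the
  convention is otherwise ambiguous.
* **Inter-plate fold shift**: |log2(day2/day1)| of the normalized
  mid-level signal, reported with the raw ratio alongside (the published
  "0.097 fold shift" convention is dimensionless and its exact formula
  unstated; the log2 shift is our documented reading).
* **siGFP knockdown**: 100·(1 − mean(siGFP)/mean(NTC)) over unstimulated
  wells imaged in the GFP channel.

All gates are pure functions of the data; rerunning QC reproduces the
report bit for bit.

## Primary hit calling

Wells with fewer than 50 cells in *both* replicates (strict comparison)
are viability casualties and classified into no group. The
positive-regulator threshold per readout is the median final z-score of
the Tlr4 control wells — the weakest of the four positive controls, so
the threshold sits at the edge of detectable pathway inhibition; on the
deposited data these medians are −1.56 (NF-κB) and −1.3 (TNF-α), which
are also the package defaults when no Tlr4 wells are available.
Negative-regulator thresholds are fixed configuration values (+3.3,
+3.0). Hit thresholds are inclusive (≤/≥).

The deposited records annotate each well with an activity score binned
from its final z-score, with *strict* inequalities and readout-specific
bins (primary NF-κB: ±1→25, >3.3/<−1.56→50, >4/<−2→75, >5/<−2.5→100;
primary TNF-α: ±1, 3/−1.3, 3.5/−1.5, 4/−2; secondary: ±1, ±2, ±3, ±4),
outcome "active"=2 iff score ≥ 50, and controls fixed at (0, 4). The
strict bins and inclusive hit thresholds coexist deliberately: a well at
exactly −1.56 is classified G1 yet scores 25. That asymmetry is in the
record schema itself and is preserved.

The knowledge-base triage that reduced the grouped genes to the
secondary-screen list is not reproducible from any record, so
`prioritize` implements a declared surrogate with the same bookkeeping:
a grouped gene is selected iff (replicate p ≤ 0.05 OR it appears in a
user-supplied annotation list) AND it is not in the canonical-pathway
list. Both lists are inputs; the bundled default canonical list is 48
TLR4/NF-κB pathway symbols and should be replaced with a real
knowledge-base export for any serious use.

## Secondary consensus calling

Per gene, readout and vendor, the median of six z-scores (3 siRNAs × 2
replicates) is taken; 4 or 5 values are tolerated with a warning (an
siRNA that failed QC), fewer are an insufficient-data flag. The four
medians are thresholded per vendor — Ambion −2, Qiagen −1, inclusive,
reflecting the consistently weaker Qiagen phenotypes — summed into
`SumAllhit`, and classified: `all4`, `three_of_four` (any three; the
records do not say whether the TNF flags were required, so we accept any
three), `both_tnf` (both TNF flags with fewer than three total). The
validated hit list is the union of the three classes. Genes with a
single vendor's siRNAs are scored but excluded from consensus, as are
genes without a macrophage expression call. Negative-regulator
consistency (both vendors above the mirrored thresholds) is counted and
reported but carries no class thresholds.

## Expression gate

A probe is detected when its detection p-value is strictly below 0.1; a
gene is expressed in macrophages when any of its probes is detected in
at least one of the four profiled conditions (±LPS in the reporter line
or in primary macrophages). Missing p-values count as not detected
(conservative), and the probe→gene collapse is any-probe, consistent
with the permissive at-least-one-condition rule. The gate only removes
genes before secondary calling; it never alters scores.

## Image quantification

Nuclei are segmented on the DNA-stain channel by Otsu threshold plus
8-connected components with a 20 px minimum area (the upstream
instrument software's method is proprietary and unspecified; Otsu is
standard and parameter-light). All morphology uses a 3×3 square
structuring element, one iteration per pixel: the nuclear core is the
nucleus eroded by 2 px; the cytosolic ring is `dilate(3) \ dilate(1)` —
a 2-px-wide ring starting 1 px outside the nucleus. Ring pixels falling
on any other nucleus are removed to prevent cross-cell contamination.
Background per channel is the *median* intensity outside all nuclei
dilated by a 4-px halo (median for robustness to stray bright pixels;
the halo keeps perinuclear cytoplasm out of the estimate), subtracted
with negatives clipped to zero. Per cell: N:C ratio = mean core green /
mean ring green; nuclear red = mean core red (the nuclear-core mean is
used for the red reporter as well; a whole-cell alternative is not
implemented). Cells with an empty core or ring, or zero cytosolic
signal, are discarded. Per well, cell measurements from all fields are
pooled and averaged unweighted (per-cell ratio averaging; whether the
upstream software averaged ratios or ratioed sums is unrecorded — this
choice is stated here and fixed). Touching nuclei are not split; no
illumination-gradient or exposure-time modeling is attempted.

These conventions make two exact invariances hold by construction:
adding a constant to any channel changes nothing (the median background
absorbs it), and scaling the green channel leaves N:C ratios unchanged.

## Synthetic screens

The generator's value model, per sample well, readout and replicate:

    value = plate_factor · baseline · max(1 + z_effect·s, 0.05) · exp(ε)

with `ε ~ N(0, σ)` lognormal well noise (`σ` set from `noise_cv`,
default 0.10), `plate_factor` lognormal across plate/replicate/readout
(`plate_cv`, default 0.10), and `s` the linear shift per z unit.
`z_effect` decomposes into a *planted* effect (positive regulators −3,
negative +3.5, on both readouts) and, for unplanted genes only, a
per-gene *background* effect shared between replicates,
`N(0, √ρ)` in z units with `ρ = replicate_correlation` (default 0.5).
The background is what produces replicate correlation among unscreened
genes — replicate noise itself is independent week to week; correlation
in real screens comes from reproducible biology. Planted regulators
carry their stated effect exactly so that recovery benchmarks measure
the pipeline, not an extra layer of effect dispersion.

In the primary design the sample-well robust SD combines background and
noise, so `s = noise_cv/√(1−ρ)` and a planted effect of −3 recovers a
robust z near −3 — attenuated by roughly 10% in practice because the MAD
is estimated on the hit-contaminated screen distribution, exactly as in
a real screen. In the secondary design z-scores anchor to the NTC wells,
whose spread is pure well noise, so `s = noise_cv`; secondary nulls are
exact nulls (their primary appearance was noise or off-target, and any
real residual biology would not be removable by sequence-independent
consensus anyway, so it is deliberately not simulated).

Controls are planted in z units per role (Tlr4 −1.56/−1.3,
Myd88 −2.66/−2.01, Irak1 −1.2/−1.0, Ikbkg −1.0/−0.9; all negative
controls 0), so the derived thresholds land near the deposited values.
siGFP and no-LPS wells carry GFP-channel intensities instead
(`gfp_baseline`, silencing fraction default 0.813). Cell counts are
Poisson–lognormal around 350 per well; a configurable lethal fraction
(default 1%) of genes draws counts around 20, failing the 50-cell floor
in both replicates.

Gene order is randomized across plates by the seed, with 307 genes per
plate by default — the mean fill of a 16,870-gene commercial library
shipped on 55 plates of 320 available sample wells — so a full-scale
simulation reproduces the 55-plate geometry with a partially filled last
plate. Secondary screens place 3 siRNAs per vendor per gene (1–3
Ambion, 4–6 Qiagen) in six separate plate regions; vendor potency
multiplies the planted effect (default Ambion 1.0, Qiagen 0.5, mirroring
the weaker Qiagen phenotypes), each siRNA draws a lognormal potency
jitter (CV 0.10), and off-target contamination adds a spurious −3 effect
per flagged siRNA (rate 0.05, or exactly k per null gene on request).
Everything is reproducible bit for bit from the seed.

What the generator deliberately does *not* emulate: spatial (edge/row)
plate effects, siRNA seed-family structure, readout-to-readout effect
correlation beyond the planted values, cell-count dependence of
intensity, or the deposited data's empirical value distributions.
Passing recovery tests therefore demonstrates correctness of the
analysis under the stated noise model, not performance on any real
screen.

The synthetic expression table gives expressed genes at least one probe
detected (p < 0.1) in at least one condition and non-expressed genes
none, so the expression gate can be exercised against exact truth.
Synthetic imaging fields place disc nuclei on a jittered grid with
guaranteed clearance, a cytoplasmic green annulus at level c, nuclear
green at c·t for planted translocation t, constant offset and Gaussian
read noise — the measured mean N:C ratio tracks t to well within 5%.

## Numerical conventions and degenerate inputs

* MAD scaling constant 1.4826 (normal consistency).
* Sample (n−1) standard deviation wherever an sd or CV is needed.
* Even-count medians: mean of the central pair.
* Float round-tripping: tables are parsed with exact `strtod` semantics
  so write→read→write is byte-identical.
* Blank images segment to zero nuclei (not an error); an all-covered
  field makes the background undefined (error); cells with empty
  core/ring are discarded silently.
* Non-positive plate medians, insufficient reference wells, and
  zero-spread plates raise typed errors rather than propagating NaNs.

## Problem sizes used by the test suite

Unit tests run on hand-built plates and screens of 100–600 genes; the
brute-force z-score cross-check uses 1,000 randomly drawn plates; the
recovery benchmarks use a 2,000-gene primary screen (100 planted
positive regulators) and a 600-gene secondary screen (30 planted hits,
one off-target siRNA per null gene); the dry-run test processes the full
16,870-gene, 55-plate, dual-readout geometry end to end. These sizes
give Monte-Carlo margins comfortably inside the asserted bounds while
keeping the default suite fast.

## Known limitations

* The prioritization rule is a surrogate for an irreproducible
  knowledge-base workflow; its bookkeeping matches, its gene content
  cannot.
* The secondary "fraction of negative control" z is a documented
  reading (NTC-anchored robust z) of an underspecified method; the raw
  NTC fraction is preserved for audit.
* The n=2 replicate t-test is honored as defined despite minimal power.
* No B-score/spatial polish, no touching-nuclei splitting, no raw
  microarray preprocessing — all outside the pipeline's scope.
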