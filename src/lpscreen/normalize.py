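"""Plate normalization, robust z-scores, and replicate aggregation.

Per-plate statistics are always computed from a declared reference
population and then applied to every non-empty well of the plate:

* percent-of-median normalization and the primary-screen robust z-score
  anchor to the *sample* wells (controls are intentionally shifted and
  would bias the location/scale estimates);
* the secondary-screen z-score anchors to the pooled non-targeting
  control (NTC) wells, because a plate dominated by pre-selected hits has
  a shifted sample median.

The robust z-score is ``(x - median) / (1.4826 * MAD)``, the usual
normal-consistent scaling of the median absolute deviation.  All
statistics are computed per plate, per replicate, per readout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import io
from .errors import ControlCoverageError, DegeneratePlateError, NormalizationError

MAD_SCALE = 1.4826
MIN_SAMPLE_WELLS = 8
MIN_NTC_WELLS = 6
_REPS = (1, 2)


def robust_location_scale(reference: np.ndarray) -> tuple[float, float]:
    """Median and 1.4826*MAD of the reference values.

    Falls back to the sample standard deviation when the MAD is zero
    (more than half the reference tied); raises
    :class:`DegeneratePlateError` when that is zero too.
    """
    ref = np.asarray(reference, dtype=float)
    ref = ref[np.isfinite(ref)]
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med)))
    if mad > 0:
        return med, MAD_SCALE * mad
    sd = float(np.std(ref, ddof=1)) if ref.size > 1 else 0.0
    if sd > 0:
        warnings.warn("MAD is zero; falling back to sample standard deviation")
        return med, sd
    raise DegeneratePlateError("reference values have zero spread")


def _group_iter(df: pd.DataFrame):
    return df.groupby(["PlateID", "Readout"], sort=False, observed=True)


def _reference_mask(df: pd.DataFrame, roles: tuple[str, ...]) -> pd.Series:
    return df["WellAnno"].isin(roles)


def plate_median_normalize(ds: io.ScreenDataset) -> io.ScreenDataset:
    """Divide each value by the per-plate median of the sample wells.

    Adds ``NormRep1``/``NormRep2`` to all non-empty wells.  Requires at
    least :data:`MIN_SAMPLE_WELLS` finite sample values per plate and a
    strictly positive median.
    """
    out = ds.copy()
    df = out.wells
    nonempty = df["WellAnno"] != io.EMPTY
    for rep in _REPS:
        src, dst = f"Rep{rep}Value", f"NormRep{rep}"
        df[dst] = np.nan
        for (plate, readout), idx in _group_iter(df).groups.items():
            sub = df.loc[idx]
            ref = sub.loc[sub["WellAnno"] == io.SAMPLE, src].to_numpy(dtype=float)
            ref = ref[np.isfinite(ref)]
            if ref.size < MIN_SAMPLE_WELLS:
                raise ControlCoverageError(
                    f"plate {plate}/{readout}: {ref.size} finite sample wells "
                    f"(need >= {MIN_SAMPLE_WELLS})"
                )
            med = float(np.median(ref))
            if med <= 0:
                raise NormalizationError(
                    f"plate {plate}/{readout} rep{rep}: non-positive sample median"
                )
            mask = nonempty.loc[idx]
            df.loc[idx[mask], dst] = df.loc[idx[mask], src] / med
    return out


def _zscore(
    ds: io.ScreenDataset,
    reference_roles: tuple[str, ...],
    min_reference: int,
    *,
    store_fraction: bool,
) -> io.ScreenDataset:
    out = ds.copy()
    df = out.wells
    use_norm = "NormRep1" in df.columns and df["NormRep1"].notna().any()
    nonempty = df["WellAnno"] != io.EMPTY
    for rep in _REPS:
        src = f"NormRep{rep}" if use_norm else f"Rep{rep}Value"
        df[f"ZscoreRep{rep}"] = np.nan
        if store_fraction:
            df[f"FractionNTCRep{rep}"] = np.nan
        for (plate, readout), idx in _group_iter(df).groups.items():
            sub = df.loc[idx]
            ref = sub.loc[
                _reference_mask(sub, reference_roles), src
            ].to_numpy(dtype=float)
            ref = ref[np.isfinite(ref)]
            if ref.size < min_reference:
                raise ControlCoverageError(
                    f"plate {plate}/{readout}: {ref.size} reference wells of "
                    f"{reference_roles} (need >= {min_reference})"
                )
            med, scale = robust_location_scale(ref)
            mask = nonempty.loc[idx]
            vals = df.loc[idx[mask], src]
            df.loc[idx[mask], f"ZscoreRep{rep}"] = (vals - med) / scale
            if store_fraction:
                if med <= 0:
                    raise NormalizationError(
                        f"plate {plate}/{readout} rep{rep}: non-positive NTC median"
                    )
                df.loc[idx[mask], f"FractionNTCRep{rep}"] = vals / med
    return out


def robust_zscore(ds: io.ScreenDataset) -> io.ScreenDataset:
    """Sample-anchored robust z-scores per plate/replicate/readout.

    Operates on ``NormRep*`` when present (the z-score is invariant to the
    per-plate median division, so raw values give identical results).
    Controls receive z-scores but do not define the statistics.
    """
    return _zscore(ds, (io.SAMPLE,), MIN_SAMPLE_WELLS, store_fraction=False)


def ntc_zscore(ds: io.ScreenDataset) -> io.ScreenDataset:
    """NTC-anchored robust z-scores (secondary-screen convention).

    Location and scale come from the pooled NTC2+NTC5 wells of each
    plate/replicate/readout.  The literal fraction-of-NTC ratio
    ``x / median_NTC`` is stored alongside in ``FractionNTCRep*`` for
    audit.
    """
    return _zscore(ds, io.NTC_ROLES, MIN_NTC_WELLS, store_fraction=True)


def replicate_pvalue(z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    """Two-sided one-sample t-test of the two replicate z-scores against 0.

    With n=2 the statistic has one degree of freedom; the test is kept
    exactly as defined despite its minimal power.  Degenerate cases:
    equal replicates with non-zero mean give p=0; mean zero gives p=1.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    mean = (z1 + z2) / 2.0
    sd = np.abs(z1 - z2) / np.sqrt(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(2.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=1)
    p = np.where(sd == 0, np.where(mean == 0, 1.0, 0.0), p)
    p = np.where(np.isnan(z1) | np.isnan(z2), np.nan, p)
    return p


def aggregate_replicates(ds: io.ScreenDataset) -> io.ScreenDataset:
    """Combine per-replicate z-scores into the final per-well score.

    ``Zscore`` is the mean of the two replicate z-scores; ``Pvalue`` the
    replicate t-test p-value.  A well with a single replicate keeps that
    replicate's z-score, is flagged by a warning, and gets no p-value.
    """
    out = ds.copy()
    df = out.wells
    if "ZscoreRep1" not in df.columns or "ZscoreRep2" not in df.columns:
        raise ValueError("run robust_zscore or ntc_zscore first")
    z1 = df["ZscoreRep1"].to_numpy(dtype=float)
    z2 = df["ZscoreRep2"].to_numpy(dtype=float)
    nonempty = (df["WellAnno"] != io.EMPTY).to_numpy()
    one_missing = nonempty & (np.isnan(z1) ^ np.isnan(z2))
    if one_missing.any():
        warnings.warn(
            f"{int(one_missing.sum())} well(s) have a single replicate; "
            "no p-value assigned"
        )
    df["Zscore"] = np.where(
        np.isnan(z1), z2, np.where(np.isnan(z2), z1, (z1 + z2) / 2.0)
    )
    df["Pvalue"] = replicate_pvalue(z1, z2)
    return out


def normalize_dataset(ds: io.ScreenDataset, method: str = "sample") -> io.ScreenDataset:
    """Full normalization chain: median-normalize, z-score, aggregate.

    ``method`` selects the z-score anchor: ``"sample"`` (primary screens)
    or ``"ntc"`` (secondary screens).
    """
    out = plate_median_normalize(ds)
    if method == "sample":
        out = robust_zscore(out)
    elif method == "ntc":
        out = ntc_zscore(out)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return aggregate_replicates(out)
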