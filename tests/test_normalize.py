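import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import make_plate
from lpscreen import io, normalize
from lpscreen.errors import ControlCoverageError, DegeneratePlateError, NormalizationError


class TestRobustLocationScale:
    def test_hand_computed_mad_example(self):
        # median 3, MAD = median{2,1,0,1,97} = 1 -> scale 1.4826
        med, scale = normalize.robust_location_scale([1, 2, 3, 4, 100])
        assert med == 3
        assert scale == pytest.approx(1.4826)
        assert (4 - med) / scale == pytest.approx(0.6745, abs=1e-4)

    def test_zero_mad_falls_back_to_sd(self):
        with pytest.warns(UserWarning, match="MAD is zero"):
            med, scale = normalize.robust_location_scale([5, 5, 5, 5, 5, 1, 9])
        assert med == 5
        assert scale == pytest.approx(np.std([5, 5, 5, 5, 5, 1, 9], ddof=1))

    def test_zero_spread_is_degenerate(self):
        with pytest.raises(DegeneratePlateError):
            normalize.robust_location_scale([2.0] * 10)


class TestPlateMedianNormalize:
    def test_constant_plate_normalizes_to_one(self):
        ds = make_plate([5.0] * 10)
        out = normalize.plate_median_normalize(ds)
        assert np.allclose(out.wells["NormRep1"], 1.0)

    def test_median_division(self):
        vals = [2.0, 4.0, 6.0] + [4.0] * 7  # median 4
        out = normalize.plate_median_normalize(make_plate(vals))
        got = out.wells["NormRep1"].iloc[:3].to_numpy()
        assert np.allclose(got, [0.5, 1.0, 1.5])

    def test_output_sample_median_is_one(self):
        rng = np.random.default_rng(1)
        ds = make_plate(list(rng.lognormal(0, 0.3, 96)))
        out = normalize.plate_median_normalize(ds)
        assert float(out.wells["NormRep1"].median()) == pytest.approx(1.0)

    def test_too_few_sample_wells_rejected(self):
        with pytest.raises(ControlCoverageError):
            normalize.plate_median_normalize(make_plate([1.0] * 5))

    def test_nonpositive_median_rejected(self):
        with pytest.raises(NormalizationError):
            normalize.plate_median_normalize(make_plate([-1.0] * 10))

    def test_controls_not_in_reference_but_normalized(self):
        ds = make_plate([2.0] * 10, extra_roles=[("Tlr4", 1.0)])
        out = normalize.plate_median_normalize(ds)
        tlr4 = out.wells[out.wells["WellAnno"] == "Tlr4"]
        assert float(tlr4["NormRep1"].iloc[0]) == pytest.approx(0.5)


class TestRobustZscore:
    def test_plate_median_maps_to_zero(self):
        rng = np.random.default_rng(2)
        vals = list(rng.normal(10, 1, 95)) + [0.0]
        vals[0] = float(np.median(vals))  # pin one well at the median
        ds = make_plate(vals)
        out = normalize.robust_zscore(ds)
        z = out.wells["ZscoreRep1"].to_numpy()
        assert abs(float(np.median(z[: len(vals)]))) < 1e-12

    def test_sample_population_median0_rsd1(self):
        rng = np.random.default_rng(3)
        ds = make_plate(list(rng.lognormal(0, 0.2, 307)))
        out = normalize.robust_zscore(normalize.plate_median_normalize(ds))
        z = out.wells.loc[out.wells["WellAnno"] == "sample", "ZscoreRep1"]
        assert float(z.median()) == pytest.approx(0.0, abs=1e-9)
        mad = float((z - z.median()).abs().median())
        assert 1.4826 * mad == pytest.approx(1.0, abs=1e-9)

    @given(
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
        seed=st.integers(0, 50),
    )
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(10, 2, 30)
        ds1 = make_plate(list(vals))
        ds2 = make_plate(list(a * vals + b))
        z1 = normalize.robust_zscore(ds1).wells["ZscoreRep1"].to_numpy()
        z2 = normalize.robust_zscore(ds2).wells["ZscoreRep1"].to_numpy()
        assert np.allclose(z1, z2, atol=1e-8)


class TestNtcZscore:
    def test_hand_computed_ntc_example(self):
        # NTC median 1.0, MAD 0.05 -> z(1.2) = 0.2/(1.4826*0.05)
        ds = make_plate(
            [1.2] + [1.0] * 9, ntc_values=[0.9, 1.0, 1.1, 1.0, 0.95, 1.05]
        )
        out = normalize.ntc_zscore(ds)
        z = float(out.wells["ZscoreRep1"].iloc[0])
        assert z == pytest.approx(0.2 / (1.4826 * 0.05), abs=1e-9)
        assert z == pytest.approx(2.698, abs=1e-3)
        frac = float(out.wells["FractionNTCRep1"].iloc[0])
        assert frac == pytest.approx(1.2)

    def test_ntc_median_maps_to_zero(self):
        ds = make_plate([2.0] * 10, ntc_values=[1.0, 1.1, 0.9, 1.0, 1.2, 0.8])
        out = normalize.ntc_zscore(ds)
        ntc = out.wells[out.wells["WellAnno"] == "NTC2"]
        assert sorted(ntc["ZscoreRep1"])[2] <= 0 <= sorted(ntc["ZscoreRep1"])[3]

    def test_too_few_ntc_wells_rejected(self):
        ds = make_plate([1.0] * 10, ntc_values=[1.0] * 5)
        with pytest.raises(ControlCoverageError):
            normalize.ntc_zscore(ds)

    def test_shift_invariance_of_ntc_z(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(5, 1, 12)
        ntc = rng.normal(5, 0.5, 8)
        z1 = normalize.ntc_zscore(make_plate(list(vals), ntc_values=list(ntc)))
        z2 = normalize.ntc_zscore(
            make_plate(list(vals + 3), ntc_values=list(ntc + 3))
        )
        assert np.allclose(
            z1.wells["ZscoreRep1"], z2.wells["ZscoreRep1"], atol=1e-9
        )


class TestAggregateReplicates:
    def _agg(self, z1, z2):
        ds = make_plate([(1.0, 1.0)] * 10)
        ds.wells["ZscoreRep1"] = z1
        ds.wells["ZscoreRep2"] = z2
        return normalize.aggregate_replicates(ds).wells.iloc[0]

    def test_equal_replicates_give_p_zero(self):
        row = self._agg(-2.0, -2.0)
        assert row["Zscore"] == -2.0 and row["Pvalue"] == 0.0

    def test_one_degree_of_freedom_closed_form(self):
        # t = -2 with df 1: p = 1 - (2/pi) arctan(2)
        row = self._agg(-3.0, -1.0)
        assert row["Zscore"] == -2.0
        assert row["Pvalue"] == pytest.approx(1 - (2 / np.pi) * np.arctan(2), abs=1e-12)
        assert row["Pvalue"] == pytest.approx(0.2952, abs=1e-4)

    def test_opposite_replicates_give_p_one(self):
        row = self._agg(1.0, -1.0)
        assert row["Zscore"] == 0.0 and row["Pvalue"] == 1.0

    def test_missing_replicate_keeps_single_z_without_p(self):
        ds = make_plate([(1.0, 1.0)] * 10)
        ds.wells["ZscoreRep1"] = 1.5
        ds.wells["ZscoreRep2"] = np.nan
        with pytest.warns(UserWarning, match="single replicate"):
            out = normalize.aggregate_replicates(ds)
        assert out.wells["Zscore"].iloc[0] == 1.5
        assert np.isnan(out.wells["Pvalue"].iloc[0])


def test_bruteforce_equivalence_on_random_plates():
    """Vectorized per-plate z-scores match an explicit per-plate loop."""
    rng = np.random.default_rng(9)
    n_plates, n_samples, n_ntc = 25, 60, 8
    frames = []
    for p in range(n_plates):
        ds = make_plate(
            list(rng.lognormal(0, 0.3, n_samples)),
            ntc_values=list(rng.lognormal(0, 0.1, n_ntc)),
            plate=f"P{p:03d}",
        )
        frames.append(ds.wells)
    ds = io.new_dataset(pd.concat(frames, ignore_index=True), "primary")
    out = normalize.robust_zscore(ds).wells
    for p, sub in out.groupby("PlateID"):
        samp = sub.loc[sub["WellAnno"] == "sample", "Rep1Value"].to_numpy()
        med = np.median(samp)
        scale = 1.4826 * np.median(np.abs(samp - med))
        expect = (sub["Rep1Value"].to_numpy() - med) / scale
        assert np.allclose(sub["ZscoreRep1"].to_numpy(), expect, atol=1e-9)
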