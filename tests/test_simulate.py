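import io as std_io

import numpy as np
import pandas as pd
import pytest

from lpscreen import io, normalize, pipeline, simulate


def table_bytes(ds):
    buf = std_io.StringIO()
    io.write_well_table(ds, buf)
    return buf.getvalue()


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = simulate.GeneratorConfig(n_genes=100, seed=7)
        a, _ = simulate.generate_screen(cfg)
        b, _ = simulate.generate_screen(cfg)
        assert table_bytes(a) == table_bytes(b)

    def test_different_seed_differs(self):
        a, _ = simulate.generate_screen(simulate.GeneratorConfig(n_genes=100, seed=7))
        b, _ = simulate.generate_screen(simulate.GeneratorConfig(n_genes=100, seed=8))
        assert table_bytes(a) != table_bytes(b)

    def test_secondary_deterministic(self):
        cfg = simulate.GeneratorConfig(n_genes=60, seed=5)
        genes = simulate.generate_gene_truth(cfg)
        truth = simulate.SyntheticTruth(genes, pd.DataFrame(), cfg)
        a, _ = simulate.generate_secondary(cfg, truth)
        b, _ = simulate.generate_secondary(cfg, truth)
        assert table_bytes(a) == table_bytes(b)


class TestGeneratedStructure:
    def test_validates_and_has_both_readouts(self, small_screen):
        ds, _ = small_screen
        ds.validate(strict=True)

    def test_control_layout_and_roles(self, small_screen):
        ds, truth = small_screen
        cfg = truth.config
        for role in io.CONTROL_ROLES:
            w = ds.wells_for_role(role)
            per_plate = w.groupby(["PlateID", "Readout"]).size()
            assert (per_plate == cfg.controls_per_role).all()
        ctrl = ds.wells_for_role(*io.CONTROL_ROLES)
        cols = ctrl["Well"].map(lambda a: io.parse_well(a)[1])
        assert set(cols) <= {1, 2, 23, 24}

    def test_truth_control_effects_signs(self, small_screen):
        _, truth = small_screen
        for role in ("Tlr4", "Myd88", "Irak1", "Ikbkg"):
            eff = truth.config.control_effects[role]
            assert eff[0] < 0 and eff[1] < 0
        for role in ("NTC2", "NTC5", "lipid", "Ppib"):
            assert truth.config.control_effects[role] == (0.0, 0.0)

    def test_lethal_fraction_fails_viability_floor(self):
        cfg = simulate.GeneratorConfig(n_genes=500, fraction_lethal=0.05, seed=11)
        ds, truth = simulate.generate_screen(cfg)
        lethal = set(truth.genes.loc[truth.genes["Lethal"], "GeneSymbol"])
        assert len(lethal) == 25
        w = ds.sample_wells()
        low = (w["Rep1CellCount"] < 50) & (w["Rep2CellCount"] < 50)
        flagged = set(w.loc[low, "GeneSymbol"])
        assert flagged == lethal

    def test_no_planted_positives_gives_null_rate_g1(self):
        cfg = simulate.GeneratorConfig(
            n_genes=614,
            fraction_positive_regulators=0.0,
            fraction_negative_regulators=0.0,
            seed=12,
        )
        ds, _ = simulate.generate_screen(cfg)
        res = pipeline.run_primary(ds)
        g1 = (res.gene_scores["Group"] == "G1").sum()
        # null false-positive rate at the default threshold: a few percent
        assert g1 / cfg.n_genes < 0.10

    def test_plate_factor_cancels_in_zscores(self):
        cfg = simulate.GeneratorConfig(n_genes=614, plate_cv=0.5, seed=13)
        ds, _ = simulate.generate_screen(cfg)
        out = normalize.normalize_dataset(ds, "sample")
        z = out.sample_wells().groupby("PlateID")["Zscore"].median()
        assert z.abs().max() < 0.2


@pytest.fixture(scope="module")
def sec():
    cfg = simulate.GeneratorConfig(
        n_genes=80, expressed_fraction=1.0, off_target_rate=0.1, seed=20
    )
    genes = simulate.generate_gene_truth(cfg)
    truth = simulate.SyntheticTruth(genes, pd.DataFrame(), cfg)
    return simulate.generate_secondary(cfg, truth)


class TestSecondaryStructure:

    def test_six_sirnas_two_vendors(self, sec):
        ds, truth = sec
        w = ds.sample_wells()
        per_gene = w[w["Readout"] == "NFKB"].groupby("GeneSymbol")["siRNAIndex"]
        assert (per_gene.nunique() == 6).all()
        assert set(truth.sirnas["Vendor"]) == {"Ambion", "Qiagen"}

    def test_same_gene_sirnas_in_distinct_wells(self, sec):
        ds, _ = sec
        w = ds.sample_wells()
        dup = w.duplicated(subset=["PlateID", "Well", "Readout"])
        assert not dup.any()
        one = w[(w["GeneSymbol"] == w["GeneSymbol"].iloc[0]) & (w["Readout"] == "NFKB")]
        assert one["Well"].nunique() == 6

    def test_vendor_potency_halves_qiagen_effect(self):
        cfg = simulate.GeneratorConfig(
            n_genes=100,
            fraction_positive_regulators=0.3,
            fraction_lethal=0.0,
            fraction_negative_regulators=0.0,
            expressed_fraction=1.0,
            off_target_rate=0.0,
            sirna_potency_cv=0.0,
            seed=21,
        )
        genes = simulate.generate_gene_truth(cfg)
        truth = simulate.SyntheticTruth(genes, pd.DataFrame(), cfg)
        ds, struth = simulate.generate_secondary(cfg, truth)
        res = pipeline.run_secondary(ds)
        hits = res.scores[res.scores["GeneSymbol"].isin(struth.genes.loc[
            struth.genes["PositiveRegulator"], "GeneSymbol"
        ])]
        ratio = (
            hits["MedianZ_Qiagen_NFKB"].median() / hits["MedianZ_Ambion_NFKB"].median()
        )
        assert ratio == pytest.approx(0.5, abs=0.12)

    def test_off_target_rate_one_on_null_single_sirna(self):
        """A single contaminated siRNA leaves the vendor median of six
        values essentially unmoved (median breakdown point)."""
        cfg = simulate.GeneratorConfig(
            n_genes=200,
            fraction_positive_regulators=0.0,
            fraction_negative_regulators=0.0,
            fraction_lethal=0.0,
            expressed_fraction=1.0,
            off_targets_per_null_gene=1,
            seed=22,
        )
        genes = simulate.generate_gene_truth(cfg)
        truth = simulate.SyntheticTruth(genes, pd.DataFrame(), cfg)
        ds, struth = simulate.generate_secondary(cfg, truth)
        res = pipeline.run_secondary(ds)
        assert (struth.sirnas.groupby("GeneSymbol")["OffTarget"].sum() == 1).all()
        meds = res.scores[
            ["MedianZ_Ambion_NFKB", "MedianZ_Qiagen_NFKB"]
        ].to_numpy()
        # clean-vendor medians stay near zero; contaminated ones shift < |effect|/2
        assert np.nanmedian(np.abs(meds)) < 1.0


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = simulate.GeneratorConfig(n_genes=123, noise_cv=0.2, seed=99)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = simulate.GeneratorConfig.from_yaml(p)
        assert back == cfg

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate.GeneratorConfig(fraction_positive_regulators=0.9,
                                     fraction_negative_regulators=0.2)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            simulate.GeneratorConfig(replicate_correlation=1.0)
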