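"""Synthetic dual-readout siRNA screens with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes so that every stage can be exercised against a known answer:

* 384-well plates with the standard control layouts, two replicates and
  two readouts (N:C translocation ratio; reporter fluorescence);
* multiplicative plate effects and per-well lognormal noise (screen
  readouts are positive intensities and ratios);
* a planted minority of positive and negative regulators whose effects
  are expressed as shifts in units of the per-replicate robust SD of the
  sample-well distribution, so a planted effect of -3 recovers a robust
  z-score near -3;
* a per-gene background effect, shared between replicates, that sets the
  replicate (Spearman) correlation among unscreened genes — planted
  regulators carry their stated effect exactly;
* control wells with their planted effects (the Tlr4 control is planted
  at the thresholds its median defines downstream);
* a secondary design with 6 siRNAs per gene from two vendors of unequal
  potency, per-siRNA off-target contamination, and same-gene siRNAs in
  separate plate regions;
* a configurable fraction of viability casualties (both replicate cell
  counts below 50).

Everything is reproducible from the configuration seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io
from .errors import LayoutCapacityError, OvercrowdedFieldError
from .images import ImageField

#: planted control shifts (z units): (NFKB, TNF).  The positive controls
#: span a range of phenotypic strength; the transfection and targeting
#: negatives are null by construction.
DEFAULT_CONTROL_EFFECTS: Mapping[str, tuple[float, float]] = {
    "lipid": (0.0, 0.0),
    "NTC2": (0.0, 0.0),
    "NTC5": (0.0, 0.0),
    "Ppib": (0.0, 0.0),
    "Tlr4": (-1.56, -1.3),
    "Myd88": (-2.66, -2.01),
    "Irak1": (-1.2, -1.0),
    "Ikbkg": (-1.0, -0.9),
}


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions for a synthetic screen.

    Effects are in robust-SD (z) units; noise and plate effects in CV
    terms.  ``genes_per_plate`` defaults to 307, the mean fill of a
    16,870-gene commercial library shipped on 55 plates of 320 sample
    wells.
    """

    n_genes: int = 2000
    design: str = "primary"
    genes_per_plate: int = 307
    controls_per_role: int = 6
    fraction_positive_regulators: float = 0.05
    fraction_negative_regulators: float = 0.02
    fraction_lethal: float = 0.01
    effect_positive: float = -3.0
    effect_negative: float = 3.5
    noise_cv: float = 0.10
    replicate_correlation: float = 0.5
    plate_cv: float = 0.10
    baseline_nfkb: float = 2.5
    baseline_tnf: float = 1000.0
    gfp_baseline: float = 500.0
    gfp_knockdown: float = 0.813
    mean_cells: float = 350.0
    lethal_mean_cells: float = 20.0
    cell_count_cv: float = 0.10
    expressed_fraction: float = 0.55
    off_target_rate: float = 0.05
    off_target_effect: float = -3.0
    off_targets_per_null_gene: int | None = None
    vendor_potency: tuple[float, float] = (1.0, 0.5)  # (Ambion, Qiagen)
    sirna_potency_cv: float = 0.10
    control_effects: dict = dataclasses.field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CONTROL_EFFECTS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_positive_regulators,
            self.fraction_negative_regulators,
            self.fraction_lethal,
        )
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("regulator/lethal fractions must lie in [0,1] and sum < 1")
        if self.noise_cv <= 0 or self.plate_cv < 0:
            raise ValueError("noise CV must be positive")
        if not 0 <= self.replicate_correlation < 1:
            raise ValueError("replicate_correlation must lie in [0, 1)")
        if self.design not in io.DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")

    # -- derived noise decomposition --------------------------------------
    @property
    def sigma_noise_log(self) -> float:
        """Lognormal sigma of the independent per-well noise."""
        return math.sqrt(math.log1p(self.noise_cv**2))

    @property
    def effect_scale(self) -> float:
        """Linear shift per z unit.

        Primary: the robust SD of the sample wells combines independent
        noise with the shared background, so one z unit is
        ``noise_cv / sqrt(1 - rho)``.  Secondary: z-scores anchor to the
        NTC wells whose spread is the pure well noise, so one z unit is
        ``noise_cv``.
        """
        if self.design == "primary":
            return self.noise_cv / math.sqrt(1.0 - self.replicate_correlation)
        return self.noise_cv

    @property
    def sigma_background_z(self) -> float:
        """SD of the shared per-gene background effect, in z units."""
        return math.sqrt(self.replicate_correlation)

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["vendor_potency"] = list(self.vendor_potency)
        d["control_effects"] = {k: list(v) for k, v in self.control_effects.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "vendor_potency" in d:
            d["vendor_potency"] = tuple(d["vendor_potency"])
        if "control_effects" in d:
            d["control_effects"] = {k: tuple(v) for k, v in d["control_effects"].items()}
        return cls(**d)


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth of one generated screen."""

    genes: pd.DataFrame
    plate_factors: pd.DataFrame
    config: GeneratorConfig
    sirnas: pd.DataFrame | None = None

    @property
    def positive_genes(self) -> list[str]:
        return sorted(self.genes.loc[self.genes["PositiveRegulator"], "GeneSymbol"])

    @property
    def negative_genes(self) -> list[str]:
        return sorted(self.genes.loc[self.genes["NegativeRegulator"], "GeneSymbol"])

    @property
    def null_genes(self) -> list[str]:
        null = ~(self.genes["PositiveRegulator"] | self.genes["NegativeRegulator"])
        return sorted(self.genes.loc[null, "GeneSymbol"])


def generate_gene_truth(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the per-gene ground truth (no wells yet).

    Planted regulators carry exactly the configured effect on both
    readouts; all other genes get an independent per-readout background
    effect shared between replicates (this is what produces replicate
    correlation among unscreened genes).  Regulator, lethal and
    expression assignments are disjoint draws from one seeded stream.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_genes
    perm = rng.permutation(n)
    n_pos = round(config.fraction_positive_regulators * n)
    n_neg = round(config.fraction_negative_regulators * n)
    n_let = round(config.fraction_lethal * n)
    pos = np.zeros(n, dtype=bool)
    neg = np.zeros(n, dtype=bool)
    lethal = np.zeros(n, dtype=bool)
    pos[perm[:n_pos]] = True
    neg[perm[n_pos : n_pos + n_neg]] = True
    lethal[perm[n_pos + n_neg : n_pos + n_neg + n_let]] = True

    bg = rng.normal(0.0, config.sigma_background_z, size=(n, 2))
    planted = np.zeros((n, 2))
    planted[pos] = config.effect_positive
    planted[neg] = config.effect_negative
    bg[pos | neg] = 0.0

    expressed = rng.random(n) < config.expressed_fraction
    order = rng.permutation(n)  # gene order across plates
    return pd.DataFrame(
        {
            "GeneSymbol": [f"Gene{i:05d}" for i in range(n)],
            "EntrezID": np.arange(100001, 100001 + n),
            "siRNAID": [f"SP-{i:05d}" for i in range(n)],
            "PlantedEffectNFKB": planted[:, 0],
            "PlantedEffectTNF": planted[:, 1],
            "BackgroundNFKB": bg[:, 0],
            "BackgroundTNF": bg[:, 1],
            "PositiveRegulator": pos,
            "NegativeRegulator": neg,
            "Lethal": lethal,
            "Expressed": expressed,
            "PlateOrder": order,
        }
    )


def _plate_factors(rng, plate_ids, plate_cv) -> pd.DataFrame:
    sigma = math.sqrt(math.log1p(plate_cv**2))
    rows = []
    for pid in plate_ids:
        for readout in io.READOUTS:
            for rep in (1, 2):
                rows.append(
                    {
                        "PlateID": pid,
                        "Readout": readout,
                        "Replicate": rep,
                        "Factor": float(np.exp(rng.normal(0.0, sigma))),
                    }
                )
    return pd.DataFrame(rows)


def _effect_factor(z_effect: np.ndarray, scale: float) -> np.ndarray:
    # a knockdown cannot push a positive readout below (a floor near) zero
    return np.clip(1.0 + np.asarray(z_effect, dtype=float) * scale, 0.05, None)


def _control_rows(
    config: GeneratorConfig,
    rng,
    layout: io.PlateLayout,
    plate_id: str,
    readout: str,
    base: float,
    factors: tuple[float, float],
):
    """Rows for the control and empty wells of one plate/readout."""
    rows = []
    r_idx = 0 if readout == "NFKB" else 1
    sn = config.sigma_noise_log
    for addr in sorted(layout.role_by_address):
        role = layout.role_by_address[addr]
        if role in (io.SAMPLE,):
            continue
        if role == io.EMPTY:
            rows.append(
                {
                    "PlateID": plate_id,
                    "Well": addr,
                    "WellAnno": role,
                    "Readout": readout,
                    "Rep1Value": np.nan,
                    "Rep2Value": np.nan,
                }
            )
            continue
        if role == "siGFP":
            level = config.gfp_baseline * (1.0 - config.gfp_knockdown)
        elif role == "noLPS":
            level = config.gfp_baseline
        else:
            eff = config.control_effects.get(role, (0.0, 0.0))[r_idx]
            level = base * float(_effect_factor(np.array(eff), config.effect_scale))
        v1 = level * factors[0] * float(np.exp(rng.normal(0.0, sn)))
        v2 = level * factors[1] * float(np.exp(rng.normal(0.0, sn)))
        row = {
            "PlateID": plate_id,
            "Well": addr,
            "WellAnno": role,
            "Readout": readout,
            "Rep1Value": v1,
            "Rep2Value": v2,
        }
        rows.append(row)
    return rows


def _draw_counts(config: GeneratorConfig, rng, mean: np.ndarray) -> np.ndarray:
    lam = mean * np.exp(rng.normal(0.0, config.cell_count_cv, size=mean.shape))
    return rng.poisson(lam)


def generate_screen(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[io.ScreenDataset, SyntheticTruth]:
    """Generate a primary (SMARTpool) screen with planted truth.

    Well value = plate factor x baseline x (1 + effect x scale) x
    lognormal noise; replicates share the gene effects but draw
    independent noise.  Cell counts make the configured lethal fraction
    fail the 50-cell viability floor in both replicates.
    """
    if config.design != "primary":
        raise ValueError("generate_screen builds primary designs; see generate_secondary")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = generate_gene_truth(config, seed=int(rng.integers(2**31)))
    layout = io.standard_layout("primary", config.controls_per_role)
    sample_addrs = layout.sample_addresses
    gpp = min(config.genes_per_plate, len(sample_addrs))
    n_plates = math.ceil(config.n_genes / gpp)
    plate_ids = [f"P{i + 1:02d}" for i in range(n_plates)]
    pf = _plate_factors(rng, plate_ids, config.plate_cv)
    pf_map = {
        (r.PlateID, r.Readout, r.Replicate): r.Factor for r in pf.itertuples()
    }

    order = genes["PlateOrder"].to_numpy().argsort()
    genes = genes.copy()
    gene_plate = np.empty(config.n_genes, dtype=object)
    gene_well = np.empty(config.n_genes, dtype=object)
    for slot, gi in enumerate(order):
        gene_plate[gi] = plate_ids[slot // gpp]
        gene_well[gi] = sample_addrs[slot % gpp]
    genes["PlateID"] = gene_plate
    genes["Well"] = gene_well

    eff = {
        "NFKB": genes["PlantedEffectNFKB"].to_numpy()
        + genes["BackgroundNFKB"].to_numpy(),
        "TNF": genes["PlantedEffectTNF"].to_numpy() + genes["BackgroundTNF"].to_numpy(),
    }
    base = {"NFKB": config.baseline_nfkb, "TNF": config.baseline_tnf}
    sn = config.sigma_noise_log
    lethal = genes["Lethal"].to_numpy()
    count_mean = np.where(lethal, config.lethal_mean_cells, config.mean_cells)

    blocks = []
    for readout in io.READOUTS:
        f = _effect_factor(eff[readout], config.effect_scale)
        factors = np.array(
            [
                [pf_map[(p, readout, 1)], pf_map[(p, readout, 2)]]
                for p in genes["PlateID"]
            ]
        )
        noise = np.exp(rng.normal(0.0, sn, size=(config.n_genes, 2)))
        vals = base[readout] * f[:, None] * factors * noise
        counts = _draw_counts(
            config, rng, np.repeat(count_mean[:, None], 2, axis=1)
        )
        blocks.append(
            pd.DataFrame(
                {
                    "PlateID": genes["PlateID"],
                    "Well": genes["Well"],
                    "WellAnno": io.SAMPLE,
                    "GeneSymbol": genes["GeneSymbol"],
                    "EntrezID": genes["EntrezID"],
                    "siRNAID": genes["siRNAID"],
                    "Readout": readout,
                    "Rep1Value": vals[:, 0],
                    "Rep2Value": vals[:, 1],
                    "Rep1CellCount": counts[:, 0],
                    "Rep2CellCount": counts[:, 1],
                }
            )
        )
        # control wells, unused sample wells, and reserved empties
        used = {
            (p, w)
            for p, w in zip(genes["PlateID"], genes["Well"])
        }
        ctrl_rows = []
        for i, pid in enumerate(plate_ids):
            factors_pr = (pf_map[(pid, readout, 1)], pf_map[(pid, readout, 2)])
            ctrl_rows.extend(
                _control_rows(
                    config, rng, layout, pid, readout, base[readout], factors_pr
                )
            )
            for addr in sample_addrs:
                if (pid, addr) not in used:
                    ctrl_rows.append(
                        {
                            "PlateID": pid,
                            "Well": addr,
                            "WellAnno": io.EMPTY,
                            "Readout": readout,
                            "Rep1Value": np.nan,
                            "Rep2Value": np.nan,
                        }
                    )
        ctrl = pd.DataFrame(ctrl_rows)
        nonempty = ctrl["WellAnno"] != io.EMPTY
        ctrl_counts = _draw_counts(
            config, rng, np.full((int(nonempty.sum()), 2), config.mean_cells)
        )
        ctrl["Rep1CellCount"] = pd.NA
        ctrl["Rep2CellCount"] = pd.NA
        ctrl.loc[nonempty, "Rep1CellCount"] = ctrl_counts[:, 0]
        ctrl.loc[nonempty, "Rep2CellCount"] = ctrl_counts[:, 1]
        blocks.append(ctrl)

    wells = pd.concat(blocks, ignore_index=True)
    ds = io.new_dataset(wells, "primary")
    ds.wells = ds.canonical()
    truth = SyntheticTruth(
        genes=genes.drop(columns=["PlateOrder"]), plate_factors=pf, config=config
    )
    return ds, truth


# ---------------------------------------------------------------------------
# secondary screens


def generate_secondary(
    config: GeneratorConfig,
    primary_truth: SyntheticTruth,
    selected_genes: Sequence[str] | None = None,
    seed: int | None = None,
) -> tuple[io.ScreenDataset, SyntheticTruth]:
    """Generate a two-vendor 6-siRNA validation screen for selected genes.

    Each gene receives 3 Ambion (siRNA 1-3) and 3 Qiagen (siRNA 4-6)
    sequences.  The vendor potency multiplies the gene's planted effect
    (default Qiagen 0.5, mirroring its consistently weaker phenotypes);
    each siRNA additionally draws a lognormal potency jitter and an
    independent off-target flag that adds a spurious seed-driven effect
    on both readouts.  Same-gene siRNAs occupy the six separate regions
    of the secondary layout.  Gene effects come from the primary truth's
    planted effects; genes without a planted effect are true nulls here
    (their primary appearance, if any, was noise or off-target).
    """
    cfg = dataclasses.replace(config, design="secondary", controls_per_role=3)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pg = primary_truth.genes.set_index("GeneSymbol")
    if selected_genes is None:
        selected_genes = list(pg.index)
    missing = [g for g in selected_genes if g not in pg.index]
    if missing:
        raise ValueError(f"genes not in primary truth: {missing[:5]}")

    layout = io.standard_layout("secondary", cfg.controls_per_role)
    sample_addrs = layout.sample_addresses
    n_regions = 6
    per_region = len(sample_addrs) // n_regions
    regions = [
        sample_addrs[r * per_region : (r + 1) * per_region] for r in range(n_regions)
    ]
    n_sel = len(selected_genes)
    n_plates = math.ceil(n_sel / per_region)
    plate_ids = [f"S{i + 1:02d}" for i in range(n_plates)]
    pf = _plate_factors(rng, plate_ids, cfg.plate_cv)
    pf_map = {(r.PlateID, r.Readout, r.Replicate): r.Factor for r in pf.itertuples()}

    planted = np.array(
        [
            (pg.at[g, "PlantedEffectNFKB"], pg.at[g, "PlantedEffectTNF"])
            for g in selected_genes
        ]
    )
    entrez = np.array([pg.at[g, "EntrezID"] for g in selected_genes])
    expressed = np.array([bool(pg.at[g, "Expressed"]) for g in selected_genes])

    potency = np.exp(
        rng.normal(0.0, math.sqrt(math.log1p(cfg.sirna_potency_cv**2)), (n_sel, 6))
    )
    vendor_mult = np.array(
        [cfg.vendor_potency[0]] * 3 + [cfg.vendor_potency[1]] * 3
    )
    if cfg.off_targets_per_null_gene is not None:
        off = np.zeros((n_sel, 6), dtype=bool)
        null_gene = (planted == 0).all(axis=1)
        k = cfg.off_targets_per_null_gene
        for i in np.flatnonzero(null_gene):
            off[i, rng.choice(6, size=k, replace=False)] = True
    else:
        off = rng.random((n_sel, 6)) < cfg.off_target_rate

    # per-siRNA total effect per readout
    eff = planted[:, None, :] * (vendor_mult * potency)[:, :, None]
    eff = eff + np.where(off[:, :, None], cfg.off_target_effect, 0.0)

    base = {"NFKB": cfg.baseline_nfkb, "TNF": cfg.baseline_tnf}
    sn = cfg.sigma_noise_log
    scale = cfg.effect_scale

    sirna_rows = []
    well_rows = []
    for gi, gene in enumerate(selected_genes):
        plate = plate_ids[gi // per_region]
        slot = gi % per_region
        for j in range(6):
            addr = regions[j][slot]
            vendor = "Ambion" if j < 3 else "Qiagen"
            sirna_id = f"{vendor[0]}{gi:05d}-{j + 1}"
            sirna_rows.append(
                {
                    "GeneSymbol": gene,
                    "EntrezID": int(entrez[gi]),
                    "siRNAID": sirna_id,
                    "siRNAIndex": j + 1,
                    "Vendor": vendor,
                    "PlateID": plate,
                    "Well": addr,
                    "Potency": float(vendor_mult[j] * potency[gi, j]),
                    "OffTarget": bool(off[gi, j]),
                    "EffectNFKB": float(eff[gi, j, 0]),
                    "EffectTNF": float(eff[gi, j, 1]),
                }
            )
            for r_idx, readout in enumerate(io.READOUTS):
                f = float(_effect_factor(np.array(eff[gi, j, r_idx]), scale))
                v = [
                    base[readout]
                    * f
                    * pf_map[(plate, readout, rep)]
                    * float(np.exp(rng.normal(0.0, sn)))
                    for rep in (1, 2)
                ]
                well_rows.append(
                    {
                        "PlateID": plate,
                        "Well": addr,
                        "WellAnno": io.SAMPLE,
                        "GeneSymbol": gene,
                        "EntrezID": int(entrez[gi]),
                        "siRNAID": sirna_id,
                        "siRNAIndex": j + 1,
                        "Readout": readout,
                        "Rep1Value": v[0],
                        "Rep2Value": v[1],
                    }
                )

    used = {(r["PlateID"], r["Well"]) for r in well_rows}
    for readout in io.READOUTS:
        for pid in plate_ids:
            factors_pr = (pf_map[(pid, readout, 1)], pf_map[(pid, readout, 2)])
            well_rows.extend(
                _control_rows(
                    cfg, rng, layout, pid, readout, base[readout], factors_pr
                )
            )
            for addr in sample_addrs:
                if (pid, addr) not in used:
                    well_rows.append(
                        {
                            "PlateID": pid,
                            "Well": addr,
                            "WellAnno": io.EMPTY,
                            "Readout": readout,
                            "Rep1Value": np.nan,
                            "Rep2Value": np.nan,
                        }
                    )

    ds = io.new_dataset(pd.DataFrame(well_rows), "secondary")
    ds.wells = ds.canonical()
    genes_df = pd.DataFrame(
        {
            "GeneSymbol": list(selected_genes),
            "EntrezID": entrez.astype(int),
            "PlantedEffectNFKB": planted[:, 0],
            "PlantedEffectTNF": planted[:, 1],
            "PositiveRegulator": (planted < 0).any(axis=1),
            "NegativeRegulator": (planted > 0).any(axis=1),
            "Expressed": expressed,
        }
    )
    truth = SyntheticTruth(
        genes=genes_df,
        plate_factors=pf,
        config=cfg,
        sirnas=pd.DataFrame(sirna_rows),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# expression tables


def generate_expression_table(
    genes: pd.DataFrame, seed: int = 0, max_probes_per_gene: int = 2
) -> pd.DataFrame:
    """Synthetic processed microarray table consistent with gene truth.

    Expressed genes get at least one probe detected (detection p < 0.1)
    in at least one of the four conditions; non-expressed genes have all
    probes undetected everywhere.  Log2 signals are drawn high for
    detected probes and near background otherwise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes.itertuples():
        n_probes = 1 + int(rng.integers(0, max_probes_per_gene))
        hot_probe = int(rng.integers(0, n_probes))
        for p in range(n_probes):
            row = {"ProbeID": f"ILMN_{g.Index:05d}_{p}", "GeneSymbol": g.GeneSymbol}
            probe_expressed = bool(g.Expressed) and p == hot_probe
            hot_cond = int(rng.integers(0, 4))
            for c, cond in enumerate(
                ("RAWG9_LPS", "RAWG9_ctrl", "BMDM_LPS", "BMDM_ctrl")
            ):
                detected = probe_expressed and (c == hot_cond or rng.random() < 0.6)
                if detected:
                    pval = float(rng.uniform(0.0, 0.08))
                    sig = float(rng.uniform(7.0, 14.0))
                else:
                    pval = float(rng.uniform(0.12, 1.0))
                    sig = float(rng.uniform(4.0, 6.5))
                row[f"Log2Signal_{cond}"] = sig
                row[f"DetectionP_{cond}"] = pval
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# image fields


def generate_image_field(
    n_cells: int = 40,
    translocation: float = 1.0,
    red_level: float = 60.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (512, 512),
    nucleus_radius: int = 7,
    cyto_width: int = 6,
    cyto_level: float = 40.0,
    nuclear_stain_level: float = 400.0,
    background: float = 50.0,
    clearance: int = 6,
) -> tuple[ImageField, pd.DataFrame]:
    """Synthetic imaging field with planted per-cell translocation.

    Nuclei are bright discs on the DNA-stain channel.  The green channel
    carries a cytoplasmic disc at ``cyto_level`` with the nuclear region
    at ``cyto_level * translocation``; the red channel a nuclear disc at
    ``red_level``.  A constant offset and Gaussian read noise are added
    to every channel.  Cells sit on a jittered grid that guarantees well
    over the required 3 px of clearance between nuclei.
    """
    rng = np.random.default_rng(seed)
    cell_r = nucleus_radius + cyto_width
    pitch = 2 * cell_r + clearance
    ny, nx = shape[0] // pitch, shape[1] // pitch
    if n_cells > ny * nx:
        raise OvercrowdedFieldError(
            f"{n_cells} cells do not fit: capacity {ny * nx} at pitch {pitch}"
        )
    stain = np.zeros(shape)
    green = np.zeros(shape)
    red = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    jitter = max(clearance // 2 - 1, 0)
    centers = []
    slots = [(i, j) for i in range(ny) for j in range(nx)]
    for i, j in slots[:n_cells]:
        cy = i * pitch + cell_r + clearance // 2 + int(rng.integers(-jitter, jitter + 1))
        cx = j * pitch + cell_r + clearance // 2 + int(rng.integers(-jitter, jitter + 1))
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nucleus = d2 <= nucleus_radius**2
        cell = d2 <= cell_r**2
        stain[nucleus] = nuclear_stain_level
        green[cell & ~nucleus] = cyto_level
        green[nucleus] = cyto_level * translocation
        red[nucleus] = red_level
        centers.append({"y": cy, "x": cx, "translocation": translocation})
    for chan in (stain, green, red):
        chan += background
        chan += rng.normal(0.0, noise_sd, size=shape)
        np.clip(chan, 0.0, None, out=chan)
    field = ImageField(nuclear_stain=stain, green=green, red=red)
    return field, pd.DataFrame(centers)
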