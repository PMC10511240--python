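"""Synthetic fixtures with known ground truth for every stage of the analysis.

Three generators live here:

* :func:`generate_ms_fixture` — CE-MS MRM peak tables emulating perchloric
  acid extracts of 1e7 yeast cells (20 uL resuspension, 15 uL of it spiked
  with the 13C internal-standard mixture), with species-specific extraction
  losses and multiplicative replicate noise on the biological amounts.
* :func:`generate_image_fixture` — multi-channel microscope fields
  (bright-field-like, nuclear marker, reporter) of non-overlapping cells
  with known per-cell nuclear:cytosolic reporter ratios and label-image
  ground truth.
* :func:`generate_relocation_timecourse` — paired 5-IP7 decay and Pho4
  nuclear-relocation series for threshold inference.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .ms_quant import (
    DEFAULT_MIGRATION_TIMES,
    SPECIES_1IP7,
    SPECIES_5IP7,
    SPECIES_IP6,
    SPECIES_IP8,
    PYROPHOSPHATES,
    SpikeMix,
    TransitionTable,
    VolumeModel,
)

__all__ = [
    "FixtureScenario",
    "ImageFieldSpec",
    "FieldFixture",
    "generate_ms_fixture",
    "generate_image_fixture",
    "generate_relocation_timecourse",
    "write_ms_fixture",
    "write_image_fixture",
    "wt_replete_scenario",
    "mutants_replete_scenario",
    "wt_starvation_scenario",
    "vip1d_starvation_scenario",
    "conc_um_to_zmol",
    "VIP1D_DECAY_C0_UM",
    "VIP1D_DECAY_K_PER_MIN",
    "RELOC_BASELINE",
    "RELOC_AMPLITUDE",
    "RELOC_THALF_VIP1D_MIN",
    "RELOC_THALF_WT_MIN",
    "RELOC_WIDTH_MIN",
]

STRAINS = ("wt", "vip1d", "kcs1d", "ddp1d", "siw14d", "vip1d_kcs1d")

DEFAULT_LOSS_FACTORS = {SPECIES_1IP7: 0.89, SPECIES_5IP7: 0.90, SPECIES_IP8: 0.75}

# Kinetic ground truth of the vip1d-like fixture: 20-fold elevated 5-IP7
# decaying exponentially, crossing 5 uM at t = 60 min, where the Pho4
# relocation logistic has its half-maximum.
VIP1D_DECAY_C0_UM = 14.0
VIP1D_DECAY_K_PER_MIN = 0.01716
RELOC_BASELINE = 0.45
RELOC_AMPLITUDE = 1.35
RELOC_THALF_VIP1D_MIN = 60.0
RELOC_THALF_WT_MIN = 10.0
RELOC_WIDTH_MIN = 12.0

_V_ACC_FL = VolumeModel().v_accessible_fl  # 34.44 fL


def conc_um_to_zmol(conc_um: float) -> float:
    """Per-cell amount (zmol) that yields a target cytosolic concentration."""
    return conc_um * _V_ACC_FL


# Replete steady-state cytosolic concentrations (uM) per strain/species.
# wt values are the measured replete levels; mutant values encode the
# fold-changes seen in phosphatase/kinase knockouts (20x 5-IP7 in vip1d,
# 10x 1-IP7 in ddp1d, 5x 5-IP7 in siw14d, near-complete losses in kcs1d
# and the double mutant).
_REPLETE_CONC_UM: dict[str, dict[str, float]] = {
    "wt": {SPECIES_1IP7: 0.5, SPECIES_5IP7: 0.7, SPECIES_IP8: 0.3},
    "vip1d": {SPECIES_1IP7: 0.05, SPECIES_5IP7: 14.0, SPECIES_IP8: 0.075},
    "kcs1d": {SPECIES_1IP7: 0.2, SPECIES_5IP7: 0.0, SPECIES_IP8: 0.0},
    "ddp1d": {SPECIES_1IP7: 5.0, SPECIES_5IP7: 0.7, SPECIES_IP8: 0.3},
    "siw14d": {SPECIES_1IP7: 0.5, SPECIES_5IP7: 3.5, SPECIES_IP8: 0.3},
    "vip1d_kcs1d": {SPECIES_1IP7: 0.02, SPECIES_5IP7: 0.0, SPECIES_IP8: 0.0},
}

# Fractional declines of the wt pools after 30 min of Pi withdrawal, and the
# fraction of 5-IP7 remaining after 4 h (the other species are depleted).
_WT_DECLINE_30MIN = {SPECIES_1IP7: 0.47, SPECIES_5IP7: 0.40, SPECIES_IP8: 0.75}
_WT_REMAINING_240MIN = {SPECIES_1IP7: 0.0, SPECIES_5IP7: 0.03, SPECIES_IP8: 0.0}


@dataclass(frozen=True)
class FixtureScenario:
    """Recipe for one synthetic CE-MS experiment.

    ``truth_amounts`` maps (strain, species, time_min) to the true per-cell
    amount in zmol.  ``loss_factors`` are the extraction survival fractions
    the generator applies (and the pipeline's recovery correction undoes).
    Sample bookkeeping defaults follow the assay: 1 mL of culture at 1e7
    cells/mL, extract resuspended in 20 uL, 15 uL of which is spiked.
    """

    name: str
    strains: tuple[str, ...]
    timepoints: tuple[float, ...]
    truth_amounts: dict[tuple[str, str, float], float]
    loss_factors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOSS_FACTORS))
    replicate_cv: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    n_cells: float = 1e7
    extract_volume_ul: float = 20.0
    aliquot_volume_ul: float = 15.0
    spike: SpikeMix = field(default_factory=SpikeMix)
    response_per_fmol: float = 50.0
    mt_jitter_sd_min: float = 0.05
    mt_sample_shift_sd_min: float = 0.1

    def __post_init__(self) -> None:
        for strain in self.strains:
            if strain not in STRAINS:
                raise ValueError(f"unknown strain label {strain!r}")
        for (strain, species, _), amt in self.truth_amounts.items():
            if strain not in self.strains:
                raise ValueError(f"truth amount for undeclared strain {strain!r}")
            if species not in PYROPHOSPHATES:
                raise ValueError(f"unknown species label {species!r}")
            if amt < 0:
                raise ValueError("truth amounts must be >= 0")
        for sp, f in self.loss_factors.items():
            if not 0.0 < f <= 1.0:
                raise ValueError(f"loss factor for {sp} must be in (0, 1]")
        if self.replicate_cv < 0:
            raise ValueError("replicate CV must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _scenario_from_conc(
    name: str,
    conc_by_strain_time: dict[str, dict[float, dict[str, float]]],
    **kwargs,
) -> FixtureScenario:
    strains = tuple(conc_by_strain_time)
    times = tuple(sorted({t for d in conc_by_strain_time.values() for t in d}))
    truth = {
        (strain, sp, t): conc_um_to_zmol(c)
        for strain, by_time in conc_by_strain_time.items()
        for t, by_sp in by_time.items()
        for sp, c in by_sp.items()
    }
    return FixtureScenario(name=name, strains=strains, timepoints=times, truth_amounts=truth, **kwargs)


def wt_replete_scenario(**kwargs) -> FixtureScenario:
    """Logarithmic growth on Pi-replete medium: 0.5/0.7/0.3 uM ground truth."""
    return _scenario_from_conc("wt_replete", {"wt": {0.0: _REPLETE_CONC_UM["wt"]}}, **kwargs)


def mutants_replete_scenario(**kwargs) -> FixtureScenario:
    """All six strains under Pi-replete conditions (mutant fold-changes)."""
    return _scenario_from_conc(
        "mutants_replete", {s: {0.0: _REPLETE_CONC_UM[s]} for s in STRAINS}, **kwargs
    )


def wt_starvation_scenario(**kwargs) -> FixtureScenario:
    """wt Pi-starvation time course (0 / 30 / 240 min)."""
    c0 = _REPLETE_CONC_UM["wt"]
    by_time = {
        0.0: dict(c0),
        30.0: {sp: c0[sp] * (1.0 - _WT_DECLINE_30MIN[sp]) for sp in c0},
        240.0: {sp: c0[sp] * _WT_REMAINING_240MIN[sp] for sp in c0},
    }
    return _scenario_from_conc("wt_starvation", {"wt": by_time}, **kwargs)


def vip1d_starvation_scenario(
    timepoints: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0),
    **kwargs,
) -> FixtureScenario:
    """vip1d 5-IP7 depletion sampled from the exponential ground truth."""
    by_time = {
        float(t): {SPECIES_5IP7: VIP1D_DECAY_C0_UM * float(np.exp(-VIP1D_DECAY_K_PER_MIN * t))}
        for t in timepoints
    }
    return _scenario_from_conc("vip1d_starvation", {"vip1d": by_time}, **kwargs)


def generate_ms_fixture(scenario: FixtureScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit an MRM peak table plus the ground-truth table for a scenario.

    Per sample, each species' analyte amount follows

        truth_zmol x n_cells x loss x (aliquot/extract) x lognormal noise

    converted to a peak area via a fixed detector response.  The 13C
    standard rows carry exactly the spike-mix amounts (noise-free, same
    response), so the isotope-dilution step stays exact.  Analyte peaks
    co-migrate with their standards up to a per-sample electrophoretic
    shift plus small per-peak jitter.
    """
    rng = np.random.default_rng(scenario.seed)
    tt = TransitionTable()
    sigma = float(np.sqrt(np.log1p(scenario.replicate_cv**2)))
    aliquot_frac = scenario.aliquot_volume_ul / scenario.extract_volume_ul

    peak_rows = []
    for strain in scenario.strains:
        for t in scenario.timepoints:
            if not any((strain, sp, t) in scenario.truth_amounts for sp in PYROPHOSPHATES):
                continue
            for rep in range(1, scenario.n_replicates + 1):
                sample_id = f"{strain}_t{t:g}_r{rep}"
                shift = rng.normal(0.0, scenario.mt_sample_shift_sd_min)
                # 13C standards: one noise-free row per spiked species
                for sp in scenario.spike.species:
                    pre, prod = tt.mz_pair(sp, "13C")
                    peak_rows.append(
                        {
                            "sample_id": sample_id,
                            "strain": strain,
                            "time_min": t,
                            "replicate": rep,
                            "precursor_mz": pre,
                            "product_mz": prod,
                            "migration_time_min": round(DEFAULT_MIGRATION_TIMES[sp] + shift, 4),
                            "peak_area": round(
                                scenario.spike.moles_fmol(sp) * scenario.response_per_fmol, 6
                            ),
                            "label": "13C",
                        }
                    )
                # 12C analytes
                for sp in PYROPHOSPHATES:
                    truth = scenario.truth_amounts.get((strain, sp, t), 0.0)
                    # mean-preserving lognormal: E[factor] = 1
                    factor = (
                        rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
                    )
                    jitter = rng.normal(0.0, scenario.mt_jitter_sd_min)
                    if truth <= 0:
                        continue
                    fmol_total = truth * factor * scenario.n_cells * 1e-6  # zmol -> fmol
                    fmol_aliquot = fmol_total * scenario.loss_factors[sp] * aliquot_frac
                    pre, prod = tt.mz_pair(sp, "12C")
                    peak_rows.append(
                        {
                            "sample_id": sample_id,
                            "strain": strain,
                            "time_min": t,
                            "replicate": rep,
                            "precursor_mz": pre,
                            "product_mz": prod,
                            "migration_time_min": round(
                                DEFAULT_MIGRATION_TIMES[sp] + shift + jitter, 4
                            ),
                            "peak_area": round(fmol_aliquot * scenario.response_per_fmol, 6),
                            "label": "12C",
                        }
                    )

    peaks = pd.DataFrame(peak_rows)
    truth = pd.DataFrame(
        [
            {"strain": strain, "time_min": t, "species": sp, "zmol_per_cell": amt}
            for (strain, sp, t), amt in sorted(scenario.truth_amounts.items())
        ]
    )
    return peaks, truth


def write_ms_fixture(scenario: FixtureScenario, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peaks, truth = generate_ms_fixture(scenario)
    p = out / f"{scenario.name}_peaks.csv"
    q = out / f"{scenario.name}_truth.csv"
    peaks.to_csv(p, index=False)
    truth.to_csv(q, index=False)
    return p, q


# ---------------------------------------------------------------------------
# Microscopy fixtures


@dataclass(frozen=True)
class ImageFieldSpec:
    """Recipe for one synthetic multi-channel field.

    Intensities are in arbitrary 16-bit camera counts.  Cells are discs
    with a darker rim on the bright-field-like channel; nuclei are blurred
    discs on the marker channel covering ``nuclear_area_fraction`` of the
    cell area; the reporter channel is flat in the cytosol and scaled by
    the per-cell true nuclear:cytosolic ratio inside the nucleus.
    """

    shape: tuple[int, int] = (768, 768)
    n_cells: int = 100
    radius_range: tuple[float, float] = (8.0, 14.0)
    nuclear_area_fraction: float = 0.08
    ratio_mean: float = 0.45
    ratio_sd: float = 0.10
    bf_background: float = 1000.0
    bf_interior: float = 3000.0
    bf_rim: float = 300.0
    rim_width: float = 2.0
    nuc_background: float = 100.0
    nuc_amplitude: float = 3000.0
    rep_background: float = 100.0
    rep_cytosol: float = 800.0
    noise_sd: float = 100.0
    min_separation: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0 < self.nuclear_area_fraction < 1:
            raise ValueError("nuclear area fraction must be in (0, 1)")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("invalid radius range")


def replete_field_spec(**kwargs) -> ImageFieldSpec:
    """Pi-replete population: reporter mostly cytosolic (mean ratio 0.45)."""
    return ImageFieldSpec(ratio_mean=0.45, ratio_sd=0.10, **kwargs)


def starved_field_spec(**kwargs) -> ImageFieldSpec:
    """Pi-starved population: reporter nuclear (mean ratio 1.8)."""
    return ImageFieldSpec(ratio_mean=1.8, ratio_sd=0.25, **kwargs)


@dataclass
class FieldFixture:
    """One generated field: channel stack, truth labels, per-cell truth."""

    images: np.ndarray          # (3, H, W) uint16: brightfield, nuclear, reporter
    cell_labels: np.ndarray     # (H, W) uint16, 0 = background
    nucleus_labels: np.ndarray  # (H, W) uint16, same ids as cell_labels
    truth: list[dict]


def generate_image_fixture(spec: ImageFieldSpec) -> FieldFixture:
    """Render one field from a spec.  Deterministic given ``spec.seed``.

    Raises ``RuntimeError`` if non-overlapping placement fails after
    bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]

    cells: list[tuple[float, float, float]] = []  # (cy, cx, r)
    max_attempts = max(200 * spec.n_cells, 1000)
    attempts = 0
    while len(cells) < spec.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells "
                f"in a {h}x{w} field after {max_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(*spec.radius_range)
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if all(
            np.hypot(cy - oy, cx - ox) >= r + orr + spec.min_separation
            for oy, ox, orr in cells
        ):
            cells.append((cy, cx, r))

    bf = np.full(spec.shape, spec.bf_background, dtype=float)
    nuc = np.full(spec.shape, spec.nuc_background, dtype=float)
    rep = np.full(spec.shape, spec.rep_background, dtype=float)
    cell_labels = np.zeros(spec.shape, dtype=np.uint16)
    nucleus_labels = np.zeros(spec.shape, dtype=np.uint16)
    truth: list[dict] = []

    for i, (cy, cx, r) in enumerate(cells, start=1):
        ratio = max(0.05, rng.normal(spec.ratio_mean, spec.ratio_sd))
        r_nuc = r * float(np.sqrt(spec.nuclear_area_fraction))
        # local window around the cell keeps rendering O(cells), not O(cells x pixels)
        y0, y1 = max(int(cy - r - 3), 0), int(cy + r + 4)
        x0, x1 = max(int(cx - r - 3), 0), int(cx + r + 4)
        d = np.hypot(yy[y0:y1, x0:x1] - cy, xx[y0:y1, x0:x1] - cx)
        disc = d <= r
        rim = disc & (d > r - spec.rim_width)
        ndisc = d <= r_nuc

        bf[y0:y1, x0:x1][disc] = spec.bf_interior
        bf[y0:y1, x0:x1][rim] = spec.bf_rim
        nuc[y0:y1, x0:x1][ndisc] = spec.nuc_background + spec.nuc_amplitude
        rep[y0:y1, x0:x1][disc & ~ndisc] = spec.rep_background + spec.rep_cytosol
        rep[y0:y1, x0:x1][ndisc] = spec.rep_background + spec.rep_cytosol * ratio
        cell_labels[y0:y1, x0:x1][disc] = i
        nucleus_labels[y0:y1, x0:x1][ndisc] = i
        truth.append(
            {
                "cell_id": i,
                "centroid": [float(cy), float(cx)],
                "radius_px": float(r),
                "nucleus_radius_px": float(r_nuc),
                "true_ratio": float(ratio),
            }
        )

    bf = ndi.gaussian_filter(bf, 0.8)
    nuc = ndi.gaussian_filter(nuc, 0.8)  # Gaussian-blob nuclei
    if spec.noise_sd > 0:
        bf = bf + rng.normal(0.0, spec.noise_sd, spec.shape)
        nuc = nuc + rng.normal(0.0, spec.noise_sd, spec.shape)
        rep = rep + rng.normal(0.0, spec.noise_sd, spec.shape)

    stack = np.stack([bf, nuc, rep]).clip(0, 65535).astype(np.uint16)
    return FieldFixture(stack, cell_labels, nucleus_labels, truth)


def write_image_fixture(spec: ImageFieldSpec, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write a field as multi-page TIFF + label TIFFs + truth JSON."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = generate_image_fixture(spec)
    paths = {
        "images": out / f"{stem}.tif",
        "cell_labels": out / f"{stem}_cells.tif",
        "nucleus_labels": out / f"{stem}_nuclei.tif",
        "truth": out / f"{stem}_truth.json",
    }
    tifffile.imwrite(paths["images"], fx.images)
    tifffile.imwrite(paths["cell_labels"], fx.cell_labels)
    tifffile.imwrite(paths["nucleus_labels"], fx.nucleus_labels)
    paths["truth"].write_text(json.dumps(fx.truth, indent=1))
    return paths


# ---------------------------------------------------------------------------
# Kinetic time courses


def relocation_logistic(t, baseline=RELOC_BASELINE, amplitude=RELOC_AMPLITUDE,
                        t_half=RELOC_THALF_VIP1D_MIN, width=RELOC_WIDTH_MIN):
    """The nuclear/cytosolic ratio logistic R(t) used as fixture ground truth."""
    t = np.asarray(t, dtype=float)
    return baseline + amplitude / (1.0 + np.exp(-(t - t_half) / width))


def decay_concentration(t, c0=VIP1D_DECAY_C0_UM, k=VIP1D_DECAY_K_PER_MIN):
    """The 5-IP7 depletion curve C(t) = C0 exp(-k t), uM, t in min."""
    t = np.asarray(t, dtype=float)
    return c0 * np.exp(-k * t)


def generate_relocation_timecourse(
    seed: int = 0,
    times: np.ndarray | None = None,
    strain: str = "vip1d",
    conc_noise_sd: float = 0.0,
    ratio_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired concentration and relocation series for one strain-like fixture.

    ``vip1d``: 20-fold elevated 5-IP7 decaying from 14 uM (k = 0.01716/min)
    with the relocation half-maximum at 60 min — so the concentration at
    the half-maximum is 5 uM.  ``wt``: fast relocation (t_half 10 min) from
    the 0.7 uM replete pool.
    """
    if times is None:
        times = np.arange(0.0, 241.0, 15.0)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)

    if strain == "vip1d":
        conc = decay_concentration(times)
        ratio = relocation_logistic(times)
    elif strain == "wt":
        conc = decay_concentration(times, c0=0.7, k=VIP1D_DECAY_K_PER_MIN)
        ratio = relocation_logistic(times, t_half=RELOC_THALF_WT_MIN, width=4.0)
    else:
        raise ValueError(f"no timecourse fixture for strain {strain!r}")

    if conc_noise_sd > 0:
        conc = np.clip(conc + rng.normal(0.0, conc_noise_sd, conc.shape), 0.0, None)
    if ratio_noise_sd > 0:
        ratio = np.clip(ratio + rng.normal(0.0, ratio_noise_sd, ratio.shape), 0.0, None)

    conc_df = pd.DataFrame(
        {"time_min": times, "value": conc, "series_id": f"{strain}_5-IP7_uM"}
    )
    reloc_df = pd.DataFrame(
        {"time_min": times, "value": ratio, "series_id": f"{strain}_IN_IC"}
    )
    return conc_df, reloc_df
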