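"""Synthetic sputum-pellet FTIR cohort generator.

Emulates the study conditions the analysis assumes: 25 cancer and 25 normal
subjects plated in triplicate, fingerprint-region spectra built from Gaussian
absorption bands on a linear baseline, with per-replicate multiplicative gain,
per-subject band-amplitude jitter, and additive detector noise.

The default band table encodes the six class-differential bands reported for
sputum (second-derivative centres, normal -> cancer):

====  ================  ==============================================
band  centre (cm^-1)    assignment
====  ================  ==============================================
A     964 -> 966        PO4= stretch; C-C stretch (protein/nucleic acid)
B     1024 -> 1024      C-O stretch, C-O bend (glycogen)
C     1049 -> 1051      C-O stretch, C-O bend (glycogen)
D     1417 -> 1411      COO- stretch, C-H bend (protein)
E     1577 -> 1577      amide II (protein/nucleic acid)
F     1656 -> 1654      amide I (protein)
====  ================  ==============================================

All six have amplitude_cancer > amplitude_normal (30-40% increases). Six
class-neutral distractor bands fill the rest of the fingerprint region so
that the screen has true negatives to control and the spectral norm is
anchored mostly in class-neutral mass (see default_bands). Optional
class-neutral mucin bands (C-O stretch at 1040/1076/1120 cm^-1) model
residual airway mucus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import SpectrumCohort, Spectrum, WavenumberGrid, raw_grid

FOUR_LN2 = 4.0 * np.log(2.0)

#: per-class smoking-status proportions (smoker, ex-smoker, never-smoker)
SMOKING_PROPORTIONS = {
    "cancer": {"smoker": 11 / 25, "ex_smoker": 11 / 25, "never_smoker": 3 / 25},
    "normal": {"smoker": 12 / 25, "ex_smoker": 5 / 25, "never_smoker": 8 / 25},
}
#: probability of a prior cancer diagnosis (controls are screened cancer-free)
PRIOR_CANCER_RATE = {"cancer": 4 / 25, "normal": 0.0}
#: probability of reporting cough before producing sputum
COUGH_RATE = {"cancer": 0.5, "normal": 6 / 25}


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band with class-specific centre and amplitude."""

    centre_normal: float
    centre_cancer: float
    fwhm: float
    amplitude_normal: float
    amplitude_cancer: float
    annotation: str = ""

    def __post_init__(self):
        if not 4.0 <= self.fwhm <= 60.0:
            raise ValueError(f"fwhm {self.fwhm} outside [4, 60] cm^-1")
        if self.amplitude_normal < 0 or self.amplitude_cancer < 0:
            raise ValueError("band amplitudes must be >= 0")

    def centre(self, class_label: str) -> float:
        return self.centre_cancer if class_label == "cancer" else self.centre_normal

    def amplitude(self, class_label: str) -> float:
        return self.amplitude_cancer if class_label == "cancer" else self.amplitude_normal

    @property
    def is_differential(self) -> bool:
        return (self.centre_normal != self.centre_cancer
                or self.amplitude_normal != self.amplitude_cancer)


def default_bands() -> list[BandSpec]:
    """Six differential bands plus six class-neutral distractors.

    Vector normalisation makes only *relative* composition observable, so a
    uniform amplitude increase would vanish. The class-neutral bands carry
    roughly two thirds of the spectral norm (standing in for the broad
    non-differential background of real pellet spectra), which keeps the
    cohort norm ratio modest (~+13%) and lets the planted 30-40% increases
    survive normalisation with a per-band standardized effect >= 2.
    """
    diff = [
        BandSpec(964.0, 966.0, 10.0, 0.050, 0.0675,
                 "PO4= stretch; C-C stretch (protein, nucleic acid)"),
        BandSpec(1024.0, 1024.0, 14.0, 0.100, 0.140, "C-O stretch/bend (glycogen)"),
        BandSpec(1049.0, 1051.0, 12.0, 0.120, 0.156, "C-O stretch/bend (glycogen)"),
        BandSpec(1417.0, 1411.0, 22.0, 0.120, 0.156, "COO- stretch, C-H bend (protein)"),
        BandSpec(1577.0, 1577.0, 24.0, 0.180, 0.252,
                 "amide II: N-H bend, C-N stretch (protein, nucleic acid)"),
        BandSpec(1656.0, 1654.0, 20.0, 0.260, 0.338, "amide I: C=O stretch (protein)"),
    ]
    neutral = [
        BandSpec(c, c, f, a, a, "class-neutral")
        for c, f, a in ((1100.0, 18.0, 0.20), (1160.0, 20.0, 0.23),
                        (1240.0, 18.0, 0.30), (1310.0, 20.0, 0.25),
                        (1460.0, 18.0, 0.33), (1740.0, 24.0, 0.25))
    ]
    return diff + neutral


def mucin_bands() -> list[BandSpec]:
    """Class-neutral mucin C-O stretch bands (airway mucus glycoproteins)."""
    return [
        BandSpec(c, c, f, a, a, "mucin C-O stretch")
        for c, f, a in ((1040.0, 16.0, 0.080), (1076.0, 16.0, 0.030),
                        (1120.0, 16.0, 0.025))
    ]


@dataclass
class CohortConfig:
    """Study-condition parameters for cohort simulation.

    Defaults emulate the sputum study: 25 subjects per class, triplicate
    plating, the default band table, a linear baseline that the two-point
    correction removes exactly, lognormal replicate gain (sd 0.05 on the log
    scale), lognormal per-subject band jitter (sd 0.08), and additive Gaussian
    noise (sd 0.004 absorbance units).
    """

    n_cancer: int = 25
    n_normal: int = 25
    replicates: int = 3
    bands: list[BandSpec] = field(default_factory=default_bands)
    baseline_intercept: float = 0.05
    baseline_slope: float = 5e-5
    baseline_curvature: float = 0.0
    gain_sd: float = 0.05
    subject_amplitude_jitter_sd: float = 0.08
    noise_sd: float = 0.004
    mucin_bands_enabled: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_cancer < 1 or self.n_normal < 1:
            raise ValueError("n_cancer and n_normal must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("gain_sd", "subject_amplitude_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.bands:
            raise ValueError("band table must be nonempty")

    def effective_bands(self) -> list[BandSpec]:
        return list(self.bands) + (mucin_bands() if self.mucin_bands_enabled else [])

    def differential_bands(self) -> list[BandSpec]:
        return [b for b in self.effective_bands() if b.is_differential]


def null_config(**overrides) -> CohortConfig:
    """Config with zero class effect: cancer band parameters set to normal's."""
    base = CohortConfig(**overrides)
    base.bands = [
        replace(b, centre_cancer=b.centre_normal, amplitude_cancer=b.amplitude_normal)
        for b in base.bands
    ]
    return base


def band_profile(centre: float, fwhm: float, amplitude: float,
                 grid: WavenumberGrid) -> np.ndarray:
    """Gaussian band: amplitude * exp(-4 ln2 (v - centre)^2 / fwhm^2)."""
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    v = grid.values
    return amplitude * np.exp(-FOUR_LN2 * (v - centre) ** 2 / fwhm**2)


def _baseline(config: CohortConfig, grid: WavenumberGrid) -> np.ndarray:
    x = grid.values - 900.0
    return (config.baseline_intercept + config.baseline_slope * x
            + config.baseline_curvature * x**2)


def _clean_signal(class_label: str, config: CohortConfig, grid: WavenumberGrid,
                  band_scales: np.ndarray) -> np.ndarray:
    total = _baseline(config, grid)
    for scale, band in zip(band_scales, config.effective_bands()):
        total = total + band_profile(
            band.centre(class_label), band.fwhm, scale * band.amplitude(class_label), grid
        )
    return total


def generate_spectrum(class_label: str, config: CohortConfig,
                      rng: np.random.Generator | None = None) -> Spectrum:
    """One raw spectrum on the canonical raw grid.

    Draws its own subject jitter, replicate gain and noise; pass the same
    seeded generator state for reproducibility.
    """
    if class_label not in ("cancer", "normal"):
        raise ValueError(f"unknown class label {class_label!r}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    grid = raw_grid()
    n_bands = len(config.effective_bands())
    scales = np.exp(rng.normal(0.0, config.subject_amplitude_jitter_sd, size=n_bands))
    gain = float(np.exp(rng.normal(0.0, config.gain_sd)))
    noise = rng.normal(0.0, config.noise_sd, size=len(grid)) if config.noise_sd > 0 \
        else np.zeros(len(grid))
    values = gain * _clean_signal(class_label, config, grid, scales) + noise
    return Spectrum(grid, values, kind="raw")


def _draw_metadata(class_label: str, rng: np.random.Generator) -> dict:
    props = SMOKING_PROPORTIONS[class_label]
    status = rng.choice(list(props), p=list(props.values()))
    return {
        "smoking_status": str(status),
        "prior_cancer": bool(rng.random() < PRIOR_CANCER_RATE[class_label]),
        "cough": bool(rng.random() < COUGH_RATE[class_label]),
    }


def generate_cohort(config: CohortConfig) -> SpectrumCohort:
    """Full labelled cohort: (n_cancer + n_normal) subjects x replicates spectra.

    Subject band jitter is shared across a subject's replicates; replicate
    gain and additive noise are independent per plated replicate.
    """
    rng = np.random.default_rng(config.seed)
    grid = raw_grid()
    n_bands = len(config.effective_bands())
    rows, meta_rows = [], []
    plan = [("cancer", f"C{i + 1:02d}") for i in range(config.n_cancer)]
    plan += [("normal", f"N{i + 1:02d}") for i in range(config.n_normal)]
    for class_label, sid in plan:
        scales = np.exp(rng.normal(0.0, config.subject_amplitude_jitter_sd, size=n_bands))
        clean = _clean_signal(class_label, config, grid, scales)
        metadata = _draw_metadata(class_label, rng)
        for rep in range(1, config.replicates + 1):
            gain = float(np.exp(rng.normal(0.0, config.gain_sd)))
            noise = rng.normal(0.0, config.noise_sd, size=len(grid))
            rows.append(gain * clean + noise)
            meta_rows.append(
                {"sample_id": sid, "replicate": rep, "class": class_label, **metadata}
            )
    return SpectrumCohort(grid, np.vstack(rows), pd.DataFrame(meta_rows), kind="raw")
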