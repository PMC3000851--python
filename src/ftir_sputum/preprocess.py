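"""Spectral preprocessing chain.

Fixed stage order: two-point baseline correction (anchors 900/1850 cm^-1,
outside the fingerprint region) -> crop to [950, 1800] -> vector
normalisation (unit Euclidean norm) -> 9-point Savitzky-Golay second
derivative. Baseline must precede cropping because its anchors lie outside
the cropped region.

Second derivatives are stored with their true sign, so absorption bands
appear as local *minima*; derivative units are absorbance * cm^2 (the filter
output is scaled by 1/step^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectrumCohort, WavenumberGrid


@dataclass
class PreprocessParams:
    anchor_low: float = 900.0
    anchor_high: float = 1850.0
    crop_low: float = 950.0
    crop_high: float = 1800.0
    sg_window: int = 9
    sg_polyorder: int = 3
    replicate_aggregate: str = "median"

    def __post_init__(self):
        if not self.anchor_low < self.crop_low < self.crop_high < self.anchor_high:
            raise ValueError(
                "require anchor_low < crop_low < crop_high < anchor_high, got "
                f"{self.anchor_low}, {self.crop_low}, {self.crop_high}, {self.anchor_high}"
            )
        if self.sg_window % 2 != 1:
            raise ValueError(f"sg_window must be odd, got {self.sg_window}")
        if self.sg_window < self.sg_polyorder + 2:
            raise ValueError("sg_window must be >= sg_polyorder + 2")
        if self.replicate_aggregate not in ("median", "mean"):
            raise ValueError("replicate_aggregate must be 'median' or 'mean'")


def _anchor_index(grid: WavenumberGrid, anchor: float) -> int:
    i = grid.nearest_index(anchor)
    if abs(grid.values[i] - anchor) > 0.5 * grid.spacing:
        raise ValueError(
            f"baseline anchor {anchor} cm^-1 outside grid span "
            f"[{grid.values[0]:.6g}, {grid.values[-1]:.6g}]"
        )
    return i


def _baseline_correct_matrix(grid: WavenumberGrid, matrix: np.ndarray,
                             params: PreprocessParams) -> np.ndarray:
    i_lo = _anchor_index(grid, params.anchor_low)
    i_hi = _anchor_index(grid, params.anchor_high)
    v = grid.values
    t = (v - v[i_lo]) / (v[i_hi] - v[i_lo])
    lines = matrix[:, [i_lo]] * (1.0 - t) + matrix[:, [i_hi]] * t
    return matrix - lines


def baseline_correct(spectrum: Spectrum, params: PreprocessParams | None = None) -> Spectrum:
    """Subtract the straight line through the two anchor-point absorbances."""
    params = params or PreprocessParams()
    corrected = _baseline_correct_matrix(
        spectrum.grid, spectrum.absorbance[None, :], params
    )[0]
    return Spectrum(spectrum.grid, corrected, kind="baseline_corrected")


def _crop_mask(grid: WavenumberGrid, params: PreprocessParams) -> np.ndarray:
    tol = 0.5 * grid.spacing * 1e-9  # guard float fuzz at exact bounds
    mask = (grid.values >= params.crop_low - tol) & (grid.values <= params.crop_high + tol)
    if not mask.any():
        raise ValueError(
            f"no grid points inside crop interval [{params.crop_low}, {params.crop_high}]"
        )
    return mask


def crop_fingerprint(spectrum: Spectrum, params: PreprocessParams | None = None) -> Spectrum:
    """Retain grid points in the closed interval [crop_low, crop_high]."""
    params = params or PreprocessParams()
    mask = _crop_mask(spectrum.grid, params)
    return Spectrum(WavenumberGrid(spectrum.grid.values[mask]),
                    spectrum.absorbance[mask], kind=spectrum.kind)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm, removing multiplicative gain."""
    norm = float(np.linalg.norm(spectrum.absorbance))
    if norm == 0.0:
        raise ValueError("cannot vector-normalise an all-zero spectrum")
    return Spectrum(spectrum.grid, spectrum.absorbance / norm, kind="normalized")


def _sg_matrix(grid: WavenumberGrid, matrix: np.ndarray,
               params: PreprocessParams) -> np.ndarray:
    if not grid.is_uniform(rtol=1e-6):
        raise ValueError("Savitzky-Golay derivative requires a uniform grid")
    if params.sg_window > len(grid):
        raise ValueError(
            f"sg_window {params.sg_window} exceeds spectrum length {len(grid)}"
        )
    return savgol_filter(matrix, params.sg_window, params.sg_polyorder,
                         deriv=2, delta=grid.spacing, mode="interp", axis=-1)


def sg_second_derivative(spectrum: Spectrum,
                         params: PreprocessParams | None = None) -> Spectrum:
    """Savitzky-Golay smoothed second derivative (boundary windows by polynomial fit)."""
    params = params or PreprocessParams()
    deriv = _sg_matrix(spectrum.grid, spectrum.absorbance[None, :], params)[0]
    return Spectrum(spectrum.grid, deriv, kind="second_derivative")


def preprocess_spectrum(spectrum: Spectrum,
                        params: PreprocessParams | None = None) -> Spectrum:
    """Full chain on one raw spectrum: baseline -> crop -> normalise -> 2nd derivative."""
    params = params or PreprocessParams()
    s = baseline_correct(spectrum, params)
    s = crop_fingerprint(s, params)
    s = vector_normalize(s)
    return sg_second_derivative(s, params)


def preprocess_cohort(cohort: SpectrumCohort,
                      params: PreprocessParams | None = None) -> SpectrumCohort:
    """Full chain applied to every spectrum of a raw cohort (vectorised)."""
    params = params or PreprocessParams()
    matrix = _baseline_correct_matrix(cohort.grid, cohort.matrix, params)
    mask = _crop_mask(cohort.grid, params)
    grid = WavenumberGrid(cohort.grid.values[mask])
    matrix = matrix[:, mask]
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    zero = np.flatnonzero(norms[:, 0] == 0)
    if zero.size:
        sid = cohort.meta.iloc[int(zero[0])]["sample_id"]
        raise ValueError(f"all-zero spectrum for sample {sid!r} cannot be normalised")
    matrix = matrix / norms
    matrix = _sg_matrix(grid, matrix, params)
    return SpectrumCohort(grid, matrix, cohort.meta.copy(), kind="second_derivative")


def aggregate_replicates(cohort: SpectrumCohort,
                         params: PreprocessParams | None = None) -> SpectrumCohort:
    """Collapse technical replicates to one spectrum per sample (pointwise median
    by default, mean optional); metadata is carried through."""
    params = params or PreprocessParams()
    agg = np.median if params.replicate_aggregate == "median" else np.mean
    rows, meta_rows = [], []
    for sid in cohort.sample_ids:
        mask = (cohort.meta["sample_id"] == sid).to_numpy()
        rows.append(agg(cohort.matrix[mask], axis=0))
        first = cohort.meta.loc[mask].iloc[0].to_dict()
        first["replicate"] = 1
        meta_rows.append(first)
    import pandas as pd

    return SpectrumCohort(cohort.grid, np.vstack(rows), pd.DataFrame(meta_rows),
                          kind=cohort.kind)


def group_median_spectrum(cohort: SpectrumCohort, class_label: str) -> Spectrum:
    """Pointwise median spectrum across the per-sample spectra of one class."""
    block = cohort.class_matrix(class_label)
    if block.shape[0] == 0:
        raise ValueError(f"no samples with class {class_label!r}")
    return Spectrum(cohort.grid, np.median(block, axis=0), kind=cohort.kind)
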