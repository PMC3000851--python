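"""Spectrum and cohort containers, CSV dialects, absorbance conversion.

The canonical wavenumber convention follows the fingerprint-region analysis:
442 evenly spaced points on [950, 1800] cm^-1 (step 850/441 ~ 1.9274 cm^-1).
The canonical *raw* grid extends this arithmetic sequence 26 steps below 950
and 26 steps above 1800 (~899.9 to ~1850.1, 494 points) so that both
baseline-anchor wavenumbers (900 and 1850 cm^-1) fall within half a grid step
of a grid point.

Wavenumbers may arrive in descending instrument order; they are normalised to
ascending internally and written ascending everywhere.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FINGERPRINT_LOW = 950.0
FINGERPRINT_HIGH = 1800.0
FINGERPRINT_POINTS = 442
GRID_STEP = (FINGERPRINT_HIGH - FINGERPRINT_LOW) / (FINGERPRINT_POINTS - 1)
RAW_PAD_STEPS = 26

BASELINE_ANCHOR_LOW = 900.0
BASELINE_ANCHOR_HIGH = 1850.0

CLASS_LABELS = ("cancer", "normal")

SPECTRUM_KINDS = ("raw", "baseline_corrected", "normalized", "second_derivative")

#: reserved (non-metadata) columns of the wide/long CSV dialects
_ID_COLUMNS = ("sample_id", "replicate", "class")


class CohortFormatError(ValueError):
    """Raised when a cohort file violates the dialect contract."""


class WavenumberGrid:
    """Strictly monotone, finite, positive wavenumber axis (cm^-1).

    Values are stored ascending regardless of input order.
    """

    __slots__ = ("values",)

    def __init__(self, values: Sequence[float]):
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two wavenumbers")
        if not np.all(np.isfinite(v)):
            raise ValueError("grid contains non-finite wavenumbers")
        if np.any(v <= 0):
            raise ValueError("wavenumbers must be positive")
        d = np.diff(v)
        if np.all(d < 0):
            v = v[::-1]
        elif not np.all(d > 0):
            raise ValueError("wavenumbers must be strictly monotone without duplicates")
        self.values = v
        self.values.setflags(write=False)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberGrid) and np.array_equal(self.values, other.values)

    def __repr__(self) -> str:
        v = self.values
        return f"WavenumberGrid({v[0]:.6g}..{v[-1]:.6g} cm-1, {v.size} points)"

    @property
    def spacing(self) -> float:
        """Nominal step (median of successive differences), cm^-1."""
        return float(np.median(np.diff(self.values)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.values)
        return bool(np.max(np.abs(d - d.mean())) <= rtol * abs(d.mean()))

    def nearest_index(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))


def fingerprint_grid() -> WavenumberGrid:
    """Canonical 442-point fingerprint grid on [950, 1800] cm^-1."""
    return WavenumberGrid(np.linspace(FINGERPRINT_LOW, FINGERPRINT_HIGH, FINGERPRINT_POINTS))


def raw_grid() -> WavenumberGrid:
    """Canonical raw grid: the fingerprint grid padded 26 steps each side (494 points)."""
    k = np.arange(-RAW_PAD_STEPS, FINGERPRINT_POINTS + RAW_PAD_STEPS)
    return WavenumberGrid(FINGERPRINT_LOW + GRID_STEP * k)


@dataclass
class Spectrum:
    """One measurement: absorbance values on a wavenumber grid."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    kind: str = "raw"

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 1 or a.size != len(self.grid):
            raise ValueError(
                f"absorbance length {a.size} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        self.absorbance = a


@dataclass
class SpectrumCohort:
    """Collection of spectra on a shared grid with per-spectrum annotations.

    ``matrix`` is (n_spectra, n_points); ``meta`` carries one row per spectrum
    with columns ``sample_id``, ``replicate``, ``class`` plus free metadata
    (smoking_status, prior_cancer, cough, ...). Row order is insertion order.
    """

    grid: WavenumberGrid
    matrix: np.ndarray
    meta: pd.DataFrame
    kind: str = "raw"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(self.grid):
            raise ValueError("matrix shape does not match grid")
        if not np.all(np.isfinite(m)):
            raise ValueError("cohort matrix contains non-finite values")
        if len(self.meta) != m.shape[0]:
            raise ValueError("meta rows do not match matrix rows")
        for col in _ID_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"meta is missing required column {col!r}")
        bad = set(self.meta["class"]) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class labels {sorted(bad)}; expected {CLASS_LABELS}")
        self.matrix = m
        self.meta = self.meta.reset_index(drop=True)
        self._check_replicates()

    def _check_replicates(self):
        for sid, grp in self.meta.groupby("sample_id", sort=False):
            reps = sorted(int(r) for r in grp["replicate"])
            if reps != list(range(1, len(reps) + 1)):
                raise ValueError(
                    f"sample {sid!r}: replicate indices {reps} are not contiguous from 1"
                )

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def sample_ids(self) -> list:
        return list(dict.fromkeys(self.meta["sample_id"]))

    @property
    def class_labels(self) -> np.ndarray:
        return self.meta["class"].to_numpy()

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[i].copy(), kind=self.kind)

    def subset(self, mask) -> "SpectrumCohort":
        mask = np.asarray(mask)
        return SpectrumCohort(
            self.grid, self.matrix[mask], self.meta.loc[mask].reset_index(drop=True), self.kind
        )

    def class_matrix(self, class_label: str) -> np.ndarray:
        if class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {class_label!r}")
        return self.matrix[self.class_labels == class_label]

    def metadata_columns(self) -> list:
        return [c for c in self.meta.columns if c not in _ID_COLUMNS]


def compute_absorbance(
    sample_intensity: Sequence[float],
    reference_intensity: Sequence[float],
    grid: WavenumberGrid,
) -> Spectrum:
    """Absorbance from sample/reference single-beam intensities: A = -log10(IS/IR)."""
    i_s = np.asarray(sample_intensity, dtype=float)
    i_r = np.asarray(reference_intensity, dtype=float)
    if i_s.shape != i_r.shape:
        raise ValueError(
            f"length mismatch: sample has {i_s.size} points, reference has {i_r.size}"
        )
    for name, arr in (("sample", i_s), ("reference", i_r)):
        bad = np.flatnonzero(~(arr > 0))
        if bad.size:
            raise ValueError(
                f"nonpositive {name} intensity at index {int(bad[0])} "
                f"(value {arr[bad[0]]!r})"
            )
    return Spectrum(grid, -np.log10(i_s / i_r), kind="raw")


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _as_text_handle(source, mode: str):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, encoding="utf-8", newline=""), True


def _fmt(x: float) -> str:
    # shortest decimal form that round-trips to the same float
    return repr(float(x))


def write_cohort_matrix(cohort: SpectrumCohort, dest, dialect: str = "wide_csv") -> None:
    """Serialise a cohort losslessly (17 significant digits) to ``dest``.

    ``dest`` may be a path or a text handle. ``wide_csv`` writes one row per
    spectrum with a wavenumber header; ``long_csv`` writes one row per
    (spectrum, wavenumber).
    """
    if dialect not in ("wide_csv", "long_csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    handle, owns = _as_text_handle(dest, "w")
    try:
        meta_cols = cohort.metadata_columns()
        wn = cohort.grid.values
        if dialect == "wide_csv":
            header = list(_ID_COLUMNS) + meta_cols + [_fmt(w) for w in wn]
            handle.write(",".join(header) + "\n")
            for i in range(cohort.n_spectra):
                row = cohort.meta.iloc[i]
                cells = [str(row["sample_id"]), str(int(row["replicate"])), str(row["class"])]
                cells += [str(row[c]) for c in meta_cols]
                cells += [_fmt(v) for v in cohort.matrix[i]]
                handle.write(",".join(cells) + "\n")
        else:
            header = list(_ID_COLUMNS) + meta_cols + ["wavenumber", "absorbance"]
            handle.write(",".join(header) + "\n")
            for i in range(cohort.n_spectra):
                row = cohort.meta.iloc[i]
                prefix = [str(row["sample_id"]), str(int(row["replicate"])), str(row["class"])]
                prefix += [str(row[c]) for c in meta_cols]
                for w, v in zip(wn, cohort.matrix[i]):
                    handle.write(",".join(prefix + [_fmt(w), _fmt(v)]) + "\n")
    finally:
        if owns:
            handle.close()


def cohort_to_csv_string(cohort: SpectrumCohort, dialect: str = "wide_csv") -> str:
    buf = io.StringIO()
    write_cohort_matrix(cohort, buf, dialect)
    return buf.getvalue()


def read_cohort_matrix(source, dialect: str = "wide_csv", kind: str = "raw") -> SpectrumCohort:
    """Parse a cohort from a path or text handle in the given dialect."""
    if dialect == "wide_csv":
        return _read_wide(source, kind)
    if dialect == "long_csv":
        return _read_long(source, kind)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_wide(source, kind: str) -> SpectrumCohort:
    handle, owns = _as_text_handle(source, "r")
    try:
        try:
            df = pd.read_csv(handle, dtype={"sample_id": str, "class": str},
                             float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise CohortFormatError(f"malformed wide_csv: {exc}") from exc
    finally:
        if owns:
            handle.close()
    for col in _ID_COLUMNS:
        if col not in df.columns:
            raise CohortFormatError(f"wide_csv is missing column {col!r}")
    wn_cols, meta_cols = [], []
    for c in df.columns:
        if c in _ID_COLUMNS:
            continue
        try:
            float(c)
            wn_cols.append(c)
        except ValueError:
            meta_cols.append(c)
    if not wn_cols:
        raise CohortFormatError("wide_csv has no wavenumber columns")
    wn = np.array([float(c) for c in wn_cols])
    order = np.argsort(wn)
    wn_cols = [wn_cols[i] for i in order]
    grid = WavenumberGrid(wn[order])
    dup = df.duplicated(subset=["sample_id", "replicate"])
    if dup.any():
        r = int(np.flatnonzero(dup.to_numpy())[0])
        raise CohortFormatError(f"duplicate (sample_id, replicate) at data row {r + 1}")
    block = df[wn_cols]
    numeric = block.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise CohortFormatError(
            f"non-numeric or missing absorbance at data row {r + 1}, wavenumber {wn_cols[c]}"
        )
    meta = df[list(_ID_COLUMNS) + meta_cols].copy()
    meta["replicate"] = meta["replicate"].astype(int)
    return SpectrumCohort(grid, numeric.to_numpy(float), meta, kind=kind)


def _read_long(source, kind: str) -> SpectrumCohort:
    handle, owns = _as_text_handle(source, "r")
    try:
        try:
            df = pd.read_csv(handle, dtype={"sample_id": str, "class": str},
                             float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise CohortFormatError(f"malformed long_csv: {exc}") from exc
    finally:
        if owns:
            handle.close()
    needed = list(_ID_COLUMNS) + ["wavenumber", "absorbance"]
    for col in needed:
        if col not in df.columns:
            raise CohortFormatError(f"long_csv is missing column {col!r}")
    meta_cols = [c for c in df.columns if c not in needed]
    for col in ("wavenumber", "absorbance"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            r = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise CohortFormatError(f"non-numeric {col} at data row {r + 1}")
        df[col] = vals
    dup = df.duplicated(subset=["sample_id", "replicate", "wavenumber"])
    if dup.any():
        r = int(np.flatnonzero(dup.to_numpy())[0])
        raise CohortFormatError(
            f"duplicate (sample_id, replicate, wavenumber) at data row {r + 1}"
        )
    keys = list(dict.fromkeys(zip(df["sample_id"], df["replicate"])))
    grid_values = np.sort(df["wavenumber"].unique())
    grid = WavenumberGrid(grid_values)
    lookup = {w: i for i, w in enumerate(grid.values)}
    matrix = np.full((len(keys), len(grid)), np.nan)
    meta_rows = []
    grouped = df.groupby(["sample_id", "replicate"], sort=False)
    for row_i, key in enumerate(keys):
        grp = grouped.get_group(key)
        if len(grp) != len(grid):
            raise CohortFormatError(
                f"sample {key[0]!r} replicate {key[1]} has {len(grp)} wavenumbers, "
                f"expected {len(grid)}"
            )
        idx = [lookup[w] for w in grp["wavenumber"]]
        matrix[row_i, idx] = grp["absorbance"].to_numpy()
        first = grp.iloc[0]
        meta_rows.append(
            {"sample_id": key[0], "replicate": int(key[1]), "class": first["class"],
             **{c: first[c] for c in meta_cols}}
        )
    return SpectrumCohort(grid, matrix, pd.DataFrame(meta_rows), kind=kind)


def build_cohort(
    grid: WavenumberGrid,
    spectra: Iterable[np.ndarray],
    sample_ids: Sequence,
    replicates: Sequence[int],
    classes: Sequence[str],
    metadata: Mapping[str, Sequence] | None = None,
    kind: str = "raw",
) -> SpectrumCohort:
    """Convenience constructor from parallel sequences."""
    matrix = np.vstack([np.asarray(s, float) for s in spectra])
    meta = pd.DataFrame(
        {"sample_id": list(sample_ids), "replicate": [int(r) for r in replicates],
         "class": list(classes)}
    )
    for k, v in (metadata or {}).items():
        meta[k] = list(v)
    return SpectrumCohort(grid, matrix, meta, kind=kind)
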