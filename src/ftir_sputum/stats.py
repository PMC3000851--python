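"""Per-wavenumber inference and peak-centre panel selection.

Every fingerprint wavenumber is tested cancer-vs-normal with the Mann-Whitney
U test on per-sample second-derivative values; p-values are adjusted by Holm's
step-down sequential Bonferroni over all tests, and surviving wavenumbers are
ranked (rank 1 = smallest raw p, ties broken by ascending wavenumber).

The normality screen (Shapiro-Wilk per wavenumber per class) is advisory:
the pipeline always proceeds nonparametrically and merely reports the
fraction of non-normal wavenumbers.

Significant wavenumbers are then matched against detected second-derivative
band centres (local minima of the class-median derivative spectra) to isolate
the prominent, chemically interpretable bands; the multivariate panel keeps
the top-ranked matched centres after excluding any within a window of the
known mucin C-O stretch wavenumbers (1040/1076/1120 cm^-1), generalising the
removal of the glycogen-region 1049 cm^-1 band as a potential mucin confound.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectra import GRID_STEP, SpectrumCohort, Spectrum

DEFAULT_MUCIN_REFS = (1040.0, 1076.0, 1120.0)
DEFAULT_MATCH_TOLERANCE = 2.0 * GRID_STEP  # two grid steps ~ 3.85 cm^-1

_EXACT_LIMIT = 12  # n1 + n2 at or below this -> exact enumeration under "auto"


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    mode: str


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 * #ties, via rank sums."""
    n1, n2 = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(x, y, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``exact`` enumerates all C(n1+n2, n1) group assignments of the pooled
    values (valid with ties); ``normal_approx`` uses the tie-corrected normal
    approximation with continuity correction; ``auto`` picks exact when
    n1 + n2 <= 12.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if x.size + y.size <= _EXACT_LIMIT else "normal_approx"
    u = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    mu = n1 * n2 / 2.0
    if mode == "exact":
        pooled = np.concatenate([x, y])
        n = pooled.size
        obs_dev = abs(u - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                hits += 1
        return MannWhitneyResult(u, hits / total, "exact")
    # tie-corrected normal approximation with continuity correction
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return MannWhitneyResult(u, 1.0, "normal_approx")  # all values tied
    dev = u - mu
    cc = 0.5 * np.sign(dev)
    z = (dev - cc) / np.sqrt(var) if dev != 0 else 0.0
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return MannWhitneyResult(u, p, "normal_approx")


def holm_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p-values and reject flags, in input order.

    adjusted_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) over the ascending order;
    reject iff adjusted <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-d sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = int(np.flatnonzero((p < 0) | (p > 1) | ~np.isfinite(p))[0])
        raise ValueError(f"p-value out of [0, 1] at index {bad}: {p[bad]!r}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    m = p.size
    order = np.argsort(p, kind="stable")
    factors = m - np.arange(m)
    adj_sorted = np.minimum(1.0, factors * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= alpha


def shapiro_wilk_screen(cohort: SpectrumCohort) -> pd.DataFrame:
    """Advisory per-wavenumber normality screen.

    Shapiro-Wilk is run within each class; the reported (W, p) is the more
    non-normal (smaller-p) class, so ``normal`` means both class samples
    passed. Zero-variance samples are flagged undefined rather than fatal.
    """
    rows = []
    blocks = {lab: cohort.class_matrix(lab) for lab in ("cancer", "normal")}
    for j, wn in enumerate(cohort.grid.values):
        best_w = best_p = np.nan
        undefined = False
        for block in blocks.values():
            v = block[:, j]
            if v.size < 3 or np.ptp(v) == 0.0:
                undefined = True
                continue
            w, p = sps.shapiro(v)
            if np.isnan(best_p) or p < best_p:
                best_w, best_p = float(w), float(p)
        rows.append({"wavenumber": wn, "shapiro_w": best_w, "shapiro_p": best_p,
                     "undefined": undefined and np.isnan(best_p)})
    return pd.DataFrame(rows)


def screen_wavenumbers(cohort: SpectrumCohort, alpha: float = 0.05) -> pd.DataFrame:
    """Full significance table over all fingerprint wavenumbers.

    ``cohort`` holds one *per-sample* second-derivative spectrum per row.
    Columns: wavenumber, u_statistic (cancer vs normal), p_raw, p_holm,
    reject, rank (1 = smallest p among rejected; NaN elsewhere), shapiro_w,
    shapiro_p.
    """
    cancer = cohort.class_matrix("cancer")
    normal = cohort.class_matrix("normal")
    if cancer.shape[0] < 2 or normal.shape[0] < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {cancer.shape[0]} cancer / "
            f"{normal.shape[0]} normal"
        )
    n_wn = len(cohort.grid)
    u = np.empty(n_wn)
    p_raw = np.empty(n_wn)
    for j in range(n_wn):
        res = mann_whitney_u(cancer[:, j], normal[:, j], mode="auto")
        u[j], p_raw[j] = res.u, res.p
    p_holm, reject = holm_adjust(p_raw, alpha)
    table = pd.DataFrame({
        "wavenumber": cohort.grid.values,
        "u_statistic": u,
        "p_raw": p_raw,
        "p_holm": p_holm,
        "reject": reject,
    })
    table["rank"] = np.nan
    rejected = table.index[table["reject"]]
    order = table.loc[rejected].sort_values(["p_raw", "wavenumber"]).index
    table.loc[order, "rank"] = np.arange(1, len(order) + 1, dtype=float)
    normality = shapiro_wilk_screen(cohort)
    table["shapiro_w"] = normality["shapiro_w"].to_numpy()
    table["shapiro_p"] = normality["shapiro_p"].to_numpy()
    return table


def detect_band_centres(spectrum: Spectrum, min_prominence: float = 0.0) -> pd.DataFrame:
    """Band centres as strict local minima of a second-derivative spectrum.

    Prominence of a minimum is its depth below the lower of the two flanking
    local maxima (spectrum endpoints count as flanking maxima). Returns a
    PeakTable with columns centre, depth (= -value), prominence, matched_rank,
    annotation; centres ascending.
    """
    if spectrum.kind != "second_derivative":
        raise ValueError("detect_band_centres expects a second-derivative spectrum")
    y = spectrum.absorbance
    v = spectrum.grid.values
    n = y.size
    interior = np.arange(1, n - 1)
    is_min = (y[interior] < y[interior - 1]) & (y[interior] < y[interior + 1])
    minima = interior[is_min]
    is_max = (y[interior] > y[interior - 1]) & (y[interior] > y[interior + 1])
    maxima = set(interior[is_max].tolist()) | {0, n - 1}
    rows = []
    for i in minima:
        left = max(j for j in maxima if j < i)
        right = min(j for j in maxima if j > i)
        prominence = min(y[left], y[right]) - y[i]
        if prominence >= min_prominence:
            rows.append({"centre": float(v[i]), "depth": float(-y[i]),
                         "prominence": float(prominence),
                         "matched_rank": np.nan, "annotation": ""})
    return pd.DataFrame(rows, columns=["centre", "depth", "prominence",
                                       "matched_rank", "annotation"])


def merge_peak_tables(*tables: pd.DataFrame,
                      min_separation: float = 1.5 * GRID_STEP) -> pd.DataFrame:
    """Union of peak tables, collapsing centres closer than ``min_separation``.

    A band whose centre shifts slightly between classes yields one nearby
    minimum in each class-median spectrum; collapsing treats the pair as one
    chemical band with centre = mean of the merged centres and depth /
    prominence = the larger of the two.
    """
    merged = pd.concat(tables, ignore_index=True).sort_values("centre")
    if merged.empty:
        return merged.reset_index(drop=True)
    groups = (merged["centre"].diff().fillna(np.inf) > min_separation).cumsum()
    out = merged.groupby(groups).agg(
        centre=("centre", "mean"), depth=("depth", "max"),
        prominence=("prominence", "max"), matched_rank=("matched_rank", "min"),
        annotation=("annotation", "first"),
    )
    return out.reset_index(drop=True)


def match_significant_to_peaks(table: pd.DataFrame, peaks: pd.DataFrame,
                               tolerance: float = DEFAULT_MATCH_TOLERANCE) -> pd.DataFrame:
    """Keep peaks with >= 1 Holm-rejected wavenumber within ``tolerance`` of
    their centre; matched_rank = best (smallest) rank among those; sorted by
    matched_rank."""
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    rejected = table.loc[table["reject"], ["wavenumber", "rank"]]
    rows = []
    for _, peak in peaks.iterrows():
        near = rejected.loc[(rejected["wavenumber"] - peak["centre"]).abs() <= tolerance]
        if len(near):
            row = peak.to_dict()
            row["matched_rank"] = float(near["rank"].min())
            rows.append(row)
    matched = pd.DataFrame(rows, columns=list(peaks.columns))
    if len(matched):
        matched = matched.sort_values("matched_rank").reset_index(drop=True)
    return matched


def select_mva_panel(matched: pd.DataFrame,
                     mucin_refs=DEFAULT_MUCIN_REFS,
                     exclusion_window: float = 10.0,
                     panel_size: int = 6) -> list[float]:
    """Panel of wavenumbers for multivariate analysis.

    Takes the top ``panel_size`` matched peaks by matched_rank, drops any
    whose centre lies within ``exclusion_window`` of a mucin reference
    wavenumber, and returns the remaining centres sorted ascending.
    """
    if matched.empty:
        raise ValueError("matched peak table is empty; cannot build a panel")
    top = matched.sort_values("matched_rank").head(panel_size)
    kept, excluded = [], []
    for centre in top["centre"]:
        near = [ref for ref in mucin_refs if abs(centre - ref) <= exclusion_window]
        (excluded if near else kept).append((float(centre), near))
    if not kept:
        detail = "; ".join(f"{c:.1f} (near mucin {refs})" for c, refs in excluded)
        raise ValueError(f"every candidate peak was mucin-excluded: {detail}")
    return sorted(c for c, _ in kept)
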