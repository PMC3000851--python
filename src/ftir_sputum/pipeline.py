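"""End-to-end pipeline: simulate/load -> preprocess -> screen -> panel -> MVA.

Every stage writes its artifact under the configured output directory and a
manifest records the full configuration, seed and library versions so a run
is re-derivable from the manifest alone. A cohort with no Holm-significant
wavenumber is reported gracefully (summary says so; the multivariate stages
are skipped) rather than raised.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .spectra import (GRID_STEP, SpectrumCohort, read_cohort_matrix,
                      write_cohort_matrix)
from .simulate import BandSpec, CohortConfig, generate_cohort
from .preprocess import (PreprocessParams, aggregate_replicates,
                         group_median_spectrum, preprocess_cohort)
from .stats import (DEFAULT_MUCIN_REFS, detect_band_centres,
                    match_significant_to_peaks, merge_peak_tables,
                    screen_wavenumbers, select_mva_panel)
from .mva import (build_panel_matrix, cluster_purity,
                  correlation_distance_matrix, cut_tree, pca_panel, to_newick,
                  upgma_tree)

log = logging.getLogger("ftir_sputum")


class ConfigError(ValueError):
    """All configuration violations, collected before aborting."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, written: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause} "
                         f"(artifacts written so far: {written or 'none'})")
        self.stage = stage
        self.written = written


@dataclass
class RunConfig:
    cohort_csv: str | None = None            # if None, simulate
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    alpha: float = 0.05
    min_prominence: float = 5e-5
    match_tolerance: float = 2.0 * GRID_STEP
    mucin_refs: tuple = DEFAULT_MUCIN_REFS
    exclusion_window: float = 10.0
    panel_size: int = 6
    distance: str = "correlation"
    standardize_pca: bool = True
    retention_threshold: float = 0.05
    n_clusters: int = 2
    out_dir: str = "ftir_run"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.distance not in ("correlation", "euclidean"):
            raise ConfigError(f"distance must be correlation or euclidean, got {self.distance!r}")
        self.cohort.seed = int(self.seed)


_CONFIG_SECTIONS = {
    "cohort": CohortConfig,
    "preprocess": PreprocessParams,
}


def validate_config(document: dict | None) -> RunConfig:
    """Build a RunConfig from a raw key-value document.

    Unknown keys are errors; every violation is collected and reported at
    once. An empty document yields the full-default configuration.
    """
    document = dict(document or {})
    errors: list[str] = []
    kwargs = {}
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    for key, value in document.items():
        if key not in top_fields:
            errors.append(f"unknown configuration key {key!r}")
            continue
        if key in _CONFIG_SECTIONS:
            cls = _CONFIG_SECTIONS[key]
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            sub_kwargs = {}
            for k, v in dict(value or {}).items():
                if k not in sub_fields:
                    errors.append(f"unknown configuration key {key}.{k!r}")
                elif k == "bands":
                    try:
                        sub_kwargs[k] = [BandSpec(**b) for b in v]
                    except (TypeError, ValueError) as exc:
                        errors.append(f"{key}.bands: {exc}")
                else:
                    sub_kwargs[k] = v
            if not errors:
                try:
                    kwargs[key] = cls(**sub_kwargs)
                except (TypeError, ValueError) as exc:
                    errors.append(f"{key}: {exc}")
        else:
            kwargs[key] = value
    if errors:
        raise ConfigError("; ".join(errors))
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _config_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    return enc(config)


@dataclass
class PipelineResult:
    cohort: SpectrumCohort
    per_sample: SpectrumCohort
    significance: pd.DataFrame
    peaks: pd.DataFrame
    matched: pd.DataFrame | None
    panel: list[float] | None
    assignment: np.ndarray | None
    purity: dict | None
    pca: object | None
    summary: str = ""
    artifacts: dict = field(default_factory=dict)


def run_full_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(str(path))
        return path

    def stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = stage("cohort")
        if config.cohort_csv is not None:
            cohort = read_cohort_matrix(config.cohort_csv, "wide_csv")
        else:
            cohort = generate_cohort(config.cohort)
            save("cohort.csv", lambda p: write_cohort_matrix(cohort, p, "wide_csv"))
        log.info("cohort: %d spectra, %d samples (%.2fs)", cohort.n_spectra,
                 len(cohort.sample_ids), time.perf_counter() - t0)
    except Exception as exc:
        raise PipelineStageError("cohort", written, exc) from exc

    try:
        stage("preprocess")
        processed = preprocess_cohort(cohort, config.preprocess)
        per_sample = aggregate_replicates(processed, config.preprocess)
        save("processed_per_sample.csv",
             lambda p: write_cohort_matrix(per_sample, p, "wide_csv"))
    except Exception as exc:
        raise PipelineStageError("preprocess", written, exc) from exc

    try:
        stage("screen")
        significance = screen_wavenumbers(per_sample, config.alpha)
        save("significance.csv", lambda p: significance.to_csv(p, index=False))
        medians = {lab: group_median_spectrum(per_sample, lab)
                   for lab in ("cancer", "normal")}
        peaks = merge_peak_tables(
            *(detect_band_centres(s, config.min_prominence) for s in medians.values())
        )
        save("peaks.csv", lambda p: peaks.to_csv(p, index=False))
    except Exception as exc:
        raise PipelineStageError("screen", written, exc) from exc

    n_significant = int(significance["reject"].sum())
    matched = panel = assignment = purity = pca = None
    panel_note = ""
    if n_significant == 0:
        panel_note = ("no Holm-significant wavenumbers at alpha="
                      f"{config.alpha}; panel selection and multivariate "
                      "analysis skipped")
        log.warning(panel_note)
    else:
        try:
            stage("panel")
            matched = match_significant_to_peaks(significance, peaks,
                                                 config.match_tolerance)
            if matched.empty:
                panel_note = ("no significant wavenumber matched a detected "
                              "band centre; multivariate analysis skipped")
                log.warning(panel_note)
            else:
                panel = select_mva_panel(matched, config.mucin_refs,
                                         config.exclusion_window, config.panel_size)
                save("panel.json", lambda p: p.write_text(
                    json.dumps({"panel_wavenumbers": panel}, indent=2)))
        except Exception as exc:
            raise PipelineStageError("panel", written, exc) from exc

    if panel is not None:
        try:
            stage("mva")
            pm = build_panel_matrix(per_sample, panel)
            if config.distance == "correlation":
                dmat = correlation_distance_matrix(pm)
            else:
                diff = pm.features[:, None, :] - pm.features[None, :, :]
                dmat = np.sqrt((diff**2).sum(-1))
            tree = upgma_tree(dmat, pm.sample_ids)
            save("tree.newick", lambda p: p.write_text(to_newick(tree) + "\n"))
            assignment = cut_tree(tree, config.n_clusters)
            clusters = pm.meta[["sample_id", "class"]].copy()
            clusters["cluster"] = assignment
            save("clusters.csv", lambda p: clusters.to_csv(p, index=False))
            purity = cluster_purity(assignment, pm.class_labels)
            pca = pca_panel(pm, config.standardize_pca, config.retention_threshold)
            save("pca_scores.csv", lambda p: pd.DataFrame(
                pca.scores, columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]
            ).assign(sample_id=pm.sample_ids, **{"class": pm.class_labels})
             .to_csv(p, index=False))
            save("pca_loadings.csv", lambda p: pd.DataFrame(
                pca.loadings, index=[f"{w:.2f}" for w in pm.wavenumbers],
                columns=[f"PC{i+1}" for i in range(pca.loadings.shape[1])]
            ).to_csv(p, index_label="wavenumber"))
            save("scree.csv", lambda p: pd.DataFrame({
                "component": np.arange(1, len(pca.variance_fraction) + 1),
                "variance_fraction": pca.variance_fraction,
                "retained": pca.variance_fraction >= config.retention_threshold,
            }).to_csv(p, index=False))
        except Exception as exc:
            raise PipelineStageError("mva", written, exc) from exc

    cfg = _config_dict(config)
    cfg_json = json.dumps(cfg, sort_keys=True)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"ftir_sputum": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "replicate_aggregation": config.preprocess.replicate_aggregate,
        "artifacts": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    written.append(str(out / "manifest.json"))

    lines = [
        f"samples: {len(per_sample.sample_ids)} "
        f"({int((per_sample.class_labels == 'cancer').sum())} cancer, "
        f"{int((per_sample.class_labels == 'normal').sum())} normal)",
        f"significant wavenumbers after Holm (alpha={config.alpha}): {n_significant}",
        f"detected band centres: {len(peaks)}",
    ]
    if panel_note:
        lines.append(panel_note)
    if matched is not None and not matched.empty:
        lines.append(f"matched significant peaks: {len(matched)}")
    if panel is not None:
        lines.append("panel wavenumbers (cm^-1): "
                     + ", ".join(f"{w:.1f}" for w in panel))
    if purity is not None:
        comp = "; ".join(
            f"cluster {int(c)}: " + ", ".join(
                f"{int(purity['contingency'].loc[c, cls])} {cls}"
                for cls in purity["contingency"].columns)
            for c in purity["contingency"].index)
        lines.append(f"two-cluster composition: {comp}")
        lines.append("class capture: " + ", ".join(
            f"{cls} {pct:.1f}%" for cls, pct in purity["capture"].items()))
    if pca is not None:
        lines.append("PCA variance fractions: "
                     + ", ".join(f"{f:.3f}" for f in pca.variance_fraction)
                     + f"; retained (>= {config.retention_threshold:.0%}): {pca.retained}")
    summary = "\n".join(lines) + "\n"
    (out / "summary.txt").write_text(summary)
    written.append(str(out / "summary.txt"))

    return PipelineResult(cohort=cohort, per_sample=per_sample,
                          significance=significance, peaks=peaks,
                          matched=matched, panel=panel, assignment=assignment,
                          purity=purity, pca=pca, summary=summary,
                          artifacts={Path(p).name: p for p in written})
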