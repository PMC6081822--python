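"""End-to-end study pipeline: cohort → per-layer signal strength, ΔS,
central serous volume, vessel density → group statistics.

The stages run in the order of the study workflow: volume normalization,
layer masks, per-layer signal strength for both devices and both scan
patterns, per-subject ΔS, CSV for detachment subjects, en-face
registration/binarization/density, then paired t-tests, ΔS-vs-CSV
regressions, and inter-device CSV agreement (regression + Bland-Altman).
Identical configuration and seed produce byte-identical report tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import angiography as ang
from . import metrics, segmentation, stats, synth
from .datamodel import ScanPatternConfig, builtin_scan_configs, \
    write_report_tables
from .errors import DegenerateInputError, OctaError

logger = logging.getLogger("octa_compare")

SLAB_LAYERS = ("superficial_retina", "deep_retina", "sattler", "haller")
DELTA_REGRESSION_LAYERS = ("deep_retina", "sattler", "haller")


@dataclass
class PipelineConfig:
    """Resolved run configuration (see ``as_dict`` for the full key set)."""

    n_normal: int = 7
    n_csr: int = 7
    n_truncated_csr: int = 0
    seed: int = 0
    patterns: tuple[str, ...] = ("3x3mm", "6x6mm")
    n_depth: int = 400
    axial_spacing_um: float = 5.0
    sattler_thickness_um: float = 100.0
    haller_thickness_um: float = 200.0
    min_gap_um: float = segmentation.DEFAULT_MIN_GAP_UM
    angio_noise_sd: float = 0.03
    faz_closing_radius_um: float = 30.0
    faz_fallback_radius_mm: float = 0.25
    device_overrides: dict = field(default_factory=dict)
    anatomical_jitter: bool = True
    out_dir: str | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise OctaError(f"unknown config keys: {sorted(unknown)}")
        if "patterns" in data:
            data["patterns"] = tuple(data["patterns"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.as_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def device_models(self) -> dict[str, synth.DeviceModel]:
        models = synth.default_device_models()
        for device, overrides in (self.device_overrides or {}).items():
            models[device] = dataclasses.replace(models[device], **overrides)
        return models

    def scan_configs(self) -> dict[tuple[str, str], ScanPatternConfig]:
        return builtin_scan_configs(n_depth=self.n_depth,
                                    axial_spacing=self.axial_spacing_um)


@dataclass
class ComparisonReport:
    """Per-subject metrics plus the group statistics tables."""

    subjects: pd.DataFrame
    deltas: pd.DataFrame
    paired_tests: pd.DataFrame
    regressions: pd.DataFrame
    bland_altman: pd.DataFrame
    metadata: dict


def _subject_scan_metrics(subject, config: ScanPatternConfig, cfg: PipelineConfig,
                          device_models) -> dict:
    """Normalization → masks → per-layer signal strength → CSV for one scan."""
    volume = subject.render_volume(config, device_models)
    normalized = metrics.normalize_volume(volume)
    surfaces = subject.measured_surfaces(config)
    choroid = segmentation.ChoroidParams(
        sattler_thickness_um=cfg.sattler_thickness_um,
        haller_thickness_um=cfg.haller_thickness_um)
    row = {"subject_id": subject.subject_id, "group": subject.group,
           "device": config.device, "pattern": config.pattern_name}
    strengths = {}
    for layer in SLAB_LAYERS:
        mask = segmentation.slab_mask(surfaces, layer, config, choroid)
        if mask.clipped:
            logger.warning("%s %s %s: %s slab clipped at the depth window",
                           subject.subject_id, config.device,
                           config.pattern_name, layer)
        s = metrics.layer_signal_strength(normalized, mask)
        strengths[layer] = s
        row[f"signal_{layer}"] = s.value
    cmask = segmentation.csr_mask(surfaces, config, cfg.min_gap_um)
    if cmask.voxel_count > 0:
        meas = segmentation.measure_csv(cmask, config)
        row["csv_mm3"] = meas.volume_mm3
        row["csv_truncated"] = meas.truncated_by_fov
        if meas.truncated_by_fov:
            logger.warning("%s %s %s: CSR region truncated by the field of view",
                           subject.subject_id, config.device,
                           config.pattern_name)
    else:
        row["csv_mm3"] = 0.0 if subject.group == "csr" else np.nan
        row["csv_truncated"] = False
    return {"row": row, "strengths": strengths}


def _angio_metrics(subject, cfg: PipelineConfig, configs, pattern: str) -> dict:
    """Registration, binarization, FAZ exclusion and density for one pattern."""
    a_sd = subject.render_angiogram(configs[("SD", pattern)],
                                    noise_sd=cfg.angio_noise_sd)
    a_ss = subject.render_angiogram(configs[("SS", pattern)],
                                    noise_sd=cfg.angio_noise_sd)
    roi = ang.register_angiograms(a_sd, a_ss)
    faz_cfg = ang.FAZConfig(closing_radius_um=cfg.faz_closing_radius_um,
                            fallback_radius_mm=cfg.faz_fallback_radius_mm)
    out = {}
    for device, angio in (("SD", a_sd), ("SS", a_ss)):
        b = ang.binarize_vessels(angio, roi)
        faz = ang.exclude_faz(b, roi, angio, faz_cfg)
        if faz.fallback_used:
            logger.warning("%s %s %s: FAZ fallback disk used",
                           subject.subject_id, device, pattern)
        out[device] = ang.vessel_density(b, roi, faz, pattern_name=pattern)
    return out


def run_pipeline(config: PipelineConfig | str | Path) -> ComparisonReport:
    """Execute the full comparison study and return the report.

    ``config`` is a :class:`PipelineConfig` or a path to its YAML form.
    When ``out_dir`` is set, the report tables, the resolved configuration
    and a run log are written there.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    t0 = time.time()
    scan_configs = {k: v for k, v in config.scan_configs().items()
                    if k[1] in config.patterns}
    device_models = config.device_models()
    cohort = synth.generate_cohort(
        config.n_normal, config.n_csr, seed=config.seed,
        configs=scan_configs, device_models=device_models,
        n_truncated_csr=config.n_truncated_csr,
        anatomical_jitter=config.anatomical_jitter)

    subject_rows, delta_rows = [], []
    for subject in cohort.subjects:
        logger.info("subject %s (%s)", subject.subject_id, subject.group)
        for pattern in config.patterns:
            per_device = {}
            for device in ("SD", "SS"):
                res = _subject_scan_metrics(
                    subject, scan_configs[(device, pattern)], config,
                    device_models)
                per_device[device] = res
            densities = _angio_metrics(subject, config, scan_configs, pattern)
            for device in ("SD", "SS"):
                row = per_device[device]["row"]
                d = densities[device]
                row["vessel_density_percent"] = d.density_percent
                row["faz_area_mm2"] = d.faz_area_mm2
                row["roi_radius_mm"] = d.roi_radius_mm
                subject_rows.append(row)
            for layer in SLAB_LAYERS:
                delta = metrics.signal_strength_difference(
                    per_device["SS"]["strengths"][layer],
                    per_device["SD"]["strengths"][layer])
                delta_rows.append({
                    "subject_id": subject.subject_id, "group": subject.group,
                    "pattern": pattern, "layer": layer, "delta_s": delta.delta,
                    "csv_mm3_sd": per_device["SD"]["row"]["csv_mm3"],
                    "csv_mm3_ss": per_device["SS"]["row"]["csv_mm3"],
                })

    subjects = pd.DataFrame(subject_rows)
    deltas = pd.DataFrame(delta_rows)
    paired = _paired_test_table(subjects, config)
    regressions = _regression_table(subjects, deltas, config)
    bland = _bland_altman_table(subjects, config)
    metadata = {"seed": config.seed, "config_hash": config.config_hash(),
                "n_subjects": len(cohort.subjects),
                "elapsed_s": round(time.time() - t0, 2),
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    report = ComparisonReport(subjects=subjects, deltas=deltas,
                              paired_tests=paired, regressions=regressions,
                              bland_altman=bland, metadata=metadata)
    report = flag_fov_outliers(report)
    if config.out_dir:
        _write_outputs(report, config)
    return report


def _paired_test_table(subjects: pd.DataFrame,
                       config: PipelineConfig) -> pd.DataFrame:
    """SD-vs-SS paired t-tests per group, pattern and metric."""
    rows = []
    metrics_cols = [f"signal_{layer}" for layer in SLAB_LAYERS] \
        + ["vessel_density_percent"]
    for group in ("normal", "csr"):
        for pattern in config.patterns:
            sel = subjects[(subjects.group == group)
                           & (subjects.pattern == pattern)]
            if sel.empty:
                continue
            sd = sel[sel.device == "SD"].set_index("subject_id")
            ss = sel[sel.device == "SS"].set_index("subject_id")
            common = sd.index.intersection(ss.index)
            for col in metrics_cols:
                x = sd.loc[common, col].to_numpy()
                y = ss.loc[common, col].to_numpy()
                base = {"group": group, "pattern": pattern, "metric": col,
                        "n": len(common),
                        "mean_sd": float(np.mean(x)) if len(x) else np.nan,
                        "std_sd": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
                        "mean_ss": float(np.mean(y)) if len(y) else np.nan,
                        "std_ss": float(np.std(y, ddof=1)) if len(y) > 1 else np.nan}
                try:
                    r = stats.paired_t_test(x, y)
                    base.update(mean_difference=r.mean_difference,
                                sd_difference=r.sd_difference,
                                t_statistic=r.t_statistic,
                                degrees_freedom=r.degrees_freedom,
                                p_value=r.p_value)
                except DegenerateInputError as exc:
                    logger.warning("paired test skipped (%s/%s/%s): %s",
                                   group, pattern, col, exc)
                    base.update(mean_difference=np.nan, sd_difference=np.nan,
                                t_statistic=np.nan, degrees_freedom=np.nan,
                                p_value=np.nan)
                rows.append(base)
    cols = ["group", "pattern", "metric", "n", "mean_sd", "std_sd", "mean_ss",
            "std_ss", "mean_difference", "sd_difference", "t_statistic",
            "degrees_freedom", "p_value"]
    return pd.DataFrame(rows, columns=cols)


def _regression_table(subjects: pd.DataFrame, deltas: pd.DataFrame,
                      config: PipelineConfig) -> pd.DataFrame:
    """ΔS-vs-CSV regressions per layer/pattern plus inter-device CSV."""
    rows = []
    csr_deltas = deltas[deltas.group == "csr"]
    for pattern in config.patterns:
        for layer in DELTA_REGRESSION_LAYERS:
            sel = csr_deltas[(csr_deltas.pattern == pattern)
                             & (csr_deltas.layer == layer)]
            sel = sel.dropna(subset=["csv_mm3_sd"])
            if len(sel) < 3:
                continue
            # regress against the mean of the two devices' CSV estimates
            x = (sel.csv_mm3_sd.to_numpy() + sel.csv_mm3_ss.to_numpy()) / 2.0
            r = stats.linear_regression(x, sel.delta_s.to_numpy())
            rows.append({"analysis": "delta_s_vs_csv", "pattern": pattern,
                         "layer": layer, "slope": r.slope,
                         "intercept": r.intercept, "r_squared": r.r_squared,
                         "p_value": r.p_value, "n": r.n})
        x, y = _paired_csv(subjects, pattern)
        if x.size >= 3:
            r = stats.linear_regression(x, y)
            rows.append({"analysis": "csv_sd_vs_ss", "pattern": pattern,
                         "layer": "csr_region", "slope": r.slope,
                         "intercept": r.intercept, "r_squared": r.r_squared,
                         "p_value": r.p_value, "n": r.n})
    cols = ["analysis", "pattern", "layer", "slope", "intercept", "r_squared",
            "p_value", "n"]
    return pd.DataFrame(rows, columns=cols)


def _paired_csv(subjects: pd.DataFrame, pattern: str):
    sel = subjects[(subjects.group == "csr") & (subjects.pattern == pattern)]
    sd = sel[sel.device == "SD"].set_index("subject_id").csv_mm3.dropna()
    ss = sel[sel.device == "SS"].set_index("subject_id").csv_mm3.dropna()
    common = sd.index.intersection(ss.index)
    return sd.loc[common].to_numpy(), ss.loc[common].to_numpy()


def _bland_altman_table(subjects: pd.DataFrame,
                        config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for pattern in config.patterns:
        x, y = _paired_csv(subjects, pattern)
        if x.size < 2:
            continue
        sel = subjects[(subjects.group == "csr")
                       & (subjects.pattern == pattern)
                       & (subjects.device == "SD")].dropna(subset=["csv_mm3"])
        ids = list(sel.subject_id)
        r = stats.bland_altman(x, y)
        outlier_ids = [i for i, flag in zip(ids, r.outliers) if flag]
        rows.append({"analysis": "csv_sd_vs_ss", "pattern": pattern,
                     "n": r.n, "mean_difference": r.mean_difference,
                     "sd_difference": r.sd_difference,
                     "lower_limit": r.lower_limit, "upper_limit": r.upper_limit,
                     "n_outliers": r.n_outliers,
                     "outlier_subjects": ";".join(outlier_ids)})
    cols = ["analysis", "pattern", "n", "mean_difference", "sd_difference",
            "lower_limit", "upper_limit", "n_outliers", "outlier_subjects"]
    return pd.DataFrame(rows, columns=cols)


def flag_fov_outliers(report: ComparisonReport) -> ComparisonReport:
    """Cross-reference field-of-view truncation with Bland-Altman outliers.

    A subject whose CSR region reaches the lateral edge of a scan field has
    a truncated CSV there; such subjects are flagged in the per-subject
    table, and the Bland-Altman table gains a column naming the flagged
    subjects among its outliers.
    """
    subjects = report.subjects.copy()
    trunc = subjects[subjects.get("csv_truncated", False) == True]  # noqa: E712
    flagged = set(trunc.subject_id) if not trunc.empty else set()
    subjects["fov_flagged"] = subjects.subject_id.isin(flagged)
    bland = report.bland_altman.copy()
    if not bland.empty:
        bland["flagged_outliers"] = [
            ";".join(sorted(set(str(o).split(";")) & flagged)) if o else ""
            for o in bland.outlier_subjects.fillna("")
        ]
    return ComparisonReport(subjects=subjects, deltas=report.deltas,
                            paired_tests=report.paired_tests,
                            regressions=report.regressions,
                            bland_altman=bland, metadata=report.metadata)


def _write_outputs(report: ComparisonReport, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_report_tables(report, out)
    report.deltas.to_csv(out / "delta_s.csv", index=False)
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.as_dict(), sort_keys=True))
    lines = [f"{k}: {v}" for k, v in report.metadata.items()]
    (out / "run.log").write_text("\n".join(lines) + "\n")
    logger.info("report written to %s", out)
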