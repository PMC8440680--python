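"""End-to-end study orchestration.

Reads en-face images plus a per-eye metadata table, applies the
signal-quality and motion-artifact gates, runs geometry → binarization →
morphometry per eye and timepoint for the ring and superior-quadrant ROIs,
assembles the cohort metric table, and runs the group statistics.  Every
output embeds the configuration hash and seed so runs are auditable and
byte-reproducible.

Quality-control metadata (signal quality index, motion-artifact score,
segmentation flag) are device/grader inputs, never computed here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, morphometry, stats
from .binarize import PhansalkarParams, phansalkar_threshold
from .image import DEFAULT_PIXEL_SCALE_UM, load_image

METRIC_COLUMNS = [
    "subject_id",
    "group",
    "timepoint",
    "roi_kind",
    "fd_count",
    "fd_percent",
    "m",
    "c",
    "r_squared",
    "intensity_mean",
    "intensity_sd",
    "kurtosis",
]

META_COLUMNS = [
    "subject_id",
    "group",
    "timepoint",
    "laterality",
    "image",
    "fovea_row",
    "fovea_col",
    "sqi",
    "motion_score",
]


@dataclass(frozen=True)
class StudyConfig:
    """All pipeline knobs; serialized (and hashed) into every output."""

    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    inner_diameter_mm: float = 4.0
    outer_diameter_mm: float = 6.0
    phansalkar: PhansalkarParams = field(default_factory=PhansalkarParams)
    min_equiv_diameter_um: float = 24.0
    bin_decades: float = 0.2
    rois: tuple[str, ...] = ("ring", "superior_quadrant")
    min_sqi: int = 7
    max_motion_score: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for roi in self.rois:
            if roi not in geometry.ROI_KINDS:
                raise ValueError(f"unknown ROI kind {roi!r}")
        if self.min_sqi < 0 or not 0 <= self.max_motion_score <= 4:
            raise ValueError("QC thresholds out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rois"] = list(self.rois)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phans = PhansalkarParams(**raw.pop("phansalkar", {}))
        if "rois" in raw:
            raw["rois"] = tuple(raw["rois"])
        return cls(phansalkar=phans, **raw)


@dataclass(frozen=True)
class EyeRecord:
    """One eye at one visit: identity, image path, geometry and QC metadata."""

    subject_id: str
    group: str
    timepoint: str
    laterality: str
    image_path: str
    fovea_center: tuple[float, float] | None
    sqi: int | None
    motion_score: int | None

    @classmethod
    def from_row(cls, row: pd.Series) -> "EyeRecord":
        def _num(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        fr, fc = _num("fovea_row"), _num("fovea_col")
        fovea = (float(fr), float(fc)) if fr is not None and fc is not None else None
        sqi = _num("sqi")
        motion = _num("motion_score")
        return cls(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            timepoint=str(row["timepoint"]),
            laterality=str(row.get("laterality", "OD")),
            image_path=str(row["image"]),
            fovea_center=fovea,
            sqi=None if sqi is None else int(sqi),
            motion_score=None if motion is None else int(motion),
        )


def qc_filter(
    records: list[EyeRecord], config: StudyConfig
) -> tuple[list[EyeRecord], list[tuple[EyeRecord, str]]]:
    """Partition records into QC passes and exclusions with reasons.

    Eyes with a signal quality index below ``min_sqi`` or a motion-artifact
    score above ``max_motion_score`` are excluded; missing QC fields exclude
    the record with reason ``missing_qc`` rather than passing silently.
    ``passed + excluded`` always accounts for every input record.
    """
    passed: list[EyeRecord] = []
    excluded: list[tuple[EyeRecord, str]] = []
    for rec in records:
        if rec.sqi is None or rec.motion_score is None:
            excluded.append((rec, "missing_qc"))
        elif rec.sqi < config.min_sqi:
            excluded.append((rec, "low_sqi"))
        elif rec.motion_score > config.max_motion_score:
            excluded.append((rec, "motion_artifact"))
        else:
            passed.append(rec)
    assert len(passed) + len(excluded) == len(records)
    return passed, excluded


def analyze_eye(
    record: EyeRecord, config: StudyConfig, images_dir=None
) -> tuple[list[dict], dict]:
    """Run geometry → threshold → morphometry for one eye.

    Returns one metric row per ROI plus the eye's log-binned size points
    (log10 area, log10 count) per ROI for the slope-comparison matrix.
    """
    path = Path(record.image_path)
    if images_dir is not None and not path.is_absolute():
        path = Path(images_dir) / path
    image = load_image(
        path, pixel_scale_um=config.pixel_scale_um, fovea_center=record.fovea_center
    )
    ring = geometry.build_ring_mask(
        image, config.inner_diameter_mm, config.outer_diameter_mm
    )
    fd_map = phansalkar_threshold(image, config.phansalkar)
    rows = []
    size_points: dict = {}
    for roi_kind in config.rois:
        if roi_kind == geometry.RING:
            roi = ring
        else:
            roi = geometry.build_quadrant_mask(
                ring, image, roi_kind, eye_side=record.laterality
            )
        fds = morphometry.extract_flow_deficits(
            fd_map, roi, config.min_equiv_diameter_um
        )
        metrics = morphometry.fd_metrics(fds)
        try:
            fit = morphometry.fit_size_distribution(fds, config.bin_decades)
            m, c, r2 = fit.m, fit.c, fit.r_squared
        except morphometry.UnderdeterminedFitError:
            m = c = r2 = float("nan")
        if fds.components:
            centers, counts = morphometry.log_bin_areas(
                fds.areas_um2, config.bin_decades
            )
            keep = counts > 0
            size_points[roi_kind] = list(
                zip(centers[keep], np.log10(counts[keep].astype(float)))
            )
        istats = morphometry.intensity_stats(image, roi)
        rows.append(
            {
                "subject_id": record.subject_id,
                "group": record.group,
                "timepoint": record.timepoint,
                "roi_kind": roi_kind,
                "fd_count": metrics.fd_count,
                "fd_percent": metrics.fd_percent,
                "m": m,
                "c": c,
                "r_squared": r2,
                "intensity_mean": istats.mean,
                "intensity_sd": istats.sd,
                "kurtosis": istats.kurtosis,
            }
        )
    return rows, size_points


def _cell_values(metrics: pd.DataFrame, metric: str, roi: str, group: str, tp: str):
    sel = metrics[
        (metrics["roi_kind"] == roi)
        & (metrics["group"] == group)
        & (metrics["timepoint"] == tp)
    ]
    return sel[metric].to_numpy(dtype=float)


def compute_group_stats(metrics: pd.DataFrame, config: StudyConfig) -> dict:
    """Baseline tests, mixed ANOVA and normality screens per metric × ROI."""
    report: dict = {}
    scalar_metrics = ["fd_percent", "intensity_mean", "intensity_sd", "kurtosis"]
    groups = sorted(metrics["group"].unique())
    for roi in config.rois:
        roi_block: dict = {}
        for metric in scalar_metrics:
            block: dict = {}
            base = {
                g: _cell_values(metrics, metric, roi, g, "baseline") for g in groups
            }
            try:
                block["baseline_normality_p"] = {
                    g: stats.ks_normality(v) for g, v in base.items() if v.size >= 3
                }
            except stats.ZeroVarianceError:
                block["baseline_normality_p"] = None
            if len(groups) == 2 and all(v.size >= 2 for v in base.values()):
                t, p = stats.unpaired_t_test(base[groups[0]], base[groups[1]])
                block["baseline_t_test"] = {"t": t, "p": p}
            long = metrics[metrics["roi_kind"] == roi][
                ["subject_id", "group", "timepoint", metric]
            ].rename(columns={metric: "value"})
            try:
                rm = stats.rm_anova_2x2(long)
                block["rm_anova"] = {
                    "interaction_f": rm.interaction_f,
                    "interaction_p": rm.interaction_p,
                    "time_f": rm.time_f,
                    "time_p": rm.time_p,
                    "group_f": rm.group_f,
                    "group_p": rm.group_p,
                    "n_per_group": rm.n_per_group,
                    "time_effect_reportable": rm.time_effect_reportable,
                }
            except (ValueError, stats.DegenerateDataError) as exc:
                block["rm_anova"] = {"error": str(exc)}
            roi_block[metric] = block
        report[roi] = roi_block
    return report


def _pooled_size_points(metrics_sizes: dict, key) -> tuple[np.ndarray, np.ndarray]:
    pts = metrics_sizes.get(key, [])
    if not pts:
        return np.empty(0), np.empty(0)
    arr = np.array(pts, dtype=float)
    return arr[:, 0], arr[:, 1]


def slope_comparison_matrix(size_points: dict, roi: str) -> dict:
    """Nested-model F-tests between pooled log–log size points of the four cells.

    ``size_points`` maps (roi, group, timepoint) to a list of
    (log10 area, log10 count) points pooled over eyes.
    """
    cells = [
        ("RPD", "baseline"),
        ("RPD", "follow_up"),
        ("control", "baseline"),
        ("control", "follow_up"),
    ]
    pairs = [
        (("RPD", "baseline"), ("control", "baseline")),
        (("RPD", "follow_up"), ("control", "follow_up")),
        (("RPD", "baseline"), ("RPD", "follow_up")),
        (("control", "baseline"), ("control", "follow_up")),
    ]
    out = {}
    for a, b in pairs:
        xa, ya = _pooled_size_points(size_points, (roi,) + a)
        xb, yb = _pooled_size_points(size_points, (roi,) + b)
        key = f"{a[0]}_{a[1]}__vs__{b[0]}_{b[1]}"
        if xa.size < 3 or xb.size < 3:
            out[key] = {"error": "insufficient points"}
            continue
        try:
            slopes, intercepts = stats.compare_regressions(xa, ya, xb, yb)
        except ValueError as exc:
            out[key] = {"error": str(exc)}
            continue
        out[key] = {
            "slopes": {"f": slopes.f_value, "p": slopes.p_value,
                       "df": [slopes.df_num, slopes.df_den]},
            "intercepts": {"f": intercepts.f_value, "p": intercepts.p_value,
                           "df": [intercepts.df_num, intercepts.df_den]},
        }
    return out


def run_study(config: StudyConfig, meta_csv, out_dir, images_dir=None) -> dict:
    """Full pipeline over a metadata table; writes metrics CSV, stats JSON, log.

    A failing eye (unreadable image, geometry mismatch) is logged and
    dropped from the metric table without aborting the run.  Returns a
    summary dict with the written paths and bookkeeping counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(meta_csv)
    missing_cols = [c for c in ("subject_id", "group", "timepoint", "image") if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata CSV missing columns {missing_cols}")
    records = [EyeRecord.from_row(row) for _, row in meta.iterrows()]
    passed, excluded = qc_filter(records, config)

    log_lines = [
        f"config_hash={config.config_hash()}",
        f"seed={config.seed}",
        f"records={len(records)} passed={len(passed)} excluded={len(excluded)}",
    ]
    for rec, reason in excluded:
        log_lines.append(
            f"excluded subject={rec.subject_id} timepoint={rec.timepoint} reason={reason}"
        )

    rows: list[dict] = []
    size_points: dict = {}
    failed = 0
    for rec in passed:
        try:
            eye_rows, eye_points = analyze_eye(rec, config, images_dir=images_dir)
        except Exception as exc:  # fail the eye, not the run
            failed += 1
            log_lines.append(
                f"failed subject={rec.subject_id} timepoint={rec.timepoint} error={exc}"
            )
            continue
        rows.extend(eye_rows)
        for roi_kind, pts in eye_points.items():
            size_points.setdefault((roi_kind, rec.group, rec.timepoint), []).extend(pts)

    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    header = f"# config_hash={config.config_hash()} seed={config.seed}\n"
    metrics_path = out_dir / "metrics.csv"
    with open(metrics_path, "w") as fh:
        fh.write(header)
        metrics.to_csv(fh, index=False, lineterminator="\n")

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_records": len(records),
        "n_passed_qc": len(passed),
        "n_excluded": len(excluded),
        "n_failed": failed,
        "exclusions": [
            {"subject_id": r.subject_id, "timepoint": r.timepoint, "reason": reason}
            for r, reason in excluded
        ],
    }
    if not metrics.empty:
        group_report = compute_group_stats(metrics, config)
        for roi in config.rois:
            group_report[roi]["slope_comparisons"] = slope_comparison_matrix(
                size_points, roi
            )
        report["stats"] = group_report
    stats_path = out_dir / "stats.json"
    stats_path.write_text(json.dumps(report, indent=2, default=float) + "\n")
    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    return {
        "metrics_csv": str(metrics_path),
        "stats_json": str(stats_path),
        "log": str(log_path),
        "n_rows": len(metrics),
        "n_passed": len(passed),
        "n_excluded": len(excluded),
        "n_failed": failed,
    }


def stats_report(metrics_csv, config: StudyConfig | None = None) -> dict:
    """Statistics report from an existing metrics CSV (no images needed)."""
    config = config or StudyConfig()
    metrics = pd.read_csv(metrics_csv, comment="#")
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stats": compute_group_stats(metrics, config),
    }
    return report
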