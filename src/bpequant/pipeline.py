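"""End-to-end per-patient and cohort runners, configuration and logging.

``run_patient`` composes the quantitative pipeline in acquisition order:
bias correction of each volume (N4) -> rigid registration of the
post-contrast volume onto the pre-contrast grid -> breast-mask construction
from the supervised chest-wall delimitation -> FGT segmentation by fuzzy
C-means -> enhancement-ratio map -> BPE20% / FGT% metrics.  ``run_cohort``
batches it over a manifest of patients and timepoints, pairs timepoints into
dBPE20%, and hands the resulting table to the statistics layer.  Every run
can write its resolved configuration next to its outputs so a run is
reproducible from the output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bpe import (
    DEFAULT_THRESHOLD,
    compute_bpe,
    compute_fgt_pct,
    default_floor,
    enhancement_ratio_map,
)
from .cohort_stats import cohen_kappa, fit_recurrence_model, pearson_r, two_sample_t
from .grid import VolumeGrid, read_volume, write_volume
from .preprocess import (
    BiasConfig,
    RegistrationConfig,
    apply_transform,
    correct_bias,
    register_post_to_pre,
)
from .segment import ChestWallSpec, SegmentConfig, build_breast_mask, segment_fgt

logger = logging.getLogger("bpequant")

__all__ = [
    "RunConfig",
    "StageError",
    "run_patient",
    "run_cohort",
    "load_chest_spec",
]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (all stage settings + seed)."""

    bias: BiasConfig = field(default_factory=BiasConfig)
    reg: RegistrationConfig = field(default_factory=RegistrationConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    bpe_threshold: float = DEFAULT_THRESHOLD
    floor_fraction: float = 0.01  # I_pre floor as a fraction of in-mask median
    valid_denominator: bool = True
    ratio_on_corrected: bool = False  # ratio from bias-corrected instead of raw volumes
    seed: int = 0
    keep_intermediates: bool = False
    output_dir: str | None = None
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("bias", BiasConfig), ("reg", RegistrationConfig), ("segment", SegmentConfig)):
            if key in d and isinstance(d[key], dict):
                known = {f.name for f in dataclasses.fields(sub)}
                extra = set(d[key]) - known
                if extra:
                    raise ValueError(f"unknown {key} config keys: {sorted(extra)}")
                val = dict(d[key])
                for f in dataclasses.fields(sub):
                    if f.name in val and isinstance(val[f.name], list):
                        val[f.name] = tuple(val[f.name])
                d[key] = sub(**val)
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _body_mask(data: np.ndarray) -> np.ndarray:
    """Air/body split for bias correction (lowest three-class Otsu cut)."""
    from .segment import body_air_threshold

    try:
        thr = body_air_threshold(data)
    except ValueError:
        thr = 0.0
    return data > thr


class StageError(RuntimeError):
    """A pipeline-stage failure, tagged with the stage and patient it came from."""

    def __init__(self, stage: str, patient_id: str, cause: Exception):
        super().__init__(f"[{stage}] patient {patient_id}: {cause}")
        self.stage = stage
        self.patient_id = patient_id
        self.cause = cause


def load_chest_spec(path: str | Path) -> ChestWallSpec:
    """Load a chest-wall spec: JSON/CSV control points or a NIfTI exclusion mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"chest-wall spec not found: {path}")
    if path.suffix in (".json",):
        payload = json.loads(path.read_text())
        pts = np.asarray(payload["control_points"], float)
        return ChestWallSpec(control_points=pts, surface_degree=int(payload.get("surface_degree", 1)))
    if path.suffix in (".csv", ".tsv"):
        pts = pd.read_csv(path, sep="," if path.suffix == ".csv" else "\t").to_numpy(float)
        return ChestWallSpec(control_points=pts)
    mask = read_volume(path)
    return ChestWallSpec(exclusion_mask=mask.data > 0.5)


def _stage(name: str, patient_id: str):
    """Context decorator reporting stage failures with stage name and timing."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise StageError(name, patient_id, exc) from exc
            logger.info("stage %-18s patient %-10s %.2fs", name, patient_id, dt)
            return False

    return _Ctx()


def run_patient(
    pre_path: str | Path | VolumeGrid,
    post_path: str | Path | VolumeGrid,
    chest_spec: str | Path | ChestWallSpec,
    config: RunConfig | None = None,
    patient_id: str = "anon",
    timepoint: str = "pre",
    tumor_mask: np.ndarray | None = None,
) -> dict:
    """Run the full quantitative pipeline for one patient study.

    Accepts file paths or in-memory ``VolumeGrid``/``ChestWallSpec`` objects.
    Returns a flat metric record (JSON/CSV-ready); deterministic for a fixed
    configuration.  Failures are raised as ``StageError`` tagged with the
    stage name and patient id.
    """
    config = config or RunConfig()

    with _stage("load", patient_id):
        pre = pre_path if isinstance(pre_path, VolumeGrid) else read_volume(pre_path)
        post = post_path if isinstance(post_path, VolumeGrid) else read_volume(post_path)
        chest = chest_spec if isinstance(chest_spec, ChestWallSpec) else load_chest_spec(chest_spec)

    with _stage("bias_correction", patient_id):
        if config.bias.enabled:
            pre_c, _ = correct_bias(pre, _body_mask(pre.data), config.bias)
            post_c, _ = correct_bias(post, _body_mask(post.data), config.bias)
        else:
            pre_c, post_c = pre, post

    with _stage("registration", patient_id):
        reg = register_post_to_pre(pre_c, post_c, config.reg)

    with _stage("breast_mask", patient_id):
        breast = build_breast_mask(pre_c, chest, config.segment, tumor_mask=tumor_mask)

    with _stage("fgt_segmentation", patient_id):
        masks = segment_fgt(pre_c, breast, config.segment)

    with _stage("bpe_metrics", patient_id):
        # The enhancement ratio is computed from raw intensities: the coil
        # bias field is shared by the pre and post acquisitions and cancels
        # exactly in (I_post - I_pre)/I_pre, whereas dividing by two
        # independently estimated fields injects their differential error
        # into the ratio.  Correction is still what segmentation and the
        # registration similarity run on.
        if config.ratio_on_corrected:
            ratio_pre, ratio_post = pre_c, reg.warped
        else:
            ratio_pre, ratio_post = pre, apply_transform(post, pre, reg)
        floor = default_floor(ratio_pre, breast, config.floor_fraction)
        emap = enhancement_ratio_map(ratio_pre, ratio_post, floor)
        result = compute_bpe(
            emap, masks, pre_c.spacing, config.bpe_threshold, config.valid_denominator
        )
        fgt_pct = compute_fgt_pct(masks, pre_c.spacing)

    record = {
        "patient_id": patient_id,
        "timepoint": timepoint,
        "v_breast": result.v_breast,
        "v_fgt": result.v_fgt,
        "v_bpe": result.v_bpe,
        "fgt_pct": fgt_pct,
        "bpe20_pct": result.bpe20_pct,
        "n_invalid": result.n_invalid,
        "threshold": result.threshold,
        "reg_translation_mm": list(reg.translation_mm),
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.save(out / "config.yaml")
        (out / f"{patient_id}_{timepoint}_metrics.json").write_text(json.dumps(record, indent=2))
        if config.keep_intermediates:
            write_volume(pre_c, out / f"{patient_id}_{timepoint}_pre_corrected.nii.gz")
            write_volume(reg.warped, out / f"{patient_id}_{timepoint}_post_warped.nii.gz")
            write_volume(pre_c.with_data(masks.fgt_mask.astype(float)), out / f"{patient_id}_{timepoint}_fgt_mask.nii.gz")
            write_volume(pre_c.with_data(emap.ratio), out / f"{patient_id}_{timepoint}_ratio.nii.gz")
    return record


def run_cohort(manifest: str | Path | dict, config: RunConfig | None = None) -> dict:
    """Run the pipeline over a cohort manifest and compute the statistics battery.

    The manifest (JSON file or dict) lists per-patient entries::

        {"patients": [{"id": ..., "timepoints": {"pre": {"pre": path, "post": path,
          "chest_spec": path}, "post": {...}}, "clinical": {...}}, ...]}

    Patients with a failed timepoint are excluded from paired analyses and
    listed under ``failures``.  Returns ``{"table": DataFrame, "failures": [...],
    "stats": {...}}``; the statistics battery runs only on the columns present.
    """
    config = config or RunConfig()
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())

    rows: list[dict] = []
    failures: list[dict] = []
    for entry in manifest["patients"]:
        pid = str(entry["id"])
        per_tp: dict[str, dict] = {}
        ok = True
        for tp, paths in entry["timepoints"].items():
            try:
                rec = run_patient(
                    paths["pre"], paths["post"], paths["chest_spec"],
                    config=config, patient_id=pid, timepoint=tp,
                )
                per_tp[tp] = rec
            except StageError as exc:
                failures.append({"patient_id": pid, "timepoint": tp, "stage": exc.stage, "error": str(exc)})
                ok = False
        if not ok:
            continue
        row = {"id": pid, **entry.get("clinical", {})}
        for tp, rec in per_tp.items():
            row[f"bpe20_{tp}"] = rec["bpe20_pct"]
            row[f"fgt_pct_{tp}"] = rec["fgt_pct"]
        if "pre" in per_tp and "post" in per_tp and per_tp["pre"]["bpe20_pct"] > 0:
            row["delta_bpe20"] = (
                100.0
                * (per_tp["post"]["bpe20_pct"] - per_tp["pre"]["bpe20_pct"])
                / per_tp["pre"]["bpe20_pct"]
            )
        rows.append(row)

    table = pd.DataFrame(sorted(rows, key=lambda r: r["id"]))
    stats = cohort_statistics(table)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.save(out / "config.yaml")
        table.to_csv(out / "cohort_table.csv", index=False)
        (out / "cohort_stats.json").write_text(json.dumps(stats, indent=2, default=str))
    return {"table": table, "failures": failures, "stats": stats}


def cohort_statistics(table: pd.DataFrame, covariates: list[str] | None = None) -> dict:
    """Statistics battery on whichever cohort columns are available."""
    stats: dict = {"n": len(table)}
    if {"bpe20_pre", "bpe20_post"} <= set(table.columns) and len(table) >= 3:
        paired = table[["bpe20_pre", "bpe20_post"]].dropna()
        r = pearson_r(paired["bpe20_pre"], paired["bpe20_post"])
        stats["pearson_bpe_pre_post"] = {"r": r.statistic, "p": r.p_value}
    if {"visual_fgt_r1", "visual_fgt_r2"} <= set(table.columns):
        k = cohen_kappa(table["visual_fgt_r1"], table["visual_fgt_r2"])
        stats["kappa_visual_fgt"] = {"kappa": k.kappa, "p": k.p_value}
    if {"bpe20_post", "pcr"} <= set(table.columns):
        g1 = table.loc[table["pcr"].astype(bool), "bpe20_post"].dropna()
        g0 = table.loc[~table["pcr"].astype(bool), "bpe20_post"].dropna()
        if len(g1) >= 2 and len(g0) >= 2:
            t = two_sample_t(g1, g0)
            stats["ttest_bpe_post_by_pcr"] = {"t": t.statistic, "p": t.p_value}
    surv_cols = {"rfs_months", "recurrence"}
    if surv_cols <= set(table.columns):
        covs = covariates or [c for c in ("bpe20_post", "age") if c in table.columns]
        try:
            cox = fit_recurrence_model(table, covs)
            stats["cox"] = {
                "n": cox.n,
                "n_events": cox.n_events,
                "lrt_p": cox.lrt_p_value,
                "hazard_ratios": cox.summary["hazard_ratio"].to_dict(),
                "coefs": cox.summary["coef"].to_dict(),
                "p_values": cox.summary["p_value"].to_dict(),
            }
        except (ValueError, RuntimeError) as exc:
            stats["cox"] = {"error": str(exc)}
    return stats
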