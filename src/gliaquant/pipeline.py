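"""End-to-end orchestration: stacks in, score tables and statistics out.

``run_pipeline`` drives the full analysis for every stack in a run config:
per-channel unsharp denoising, decision-tree thresholding, cortex
segmentation, plane scoring, then per-animal global scores, depth-profile
sliding windows and the group/correlation statistics.  Per-stack failures
are isolated and logged so one corrupt file does not sink a run; outputs
are deterministic given the config, and every output file carries the
config hash in a header line for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import binarize, cortex, scoring, stats
from .stacks import CHANNELS, StackRecord, normalize_z, read_stack

logger = logging.getLogger("gliaquant")


@dataclass(frozen=True)
class StackEntry:
    path: Path
    animal_id: str
    group: str
    z_orientation: str = "ventral_first"
    keep_range: tuple[int, int] | None = None


@dataclass
class BinarizeSettings:
    min_size: int = 75
    blowout_threshold: float = 0.07
    blackout_threshold: float = 0.02
    band_axis: int = 0
    connectivity: int = 2


@dataclass
class RunConfig:
    stacks: list[StackEntry]
    output_dir: Path = Path("results")
    denoise: dict[str, binarize.DenoiseParams] = field(
        default_factory=lambda: dict(binarize.DEFAULT_DENOISE)
    )
    binarize: BinarizeSettings = field(default_factory=BinarizeSettings)
    segmentation: cortex.SegmentationParams = field(
        default_factory=cortex.SegmentationParams
    )
    body_filter: scoring.CellBodyFilter = field(default_factory=scoring.CellBodyFilter)
    clip_ami_to_cortex: bool = False
    window_width: float = 10.0
    window_step: float = 1.0
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; stack paths are resolved against the file."""
    path = Path(path)
    raw: Mapping[str, Any] = yaml.safe_load(path.read_text())
    base = path.parent

    entries = []
    for item in raw.get("stacks", []):
        keep = item.get("keep_range")
        entries.append(
            StackEntry(
                path=(base / item["path"]).resolve(),
                animal_id=item.get("animal_id", Path(item["path"]).stem),
                group=item["group"],
                z_orientation=item.get("z_orientation", "ventral_first"),
                keep_range=tuple(keep) if keep is not None else None,
            )
        )
    if not entries:
        raise ValueError(f"{path}: config lists no stacks")

    cfg = RunConfig(stacks=entries)
    if "output_dir" in raw:
        out = Path(raw["output_dir"])
        cfg.output_dir = out if out.is_absolute() else base / out
    if "denoise" in raw:
        for channel, params in raw["denoise"].items():
            if channel not in CHANNELS:
                raise ValueError(f"unknown denoise channel {channel!r}")
            cfg.denoise[channel] = binarize.DenoiseParams(**params)
    if "binarize" in raw:
        cfg.binarize = BinarizeSettings(**raw["binarize"])
    if "segmentation" in raw:
        cfg.segmentation = cortex.SegmentationParams(**raw["segmentation"])
    if "body_filter" in raw:
        cfg.body_filter = scoring.CellBodyFilter(**raw["body_filter"])
    for key in ("clip_ami_to_cortex", "window_width", "window_step", "seed", "log_level"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


def config_hash(config: RunConfig) -> str:
    """Short stable digest of the analysis configuration.

    The output directory and log level are excluded: the hash identifies
    what was computed and from which inputs, not where results were put.
    """

    def _plain(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        return obj

    plain = _plain(dataclasses.asdict(config))
    plain.pop("output_dir", None)
    plain.pop("log_level", None)
    payload = json.dumps(plain, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def process_stack(
    record: StackRecord, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Denoise, threshold, segment and score every plane of one stack.

    Returns the plane-score table and the per-plane threshold decision log.
    """
    record = normalize_z(record)
    bs = config.binarize
    score_rows = []
    decision_rows = []
    for z in range(record.n_planes):
        masks: dict[str, np.ndarray] = {}
        for channel in CHANNELS:
            denoised = binarize.unsharp_mask(
                record.channel(z, channel), config.denoise[channel]
            )
            mask, decision = binarize.select_threshold(
                denoised,
                channel,
                min_size=bs.min_size,
                blowout_threshold=bs.blowout_threshold,
                blackout_threshold=bs.blackout_threshold,
                band_axis=bs.band_axis,
                connectivity=bs.connectivity,
            )
            masks[channel] = mask
            decision_rows.append(
                {
                    "animal_id": record.animal_id,
                    "group": record.group,
                    "z_index": z,
                    **dataclasses.asdict(decision),
                }
            )
        seg = cortex.segment_cortex(
            masks["cortex_glia"], masks["nuclei"], config.segmentation
        )
        plane = scoring.score_plane(
            masks["astrocyte"],
            masks["cortex_glia"],
            seg,
            animal_id=record.animal_id,
            group=record.group,
            z_index=z,
            z_norm=float(record.z_norm[z]),
            body_filter=config.body_filter,
            clip_ami_to_cortex=config.clip_ami_to_cortex,
        )
        score_rows.append(dataclasses.asdict(plane))
    return pd.DataFrame(score_rows), pd.DataFrame(decision_rows)


@dataclass
class RunResult:
    scores: pd.DataFrame
    decisions: pd.DataFrame
    global_scores: pd.DataFrame
    window_profiles: pd.DataFrame
    window_correlation: pd.DataFrame
    statistics: dict
    failures: list[tuple[str, str]]
    output_files: dict[str, Path]


def _write_csv(df: pd.DataFrame, path: Path, digest: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# gliaquant config={digest}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _run_statistics(global_scores: pd.DataFrame) -> dict:
    out: dict[str, Any] = {"n_animals": int(len(global_scores))}
    groups = sorted(global_scores["group"].unique())
    if len(groups) >= 2 and len(global_scores) >= 3:
        for col in ("ami", "ais"):
            by_group = {
                g: global_scores.loc[global_scores["group"] == g, col].dropna().to_numpy()
                for g in groups
            }
            by_group = {g: v for g, v in by_group.items() if v.size}
            if len(by_group) >= 2:
                kd = stats.kruskal_dunn(by_group)
                out[f"kruskal_{col}"] = {
                    "h": kd.h,
                    "p": kd.p,
                    "pairwise": kd.pairwise.to_dict(orient="records"),
                }
    both = global_scores.dropna(subset=["ami", "ais"])
    if len(both) >= 3 and both["ami"].nunique() > 1 and both["ais"].nunique() > 1:
        rho, p = stats.spearman(both["ami"], both["ais"])
        out["spearman_global"] = {"rho": rho, "p": p}
    return out


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline over every stack in ``config``.

    Per-stack read/processing failures are logged and isolated; the run
    continues and the failures are reported in the result (the CLI exits
    non-zero when any occurred).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config_hash(config)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, str(config.log_level).upper(), logging.INFO))
    logger.info("run config hash %s (%d stacks)", digest, len(config.stacks))

    all_scores, all_decisions, failures = [], [], []
    try:
        for entry in sorted(config.stacks, key=lambda e: e.animal_id):
            try:
                record = read_stack(
                    entry.path,
                    group=entry.group,
                    animal_id=entry.animal_id,
                    z_orientation=entry.z_orientation,
                    keep_range=entry.keep_range,
                )
                scores_df, decisions_df = process_stack(record, config)
            except Exception as exc:  # noqa: BLE001 - isolation contract
                logger.error("stack %s failed: %s", entry.animal_id, exc)
                failures.append((entry.animal_id, str(exc)))
                continue
            logger.info("scored stack %s (%d planes)", entry.animal_id, len(scores_df))
            all_scores.append(scores_df)
            all_decisions.append(decisions_df)
    finally:
        logger.removeHandler(handler)
        handler.close()

    if not all_scores:
        raise RuntimeError("no stack could be processed; see run.log")

    scores = pd.concat(all_scores, ignore_index=True)
    decisions = pd.concat(all_decisions, ignore_index=True)
    global_scores = stats.animal_global_scores(scores)
    profiles, correlation = stats.sliding_window(
        scores, width=config.window_width, step=config.window_step
    )
    statistics = _run_statistics(global_scores)
    statistics["config_hash"] = digest
    statistics["failures"] = [{"animal_id": a, "error": e} for a, e in failures]

    files = {
        "scores": outdir / "scores.csv",
        "decisions": outdir / "decisions.csv",
        "global_scores": outdir / "global_scores.csv",
        "window_profiles": outdir / "window_profiles.csv",
        "window_correlation": outdir / "window_correlation.csv",
        "statistics": outdir / "statistics.json",
        "log": log_path,
    }
    _write_csv(scores, files["scores"], digest)
    _write_csv(decisions, files["decisions"], digest)
    _write_csv(global_scores, files["global_scores"], digest)
    _write_csv(profiles, files["window_profiles"], digest)
    _write_csv(correlation, files["window_correlation"], digest)
    files["statistics"].write_text(json.dumps(statistics, indent=2, default=float))

    return RunResult(
        scores=scores,
        decisions=decisions,
        global_scores=global_scores,
        window_profiles=profiles,
        window_correlation=correlation,
        statistics=statistics,
        failures=failures,
        output_files=files,
    )


def _load_binary_mask(path: Path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path)) > 0


def validate_run(
    config: RunConfig,
    *,
    manual_mask_dir: str | Path | None = None,
    manual_scores: pd.DataFrame | str | Path | None = None,
) -> dict:
    """Compare the automated pipeline against manual annotations.

    ``manual_mask_dir`` holds manually traced cortex masks named
    ``{animal_id}_z{z}_cortex.tif``; overlap (OL/M, OL/A) is reported per
    plane.  ``manual_scores`` is a table with columns ``animal_id`` plus
    any of ``mgs`` (ordinal globularity, optionally one column per rater
    as ``mgs_<rater>``) and ``mis`` (manual infiltration percent); it is
    joined to automated global scores for the validation regression,
    rater-agreement ICC(3,k) and per-group manual-vs-automated
    Kruskal-Wallis comparisons.
    """
    result = run_pipeline(config)
    report: dict[str, Any] = {"config_hash": result.statistics["config_hash"]}

    if manual_mask_dir is not None:
        mask_dir = Path(manual_mask_dir)
        rows = []
        unmatched = []
        for entry in sorted(config.stacks, key=lambda e: e.animal_id):
            try:
                record = read_stack(
                    entry.path,
                    group=entry.group,
                    animal_id=entry.animal_id,
                    z_orientation=entry.z_orientation,
                    keep_range=entry.keep_range,
                )
            except ValueError:
                continue
            for z in range(record.n_planes):
                mask_path = mask_dir / f"{entry.animal_id}_z{z}_cortex.tif"
                if not mask_path.exists():
                    unmatched.append(mask_path.name)
                    continue
                manual = _load_binary_mask(mask_path)
                bs = config.binarize
                masks = {}
                for channel in ("cortex_glia", "nuclei"):
                    denoised = binarize.unsharp_mask(
                        record.channel(z, channel), config.denoise[channel]
                    )
                    masks[channel], _ = binarize.select_threshold(
                        denoised,
                        channel,
                        min_size=bs.min_size,
                        blowout_threshold=bs.blowout_threshold,
                        blackout_threshold=bs.blackout_threshold,
                        band_axis=bs.band_axis,
                        connectivity=bs.connectivity,
                    )
                seg = cortex.segment_cortex(
                    masks["cortex_glia"], masks["nuclei"], config.segmentation
                )
                metrics = cortex.overlap_metrics(seg.mask, manual)
                rows.append(
                    {
                        "animal_id": entry.animal_id,
                        "z_index": z,
                        "ol_m": metrics.ol_m,
                        "ol_a": metrics.ol_a,
                    }
                )
        overlap = pd.DataFrame(rows)
        report["segmentation_overlap"] = {
            "per_plane": overlap.to_dict(orient="records"),
            "mean_ol_m": float(overlap["ol_m"].mean()) if len(overlap) else None,
            "mean_ol_a": float(overlap["ol_a"].mean()) if len(overlap) else None,
            "unmatched_masks": unmatched,
        }

    if manual_scores is not None:
        if not isinstance(manual_scores, pd.DataFrame):
            manual_scores = pd.read_csv(manual_scores, comment="#")
        joined = result.global_scores.merge(manual_scores, on="animal_id", how="inner")
        report["n_joined_animals"] = int(len(joined))
        if len(joined) == 0:
            report["warning"] = "no manual scores joined by animal_id"
        if "mis" in joined.columns and len(joined) >= 3:
            reg = stats.validation_regression(joined["mis"], joined["ais"])
            report["ais_vs_mis"] = {
                "slope": reg.slope,
                "intercept": reg.intercept,
                "slope_ci": list(reg.slope_ci),
                "r2": reg.r2,
                "p": reg.p,
                "n_outliers": int(reg.outliers.sum()),
                "refit_slope": reg.refit_slope,
            }
            per_group = {}
            for group, g in joined.groupby("group"):
                if len(g) >= 2:
                    kd = stats.kruskal_dunn({"manual": g["mis"], "auto": g["ais"]})
                    per_group[group] = {"h": kd.h, "p": kd.p}
            report["manual_vs_auto_by_group"] = per_group
        rater_cols = [c for c in joined.columns if c.startswith("mgs")]
        if len(rater_cols) >= 2 and len(joined) >= 2:
            icc = stats.icc3k(joined[rater_cols].to_numpy())
            report["mgs_icc3k"] = {"icc": icc.icc, "f": icc.f, "p": icc.p}
        if "mgs" in joined.columns and len(joined) >= 3:
            rho, p = stats.spearman(joined["mgs"], joined["ami"])
            report["ami_vs_mgs_spearman"] = {"rho": rho, "p": p}

    outdir = Path(config.output_dir)
    (outdir / "validation.json").write_text(json.dumps(report, indent=2, default=float))
    return report
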