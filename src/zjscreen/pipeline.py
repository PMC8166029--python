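"""End-to-end orchestration: mine -> screen -> quantify images -> match peaks.

A :class:`RunConfig` (YAML-serializable, unknown keys rejected) drives the
run; every stage writes into its own subdirectory of ``out_dir`` and the run
ends with a manifest recording the config hash, per-file SHA-256 checksums
and the stage list. Re-running the same config reproduces identical
checksums. A failing stage aborts the run with the stage named and its
partial outputs moved aside under a ``.quarantine`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from pathlib import Path

import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import hcs_quant, msmatch, screening_stats, textmine
from .syndata import (
    CorpusSpec,
    ImageSpec,
    PlateSpec,
    default_reference_standards,
    generate_corpus,
    generate_images,
    generate_peaklist,
    generate_plate,
)
from .syndata.images import save_roi

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "load_config", "save_config"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Model):
    mine: bool = True
    screen: bool = True
    images: bool = True
    msmatch: bool = True


class CorpusConfig(_Model):
    n_formulae: int = 10
    n_symptoms: int = 10
    n_filler: int = 30
    planted_pairs: list[tuple[int, int]] = Field(default=[(0, 0)])
    p_assoc: float = 0.9
    p_bg: float = 0.02
    n_sentences: int = 2000
    sentence_len: int = 12


class MiningConfig(_Model):
    dim: int = 100
    window: int = 5
    epochs: int = 5
    negative: int = 5
    min_count: int = 1
    subsample_t: float = 1e-3
    start_lr: float = 0.025
    end_lr: float = 1e-4
    workers: int = 1
    top_k_formulae: int = 3  # formulae carried forward to the screen
    combine: str = "mean"


class PlateConfig(_Model):
    lambda_control: float = 5.0
    lambda_model: float = 20.0
    mu_ros_control: float = 6.9
    mu_ros_model: float = 7.6
    sigma_ros: float = 0.2
    n_embryos: int = 10
    # (neutrophil, ROS) true effects cycled over the candidate arms
    candidate_effects: list[tuple[float, float]] = Field(
        default=[(0.9, 0.9), (0.9, 0.1), (0.2, 0.2)]
    )
    plate_file: str | None = None  # load this CSV instead of simulating


class HitThresholds(_Model):
    theta_recovery: float = screening_stats.THETA_RECOVERY
    theta_ros: float = screening_stats.THETA_ROS


class ImagesConfig(_Model):
    n_images: int = 4
    shape: tuple[int, int] = (256, 256)
    n_spots_inside: int = 7
    n_spots_outside: int = 3
    spot_radius: float = 5.0
    spot_peak: float = 20000.0
    background: float = 5000.0
    noise_sd: float = 2000.0
    min_area: int = 4


class PeaksConfig(_Model):
    mz_jitter_ppm: float = 3.0
    rt_jitter_min: float = 0.05
    decoys: int = 5
    mz_tol_ppm: float = 10.0
    rt_tol: float = 0.2


class RunConfig(_Model):
    seed: int = 0
    out_dir: str = "runs/demo"
    stages: StageToggles = StageToggles()
    corpus: CorpusConfig = CorpusConfig()
    mining: MiningConfig = MiningConfig()
    plate: PlateConfig = PlateConfig()
    thresholds: HitThresholds = HitThresholds()
    images: ImagesConfig = ImagesConfig()
    peaks: PeaksConfig = PeaksConfig()


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=True),
        encoding="utf-8",
    )


def load_config(path: str | Path) -> RunConfig:
    return RunConfig(**(yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_mine(config: RunConfig, out: Path) -> dict:
    # pydantic lists -> the tuple-of-tuples the spec dataclass expects
    spec = CorpusSpec(
        **{**config.corpus.model_dump(),
           "planted_pairs": tuple(tuple(p) for p in config.corpus.planted_pairs),
           "seed": config.seed}
    )
    corpus = generate_corpus(spec)
    corpus.save(out / "corpus.txt", out / "dictionary.tsv")

    m = config.mining
    params = textmine.SkipGramParams(
        dim=m.dim, seed=config.seed, workers=m.workers, window=m.window,
        epochs=m.epochs, negative=m.negative, start_lr=m.start_lr,
        end_lr=m.end_lr, min_count=m.min_count, subsample_t=m.subsample_t,
    )
    model = textmine.train_skipgram(corpus, params)
    model.save(out / "embedding.tsv", out / "embedding.json")

    queries = sorted({s for _, s in corpus.planted_pairs})
    formulae = sorted(corpus.formulae)
    ranking = textmine.associations.aggregate_ranking(
        model, queries, formulae, combine=m.combine
    )
    pd.DataFrame(
        {
            "query": [r.query for r in ranking],
            "candidate": [r.candidate for r in ranking],
            "cosine": [round(r.score, 6) for r in ranking],
            "rank": [r.rank for r in ranking],
        }
    ).to_csv(out / "rankings.csv", index=False)

    selected = [r.candidate for r in ranking[: m.top_k_formulae]]
    (out / "selected_formulae.txt").write_text("\n".join(selected) + "\n", encoding="utf-8")

    # reverse check runs on the query symptoms: do the formulae retrieved for
    # them point back when the retrieval direction is flipped?
    table, consistency = textmine.bidirectional_validate(
        model, formulae, queries, k=m.top_k_formulae
    )
    table.to_csv(out / "bidirectional.csv", index=False, float_format="%.6f")
    return {"selected_formulae": selected, "bidirectional_consistency": consistency}


def _stage_screen(config: RunConfig, out: Path, selected: list[str] | None) -> dict:
    p = config.plate
    if p.plate_file is not None:
        path = Path(p.plate_file)
        if not path.exists():
            raise FileNotFoundError(f"plate file not found: {path}")
        plate = pd.read_csv(path)
    else:
        names = selected or [f"candidate_{i:02d}" for i in range(len(p.candidate_effects))]
        effects = [p.candidate_effects[i % len(p.candidate_effects)] for i in range(len(names))]
        spec = PlateSpec(
            lambda_control=p.lambda_control, lambda_model=p.lambda_model,
            mu_ros_control=p.mu_ros_control, mu_ros_model=p.mu_ros_model,
            sigma_ros=p.sigma_ros, n_embryos=p.n_embryos,
            candidates=tuple((n, e[0], e[1]) for n, e in zip(names, effects)),
            seed=config.seed + 1,
        )
        plate = generate_plate(spec).table
    plate.to_csv(out / "plate.csv", index=False)

    calls = screening_stats.call_hits(
        plate, config.thresholds.theta_recovery, config.thresholds.theta_ros
    )
    screening_stats.hitcalls_to_frame(calls).to_csv(out / "hits.csv", index=False, float_format="%.6f")
    screening_stats.heatmap_matrix(calls).to_csv(out / "heatmap.csv", float_format="%.6f")

    summaries = [
        screening_stats.summarize_group(g["neutrophil_count"], group=name)
        for name, g in plate.groupby("group")
    ]
    pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
        out / "group_summary.csv", index=False, float_format="%.6f"
    )
    comparison = screening_stats.compare_groups(
        {
            "control": plate.loc[plate["group"] == "control", "neutrophil_count"],
            "model": plate.loc[plate["group"] == "model", "neutrophil_count"],
        }
    )
    (out / "model_vs_control.json").write_text(
        json.dumps(comparison, indent=1), encoding="utf-8"
    )
    return {"n_candidates": len(calls), "n_dual_hits": sum(c.dual_hit for c in calls)}


def _stage_images(config: RunConfig, out: Path) -> dict:
    c = config.images
    rows = []
    roi = None
    for i in range(c.n_images):
        spec = ImageSpec(
            shape=tuple(c.shape), n_spots_inside=c.n_spots_inside,
            n_spots_outside=c.n_spots_outside, spot_radius=c.spot_radius,
            spot_peak=c.spot_peak, background=c.background,
            noise_sd=c.noise_sd, seed=config.seed + 100 + i,
        )
        img, truth = generate_images(spec)
        tifffile.imwrite(out / f"image_{i:03d}.tif", img)
        (out / f"image_{i:03d}.truth.json").write_text(json.dumps(truth), encoding="utf-8")
        if roi is None:
            roi = hcs_quant.ROI(vertices=list(spec.roi))
            save_roi(spec.roi, out / "roi.json")
        spots = hcs_quant.count_spots(img, roi, min_area=c.min_area)
        rows.append(
            {
                "image_id": f"image_{i:03d}",
                "n_spots": spots.count,
                "true_n_spots": len(truth["inside_centers"]),
                "mean_intensity": round(hcs_quant.mean_roi_intensity(img, roi), 4),
            }
        )
    quant = pd.DataFrame(rows)
    quant.to_csv(out / "quant.csv", index=False)
    return {"n_images": len(rows),
            "exact_counts": int((quant["n_spots"] == quant["true_n_spots"]).sum())}


def _stage_msmatch(config: RunConfig, out: Path) -> dict:
    c = config.peaks
    refs = default_reference_standards()
    refs.to_csv(out / "references.csv", index=False)
    observed = generate_peaklist(
        refs, mz_jitter_ppm=c.mz_jitter_ppm, rt_jitter_min=c.rt_jitter_min,
        decoys=c.decoys, seed=config.seed + 200, tolerance_ppm=c.mz_tol_ppm,
    )
    observed.to_csv(out / "observed.csv", index=False, float_format="%.6f")
    result = msmatch.match_peaks(
        observed, refs, mz_tol_ppm=c.mz_tol_ppm, rt_tol=c.rt_tol
    )
    result.to_frame().to_csv(out / "matches.csv", index=False, float_format="%.6f")
    (out / "unmatched.json").write_text(
        json.dumps(
            {
                "observed_indices": result.unmatched_observed,
                "references": result.unmatched_references,
            }
        ),
        encoding="utf-8",
    )
    return {"n_matches": len(result.matches),
            "n_unmatched_references": len(result.unmatched_references)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")

    stage_fns = []
    if config.stages.mine:
        stage_fns.append(("mine", _stage_mine))
    if config.stages.screen:
        stage_fns.append(("screen", _stage_screen))
    if config.stages.images:
        stage_fns.append(("images", _stage_images))
    if config.stages.msmatch:
        stage_fns.append(("msmatch", _stage_msmatch))

    log_path = out / "run.log"
    log = open(log_path, "w", encoding="utf-8")
    completed: list[str] = []
    stage_info: dict[str, dict] = {}
    selected: list[str] | None = None
    try:
        for name, fn in stage_fns:
            stage_dir = out / name
            quarantine = out / f"{name}.quarantine"
            if quarantine.exists():
                shutil.rmtree(quarantine)
            if stage_dir.exists():
                shutil.rmtree(stage_dir)
            stage_dir.mkdir()
            log.write(json.dumps({"event": "stage_start", "stage": name}) + "\n")
            try:
                if name == "screen":
                    info = fn(config, stage_dir, selected)
                else:
                    info = fn(config, stage_dir)
                if name == "mine":
                    selected = info["selected_formulae"]
            except Exception as exc:
                stage_dir.rename(quarantine)
                log.write(
                    json.dumps({"event": "stage_failed", "stage": name, "error": str(exc)})
                    + "\n"
                )
                raise PipelineStageError(name, exc) from exc
            completed.append(name)
            stage_info[name] = info
            log.write(json.dumps({"event": "stage_done", "stage": name, **_json_safe(info)}) + "\n")
    finally:
        log.close()

    checksums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name not in ("manifest.json", "run.log"):
            checksums[str(path.relative_to(out))] = _sha256(path)
    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(config.model_dump_json().encode()).hexdigest(),
        "stages_completed": completed,
        "stage_info": _json_safe(stage_info),
        "outputs": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest


def _json_safe(obj):
    return json.loads(json.dumps(obj, default=str))
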