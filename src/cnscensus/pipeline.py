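"""Configurable multi-stage pipeline with a run manifest.

Stages (any subset, executed in canonical order):

``simulate-phantom`` -> ``segment`` -> ``simulate-cohort`` ->
``distances`` -> ``persist`` -> ``gram`` -> ``classify`` -> ``stats``

Each stage reads either the previous stage's in-memory output or the
file named in its config section, writes its results under ``out_dir``,
and appends to the run manifest (inputs, outputs, seeds, package
version).  Reruns with the same config reproduce all outputs: every
random stage is seeded from the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core import (CensusError, ExperimentConfig, SegmentationConfig, Sex)
from . import io as cio
from .classify import run_experiment
from .distances import feature_matrix
from .segmentation import (denoise_curvature_flow, detect_blobs,
                           extract_centroids, filter_by_volume)
from .stats import build_census_report
from .synthetic import (CohortSpec, PhantomSpec, generate_cohort,
                        generate_phantom)
from .tda import alpha_persistence_degree1, gram_matrix, subsample_cloud

__all__ = ["PipelineConfig", "run_pipeline", "STAGE_ORDER"]

log = logging.getLogger(__name__)

STAGE_ORDER = ["simulate-phantom", "segment", "simulate-cohort", "distances",
               "persist", "gram", "classify", "stats"]


@dataclass
class PipelineConfig:
    """Stage toggles plus per-stage sections (plain dicts from YAML)."""

    stages: list[str]
    out_dir: Path
    master_seed: int = 0
    sections: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        stages = list(raw.get("stages", []))
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise CensusError(f"unknown stage(s): {unknown}")
        return cls(stages=[s for s in STAGE_ORDER if s in stages],
                   out_dir=Path(raw.get("out_dir", "census-run")),
                   master_seed=int(raw.get("seed", 0)),
                   sections={k: v for k, v in raw.items()
                             if k not in ("stages", "out_dir", "seed")})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in order; return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.master_seed,
                      "stages": [], "outputs": {}}
    state: dict = {}
    for stage in config.stages:
        section = dict(config.sections.get(stage.replace("-", "_"), {}))
        try:
            outputs = _STAGE_FNS[stage](section, state, out,
                                        config.master_seed)
        except Exception as exc:
            manifest["failed_stage"] = stage
            (out / "manifest.partial.json").write_text(
                json.dumps(manifest, indent=2, default=str))
            raise CensusError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append({"name": stage, "config": section})
        manifest["outputs"][stage] = [str(p) for p in outputs]
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_simulate_phantom(section, state, out, seed):
    spec = PhantomSpec(**{**{"seed": seed}, **section})
    vol, truth = generate_phantom(spec)
    vol_path = cio.write_volume(vol, out / "phantom.tif")
    truth_path = cio.write_point_cloud_table([truth], out / "phantom_truth.csv")
    state["volume"], state["truth"] = vol, truth
    return [vol_path, truth_path]


def _stage_segment(section, state, out, seed):
    if "input" in section:
        vol = cio.read_volume(section["input"],
                              spacing=section.get("spacing"))
    elif "volume" in state:
        vol = state["volume"]
    else:
        raise CensusError("segment stage needs an input volume")
    cfg = SegmentationConfig(**{k: v for k, v in section.items()
                                if k not in ("input", "spacing")})
    den = denoise_curvature_flow(vol, cfg.denoise_iterations,
                                 cfg.denoise_timestep)
    seg = filter_by_volume(detect_blobs(den, cfg), cfg.min_volume_um3)
    cloud = extract_centroids(seg, animal_id="segmented")
    path = cio.write_point_cloud_table([cloud], out / "centroids.csv")
    labels_path = out / "labels.tif"
    import tifffile
    tifffile.imwrite(labels_path, seg.labels.astype(np.int32))
    state["centroids"] = cloud
    return [path, labels_path]


def _stage_simulate_cohort(section, state, out, seed):
    spec = CohortSpec(**{**{"seed": seed}, **section})
    clouds = generate_cohort(spec)
    path = cio.write_point_cloud_table(clouds, out / "cohort.csv")
    state["clouds"] = clouds
    return [path]


def _load_clouds(section, state):
    if "input" in section:
        return cio.read_point_cloud_table(section["input"])
    if "clouds" in state:
        return state["clouds"]
    raise CensusError("stage needs a cohort (run simulate-cohort or set input)")


def _stage_distances(section, state, out, seed):
    clouds = _load_clouds(section, state)
    which = tuple(section.get("features", ("mean", "variance")))
    feats = feature_matrix(clouds, which=which)
    import pandas as pd
    df = pd.DataFrame(feats, columns=list(which))
    df.insert(0, "animal_id", [c.animal_id for c in clouds])
    path = out / "distance_features.csv"
    df.to_csv(path, index=False)
    state["features"] = feats
    return [path]


def _experiment_config(section, seed) -> ExperimentConfig:
    keys = ExperimentConfig.__dataclass_fields__.keys()
    return ExperimentConfig(**{**{"master_seed": seed},
                               **{k: v for k, v in section.items()
                                  if k in keys}})


def _stage_persist(section, state, out, seed):
    clouds = _load_clouds(section, state)
    cfg = _experiment_config(section, seed)
    diagrams = []
    group_ids, item_ids, labels = [], [], []
    for ai, cloud in enumerate(sorted(clouds, key=lambda c: c.animal_id)):
        sset = subsample_cloud(cloud, min(cfg.subsample_size, cloud.n_points),
                               cfg.subsample_repeats, seed=seed + ai)
        for r, sub in enumerate(sset.clouds):
            diagrams.append((f"{cloud.animal_id}:{r:03d}",
                             alpha_persistence_degree1(sub)))
            item_ids.append(f"{cloud.animal_id}:{r:03d}")
            group_ids.append(cloud.animal_id)
            labels.append(cloud.sex.value)
    path = cio.write_diagram_csv(diagrams, out / "diagrams.csv")
    state["diagrams"] = [d for _, d in diagrams]
    state["item_ids"], state["group_ids"] = item_ids, group_ids
    state["labels"] = labels
    return [path]


def _stage_gram(section, state, out, seed):
    if "diagrams" not in state:
        if "input" in section:
            loaded = cio.read_diagram_csv(section["input"])
            state["item_ids"] = list(loaded)
            state["diagrams"] = list(loaded.values())
            state["group_ids"] = [i.split(":")[0] for i in loaded]
            state.setdefault("labels", None)
        else:
            raise CensusError("gram stage needs diagrams")
    cfg = _experiment_config(section, seed)
    gram = gram_matrix(state["diagrams"], state["group_ids"],
                       cfg.heat_bandwidth_sigma, item_ids=state["item_ids"],
                       max_points=section.get("max_points"))
    path = cio.write_gram_tsv(gram, out / "gram.tsv")
    state["gram"] = gram
    return [path]


def _stage_classify(section, state, out, seed):
    if "gram" not in state and "input" in section:
        state["gram"] = cio.read_gram_tsv(section["input"])
    if "gram" not in state or state.get("labels") is None:
        raise CensusError("classify stage needs a gram matrix and labels")
    cfg = _experiment_config(section, seed)
    result = run_experiment(state["gram"], state["labels"], cfg)
    import pandas as pd
    per_split = pd.DataFrame(result.per_split,
                             columns=["rho_true", "rho_control"])
    per_split.insert(0, "split_id", np.arange(len(per_split)))
    csv_path = out / "classification.csv"
    per_split.to_csv(csv_path, index=False)
    json_path = out / "classification_summary.json"
    json_path.write_text(json.dumps(
        {"overlap_fraction": result.overlap_fraction,
         "n_splits": int(len(per_split))}, indent=2))
    state["classification"] = result
    return [csv_path, json_path]


def _stage_stats(section, state, out, seed):
    if "input" in section:
        import pandas as pd
        from .core import CensusLineSummary
        df = pd.read_csv(section["input"])
        rows = [CensusLineSummary(r.line, Sex.parse(r.sex), float(r.mean),
                                  float(r.cv_percent), int(r.n))
                for r in df.itertuples()]
        table = build_census_report(rows,
                                    glia_line=section.get("glia_line", "repo"))
    else:
        from .study import study_census_report
        table = study_census_report()
    path = out / "census_report.json"
    path.write_text(json.dumps(table.derived, indent=2, sort_keys=True))
    state["census"] = table
    return [path]


_STAGE_FNS = {
    "simulate-phantom": _stage_simulate_phantom,
    "segment": _stage_segment,
    "simulate-cohort": _stage_simulate_cohort,
    "distances": _stage_distances,
    "persist": _stage_persist,
    "gram": _stage_gram,
    "classify": _stage_classify,
    "stats": _stage_stats,
}
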