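"""End-to-end orchestration: config-driven runs of the full study pipeline.

One *arm* = one synthetic population (e.g. female-left) carried through:
generate -> rigid ICP prealignment to the first subject -> voxelize (binary
occupancy -> distance-ramp pseudo-intensity) -> train/test split -> build
both template arms (iterative average-image template; correspondence mean
shape) -> evaluate (landmark transfer to training subjects + PCA; distance
model between the arms) -> validate (landmark prediction on held-out
subjects, RMSE, paired t-test, percent improvement).

Every random operation derives its seed from one root seed via named
substreams, so a run is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import evaluate, validate
from .geometry import (ScalarVolume, soft_occupancy, voxelize,
                       write_landmarks, write_stl, save_nrrd)
from .population import (LANDMARK_NAMES, PopulationSpec, make_base_shape,
                         make_population, scaled_spec, write_population)
from .registration import icp_align
from .template import (RegParams, TemplateResult, build_template,
                       correspondence_mean_shape)

log = logging.getLogger(__name__)

ARM_TEMPLATE = "template"
ARM_CORRESPONDENCE = "correspondence-mean"


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    Defaults mirror the four-arm study layout (female/male x left/right with
    50/50/43/43 subjects) at full 300 mm scale; ``desk_scale`` < 1 shrinks
    the bone and every millimetre quantity uniformly for tractable runs.
    """

    arms: dict = field(default_factory=lambda: {
        "female-left": 50, "female-right": 50,
        "male-left": 43, "male-right": 43,
    })
    n_modes: int = 5
    mode_amplitudes: tuple = (5.0, 4.0, 3.0, 2.5, 2.0)
    pose_rotation_sd: float = 2.0
    pose_translation_sd: float = 2.0
    vertex_noise_sd: float = 0.05
    length: float = 300.0
    desk_scale: float = 1.0
    resolution: int = 2
    spacing: float = 1.0
    padding: int = 6
    ramp_width: float = 4.0
    icp_trim: float = 0.85
    icp_normal_cos: float = 0.5
    icp_max_rotation_deg: float = 10.0
    train_fraction: float = 0.82
    n_iterations: int = 4
    seed: int = 0
    outdir: str = "boneatlas_run"
    reg: RegParams = field(default_factory=RegParams)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        reg = data.pop("reg", None)
        cfg = cls(**data)
        if reg:
            cfg.reg = RegParams(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in reg.items()})
        return cfg

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(data, indent=2, default=list))

    def population_spec(self, arm: str, seed: int) -> PopulationSpec:
        spec = PopulationSpec(
            n_subjects=self.arms[arm], n_modes=self.n_modes,
            mode_amplitudes=tuple(self.mode_amplitudes),
            pose_rotation_sd=self.pose_rotation_sd,
            pose_translation_sd=self.pose_translation_sd,
            vertex_noise_sd=self.vertex_noise_sd, seed=seed)
        if self.desk_scale != 1.0:
            spec = scaled_spec(spec, self.desk_scale)
        return spec

    @property
    def scaled_length(self) -> float:
        return self.length * self.desk_scale


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic named child seed below 2**31."""
    h = np.uint64(14695981039346656037)
    for b in f"{root_seed}:{name}".encode():
        h = np.uint64((int(h) ^ b) * 1099511628211 % (1 << 64))
    return int(h % np.uint64(2 ** 31 - 1))


@dataclass
class ArmData:
    """One arm's population after prealignment and voxelization."""

    name: str
    aligned_meshes: list
    true_landmarks: list          # in the common (first-subject) frame
    volumes: list[ScalarVolume]
    split: validate.SplitResult
    base_mesh: object
    base_landmarks: object


def prepare_arm(config: RunConfig, arm: str) -> ArmData:
    """Generate, ICP-prealign and voxelize one arm; split train/test."""
    base, base_lm = make_base_shape(config.resolution, length=config.scaled_length)
    spec = config.population_spec(arm, substream_seed(config.seed, f"pop:{arm}"))
    samples = make_population(base, base_lm, spec)

    aligned, true_lms = [], []
    icp_seed = substream_seed(config.seed, f"icp:{arm}")
    for s in samples:
        rigid, mesh, _ = icp_align(s.mesh, samples[0].mesh, subsample=1200,
                                   seed=icp_seed, trim=config.icp_trim,
                                   normal_cos=config.icp_normal_cos,
                                   max_rotation_deg=config.icp_max_rotation_deg)
        aligned.append(mesh)
        true_lms.append(s.landmarks.with_points(rigid.apply(s.landmarks.points)))

    volumes = [soft_occupancy(voxelize(m, config.spacing, config.padding),
                              config.ramp_width) for m in aligned]
    split = validate.split_data(list(range(len(samples))),
                                train_fraction=config.train_fraction,
                                seed=substream_seed(config.seed, f"split:{arm}"))
    return ArmData(arm, aligned, true_lms, volumes, split, base, base_lm)


def run_arm(config: RunConfig, arm: str, outdir: Path | None = None) -> dict:
    """Full pipeline for one arm; returns a result dictionary.

    Writes artifacts (template NRRD/STL, PCA CSV, histogram CSV, validation
    CSV/JSON) under ``outdir`` when given.
    """
    data = prepare_arm(config, arm)
    train_vols = [data.volumes[i] for i in data.split.train_ids]
    train_meshes = [data.aligned_meshes[i] for i in data.split.train_ids]

    # arm 1: iterative average-image template
    result = build_template(train_vols, n_iterations=config.n_iterations,
                            reg_params=config.reg)
    template_lm = evaluate.annotate_template(data.base_mesh, data.base_landmarks,
                                             result.surface)

    # arm 2: correspondence mean shape (known topology on synthetic data)
    mean_shape = correspondence_mean_shape(train_meshes, use_known_topology=True)
    mean_lm = evaluate.annotate_template(data.base_mesh, data.base_landmarks,
                                         mean_shape)
    mean_volume = soft_occupancy(
        voxelize(mean_shape, config.spacing, config.padding), config.ramp_width)

    # evaluation on training subjects
    clouds = evaluate.transfer_landmarks_to_training(
        template_lm, result.per_subject_transforms)
    pca = evaluate.pca_explained_variance(clouds, procrustes=True)
    dist_model = evaluate.compare_templates(result.surface, mean_shape)

    # validation on held-out subjects
    preds = {ARM_TEMPLATE: [], ARM_CORRESPONDENCE: []}
    truths = []
    for i in data.split.test_ids:
        assert i not in data.split.train_ids
        test_vol = data.volumes[i]
        preds[ARM_TEMPLATE].append(validate.predict_landmarks(
            result.template, template_lm, test_vol, config.reg, str(i)))
        preds[ARM_CORRESPONDENCE].append(validate.predict_landmarks(
            mean_volume, mean_lm, test_vol, config.reg, str(i)))
        truths.append(data.true_landmarks[i])
    report = validate.build_report(data.split.test_ids, preds, truths,
                                   ARM_TEMPLATE, ARM_CORRESPONDENCE)

    out = {
        "arm": arm,
        "n_train": len(data.split.train_ids),
        "n_test": len(data.split.test_ids),
        "cumulative_explained_7": float(pca.cumulative_fraction[6]),
        "iteration_log": result.iteration_log,
        "rmse": report.summary,
        "t_statistic": report.t_statistic,
        "p_value": report.p_value,
        "improvement_pct": report.improvement_pct_a_over_b,
    }
    if outdir is not None:
        outdir = Path(outdir) / arm
        outdir.mkdir(parents=True, exist_ok=True)
        save_nrrd(result.template, outdir / "template.nrrd")
        write_stl(result.surface, outdir / "template_surface.stl")
        write_stl(mean_shape, outdir / "correspondence_mean.stl")
        write_landmarks(template_lm, outdir / "template_landmarks.csv")
        evaluate.write_pca_csv(pca, outdir / "pca_explained_variance.csv")
        evaluate.write_distance_histogram_csv(dist_model,
                                              outdir / "distance_histogram.csv")
        evaluate.plot_scree(pca, outdir / "scree.png")
        evaluate.plot_distance_histogram(dist_model,
                                         outdir / "distance_histogram.png")
        _write_validation_csv(report, outdir / "validation.csv")
        (outdir / "summary.json").write_text(json.dumps(out, indent=2))
        _log_csv(result.iteration_log, outdir / "iteration_log.csv")
    return out


def _write_validation_csv(report, path: Path) -> None:
    import pandas as pd

    rows = []
    for arm, errs in report.per_subject_errors.items():
        for sid, e, r in zip(report.subject_ids, errs,
                             report.per_subject_rmse[arm]):
            row = {"arm": arm, "subject": sid, "rmse_mm": r}
            row.update({name: float(v) for name, v in zip(LANDMARK_NAMES, e)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def _log_csv(rows: list[dict], path: Path) -> None:
    import pandas as pd
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8f")


def synth_to_disk(config: RunConfig, arm: str, outdir: str | Path) -> Path:
    """Write one arm's raw population (STL + landmarks + manifest)."""
    base, base_lm = make_base_shape(config.resolution, length=config.scaled_length)
    spec = config.population_spec(arm, substream_seed(config.seed, f"pop:{arm}"))
    samples = make_population(base, base_lm, spec)
    return write_population(samples, spec, Path(outdir) / arm)
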