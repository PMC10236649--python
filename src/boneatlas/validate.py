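"""Surgical-planning validation: train/test split, landmark prediction on
held-out subjects, RMSE scoring, paired t-tests and percent improvement.

Both template arms are validated identically: the held-out subject volume is
registered to the arm's template image with the same affine + deformable
engine and parameters, and the arm's template landmarks are pushed through
the resulting template->subject map.  Per-subject RMSE averages over the 11
landmarks first; arms are compared pairwise over test subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .geometry import LandmarkSet, ScalarVolume
from .template import RegParams, register_subject

TRAIN_FRACTION = 0.82


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list
    seed: int
    train_fraction: float


def split_data(ids: list, train_fraction: float = TRAIN_FRACTION,
               seed: int = 0) -> SplitResult:
    """Uniform random split; |train| = round-half-up of train_fraction * n.

    (50 subjects -> 41 train / 9 test; 43 -> 35 / 8.)
    """
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must lie in (0, 1)")
    ids = list(ids)
    if len(ids) < 2:
        raise ValidationError("need at least two subjects to split")
    n_train = int(np.floor(train_fraction * len(ids) + 0.5))
    n_train = min(max(n_train, 1), len(ids) - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return SplitResult(train, test, seed, train_fraction)


def predict_landmarks(template: ScalarVolume, template_landmarks: LandmarkSet,
                      test_volume: ScalarVolume,
                      reg_params: RegParams | None = None,
                      subject_id: str = "") -> LandmarkSet:
    """Transfer template landmarks onto one held-out subject.

    Registers the subject (moving) to the template (fixed) and applies the
    template->subject map to the landmarks.
    """
    params = reg_params or RegParams()
    transform, _ = register_subject(test_volume, template, params)
    pts = transform.apply_points(template_landmarks.points)
    return template_landmarks.with_points(pts, frame=f"predicted_{subject_id}")


def rmse(pred: LandmarkSet, truth: LandmarkSet) -> float:
    """Root mean squared Euclidean landmark error (mm)."""
    if pred.names != truth.names:
        raise ValidationError("landmark names/order differ")
    d2 = np.sum((pred.points - truth.points) ** 2, axis=1)
    return float(np.sqrt(np.mean(d2)))


def paired_t_test(rmse_a: list[float] | np.ndarray,
                  rmse_b: list[float] | np.ndarray) -> tuple[float, float]:
    """Classical paired t-test on per-subject RMSE differences (two-sided).

    Degenerate cases: all-zero differences -> (0, 1); zero variance with a
    nonzero mean -> (signed inf, 0).
    """
    a = np.asarray(rmse_a, dtype=float)
    b = np.asarray(rmse_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("paired t-test needs two equal-length arrays, n >= 2")
    d = a - b
    n = len(d)
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def improvement_pct(rmse_a_mean: float, rmse_b_mean: float) -> float:
    """Percent improvement of arm A over arm B: (B - A) / B * 100."""
    if rmse_b_mean <= 0:
        raise ValidationError("reference RMSE must be positive")
    return float((rmse_b_mean - rmse_a_mean) / rmse_b_mean * 100.0)


@dataclass
class ValidationReport:
    subject_ids: list
    per_subject_errors: dict        # arm -> list of (11,) landmark error norms
    per_subject_rmse: dict          # arm -> (n_test,) array
    summary: dict                   # arm -> {mean, min, max}
    t_statistic: float
    p_value: float
    improvement_pct_a_over_b: float
    arm_a: str = "template"
    arm_b: str = "correspondence-mean"


def build_report(subject_ids: list,
                 predictions: dict[str, list[LandmarkSet]],
                 truths: list[LandmarkSet],
                 arm_a: str, arm_b: str) -> ValidationReport:
    """Score two arms' predictions against shared ground truth."""
    errors: dict[str, list[np.ndarray]] = {}
    rmses: dict[str, np.ndarray] = {}
    for arm, preds in predictions.items():
        if len(preds) != len(truths):
            raise ValidationError(f"arm {arm}: prediction/truth count mismatch")
        errs = [np.linalg.norm(p.points - t.points, axis=1)
                for p, t in zip(preds, truths)]
        errors[arm] = errs
        rmses[arm] = np.array([rmse(p, t) for p, t in zip(preds, truths)])
    summary = {arm: {"mean": float(r.mean()), "min": float(r.min()),
                     "max": float(r.max())}
               for arm, r in rmses.items()}
    if len(truths) >= 2:
        t, p = paired_t_test(rmses[arm_a], rmses[arm_b])
    else:  # a single held-out subject cannot support a paired test
        t, p = float("nan"), float("nan")
    imp = improvement_pct(summary[arm_a]["mean"], summary[arm_b]["mean"])
    return ValidationReport(list(subject_ids), errors, rmses, summary,
                            t, p, imp, arm_a, arm_b)
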