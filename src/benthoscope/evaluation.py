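"""Detection metrics, the annotation-time model and the parameter search.

Detection is scored at region level against circle/point ground truth:

* ``TP_θ`` — objects of interest whose centre lies inside some detected
  region; ``FN_θ`` — objects in no region.  ``recall = TP_θ/(TP_θ+FN_θ)``.
* ``TP_ρ`` — detected regions containing at least one object centre;
  ``FP_ρ`` — regions containing none.  ``precision = TP_ρ/(TP_ρ+FP_ρ)``.

A region holding k objects contributes k to ``TP_θ`` but 1 to ``TP_ρ``.
The F2 score ``5·R·P / (4·P + R)`` weights recall over precision — missing
an organism on the seabed costs more than dismissing a false alarm during
review.

The time model is linear: assisted annotation costs a per-image review rate
plus a constant set-up (the manual filter/refine work on a fixed-size
training subset), traditional annotation a per-image rate alone; the
break-even size and speed-up follow in closed form.  The default rates are
data, not constants — they can be recomputed from logged review sessions
(see :data:`BENCHMARK_SESSIONS`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .proposals import TrainingProposal
from .review import CircleAnnotation

__all__ = [
    "DetectionEvalResult", "TimeModelParams", "match_detections", "f2_score",
    "tau_assisted", "tau_manual", "speedup", "breakeven", "parameter_search",
    "BENCHMARK_SESSIONS", "benchmark_time_params", "stage2_intercept",
    "mean_rate", "DEFAULT_GRID",
]


# ---------------------------------------------------------------------------
# Published benchmark sessions (inputs to the time model)
#
# One row per survey: detection scores of the final segmentation on the
# 50-image validation subsets, per-image durations of the manual steps on
# the 500-image training subsets, and candidate-review statistics.

BENCHMARK_SESSIONS = pd.DataFrame(
    [
        # survey, recall%, precision%, n_training_samples,
        # filter+refine s/image, n_candidates, n_accepted, review s/image
        ("JC77", 91.7, 50.5, 1040, 14.54, 501, 276, 7.44),
        ("PAP", 77.2, 14.3, 200, 54.03, 308, 54, 27.55),
        ("SO242", 83.4, 26.1, 600, 5.39, 1094, 257, 20.04),
    ],
    columns=["survey", "recall_pct", "precision_pct", "n_training_samples",
             "filter_refine_s_per_image", "n_candidates", "n_accepted",
             "review_s_per_image"],
)

#: traditional (fully manual) annotation rate, s per image, averaged over
#: the three benchmark surveys' expert sessions
TRADITIONAL_RATE_S_PER_IMAGE = 89.27

#: number of images in each benchmark training subset
TRAINING_SUBSET_SIZE = 500


@dataclass(frozen=True)
class TimeModelParams:
    """Constants of the linear annotation-time model (seconds)."""

    review_rate: float = 18.34  # s/image: candidate review
    setup_cost: float = 12327.0  # s: filter+refine of the training subset
    trad_rate: float = 89.27  # s/image: traditional annotation

    def __post_init__(self):
        if min(self.review_rate, self.setup_cost, self.trad_rate) < 0:
            raise ValueError("time-model parameters must be nonnegative")


def mean_rate(rates: Sequence[float], decimals: int | None = 2) -> float:
    """Unweighted mean of per-survey rates, optionally rounded."""
    m = float(np.mean(rates))
    return round(m, decimals) if decimals is not None else m


def stage2_intercept(sessions: pd.DataFrame = BENCHMARK_SESSIONS,
                     subset_size: int = TRAINING_SUBSET_SIZE) -> float:
    """Set-up cost in seconds: mean over surveys of (filter+refine rate ×
    training-subset size), rounded to whole seconds."""
    per_survey = sessions["filter_refine_s_per_image"] * subset_size
    return float(round(per_survey.mean()))


def benchmark_time_params(sessions: pd.DataFrame = BENCHMARK_SESSIONS) -> TimeModelParams:
    """Recompute the time-model constants from the benchmark sessions."""
    return TimeModelParams(
        review_rate=mean_rate(sessions["review_s_per_image"]),
        setup_cost=stage2_intercept(sessions),
        trad_rate=TRADITIONAL_RATE_S_PER_IMAGE,
    )


# ---------------------------------------------------------------------------
# Detection metrics

@dataclass
class DetectionEvalResult:
    """Region-level detection scores."""

    tp_theta: int
    fn_theta: int
    tp_rho: int
    fp_rho: int
    precision_defined: bool = True

    @property
    def recall(self) -> float:
        denom = self.tp_theta + self.fn_theta
        return self.tp_theta / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = self.tp_rho + self.fp_rho
        return self.tp_rho / denom if denom else 0.0

    @property
    def f2(self) -> float:
        return f2_score(self.recall, self.precision)

    def as_row(self) -> dict:
        return {"tp_theta": self.tp_theta, "fn_theta": self.fn_theta,
                "tp_rho": self.tp_rho, "fp_rho": self.fp_rho,
                "recall": self.recall, "precision": self.precision,
                "f2": self.f2}


def f2_score(recall: float, precision: float) -> float:
    """F-beta at beta=2: ``5·R·P / (4·P + R)``; 0 when both are 0."""
    if recall < 0 or precision < 0:
        raise ValueError("recall and precision must be nonnegative")
    denom = 4.0 * precision + recall
    if denom == 0.0:
        return 0.0
    return 5.0 * recall * precision / denom


def _contains(region, cx: float, cy: float, mode: str) -> bool:
    if isinstance(region, TrainingProposal):
        if mode != "center":
            raise ValueError("square regions support only centre containment")
        return (region.x <= cx < region.x + region.edge
                and region.y <= cy < region.y + region.edge)
    if isinstance(region, CircleAnnotation):
        return (cx - region.cx) ** 2 + (cy - region.cy) ** 2 <= region.radius**2
    raise TypeError(f"unsupported region type {type(region)!r}")


def match_detections(
    regions: Sequence[TrainingProposal | CircleAnnotation],
    ground_truth: Sequence[CircleAnnotation],
    containment: str = "center",
) -> DetectionEvalResult:
    """Count containment matches between detected regions and ground truth.

    An object counts as found (``TP_θ``) if its centre lies inside at least
    one region; a region counts as correct (``TP_ρ``) if it contains at
    least one object centre.  Regions may be square proposals or circle
    candidates; ground truth supplies centre points.
    """
    gt_by_image: dict[str, list[CircleAnnotation]] = {}
    for g in ground_truth:
        gt_by_image.setdefault(g.image_id, []).append(g)

    tp_rho = 0
    fp_rho = 0
    found: set[tuple[str, int]] = set()  # TP_θ counts distinct objects
    for region in regions:
        image_id = region.image_id
        hits = 0
        for gi, g in enumerate(gt_by_image.get(image_id, [])):
            if _contains(region, g.cx, g.cy, containment):
                hits += 1
                found.add((image_id, gi))
        if hits:
            tp_rho += 1
        else:
            fp_rho += 1
    n_objects = sum(len(v) for v in gt_by_image.values())
    fn_theta = n_objects - len(found)
    return DetectionEvalResult(tp_theta=len(found), fn_theta=fn_theta,
                               tp_rho=tp_rho, fp_rho=fp_rho,
                               precision_defined=bool(tp_rho + fp_rho))


# ---------------------------------------------------------------------------
# Time model

def tau_assisted(n: float, params: TimeModelParams = TimeModelParams()) -> float:
    """Seconds to annotate ``n`` images with the assisted workflow."""
    if n < 0:
        raise ValueError("image count must be >= 0")
    return params.review_rate * n + params.setup_cost


def tau_manual(n: float, params: TimeModelParams = TimeModelParams()) -> float:
    """Seconds to annotate ``n`` images traditionally."""
    if n < 0:
        raise ValueError("image count must be >= 0")
    return params.trad_rate * n


def speedup(n: float, params: TimeModelParams = TimeModelParams()) -> float:
    """Fold speed-up of the assisted workflow at dataset size ``n``."""
    return tau_manual(n, params) / tau_assisted(n, params)


def breakeven(params: TimeModelParams = TimeModelParams()) -> float:
    """Exact dataset size at which the assisted workflow becomes faster.

    Raises if the traditional rate does not exceed the review rate (no
    crossover exists).
    """
    if params.trad_rate <= params.review_rate:
        raise ValueError("no crossover: traditional rate <= review rate")
    return params.setup_cost / (params.trad_rate - params.review_rate)


# ---------------------------------------------------------------------------
# Parameter search

DEFAULT_GRID = {
    "n_clusters": (1, 5, 10, 50, 100),
    "patch_edge": (29, 39),
    "compression": (0.1, 0.2),
}


def parameter_search(
    run_stage1: Callable[[int, int, float], Sequence[TrainingProposal]],
    ground_truth: Sequence[CircleAnnotation],
    grid: Mapping[str, Sequence] = DEFAULT_GRID,
) -> pd.DataFrame:
    """Evaluate detection over a grid of (K, patch edge, compression).

    ``run_stage1(n_clusters, patch_edge, compression)`` runs clustering,
    background-model training and proposal extraction end to end (with a
    shared seed) and returns the proposals; each triplet becomes one row of
    recall/precision/F2.  Errors are re-raised with the offending triplet
    named.
    """
    rows = []
    keys = ("n_clusters", "patch_edge", "compression")
    for combo in itertools.product(*(grid[k] for k in keys)):
        k, r_e, s_c = combo
        try:
            proposals = run_stage1(k, r_e, s_c)
        except Exception as exc:
            raise RuntimeError(
                f"parameter search failed at K={k}, patch_edge={r_e}, "
                f"compression={s_c}: {exc}") from exc
        res = match_detections(proposals, ground_truth)
        rows.append({"n_clusters": k, "patch_edge": r_e, "compression": s_c,
                     **res.as_row()})
    return pd.DataFrame(rows)


def time_model_curve(n_values: Sequence[int],
                     params: TimeModelParams = TimeModelParams()) -> pd.DataFrame:
    """Table of (n, τ assisted, τ traditional) for export/plotting."""
    return pd.DataFrame({
        "n": list(n_values),
        "tau_assisted_s": [tau_assisted(n, params) for n in n_values],
        "tau_manual_s": [tau_manual(n, params) for n in n_values],
    })
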