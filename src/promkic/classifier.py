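"""Single-layer perceptron over rasterized promoter patterns.

Ten output units — one per promoter class — share a 93,264-pixel input
retina (the flattened 348x268 raster).  The raster is presented to the
retina the way a plotted pattern is seen: each point has a finite
receptive footprint, realized as a Gaussian smoothing of the count
raster, and the smoothed image is L2-normalized so classification
depends on the pattern's shape and density, not on how many windows it
contains or any global intensity scale.

Training uses the classic multiclass perceptron rule from zero weights:
when the predicted class differs from the true one, the true class's
weight vector gains the input and the wrongly winning class's loses
it.  On linearly separable training sets the final iterate reaches
100% training accuracy (perceptron convergence).  The model keeps two
weight sets: the final iterate, which carries that memorization
guarantee, and the running average over all updates (averaged
perceptron), which generalizes better to held-out promoters and is the
default for scoring.  Features are centered on the training mean
during the updates; the mean is folded into the stored bias, so
scoring is a plain affine map of the raster features.

A classification reports the raw per-class activation ("match score")
and a min-max normalization of the ten scores to [0, 100] ("match
percentage").  A pattern whose top two match percentages are within a
small margin is flagged *transitional*: it sits between two class
archetypes, which the underlying biology reads as an evolutionary
intermediate produced by gradual gain or loss of repeat tracts.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .pattern import PatternRaster

#: The ten promoter classes, in canonical presentation order.
CLASS_LABELS: tuple[str, ...] = (
    "AT_based",
    "CG_based",
    "ATCG_compact",
    "ATCG_balanced",
    "ATCG_middle",
    "ATCG_less",
    "AT_less",
    "CG_less",
    "AT_spike",
    "CG_spike",
)

#: Default margin (percentage points) under which the best and
#: runner-up classes are considered jointly matched.
TRANSITIONAL_THRESHOLD = 5.0

#: Default receptive-footprint width (pixels) of the retina smoothing.
SMOOTHING_SIGMA = 5.0


def raster_features(raster: PatternRaster, sigma: float = SMOOTHING_SIGMA) -> np.ndarray:
    """Flattened, Gaussian-smoothed, L2-normalized raster intensities."""
    g = gaussian_filter(raster.intensity.astype(np.float32), sigma=sigma)
    x = g.ravel()
    norm = float(np.linalg.norm(x))
    return x / norm if norm > 0 else x


@dataclass
class PerceptronModel:
    """Weights of the 10-way perceptron plus its training provenance.

    ``weights``/``bias`` are the averaged-perceptron parameters used
    for scoring by default; ``weights_final``/``bias_final`` are the
    last training iterate.
    """

    weights: np.ndarray  # (input_size, n_classes), averaged
    bias: np.ndarray  # (n_classes,), averaged, training mean folded in
    weights_final: np.ndarray
    bias_final: np.ndarray
    labels: tuple[str, ...] = CLASS_LABELS
    learning_rate: float = 0.1
    smoothing_sigma: float = SMOOTHING_SIGMA
    epochs_run: int = 0
    training_log: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def input_size(self) -> int:
        return self.weights.shape[0]

    def save(self, path: str | Path) -> None:
        def enc(a: np.ndarray) -> str:
            return base64.b64encode(a.astype(np.float64).tobytes()).decode()

        payload = {
            "labels": list(self.labels),
            "learning_rate": self.learning_rate,
            "smoothing_sigma": self.smoothing_sigma,
            "epochs_run": self.epochs_run,
            "training_log": self.training_log,
            "seed": self.seed,
            "shape": list(self.weights.shape),
            "weights": enc(self.weights),
            "bias": enc(self.bias),
            "weights_final": enc(self.weights_final),
            "bias_final": enc(self.bias_final),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PerceptronModel":
        payload = json.loads(Path(path).read_text())
        shape = tuple(payload["shape"])

        def dec(key: str, shp=None) -> np.ndarray:
            a = np.frombuffer(base64.b64decode(payload[key]), dtype=np.float64)
            return a.reshape(shp).copy() if shp else a.copy()

        return cls(
            weights=dec("weights", shape),
            bias=dec("bias"),
            weights_final=dec("weights_final", shape),
            bias_final=dec("bias_final"),
            labels=tuple(payload["labels"]),
            learning_rate=payload["learning_rate"],
            smoothing_sigma=payload["smoothing_sigma"],
            epochs_run=payload["epochs_run"],
            training_log=list(payload["training_log"]),
            seed=payload["seed"],
        )


@dataclass(frozen=True)
class ClassificationResult:
    sequence_id: str
    scores: dict[str, float]
    match_percentage: dict[str, float]
    best: str
    runner_up: str
    margin: float
    transitional: bool


def _argmax_with_tiebreak(scores: np.ndarray, labels: tuple[str, ...]) -> int:
    """Index of the max score; exact ties go to the alphabetically first label."""
    best = np.flatnonzero(scores == scores.max())
    if best.size == 1:
        return int(best[0])
    return int(min(best, key=lambda i: labels[i]))


def train(
    rasters: list[PatternRaster],
    labels: list[str],
    learning_rate: float = 0.1,
    max_epochs: int = 1000,
    seed: int = 0,
    smoothing_sigma: float = SMOOTHING_SIGMA,
    class_labels: tuple[str, ...] = CLASS_LABELS,
) -> PerceptronModel:
    """Train the one-vs-rest perceptron on labeled rasters.

    Training is deterministic: weights start at zero and the seed only
    drives the per-epoch shuffle.  Stops early once an epoch makes no
    mistake; the per-epoch training accuracy is kept in
    ``model.training_log``.
    """
    if not rasters:
        raise ValueError("training set is empty")
    missing = sorted(set(class_labels) - set(labels))
    if missing:
        raise ValueError(f"training data lacks examples of: {', '.join(missing)}")
    unknown = sorted(set(labels) - set(class_labels))
    if unknown:
        raise ValueError(f"unknown class labels: {', '.join(unknown)}")
    shapes = {r.intensity.shape for r in rasters}
    if len(shapes) != 1:
        raise ValueError(f"rasters have mixed dimensions: {sorted(shapes)}")

    n_classes = len(class_labels)
    label_idx = {lab: i for i, lab in enumerate(class_labels)}
    y = np.array([label_idx[lab] for lab in labels])

    X = np.stack([raster_features(r, smoothing_sigma) for r in rasters])
    mu = X.mean(axis=0)
    Xc = X - mu
    input_size = X.shape[1]

    lr = learning_rate
    W = np.zeros((input_size, n_classes))
    b = np.zeros(n_classes)
    # lazy accumulators for the averaged perceptron: U collects t-weighted
    # updates so that W_avg = W - U / t_total
    U = np.zeros((input_size, n_classes))
    ub = np.zeros(n_classes)
    t = 1
    rng = np.random.default_rng(seed)
    log: list[float] = []
    epochs_run = 0
    for _ in range(max_epochs):
        order = rng.permutation(len(rasters))
        errors = 0
        for i in order:
            scores = Xc[i] @ W + b
            pred = _argmax_with_tiebreak(scores, class_labels)
            if pred != y[i]:
                errors += 1
                W[:, y[i]] += lr * Xc[i]
                b[y[i]] += lr
                W[:, pred] -= lr * Xc[i]
                b[pred] -= lr
                U[:, y[i]] += t * lr * Xc[i]
                ub[y[i]] += t * lr
                U[:, pred] -= t * lr * Xc[i]
                ub[pred] -= t * lr
            t += 1
        epochs_run += 1
        log.append(100.0 * (len(rasters) - errors) / len(rasters))
        if errors == 0:
            break
    W_avg = W - U / t
    b_avg = b - ub / t
    # fold the feature centering into the bias: (x - mu)W + b = xW + (b - muW)
    return PerceptronModel(
        weights=W_avg,
        bias=b_avg - mu @ W_avg,
        weights_final=W,
        bias_final=b - mu @ W,
        labels=class_labels,
        learning_rate=lr,
        smoothing_sigma=smoothing_sigma,
        epochs_run=epochs_run,
        training_log=log,
        seed=seed,
    )


def classify(
    model: PerceptronModel,
    raster: PatternRaster,
    threshold: float = TRANSITIONAL_THRESHOLD,
    sequence_id: str = "anonymous",
    weight_set: str = "averaged",
) -> ClassificationResult:
    """Score a raster against all classes and flag transitional states.

    ``weight_set`` selects the averaged-perceptron weights (default,
    better held-out behaviour) or the final iterate ("final", which
    memorizes a separable training set exactly).
    """
    if raster.intensity.size != model.input_size:
        raise ValueError(
            f"raster has {raster.intensity.size} pixels but the model "
            f"expects {model.input_size}"
        )
    x = raster_features(raster, model.smoothing_sigma)
    if weight_set == "averaged":
        scores = x @ model.weights + model.bias
    elif weight_set == "final":
        scores = x @ model.weights_final + model.bias_final
    else:
        raise ValueError("weight_set must be 'averaged' or 'final'")
    best_i = _argmax_with_tiebreak(scores, model.labels)
    lo, hi = scores.min(), scores.max()
    if hi > lo:
        pct = 100.0 * (scores - lo) / (hi - lo)
    else:
        pct = np.full_like(scores, 100.0)
    order = np.argsort(-pct, kind="stable")
    runner_i = next(int(i) for i in order if int(i) != best_i)
    margin = float(pct[best_i] - pct[runner_i])
    return ClassificationResult(
        sequence_id=sequence_id,
        scores={lab: float(s) for lab, s in zip(model.labels, scores)},
        match_percentage={lab: float(p) for lab, p in zip(model.labels, pct)},
        best=model.labels[best_i],
        runner_up=model.labels[runner_i],
        margin=margin,
        transitional=margin < threshold,
    )


def detect_transitional(
    result: ClassificationResult, threshold: float = TRANSITIONAL_THRESHOLD
) -> bool:
    """True iff the best/runner-up margin is strictly below the threshold."""
    return result.margin < threshold


def evaluate(
    model: PerceptronModel,
    rasters: list[PatternRaster],
    labels: list[str],
    weight_set: str = "averaged",
) -> tuple[np.ndarray, dict[str, float], float]:
    """Confusion matrix (rows = truth), per-class recall, macro recall."""
    if not rasters:
        raise ValueError("evaluation set is empty")
    n = len(model.labels)
    idx = {lab: i for i, lab in enumerate(model.labels)}
    cm = np.zeros((n, n), dtype=int)
    for raster, lab in zip(rasters, labels):
        res = classify(model, raster, weight_set=weight_set)
        cm[idx[lab], idx[res.best]] += 1
    recall = {}
    for lab, i in idx.items():
        row = cm[i].sum()
        recall[lab] = float(cm[i, i] / row) if row else float("nan")
    present = [r for r in recall.values() if not np.isnan(r)]
    macro = float(np.mean(present))
    return cm, recall, macro
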