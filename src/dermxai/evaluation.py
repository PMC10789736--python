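"""Quantitative evaluation: accuracy, attention placement, faithfulness,
overlap statistics and paired significance tests.

The metrics mirror how an attention-supervised dermoscopy classifier is
judged:

* balanced accuracy (mean of per-class recalls) with percentile-bootstrap
  confidence intervals;
* the *attribution ratio* — mean attention inside the lesion divided by
  mean attention outside it; high values indicate lesion-focused
  reasoning, since artefacts (rulers, ink) live outside the lesion;
* explanation *faithfulness* by contrastive deletion — the drop in the
  diagnosis-driving output score when the pixels an explanation marks as
  important are randomised, swept over importance thresholds;
* Sørensen-Dice overlap between label sets (from TP/FP/FN counts) and
  between soft masks (with a smoothing term), plus per-image pairwise
  rater agreement;
* two-sided paired/unpaired tests with Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from dermxai.ontology import DiagnosisClass, Ontology


@dataclass
class BootstrapConfig:
    n_samples: int = 10000
    seed: int = 42
    alpha: float = 0.05
    method: str = "percentile"

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class OverlapResult:
    value: float
    tp: int | None = None
    fp: int | None = None
    fn: int | None = None


@dataclass
class RaterPairOverlap:
    image_id: str
    rater_a: str
    rater_b: str
    result: OverlapResult = field(default_factory=lambda: OverlapResult(0.0))


@dataclass
class MaskOverlapConfig:
    epsilon: float = 1.0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class FaithfulnessCurve:
    thresholds: list
    mean_score_change: list
    ci_low: list
    ci_high: list
    n_images: int


@dataclass
class TestResult:
    statistic: float
    p_value: float
    adjusted_p: float
    test: str
    n: int


# ---------------------------------------------------------------------
# balanced accuracy
# ---------------------------------------------------------------------


def _as_melanoma_bool(values) -> np.ndarray:
    out = []
    for v in values:
        if isinstance(v, DiagnosisClass):
            out.append(v is DiagnosisClass.MELANOMA)
        elif isinstance(v, str):
            out.append(DiagnosisClass(v) is DiagnosisClass.MELANOMA)
        else:
            out.append(bool(v))
    return np.asarray(out, dtype=bool)


def balanced_accuracy(predicted, truth) -> float:
    """Mean of sensitivity and specificity."""
    p = _as_melanoma_bool(predicted)
    t = _as_melanoma_bool(truth)
    if len(p) != len(t):
        raise ValueError("length mismatch")
    if t.all() or not t.any():
        raise ValueError("both classes must be present in the truth")
    sens = float((p & t).sum() / t.sum())
    spec = float((~p & ~t).sum() / (~t).sum())
    return 0.5 * (sens + spec)


def balanced_accuracy_ci(predicted, truth, cfg: BootstrapConfig | None = None):
    """Balanced accuracy with a seeded percentile-bootstrap CI.

    Resampling is at the image level; bootstrap draws that lose one of the
    two truth classes are dropped from the percentile computation.
    Returns ``(estimate, ci_low, ci_high)``.
    """
    cfg = cfg or BootstrapConfig()
    p = _as_melanoma_bool(predicted)
    t = _as_melanoma_bool(truth)
    estimate = balanced_accuracy(p, t)
    n = len(t)
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, n, size=(cfg.n_samples, n))
    ts = t[idx]
    ps = p[idx]
    pos = ts.sum(axis=1)
    neg = n - pos
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = (ps & ts).sum(axis=1) / pos
        spec = (~ps & ~ts).sum(axis=1) / neg
    ba = 0.5 * (sens + spec)
    ba = ba[(pos > 0) & (neg > 0)]
    lo, hi = np.percentile(ba, [100 * cfg.alpha / 2, 100 * (1 - cfg.alpha / 2)])
    return estimate, float(lo), float(hi)


# ---------------------------------------------------------------------
# attribution ratio
# ---------------------------------------------------------------------


def attribution_ratio(attention_values, lesion_mask) -> float:
    """Mean attention inside the lesion over mean attention outside it.

    Returns ``inf`` (flagged, excluded from aggregates) when the outside
    mean is zero; raises when the mask is all-inside or all-outside.
    """
    a = np.asarray(attention_values, dtype=np.float64)
    m = np.asarray(lesion_mask, dtype=bool)
    if a.shape != m.shape:
        raise ValueError("shape mismatch between attention map and lesion mask")
    if m.all() or not m.any():
        raise ValueError("lesion mask needs both inside and outside pixels")
    inside = a[m].mean()
    outside = a[~m].mean()
    if outside == 0.0:
        warnings.warn("zero outside-lesion attribution: infinite ratio", stacklevel=2)
        return float("inf")
    return float(inside / outside)


def mean_attribution_ratio(ratios):
    """Mean over finite ratios; returns ``(mean, n_finite, n_infinite)``."""
    arr = np.asarray(ratios, dtype=np.float64)
    finite = arr[np.isfinite(arr)]
    mean = float(finite.mean()) if finite.size else float("nan")
    return mean, int(finite.size), int(arr.size - finite.size)


# ---------------------------------------------------------------------
# Dice overlap
# ---------------------------------------------------------------------


def dsc_label_sets(a: set, b: set) -> OverlapResult:
    """Sørensen-Dice between two label sets from TP/FP/FN counts.

    Two empty sets count as full agreement (value 1): raters who agree on
    "no characteristics" agree completely.
    """
    a, b = set(a), set(b)
    tp = len(a & b)
    fp = len(b - a)
    fn = len(a - b)
    value = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    return OverlapResult(value=value, tp=tp, fp=fp, fn=fn)


def dsc_soft_masks(a, b, cfg: MaskOverlapConfig | None = None) -> float:
    """Soft-mask Dice ``(2*sum(a*b) + eps) / (sum(a) + sum(b) + eps)``."""
    cfg = cfg or MaskOverlapConfig()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    return float((2.0 * (a * b).sum() + cfg.epsilon) / (a.sum() + b.sum() + cfg.epsilon))


def pairwise_rater_overlap(annotations: dict) -> list:
    """Per-image label-set overlap for every unordered rater pair.

    ``annotations`` maps image id -> {rater id -> set of criterion ids}.
    Images with a single rater contribute nothing; an input with no
    multi-rater image yields an empty list with a warning.
    """
    results = []
    for image_id in sorted(annotations):
        raters = sorted(annotations[image_id])
        for i in range(len(raters)):
            for j in range(i + 1, len(raters)):
                res = dsc_label_sets(
                    annotations[image_id][raters[i]], annotations[image_id][raters[j]]
                )
                results.append(
                    RaterPairOverlap(image_id, raters[i], raters[j], res)
                )
    if not results:
        warnings.warn("no image has more than one rater", stacklevel=2)
    return results


# ---------------------------------------------------------------------
# significance tests
# ---------------------------------------------------------------------

_PAIRED_TESTS = {"paired_t", "wilcoxon", "spearman"}


def compare_paired(values_a, values_b, test: str, bonferroni_m: int = 1) -> TestResult:
    """Two-sided test with Bonferroni-adjusted p (``min(1, m*p)``)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if test in _PAIRED_TESTS and len(a) != len(b):
        raise ValueError(f"{test} requires equal lengths")
    if min(len(a), len(b)) < 3:
        raise ValueError("need n >= 3")
    if bonferroni_m < 1:
        raise ValueError("bonferroni_m must be >= 1")

    if test == "paired_t":
        if np.allclose(a - b, (a - b)[0]):
            raise ValueError("zero-variance paired differences: t undefined")
        stat, p = stats.ttest_rel(a, b)
    elif test == "wilcoxon":
        stat, p = stats.wilcoxon(a, b)
    elif test == "mann_whitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "spearman":
        stat, p = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown test: {test!r}")
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        adjusted_p=float(min(1.0, bonferroni_m * p)),
        test=test,
        n=len(a),
    )


# ---------------------------------------------------------------------
# faithfulness by contrastive deletion
# ---------------------------------------------------------------------

DEFAULT_FAITHFULNESS_THRESHOLDS = tuple(range(5, 100, 5))  # 5, 10, ..., 95


def _top_fraction_mask(values: np.ndarray, fraction: float) -> np.ndarray:
    """Top ``fraction`` of pixels by value, stable raster-order ties."""
    h, w = values.shape
    k = int(np.floor(fraction * h * w))
    flat = values.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    mask = np.zeros(h * w, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(h, w)


def diagnosis_attribution(prediction, model, T=None, ontology: Ontology | None = None,
                          detection_threshold: float = 0.5):
    """Attribution map and output score that drive the diagnosis.

    Baseline (single-output) models: the melanoma probability and its CAM.
    Characteristic models: the mean calibrated score over the criteria
    detected on the image (falling back to the max-score criterion when
    nothing is detected) and the mean CAM over those criteria.
    """
    from dermxai.decision import TemperatureVector, calibrate_scores

    if model.n_outputs == 1:
        score = float(prediction.scores[0])
        amap = prediction.attention[0].values
        return amap, score, [0]
    T = T or TemperatureVector.identity(model.n_outputs)
    cal = calibrate_scores(prediction.logits, T)
    detected = [c for c in range(model.n_outputs) if cal[c] >= detection_threshold]
    if not detected:
        detected = [int(np.argmax(cal))]
    amap = np.mean([prediction.attention[c].values for c in detected], axis=0)
    score = float(np.mean([cal[c] for c in detected]))
    return amap, score, detected


def _contrastive_score(model, image, pixel_mask, rng, T, detected):
    """Model output score after randomising the masked pixels."""
    from dermxai.model import predict_characteristics
    from dermxai.decision import TemperatureVector, calibrate_scores

    img = np.array(image, copy=True)
    img[pixel_mask] = rng.uniform(0.0, 1.0, size=(int(pixel_mask.sum()), 3))
    pred = predict_characteristics(model, img)
    if model.n_outputs == 1:
        return float(pred.scores[0])
    T = T or TemperatureVector.identity(model.n_outputs)
    cal = calibrate_scores(pred.logits, T)
    return float(np.mean([cal[c] for c in detected]))


def faithfulness_curve(
    model,
    images,
    thresholds=DEFAULT_FAITHFULNESS_THRESHOLDS,
    rng=None,
    T=None,
    bootstrap: BootstrapConfig | None = None,
) -> FaithfulnessCurve:
    """Mean output-score drop after randomising the top-t% attributed pixels.

    For every threshold t the pixels in the top t percent of the image's
    attribution map (percentile rule with stable ties) are replaced by
    uniform random values per channel, and the change original-minus-
    contrastive of the diagnosis-driving score is averaged over images.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])) or not all(
        0 < t < 100 for t in thresholds
    ):
        raise ValueError("thresholds must be strictly increasing within (0, 100)")
    if not len(images):
        raise ValueError("no images")
    from dermxai.model import predict_characteristics

    rng = rng or np.random.default_rng(0)
    bootstrap = bootstrap or BootstrapConfig(n_samples=1000)
    changes = np.zeros((len(images), len(thresholds)))
    for i, image in enumerate(images):
        pred = predict_characteristics(model, image)
        amap, score, detected = diagnosis_attribution(pred, model, T)
        for j, t in enumerate(thresholds):
            pix = _top_fraction_mask(amap, t / 100.0)
            contr = _contrastive_score(model, image, pix, rng, T, detected)
            changes[i, j] = score - contr

    mean = changes.mean(axis=0)
    brng = np.random.default_rng(bootstrap.seed)
    idx = brng.integers(0, len(images), size=(bootstrap.n_samples, len(images)))
    boot = changes[idx].mean(axis=1)  # (B, n_thresholds)
    lo, hi = np.percentile(
        boot, [100 * bootstrap.alpha / 2, 100 * (1 - bootstrap.alpha / 2)], axis=0
    )
    return FaithfulnessCurve(
        thresholds=thresholds,
        mean_score_change=mean.tolist(),
        ci_low=lo.tolist(),
        ci_high=hi.tolist(),
        n_images=len(images),
    )


def faithfulness_salient_vs_random(model, images, fraction=0.2, rng=None, T=None):
    """Paired comparison: score drop for salient vs equal-area random pixels.

    Returns ``(mean_salient_change, mean_random_change, per_image_pairs)``.
    """
    from dermxai.model import predict_characteristics

    rng = rng or np.random.default_rng(0)
    pairs = []
    for image in images:
        pred = predict_characteristics(model, image)
        amap, score, detected = diagnosis_attribution(pred, model, T)
        pix = _top_fraction_mask(amap, fraction)
        sal = score - _contrastive_score(model, image, pix, rng, T, detected)
        h, w = amap.shape
        k = int(pix.sum())
        # equal-area random region avoiding the salient pixels
        candidates = np.flatnonzero(~pix.ravel())
        chosen = rng.choice(candidates, size=min(k, len(candidates)), replace=False)
        rmask = np.zeros(h * w, dtype=bool)
        rmask[chosen] = True
        rnd = score - _contrastive_score(
            model, image, rmask.reshape(h, w), rng, T, detected
        )
        pairs.append((sal, rnd))
    arr = np.asarray(pairs)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean()), arr
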