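"""Calibration, detection, the diagnosis rule and explanation assembly.

The raw sigmoid outputs of a neural network are known to be over-confident,
so each output class is calibrated with its own temperature: the logit is
divided by a fitted positive scalar before the sigmoid. Calibrated scores
drive three decisions:

* *detection* — a characteristic is detected when its calibrated score
  reaches the detection threshold (default 0.5);
* *diagnosis* — melanoma iff at least two melanoma-class characteristics
  are detected, nevus otherwise;
* *evidence wording / certainty* — a characteristic has "strong evidence"
  when its calibrated score is strictly above 0.7; the classifier is
  *certain* when at least one characteristic has strong evidence. If no
  characteristic passes 0.7, the explanation falls back to the single most
  certain characteristic at the "some evidence" level.

Visual explanations outline the top 20% attribution pixels of each
reported characteristic's attention map as polygons (an absolute-threshold
mode at 0.7 is available as an alternative).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from skimage import measure as skmeasure

from dermxai.ontology import (
    DiagnosisClass,
    Findings,
    Ontology,
    render_textual_explanation,
)

STRONG_EVIDENCE_THRESHOLD = 0.7
DEFAULT_DETECTION_THRESHOLD = 0.5
DEFAULT_REGION_FRACTION = 0.20
TEMPERATURE_BOUNDS = (0.05, 20.0)


@dataclass
class TemperatureVector:
    """One fitted temperature per output class (all strictly positive)."""

    temperatures: np.ndarray

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=np.float64)
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be positive")

    @classmethod
    def identity(cls, n: int) -> "TemperatureVector":
        return cls(np.ones(n))

    def __len__(self):
        return len(self.temperatures)


@dataclass
class DetectionSet:
    """Criteria whose calibrated score reached the detection threshold."""

    detected: set
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD


@dataclass
class Explanation:
    """Multimodal explanation: diagnosis, findings, regions and text."""

    diagnosis: DiagnosisClass
    findings: Findings
    regions: dict  # criterion id -> {"mask": (H,W) bool, "polygons": [...]}
    text: str
    classifier_certain: bool
    calibrated_scores: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "diagnosis": self.diagnosis.value,
            "classifier_certain": self.classifier_certain,
            "findings": {
                "strong": sorted(self.findings.strong),
                "some": sorted(self.findings.some),
            },
            "calibrated_scores": {k: float(v) for k, v in self.calibrated_scores.items()},
            "text": self.text,
            "regions": {
                cid: {"polygons": [np.asarray(p).tolist() for p in r["polygons"]]}
                for cid, r in self.regions.items()
            },
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------
# temperature scaling
# ---------------------------------------------------------------------


def _binary_nll(logits, labels, T):
    z = logits / T
    # stable: -[y*log sigmoid(z) + (1-y)*log sigmoid(-z)]
    return float(np.mean(np.maximum(z, 0) - z * labels + np.log1p(np.exp(-np.abs(z)))))


def fit_temperatures(val_logits, val_labels) -> TemperatureVector:
    """Fit one temperature per class by minimising validation NLL.

    Classes whose validation labels are degenerate (a single value) keep
    T = 1 with a warning. The NLL at the returned temperature never
    exceeds the NLL at T = 1.
    """
    z = np.asarray(val_logits, dtype=np.float64)
    y = np.asarray(val_labels, dtype=np.float64)
    if z.ndim == 1:
        z, y = z[:, None], y[:, None]
    if z.size == 0:
        raise ValueError("empty validation set")
    if z.shape != y.shape:
        raise ValueError("logit/label shape mismatch")
    temps = np.ones(z.shape[1])
    for c in range(z.shape[1]):
        zc, yc = z[:, c], y[:, c]
        if len(np.unique(yc)) < 2:
            warnings.warn(
                f"class {c}: single label value on validation data, keeping T=1",
                stacklevel=2,
            )
            continue
        res = minimize_scalar(
            lambda t: _binary_nll(zc, yc, t),
            bounds=TEMPERATURE_BOUNDS,
            method="bounded",
            options={"xatol": 1e-4},
        )
        if _binary_nll(zc, yc, res.x) <= _binary_nll(zc, yc, 1.0):
            temps[c] = res.x
    return TemperatureVector(temps)


def calibrate_scores(logits, T: TemperatureVector) -> np.ndarray:
    """sigmoid(logit_c / T_c) — a per-class monotone transform."""
    z = np.asarray(logits, dtype=np.float64)
    t = T.temperatures
    if z.shape[-1] != len(t):
        raise ValueError(f"got {z.shape[-1]} logits for {len(t)} temperatures")
    return 1.0 / (1.0 + np.exp(-z / t))


# ---------------------------------------------------------------------
# evidence, detection, diagnosis
# ---------------------------------------------------------------------


def evidence_level(calibrated_score: float) -> str:
    """"strong" iff the calibrated score is strictly above 0.7, else "some"."""
    s = float(calibrated_score)
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"score {s} outside [0, 1]")
    return "strong" if s > STRONG_EVIDENCE_THRESHOLD else "some"


def detect_characteristics(
    calibrated_scores,
    ontology: Ontology,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> DetectionSet:
    """Criteria with calibrated score >= threshold (inclusive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("detection threshold must be in (0, 1)")
    scores = np.asarray(calibrated_scores, dtype=np.float64)
    if scores.shape[-1] != len(ontology):
        raise ValueError(
            f"got {scores.shape[-1]} scores for {len(ontology)} criteria"
        )
    detected = {ontology.ids[i] for i in range(len(ontology)) if scores[i] >= threshold}
    return DetectionSet(detected=detected, detection_threshold=threshold)


def infer_diagnosis(detections: DetectionSet, ontology: Ontology) -> DiagnosisClass:
    """Melanoma iff at least two melanoma-class criteria are detected.

    Nevus-class detections never contribute to the melanoma count.
    """
    n_mel = sum(
        1
        for cid in detections.detected
        if ontology.get(cid).class_association is DiagnosisClass.MELANOMA
    )
    return DiagnosisClass.MELANOMA if n_mel >= 2 else DiagnosisClass.NEVUS


# ---------------------------------------------------------------------
# explanation regions
# ---------------------------------------------------------------------


def extract_explanation_region(
    attention_values: np.ndarray,
    fraction: float = DEFAULT_REGION_FRACTION,
    mode: str = "percentile",
    absolute_threshold: float = STRONG_EVIDENCE_THRESHOLD,
):
    """Select the most-attributed pixels and trace their boundary polygons.

    In the default ``percentile`` mode exactly ``floor(fraction * H * W)``
    pixels with the highest attribution are selected, ties broken by
    stable raster (row-major) order; in ``absolute`` mode all pixels at or
    above ``absolute_threshold`` are selected instead. Polygons are the
    traced boundaries of the mask's 8-connected components, vertices in
    0-based ``[x, y]`` pixel coordinates.

    Returns ``(mask, polygons)``.
    """
    vals = np.asarray(attention_values, dtype=np.float64)
    if vals.ndim != 2:
        raise ValueError("attention map must be 2-D")
    h, w = vals.shape
    mask = np.zeros((h, w), dtype=bool)
    if mode == "percentile":
        if not (0.0 < fraction < 1.0):
            raise ValueError("fraction must be in (0, 1)")
        k = int(np.floor(fraction * h * w))
        flat = vals.ravel()
        # sort by value descending, then raster index ascending (stable ties)
        order = np.lexsort((np.arange(flat.size), -flat))
        mask.ravel()[order[:k]] = True
    elif mode == "absolute":
        mask = vals >= absolute_threshold
    else:
        raise ValueError(f"unknown region mode: {mode!r}")

    labelled = skmeasure.label(mask, connectivity=2)
    polygons = []
    for region_id in range(1, labelled.max() + 1):
        comp = labelled == region_id
        padded = np.pad(comp.astype(float), 1)
        contours = skmeasure.find_contours(padded, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len) - 1.0  # unpad
        # (row, col) -> (x, y)
        polygons.append(np.stack([contour[:, 1], contour[:, 0]], axis=1))
    return mask, polygons


# ---------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------


def assemble_explanation(
    prediction,
    T: TemperatureVector,
    ontology: Ontology,
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
    region_fraction: float = DEFAULT_REGION_FRACTION,
) -> Explanation:
    """Full explanation pipeline: calibrate, detect, diagnose, render.

    Regions are shown for every strong-evidence criterion; when none is
    strong, the single most certain criterion is reported at the "some
    evidence" level (ties broken by ontology order), so the explanation is
    never empty.
    """
    scores = np.asarray(prediction.scores, dtype=np.float64)
    if scores.shape[-1] != len(ontology):
        raise ValueError(
            f"prediction has {scores.shape[-1]} outputs for {len(ontology)} criteria"
        )
    calibrated = calibrate_scores(prediction.logits, T)
    detections = detect_characteristics(calibrated, ontology, detection_threshold)
    diagnosis = infer_diagnosis(detections, ontology)

    strong = {
        ontology.ids[c]
        for c in range(len(ontology))
        if evidence_level(calibrated[c]) == "strong"
    }
    if strong:
        findings = Findings(strong=strong, some=set())
        report_ids = strong
        certain = True
    else:
        best = int(np.argmax(calibrated))  # argmax is the first max: stable
        findings = Findings(strong=set(), some={ontology.ids[best]})
        report_ids = {ontology.ids[best]}
        certain = False

    attention_by_class = {a.class_id: a for a in prediction.attention}
    regions = {}
    for cid in report_ids:
        amap = attention_by_class[ontology.index_of(cid)]
        mask, polys = extract_explanation_region(amap.values, region_fraction)
        regions[cid] = {"mask": mask, "polygons": polys}

    text = render_textual_explanation(findings, ontology)
    return Explanation(
        diagnosis=diagnosis,
        findings=findings,
        regions=regions,
        text=text,
        classifier_certain=certain,
        calibrated_scores={
            ontology.ids[c]: float(calibrated[c]) for c in range(len(ontology))
        },
    )
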