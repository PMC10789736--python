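"""Synthetic dermoscopy-like image generator with known ground truth.

Real training data for the characteristic classifier consists of dermoscopic
photographs with expert-drawn regions of interest for every catalogue
criterion. This module emulates that structure at configurable scale: a
pigmented elliptical lesion on a skin-tone background, a small library of
parametric *motifs* — one visually distinctive renderer per supported
criterion — drawn inside the lesion at recorded mask locations, multi-hot
labels derived from the drawn motifs, a diagnosis derived from the
two-melanoma-criteria rule, optional spurious artefacts (rulers, ink
markings) strictly outside the lesion, and lesion-level train/val/test
splits that never share a lesion or patient between sets.

Cosmetic fidelity is explicitly not a goal: the motifs are colour/shape
codes that make each criterion visually separable by construction, so a
small network can learn them quickly and every downstream contract
(attention supervision, diagnosis rule, evaluation metrics) is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from dermxai.ontology import DiagnosisClass, Ontology, default_ontology

# criteria with a motif renderer; localisation-specific criteria and the
# melanoma simulator (annotator judgement, not a visual motif) are excluded
DEFAULT_CRITERIA_SUBSET = (
    # melanoma motifs
    "thick_reticular_lines",
    "eccentric_structureless_area",
    "grey_patterns",
    "polymorphous_vessels",
    "peripheral_black_dots",
    "white_lines",
    # nevus motifs
    "one_pattern_one_colour",
    "symmetric_patterns",
    "monomorphic_vessels",
    "radial_lines_circumferential",
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the structure of the real annotation study: a
    class-balanced held-out test set drawn first at lesion level, the
    remaining lesions split 82:18 into train and validation, and one
    image per lesion unless ``images_per_lesion`` says otherwise.
    """

    image_size: tuple = (224, 224)
    criteria_subset: tuple = DEFAULT_CRITERIA_SUBSET
    melanoma_fraction: float = 0.5
    n_lesions: int = 120
    images_per_lesion: int = 1
    artefact_probability: float = 0.0
    artefact_diagnosis_bias: float = 0.0
    noise_level: float = 0.02
    seed: int = 0
    test_fraction: float = 0.2

    def validate(self, ontology: Ontology) -> None:
        if not (0.0 <= self.melanoma_fraction <= 1.0):
            raise ConfigError("melanoma_fraction must be in [0, 1]")
        if not (0.0 <= self.artefact_probability <= 1.0):
            raise ConfigError("artefact_probability must be in [0, 1]")
        if not (-1.0 <= self.artefact_diagnosis_bias <= 1.0):
            raise ConfigError("artefact_diagnosis_bias must be in [-1, 1]")
        if self.images_per_lesion < 1:
            raise ConfigError("images_per_lesion must be >= 1")
        unknown = [c for c in self.criteria_subset if c not in ontology]
        if unknown:
            raise ConfigError(f"criteria_subset ids not in ontology: {unknown}")
        n_mel = sum(
            1
            for c in self.criteria_subset
            if ontology.get(c).class_association is DiagnosisClass.MELANOMA
        )
        if n_mel < 2:
            raise ConfigError(
                "criteria_subset needs >= 2 melanoma criteria "
                "(melanoma samples are unconstructible otherwise)"
            )


@dataclass
class AnnotatedSample:
    """One image with full ground-truth annotation.

    ``characteristic_masks`` stores only the criteria present in the image
    (absent criteria are implicit all-zero masks); use :meth:`mask_stack`
    to obtain the dense per-criterion stack aligned with an ontology order.
    """

    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    lesion_mask: np.ndarray  # (H, W) bool
    characteristic_masks: dict  # criterion id -> (H, W) float32 in [0, 1]
    labels: np.ndarray  # (C,) int8, multi-hot over ontology order
    diagnosis: DiagnosisClass
    lesion_id: str
    patient_id: str
    split: str = "train"
    image_id: str = ""
    artifact: str | None = None

    def mask_stack(self, ontology: Ontology, dtype=np.float32) -> np.ndarray:
        """Dense (C, H, W) stack of characteristic masks in ontology order."""
        h, w = self.lesion_mask.shape
        out = np.zeros((len(ontology), h, w), dtype=dtype)
        for cid, m in self.characteristic_masks.items():
            out[ontology.index_of(cid)] = m
        return out


@dataclass
class DatasetBundle:
    """A generated dataset: samples plus the ontology and config they obey."""

    samples: list
    ontology: Ontology
    config: GeneratorConfig

    @property
    def N(self) -> int:
        return len(self.samples)

    @property
    def C(self) -> int:
        return len(self.ontology)

    def split(self, name: str) -> list:
        return [s for s in self.samples if s.split == name]


def diagnosis_from_labels(labels: np.ndarray, ontology: Ontology) -> DiagnosisClass:
    """Apply the diagnosis rule to a multi-hot label vector.

    Melanoma iff at least two melanoma-class labels are set; nevus-class
    labels never contribute to the count.
    """
    mel_idx = [ontology.index_of(c) for c in ontology.ids_of_class(DiagnosisClass.MELANOMA)]
    n = int(np.asarray(labels)[mel_idx].sum())
    return DiagnosisClass.MELANOMA if n >= 2 else DiagnosisClass.NEVUS


def validate_sample(sample: AnnotatedSample, ontology: Ontology) -> None:
    """Check the three AnnotatedSample invariants; raise AssertionError."""
    stack = sample.mask_stack(ontology)
    mass = stack.reshape(len(ontology), -1).sum(axis=1)
    assert np.array_equal(
        (mass > 0).astype(np.int8), sample.labels.astype(np.int8)
    ), "labels must flag exactly the criteria with positive mask mass"
    outside = stack[:, ~sample.lesion_mask]
    assert not np.any(outside > 0), "characteristic masks must lie inside the lesion"
    assert (
        diagnosis_from_labels(sample.labels, ontology) == sample.diagnosis
    ), "diagnosis must follow the >=2-melanoma-criteria rule"


# ---------------------------------------------------------------------
# motif renderers
# ---------------------------------------------------------------------
# Each renderer paints its motif onto `img` (H, W, 3) inside the allowed
# region and returns the boolean footprint of the painted pixels. Colours
# and shapes are deliberately distinctive per criterion.


def _paint(img, rr, cc, colour, allowed):
    h, w = allowed.shape
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rr, cc = rr[keep], cc[keep]
    keep = allowed[rr, cc]
    rr, cc = rr[keep], cc[keep]
    img[rr, cc] = colour
    foot = np.zeros((h, w), dtype=bool)
    foot[rr, cc] = True
    return foot


def _anchor(rng, allowed, margin_frac=0.0):
    """Random pixel inside the allowed region."""
    ys, xs = np.nonzero(allowed)
    if len(ys) == 0:
        raise ConfigError("no room inside the lesion for a motif")
    k = rng.integers(len(ys))
    return int(ys[k]), int(xs[k])


def _disc(img, allowed, rng, colour, rfrac):
    h, w = allowed.shape
    r = max(2, int(rfrac * min(h, w)))
    cy, cx = _anchor(rng, ndimage.binary_erosion(allowed, iterations=min(r, 10)) if r < min(h, w) // 2 else allowed)
    rr, cc = skdraw.disk((cy, cx), r, shape=(h, w))
    return _paint(img, rr, cc, colour, allowed)


def _render_grey_patterns(img, allowed, lesion_geom, rng):
    return _disc(img, allowed, rng, np.array([0.52, 0.52, 0.58]), 0.11)


def _render_eccentric_area(img, allowed, lesion_geom, rng):
    # offset blob toward the lesion boundary
    cy, cx, ry, rx, _ = lesion_geom
    h, w = allowed.shape
    ang = rng.uniform(0, 2 * np.pi)
    ay = int(cy + 0.55 * ry * np.sin(ang))
    ax = int(cx + 0.55 * rx * np.cos(ang))
    r = max(3, int(0.11 * min(h, w)))
    rr, cc = skdraw.disk((ay, ax), r, shape=(h, w))
    # saturated orange: "any colour except skin colour, white and grey"
    return _paint(img, rr, cc, np.array([0.90, 0.45, 0.02]), allowed)


def _render_white_lines(img, allowed, lesion_geom, rng):
    h, w = allowed.shape
    cy, cx = _anchor(rng, allowed)
    length = max(8, int(0.22 * min(h, w)))
    ang = rng.uniform(0, np.pi)
    dy, dx = np.sin(ang), np.cos(ang)
    foot = np.zeros((h, w), dtype=bool)
    for off in (-4, -3, -2, 1, 2, 3):  # two bands, each ~3 px thick
        y0 = int(cy + off * dx)
        x0 = int(cx - off * dy)
        y1, x1 = int(y0 + dy * length), int(x0 + dx * length)
        rr, cc = skdraw.line(y0, x0, y1, x1)
        foot |= _paint(img, rr, cc, np.array([0.99, 0.99, 0.97]), allowed)
    return foot


def _render_reticular_lines(img, allowed, lesion_geom, rng):
    h, w = allowed.shape
    cy, cx = _anchor(rng, allowed)
    half = max(6, int(0.11 * min(h, w)))
    foot = np.zeros((h, w), dtype=bool)
    step = max(3, half // 2)
    colour = np.array([0.05, 0.10, 0.38])
    for off in range(-half, half + 1, step):
        for t in (0, 1):  # 2 px thick grid lines
            rr, cc = skdraw.line(cy + off + t, cx - half, cy + off + t, cx + half)
            foot |= _paint(img, rr, cc, colour, allowed)
            rr, cc = skdraw.line(cy - half, cx + off + t, cy + half, cx + off + t)
            foot |= _paint(img, rr, cc, colour, allowed)
    return foot


def _render_polymorphous_vessels(img, allowed, lesion_geom, rng):
    h, w = allowed.shape
    cy, cx = _anchor(rng, allowed)
    foot = np.zeros((h, w), dtype=bool)
    spread = max(6, int(0.12 * min(h, w)))
    for _ in range(14):
        ay = cy + int(rng.integers(-spread, spread + 1))
        ax = cx + int(rng.integers(-spread, spread + 1))
        r = int(rng.integers(1, 5))  # varied sizes: polymorphous
        rr, cc = skdraw.disk((ay, ax), r, shape=(h, w))
        foot |= _paint(img, rr, cc, np.array([0.82, 0.12, 0.14]), allowed)
    return foot


def _render_peripheral_black_dots(img, allowed, lesion_geom, rng):
    cy, cx, ry, rx, theta = lesion_geom
    h, w = allowed.shape
    foot = np.zeros((h, w), dtype=bool)
    n_dots = int(rng.integers(10, 15))
    phases = rng.uniform(0, 2 * np.pi, size=n_dots)
    for ang in phases:
        ay = int(cy + 0.75 * ry * np.sin(ang))
        ax = int(cx + 0.75 * rx * np.cos(ang))
        rr, cc = skdraw.disk((ay, ax), 3, shape=(h, w))
        foot |= _paint(img, rr, cc, np.array([0.05, 0.04, 0.04]), allowed)
    return foot


def _render_one_pattern(img, allowed, lesion_geom, rng):
    return _disc(img, allowed, rng, np.array([0.76, 0.56, 0.42]), 0.11)


def _render_symmetric_patterns(img, allowed, lesion_geom, rng):
    cy, cx, ry, rx, _ = lesion_geom
    h, w = allowed.shape
    dy = int(rng.uniform(0.3, 0.5) * ry)
    dx = int(rng.uniform(0.3, 0.5) * rx)
    r = max(4, int(0.08 * min(h, w)))
    colour = np.array([0.45, 0.52, 0.18])
    foot = np.zeros((h, w), dtype=bool)
    for sy, sx in ((dy, dx), (-dy, -dx)):  # mirrored about the centre
        rr, cc = skdraw.disk((int(cy + sy), int(cx + sx)), r, shape=(h, w))
        foot |= _paint(img, rr, cc, colour, allowed)
    return foot


def _render_monomorphic_vessels(img, allowed, lesion_geom, rng):
    h, w = allowed.shape
    cy, cx = _anchor(rng, allowed)
    foot = np.zeros((h, w), dtype=bool)
    step = max(5, int(0.05 * min(h, w)))
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            rr, cc = skdraw.disk((cy + i * step, cx + j * step), 2, shape=(h, w))
            foot |= _paint(img, rr, cc, np.array([0.93, 0.52, 0.62]), allowed)
    return foot


def _render_radial_circumferential(img, allowed, lesion_geom, rng):
    cy, cx, ry, rx, _ = lesion_geom
    h, w = allowed.shape
    foot = np.zeros((h, w), dtype=bool)
    n_spokes = 24
    for k in range(n_spokes):  # full circumference
        ang = 2 * np.pi * k / n_spokes
        y0 = int(cy + 0.62 * ry * np.sin(ang))
        x0 = int(cx + 0.62 * rx * np.cos(ang))
        y1 = int(cy + 0.92 * ry * np.sin(ang))
        x1 = int(cx + 0.92 * rx * np.cos(ang))
        rr, cc = skdraw.line(y0, x0, y1, x1)
        foot |= _paint(img, rr, cc, np.array([0.42, 0.03, 0.10]), allowed)
    return foot


MOTIF_RENDERERS: dict[str, Callable] = {
    "thick_reticular_lines": _render_reticular_lines,
    "eccentric_structureless_area": _render_eccentric_area,
    "grey_patterns": _render_grey_patterns,
    "polymorphous_vessels": _render_polymorphous_vessels,
    "peripheral_black_dots": _render_peripheral_black_dots,
    "white_lines": _render_white_lines,
    "one_pattern_one_colour": _render_one_pattern,
    "symmetric_patterns": _render_symmetric_patterns,
    "monomorphic_vessels": _render_monomorphic_vessels,
    "radial_lines_circumferential": _render_radial_circumferential,
}


# ---------------------------------------------------------------------
# sample generation
# ---------------------------------------------------------------------


def _lesion_layout(config, rng):
    """Background, lesion ellipse and mask (no motifs, no noise)."""
    h, w = config.image_size
    base = np.array([0.86, 0.70, 0.62]) + rng.uniform(-0.04, 0.04, size=3)
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = base
    # gentle illumination gradient
    gy = np.linspace(-0.03, 0.03, h)[:, None, None]
    img = np.clip(img + gy, 0, 1).astype(np.float32)

    cy = h / 2 + rng.uniform(-0.08, 0.08) * h
    cx = w / 2 + rng.uniform(-0.08, 0.08) * w
    ry = rng.uniform(0.24, 0.33) * h
    rx = rng.uniform(0.24, 0.33) * w
    theta = rng.uniform(0, np.pi)
    rr, cc = skdraw.ellipse(cy, cx, ry, rx, shape=(h, w), rotation=theta)
    lesion = np.zeros((h, w), dtype=bool)
    lesion[rr, cc] = True
    colour = np.array([0.46, 0.30, 0.22]) + rng.uniform(-0.04, 0.04, size=3)
    img[lesion] = colour
    return img, lesion, (cy, cx, ry, rx, theta)


def _choose_motifs(config, ontology, rng, diagnosis):
    mel = [
        c
        for c in config.criteria_subset
        if ontology.get(c).class_association is DiagnosisClass.MELANOMA
    ]
    nev = [c for c in config.criteria_subset if c not in mel]
    if diagnosis is DiagnosisClass.MELANOMA:
        n_mel = int(rng.integers(2, min(4, len(mel)) + 1))
        n_nev = int(rng.integers(0, min(2, len(nev)) + 1))
    else:
        n_mel = int(rng.integers(0, 2))  # 0 or 1: below the rule threshold
        n_nev = int(rng.integers(1, min(3, len(nev)) + 1)) if nev else 0
        if n_mel == 0 and n_nev == 0:
            n_nev = 1
    chosen = list(rng.choice(mel, size=n_mel, replace=False)) if n_mel else []
    chosen += list(rng.choice(nev, size=n_nev, replace=False)) if n_nev else []
    return [str(c) for c in chosen]


MASK_DILATION_PX = 2  # stand-in for the looseness of hand-drawn ROIs


def _render_clean(config, ontology, rng, diagnosis):
    img, lesion, geom = _lesion_layout(config, rng)
    allowed = ndimage.binary_erosion(lesion, iterations=3)
    chosen = _choose_motifs(config, ontology, rng, diagnosis)
    masks: dict[str, np.ndarray] = {}
    dil = ndimage.generate_binary_structure(2, 2)
    for cid in chosen:
        foot = MOTIF_RENDERERS[cid](img, allowed, geom, rng)
        if not foot.any():  # fall back to a guaranteed-nonempty disc
            foot = _disc(img, allowed, rng, np.array([0.5, 0.5, 0.5]), 0.04)
        m = ndimage.binary_dilation(foot, structure=dil, iterations=MASK_DILATION_PX)
        masks[cid] = (m & lesion).astype(np.float32)
    labels = np.zeros(len(ontology), dtype=np.int8)
    for cid in masks:
        labels[ontology.index_of(cid)] = 1
    return img, lesion, masks, labels


def generate_sample(
    config: GeneratorConfig,
    rng: np.random.Generator,
    diagnosis: DiagnosisClass | str,
    ontology: Ontology | None = None,
    lesion_id: str = "L0000",
    patient_id: str = "P0000",
    split: str = "train",
    image_id: str = "",
) -> AnnotatedSample:
    """Generate one annotated image with the requested diagnosis.

    Melanoma samples carry at least two melanoma motifs; nevus samples at
    most one melanoma motif and at least one nevus motif, so the diagnosis
    rule applied to the labels reproduces the requested diagnosis.
    """
    ontology = ontology or default_ontology()
    config.validate(ontology)
    diagnosis = DiagnosisClass(diagnosis)
    img, lesion, masks, labels = _render_clean(config, ontology, rng, diagnosis)
    if config.noise_level > 0:
        img = img + rng.normal(0.0, config.noise_level, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    sample = AnnotatedSample(
        image=img,
        lesion_mask=lesion,
        characteristic_masks=masks,
        labels=labels,
        diagnosis=diagnosis,
        lesion_id=lesion_id,
        patient_id=patient_id,
        split=split,
        image_id=image_id or f"{lesion_id}_0",
    )
    return sample


# ---------------------------------------------------------------------
# artefacts
# ---------------------------------------------------------------------


def inject_artifact(
    sample: AnnotatedSample, kind: str, rng: np.random.Generator
) -> AnnotatedSample:
    """Return a copy of the sample with a spurious artefact added.

    Artefact pixels are drawn strictly outside the lesion mask; the
    annotation (labels, masks, diagnosis) is untouched. ``kind`` is
    ``"ruler"`` (tick marks along one image edge) or ``"marker"``
    (violet ink blob near a corner).
    """
    lesion = sample.lesion_mask
    outside = ~lesion
    if not outside.any():
        raise ValueError("lesion covers the whole frame: no room for an artefact")
    h, w = lesion.shape
    img = sample.image.copy()

    if kind == "ruler":
        edge = int(rng.integers(0, 4))
        colour = np.array([0.15, 0.15, 0.18])
        n_ticks = max(6, w // 12)
        offs = np.linspace(3, (w if edge < 2 else h) - 4, n_ticks).astype(int)
        tick_len = max(4, h // 20)
        for o in offs:
            if edge == 0:  # top
                rr, cc = skdraw.line(1, o, tick_len, o)
            elif edge == 1:  # bottom
                rr, cc = skdraw.line(h - 2, o, h - 1 - tick_len, o)
            elif edge == 2:  # left
                rr, cc = skdraw.line(o, 1, o, tick_len)
            else:  # right
                rr, cc = skdraw.line(o, w - 2, o, w - 1 - tick_len)
            _paint(img, rr, cc, colour, outside)
    elif kind == "marker":
        # corner quadrant with the most outside-lesion room
        corners = [(h // 6, w // 6), (h // 6, 5 * w // 6), (5 * h // 6, w // 6), (5 * h // 6, 5 * w // 6)]
        cy, cx = corners[int(rng.integers(0, 4))]
        cy += int(rng.integers(-h // 12, h // 12 + 1))
        cx += int(rng.integers(-w // 12, w // 12 + 1))
        r = max(3, min(h, w) // 14)
        rr, cc = skdraw.disk((cy, cx), r, shape=(h, w))
        _paint(img, rr, cc, np.array([0.55, 0.20, 0.65]), outside)
    else:
        raise ValueError(f"unknown artefact kind: {kind!r}")

    return replace(sample, image=img, artifact=kind)


# ---------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------


def _artefact_prob(config: GeneratorConfig, diagnosis: DiagnosisClass) -> float:
    """Per-image artefact probability, shifted by the diagnosis bias.

    A positive bias makes artefacts more common on melanoma images (the
    spurious-correlation condition); the shift is +/- bias/2 around the
    base probability, clipped to [0, 1].
    """
    p = config.artefact_probability
    b = config.artefact_diagnosis_bias
    shift = b / 2.0 if diagnosis is DiagnosisClass.MELANOMA else -b / 2.0
    return float(np.clip(p + shift, 0.0, 1.0))


def generate_dataset(
    config: GeneratorConfig, ontology: Ontology | None = None
) -> DatasetBundle:
    """Generate a full dataset bundle with lesion-level splits.

    The test split is drawn class-balanced first (mirroring a fixed-size
    balanced test design); the remaining lesions are split 82:18 into
    train and validation at the lesion level, so no lesion or patient
    appears in two splits.
    """
    ontology = ontology or default_ontology()
    config.validate(ontology)
    rng = np.random.default_rng(config.seed)

    n_mel = int(round(config.melanoma_fraction * config.n_lesions))
    diagnoses = [DiagnosisClass.MELANOMA] * n_mel + [DiagnosisClass.NEVUS] * (
        config.n_lesions - n_mel
    )
    rng.shuffle(diagnoses)

    n_test = int(round(config.test_fraction * config.n_lesions))
    n_test_per_class = n_test // 2
    mel_ids = [i for i, d in enumerate(diagnoses) if d is DiagnosisClass.MELANOMA]
    nev_ids = [i for i, d in enumerate(diagnoses) if d is DiagnosisClass.NEVUS]
    if len(mel_ids) < n_test_per_class or len(nev_ids) < n_test_per_class:
        raise ConfigError("n_lesions too small for a class-balanced test split")
    test_set = set(rng.choice(mel_ids, n_test_per_class, replace=False)) | set(
        rng.choice(nev_ids, n_test_per_class, replace=False)
    )
    remainder = [i for i in range(config.n_lesions) if i not in test_set]
    rng.shuffle(remainder)
    n_train = int(round(0.82 * len(remainder)))
    if n_train == 0 or n_train == len(remainder):
        raise ConfigError("n_lesions too small for an 82:18 train/val split")
    split_of = {}
    for i in test_set:
        split_of[i] = "test"
    for i in remainder[:n_train]:
        split_of[i] = "train"
    for i in remainder[n_train:]:
        split_of[i] = "val"

    samples = []
    for i in range(config.n_lesions):
        lesion_id = f"L{i:04d}"
        patient_id = f"P{i:04d}"
        diagnosis = diagnoses[i]
        lesion_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        img, lesion, masks, labels = _render_clean(config, ontology, lesion_rng, diagnosis)
        for j in range(config.images_per_lesion):
            im = img
            if j > 0:  # re-photograph: small global brightness change
                im = np.clip(img + lesion_rng.uniform(-0.03, 0.03), 0, 1)
            if config.noise_level > 0:
                im = im + lesion_rng.normal(0.0, config.noise_level, size=img.shape)
            im = np.clip(im, 0.0, 1.0).astype(np.float32)
            s = AnnotatedSample(
                image=im,
                lesion_mask=lesion,
                characteristic_masks=masks,
                labels=labels.copy(),
                diagnosis=diagnosis,
                lesion_id=lesion_id,
                patient_id=patient_id,
                split=split_of[i],
                image_id=f"{lesion_id}_{j}",
            )
            if lesion_rng.uniform() < _artefact_prob(config, diagnosis):
                kind = "ruler" if lesion_rng.uniform() < 0.5 else "marker"
                s = inject_artifact(s, kind, lesion_rng)
            samples.append(s)

    return DatasetBundle(samples=samples, ontology=ontology, config=config)
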