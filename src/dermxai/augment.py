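"""Declarative image augmentation for training.

A pipeline is a sequence of dicts ``{"name": ..., "p": ..., **params}``
applied in order; geometric operations are applied identically to the
image and to the stack of characteristic masks so the attention targets
stay aligned. Any subset of operations may be disabled for deterministic
tests by passing a shorter pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import exposure as skexposure
from skimage.transform import resize as sk_resize


def _resize(img, masks, hw):
    if img.shape[:2] != tuple(hw):
        img = sk_resize(img, hw, order=1, anti_aliasing=True, preserve_range=True)
        if masks is not None:
            masks = np.stack(
                [sk_resize(m, hw, order=0, preserve_range=True) for m in masks]
            )
    return img.astype(np.float32), masks


def _shift_scale_rotate(img, masks, rng, shift_limit, scale_limit, rotate_limit):
    h, w = img.shape[:2]
    angle = np.deg2rad(rng.uniform(-rotate_limit, rotate_limit))
    scale = 1.0 + rng.uniform(-scale_limit, scale_limit)
    ty = rng.uniform(-shift_limit, shift_limit) * h
    tx = rng.uniform(-shift_limit, shift_limit) * w
    cos, sin = np.cos(angle), np.sin(angle)
    # inverse map for ndimage.affine_transform (output -> input coords)
    A = np.array([[cos, -sin], [sin, cos]]) / scale
    centre = np.array([h / 2, w / 2])
    offset = centre - A @ (centre + np.array([ty, tx]))

    out = np.stack(
        [
            ndimage.affine_transform(img[..., c], A, offset=offset, order=1, mode="nearest")
            for c in range(img.shape[2])
        ],
        axis=-1,
    )
    if masks is not None:
        masks = np.stack(
            [
                ndimage.affine_transform(m, A, offset=offset, order=0, mode="constant")
                for m in masks
            ]
        )
    return out.astype(np.float32), masks


def _hsv_shift(img, rng, hue_limit, sat_limit, val_limit):
    hsv = skcolor.rgb2hsv(np.clip(img, 0, 1))
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-hue_limit, hue_limit) / 360.0) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] + rng.uniform(-sat_limit, sat_limit) / 255.0, 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] + rng.uniform(-val_limit, val_limit) / 255.0, 0, 1)
    return skcolor.hsv2rgb(hsv).astype(np.float32)


def _color_jitter(img, rng):
    brightness = 1.0 + rng.uniform(-0.2, 0.2)
    contrast = 1.0 + rng.uniform(-0.2, 0.2)
    saturation = 1.0 + rng.uniform(-0.2, 0.2)
    out = img * brightness
    mean = out.mean()
    out = (out - mean) * contrast + mean
    grey = out.mean(axis=2, keepdims=True)
    out = grey + (out - grey) * saturation
    return np.clip(out, 0, 1).astype(np.float32)


def apply_pipeline(img, masks, pipeline, target_hw, rng):
    """Apply an augmentation pipeline to one image (+ optional mask stack).

    ``img`` is (H, W, 3) float in [0, 1]; ``masks`` is (C, H, W) or None.
    Stochastic ops require ``rng``; a pipeline containing only
    deterministic ops (resize/normalize) may pass ``rng=None``.
    """
    img = np.asarray(img, dtype=np.float32)
    for op in pipeline:
        name = op["name"]
        p = op.get("p", 1.0)
        if p < 1.0 and (rng is None or rng.uniform() >= p):
            continue
        if name == "transpose":
            img = np.transpose(img, (1, 0, 2))
            if masks is not None:
                masks = np.transpose(masks, (0, 2, 1))
        elif name == "vertical_flip":
            img = img[::-1]
            if masks is not None:
                masks = masks[:, ::-1]
        elif name == "horizontal_flip":
            img = img[:, ::-1]
            if masks is not None:
                masks = masks[:, :, ::-1]
        elif name == "color_jitter":
            img = _color_jitter(img, rng)
        elif name == "clahe":
            img = skexposure.equalize_adapthist(
                np.clip(img, 0, 1), clip_limit=op.get("clip_limit", 4.0) / 400.0
            ).astype(np.float32)
        elif name == "hue_saturation_value":
            img = _hsv_shift(
                img,
                rng,
                op.get("hue_shift_limit", 10),
                op.get("sat_shift_limit", 20),
                op.get("val_shift_limit", 10),
            )
        elif name == "shift_scale_rotate":
            img, masks = _shift_scale_rotate(
                img,
                masks,
                rng,
                op.get("shift_limit", 0.1),
                op.get("scale_limit", 0.1),
                op.get("rotate_limit", 15),
            )
        elif name == "resize":
            img, masks = _resize(img, masks, target_hw)
        elif name == "normalize":
            pass  # input scaling happens inside the model
        else:
            raise ValueError(f"unknown augmentation op: {name!r}")
    img, masks = _resize(img, masks, target_hw)
    img = np.ascontiguousarray(img)
    if masks is not None:
        masks = np.ascontiguousarray(masks)
    return img, masks
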