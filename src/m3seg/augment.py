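"""On-the-fly training augmentation.

One call to :func:`augment` is one stochastic draw of the pipeline:

* geometric — horizontal flip (p=0.5), a jointly-sampled affine
  (rotation up to ±20°, translation, isotropic scaling) and elastic
  deformation — applied identically to image and mask (mask resampled
  nearest-neighbour so labels stay crisp);
* structural — random occlusion holes (image only);
* intensity — brightness/contrast, Gaussian noise, CLAHE (image only).

Draws are reproducible: the generator is derived from
``(policy.seed, draw_seed)``, and the parameters actually applied are
recorded in ``sample.meta['augment_record']``. Augmentation is a
training-time concern only; evaluation and prediction paths never call it.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import AugmentationPolicy
from .data import SegmentationSample

__all__ = ["sample_params", "apply_params", "augment"]


def _rng_for(policy: AugmentationPolicy, draw_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(policy.seed), int(draw_seed)]))


def sample_params(policy: AugmentationPolicy, rng: np.random.Generator) -> dict:
    """Draw one set of transform parameters (the stochastic part of a draw)."""
    params: dict = {"flip": bool(rng.random() < policy.flip_prob)}
    if rng.random() < policy.affine_prob:
        params["affine"] = {
            "angle": float(rng.uniform(-policy.rotate_limit, policy.rotate_limit)),
            "translate": tuple(rng.uniform(-policy.translate_frac, policy.translate_frac, 2)),
            "scale": float(rng.uniform(*policy.scale_range)),
        }
    if rng.random() < policy.elastic_prob:
        params["elastic"] = {"seed": int(rng.integers(2**31))}
    if rng.random() < policy.occlusion_prob:
        n = int(rng.integers(1, policy.occlusion_max_holes + 1))
        params["occlusion"] = [
            {
                "size": int(rng.integers(4, policy.occlusion_max_size + 1)),
                "pos": tuple(rng.random(2)),
            }
            for _ in range(n)
        ]
    if rng.random() < policy.brightness_contrast_prob:
        params["brightness_contrast"] = {
            "brightness": float(rng.uniform(-policy.brightness_limit, policy.brightness_limit)),
            "contrast": float(rng.uniform(-policy.contrast_limit, policy.contrast_limit)),
        }
    if rng.random() < policy.noise_prob:
        params["noise"] = {"sigma": float(rng.uniform(0, policy.noise_sigma)),
                           "seed": int(rng.integers(2**31))}
    if rng.random() < policy.clahe_prob:
        params["clahe"] = {"clip": policy.clahe_clip}
    return params


def _affine_matrix(shape, angle_deg: float, translate, scale: float, flip: bool):
    """Output->input affine map about the image centre (row, col convention)."""
    h, w = shape
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    if flip:
        rot = rot @ np.array([[1.0, 0.0], [0.0, -1.0]])  # mirror columns
    forward = scale * rot
    inv = np.linalg.inv(forward)
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([translate[0] * h, translate[1] * w])
    offset = centre - inv @ (centre + shift) + 0.0
    return inv, offset


def _warp(arr: np.ndarray, matrix, offset, order: int) -> np.ndarray:
    if arr.ndim == 3:  # channel-last image
        return np.stack(
            [ndimage.affine_transform(arr[..., c], matrix, offset=offset, order=order,
                                      mode="constant", cval=0.0)
             for c in range(arr.shape[-1])], axis=-1)
    return ndimage.affine_transform(arr, matrix, offset=offset, order=order,
                                    mode="constant", cval=0.0)


def _elastic_fields(shape, alpha: float, sigma: float, seed: int):
    rng = np.random.default_rng(seed)
    fields = []
    for _ in range(2):
        noise = rng.uniform(-1, 1, size=shape)
        fields.append(ndimage.gaussian_filter(noise, sigma) * alpha)
    return fields


def _elastic_warp(arr: np.ndarray, fields, order: int) -> np.ndarray:
    h, w = arr.shape[:2]
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = [rows + fields[0], cols + fields[1]]
    if arr.ndim == 3:
        return np.stack(
            [ndimage.map_coordinates(arr[..., c], coords, order=order,
                                     mode="constant", cval=0.0)
             for c in range(arr.shape[-1])], axis=-1)
    return ndimage.map_coordinates(arr, coords, order=order, mode="constant", cval=0.0)


def apply_params(sample: SegmentationSample, policy: AugmentationPolicy,
                 params: dict) -> SegmentationSample:
    """Deterministically apply one parameter draw to a sample."""
    image = np.asarray(sample.image, dtype=np.float64).copy()
    mask = np.asarray(sample.mask).copy()
    shape = mask.shape

    affine = params.get("affine")
    flip = params.get("flip", False)
    if affine is not None or flip:
        aff = affine or {"angle": 0.0, "translate": (0.0, 0.0), "scale": 1.0}
        matrix, offset = _affine_matrix(shape, aff["angle"], aff["translate"],
                                        aff["scale"], flip)
        image = _warp(image, matrix, offset, order=1)
        mask = _warp(mask, matrix, offset, order=0)

    if "elastic" in params:
        fields = _elastic_fields(shape, policy.elastic_alpha, policy.elastic_sigma,
                                 params["elastic"]["seed"])
        image = _elastic_warp(image, fields, order=1)
        mask = _elastic_warp(mask, fields, order=0)

    for hole in params.get("occlusion", []):
        size = hole["size"]
        r0 = int(hole["pos"][0] * max(1, shape[0] - size))
        c0 = int(hole["pos"][1] * max(1, shape[1] - size))
        image[r0:r0 + size, c0:c0 + size] = 0.0

    bc = params.get("brightness_contrast")
    if bc is not None:
        image = (image - 0.5) * (1.0 + bc["contrast"]) + 0.5 + bc["brightness"]

    noise = params.get("noise")
    if noise is not None:
        nrng = np.random.default_rng(noise["seed"])
        image = image + nrng.normal(0.0, noise["sigma"], size=image.shape)

    if "clahe" in params:
        from skimage.exposure import equalize_adapthist

        # skimage expresses the clip limit as a fraction; 2.0 on the
        # conventional scale maps to 0.02 here
        clipped = np.clip(image, 0.0, 1.0)
        image = equalize_adapthist(clipped, clip_limit=params["clahe"]["clip"] / 100.0)

    image = np.clip(image, 0.0, 1.0)
    out = SegmentationSample(image=image, mask=mask.astype(sample.mask.dtype),
                             spacing=sample.spacing, source=sample.source,
                             meta=dict(sample.meta))
    out.meta["augment_record"] = params
    return out


def augment(sample: SegmentationSample, policy: AugmentationPolicy,
            draw_seed: int) -> SegmentationSample:
    """One reproducible stochastic draw of the augmentation pipeline."""
    rng = _rng_for(policy, draw_seed)
    return apply_params(sample, policy, sample_params(policy, rng))
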