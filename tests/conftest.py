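"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive corner-pair search,
direct point-in-ellipse rasterization, pairwise AUC) so they stay
independent of the production code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from strokevol.geometry import LesionImage, SliceMask


def _all_corner_points(slc: SliceMask) -> np.ndarray:
    """Every corner of every lesion pixel — no boundary pruning, no hull."""
    rr, cc = np.nonzero(slc.mask)
    dr, dc = slc.spacing
    offs = np.array([(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)])
    r = (rr[:, None] + offs[None, :, 0]).ravel() * dr
    c = (cc[:, None] + offs[None, :, 1]).ravel() * dc
    return np.unique(np.column_stack([r, c]), axis=0)


def brute_force_feret(slc: SliceMask) -> float:
    """Exhaustive max distance over ALL lesion pixel corners, in cm."""
    pts = _all_corner_points(slc)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max())) / 10.0


def brute_force_projection_width(slc: SliceMask, direction) -> float:
    """Exhaustive projection width perpendicular to `direction`, in cm."""
    direction = np.asarray(direction, float)
    perp = np.array([-direction[1], direction[0]])
    proj = _all_corner_points(slc) @ perp
    return float(proj.max() - proj.min()) / 10.0


def pairwise_auc(scores, truth) -> float:
    """Brute-force AUC over all positive-negative pairs (ties count half)."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    pos = scores[truth]
    neg = scores[~truth]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def digital_ellipse(
    semi_major_mm: float,
    semi_minor_mm: float,
    angle_deg: float = 0.0,
    spacing=(1.0, 1.0),
    pad_mm: float = 3.0,
) -> SliceMask:
    """Rasterize a rotated ellipse by the pixel-centre membership test."""
    theta = np.deg2rad(angle_deg)
    extent = max(semi_major_mm, semi_minor_mm) + pad_mm
    dr, dc = spacing
    nr = int(2 * np.ceil(extent / dr)) + 1
    nc = int(2 * np.ceil(extent / dc)) + 1
    r0, c0 = (nr - 1) / 2 * dr, (nc - 1) / 2 * dc
    rows = np.arange(nr)[:, None] * dr - r0
    cols = np.arange(nc)[None, :] * dc - c0
    u = rows * np.cos(theta) + cols * np.sin(theta)
    v = -rows * np.sin(theta) + cols * np.cos(theta)
    mask = (u / semi_major_mm) ** 2 + (v / semi_minor_mm) ** 2 <= 1.0
    return SliceMask(mask=mask, spacing=spacing, slice_index=0)


def single_slice_image(mask2d, spacing3=(5.0, 1.0, 1.0), patient_id="t") -> LesionImage:
    return LesionImage(
        mask=np.asarray(mask2d, bool)[None, :, :], spacing=spacing3, patient_id=patient_id
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, max_side=12) -> np.ndarray:
    """A small random nonempty boolean mask (blobby, not pure noise)."""
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    mask = rng.random((h, w)) < rng.uniform(0.2, 0.8)
    if not mask.any():
        mask[rng.integers(h), rng.integers(w)] = True
    return mask
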