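"""Synthetic validation data: geometric phantom, limited-angle projections,
and random per-image shift injection."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .geometry import TiltGeometry, TiltSeries, Volume, forward_project
from .warp import ShiftSet, warp_stack

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_dataset",
    "default_limited_angle_geometry",
]

_KINDS = ("cube", "cuboid", "sphere", "ellipsoid")


@dataclass
class PhantomSpec:
    """Recipe for a random geometric-shape phantom volume."""

    size: int = 64
    n_shapes: int = 12
    shape_kinds: Tuple[str, ...] = _KINDS
    intensity_range: Tuple[float, float] = (0.2, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.size < 16:
            raise ValueError("phantom size must be >= 16 voxels")
        if self.n_shapes < 1:
            raise ValueError("need at least one shape")
        bad = set(self.shape_kinds) - set(_KINDS)
        if bad:
            raise ValueError(f"unknown shape kinds: {sorted(bad)}")
        lo, hi = self.intensity_range
        if not lo <= hi:
            raise ValueError("intensity_range must be (lo, hi) with lo <= hi")


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation (QR of a Gaussian matrix, det fixed to +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_phantom(spec: PhantomSpec) -> Volume:
    """Assemble randomly placed, sized and oriented solid shapes.

    Shapes are drawn in order and written with constant intensity; overlaps
    are resolved last-writer-wins.  Deterministic in ``spec.seed``;
    background is zero.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    vol = np.zeros((s, s, s))
    coords = np.stack(
        np.meshgrid(*([np.arange(s) - (s - 1) / 2.0] * 3), indexing="ij")
    )  # (3, s, s, s)
    flat = coords.reshape(3, -1)
    lo, hi = spec.intensity_range
    for _ in range(spec.n_shapes):
        kind = spec.shape_kinds[rng.integers(len(spec.shape_kinds))]
        center = rng.uniform(-0.28, 0.28, size=3) * s
        intensity = rng.uniform(lo, hi)
        if kind in ("cube", "sphere"):
            half = np.full(3, rng.uniform(0.06, 0.16) * s)
        else:
            half = rng.uniform(0.05, 0.18, size=3) * s
        rot = _rotation_matrix(rng) if kind in ("cuboid", "ellipsoid") else np.eye(3)
        local = rot.T @ (flat - center[:, None])
        if kind in ("cube", "cuboid"):
            inside = np.all(np.abs(local) <= half[:, None], axis=0)
        else:
            inside = np.sum((local / half[:, None]) ** 2, axis=0) <= 1.0
        vol.reshape(-1)[inside] = intensity
    return Volume(vol)


def default_limited_angle_geometry(
    size: int, tilt_max: float = 60.0, step: float = 1.0
) -> TiltGeometry:
    """Standard limited-angle setup: angles -tilt_max..tilt_max in ``step``
    degree increments (121 projections with the defaults), cubic volume."""
    n = int(round(2 * tilt_max / step)) + 1
    angles = np.linspace(-tilt_max, tilt_max, n)
    return TiltGeometry(angles, (size, size, size), (size, size))


def make_dataset(
    spec: PhantomSpec,
    geom: TiltGeometry | None = None,
    shift_sigma: float = 1.0,
    seed: int | None = None,
    backend=None,
):
    """Generate a shifted tilt series with known ground truth.

    Projects the phantom over the limited angular range, draws iid
    ``Normal(0, shift_sigma^2)`` shifts per component and angle, and injects
    them by sub-pixel translation of each projection image.

    Returns ``(shifted TiltSeries, true ShiftSet, ground-truth Volume)``.
    """
    if shift_sigma < 0:
        raise ValueError("shift_sigma must be >= 0")
    if geom is None:
        geom = default_limited_angle_geometry(spec.size)
    u_gt = make_phantom(spec)
    b_clean = forward_project(u_gt, geom, backend)
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    f_true = ShiftSet(rng.normal(0.0, 1.0, size=(2, geom.n_angles)) * shift_sigma)
    b_shifted = warp_stack(b_clean, f_true) if shift_sigma > 0 else b_clean
    return b_shifted, f_true, u_gt
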