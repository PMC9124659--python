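"""Tilt-dependent projection mask and the closed-form per-angle shift update."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import TiltGeometry, TiltSeries, Volume, forward_project
from .warp import ShiftSet, central_gradient, warp_stack

__all__ = ["Mask", "MaskError", "build_mask", "shift_update"]

log = logging.getLogger(__name__)

_COND_LIMIT = 1e8


class MaskError(ValueError):
    """Raised when no valid mask band exists for a geometry."""


@dataclass
class Mask:
    """Binary per-pixel weights on projection space, shape ``(n_a, m, n)``."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.weights.shape}")
        vals = np.unique(self.weights)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("mask weights must be binary")


def build_mask(geom: TiltGeometry, margin_px: int = 2) -> Mask:
    """Mask excluding projection regions that are not reconstructed.

    Because tilting compresses the imaged structures perpendicular to the
    tilt axis, the usable detector band at tilt angle ``a`` is the centered
    column interval of half-width ``(n/2) * cos|a| - margin_px``; outside it
    the projection sees volume regions that fall off the reconstruction
    support.  Along the tilt axis a fixed ``margin_px`` border is zeroed.
    """
    if margin_px < 0:
        raise ValueError("margin_px must be non-negative")
    m, n = geom.det_shape
    weights = np.zeros(geom.series_shape())
    col_coord = np.abs(np.arange(n) - (n - 1) / 2.0)
    for i, a in enumerate(geom.angles_deg):
        half = (n / 2.0) * np.cos(np.deg2rad(abs(a))) - margin_px
        if half <= 0:
            raise MaskError(
                f"empty mask band at angle {a} deg (n={n}, margin={margin_px})"
            )
        band = col_coord <= half
        weights[i, :, band.nonzero()[0]] = 1.0
    if margin_px > 0:
        weights[:, :margin_px, :] = 0.0
        weights[:, m - margin_px:, :] = 0.0
    return Mask(weights)


def shift_update(
    u: Volume,
    b: TiltSeries,
    f_i: ShiftSet,
    mask: Mask,
    geom: TiltGeometry,
    backend=None,
    Au: TiltSeries | None = None,
) -> ShiftSet:
    """Closed-form re-computation of the per-angle shifts given ``u``.

    Minimizes, independently for every tilt angle, the masked quadratic
    mismatch between ``A u`` and the linearized warp of ``b`` around the
    current estimate ``f_i``; each angle reduces to a 2x2 normal-equation
    solve over its pixels (a Lucas-Kanade normal form).  With the package's
    shift convention the per-angle solution is

        ``f = H^-1 sum_px g M (b_f - A u + <g, f_i>)``,
        ``H = sum_px M g g^T``,

    where ``g`` is the central-difference gradient of the warped image
    ``b_f = W(b, f_i)``, recomputed from the warped stack at every call.

    If a normal matrix is singular or has condition number above 1e8 (no
    usable gradient inside the mask) the previous shift is kept for that
    angle and a warning is logged.

    ``Au`` may be supplied to reuse an already-computed forward projection.
    """
    if Au is None:
        Au = forward_project(u, geom, backend)
    b_f = warp_stack(b, f_i)
    grad = central_gradient(b_f)
    M = mask.weights
    g0, g1 = grad[0], grad[1]

    # 2x2 normal matrices and right-hand sides, all angles at once
    h00 = np.sum(M * g0 * g0, axis=(1, 2))
    h01 = np.sum(M * g0 * g1, axis=(1, 2))
    h11 = np.sum(M * g1 * g1, axis=(1, 2))
    resid = (
        b_f.images
        - Au.images
        + g0 * f_i.shifts[0][:, None, None]
        + g1 * f_i.shifts[1][:, None, None]
    )
    r0 = np.sum(M * g0 * resid, axis=(1, 2))
    r1 = np.sum(M * g1 * resid, axis=(1, 2))

    out = f_i.shifts.copy()
    for i in range(b.n_angles):
        H = np.array([[h00[i], h01[i]], [h01[i], h11[i]]])
        r = np.array([r0[i], r1[i]])
        evals, evecs = np.linalg.eigh(H)
        good = evals > evals.max() / _COND_LIMIT if evals.max() > 0 else evals > 0
        if not good.all():
            log.warning(
                "degenerate shift normal matrix at angle index %d "
                "(eigenvalues %s); updating usable directions only", i, evals,
            )
        if not good.any():
            continue  # no gradient information inside the mask: keep f_i
        # solve on the well-conditioned eigenspace, keep f_i on the rest
        V = evecs[:, good]
        out[:, i] = f_i.shifts[:, i] + V @ (
            (V.T @ (r - H @ f_i.shifts[:, i])) / evals[good]
        )
    return ShiftSet(out)
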