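"""Per-projection 2D translation, its linearization, and pre-alignment.

Shift convention
----------------
A shift vector is ``(f0, f1)`` where ``f0`` is the horizontal component
(along detector columns, perpendicular to the tilt axis) and ``f1`` is the
vertical component (along detector rows, the tilt axis).  A positive shift
moves image *content* toward increasing pixel index:

    ``W(b, f)(r, c) = b(r - f1, c - f0)``.

With this convention the first-order expansion of the warp around ``f_i``
carries a minus sign on the spatial gradient,

    ``W(b, f) ~= W(b, f_i) - <grad W(b, f_i), f - f_i>``,

which makes the expansion exact on linear (ramp) images; the ramp unit test
pins this sign down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .geometry import TiltSeries

__all__ = [
    "ShiftSet",
    "warp_stack",
    "central_gradient",
    "linearized_warp",
    "cosine_stretch",
    "prealign_crosscorr",
]

log = logging.getLogger(__name__)


@dataclass
class ShiftSet:
    """Per-angle 2D translation vectors, shape ``(2, n_angles)`` in pixels.

    Row 0 holds the horizontal components ``f0``, row 1 the vertical
    components ``f1``.
    """

    shifts: np.ndarray

    def __post_init__(self):
        self.shifts = np.atleast_2d(np.asarray(self.shifts, dtype=np.float64))
        if self.shifts.ndim != 2 or self.shifts.shape[0] != 2:
            raise ValueError(f"shifts must have shape (2, n_angles), got {self.shifts.shape}")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts contain non-finite values")

    @property
    def n_angles(self) -> int:
        return self.shifts.shape[1]

    @classmethod
    def zeros(cls, n_angles: int) -> "ShiftSet":
        return cls(np.zeros((2, n_angles)))

    def __neg__(self) -> "ShiftSet":
        return ShiftSet(-self.shifts)


def _check_match(b: TiltSeries, f: ShiftSet) -> None:
    if b.n_angles != f.n_angles:
        raise ValueError(
            f"tilt series has {b.n_angles} images but shift set has {f.n_angles}"
        )


def warp_stack(b: TiltSeries, f: ShiftSet) -> TiltSeries:
    """Translate each projection image by its shift vector.

    Bilinear (sub-pixel) interpolation; pixels pulled from outside the image
    support are filled by edge replication.
    """
    _check_match(b, f)
    out = np.empty_like(b.images)
    for i in range(b.n_angles):
        f0, f1 = f.shifts[:, i]
        if f0 == 0.0 and f1 == 0.0:
            out[i] = b.images[i]
        else:
            # ndimage.shift moves content by +shift along each axis: (rows, cols)
            out[i] = ndimage.shift(
                b.images[i], (f1, f0), order=1, mode="nearest", prefilter=False
            )
    return TiltSeries(out, b.angles_deg)


def central_gradient(b: TiltSeries) -> np.ndarray:
    """Spatial gradients of every projection image, shape ``(2, n_a, m, n)``.

    Component 0 is the horizontal derivative (along columns), component 1 the
    vertical derivative (along rows), matching the shift component order.
    Interior pixels use centered differences, boundaries one-sided ones.
    """
    g0 = np.gradient(b.images, axis=2)
    g1 = np.gradient(b.images, axis=1)
    return np.stack([g0, g1])


def linearized_warp(b: TiltSeries, f_i: ShiftSet, f: ShiftSet) -> TiltSeries:
    """First-order Taylor approximation of ``warp_stack(b, f)`` around ``f_i``."""
    _check_match(b, f_i)
    _check_match(b, f)
    b_f = warp_stack(b, f_i)
    grad = central_gradient(b_f)
    df = f.shifts - f_i.shifts
    out = (
        b_f.images
        - grad[0] * df[0][:, None, None]
        - grad[1] * df[1][:, None, None]
    )
    return TiltSeries(out, b.angles_deg)


def cosine_stretch(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Dilate an image by ``1 / cos(angle)`` along the column axis.

    Undoes the foreshortening of structures perpendicular to the tilt axis at
    tilt angle ``angle_deg``; the output lives on the same pixel grid.
    """
    if abs(angle_deg) >= 90.0:
        raise ValueError(f"cannot stretch at |angle| >= 90 degrees, got {angle_deg}")
    c = np.cos(np.deg2rad(angle_deg))
    if c == 1.0:
        return np.array(image, dtype=float, copy=True)
    image = np.asarray(image, dtype=float)
    m, n = image.shape
    center = (n - 1) / 2.0
    cols = center + (np.arange(n) - center) * c  # sample at compressed coords
    rows = np.arange(m)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(
        image, [rr, cc], order=1, mode="nearest", prefilter=False
    )


def _pair_offset(ref: np.ndarray, mov: np.ndarray, upsample_factor: int) -> np.ndarray:
    """Displacement (drow, dcol) of ``mov``'s content relative to ``ref``."""
    if ref.std() == 0.0 or mov.std() == 0.0:
        log.warning("flat projection image encountered during pre-alignment; "
                    "assuming zero offset for this pair")
        return np.zeros(2)
    # Hann window suppresses the wrap-around edge artefacts of the FFT
    # correlation; unnormalized correlation is robust for smooth images.
    win = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
    # phase_cross_correlation returns the shift that registers mov onto ref,
    # i.e. the negative of mov's content displacement.
    shift, _, _ = phase_cross_correlation(
        ref * win, mov * win, upsample_factor=upsample_factor, normalization=None
    )
    return -np.asarray(shift, dtype=float)


def prealign_crosscorr(b: TiltSeries, upsample_factor: int = 10) -> ShiftSet:
    """Coarse translational alignment by chained cross-correlation.

    Each image is cosine-stretched before correlation so successive tilts
    become comparable; pairwise sub-pixel offsets (upsampled phase
    correlation) are accumulated outward from the projection nearest 0
    degrees in both angular directions.

    Returns the estimated *displacement* of every image relative to the
    reference chain, in unstretched pixel coordinates — the same convention
    in which synthetic shifts are injected.  Applying ``warp_stack`` with the
    negated result registers the stack.
    """
    angles = np.asarray(b.angles_deg, dtype=float)
    i_ref = int(np.argmin(np.abs(angles)))
    stretched = [cosine_stretch(b.images[i], angles[i]) for i in range(b.n_angles)]
    cos = np.cos(np.deg2rad(angles))

    # cumulative content displacement in stretched (object) coordinates
    t = np.zeros((b.n_angles, 2))
    for i in range(i_ref + 1, b.n_angles):
        t[i] = t[i - 1] + _pair_offset(stretched[i - 1], stretched[i], upsample_factor)
    for i in range(i_ref - 1, -1, -1):
        t[i] = t[i + 1] + _pair_offset(stretched[i + 1], stretched[i], upsample_factor)

    shifts = np.zeros((2, b.n_angles))
    shifts[0] = t[:, 1] * cos  # horizontal: stretched -> pixel coordinates
    shifts[1] = t[:, 0]  # vertical: unaffected by stretching
    return ShiftSet(shifts)
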