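"""Parallel-beam, single-axis tilt geometry: forward projector A and adjoint A*.

Conventions (fixed once, used everywhere in the package):

* A volume has shape ``(z, m, n)``: ``z`` depth slices of ``m x n`` pixels.
* The tilt axis is the detector *row* axis (axis ``m``), i.e. rotation mixes
  the depth axis ``z`` with the in-plane column axis ``n``; detector rows map
  one-to-one onto volume rows for every tilt angle.
* At 0 degrees a projection is the plain sum of the volume along ``z``.
* Angles are in degrees, right-handed rotation in the (z, n) plane.
* Voxel and detector pixel sizes are equal and isotropic.

The default backend is a ray-driven (Joseph-style) projector realised as a
per-geometry sparse matrix so that the adjoint is the exact algebraic
transpose of the forward operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GeometryError",
    "TiltGeometry",
    "Volume",
    "TiltSeries",
    "ProjectorBackend",
    "SparseRayBackend",
    "get_backend",
    "register_backend",
    "forward_project",
    "back_project",
]


class GeometryError(ValueError):
    """Raised when volumes, tilt series and geometries are inconsistent."""


@dataclass(frozen=True)
class TiltGeometry:
    """Index sets of the projection operator.

    Parameters
    ----------
    angles_deg:
        Strictly increasing tilt angles in degrees, all within [-90, 90].
    vol_shape:
        ``(z, m, n)`` voxel counts of the reconstruction volume.
    det_shape:
        ``(m, n)`` detector pixel counts; must match the projection images
        of any tilt series used with this geometry.
    voxel_size:
        Isotropic voxel/pixel edge length in arbitrary units.
    """

    angles_deg: tuple
    vol_shape: Tuple[int, int, int]
    det_shape: Tuple[int, int]
    voxel_size: float = 1.0

    def __post_init__(self):
        angles = tuple(float(a) for a in np.atleast_1d(self.angles_deg))
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "vol_shape", tuple(int(s) for s in self.vol_shape))
        object.__setattr__(self, "det_shape", tuple(int(s) for s in self.det_shape))
        if len(self.vol_shape) != 3 or any(s < 1 for s in self.vol_shape):
            raise GeometryError(f"vol_shape must be 3 positive ints, got {self.vol_shape}")
        if len(self.det_shape) != 2 or any(s < 1 for s in self.det_shape):
            raise GeometryError(f"det_shape must be 2 positive ints, got {self.det_shape}")
        arr = np.asarray(angles, dtype=float)
        if arr.size == 0:
            raise GeometryError("at least one tilt angle is required")
        if np.any(np.diff(arr) <= 0):
            raise GeometryError("tilt angles must be strictly increasing")
        if np.any(np.abs(arr) > 90.0):
            raise GeometryError("tilt angles must lie within [-90, 90] degrees")
        if self.det_shape[0] != self.vol_shape[1]:
            raise GeometryError(
                "detector rows must match volume rows (single-axis tilt about "
                f"the row axis): det m={self.det_shape[0]}, vol m={self.vol_shape[1]}"
            )
        if self.voxel_size <= 0:
            raise GeometryError("voxel_size must be positive")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(np.asarray(self.angles_deg))

    def series_shape(self) -> Tuple[int, int, int]:
        return (self.n_angles, *self.det_shape)


def _check_finite(data: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{what} contains non-finite values")


@dataclass
class Volume:
    """Real-valued 3D reconstruction volume, shape ``(z, m, n)``."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"volume must be 3D, got shape {self.data.shape}")
        _check_finite(self.data, "volume")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class TiltSeries:
    """Stack of projection images with their tilt angles.

    ``images`` has shape ``(n_angles, m, n)``; ``angles_deg`` matches the
    first axis.
    """

    images: np.ndarray
    angles_deg: tuple

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.angles_deg = tuple(float(a) for a in np.atleast_1d(self.angles_deg))
        if self.images.ndim != 3:
            raise GeometryError(f"tilt series must be 3D, got {self.images.shape}")
        if self.images.shape[0] != len(self.angles_deg):
            raise GeometryError(
                f"{self.images.shape[0]} images but {len(self.angles_deg)} angles"
            )
        _check_finite(self.images, "tilt series")

    @property
    def n_angles(self) -> int:
        return self.images.shape[0]

    @property
    def det_shape(self) -> Tuple[int, int]:
        return self.images.shape[1:]


class ProjectorBackend:
    """Plug-in contract for projector implementations.

    Subclasses must implement :meth:`project` and :meth:`backproject`; the
    absolute row/column sum queries used for diagonal preconditioning default
    to applications of the operator to constant inputs, which is exact for
    backends with non-negative ray weights.
    """

    name = "abstract"

    def project(self, u: np.ndarray, geom: TiltGeometry) -> np.ndarray:
        raise NotImplementedError

    def backproject(self, stack: np.ndarray, geom: TiltGeometry) -> np.ndarray:
        raise NotImplementedError

    def row_abs_sums(self, geom: TiltGeometry, power: float = 1.0) -> np.ndarray:
        """Per-detector-pixel sums of |A_ij|^power, shape (n_angles, m, n)."""
        if power != 1.0:
            raise NotImplementedError(
                f"backend {self.name!r} only supports power=1 row sums"
            )
        return self.project(np.ones(geom.vol_shape), geom)

    def col_abs_sums(
        self, geom: TiltGeometry, weights: np.ndarray | None = None, power: float = 1.0
    ) -> np.ndarray:
        """Per-voxel sums of ``weights_i * |A_ij|^power``, shape (z, m, n).

        ``weights`` defaults to ones over projection space; passing a binary
        mask yields the masked column sums needed by the preconditioner.
        """
        if power != 1.0:
            raise NotImplementedError(
                f"backend {self.name!r} only supports power=1 column sums"
            )
        if weights is None:
            weights = np.ones(geom.series_shape())
        return self.backproject(weights, geom)


class SparseRayBackend(ProjectorBackend):
    """Ray-driven (Joseph-style) projector realised as a sparse matrix.

    For each tilt angle, a detector pixel's ray is traced through the (z, n)
    plane stepping along the major axis (depth for |angle| <= 45 deg, columns
    above) with linear interpolation along the minor axis and a path-length
    weight of 1/cos (resp. 1/|sin|); at 0 degrees this reduces exactly to a
    sum over depth.  The full operator factorises over detector rows, so one
    sparse matrix of shape ``(n_angles * n_det, z * n)`` applied to the
    row-major unfolding of the volume computes all projections at once, and
    the adjoint is the exact algebraic transpose.
    """

    name = "numpy"

    def __init__(self):
        self._cache: dict = {}

    # -- matrix construction -------------------------------------------------
    def _key(self, geom: TiltGeometry):
        z, _, n = geom.vol_shape
        return (geom.angles_deg, z, n, geom.det_shape[1])

    def matrix(self, geom: TiltGeometry) -> sp.csr_matrix:
        key = self._key(geom)
        mat = self._cache.get(key)
        if mat is None:
            mat = self._build(geom)
            self._cache[key] = mat
        return mat

    @staticmethod
    def _build(geom: TiltGeometry) -> sp.csr_matrix:
        z, _, n = geom.vol_shape
        n_det = geom.det_shape[1]
        zc, xc = (z - 1) / 2.0, (n - 1) / 2.0
        tc = (n_det - 1) / 2.0
        blocks = []
        for a in geom.angles_rad:
            ca, sa = np.cos(a), np.sin(a)
            t = np.arange(n_det) - tc  # centred detector coordinates
            if abs(sa) <= abs(ca):  # step along depth, interpolate columns
                steps = np.arange(z)
                # x solves t = x cos(a) + z sin(a) for each depth slice
                coord = (t[:, None] - (steps - zc)[None, :] * sa) / ca + xc
                weight = 1.0 / abs(ca)
                idx_of = lambda step, i0: step * n + i0  # noqa: E731
                minor_max = n
            else:  # step along columns, interpolate depth
                steps = np.arange(n)
                coord = (t[:, None] - (steps - xc)[None, :] * ca) / sa + zc
                weight = 1.0 / abs(sa)
                idx_of = lambda step, i0: i0 * n + step  # noqa: E731
                minor_max = z
            i0 = np.floor(coord).astype(np.int64)
            frac = coord - i0
            rows2 = np.broadcast_to(np.arange(n_det)[:, None], coord.shape)
            steps2 = np.broadcast_to(steps[None, :], coord.shape)
            rows_all, cols_all, wts_all = [], [], []
            for di, w in ((0, (1.0 - frac) * weight), (1, frac * weight)):
                ok = (i0 + di >= 0) & (i0 + di < minor_max) & (w > 0)
                rows_all.append(rows2[ok])
                cols_all.append(idx_of(steps2[ok], (i0 + di)[ok]))
                wts_all.append(w[ok])
            blocks.append(
                sp.coo_matrix(
                    (np.concatenate(wts_all),
                     (np.concatenate(rows_all), np.concatenate(cols_all))),
                    shape=(n_det, z * n),
                ).tocsr()
            )
        return sp.vstack(blocks, format="csr")

    # -- operator applications ----------------------------------------------
    def project(self, u: np.ndarray, geom: TiltGeometry) -> np.ndarray:
        z, m, n = geom.vol_shape
        n_det = geom.det_shape[1]
        u2 = np.ascontiguousarray(np.asarray(u).transpose(0, 2, 1)).reshape(z * n, m)
        proj = self.matrix(geom) @ u2  # (n_angles * n_det, m)
        return proj.reshape(geom.n_angles, n_det, m).transpose(0, 2, 1)

    def backproject(self, stack: np.ndarray, geom: TiltGeometry) -> np.ndarray:
        z, m, n = geom.vol_shape
        n_det = geom.det_shape[1]
        b2 = np.ascontiguousarray(np.asarray(stack).transpose(0, 2, 1)).reshape(
            geom.n_angles * n_det, m
        )
        vol = self.matrix(geom).T @ b2  # (z * n, m)
        return vol.reshape(z, n, m).transpose(0, 2, 1)

    def _powered(self, geom: TiltGeometry, power: float) -> sp.csr_matrix:
        mat = self.matrix(geom)
        if power == 1.0:
            return mat
        out = mat.copy()
        out.data = np.abs(out.data) ** power
        return out

    def row_abs_sums(self, geom: TiltGeometry, power: float = 1.0) -> np.ndarray:
        n_det = geom.det_shape[1]
        rs = np.asarray(self._powered(geom, power).sum(axis=1)).ravel()
        rs = rs.reshape(geom.n_angles, n_det)  # identical for every detector row
        return np.broadcast_to(rs[:, None, :], geom.series_shape()).copy()

    def col_abs_sums(
        self, geom: TiltGeometry, weights: np.ndarray | None = None, power: float = 1.0
    ) -> np.ndarray:
        z, m, n = geom.vol_shape
        n_det = geom.det_shape[1]
        if weights is None:
            weights = np.ones(geom.series_shape())
        w2 = np.ascontiguousarray(np.asarray(weights).transpose(0, 2, 1)).reshape(
            geom.n_angles * n_det, m
        )
        cs = self._powered(geom, power).T @ w2
        return cs.reshape(z, n, m).transpose(0, 2, 1)


_BACKENDS: Mapping[str, ProjectorBackend] = {}


def register_backend(name: str, backend: ProjectorBackend) -> None:
    """Register a projector backend under ``name`` (overwrites silently)."""
    _BACKENDS[name] = backend  # type: ignore[index]


def get_backend(backend: "str | ProjectorBackend | None") -> ProjectorBackend:
    if backend is None:
        backend = "numpy"
    if isinstance(backend, ProjectorBackend):
        return backend
    try:
        return _BACKENDS[backend]
    except KeyError:
        raise ValueError(
            f"unknown projector backend {backend!r}; registered: {sorted(_BACKENDS)}"
        ) from None


register_backend("numpy", SparseRayBackend())


def _check_vol(u: Volume, geom: TiltGeometry) -> None:
    if u.shape != geom.vol_shape:
        raise GeometryError(f"volume shape {u.shape} != geometry {geom.vol_shape}")


def _check_series(b: TiltSeries, geom: TiltGeometry) -> None:
    if b.images.shape != geom.series_shape():
        raise GeometryError(
            f"tilt series shape {b.images.shape} != geometry {geom.series_shape()}"
        )


def forward_project(
    u: Volume, geom: TiltGeometry, backend: "str | ProjectorBackend | None" = None
) -> TiltSeries:
    """Apply the forward operator A: volume -> tilt series."""
    _check_vol(u, geom)
    stack = get_backend(backend).project(u.data, geom)
    return TiltSeries(stack, geom.angles_deg)


def back_project(
    b: TiltSeries, geom: TiltGeometry, backend: "str | ProjectorBackend | None" = None
) -> Volume:
    """Apply the adjoint operator A*: tilt series -> volume."""
    _check_series(b, geom)
    return Volume(get_backend(backend).backproject(b.images, geom))
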