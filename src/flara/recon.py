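"""Masked TV-regularized reconstruction sub-problem.

Solves

    min_u  1/2 || M (A u - b_f) ||^2  +  lambda ||grad u||_{2,1}

as a saddle-point problem over the primal volume ``u`` and two dual
variables: ``p`` (TV dual, one 3-vector per voxel, constrained to the
pointwise ball ||p_v||_2 <= lambda) and ``q`` (data dual, one scalar per
projection pixel).  One iteration of a diagonally preconditioned primal-dual
scheme performs a proximal ascent in (q, p) followed by a descent in ``u``
and an extrapolation step.

The linear term ``<M(A u - b_f), q>`` is handled by ascending on the masked
residual: the exact prox of the tilted conjugate ``1/2||q||^2 + <q, M b_f>``
at ``q + sigma * M A u_bar`` equals ``(q + sigma * M (A u_bar - b_f)) / (1 +
sigma)``, which is the update implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .align import Mask
from .geometry import TiltGeometry, TiltSeries, Volume, get_backend

__all__ = [
    "PDState",
    "ReconConfig",
    "grad3d",
    "div3d",
    "prox_data_dual",
    "proj_l2inf_ball",
    "init_preconditioners",
    "pd_iteration",
    "primal_energy",
    "total_variation",
]

log = logging.getLogger(__name__)

_SUM_FLOOR = 1e-6


@dataclass
class ReconConfig:
    """Parameters of the reconstruction / joint loop.

    ``lam`` weighs the TV regularizer against the data fidelity; ``n_iter``
    is the number of outer iterations; ``precond_alpha`` the diagonal
    preconditioning exponent.
    """

    lam: float = 0.1
    n_iter: int = 2000
    precond_alpha: float = 1.0
    margin_px: int = 2
    backend: str = "numpy"
    seed: int = 0
    theta: float = 1.0
    nonneg: bool = False
    early_stop_tol: float | None = None

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0.0 <= self.precond_alpha <= 2.0:
            raise ValueError("precond_alpha must lie in [0, 2]")


@dataclass
class PDState:
    """Primal-dual iterate: primal ``u``, extrapolation ``u_bar``, duals
    ``p`` (3, z, m, n) and ``q`` (n_a, m, n), plus per-element step sizes."""

    u: np.ndarray
    u_bar: np.ndarray
    p: np.ndarray
    q: np.ndarray
    tau: np.ndarray
    sigma_p: np.ndarray
    sigma_q: np.ndarray
    theta: float = 1.0

    @classmethod
    def initialize(
        cls, geom: TiltGeometry, mask: Mask, cfg: ReconConfig
    ) -> "PDState":
        """Zero-initialized state with preconditioned step sizes."""
        tau, sigma_p, sigma_q = init_preconditioners(
            geom, mask, cfg.precond_alpha, cfg.backend
        )
        z, m, n = geom.vol_shape
        return cls(
            u=np.zeros((z, m, n)),
            u_bar=np.zeros((z, m, n)),
            p=np.zeros((3, z, m, n)),
            q=np.zeros(geom.series_shape()),
            tau=tau,
            sigma_p=sigma_p,
            sigma_q=sigma_q,
            theta=cfg.theta,
        )


def grad3d(u: np.ndarray) -> np.ndarray:
    """Forward-difference 3D gradient, shape (3, z, m, n).

    Component ordering is (d/dz, d/drow, d/dcol); the far edge along each
    axis uses a zero (Neumann) difference.
    """
    u = np.asarray(u)
    g = np.zeros((3, *u.shape))
    g[0, :-1] = u[1:] - u[:-1]
    g[1, :, :-1] = u[:, 1:] - u[:, :-1]
    g[2, :, :, :-1] = u[:, :, 1:] - u[:, :, :-1]
    return g


def div3d(p: np.ndarray) -> np.ndarray:
    """Discrete divergence, the negative adjoint of :func:`grad3d`.

    Satisfies ``<grad3d(u), p> == <u, -div3d(p)>`` exactly.
    """
    p = np.asarray(p)
    out = np.zeros(p.shape[1:])
    out[0] += p[0, 0]
    out[1:-1] += p[0, 1:-1] - p[0, :-2]
    out[-1] += -p[0, -2]
    out[:, 0] += p[1, :, 0]
    out[:, 1:-1] += p[1, :, 1:-1] - p[1, :, :-2]
    out[:, -1] += -p[1, :, -2]
    out[:, :, 0] += p[2, :, :, 0]
    out[:, :, 1:-1] += p[2, :, :, 1:-1] - p[2, :, :, :-2]
    out[:, :, -1] += -p[2, :, :, -2]
    return out


def prox_data_dual(q_tilde: np.ndarray, sigma_q) -> np.ndarray:
    """Prox of ``sigma * (1/2 ||.||^2)`` in the dual: ``q / (1 + sigma)``."""
    return q_tilde / (1.0 + sigma_q)


def proj_l2inf_ball(p_tilde: np.ndarray, lam: float) -> np.ndarray:
    """Project each voxel's 3-vector onto the L2 ball of radius ``lam``."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    norms = np.sqrt(np.sum(p_tilde * p_tilde, axis=0))
    return p_tilde / np.maximum(1.0, norms / lam)


def _grad_col_counts(shape) -> np.ndarray:
    """Per-voxel count of finite-difference stencil entries touching it."""
    counts = np.zeros(shape)
    for ax, size in enumerate(shape):
        contrib = np.ones(size)
        contrib[-1] = 0.0  # no own forward difference at the far edge
        contrib[1:] += 1.0  # neighbour's difference reaches in
        sl = [None] * 3
        sl[ax] = slice(None)
        counts += contrib[tuple(sl)]
    return counts


def init_preconditioners(
    geom: TiltGeometry, mask: Mask, alpha: float = 1.0, backend=None
):
    """Diagonal step sizes for the stacked operator ``K = [M A; grad]``.

    Dual steps are reciprocals of row sums of ``|K_ij|^(2 - alpha)``, primal
    steps reciprocals of column sums of ``|K_ij|^alpha``; this guarantees the
    preconditioned primal-dual convergence condition for any ``alpha`` in
    [0, 2].  Rows of ``A`` zeroed by the mask fall back to the unmasked row
    sum (their dual never moves, but the step stays finite); residual zero
    sums are floored at 1e-6.
    """
    if not 0.0 <= alpha <= 2.0:
        raise ValueError("alpha must lie in [0, 2]")
    be = get_backend(backend)
    M = mask.weights

    row_a = be.row_abs_sums(geom, power=2.0 - alpha)
    row_masked = np.where(M > 0, row_a * M, row_a)
    n_floor = int(np.sum(row_masked <= 0))
    if n_floor:
        log.info("flooring %d zero projector row sums", n_floor)
    sigma_q = 1.0 / np.maximum(row_masked, _SUM_FLOOR)

    col_a = be.col_abs_sums(geom, weights=M, power=alpha)
    grad_counts = _grad_col_counts(geom.vol_shape)
    tau = 1.0 / np.maximum(col_a + grad_counts, _SUM_FLOOR)

    # each gradient row has two unit entries except at the far edge (empty row)
    sigma_p = np.empty((3, *geom.vol_shape))
    for ax in range(3):
        rs = np.full(geom.vol_shape, 2.0)
        sl = [slice(None)] * 3
        sl[ax] = -1
        rs[tuple(sl)] = _SUM_FLOOR
        sigma_p[ax] = 1.0 / rs
    return tau, sigma_p, sigma_q


def pd_iteration(
    state: PDState,
    b_f: TiltSeries,
    mask: Mask,
    geom: TiltGeometry,
    cfg: ReconConfig,
) -> PDState:
    """One preconditioned primal-dual iteration on the saddle problem.

    Dual ascent with proximal/projection steps, primal descent, then
    extrapolation with ``theta``; ``u`` is unconstrained unless
    ``cfg.nonneg`` is set.  Raises ``FloatingPointError`` on non-finite
    iterates.
    """
    be = get_backend(cfg.backend)
    M = mask.weights

    Au_bar = be.project(state.u_bar, geom)
    q = prox_data_dual(state.q + state.sigma_q * M * (Au_bar - b_f.images), state.sigma_q)
    p = proj_l2inf_ball(state.p + state.sigma_p * grad3d(state.u_bar), cfg.lam)

    descent = be.backproject(M * q, geom) - div3d(p)
    u_new = state.u - state.tau * descent
    if cfg.nonneg:
        np.maximum(u_new, 0.0, out=u_new)
    if not np.all(np.isfinite(u_new)):
        raise FloatingPointError(
            "primal iterate diverged (non-finite values); check step sizes"
        )
    u_bar = u_new + state.theta * (u_new - state.u)
    return replace(state, u=u_new, u_bar=u_bar, p=p, q=q)


def total_variation(u: np.ndarray) -> float:
    """Isotropic TV: sum of pointwise gradient-vector magnitudes."""
    g = grad3d(u)
    return float(np.sum(np.sqrt(np.sum(g * g, axis=0))))


def primal_energy(
    u: np.ndarray,
    b_f: TiltSeries,
    mask: Mask,
    geom: TiltGeometry,
    lam: float,
    backend=None,
    Au: np.ndarray | None = None,
) -> float:
    """Primal objective: masked data fidelity plus weighted TV."""
    if Au is None:
        Au = get_backend(backend).project(u, geom)
    resid = mask.weights * (Au - b_f.images)
    return 0.5 * float(np.sum(resid * resid)) + lam * total_variation(u)
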