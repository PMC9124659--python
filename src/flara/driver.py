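"""Joint alignment-reconstruction loop.

Each outer iteration interleaves exactly one preconditioned primal-dual
reconstruction step with one closed-form shift re-computation: the observed
projections are first translated by the current correction, one primal-dual
iteration updates the volume and both duals against the translated stack,
and the shifts are then re-computed in closed form from the new volume —
never refined by gradient steps on a stale estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import Mask, build_mask, shift_update
from .geometry import TiltGeometry, TiltSeries, Volume, get_backend
from .metrics import psnr
from .recon import PDState, ReconConfig, pd_iteration, primal_energy
from .warp import ShiftSet, prealign_crosscorr, warp_stack

__all__ = ["History", "flara"]

log = logging.getLogger(__name__)


@dataclass
class History:
    """Per-iteration diagnostics of a joint run."""

    energy: list = field(default_factory=list)
    shifts: list = field(default_factory=list)  # estimated displacements (2, n_a)
    shift_delta: list = field(default_factory=list)  # max |f^{i+1} - f^i|
    psnr: list = field(default_factory=list)  # only when ground truth given

    def as_dict(self) -> dict:
        return {
            "energy": [float(e) for e in self.energy],
            "shifts": [s.tolist() for s in self.shifts],
            "shift_delta": [float(d) for d in self.shift_delta],
            "psnr": [float(v) for v in self.psnr],
        }


def default_geometry(b: TiltSeries) -> TiltGeometry:
    """Cube-in-depth geometry matching a tilt series: vol (n, m, n)."""
    m, n = b.det_shape
    return TiltGeometry(b.angles_deg, (n, m, n), (m, n))


def flara(
    b: TiltSeries,
    cfg: ReconConfig,
    geom: TiltGeometry | None = None,
    u_gt: Volume | None = None,
    f0: ShiftSet | None = None,
    freeze_shifts: bool = False,
    prealign: bool = True,
    energy_every: int = 10,
):
    """Run the joint loop; returns ``(Volume, ShiftSet, History)``.

    The returned ``ShiftSet`` holds the estimated per-image *displacements*
    (same convention as shifts injected on synthetic data); internally the
    loop maintains their negation, the correction applied to the observed
    stack before every reconstruction step.

    Parameters
    ----------
    b:
        Observed (mis-aligned) tilt series.
    cfg:
        Reconstruction configuration; ``cfg.n_iter`` outer iterations.
    geom:
        Geometry; defaults to a cubic volume matching the detector.
    u_gt:
        Optional ground-truth volume; enables a PSNR trace in the history.
    f0:
        Optional initial displacement estimate, overriding pre-alignment.
    freeze_shifts:
        If true, skip the shift re-computation (pure reconstruction with the
        initial alignment held fixed).
    prealign:
        Run cross-correlation pre-alignment for the initial estimate; if
        false (and no ``f0``), start from zero shifts.
    """
    if geom is None:
        geom = default_geometry(b)
    backend = get_backend(cfg.backend)
    mask = build_mask(geom, cfg.margin_px)

    if f0 is not None:
        f_disp = ShiftSet(f0.shifts.copy())
    elif prealign:
        f_disp = prealign_crosscorr(b)
        log.info("pre-alignment: max |f0| = %.3f px", np.abs(f_disp.shifts).max())
    else:
        f_disp = ShiftSet.zeros(b.n_angles)
    f_corr = -f_disp  # correction applied to the observed stack

    state = PDState.initialize(geom, mask, cfg)
    history = History()
    history.shifts.append(-f_corr.shifts.copy())

    for it in range(1, cfg.n_iter + 1):
        b_f = warp_stack(b, f_corr)
        state = pd_iteration(state, b_f, mask, geom, cfg)
        Au = TiltSeries(backend.project(state.u, geom), geom.angles_deg)

        if not freeze_shifts:
            f_new = shift_update(
                Volume(state.u), b, f_corr, mask, geom, backend=cfg.backend, Au=Au
            )
            delta = float(np.abs(f_new.shifts - f_corr.shifts).max())
            f_corr = f_new
        else:
            delta = 0.0
        history.shift_delta.append(delta)
        history.shifts.append(-f_corr.shifts.copy())

        if it % energy_every == 0 or it == cfg.n_iter:
            e = primal_energy(
                state.u, b_f, mask, geom, cfg.lam, backend=cfg.backend, Au=Au.images
            )
            if not np.isfinite(e):
                log.error("energy diverged at iteration %d; aborting", it)
                break
            history.energy.append(e)
            if u_gt is not None:
                history.psnr.append(psnr(Volume(state.u), u_gt))
            log.info(
                "iter %d: energy %.6g, max shift delta %.4g px", it, e, delta
            )

        if (
            cfg.early_stop_tol is not None
            and not freeze_shifts
            and delta < cfg.early_stop_tol
            and it > 1
        ):
            log.info("shift trace stabilized at iteration %d; stopping early", it)
            break

    return Volume(state.u), ShiftSet(-f_corr.shifts), history
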