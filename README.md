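# flara

Fiducial-less joint alignment and reconstruction for limited-angle electron
tomography.

Tilt series acquired by single-axis tilting (typically ±60°) suffer from
per-image translational misalignment caused by stage instabilities.  Instead
of aligning on gold fiducial markers before reconstructing, `flara` solves a
joint problem: a masked, TV-regularized least-squares reconstruction

```
min_{u, f}  1/2 || M (A u − W(b, f)) ||²  +  λ ||∇u||_{2,1}
```

where `A` is the parallel-beam projector, `W(b, f)` translates each
projection image by its 2D shift vector `f`, and `M` masks projection
regions that are not reconstructed at the given tilt angle.  The warp is
linearized to first order, which turns the shift sub-problem into one 2×2
linear solve per tilt angle; the reconstruction sub-problem is solved as a
saddle-point problem with a diagonally preconditioned primal-dual scheme.
The outer loop interleaves **exactly one** primal-dual iteration with one
closed-form shift re-computation, starting from a cosine-stretched
cross-correlation pre-alignment.

## Layout

| module | contents |
|---|---|
| `flara.geometry` | tilt geometry, `Volume`/`TiltSeries` types, pluggable projector backends (default: sparse ray-driven operator with an exact-transpose adjoint) |
| `flara.warp` | sub-pixel warping `W`, central-difference gradients, first-order linearized warp, cosine stretching, cross-correlation pre-alignment |
| `flara.align` | tilt-dependent projection mask `M`, closed-form per-angle shift update |
| `flara.recon` | 3D TV operators, proximal maps, diagonal preconditioning, the primal-dual iteration, energies |
| `flara.driver` | the joint loop (`flara.flara`), run history |
| `flara.phantom` | geometric-shape phantom, limited-angle dataset simulation with injected standard-normal shifts |
| `flara.metrics` | PSNR (plain and translation-gauge-registered), per-component shift error statistics with gauge handling |
| `flara.io` / `flara.cli` | MRC / TIFF / `.tlt` / shifts-TSV readers and writers, `flara` command line |

## Command line

```sh
# synthetic dataset: phantom volume, shifted tilt series, angles, true shifts
flara simulate --size 64 --n-shapes 12 --shift-sigma 1.0 --seed 0 --out-dir sim/

# joint alignment + reconstruction
flara reconstruct --tilt-series sim/tilt_series.mrc --angles sim/angles.tlt \
    --lambda 0.1 --iters 1000 --out-dir rec/

# score against ground truth
flara evaluate --recon rec/reconstruction.mrc --truth-volume sim/volume.mrc \
    --est-shifts rec/shifts.tsv --true-shifts sim/true_shifts.tsv \
    --gauge projective --out metrics.json
```

`flara reconstruct` also accepts a YAML config (`--config`) mirroring every
flag; explicit CLI flags win.  Real data: an MRC stack (or multi-page TIFF)
plus a `.tlt`/`.rawtlt` file with one tilt angle in degrees per line.

### Conventions

* Volumes are `(z, m, n)`; the tilt axis is the detector row axis; the 0°
  projection is the sum along `z`.
* A shift `(f0, f1)` moves image content by `f0` pixels along columns
  (horizontal, perpendicular to the tilt axis) and `f1` along rows.
  `flara.flara` and `prealign_crosscorr` return estimated *displacements*,
  directly comparable to shifts injected by the simulator.
* Absolute object position is unrecoverable (gauge freedom): an in-plane
  volume translation `(dx, dz)` changes the apparent horizontal shifts by
  `dx·cosα + dz·sinα` and the vertical ones by a constant.  Use
  `gauge="projective"` in `shift_error_stats` to remove exactly this
  subspace, and `metrics.registered_psnr` to compare volumes up to a global
  translation.

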