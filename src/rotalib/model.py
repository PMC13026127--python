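"""Dirichlet-smoothed rotamer probability model over a context grid.

The model estimates P(r | x) for rotamer r of one amino acid at context bin
x = (phi-bin, psi-bin, ...).  Pipeline:

1. accumulate raw counts C_r(x): each training residue is assigned to its
   nearest rotamer (minimal canonical-frame RMSD to the cluster centroids)
   and to its context bin;
2. smooth each rotamer's count field with a separable circular Gaussian
   kernel, C~_r(x) = sum_y prod_i K_i(y_i - x_i) C_r(y), wrapping periodic
   axes across the -180/+180 seam and renormalizing truncated kernels at
   categorical-axis boundaries;
3. form the Dirichlet posterior
   P(r|x) = (C~_r(x) + alpha * pi_r) / (sum_r' C~_r'(x) + alpha),
   which is strictly positive everywhere for alpha > 0 and reduces to the
   empirical frequency table as alpha -> 0 with no smoothing;
4. predict by maximum posterior at the residue's bin, emitting the winning
   rotamer's canonical chi vector.

Defaults (alpha = 40, kernel radius 1 bin, sigma 1 bin, uniform prior) give
modest regularization without blurring distinct conformational basins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve1d

from .clustering import RotamerSet
from .context import ContextGrid, encode_context
from .geometry import ChiSet, reconstruct_sidechain

__all__ = [
    "SmoothingKernel",
    "CountModel",
    "PredictionResult",
    "gaussian_kernel_1d",
    "accumulate_counts",
    "smooth_counts",
    "apply_fill_missing_only",
    "dirichlet_posterior",
    "build_model",
    "predict",
    "predict_batch",
    "assign_rotamer",
]

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 40.0
DEFAULT_RADIUS = 1
DEFAULT_SIGMA = 1.0


class ModelError(ValueError):
    pass


def gaussian_kernel_1d(radius: int, sigma: float) -> np.ndarray:
    """Normalized Gaussian weights w_j ~ exp(-j^2 / 2 sigma^2), j in [-R, R]."""
    if radius < 0:
        raise ModelError("radius must be >= 0")
    if sigma <= 0:
        raise ModelError("sigma must be > 0")
    j = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-j * j / (2.0 * sigma * sigma))
    return w / w.sum()


@dataclass(frozen=True)
class SmoothingKernel:
    """Per-axis separable smoothing parameters matched to a grid."""

    radii: tuple[int, ...]
    sigmas: tuple[float, ...]
    periodic: tuple[bool, ...]

    def __post_init__(self):
        if not (len(self.radii) == len(self.sigmas) == len(self.periodic)):
            raise ModelError("kernel axis lists must share one length")
        for r, s in zip(self.radii, self.sigmas):
            gaussian_kernel_1d(r, s)  # validates

    @classmethod
    def for_grid(cls, grid: ContextGrid,
                 radius: int | Sequence[int] = DEFAULT_RADIUS,
                 sigma: float | Sequence[float] = DEFAULT_SIGMA) -> "SmoothingKernel":
        d = grid.ndim
        radii = tuple([radius] * d) if np.isscalar(radius) else tuple(radius)
        sigmas = tuple([sigma] * d) if np.isscalar(sigma) else tuple(sigma)
        return cls(radii, sigmas, tuple(ax.periodic for ax in grid.axes))

    def weights(self, axis: int) -> np.ndarray:
        return gaussian_kernel_1d(self.radii[axis], self.sigmas[axis])


@dataclass(frozen=True)
class PredictionResult:
    aa_type: str
    x: tuple[int, ...]
    rotamer_id: int | None
    canonical_chi: ChiSet | None
    posterior_prob: float | None
    status: str  # "predicted" | "out_of_grid"


@dataclass
class CountModel:
    """Per-amino-acid raw/smoothed/posterior tensors over (rotamer, bins)."""

    aa_type: str
    grid: ContextGrid
    rotamers: RotamerSet
    raw_counts: np.ndarray
    smoothed_counts: np.ndarray
    alpha: float
    prior: np.ndarray
    posterior: np.ndarray
    kernel: SmoothingKernel | None = None
    fill_missing_only: bool = False

    @property
    def n_rotamers(self) -> int:
        return self.raw_counts.shape[0]

    def argmax_table(self) -> np.ndarray:
        """Per-bin winning rotamer id (first index wins ties = largest cluster)."""
        return np.argmax(self.posterior, axis=0)


def assign_rotamer(chi: Sequence[float], rotamers: RotamerSet) -> int:
    """Nearest rotamer by canonical-frame RMSD of the reconstructed sidechain."""
    conf = reconstruct_sidechain(rotamers.aa_type, chi)
    cen = rotamers.centroid_coords  # (k, n_atoms, 3)
    d = cen - conf.coords[None, :, :]
    rmsd = np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))
    return int(np.argmin(rmsd))


def accumulate_counts(train: Sequence, grid: ContextGrid,
                      rotamers: RotamerSet) -> np.ndarray:
    """Raw count tensor C_r(x) of shape (n_rotamers, *grid.shape)."""
    counts = np.zeros((len(rotamers),) + grid.shape, dtype=float)
    for res in train:
        if res.aa_type != rotamers.aa_type:
            raise ModelError(
                f"residue {res.aa_type} in {rotamers.aa_type} model")
        r = assign_rotamer(res.chi, rotamers)
        x = encode_context(res, grid)
        counts[(r,) + x] += 1
    return counts


def smooth_counts(raw: np.ndarray, kernel: SmoothingKernel,
                  grid: ContextGrid) -> np.ndarray:
    """Separable convolution along every grid axis of the count tensor.

    Periodic axes wrap; categorical axes use a truncated kernel renormalized
    at the boundary so each output bin's effective weights still sum to one.
    Total per-rotamer mass is conserved exactly on fully periodic grids.
    """
    if len(kernel.radii) != grid.ndim:
        raise ModelError("kernel dimensionality does not match grid")
    out = np.asarray(raw, dtype=float)
    if out.shape[1:] != grid.shape:
        raise ModelError("tensor shape does not match grid")
    for ax in range(grid.ndim):
        if kernel.radii[ax] == 0:
            continue
        w = kernel.weights(ax)
        taxis = ax + 1  # axis 0 is the rotamer index
        if kernel.periodic[ax]:
            out = convolve1d(out, w, axis=taxis, mode="wrap")
        else:
            num = convolve1d(out, w, axis=taxis, mode="constant", cval=0.0)
            ones = np.ones(out.shape[taxis])
            den = convolve1d(ones, w, mode="constant", cval=0.0)
            shape = [1] * out.ndim
            shape[taxis] = -1
            out = num / den.reshape(shape)
    return out


def apply_fill_missing_only(raw: np.ndarray,
                            smoothed: np.ndarray) -> np.ndarray:
    """Keep raw counts in occupied bins; use smoothed counts only where empty."""
    if raw.shape != smoothed.shape:
        raise ModelError("raw and smoothed tensors must share a shape")
    occupied = raw.sum(axis=0) > 0
    return np.where(occupied[None, ...], raw, smoothed)


def dirichlet_posterior(counts: np.ndarray, alpha: float,
                        prior: np.ndarray) -> np.ndarray:
    """P(r|x) = (c_r(x) + alpha pi_r) / (sum_r' c_r'(x) + alpha)."""
    if alpha < 0:
        raise ModelError("alpha must be >= 0")
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (counts.shape[0],):
        raise ModelError("prior length must equal the number of rotamers")
    if abs(prior.sum() - 1.0) > 1e-9:
        raise ModelError("prior must sum to 1")
    total = counts.sum(axis=0)
    if alpha == 0 and np.any(total <= 0):
        raise ModelError("alpha = 0 requires every bin to hold counts")
    shape = (-1,) + (1,) * (counts.ndim - 1)
    return (counts + alpha * prior.reshape(shape)) / (total + alpha)


def build_model(train: Sequence, grid: ContextGrid, rotamers: RotamerSet,
                kernel: SmoothingKernel | None = None,
                alpha: float = DEFAULT_ALPHA,
                prior: np.ndarray | None = None,
                fill_missing_only: bool = False,
                raw_counts: np.ndarray | None = None) -> CountModel:
    """Accumulate, smooth, optionally hybridize, and normalize.

    ``raw_counts`` may be supplied to rebuild with new hyperparameters
    without re-scanning the training residues.
    """
    if kernel is None:
        kernel = SmoothingKernel.for_grid(grid)
    if prior is None:
        prior = np.full(len(rotamers), 1.0 / len(rotamers))
    if raw_counts is None:
        raw_counts = accumulate_counts(train, grid, rotamers)
    smoothed = smooth_counts(raw_counts, kernel, grid)
    effective = (apply_fill_missing_only(raw_counts, smoothed)
                 if fill_missing_only else smoothed)
    posterior = dirichlet_posterior(effective, alpha, np.asarray(prior, float))
    return CountModel(
        aa_type=rotamers.aa_type,
        grid=grid,
        rotamers=rotamers,
        raw_counts=raw_counts,
        smoothed_counts=smoothed,
        alpha=float(alpha),
        prior=np.asarray(prior, dtype=float),
        posterior=posterior,
        kernel=kernel,
        fill_missing_only=fill_missing_only,
    )


def predict(model: CountModel, x: Sequence[int]) -> PredictionResult:
    """Maximum-posterior rotamer at bin x, or out_of_grid off the support."""
    x = tuple(int(v) for v in x)
    model.grid._check(x)
    if not model.grid.contains(x):
        return PredictionResult(model.aa_type, x, None, None, None,
                                "out_of_grid")
    p = model.posterior[(slice(None),) + x]
    rid = int(np.argmax(p))  # ties -> lowest id = largest training cluster
    return PredictionResult(model.aa_type, x, rid,
                            model.rotamers.clusters[rid].canonical_chi,
                            float(p[rid]), "predicted")


def predict_batch(model: CountModel,
                  xs: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized prediction for many bin vectors.

    Returns (rotamer_ids, in_grid_mask); ids are -1 off the global grid.
    """
    xs = np.asarray(xs, dtype=int)
    if xs.ndim != 2 or xs.shape[1] != model.grid.ndim:
        raise ModelError("xs must be (n, d) bin vectors")
    table = model.argmax_table()
    ids = table[tuple(xs[:, i] for i in range(xs.shape[1]))]
    if model.grid.global_bins is None:
        mask = np.ones(len(xs), dtype=bool)
    else:
        gb = model.grid.global_bins
        mask = np.fromiter((tuple(row) in gb for row in xs), bool, len(xs))
    ids = np.where(mask, ids, -1)
    return ids, mask
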