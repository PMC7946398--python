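"""Regularization-strength selection policies.

Two policies are implemented:

* ``adaptive_noise`` -- per dose level, pick the candidate lambda whose
  single-slice reconstruction has noise SD closest to a target (default
  7.4 HU, the low-noise-protocol FBP level).  Regularization then grows as
  dose falls and the noise magnitude stays roughly constant.
* ``fixed`` -- one weak/medium/strong triple shared by all dose levels.
  The medium strength is the lambda whose reconstruction MTF (from the
  air-gap LSF) is closest, in least squares up to the FBP 10%-modulation
  frequency, to the FBP MTF at the reference dose; weak and strong sit at
  roughly medium/3 and 4 x medium on the candidate grid.

Candidate grids are log-spaced; the absolute scale is system dependent, so
the grid is anchored by a gradient-balance heuristic at the reference dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cacstudy import iq_metrics, recon_ir
from cacstudy.fanbeam_sim import FanBeamGeometry, Sinogram
from cacstudy.phantom_forge import GapSpec, GridSpec, MaterialModel


@dataclass
class LambdaPolicy:
    mode: str  # "adaptive_noise" or "fixed"
    target_noise: float = 7.4
    fixed_levels: dict = field(default_factory=dict)  # {"weak": l, "medium": l, "strong": l}
    lambda_grid: np.ndarray | None = None
    per_frames_lambda: dict = field(default_factory=dict)  # n_frames -> lambda

    def __post_init__(self) -> None:
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if np.any(g <= 0) or np.any(np.diff(g) <= 0):
                raise ValueError("lambda grid must be positive and strictly increasing")
        if self.fixed_levels:
            w, m, s = (self.fixed_levels[k] for k in ("weak", "medium", "strong"))
            if not w < m < s:
                raise ValueError("fixed levels must satisfy weak < medium < strong")


def lambda_grid_for(
    sinogram: Sinogram,
    geometry: FanBeamGeometry,
    grid: GridSpec,
    materials: MaterialModel,
    regularizer: str,
    n_candidates: int = 12,
    decades: float = 3.0,
) -> np.ndarray:
    """Log-spaced candidate grid anchored by a gradient-balance heuristic.

    The anchor equates the norms of the fidelity gradient *at the FBP
    solution* (where residuals sit at the noise scale) and of the
    regularizer gradient of that image; a lambda of this order trades the
    two terms against each other.  Balancing at u = 0 instead would compare
    against the full signal and overshoot by orders of magnitude.  The grid
    brackets the anchor by ``decades/2`` in both directions.
    """
    from cacstudy.recon_fbp import FbpKernel, fbp

    u_ref = fbp(sinogram, FbpKernel(), grid, materials, output="mu").image
    cfg = recon_ir.IrConfig(regularizer=regularizer, lam=0.0)
    grad_fid = recon_ir.gradient(u_ref, sinogram, geometry, grid, cfg)
    grad_reg = recon_ir.regularizer_gradient(u_ref, recon_ir.IrConfig(regularizer=regularizer, lam=1.0))
    anchor = np.linalg.norm(grad_fid) / max(np.linalg.norm(grad_reg), 1e-300)
    return anchor * np.logspace(-decades / 2.0, decades / 2.0, n_candidates)


@dataclass
class SelectionResult:
    lam: float
    noise_sd: dict  # lambda -> measured noise SD (HU)
    warning: str | None = None


def batch_reconstruct(sinogram, geometry, grid, materials, regularizer, lambdas, n_iterations):
    """One reconstruction per candidate lambda, solved as a single batch."""
    cfg = recon_ir.IrConfig(regularizer=regularizer, lam=0.0, n_iterations=n_iterations)
    recs, _ = recon_ir.solve_batch(
        [sinogram] * len(lambdas), geometry, grid, materials, list(lambdas), cfg
    )
    return [r.image for r in recs]


def adaptive_lambda(
    sinogram: Sinogram,
    geometry: FanBeamGeometry,
    grid: GridSpec,
    materials: MaterialModel,
    regularizer: str,
    lambda_grid: np.ndarray,
    target_noise: float,
    noise_roi: np.ndarray,
    n_iterations: int = 500,
    images: list[np.ndarray] | None = None,
) -> SelectionResult:
    """Pick the grid lambda whose reconstruction noise is closest to target.

    ``images`` may supply precomputed reconstructions for the same grid of
    lambdas to avoid recomputation across policies.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    if images is None:
        images = batch_reconstruct(sinogram, geometry, grid, materials, regularizer, lambda_grid, n_iterations)
    sds = {float(l): iq_metrics.noise_sd(img, noise_roi) for l, img in zip(lambda_grid, images)}
    measured = np.array([sds[float(l)] for l in lambda_grid])
    best = int(np.argmin(np.abs(measured - target_noise)))
    warning = None
    if measured.min() > 2 * target_noise or measured.max() < 0.5 * target_noise:
        warning = "target noise far outside the candidate range"
    return SelectionResult(lam=float(lambda_grid[best]), noise_sd=sds, warning=warning)


def mtf_match_lambda(
    fbp_image: np.ndarray,
    candidate_images: dict[float, np.ndarray],
    gap: GapSpec,
    pixel_spacing: tuple[float, float],
) -> float:
    """Medium strength: the candidate whose MTF best matches the FBP MTF."""
    if len(candidate_images) < 2:
        raise ValueError("need at least two candidates for MTF matching")
    mtf_ref = iq_metrics.mtf_from_gap(fbp_image, gap, pixel_spacing)
    f_max = mtf_ref.f10
    distances = {
        lam: iq_metrics.mtf_distance(mtf_ref, iq_metrics.mtf_from_gap(img, gap, pixel_spacing), f_max)
        for lam, img in candidate_images.items()
    }
    return min(distances, key=distances.get)


def fixed_levels_from_grid(lambda_grid: np.ndarray, medium: float) -> dict[str, float]:
    """Weak/medium/strong levels: ~medium/3 and ~4 x medium, snapped to grid."""
    grid = np.asarray(lambda_grid, dtype=float)
    if medium not in grid:
        raise ValueError("medium must be a grid value")
    below = grid[grid < medium]
    above = grid[grid > medium]
    if below.size == 0 or above.size == 0:
        raise ValueError("grid too narrow around the medium value")
    weak = float(below[np.argmin(np.abs(np.log(below) - np.log(medium / 3.0)))])
    strong = float(above[np.argmin(np.abs(np.log(above) - np.log(4.0 * medium)))])
    return {"weak": weak, "medium": float(medium), "strong": strong}
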