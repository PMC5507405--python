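"""Chemotactic self-organisation of mesenchymal cells (Keller-Segel type).

Cell density rho moves by diffusion plus chemotaxis up the gradient of a
self-secreted attractant c, with a volume-filling sensitivity that shuts off
as the packing density rho_max is approached:

    d rho / dt = D_rho lap(rho) - div( chi0 (1 - rho/rho_max) rho grad c )
    d c   / dt = D_c   lap(c)   + alpha rho - delta c - bmp_level c + sources

Aggregation-suppressing BMP activity is modelled as additional attractant
degradation (``bmp_level``); fixed point sources model attractant-loaded
beads.  The uniform state (rho_bar, alpha rho_bar/(delta+bmp)) destabilises
into periodic aggregates when chi0 exceeds the threshold
D_rho (delta + bmp) / (alpha rho_bar (1 - rho_bar/rho_max)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fields import (
    CFLError,
    Grid2D,
    check_diffusive_cfl,
    chemotactic_divergence,
    diffusive_divergence,
)
from .rd import FieldState


@dataclass
class ChemotaxisParams:
    D_rho: float = 0.05     # cell diffusivity, length^2/h
    D_c: float = 1.0        # attractant diffusivity
    chi0: float = 1.0       # chemotactic sensitivity
    rho_max: float = 1.0    # volume-filling packing density
    alpha: float = 1.0      # attractant secretion rate per cell
    delta: float = 1.0      # attractant decay rate, 1/h
    bmp_level: float = 0.0  # extra attractant degradation (BMP activity)
    sources: list[tuple[float, float, float]] = field(default_factory=list)  # (x, y, rate)
    rho_bar: float = 0.5    # mean initial cell density

    def __post_init__(self):
        for name in ("D_rho", "D_c", "chi0", "alpha", "delta", "bmp_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rho_max <= 0:
            raise ValueError("rho_max must be positive")


def aggregation_threshold(params: ChemotaxisParams) -> float:
    """Critical chi0 above which the uniform state is linearly unstable."""
    mobility = params.rho_bar * (1.0 - params.rho_bar / params.rho_max)
    if mobility <= 0 or params.alpha == 0:
        return np.inf
    return params.D_rho * (params.delta + params.bmp_level) / (params.alpha * mobility)


def uniform_growth_rate(params: ChemotaxisParams, k: float) -> float:
    """Leading eigenvalue of the linearization about the uniform state at wavenumber k."""
    mobility = params.rho_bar * (1.0 - params.rho_bar / params.rho_max)
    A = np.array(
        [
            [-params.D_rho * k**2, params.chi0 * mobility * k**2],
            [params.alpha, -params.D_c * k**2 - params.delta - params.bmp_level],
        ]
    )
    return float(np.linalg.eigvals(A).real.max())


def _source_field(params: ChemotaxisParams, grid: Grid2D) -> np.ndarray | None:
    if not params.sources:
        return None
    src = np.zeros(grid.shape)
    for x, y, rate in params.sources:
        j = int(np.clip(round(x / grid.h - 0.5), 0, grid.nx - 1))
        i = int(np.clip(round(y / grid.h - 0.5), 0, grid.ny - 1))
        src[i, j] += rate / grid.h**2  # point source spread over one cell
    return src


def simulate_chemotaxis(
    params: ChemotaxisParams,
    grid: Grid2D,
    t_end: float,
    dt: float,
    seed: int = 0,
    noise_amp: float = 1e-2,
    save_every: float | None = None,
    rho_init: np.ndarray | None = None,
    c_init: np.ndarray | None = None,
    boundary_c: dict[str, str] | None = None,
) -> list[FieldState]:
    """Integrate the aggregation model; snapshots carry fields 'rho' and 'c'.

    The cell field always respects the grid boundary (cells cannot leave a
    no-flux tissue edge); ``boundary_c`` optionally overrides the attractant
    boundary, e.g. an absorbing cut edge where the secreted factor dilutes
    into the medium.  Total rho under no-flux boundaries is conserved to
    rounding error.
    """
    check_diffusive_cfl(dt, grid.h, max(params.D_rho, params.D_c))
    rng = np.random.default_rng(seed)
    if rho_init is not None:
        rho = np.array(rho_init, dtype=float, copy=True)
    else:
        rho = params.rho_bar * (1.0 + noise_amp * rng.standard_normal(grid.shape))
        rho = np.clip(rho, 0.0, params.rho_max)
    if c_init is not None:
        c = np.array(c_init, dtype=float, copy=True)
    else:
        c = params.alpha * rho / (params.delta + params.bmp_level + 1e-300)
    bc_c = boundary_c or grid.boundary
    src = _source_field(params, grid)
    decay = params.delta + params.bmp_level

    n_steps = int(round(t_end / dt))
    save_every = save_every if save_every is not None else t_end
    save_stride = max(1, int(round(save_every / dt)))
    out = [FieldState({"rho": rho.copy(), "c": c.copy()}, 0.0)]
    for step in range(1, n_steps + 1):
        adv, vmax = chemotactic_divergence(
            rho, c, params.chi0, params.rho_max, grid, grid.boundary, bc_c
        )
        if vmax * dt / grid.h > 0.5:
            raise CFLError(
                f"advective CFL violated at step {step}; use dt <= {0.5 * grid.h / vmax:.4g}"
            )
        drho = diffusive_divergence(rho, params.D_rho, grid, grid.boundary) + adv
        dc = diffusive_divergence(c, params.D_c, grid, bc_c) + params.alpha * rho - decay * c
        if src is not None:
            dc = dc + src
        rho = rho + dt * drho
        c = c + dt * dc
        if not np.isfinite(rho).all() or not np.isfinite(c).all():
            raise FloatingPointError(f"simulation diverged at step {step}")
        if step % save_stride == 0 or step == n_steps:
            out.append(FieldState({"rho": rho.copy(), "c": c.copy()}, step * dt))
    return out


def exemplar_params(chi0: float = 1.0, **overrides) -> ChemotaxisParams:
    """Shipped aggregation exemplar, ~5x above the instability threshold."""
    return replace(ChemotaxisParams(chi0=chi0), **overrides)
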