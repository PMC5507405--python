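"""Finite-difference grids and flux-form spatial operators.

Fields live on a regular nx x ny grid (arrays indexed [y, x], spacing h).
Per-edge boundary conditions: ``no_flux`` (reflecting; zero normal flux),
``periodic``, or ``dirichlet_zero`` (the field value is clamped to zero on
the edge — a perfect sink for deviations).  Diffusion and chemotactic
advection are discretized in flux form on cell faces, so that under no-flux
boundaries the total field mass is conserved to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EDGES = ("left", "right", "bottom", "top")
CONDITIONS = ("no_flux", "periodic", "dirichlet_zero")


class CFLError(RuntimeError):
    pass


def _normalize_boundary(boundary) -> dict[str, str]:
    if isinstance(boundary, str):
        bc = {e: boundary for e in EDGES}
    else:
        bc = dict(boundary)
    for e in EDGES:
        if bc.get(e) not in CONDITIONS:
            raise ValueError(f"bad boundary condition for edge {e}: {bc.get(e)!r}")
    for a, b in (("left", "right"), ("bottom", "top")):
        if ("periodic" in (bc[a], bc[b])) and bc[a] != bc[b]:
            raise ValueError(f"periodic boundaries must pair up ({a}/{b})")
    return bc


@dataclass
class Grid2D:
    nx: int
    ny: int
    h: float = 1.0
    boundary: object = "periodic"  # str or per-edge dict

    def __post_init__(self):
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8x8")
        if self.h <= 0:
            raise ValueError("spacing must be positive")
        self.boundary = _normalize_boundary(self.boundary)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = (np.arange(self.nx) + 0.5) * self.h
        y = (np.arange(self.ny) + 0.5) * self.h
        return x, y


def ghost_pad(f: np.ndarray, bc: dict[str, str]) -> np.ndarray:
    """Pad a (ny, nx) field with one ghost cell per side according to bc."""
    ny, nx = f.shape
    g = np.zeros((ny + 2, nx + 2), dtype=f.dtype)
    g[1:-1, 1:-1] = f
    g[1:-1, 0] = {"no_flux": f[:, 0], "periodic": f[:, -1], "dirichlet_zero": -f[:, 0]}[bc["left"]]
    g[1:-1, -1] = {"no_flux": f[:, -1], "periodic": f[:, 0], "dirichlet_zero": -f[:, -1]}[bc["right"]]
    g[0, 1:-1] = {"no_flux": f[0, :], "periodic": f[-1, :], "dirichlet_zero": -f[0, :]}[bc["bottom"]]
    g[-1, 1:-1] = {"no_flux": f[-1, :], "periodic": f[0, :], "dirichlet_zero": -f[-1, :]}[bc["top"]]
    return g


def laplacian(f: np.ndarray, grid: Grid2D, bc: dict[str, str] | None = None) -> np.ndarray:
    """Five-point Laplacian; with no-flux ghosts it is discretely conservative."""
    bc = bc or grid.boundary
    g = ghost_pad(f, bc)
    return (
        g[1:-1, 2:] + g[1:-1, :-2] + g[2:, 1:-1] + g[:-2, 1:-1] - 4.0 * f
    ) / grid.h**2


def face_gradients(f: np.ndarray, grid: Grid2D, bc: dict[str, str] | None = None):
    """Gradients on cell faces: gx has shape (ny, nx+1), gy (ny+1, nx)."""
    bc = bc or grid.boundary
    g = ghost_pad(f, bc)
    gx = (g[1:-1, 1:] - g[1:-1, :-1]) / grid.h
    gy = (g[1:, 1:-1] - g[:-1, 1:-1]) / grid.h
    return gx, gy


def _zero_boundary_normal_faces(gx, gy, bc):
    if bc["left"] == "no_flux":
        gx[:, 0] = 0.0
    if bc["right"] == "no_flux":
        gx[:, -1] = 0.0
    if bc["bottom"] == "no_flux":
        gy[0, :] = 0.0
    if bc["top"] == "no_flux":
        gy[-1, :] = 0.0


def diffusive_divergence(
    f: np.ndarray, D: float, grid: Grid2D, bc: dict[str, str] | None = None
) -> np.ndarray:
    """div(D grad f) in flux form (exactly mass-conserving under no-flux)."""
    bc = bc or grid.boundary
    gx, gy = face_gradients(f, grid, bc)
    _zero_boundary_normal_faces(gx, gy, bc)
    Fx, Fy = D * gx, D * gy
    return (Fx[:, 1:] - Fx[:, :-1]) / grid.h + (Fy[1:, :] - Fy[:-1, :]) / grid.h


def chemotactic_divergence(
    rho: np.ndarray,
    c: np.ndarray,
    chi0: float,
    rho_max: float,
    grid: Grid2D,
    bc_rho: dict[str, str] | None = None,
    bc_c: dict[str, str] | None = None,
) -> tuple[np.ndarray, float]:
    """-div(chi0 (1 - rho/rho_max) rho grad c) with upwinded cell density.

    The advective face flux carries rho from the upwind cell (which keeps
    rho nonnegative for CFL-respecting steps) times the volume-filling
    factor 1 - rho/rho_max of the receiving cell (which makes the flux
    vanish as the receiver reaches packing density).  Returns (divergence
    contribution to d rho/dt, max face speed) for CFL monitoring.
    """
    bc_rho = bc_rho or grid.boundary
    bc_c = bc_c or grid.boundary
    gx, gy = face_gradients(c, grid, bc_c)
    vx, vy = chi0 * gx, chi0 * gy

    gr = ghost_pad(rho, bc_rho)
    up = np.clip(gr, 0.0, None)
    fill = np.clip(1.0 - gr / rho_max, 0.0, 1.0)
    upxL, upxR = up[1:-1, :-1], up[1:-1, 1:]
    upyL, upyR = up[:-1, 1:-1], up[1:, 1:-1]
    fxL, fxR = fill[1:-1, :-1], fill[1:-1, 1:]
    fyL, fyR = fill[:-1, 1:-1], fill[1:, 1:-1]
    Fx = vx * np.where(vx > 0, upxL * fxR, upxR * fxL)
    Fy = vy * np.where(vy > 0, upyL * fyR, upyR * fyL)
    # a no-flux wall blocks cells even where the attractant gradient does not vanish
    if bc_rho["left"] == "no_flux":
        Fx[:, 0] = 0.0
    if bc_rho["right"] == "no_flux":
        Fx[:, -1] = 0.0
    if bc_rho["bottom"] == "no_flux":
        Fy[0, :] = 0.0
    if bc_rho["top"] == "no_flux":
        Fy[-1, :] = 0.0
    div = (Fx[:, 1:] - Fx[:, :-1]) / grid.h + (Fy[1:, :] - Fy[:-1, :]) / grid.h
    vmax = max(float(np.abs(vx).max(initial=0.0)), float(np.abs(vy).max(initial=0.0)))
    return -div, vmax


def check_diffusive_cfl(dt: float, h: float, d_max: float, safety: float = 1.0) -> None:
    limit = safety * h**2 / (4.0 * d_max)
    if dt > limit:
        raise CFLError(
            f"dt={dt} violates the diffusive stability limit; use dt <= {limit:.4g}"
        )
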