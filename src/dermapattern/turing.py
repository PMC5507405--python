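"""Linear stability analysis of the signed interaction network.

A reaction-diffusion system linearized about a homogeneous steady state is
``du/dt = J u + diag(d) lap(u)``.  A spatial perturbation of wavenumber k
grows at rate ``growth(k) = max Re eig(J - k^2 diag(d))``.  Diffusion-driven
(Turing) instability means the well-mixed system is stable
(``growth(0) < 0``) while some finite-wavelength band grows
(``growth(k) > 0`` for some k > 0); the fastest-growing wavenumber k*
predicts the emergent pattern wavelength 2*pi/k*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .network import SignedInteractionMatrix


@dataclass
class ReactionDiffusionModel:
    species: tuple[str, ...]
    jacobian: np.ndarray          # n x n, per-hour rates about the steady state
    diffusivities: np.ndarray     # n positive, length^2 / hour
    saturation: float = 0.5       # scale of the tanh kinetics used in simulation

    def __post_init__(self):
        self.jacobian = np.asarray(self.jacobian, dtype=float)
        self.diffusivities = np.asarray(self.diffusivities, dtype=float)
        n = len(self.species)
        if self.jacobian.shape != (n, n):
            raise ValueError("jacobian shape does not match species")
        if not np.isfinite(self.jacobian).all():
            raise ValueError("jacobian must be finite")
        if self.diffusivities.shape != (n,) or (self.diffusivities <= 0).any():
            raise ValueError("diffusivities must be n positive reals")

    @property
    def n(self) -> int:
        return len(self.species)


@dataclass
class DispersionResult:
    k_grid: np.ndarray
    growth: np.ndarray
    turing: bool
    unstable_band: tuple[float, float] | None
    k_star: float | None
    growth_star: float | None
    oscillatory: bool  # leading eigenvalue at k* has nonzero imaginary part


def build_model(
    matrix: SignedInteractionMatrix,
    magnitudes: np.ndarray | float = 1.0,
    decay: np.ndarray | float = 1.0,
    diffusivities: np.ndarray | float = 1.0,
    saturation: float = 0.5,
) -> ReactionDiffusionModel:
    """Parameterize the sign matrix: J[i,j] = sign * magnitude off-diagonal,
    J[i,i] = sign * magnitude - decay[i]."""
    n = len(matrix.species)
    mag = np.broadcast_to(np.asarray(magnitudes, dtype=float), (n, n)).copy()
    dec = np.broadcast_to(np.asarray(decay, dtype=float), (n,)).copy()
    dif = np.broadcast_to(np.asarray(diffusivities, dtype=float), (n,)).copy()
    if (dec <= 0).any():
        raise ValueError("decay rates must be positive")
    if (mag < 0).any():
        raise ValueError("magnitudes must be nonnegative")
    J = matrix.M * mag
    J[np.diag_indices(n)] = np.diag(matrix.M) * np.diag(mag) - dec
    return ReactionDiffusionModel(matrix.species, J, dif, saturation)


def growth_rate(model: ReactionDiffusionModel, k: float | np.ndarray) -> np.ndarray:
    """max Re eig(J - k^2 diag(d)) for each wavenumber k."""
    ks = np.atleast_1d(np.asarray(k, dtype=float))
    out = np.empty_like(ks)
    for i, kv in enumerate(ks):
        A = model.jacobian - kv**2 * np.diag(model.diffusivities)
        out[i] = np.linalg.eigvals(A).real.max()
    return out


def _leading_imag(model: ReactionDiffusionModel, k: float) -> float:
    A = model.jacobian - k**2 * np.diag(model.diffusivities)
    ev = np.linalg.eigvals(A)
    return float(abs(ev[np.argmax(ev.real)].imag))


def dispersion(
    model: ReactionDiffusionModel, k_max: float = 10.0, n_k: int = 256
) -> DispersionResult:
    """Dispersion curve on a uniform k grid with local refinement of the peak."""
    if k_max <= 0 or n_k < 2:
        raise ValueError("need k_max > 0 and n_k >= 2")
    k_grid = np.linspace(0.0, k_max, n_k)
    growth = growth_rate(model, k_grid)
    if not np.isfinite(growth).all():
        raise ArithmeticError(f"eigen-solver failure for jacobian {model.jacobian!r}")
    g0 = growth[0]
    # refine the peak with a bounded scalar search around the coarse argmax;
    # done unconditionally so that a narrow unstable band falling between
    # grid points is still detected
    i = 1 + int(np.argmax(growth[1:]))
    lo = k_grid[max(i - 1, 0)]
    hi = k_grid[min(i + 1, n_k - 1)]
    res = minimize_scalar(
        lambda k: -growth_rate(model, k)[0], bounds=(lo, hi), method="bounded"
    )
    k_star = float(res.x)
    g_star = float(-res.fun)
    turing = bool(g0 < 0 and g_star > 0)
    band = None
    oscillatory = False
    if turing:
        if (growth > 0).any():
            band = _zero_crossings(k_grid, growth)
        else:  # band narrower than the grid spacing
            band = (k_star, k_star)
        oscillatory = _leading_imag(model, k_star) > 1e-9
    else:
        k_star = None
        g_star = None
    return DispersionResult(k_grid, growth, turing, band, k_star, g_star, oscillatory)


def _zero_crossings(k_grid: np.ndarray, growth: np.ndarray) -> tuple[float, float]:
    """Linearly interpolated (k_min, k_max) of the positive-growth band."""
    above = growth > 0
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]

    def interp(a, b):
        ka, kb = k_grid[a], k_grid[b]
        ga, gb = growth[a], growth[b]
        return ka + (kb - ka) * (-ga) / (gb - ga)

    k_lo = interp(i0 - 1, i0) if i0 > 0 else float(k_grid[0])
    k_hi = interp(i1 + 1, i1) if i1 < len(k_grid) - 1 else float(k_grid[-1])
    return (float(k_lo), float(k_hi))


def classify_turing(
    model: ReactionDiffusionModel, k_max: float = 10.0, n_k: int = 256
) -> tuple[bool, dict]:
    """Turing flag plus diagnostics (growth at k=0, peak growth, k*)."""
    disp = dispersion(model, k_max=k_max, n_k=n_k)
    diagnostics = {
        "growth_at_zero": float(disp.growth[0]),
        "max_growth": float(disp.growth.max()),
        "k_star": disp.k_star,
        "unstable_band": disp.unstable_band,
        "oscillatory": disp.oscillatory,
    }
    return disp.turing, diagnostics


@dataclass
class SamplerConfig:
    """Log-uniform ranges for the parameter scan."""

    magnitude_range: tuple[float, float] = (0.1, 10.0)
    decay_range: tuple[float, float] = (0.1, 10.0)
    diffusivity_range: tuple[float, float] = (0.1, 10.0)

    def __post_init__(self):
        for lo, hi in (self.magnitude_range, self.decay_range, self.diffusivity_range):
            if not (0 < lo <= hi):
                raise ValueError("ranges must satisfy 0 < lo <= hi")


@dataclass
class ScanReport:
    n_samples: int
    n_turing: int
    fraction_turing: float
    k_star_values: np.ndarray
    exemplar: dict | None = field(default=None)


def _log_uniform(rng, lo, hi, size):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def scan_parameters(
    matrix: SignedInteractionMatrix,
    config: SamplerConfig | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    k_max: float = 10.0,
    n_k: int = 128,
) -> ScanReport:
    """Robustness scan: sample magnitudes/decays/diffusivities log-uniformly,
    classify each draw, and report the Turing-unstable fraction."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cfg = config or SamplerConfig()
    rng = np.random.default_rng(seed)
    n = len(matrix.species)
    n_turing = 0
    k_stars = []
    exemplar = None
    for _ in range(n_samples):
        mag = _log_uniform(rng, *cfg.magnitude_range, (n, n))
        dec = _log_uniform(rng, *cfg.decay_range, n)
        dif = _log_uniform(rng, *cfg.diffusivity_range, n)
        model = build_model(matrix, mag, dec, dif)
        turing, diag = classify_turing(model, k_max=k_max, n_k=n_k)
        if turing:
            n_turing += 1
            k_stars.append(diag["k_star"])
            if exemplar is None:
                exemplar = {
                    "magnitudes": mag,
                    "decay": dec,
                    "diffusivities": dif,
                    "k_star": diag["k_star"],
                    "max_growth": diag["max_growth"],
                }
    return ScanReport(
        n_samples=n_samples,
        n_turing=n_turing,
        fraction_turing=n_turing / n_samples,
        k_star_values=np.asarray(k_stars),
        exemplar=exemplar,
    )
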