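"""Synthetic inputs with the statistical structure the analyses assume.

Generates (i) biased-random-walk cell trajectories with a late-onset
attraction switch and optional chemokinesis, emulating tracked dermal cells;
(ii) perturbation fold-change tables drawn from a known signed interaction
matrix; (iii) exponential decay time courses with multiplicative noise; and
(iv) rasterized nuclear-reporter movies of simulated cell fields.  Every
generator is seeded and ships its ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .network import SignedInteractionMatrix


@dataclass
class TrackGenConfig:
    """Study-condition defaults for the trajectory generator.

    Cells take one step per 20-min frame with Rayleigh step lengths
    (scale chemokinesis * step_scale) and uniform headings.  In the final
    ``switch_time`` minutes, cells within ``attraction_radius`` of a
    condensate centre draw headings from a von Mises distribution aimed at
    the centre with concentration 10 b / (1 - b); a cell reaching
    ``capture_radius`` is recorded as entered and tracking halts.
    """

    arena: tuple[float, float] = (400.0, 400.0)  # micrometres
    n_condensates: int = 4
    n_cells: int = 370
    frame_interval: float = 20.0     # minutes
    duration: float = 1500.0         # minutes (>= the 1,500-min analysis window)
    step_scale: float = 1.5          # um, Rayleigh scale per frame
    bias: float = 0.8                # directional bias b in [0, 1]
    switch_time: float = 360.0       # minutes before end with attraction on
    attraction_radius: float = 45.0  # um
    capture_radius: float = 15.0     # um
    chemokinesis: float = 1.0        # step-scale multiplier kappa >= 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [0, 1]")
        if self.capture_radius >= self.attraction_radius:
            raise ValueError("capture_radius must be smaller than attraction_radius")
        if self.chemokinesis < 1.0:
            raise ValueError("chemokinesis multiplier must be >= 1")


def vonmises_concentration(bias: float) -> float:
    """Map bias b in [0,1] to a von Mises concentration; b=0 is exactly uniform."""
    return 10.0 * bias / (1.0 - bias + 1e-9)


def _condensate_centers(cfg: TrackGenConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid placement keeps centres well separated for any count."""
    w, h = cfg.arena
    ncols = int(np.ceil(np.sqrt(cfg.n_condensates)))
    nrows = int(np.ceil(cfg.n_condensates / ncols))
    centers = []
    for i in range(cfg.n_condensates):
        r, c = divmod(i, ncols)
        cx = (c + 0.5) * w / ncols
        cy = (r + 0.5) * h / nrows
        jitter = rng.uniform(-0.1, 0.1, 2) * np.array([w / ncols, h / nrows])
        centers.append([cx + jitter[0], cy + jitter[1]])
    return np.asarray(centers)


def gen_tracks(
    cfg: TrackGenConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate trajectories; returns (tracks, rois, ground truth) tables.

    tracks: track_id, frame, t_min, x_um, y_um (rows stop at entry).
    rois: condensate_id, cx_um, cy_um, radius_um (radius = capture radius).
    truth: track_id, true_class, true_entry_time_min.
    """
    cfg = cfg or TrackGenConfig()
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.arena
    centers = _condensate_centers(cfg, rng)
    n_frames = int(cfg.duration // cfg.frame_interval) + 1
    switch_at = cfg.duration - cfg.switch_time
    kappa_vm = vonmises_concentration(cfg.bias)

    pos = rng.uniform((0, 0), (w, h), size=(cfg.n_cells, 2))
    entered = np.full(cfg.n_cells, False)
    entry_time = np.full(cfg.n_cells, np.nan)

    rows = []
    for frame in range(n_frames):
        t = frame * cfg.frame_interval
        for cid in range(cfg.n_cells):
            if entered[cid] and t > entry_time[cid]:
                continue  # tracking halted on entry
            rows.append((cid, frame, t, pos[cid, 0], pos[cid, 1]))
        if frame == n_frames - 1:
            break
        # advance all not-yet-entered cells by one step
        active = ~entered
        n_active = int(active.sum())
        steps = rng.rayleigh(cfg.chemokinesis * cfg.step_scale, size=n_active)
        headings = rng.uniform(0, 2 * np.pi, size=n_active)
        t_next = t + cfg.frame_interval
        if t_next >= switch_at and cfg.bias > 0:
            p = pos[active]
            d = p[:, None, :] - centers[None, :, :]
            dist = np.hypot(d[..., 0], d[..., 1])
            nearest = dist.argmin(axis=1)
            r_near = dist[np.arange(n_active), nearest]
            attracted = r_near <= cfg.attraction_radius
            if attracted.any():
                tgt = centers[nearest[attracted]]
                aim = np.arctan2(tgt[:, 1] - p[attracted, 1], tgt[:, 0] - p[attracted, 0])
                headings[attracted] = rng.vonmises(aim, kappa_vm, size=int(attracted.sum()))
        delta = np.column_stack([steps * np.cos(headings), steps * np.sin(headings)])
        # the arena is the spawn region of an unbounded plane: no walls, so
        # with bias 0 every window's angle distribution is exactly isotropic
        pos[active] = pos[active] + delta
        # capture: condensates only exist once the attraction switch has
        # fired, so entry is possible only from then on
        if t_next >= switch_at:
            d = pos[:, None, :] - centers[None, :, :]
            dist = np.hypot(d[..., 0], d[..., 1]).min(axis=1)
            newly = (~entered) & (dist <= cfg.capture_radius)
            entered[newly] = True
            entry_time[newly] = t_next

    tracks = pd.DataFrame(rows, columns=["track_id", "frame", "t_min", "x_um", "y_um"])
    rois = pd.DataFrame(
        {
            "condensate_id": np.arange(len(centers)),
            "cx_um": centers[:, 0],
            "cy_um": centers[:, 1],
            "radius_um": cfg.capture_radius,
        }
    )
    truth = pd.DataFrame(
        {
            "track_id": np.arange(cfg.n_cells),
            "true_class": np.where(entered, "condensate", "intercondensate"),
            "true_entry_time_min": entry_time,
        }
    )
    return tracks, rois, truth


# ---------------------------------------------------------------------------
# Fold-change tables


def gen_foldchange_table(
    matrix: SignedInteractionMatrix,
    effect: float = 2.5,
    noise_sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    genes_per_species: int = 2,
    pathways: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Fold-change records drawn from a known signed matrix.

    For each perturbed pathway j and target species i with M[i,j] != 0, the
    stimulated condition draws gene-level log fold changes from
    Normal(sign * ln(effect), noise_sd) per replicate (the inhibited
    condition flips the sign); unregulated genes draw from Normal(0,
    noise_sd).  The reported fold change is the geometric replicate mean and
    the p-value a one-sample t test of the replicate logs against zero.
    Returns the table and the gene -> species grouping.
    """
    if effect <= 1:
        raise ValueError("effect must exceed 1")
    rng = np.random.default_rng(seed)
    perturbed = pathways if pathways is not None else matrix.species
    genes = {
        sp: [f"{sp}_g{g}" for g in range(genes_per_species)] for sp in matrix.species
    }
    grouping = {g: sp for sp, gs in genes.items() for g in gs}
    rows = []
    for pathway in perturbed:
        j = matrix.index(pathway)
        for sp in matrix.species:
            i = matrix.index(sp)
            sign = int(matrix[i, j])
            for gene in genes[sp]:
                for direction, flip in (("stimulated", 1), ("inhibited", -1)):
                    mu = flip * sign * np.log(effect)
                    if noise_sd > 0:
                        logs = rng.normal(mu, noise_sd, size=replicates)
                        fc = float(np.exp(logs.mean()))
                        from scipy import stats as _st

                        _, p = _st.ttest_1samp(logs, 0.0)
                        p = float(p)
                    else:
                        fc = float(np.exp(mu))
                        p = 0.0 if mu != 0 else 1.0
                    rows.append(
                        {
                            "gene": gene,
                            "pathway": pathway,
                            "direction": direction,
                            "fold_change": fc,
                            "p_value": p,
                        }
                    )
    return pd.DataFrame(rows), grouping


# ---------------------------------------------------------------------------
# Decay time courses


def gen_decay_table(
    n_genes: int = 500,
    k_range: tuple[float, float] = (1.0 / 300.0, 1.0 / 20.0),
    times: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0),
    cv: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exponential decay series with multiplicative lognormal noise.

    Decay rates are log-uniform over ``k_range`` (per minute).  Abundances
    are exp(-k t) times lognormal noise of coefficient of variation ``cv``;
    the reference transcript is constant up to the same noise.  Returns
    (table with gene,time_min,abundance,reference_abundance; truth with
    gene,k_true,t_half_true_min).
    """
    if 0.0 not in times:
        raise ValueError("times must include 0")
    rng = np.random.default_rng(seed)
    ks = np.exp(rng.uniform(np.log(k_range[0]), np.log(k_range[1]), size=n_genes))
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    times_arr = np.asarray(times, dtype=float)
    rows = []
    for g in range(n_genes):
        gene = f"gene_{g:04d}"
        clean = np.exp(-ks[g] * times_arr)
        noise = np.exp(rng.normal(0.0, sigma, size=len(times_arr))) if sigma else 1.0
        ref_noise = np.exp(rng.normal(0.0, sigma, size=len(times_arr))) if sigma else np.ones(len(times_arr))
        ab = clean * noise
        for tt, a, r in zip(times_arr, np.atleast_1d(ab), ref_noise):
            rows.append(
                {"gene": gene, "time_min": tt, "abundance": a, "reference_abundance": r}
            )
    truth = pd.DataFrame(
        {
            "gene": [f"gene_{g:04d}" for g in range(n_genes)],
            "k_true": ks,
            "t_half_true_min": np.log(2) / ks,
        }
    )
    return pd.DataFrame(rows), truth


def advect_tracers(
    trajectory,
    grid,
    params,
    n_tracers: int = 400,
    seed: int = 0,
    substeps: int = 20,
) -> np.ndarray:
    """Carry tracer cells through a saved chemotaxis simulation.

    Tracers start uniformly over the domain and move with the chemotactic
    drift chi0 (1 - rho/rho_max) grad c evaluated on each snapshot interval,
    plus a Brownian kick matching the cell diffusivity; reflecting walls.
    Returns positions (n_snapshots, n_tracers, 2) in the grid's length
    units, suitable for rasterization into a nuclear-reporter movie.
    """
    from scipy.interpolate import RegularGridInterpolator

    rng = np.random.default_rng(seed)
    Lx, Ly = grid.nx * grid.h, grid.ny * grid.h
    xs, ys = grid.cell_centers()
    pos = rng.uniform((0, 0), (Lx, Ly), size=(n_tracers, 2))
    out = [pos.copy()]
    for a, b in zip(trajectory[:-1], trajectory[1:]):
        rho, c = a.fields["rho"], a.fields["c"]
        gy, gx = np.gradient(c, grid.h)
        mob = np.clip(1.0 - rho / params.rho_max, 0.0, 1.0)
        vx = RegularGridInterpolator((ys, xs), params.chi0 * mob * gx, bounds_error=False, fill_value=0.0)
        vy = RegularGridInterpolator((ys, xs), params.chi0 * mob * gy, bounds_error=False, fill_value=0.0)
        dt = (b.time - a.time) / substeps
        sig = np.sqrt(2.0 * params.D_rho * dt)
        for _ in range(substeps):
            pts = pos[:, ::-1]  # (y, x) ordering
            pos[:, 0] += vx(pts) * dt + sig * rng.standard_normal(n_tracers)
            pos[:, 1] += vy(pts) * dt + sig * rng.standard_normal(n_tracers)
            # reflecting walls
            pos[:, 0] = Lx - np.abs(Lx - np.abs(pos[:, 0]))
            pos[:, 1] = Ly - np.abs(Ly - np.abs(pos[:, 1]))
        out.append(pos.copy())
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Rasterized movies


def rasterize_positions(
    positions: np.ndarray,
    image_shape: tuple[int, int],
    psf_sigma: float = 2.0,
    background_noise: float = 0.0,
    seed: int = 0,
    pixel_size: float = 1.0,
    amplitude: float = 100.0,
) -> np.ndarray:
    """Render per-frame cell positions as Gaussian nuclear spots.

    positions: (n_frames, n_cells, 2) array of (x, y) in length units;
    coordinates are divided by ``pixel_size``.  Each cell deposits a unit
    impulse with bilinear subpixel weighting, the frame is blurred with an
    isotropic Gaussian PSF, and additive Gaussian background noise is
    applied.  Returns a float32 stack (n_frames, ny, nx).
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=float) / pixel_size
    n_frames = positions.shape[0]
    ny, nx = image_shape
    stack = np.zeros((n_frames, ny, nx), dtype=np.float64)
    for f in range(n_frames):
        im = stack[f]
        for x, y in positions[f]:
            if not (0 <= x < nx - 1 and 0 <= y < ny - 1):
                continue
            ix, iy = int(x), int(y)
            fx, fy = x - ix, y - iy
            im[iy, ix] += (1 - fx) * (1 - fy)
            im[iy, ix + 1] += fx * (1 - fy)
            im[iy + 1, ix] += (1 - fx) * fy
            im[iy + 1, ix + 1] += fx * fy
        stack[f] = ndimage.gaussian_filter(im, psf_sigma) * amplitude
    if background_noise > 0:
        stack += rng.normal(0.0, background_noise, size=stack.shape)
    return stack.astype(np.float32)


def tracks_to_positions(tracks: pd.DataFrame) -> np.ndarray:
    """Pivot a track table into an (n_frames, n_cells, 2) position array.

    Cells whose tracking halted early hold their last position (entered
    cells sit in the condensate), matching what a nuclear reporter shows.
    """
    frames = np.sort(tracks["frame"].unique())
    ids = np.sort(tracks["track_id"].unique())
    fidx = {f: i for i, f in enumerate(frames)}
    cidx = {c: i for i, c in enumerate(ids)}
    pos = np.full((len(frames), len(ids), 2), np.nan)
    for row in tracks.itertuples(index=False):
        pos[fidx[row.frame], cidx[row.track_id]] = (row.x_um, row.y_um)
    # forward-fill halted tracks
    for f in range(1, len(frames)):
        missing = np.isnan(pos[f, :, 0])
        pos[f, missing] = pos[f - 1, missing]
    return pos


def write_tiff(path, stack: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, stack)
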