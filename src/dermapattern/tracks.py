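"""Cell-trajectory statistics for condensate formation.

Tracked dermal cells are classed as *condensate* (the track ends inside a
condensate region of interest; tracking is halted on entry) or
*intercondensate* (never incorporated).  Each track is cut into 6-h windows
counted backward from an anchor (entry time, or track end for intercondensate
cells).  Per window we record the Euclidean angle between the net
displacement and the direction to the future condensate centre (0-180 deg),
the Euclidean and accumulated distances, and the persistence
(Euclidean/accumulated).  Directionality is tested with a one-sample
Kolmogorov-Smirnov test against Uniform(0, 180); group contrasts use
Kruskal-Wallis followed by Bonferroni-corrected Mann-Whitney U tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

WINDOW_MIN = 360.0  # 6-h windows

CONDENSATE = "condensate"
INTERCONDENSATE = "intercondensate"


@dataclass
class CondensateROI:
    condensate_id: int
    center: tuple[float, float]  # micrometres
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")

    def contains(self, x, y) -> np.ndarray:
        return np.hypot(np.asarray(x) - self.center[0], np.asarray(y) - self.center[1]) <= self.radius


@dataclass
class Track:
    track_id: int
    t: np.ndarray  # minutes, strictly increasing
    x: np.ndarray  # micrometres
    y: np.ndarray
    cls: str | None = None
    entry_time: float | None = None
    condensate_id: int | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t) == 0:
            raise ValueError(f"track {self.track_id} has no samples")
        if len(self.t) < 2:
            raise ValueError(f"track {self.track_id} needs >= 2 samples")
        if (np.diff(self.t) <= 0).any():
            raise ValueError(f"track {self.track_id}: times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class WindowRecord:
    track_id: int
    window_label: str          # "0-6 h" = the window ending at the anchor
    window_index: int          # 0 = 0-6 h before anchor
    cls: str
    euclid_angle: float        # degrees in [0, 180]; NaN when undefined
    euclid_dist: float
    accum_dist: float
    persistence: float
    angle_defined: bool


@dataclass
class TrackSummary:
    track_id: int
    cls: str
    accumulated_velocity: float  # um/min
    euclidean_velocity: float
    persistence: float


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    n_comparisons: int = 1
    groups: tuple[str, ...] = ()

    @property
    def p_corrected(self) -> float:
        return min(1.0, self.p_value * self.n_comparisons)


# ---------------------------------------------------------------------------
# I/O


def load_tracks_csv(path, pixel_size_um: float = 1.0) -> list[Track]:
    """Read `track_id,frame,t_min,x_um,y_um` (or pixel coordinates scaled by
    ``pixel_size_um``) into Track objects."""
    return tracks_from_frame(pd.read_csv(path), pixel_size_um)


def tracks_from_frame(df: pd.DataFrame, pixel_size_um: float = 1.0) -> list[Track]:
    """Track objects from an in-memory table with the track-CSV columns."""
    out = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("t_min")
        out.append(
            Track(
                track_id=int(tid),
                t=sub["t_min"].to_numpy(),
                x=sub["x_um"].to_numpy() * pixel_size_um,
                y=sub["y_um"].to_numpy() * pixel_size_um,
            )
        )
    return out


def rois_from_frame(df: pd.DataFrame) -> list[CondensateROI]:
    return [
        CondensateROI(int(r.condensate_id), (float(r.cx_um), float(r.cy_um)), float(r.radius_um))
        for r in df.itertuples(index=False)
    ]


def load_rois_csv(path) -> list[CondensateROI]:
    df = pd.read_csv(path)
    return [
        CondensateROI(int(r.condensate_id), (float(r.cx_um), float(r.cy_um)), float(r.radius_um))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Classification and windowing


def nearest_roi(rois: list[CondensateROI], x: float, y: float) -> CondensateROI:
    return min(rois, key=lambda r: math.hypot(x - r.center[0], y - r.center[1]))


def classify_tracks(tracks: list[Track], rois: list[CondensateROI]) -> list[Track]:
    """Assign condensate/intercondensate identity and truncate at entry.

    A cell acquires condensate identity iff its final sample lies inside an
    ROI.  Entry time is the first time from which the track stays inside that
    ROI until its end; samples after entry are discarded (tracking halted on
    entry).
    """
    if not rois:
        raise ValueError("rois must be non-empty")
    out = []
    for tr in tracks:
        final_roi = next(
            (r for r in rois if r.contains(tr.x[-1], tr.y[-1])), None
        )
        if final_roi is None:
            out.append(replace(tr, cls=INTERCONDENSATE, entry_time=None, condensate_id=None))
            continue
        inside = final_roi.contains(tr.x, tr.y)
        outside_idx = np.nonzero(~inside)[0]
        entry_idx = 0 if len(outside_idx) == 0 else int(outside_idx[-1]) + 1
        entry_idx = max(entry_idx, 1)  # keep >= 2 samples
        out.append(
            Track(
                track_id=tr.track_id,
                t=tr.t[: entry_idx + 1],
                x=tr.x[: entry_idx + 1],
                y=tr.y[: entry_idx + 1],
                cls=CONDENSATE,
                entry_time=float(tr.t[entry_idx]),
                condensate_id=final_roi.condensate_id,
            )
        )
    return out


def _angle_to_center(dx: float, dy: float, to_center: tuple[float, float]) -> float:
    """Angle (deg, 0-180) between a displacement and the direction to the centre."""
    norm_d = math.hypot(dx, dy)
    norm_c = math.hypot(*to_center)
    if norm_d == 0 or norm_c == 0:
        return float("nan")
    cosang = (dx * to_center[0] + dy * to_center[1]) / (norm_d * norm_c)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def segment_windows(
    track: Track,
    rois: list[CondensateROI],
    window_min: float = WINDOW_MIN,
    max_windows: int | None = None,
) -> list[WindowRecord]:
    """Cut a classified track into windows counted backward from its anchor.

    The anchor is the entry time for condensate tracks and the final sample
    time otherwise.  Windows that are not fully covered by the track or hold
    fewer than 2 samples are discarded.  The angle reference is the vector
    from the window-start position to the future condensate centre: the
    entered condensate for condensate tracks, and the prospective centre
    nearest the window-start position for intercondensate tracks (chosen at
    the window start so that an unbiased walk gives an exactly isotropic
    angle distribution).  Zero-net-displacement windows get an undefined
    angle but keep persistence = 0.
    """
    if track.cls is None:
        raise ValueError("track must be classified first")
    anchor = track.entry_time if track.cls == CONDENSATE else float(track.t[-1])
    assigned = None
    if track.cls == CONDENSATE and track.condensate_id is not None:
        assigned = next(r for r in rois if r.condensate_id == track.condensate_id).center
    records = []
    w = 0
    while max_windows is None or w < max_windows:
        hi = anchor - w * window_min
        lo = hi - window_min
        if lo < track.t[0] - 1e-9:
            break
        sel = (track.t >= lo - 1e-9) & (track.t <= hi + 1e-9)
        idx = np.nonzero(sel)[0]
        if len(idx) >= 2:
            xs, ys = track.x[idx], track.y[idx]
            dx, dy = xs[-1] - xs[0], ys[-1] - ys[0]
            euclid = math.hypot(dx, dy)
            accum = float(np.hypot(np.diff(xs), np.diff(ys)).sum())
            center = assigned if assigned is not None else nearest_roi(rois, xs[0], ys[0]).center
            to_center = (center[0] - xs[0], center[1] - ys[0])
            angle = _angle_to_center(dx, dy, to_center)
            records.append(
                WindowRecord(
                    track_id=track.track_id,
                    window_label=f"{6 * w}-{6 * (w + 1)} h",
                    window_index=w,
                    cls=track.cls,
                    euclid_angle=angle,
                    euclid_dist=euclid,
                    accum_dist=accum,
                    persistence=min(1.0, euclid / accum) if accum > 0 else 0.0,
                    angle_defined=not math.isnan(angle),
                )
            )
        w += 1
    return records


def track_summaries(track: Track) -> TrackSummary:
    """Whole-track accumulated/Euclidean velocity and persistence."""
    if track.duration <= 0:
        raise ValueError("track duration must be positive")
    accum = float(np.hypot(np.diff(track.x), np.diff(track.y)).sum())
    euclid = math.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0])
    return TrackSummary(
        track_id=track.track_id,
        cls=track.cls or "unclassified",
        accumulated_velocity=accum / track.duration,
        euclidean_velocity=euclid / track.duration,
        persistence=min(1.0, euclid / accum) if accum > 0 else 0.0,
    )


def windows_frame(records: list[WindowRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def summaries_frame(tracks: list[Track]) -> pd.DataFrame:
    return pd.DataFrame([vars(track_summaries(tr)) for tr in tracks])


# ---------------------------------------------------------------------------
# Join probability


def join_probability(
    tracks: list[Track], rois: list[CondensateROI], bin_edges: np.ndarray
) -> pd.DataFrame:
    """P(joining the condensate) vs initial distance to the nearest final
    condensate centre, per radial bin.  Bins with < 5 tracks are flagged."""
    if not tracks:
        raise ValueError("no tracks supplied")
    bin_edges = np.asarray(bin_edges, dtype=float)
    r0 = np.array(
        [
            min(math.hypot(tr.x[0] - r.center[0], tr.y[0] - r.center[1]) for r in rois)
            for tr in tracks
        ]
    )
    joined = np.array([tr.cls == CONDENSATE for tr in tracks])
    which = np.digitize(r0, bin_edges) - 1
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = which == b
        n = int(sel.sum())
        rows.append(
            {
                "bin_center": 0.5 * (bin_edges[b] + bin_edges[b + 1]),
                "n_tracks": n,
                "probability": float(joined[sel].mean()) if n else float("nan"),
                "low_n": n < 5,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistical tests


def ks_uniform(angles: np.ndarray, exact: bool = False) -> TestResult:
    """One-sample KS test of Euclidean angles against Uniform(0, 180)."""
    angles = np.asarray(angles, dtype=float)
    if len(angles) < 5:
        raise ValueError("need at least 5 angles")
    if ((angles < 0) | (angles > 180)).any():
        raise ValueError("angles must lie in [0, 180] degrees")
    method = "exact" if exact else "asymp"
    res = stats.kstest(angles, stats.uniform(loc=0, scale=180).cdf, method=method)
    return TestResult("ks_uniform", float(res.statistic), float(res.pvalue), (len(angles),))


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> TestResult:
    res = stats.ks_2samp(a, b, method="asymp")
    return TestResult(
        "ks_two_sample", float(res.statistic), float(res.pvalue), (len(a), len(b))
    )


def group_compare(groups: dict[str, np.ndarray]) -> list[TestResult]:
    """Omnibus Kruskal-Wallis followed by all pairwise two-sided Mann-Whitney
    U tests with Bonferroni correction (multiplier = number of pairs)."""
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(a) < 3 for a in arrays):
        raise ValueError("each group needs n >= 3")
    results: list[TestResult] = []
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        results.append(
            TestResult("kruskal_wallis", float("nan"), float("nan"),
                       tuple(len(a) for a in arrays), groups=tuple(labels))
        )
        return results
    H, p = stats.kruskal(*arrays)
    results.append(
        TestResult("kruskal_wallis", float(H), float(p),
                   tuple(len(a) for a in arrays), groups=tuple(labels))
    )
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    for i, j in pairs:
        U, p = stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
        results.append(
            TestResult(
                "mann_whitney_bonferroni",
                float(U),
                float(p),
                (len(arrays[i]), len(arrays[j])),
                n_comparisons=len(pairs),
                groups=(labels[i], labels[j]),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Pipeline


def analyze_tracks(
    tracks: list[Track],
    rois: list[CondensateROI],
    window_min: float = WINDOW_MIN,
    max_windows: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """classify -> window -> summarize; returns (window records, per-track summaries)."""
    classified = classify_tracks(tracks, rois)
    records: list[WindowRecord] = []
    for tr in classified:
        records.extend(segment_windows(tr, rois, window_min, max_windows))
    return windows_frame(records), summaries_frame(classified)
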