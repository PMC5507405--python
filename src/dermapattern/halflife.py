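"""Transcript decay rates and half-lives from transcription-blocked time courses.

After blocking transcription, abundance of a first-order-decaying transcript
follows ``rel_expr(t) = exp(-k t)`` once normalized to a stable reference
transcript and to its own t=0 level; the half-life is ``t_half = ln2 / k``.
Fast-turnover transcripts (t_half <= 90 min by default) that encode
extracellular pathway components and are detectably expressed are the
candidate drivers of rapid pattern formation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class EstimationError(ValueError):
    pass


@dataclass
class DecaySeries:
    gene: str
    times: np.ndarray       # minutes, strictly increasing, starts at 0
    rel_expr: np.ndarray    # normalized so rel_expr(0) == 1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rel_expr = np.asarray(self.rel_expr, dtype=float)
        if self.times[0] != 0:
            raise ValueError("series must include t = 0")
        if (np.diff(self.times) <= 0).any() or (self.times < 0).any():
            raise ValueError("times must be nonnegative and strictly increasing")


@dataclass
class HalfLifeEstimate:
    gene: str
    k: float            # 1/min, >= 0
    t_half: float       # minutes; inf when k == 0
    r_squared: float
    n_points: int
    stable: bool        # True when k == 0 (no measurable decay)
    se_k: float = float("nan")       # regression SE of k (log scale)
    se_t_half: float = float("nan")  # delta-method SE of t_half
    # noise-model internals, used for screen-level variance pooling
    log_rss: float = float("nan")
    log_rss_dof: float = float("nan")
    slope_var_factor: float = float("nan")


@dataclass
class CandidateFilter:
    t_half_max: float = 90.0
    require_extracellular: bool = True
    expression_floor: float = 0.0

    def __post_init__(self):
        if self.t_half_max <= 0:
            raise ValueError("t_half_max must be positive")


def normalize_series(
    gene: str,
    times: np.ndarray,
    raw: np.ndarray,
    reference: np.ndarray | None = None,
) -> DecaySeries:
    """rel_expr(t) = (raw(t)/reference(t)) / (raw(0)/reference(0))."""
    times = np.asarray(times, dtype=float)
    raw = np.asarray(raw, dtype=float)
    if (raw <= 0).any():
        raise ValueError(f"{gene}: abundances must be positive")
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != raw.shape:
            raise ValueError("reference grid does not match raw grid")
        if (reference <= 0).any():
            raise ValueError(f"{gene}: reference abundances must be positive")
        ratio = raw / reference
    else:
        ratio = raw
    return DecaySeries(gene, times, ratio / ratio[0])


def fit_decay(series: DecaySeries, free_intercept: bool = False) -> HalfLifeEstimate:
    """Least-squares exponential fit via log-linear regression.

    By default the intercept is fixed at 0 (rel_expr(0) == 1 by construction);
    ``free_intercept=True`` fits ln(rel_expr) = a - k t as a robustness check.
    The decay rate is clamped at >= 0 and R^2 is computed on the natural
    (exponential) scale.
    """
    usable = series.rel_expr > 0
    if not usable.all():
        warnings.warn(
            f"{series.gene}: dropped {int((~usable).sum())} nonpositive point(s)",
            stacklevel=2,
        )
    t = series.times[usable]
    y = series.rel_expr[usable]
    if len(t) < 3 or 0.0 not in t:
        raise EstimationError(f"{series.gene}: need >= 3 usable points including t=0")
    ln_y = np.log(y)
    if free_intercept:
        slope, _ = np.polyfit(t, ln_y, 1)
        dof = len(t) - 2
    else:
        # minimize sum (ln y - slope * t)^2  =>  slope = <t, ln y> / <t, t>
        slope = float(ln_y @ t / (t @ t)) if (t @ t) > 0 else 0.0
        dof = len(t) - 1
    k = max(0.0, -float(slope))
    rss, rss_dof, var_factor = _slope_se_parts(t, ln_y - slope * t, free_intercept)
    se_k = math.sqrt(rss / rss_dof * var_factor) if rss_dof > 0 else float("nan")
    se_t = math.log(2) / k**2 * se_k if k > 0 else float("nan")
    y_hat = np.exp(-k * t)
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    r2 = float(np.clip(r2, 0.0, 1.0))
    return HalfLifeEstimate(
        gene=series.gene,
        k=k,
        t_half=math.inf if k == 0 else math.log(2) / k,
        r_squared=r2,
        n_points=int(len(t)),
        stable=k == 0,
        se_k=se_k,
        se_t_half=se_t,
        log_rss=rss,
        log_rss_dof=rss_dof,
        slope_var_factor=var_factor,
    )


def _slope_se_parts(
    t: np.ndarray, resid: np.ndarray, free_intercept: bool
) -> tuple[float, float, float]:
    """Noise-model pieces for the log-linear slope SE: (rss, dof, var factor).

    Because every point is normalized to the (noisy) t=0 measurement, the
    log-scale errors share a common component: Cov = sigma^2 (I + 1 1^T)
    over the t>0 points.  The through-origin OLS slope keeps its point
    estimate but its variance, Var(slope) = sigma^2 * var_factor, and the
    residual-based sigma^2 = rss / dof are propagated under that
    covariance.  The free-intercept fit absorbs the common component, so
    the ordinary OLS formulas apply there.
    """
    nan = (float("nan"),) * 3
    if free_intercept:
        dof = len(t) - 2
        if dof <= 0:
            return nan
        tc = t - t.mean()
        return float(resid @ resid), float(dof), 1.0 / float(tc @ tc)
    pos = t > 0
    tp, r = t[pos], resid[pos]
    m = len(tp)
    if m < 2:
        return nan
    S2 = float(tp @ tp)
    H = np.outer(tp, tp) / S2
    omega = np.eye(m) + 1.0
    P = np.eye(m) - H
    dof = float(np.trace(P @ omega @ P))
    if dof <= 0:
        return nan
    return float(r @ r), dof, float(tp @ omega @ tp) / S2**2


def halflife_from_ratio(t: float, rel_expr: float) -> float:
    """Single post-block time point estimator: t_half = -t ln2 / ln(rel_expr).

    Paired-design closed form; returns inf when the transcript has not decayed.
    """
    if t <= 0 or rel_expr <= 0:
        raise ValueError("need t > 0 and rel_expr > 0")
    if rel_expr >= 1:
        return math.inf
    return -t * math.log(2) / math.log(rel_expr)


def fit_decay_table(df: pd.DataFrame, pooled_se: bool = True, **kwargs) -> pd.DataFrame:
    """Fit every gene in a long table gene,time_min,rel_expr (or with
    abundance[,reference_abundance] columns to be normalized first).

    With ``pooled_se`` (default) the log-scale noise variance is pooled
    across the whole screen — all transcripts share the measurement noise
    level — which makes the per-gene half-life standard errors well
    determined even from a handful of time points.
    """
    rows = []
    ests: list[HalfLifeEstimate] = []
    for gene, sub in df.groupby("gene", sort=True):
        sub = sub.sort_values("time_min")
        if "rel_expr" in sub.columns:
            series = DecaySeries(
                str(gene), sub["time_min"].to_numpy(), sub["rel_expr"].to_numpy()
            )
        else:
            ref = (
                sub["reference_abundance"].to_numpy()
                if "reference_abundance" in sub.columns
                else None
            )
            series = normalize_series(
                str(gene), sub["time_min"].to_numpy(), sub["abundance"].to_numpy(), ref
            )
        est = fit_decay(series, **kwargs)
        ests.append(est)
        rows.append(
            {
                "gene": est.gene,
                "k_per_min": est.k,
                "t_half_min": est.t_half,
                "r_squared": est.r_squared,
                "se_t_half_min": est.se_t_half,
                "n_points": est.n_points,
                "stable": est.stable,
            }
        )
    out = pd.DataFrame(rows)
    if pooled_se and len(ests) > 1:
        rss = np.nansum([e.log_rss for e in ests])
        dof = np.nansum([e.log_rss_dof for e in ests])
        if dof > 0:
            sigma2 = rss / dof
            se_k = np.sqrt(sigma2 * np.array([e.slope_var_factor for e in ests]))
            ks = out["k_per_min"].to_numpy()
            with np.errstate(divide="ignore"):
                out["se_t_half_min"] = np.where(ks > 0, np.log(2) / ks**2 * se_k, np.nan)
    return out


def filter_candidates(
    estimates: pd.DataFrame,
    annotation: pd.DataFrame,
    flt: CandidateFilter | None = None,
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the fast-turnover candidate filter with a per-criterion report.

    estimates: gene, t_half_min.  annotation: gene, class (ligand / receptor /
    extracellular antagonist / other) and optionally pathway.  expression:
    gene plus compartment abundance columns; a gene passes expression when any
    compartment is >= the floor.  The half-life threshold is inclusive.
    """
    flt = flt or CandidateFilter()
    extracellular = {"ligand", "receptor", "extracellular antagonist"}
    ann = annotation.set_index("gene")
    report = estimates[["gene", "t_half_min"]].copy()
    report["pass_half_life"] = report["t_half_min"] <= flt.t_half_max
    classes = report["gene"].map(ann["class"] if "class" in ann.columns else {})
    report["annotation"] = classes.fillna("unannotated")
    report["pass_extracellular"] = (
        classes.isin(extracellular) if flt.require_extracellular else True
    )
    if expression is not None:
        expr = expression.set_index("gene")
        levels = expr.select_dtypes("number")
        report["pass_expression"] = report["gene"].map(
            (levels >= flt.expression_floor).any(axis=1)
        ).fillna(False)
    else:
        report["pass_expression"] = True
    report["candidate"] = (
        report["pass_half_life"] & report["pass_extracellular"] & report["pass_expression"]
    )
    return report
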