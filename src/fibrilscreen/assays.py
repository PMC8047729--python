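"""Radioligand binding-assay models and fits.

Three designs are supported:

* single-concentration screens normalized to percent of specific binding,
  compared against a control group with one-way ANOVA plus Dunnett's
  many-to-one test (star tiers at p < 0.0332 / 0.0021 / 0.0002 / 0.0001);
* competition curves fit to the one-site displacement model
  ``Y = bottom + (top − bottom) / (1 + 10^(log10 x − log10 IC50))``
  (unit Hill slope), reporting IC50 with an asymptotic 95% CI computed on
  the log10 IC50 scale and back-transformed (hence asymmetric in molar);
* saturation curves fit to the binding hyperbola ``Y = Bmax·X/(Kd + X)``
  on specific binding (total minus matched nonspecific), with the Kd CI
  handled the same way on the log scale.

Dunnett-adjusted p-values are computed deterministically by double Gauss
quadrature over the shared-control factorization of the equicorrelated
multivariate t distribution; the construction is exact for unbalanced
group sizes as well.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

#: Figure-legend star convention.
DEFAULT_TIERS = ((0.0001, "****"), (0.0002, "***"), (0.0021, "**"), (0.0332, "*"))


class Condition(str, Enum):
    TOTAL = "TOTAL"
    NONSPECIFIC = "NONSPECIFIC"
    SAMPLE = "SAMPLE"


class DegenerateWindowError(ValueError):
    pass


class AssayDesignError(ValueError):
    pass


class FitFailureError(RuntimeError):
    pass


@dataclass(frozen=True)
class BindingMeasurement:
    compound_id: str
    site_label: str
    x: float  # molar (competitor or radioligand concentration)
    counts: float  # CPM
    replicate: int
    condition: Condition = Condition.SAMPLE

    def __post_init__(self):
        if self.x < 0:
            raise ValueError("concentration must be non-negative")
        if self.counts < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class CompetitionFit:
    ic50: float  # molar
    log_ic50: float  # log10 molar
    top: float
    bottom: float
    ci95_ic50: tuple[float, float]  # molar
    residual_sd: float
    n_points: int
    converged: bool = True


@dataclass(frozen=True)
class SaturationFit:
    kd: float  # molar
    bmax: float
    ci95_kd: tuple[float, float]
    residual_sd: float
    n_points: int
    ns_slope: float | None = None
    converged: bool = True


@dataclass(frozen=True)
class ScreenStats:
    compound_id: str
    mean_percent_bound: float
    sd: float
    n: int
    p_adj: float
    tier: str
    t_stat: float = float("nan")


def percent_bound(sample_counts: float, total_counts: float, nonspecific_counts: float) -> float:
    """Percent of the specific-binding window: 100·(sample − NS)/(total − NS)."""
    if total_counts <= nonspecific_counts:
        raise DegenerateWindowError("total binding must exceed nonspecific binding")
    value = 100.0 * (sample_counts - nonspecific_counts) / (total_counts - nonspecific_counts)
    if not -5.0 <= value <= 105.0:
        logger.warning("percent_bound %.1f%% outside the expected [0, 100] window", value)
    return value


# ---------------------------------------------------------------------------
# Curve models and fits
# ---------------------------------------------------------------------------

def competition_model(x, top, bottom, log_ic50):
    """One-site competition, unit Hill slope; x in molar."""
    with np.errstate(divide="ignore"):
        logx = np.log10(x)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (logx - log_ic50))


def saturation_model(x, bmax, log_kd):
    return bmax * x / (10.0 ** log_kd + x)


def _check_design(x: np.ndarray, min_levels: int = 5, min_span_log: float = 2.0):
    levels = np.unique(x)
    if levels.size < min_levels:
        raise AssayDesignError(
            f"need >= {min_levels} distinct concentrations, got {levels.size}"
        )
    span = np.log10(levels.max()) - np.log10(levels.min())
    if span < min_span_log:
        raise AssayDesignError(
            f"concentrations must span >= {min_span_log} log units (got {span:.2f})"
        )


def _ci_from_log_param(value_log: float, se_log: float, df: int) -> tuple[float, float]:
    tcrit = stats.t.ppf(0.975, df) if df > 0 else float("inf")
    return (10.0 ** (value_log - tcrit * se_log), 10.0 ** (value_log + tcrit * se_log))


def fit_competition(data: list[BindingMeasurement]) -> CompetitionFit:
    """Least-squares fit of the one-site displacement curve to SAMPLE records.

    All replicate points are fit directly (unweighted).  The 95% CI is
    asymptotic on log10 IC50.
    """
    pts = [m for m in data if m.condition == Condition.SAMPLE and m.x > 0]
    if not pts:
        raise AssayDesignError("no SAMPLE measurements with positive concentration")
    x = np.array([m.x for m in pts])
    y = np.array([m.counts for m in pts])
    _check_design(x)

    top0, bottom0 = float(y.max()), float(y.min())
    half = bottom0 + 0.5 * (top0 - bottom0)
    log_ic50_0 = float(np.log10(x[np.argmin(np.abs(y - half))]))
    try:
        popt, pcov = curve_fit(
            competition_model,
            x,
            y,
            p0=[top0, bottom0, log_ic50_0],
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"competition fit did not converge: {exc}") from exc
    top, bottom, log_ic50 = (float(v) for v in popt)
    if bottom > top:
        top, bottom = bottom, top  # orientation convention
    resid = y - competition_model(x, *popt)
    df = max(len(x) - 3, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / df))
    se_log = float(np.sqrt(max(pcov[2, 2], 0.0)))
    return CompetitionFit(
        ic50=10.0 ** log_ic50,
        log_ic50=log_ic50,
        top=top,
        bottom=bottom,
        ci95_ic50=_ci_from_log_param(log_ic50, se_log, df),
        residual_sd=residual_sd,
        n_points=len(x),
    )


def specific_binding(data: list[BindingMeasurement]) -> list[BindingMeasurement]:
    """TOTAL minus NONSPECIFIC, matched on (concentration, replicate).

    If replicate structure differs, the mean nonspecific signal at each
    concentration is subtracted instead.
    """
    totals = [m for m in data if m.condition == Condition.TOTAL]
    nonspec = [m for m in data if m.condition == Condition.NONSPECIFIC]
    if not totals or not nonspec:
        raise AssayDesignError("both TOTAL and NONSPECIFIC conditions are required")
    ns_by_key = {(m.x, m.replicate): m.counts for m in nonspec}
    ns_df = pd.DataFrame({"x": [m.x for m in nonspec], "counts": [m.counts for m in nonspec]})
    ns_mean_by_x = ns_df.groupby("x")["counts"].mean().to_dict()
    out = []
    for m in totals:
        ns = ns_by_key.get((m.x, m.replicate), ns_mean_by_x.get(m.x))
        if ns is None:
            raise AssayDesignError(f"no NONSPECIFIC measurement at x={m.x:g}")
        out.append(
            BindingMeasurement(
                compound_id=m.compound_id,
                site_label=m.site_label,
                x=m.x,
                counts=max(m.counts - ns, 0.0),
                replicate=m.replicate,
                condition=Condition.SAMPLE,
            )
        )
    return out


def fit_saturation(
    data: list[BindingMeasurement], subtract_nonspecific: bool = True
) -> SaturationFit:
    """Fit the binding hyperbola Y = Bmax·X/(Kd + X) to specific binding."""
    if subtract_nonspecific:
        pts = specific_binding(data)
    else:
        pts = [m for m in data if m.condition in (Condition.SAMPLE, Condition.TOTAL)]
    pts = [m for m in pts if m.x > 0]
    if not pts:
        raise AssayDesignError("no positive-concentration measurements")
    x = np.array([m.x for m in pts])
    y = np.array([m.counts for m in pts])
    _check_design(x, min_levels=5, min_span_log=1.0)

    bmax0 = float(y.max()) or 1.0
    half = 0.5 * bmax0
    log_kd0 = float(np.log10(x[np.argmin(np.abs(y - half))]))
    try:
        popt, pcov = curve_fit(
            saturation_model, x, y, p0=[bmax0, log_kd0], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitFailureError(f"saturation fit did not converge: {exc}") from exc
    bmax, log_kd = (float(v) for v in popt)
    resid = y - saturation_model(x, *popt)
    df = max(len(x) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / df))
    se_log = float(np.sqrt(max(pcov[1, 1], 0.0)))
    return SaturationFit(
        kd=10.0 ** log_kd,
        bmax=bmax,
        ci95_kd=_ci_from_log_param(log_kd, se_log, df),
        residual_sd=residual_sd,
        n_points=len(x),
    )


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparison
# ---------------------------------------------------------------------------

def _dunnett_max_cdf(
    q: np.ndarray, group_sizes: np.ndarray, n_control: int, df: int,
    n_z: int = 64, n_u: int = 64,
) -> np.ndarray:
    """P(max_j |T_j| ≤ q) for Dunnett statistics sharing one control group.

    Conditioning on the control mean (standard normal node z) and the pooled
    SD factor (u = S/σ) factorizes the joint probability into a product over
    groups; both integrals are evaluated by Gauss quadrature (Gauss–Hermite
    in z, Gauss–Legendre in u over the sqrt(χ²_ν/ν) density support).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    zs, zw = np.polynomial.hermite_e.hermegauss(n_z)  # weight exp(-z²/2)
    zw = zw / np.sqrt(2 * np.pi)
    u_lo = math.sqrt(stats.chi2.ppf(1e-12, df) / df)
    u_hi = math.sqrt(stats.chi2.ppf(1 - 1e-12, df) / df)
    us, uw = np.polynomial.legendre.leggauss(n_u)
    us = 0.5 * (us + 1) * (u_hi - u_lo) + u_lo
    uw = uw * 0.5 * (u_hi - u_lo)
    log_norm = (df / 2) * math.log(df / 2) - math.lgamma(df / 2) + math.log(2)
    u_dens = np.exp(log_norm + (df - 1) * np.log(us) - df * us**2 / 2)

    # shapes: z (Z,1,1), u (1,U,1), q (1,1,Q)
    z = zs[:, None, None]
    u = us[None, :, None]
    qq = q[None, None, :]
    prod = np.ones((n_z, n_u, q.size))
    for n_j in np.unique(group_sizes):
        count = int(np.sum(group_sizes == n_j))
        s_j = math.sqrt(1.0 / n_j + 1.0 / n_control)
        upper = math.sqrt(n_j) * (qq * u * s_j + z / math.sqrt(n_control))
        lower = math.sqrt(n_j) * (-qq * u * s_j + z / math.sqrt(n_control))
        term = stats.norm.cdf(upper) - stats.norm.cdf(lower)
        prod *= np.clip(term, 0.0, 1.0) ** count
    inner = np.einsum("zuq,u->zq", prod, uw * u_dens)
    return np.einsum("zq,z->q", inner, zw)


def dunnett_pvalues(
    t_obs: np.ndarray, group_sizes: np.ndarray, n_control: int, df: int
) -> np.ndarray:
    """Two-sided Dunnett-adjusted p-values for observed t statistics."""
    t_abs = np.abs(np.atleast_1d(np.asarray(t_obs, dtype=float)))
    p = 1.0 - _dunnett_max_cdf(t_abs, np.asarray(group_sizes), n_control, df)
    return np.clip(p, 0.0, 1.0)


def assign_tier(p_adj: float, tiers=DEFAULT_TIERS) -> str:
    for threshold, label in sorted(tiers):
        if p_adj < threshold:
            return label
    return "ns"


def dunnett_screen(
    groups: dict[str, np.ndarray],
    control: np.ndarray,
    tiers=DEFAULT_TIERS,
) -> tuple[float, list[ScreenStats]]:
    """One-way ANOVA plus Dunnett's many-to-one test against the control.

    Returns ``(F statistic, per-compound ScreenStats)``.  If every value in
    every group is identical the design is degenerate: F is NaN and all
    adjusted p-values are 1 by convention.
    """
    if len(groups) < 1:
        raise AssayDesignError("at least one treatment group is required")
    control = np.asarray(control, dtype=float)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in {**arrays, "control": control}.items():
        if arr.size < 2:
            raise AssayDesignError(f"group {name!r} needs n >= 2 replicates")

    all_values = np.concatenate([control, *arrays.values()])
    if np.ptp(all_values) == 0.0:
        logger.warning("degenerate screen: all observations identical")
        return float("nan"), [
            ScreenStats(k, float(np.mean(v)), 0.0, v.size, 1.0, "ns")
            for k, v in arrays.items()
        ]

    f_stat, _ = stats.f_oneway(control, *arrays.values())

    k = len(arrays)
    n0 = control.size
    sizes = np.array([v.size for v in arrays.values()])
    df = int(n0 + sizes.sum() - (k + 1))
    ss_within = np.sum((control - control.mean()) ** 2) + sum(
        np.sum((v - v.mean()) ** 2) for v in arrays.values()
    )
    pooled_var = ss_within / df
    if pooled_var <= 0:
        pooled_var = 1e-300  # all within-group variance zero but means differ
    t_stats = np.array(
        [
            (v.mean() - control.mean())
            / math.sqrt(pooled_var * (1.0 / v.size + 1.0 / n0))
            for v in arrays.values()
        ]
    )
    p_adj = dunnett_pvalues(t_stats, sizes, n0, df)
    results = [
        ScreenStats(
            compound_id=name,
            mean_percent_bound=float(v.mean()),
            sd=float(v.std(ddof=1)),
            n=int(v.size),
            p_adj=float(p),
            tier=assign_tier(float(p), tiers),
            t_stat=float(t),
        )
        for (name, v), p, t in zip(arrays.items(), p_adj, t_stats)
    ]
    return float(f_stat), results


# ---------------------------------------------------------------------------
# CSV interface (schema: compound_id, site, condition, x_molar, counts, replicate)
# ---------------------------------------------------------------------------

def read_measurements_csv(path) -> list[BindingMeasurement]:
    df = pd.read_csv(path)
    required = {"compound_id", "site", "condition", "x_molar", "counts", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay CSV missing columns: {sorted(missing)}")
    return [
        BindingMeasurement(
            compound_id=str(r.compound_id),
            site_label=str(r.site),
            x=float(r.x_molar),
            counts=float(r.counts),
            replicate=int(r.replicate),
            condition=Condition(str(r.condition)),
        )
        for r in df.itertuples()
    ]


def measurements_to_frame(data: list[BindingMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [m.compound_id for m in data],
            "site": [m.site_label for m in data],
            "condition": [m.condition.value for m in data],
            "x_molar": [m.x for m in data],
            "counts": [m.counts for m in data],
            "replicate": [m.replicate for m in data],
        }
    )
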