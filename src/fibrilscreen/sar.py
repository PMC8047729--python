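"""SAR free-energy correlation: ΔΔG pairs, regression, structure ranking.

Experimental relative binding free energies are derived from IC50 ratios to
a reference compound, ΔΔG = R·T·ln(IC50/IC50_ref) with R = 1.987×10⁻³
kcal mol⁻¹ K⁻¹ (T defaults to 310.15 K, the assay temperature).  Simulated
ΔΔG values come from pose-score differences to the same reference divided
by a fixed energy-unit scale (default 2.94 score units per kcal/mol).  For
each candidate fibril structure the two ΔΔG series are regressed (OLS) and
structures are ranked by R², ties by Kendall τ — the structure that best
explains the measured SAR ranks first.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GAS_CONSTANT_KCAL = 1.987e-3  # kcal mol⁻¹ K⁻¹
DEFAULT_TEMPERATURE = 310.15  # K (37 °C assay)
DEFAULT_SCORE_SCALE = 2.94  # score units per kcal/mol


class CensoredInputError(ValueError):
    """A right-censored affinity cannot be converted to a point ΔΔG."""


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class AffinityRecord:
    compound_id: str
    site_label: str
    ic50: float  # molar; for censored records, the bound
    ci95: tuple[float, float] | None = None
    censored: bool = False

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ValueError("ic50 (or its censoring bound) must be positive")


@dataclass(frozen=True)
class DDGPair:
    compound_id: str
    structure_id: str
    ddg_exp: float  # kcal/mol
    ddg_sim: float  # kcal/mol

    def __post_init__(self):
        if not (math.isfinite(self.ddg_exp) and math.isfinite(self.ddg_sim)):
            raise ValueError("ΔΔG values must be finite")


@dataclass(frozen=True)
class CorrelationReport:
    structure_id: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    rank_tau: float
    compound_ids: tuple[str, ...]


def ddg_from_ic50(
    ic50: float, ic50_ref: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """R·T·ln(IC50/IC50_ref), kcal/mol."""
    if ic50 <= 0 or ic50_ref <= 0:
        raise ValueError("concentrations must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(ic50 / ic50_ref)


def ddg_from_record(
    record: AffinityRecord, reference: AffinityRecord, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    if record.censored or reference.censored:
        raise CensoredInputError(
            f"censored affinity for {record.compound_id if record.censored else reference.compound_id}"
        )
    return ddg_from_ic50(record.ic50, reference.ic50, temperature)


def ddg_from_score(score: float, score_ref: float, scale: float = DEFAULT_SCORE_SCALE) -> float:
    """(score − score_ref)/scale, kcal/mol; lower scores are better binders."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return (score - score_ref) / scale


def build_ddg_pairs(
    affinities: list[AffinityRecord],
    scores,  # list of ScoreRecord-like (compound_id, structure_id, score)
    reference_compound: str,
    site_label: str,
    temperature: float = DEFAULT_TEMPERATURE,
    scale: float = DEFAULT_SCORE_SCALE,
    include_reference: bool = True,
    censored_policy: str = "exclude",  # or "bound"
) -> list[DDGPair]:
    """Match experimental and simulated ΔΔG per compound per structure.

    Censored affinities are excluded by default; ``censored_policy="bound"``
    maps them to their censoring bound (clearly an approximation).
    """
    by_compound = {
        a.compound_id: a for a in affinities if a.site_label == site_label
    }
    if reference_compound not in by_compound:
        raise InsufficientDataError(
            f"reference compound {reference_compound!r} missing for site {site_label!r}"
        )
    ref = by_compound[reference_compound]
    if ref.censored:
        raise CensoredInputError("reference compound affinity is censored")

    ref_scores = {
        s.structure_id: s.score for s in scores if s.compound_id == reference_compound
    }
    pairs = []
    for s in scores:
        aff = by_compound.get(s.compound_id)
        if aff is None or s.structure_id not in ref_scores:
            continue
        if aff.censored and censored_policy == "exclude":
            continue
        if s.compound_id == reference_compound and not include_reference:
            continue
        if aff.censored:
            exp = ddg_from_ic50(aff.ic50, ref.ic50, temperature)
        else:
            exp = ddg_from_record(aff, ref, temperature)
        sim = ddg_from_score(s.score, ref_scores[s.structure_id], scale)
        pairs.append(
            DDGPair(
                compound_id=s.compound_id,
                structure_id=s.structure_id,
                ddg_exp=exp,
                ddg_sim=sim,
            )
        )
    return pairs


def correlate(pairs: list[DDGPair]) -> CorrelationReport:
    """OLS of simulated on experimental ΔΔG plus Kendall rank agreement."""
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >= 3 ΔΔG pairs, got {len(pairs)}")
    structures = {p.structure_id for p in pairs}
    if len(structures) != 1:
        raise ValueError("correlate expects pairs from a single structure")
    x = np.array([p.ddg_exp for p in pairs])
    y = np.array([p.ddg_sim for p in pairs])
    fit = stats.linregress(x, y)
    tau = stats.kendalltau(x, y).statistic
    return CorrelationReport(
        structure_id=next(iter(structures)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(pairs),
        rank_tau=float(tau),
        compound_ids=tuple(p.compound_id for p in pairs),
    )


def rank_structures(reports: list[CorrelationReport]) -> list[CorrelationReport]:
    """Best-explaining structure first: R² desc, then τ desc, then id."""
    if not reports:
        raise InsufficientDataError("no correlation reports to rank")
    return sorted(reports, key=lambda r: (-r.r_squared, -r.rank_tau, r.structure_id))


# ---------------------------------------------------------------------------
# CSV / JSON interfaces
# ---------------------------------------------------------------------------

def read_affinity_csv(path) -> list[AffinityRecord]:
    """Schema: compound_id, site, ic50_nM, ci_low, ci_high, censored."""
    df = pd.read_csv(path)
    required = {"compound_id", "site", "ic50_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"affinity CSV missing columns: {sorted(missing)}")
    records = []
    for r in df.itertuples():
        ci = None
        if "ci_low" in df.columns and "ci_high" in df.columns:
            lo, hi = float(r.ci_low), float(r.ci_high)
            if np.isfinite(lo) and np.isfinite(hi):
                ci = (lo * 1e-9, hi * 1e-9)
        censored = bool(getattr(r, "censored", False))
        records.append(
            AffinityRecord(
                compound_id=str(r.compound_id),
                site_label=str(r.site),
                ic50=float(r.ic50_nM) * 1e-9,
                ci95=ci,
                censored=censored,
            )
        )
    return records


def report_to_dict(report: CorrelationReport) -> dict:
    return {
        "structure_id": report.structure_id,
        "slope": report.slope,
        "intercept": report.intercept,
        "r_squared": report.r_squared,
        "n": report.n,
        "rank_tau": report.rank_tau,
        "compound_ids": list(report.compound_ids),
    }


def reports_to_json(reports: list[CorrelationReport]) -> str:
    return json.dumps([report_to_dict(r) for r in reports], indent=2, sort_keys=True)


def scatter_table(pairs: list[DDGPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [p.compound_id for p in pairs],
            "structure_id": [p.structure_id for p in pairs],
            "ddg_exp": [p.ddg_exp for p in pairs],
            "ddg_sim": [p.ddg_sim for p in pairs],
        }
    )
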