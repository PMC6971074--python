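"""Cohort-level summaries: core geometry, clinical-table aggregates and
across-case composition statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PHENOTYPE_STATES

__all__ = ["core_area", "CohortSummary", "summarize_clinical",
           "aggregate_composition", "format_report"]

FIGO_BUCKETS = ("IB", "IIB", "IIIB/C", "IVB", "unknown")


def core_area(n_cores: int = 2, diameter_mm: float = 2.0) -> float:
    """Analyzed tissue area in mm²: n circular cores of the given diameter.

    The standard design — two random 2 mm cores per case — gives
    2 · π · 1² ≈ 6.28 mm² (≈ 40 high-power fields)."""
    if n_cores < 1:
        raise ValueError("n_cores must be >= 1")
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be > 0")
    return n_cores * math.pi * (diameter_mm / 2.0) ** 2


@dataclass
class CohortSummary:
    n_cases: int
    age_mean: float
    age_sd: float
    age_min: float
    age_max: float
    pct_postmenopausal: int
    figo_counts: dict
    tmn_stage_counts: dict
    phenotype_state_counts: dict
    composition_mean: dict | None = None
    composition_sd: dict | None = None
    flags: list = field(default_factory=list)


def _figo_bucket(value) -> str:
    if pd.isna(value):
        return "unknown"
    v = str(value)
    if v in ("IIIB", "IIIC"):
        return "IIIB/C"
    return v


def summarize_clinical(clinical: pd.DataFrame) -> CohortSummary:
    """Cohort aggregates of the validated clinical table.

    Ages use the sample (n−1) standard deviation; the post-menopausal
    share is rounded to an integer percent; TMN is tallied by its
    leading stage token (pT1/pT2/pT3, NA excluded); FIGO stages IIIB and
    IIIC are pooled. Raw values are kept at full precision — rounding
    happens only in ``format_report``.
    """
    if not len(clinical):
        raise ValueError("empty clinical table")
    ages = clinical["age"].to_numpy(dtype=float)
    flags = []
    if len(ages) > 1:
        sd = float(np.std(ages, ddof=1))
    else:
        sd = 0.0
        flags.append("age_sd undefined for a single case; reported as 0")
    pct = int(round(100.0 * (clinical["menopause"] == "Yes").mean()))
    tmn = clinical["tmn"].dropna().astype(str)
    tmn_counts: dict[str, int] = {}
    for v in tmn:
        token = v[:3]  # pT1 / pT2 / pT3
        tmn_counts[token] = tmn_counts.get(token, 0) + 1
    figo_counts = {b: 0 for b in FIGO_BUCKETS}
    for v in clinical["figo"]:
        figo_counts[_figo_bucket(v)] += 1
    figo_counts = {b: c for b, c in figo_counts.items() if c}
    state_counts = {s: int((clinical["predominant_phenotype"] == s).sum())
                    for s in PHENOTYPE_STATES
                    if (clinical["predominant_phenotype"] == s).any()}
    return CohortSummary(
        n_cases=len(clinical),
        age_mean=float(ages.mean()), age_sd=sd,
        age_min=float(ages.min()), age_max=float(ages.max()),
        pct_postmenopausal=pct,
        figo_counts=figo_counts,
        tmn_stage_counts=dict(sorted(tmn_counts.items())),
        phenotype_state_counts=state_counts,
        flags=flags,
    )


def aggregate_composition(compositions) -> pd.DataFrame:
    """Across-case mean ± sample sd of per-type composition percentages.

    ``compositions`` is a sequence of ``type -> percent`` maps (one per
    case); a type absent from a case counts as 0%. With fewer than two
    cases the sd is NA.
    """
    comps = list(compositions)
    if not comps:
        raise ValueError("no compositions given")
    types = sorted({t for c in comps for t in c})
    mat = np.array([[c.get(t, 0.0) for t in types] for c in comps], dtype=float)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(comps) > 1 else np.full(len(types), np.nan)
    return pd.DataFrame({"mean_pct": mean, "sd_pct": sd}, index=pd.Index(types, name="cell_type"))


def format_report(summary: CohortSummary) -> str:
    """Human-readable cohort report (means to 1 decimal, percents integer)."""
    lines = [
        f"Cases: {summary.n_cases}",
        f"Age: {summary.age_mean:.1f} +/- {summary.age_sd:.1f} years "
        f"({summary.age_min:.0f}-{summary.age_max:.0f})",
        f"Post-menopausal: {summary.pct_postmenopausal}%",
        "TMN: " + ", ".join(f"{k}: {v}" for k, v in summary.tmn_stage_counts.items()),
        "FIGO: " + ", ".join(f"{k}: {v}" for k, v in summary.figo_counts.items()),
        "Predominant T-cell phenotype: "
        + ", ".join(f"{k}: {v}" for k, v in summary.phenotype_state_counts.items()),
    ]
    if summary.composition_mean:
        lines.append("Composition (% of infiltrate): " + ", ".join(
            f"{t}: {m:.0f}+/-{summary.composition_sd.get(t, float('nan')):.0f}"
            for t, m in summary.composition_mean.items()))
    for f in summary.flags:
        lines.append(f"NOTE: {f}")
    return "\n".join(lines)
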