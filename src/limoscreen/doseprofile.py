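"""Creatinine-normalised quantitative profiling and dose accounting.

Urinary metabolite intensities are divided by urinary creatinine to correct
for urine concentration, averaged per dose group, and expressed as percent
of the summed metabolite signal per group.  Comparing the percent profiles
of a low- and a high-dose group exposes "metabolic switching": routes whose
share of the total grows or shrinks with dose.  Two-group comparisons are
routed by a Shapiro-Wilk normality check to either a two-sample t-test or
the Wilcoxon rank-sum test.  Small helpers cover the dose arithmetic
(percent loss of a volatile supplement during feed production, and the
body-surface-area based animal-to-human dose conversion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleMeta",
    "normalize_by_creatinine",
    "group_means",
    "percent_of_total",
    "profile_table",
    "group_compare",
    "switching_report",
    "percent_loss",
    "human_equivalent_dose",
    "KM_MOUSE",
    "KM_HUMAN",
]

#: FDA body-surface-area conversion factors (dose mg/kg x Km_animal/Km_human)
KM_MOUSE = 3.0
KM_HUMAN = 37.0


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: dose group, tissue and urinary creatinine."""

    sample_id: str
    group: str
    tissue: str = "urine"
    creatinine: Optional[float] = None

    def __post_init__(self):
        if self.tissue not in ("urine", "liver"):
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.creatinine is not None and self.creatinine <= 0:
            raise ValueError("creatinine must be positive when given")


def normalize_by_creatinine(intensity: float, creatinine: float) -> float:
    """Divide a urinary intensity by the sample's creatinine concentration."""
    if creatinine <= 0:
        raise ValueError("creatinine must be positive")
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    return intensity / creatinine


def group_means(
    normalized: pd.DataFrame, groups: Dict[str, str]
) -> pd.DataFrame:
    """Mean and SD per (metabolite, group) from a metabolite x sample table.

    Zeros are real observations: a non-detected metabolite contributes 0 to
    its group mean.
    """
    long = normalized.T
    long["__group"] = [groups[s] for s in long.index]
    g = long.groupby("__group")
    means = g.mean().T
    sds = g.std(ddof=1).T
    return pd.concat({"mean": means, "sd": sds}, axis=1)


def percent_of_total(means: pd.Series) -> pd.Series:
    """Each metabolite's share (in %) of the summed group means."""
    if (means < 0).any():
        raise ValueError("negative group mean")
    total = means.sum()
    if total <= 0:
        raise ValueError("all-zero group: percent of total undefined")
    return means / total * 100.0


def profile_table(
    intensities: pd.DataFrame,
    meta: Sequence[SampleMeta],
    tissue: str = "urine",
) -> pd.DataFrame:
    """Full profile: creatinine-normalise, average per group, add percents.

    ``intensities`` is metabolite x sample.  Returns a table indexed by
    metabolite with a (statistic, group) column MultiIndex carrying mean,
    sd and percent-of-total per group.
    """
    by_id = {m.sample_id: m for m in meta}
    cols = [c for c in intensities.columns
            if c in by_id and by_id[c].tissue == tissue]
    if not cols:
        raise ValueError(f"no {tissue} samples in intensity table")
    norm = intensities[cols].copy()
    if tissue == "urine":
        for c in cols:
            if by_id[c].creatinine is None:
                raise ValueError(f"sample {c} lacks creatinine")
            norm[c] = norm[c] / by_id[c].creatinine
    groups = {c: by_id[c].group for c in cols}
    gm = group_means(norm, groups)
    pct = gm["mean"].apply(percent_of_total, axis=0)
    return pd.concat({"mean": gm["mean"], "sd": gm["sd"], "percent": pct}, axis=1)


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # "t" or "ranksum"
    statistic: float
    pvalue: float
    shapiro_p: tuple  # per-group Shapiro-Wilk p-values


def group_compare(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Two-group comparison routed by normality.

    Both groups must pass Shapiro-Wilk at ``alpha`` for the two-sided
    two-sample t-test; otherwise the Wilcoxon rank-sum test is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    sp_a = stats.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
    sp_b = stats.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0
    if sp_a > alpha and sp_b > alpha:
        res = stats.ttest_ind(a, b)
        return ComparisonResult("t", float(res.statistic), float(res.pvalue),
                                (sp_a, sp_b))
    res = stats.ranksums(a, b)
    return ComparisonResult("ranksum", float(res.statistic), float(res.pvalue),
                            (sp_a, sp_b))


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Optional Benjamini-Hochberg adjustment (off by default in reports)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float))


def switching_report(
    percent_low: pd.Series,
    percent_high: pd.Series,
    dead_band: float = 0.5,
) -> pd.DataFrame:
    """Per-metabolite change in percent participation between two doses.

    ``delta = percent_high - percent_low`` (percentage points); metabolites
    are classed increased/decreased/stable with a ``dead_band`` around zero.
    """
    if set(percent_low.index) != set(percent_high.index):
        raise ValueError("metabolite sets differ between profiles")
    high = percent_high.reindex(percent_low.index)
    delta = high - percent_low
    direction = pd.Series(
        np.where(delta > dead_band, "increased",
                 np.where(delta < -dead_band, "decreased", "stable")),
        index=delta.index,
    )
    out = pd.DataFrame({
        "percent_low": percent_low,
        "percent_high": high,
        "delta": delta,
        "direction": direction,
    })
    return out.sort_values("delta", ascending=False)


def percent_loss(nominal: float, measured: float) -> float:
    """Percent loss of content relative to the nominal formulation."""
    if nominal <= 0:
        raise ValueError("nominal content must be positive")
    return (nominal - measured) / nominal * 100.0


def human_equivalent_dose(
    animal_dose: float, km_animal: float = KM_MOUSE, km_human: float = KM_HUMAN
) -> float:
    """Body-surface-area scaled human equivalent dose, mg/kg.

    ``HED = dose x Km_animal / Km_human`` with the standard factors
    (mouse 3, human 37).  A zero dose maps to zero.
    """
    if animal_dose < 0:
        raise ValueError("dose must be >= 0")
    if km_animal <= 0 or km_human <= 0:
        raise ValueError("Km factors must be positive")
    return animal_dose * km_animal / km_human
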