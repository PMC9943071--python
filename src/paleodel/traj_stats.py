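"""Allele-frequency stability and companion-based deletion annotation.

The chi-square stability statistic quantifies how much a variant's
lineage-based allele frequency moved between 50,000 and 5,000 years
before present.  For each variant, f(t) is the fraction of the remaining
ancestral lineages of the present-day sample that carry the derived
allele at time t.  The raw change Delta = f(5 ky) - f(50 ky) is
standardized within strata of present-day allele frequency and squared;
under neutrality the statistic is approximately chi-square with one
degree of freedom, and balanced (stable) variants show smaller values.

Deletions themselves carry no published ages or balancing-selection
scores, so both are transferred from the SNVs in LD with the deletion:
age as the maximum (joint-clock median ages) or as the mean over
companions tagging at r^2 > 0.9; the stdbeta2 balancing-selection score
either as the maximum over companions (BETAMAX) or as the score of the
closest companion among those with the highest r^2 (BETAPRIME).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ld_classify import LDCompanion

__all__ = [
    "chi2_stability",
    "assign_age_hgd",
    "assign_age_mean",
    "assign_beta",
    "annotate_deletions",
    "rank_sum_compare",
]


def _nearest_time(times: np.ndarray, target: float) -> float:
    return float(times[np.argmin(np.abs(times - target))])


def chi2_stability(trajectories: pd.DataFrame, t_recent: float = 5_000.0,
                   t_old: float = 50_000.0, min_lineage_frac: float = 0.10,
                   n_strata: int = 10) -> pd.DataFrame:
    """Chi-square stability statistic per variant.

    ``trajectories``: tidy frame with columns variant_id, time_years,
    derived_lineages, total_lineages, n_sample and present_derived (see
    :func:`paleodel.demog.lineage_trajectories`).  Frequencies are read at
    the grid times nearest ``t_recent`` and ``t_old``.  Variants whose
    remaining lineage count at ``t_old`` does not exceed
    ``min_lineage_frac`` of the present-day sample size are excluded.
    Delta is standardized within ``n_strata`` quantile bins of present-day
    frequency; a stratum with fewer than 2 members cannot provide a
    standard deviation and its variants are flagged unstandardizable; a
    stratum whose deltas are all equal (zero SD) yields z = 0.

    Returns a per-variant frame with columns: variant_id, present_freq,
    f_recent, f_old, delta, included, stratum, z, chi2.
    """
    required = {"variant_id", "time_years", "derived_lineages",
                "total_lineages", "n_sample", "present_derived"}
    missing = required - set(trajectories.columns)
    if missing:
        raise ValueError(f"trajectory table lacks columns: {sorted(missing)}")
    times = np.sort(trajectories["time_years"].unique())
    tr = _nearest_time(times, t_recent)
    to = _nearest_time(times, t_old)
    recent = trajectories[trajectories["time_years"] == tr].set_index("variant_id")
    old = trajectories[trajectories["time_years"] == to].set_index("variant_id")
    df = pd.DataFrame({
        "variant_id": recent.index,
        "n_sample": recent["n_sample"],
        "present_freq": recent["present_derived"] / recent["n_sample"],
        "f_recent": recent["derived_lineages"] / recent["total_lineages"],
        "f_old": old["derived_lineages"] / old["total_lineages"],
        "lineages_old": old["total_lineages"],
    }).reset_index(drop=True)
    df["delta"] = df["f_recent"] - df["f_old"]
    df["included"] = df["lineages_old"] > min_lineage_frac * df["n_sample"]
    df["stratum"] = pd.Series(pd.NA, index=df.index, dtype="object")
    df["z"] = np.nan
    df["chi2"] = np.nan
    inc = df["included"]
    if inc.any():
        strata = pd.qcut(df.loc[inc, "present_freq"], q=n_strata,
                         duplicates="drop", labels=False)
        df.loc[inc, "stratum"] = strata
        for _, idx in df.loc[inc].groupby("stratum", sort=False).groups.items():
            deltas = df.loc[idx, "delta"]
            if len(idx) < 2:
                continue  # unstandardizable: z stays NaN
            sd = deltas.std(ddof=1)
            # all-equal deltas: guard against floating noise in the SD
            if sd <= 1e-12 * max(1.0, float(np.abs(deltas).max())):
                z = np.zeros(len(idx))
            else:
                z = (deltas - deltas.mean()) / sd
            df.loc[idx, "z"] = z
            df.loc[idx, "chi2"] = np.asarray(z) ** 2
    return df


def _ages_of(companions, age_table: Mapping[str, float]) -> list[float]:
    out = []
    for c in companions:
        key = c.snv_id if isinstance(c, LDCompanion) else c
        if key in age_table and not pd.isna(age_table[key]):
            out.append(float(age_table[key]))
    return out


def assign_age_hgd(companions: Sequence, age_table: Mapping[str, float]) -> float:
    """Deletion age as the highest companion age estimate (dating-database
    rule).  Returns NaN when no companion has an age row."""
    ages = _ages_of(companions, age_table)
    return max(ages) if ages else float("nan")


def assign_age_mean(companions: Sequence[LDCompanion],
                    age_table: Mapping[str, float],
                    r2_min: float = 0.9) -> float:
    """Deletion age as the mean age of companions tagging the deletion at
    r^2 above ``r2_min`` (genealogy-based rule).  NaN when none qualify."""
    tagging = [c for c in companions if c.r2 > r2_min]
    ages = _ages_of(tagging, age_table)
    return float(np.mean(ages)) if ages else float("nan")


def assign_beta(companions: Sequence[LDCompanion],
                score_table: Mapping[str, float],
                mode: str = "BETAMAX") -> float:
    """stdbeta2 estimate for a deletion from its scored companions.

    BETAMAX: highest score among companions.  BETAPRIME: among companions
    attaining the maximal r^2, the score of the one nearest the deletion
    (distance ties broken by lower position).  NaN when no companion has
    a score row.
    """
    scored = [c for c in companions
              if c.snv_id in score_table and not pd.isna(score_table[c.snv_id])]
    if not scored:
        return float("nan")
    if mode == "BETAMAX":
        return float(max(score_table[c.snv_id] for c in scored))
    if mode == "BETAPRIME":
        top_r2 = max(c.r2 for c in scored)
        top = [c for c in scored if c.r2 == top_r2]
        chosen = min(top, key=lambda c: (c.distance, c.position))
        return float(score_table[chosen.snv_id])
    raise ValueError("mode must be BETAMAX or BETAPRIME")


def annotate_deletions(companions_by_deletion: Mapping[str, Sequence[LDCompanion]],
                       age_table: Mapping[str, float],
                       score_table: Mapping[str, float],
                       r2_min: float = 0.9) -> pd.DataFrame:
    """Per-deletion table of age_hgd, age_mean, betamax and betaprime."""
    rows = []
    for del_id, comps in companions_by_deletion.items():
        rows.append((del_id,
                     assign_age_hgd(comps, age_table),
                     assign_age_mean(comps, age_table, r2_min=r2_min),
                     assign_beta(comps, score_table, mode="BETAMAX"),
                     assign_beta(comps, score_table, mode="BETAPRIME")))
    return pd.DataFrame(rows, columns=["deletion_id", "age_hgd", "age_mean",
                                       "betamax", "betaprime"])


def rank_sum_compare(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of a statistic between two
    deletion sets (e.g. chi2 or stdbeta2 of ancient vs non-ancient).
    NaNs are dropped.  Returns (U statistic, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty after NaN removal")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
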