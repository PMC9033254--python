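"""Germination-stage trait computation for alkali-tolerance screens.

A 7-day Petri-dish germination assay yields, per accession x condition x
replicate, the number of newly germinated seeds on each day plus end-point
root and shoot lengths.  From these we compute the seven germination-related
traits under each condition (suffix ``S`` for alkali stress, ``C`` for
control) and the seven stress:control ratio traits (prefix ``R``), the
panel-level summaries (range, mean, SD, CV), trait correlations, relative
alkali damage, and subpopulation comparisons.

Traits
------
GR   germination rate: cumulative germinated fraction at day 7.
GE   germination energy: cumulative germinated fraction at day 3.
GI   germination index: (1/N0) * sum_t C_t / t over days 1..7, where C_t is
     the cumulative germinated count through day t.  Rewards early
     germination; maximum sum(1/t for t=1..7) ~ 2.593 when every seed
     germinates on day 1.
MGT  mean germination time: count-weighted mean day of new germinations;
     undefined (missing) when nothing germinated.
VI   vigor index: mean shoot length (cm) x GI.
RL / SL  mean root / shoot length (cm) at day 7.

Ratio traits (RGR, RGE, RGI, RMGT, RVI, RRL, RSL) divide the
replicate-averaged stress value by the replicate-averaged control value and
are the assay's alkali-damage metric; a ratio is missing when the control
value is zero or either side is missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

N_DAYS = 7
CONDITIONS = ("control", "stress")

#: Condition traits in canonical (Table-style) column order.
CONDITION_TRAITS = (
    "MGTS", "MGTC", "GRS", "GRC", "GIS", "GIC", "VIS", "VIC",
    "RLS", "RLC", "SLS", "SLC", "GES", "GEC",
)
#: Stress:control ratio traits.
RATIO_TRAITS = ("RMGT", "RGR", "RGI", "RVI", "RRL", "RSL", "RGE")
ALL_TRAITS = CONDITION_TRAITS + RATIO_TRAITS

#: Base trait name -> ratio trait name.
_RATIO_OF = {
    "MGT": "RMGT", "GR": "RGR", "GI": "RGI", "VI": "RVI",
    "RL": "RRL", "SL": "RSL", "GE": "RGE",
}

GI_MAX = float(sum(1.0 / t for t in range(1, N_DAYS + 1)))


@dataclass
class GerminationCounts:
    """Daily new-germination counts for one accession x condition x replicate.

    ``new_counts[t-1]`` is the number of seeds newly germinated on day ``t``
    (t = 1..7); ``n0`` is the number of seeds sown.  ``root_length_cm`` /
    ``shoot_length_cm`` are the replicate's mean measured lengths, or None
    when not measured.
    """

    accession_id: str
    condition: str
    replicate: int
    n0: int
    new_counts: np.ndarray
    root_length_cm: float | None = None
    shoot_length_cm: float | None = None

    def __post_init__(self) -> None:
        self.new_counts = np.asarray(self.new_counts, dtype=int)
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.new_counts.shape != (N_DAYS,):
            raise ValueError(f"new_counts must have length {N_DAYS}")
        if (self.new_counts < 0).any():
            raise ValueError("negative germination count")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if int(self.new_counts.sum()) > self.n0:
            raise ValueError(
                f"germinated seeds ({int(self.new_counts.sum())}) exceed "
                f"total seeds ({self.n0}) for accession {self.accession_id!r} "
                f"({self.condition}, replicate {self.replicate})"
            )

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.new_counts)

    @property
    def total_germinated(self) -> int:
        return int(self.new_counts.sum())


# ---------------------------------------------------------------------------
# single-assay trait values
# ---------------------------------------------------------------------------

def germination_rate(counts: GerminationCounts, day: int) -> float:
    """Cumulative germinated fraction through ``day`` (GR: day 7, GE: day 3)."""
    if not 1 <= day <= N_DAYS:
        raise ValueError(f"day must be in 1..{N_DAYS}, got {day}")
    if counts.n0 == 0:
        raise ValueError("n0 is zero")
    return float(counts.cumulative[day - 1]) / counts.n0


def mean_germination_time(counts: GerminationCounts) -> float:
    """Count-weighted mean day of new germinations; NaN if none germinated."""
    total = counts.total_germinated
    if total == 0:
        logger.debug(
            "MGT undefined (zero germination) for %s/%s/r%d",
            counts.accession_id, counts.condition, counts.replicate,
        )
        return math.nan
    days = np.arange(1, N_DAYS + 1)
    return float((days * counts.new_counts).sum() / total)


def germination_index(counts: GerminationCounts) -> float:
    """(1/N0) * sum over days of cumulative-count / day."""
    if counts.n0 == 0:
        raise ValueError("n0 is zero")
    days = np.arange(1, N_DAYS + 1)
    return float((counts.cumulative / days).sum() / counts.n0)


def vigor_index(mean_shoot_length: float | None, gi: float | None) -> float:
    """Mean shoot length (cm) times germination index; NaN if either missing."""
    if mean_shoot_length is None or gi is None:
        return math.nan
    if math.isnan(mean_shoot_length) or math.isnan(gi):
        return math.nan
    if mean_shoot_length < 0 or gi < 0:
        raise ValueError("vigor index inputs must be non-negative")
    return float(mean_shoot_length * gi)


def _replicate_traits(counts: GerminationCounts) -> dict[str, float]:
    gr = germination_rate(counts, N_DAYS)
    ge = germination_rate(counts, 3)
    gi = germination_index(counts)
    mgt = mean_germination_time(counts)
    rl = math.nan if counts.root_length_cm is None else float(counts.root_length_cm)
    sl = math.nan if counts.shoot_length_cm is None else float(counts.shoot_length_cm)
    vi = vigor_index(sl, gi) if not math.isnan(sl) else math.nan
    return {"MGT": mgt, "GR": gr, "GI": gi, "VI": vi, "RL": rl, "SL": sl, "GE": ge}


# ---------------------------------------------------------------------------
# per-accession trait table
# ---------------------------------------------------------------------------

def ratio_traits(stress: Mapping[str, float], control: Mapping[str, float]) -> dict[str, float]:
    """Stress/control ratios of the seven base traits.

    ``stress`` and ``control`` map base trait names (MGT, GR, ...) to
    replicate-averaged values.  A ratio is NaN when the control value is zero
    or either value is missing.
    """
    out: dict[str, float] = {}
    for base, name in _RATIO_OF.items():
        s = stress.get(base, math.nan)
        c = control.get(base, math.nan)
        if c is None or s is None or math.isnan(c) or math.isnan(s) or c == 0:
            out[name] = math.nan
        else:
            out[name] = s / c
    return out


def compute_trait_table(counts: Iterable[GerminationCounts]) -> pd.DataFrame:
    """Per-accession table of the 21 traits (14 condition + 7 ratio).

    Traits are computed per replicate, averaged over replicates within a
    condition (NaN replicates excluded), and the ratio traits are formed from
    the replicate-averaged condition values.
    """
    per_acc: dict[str, dict[str, list[dict[str, float]]]] = {}
    for gc in counts:
        per_acc.setdefault(gc.accession_id, {}).setdefault(gc.condition, []).append(
            _replicate_traits(gc)
        )

    rows = []
    for acc in sorted(per_acc):
        avg: dict[str, dict[str, float]] = {}
        for cond in CONDITIONS:
            reps = per_acc[acc].get(cond, [])
            avg[cond] = {}
            for base in _RATIO_OF:
                vals = [r[base] for r in reps if not math.isnan(r[base])]
                avg[cond][base] = float(np.mean(vals)) if vals else math.nan
        row: dict[str, float] = {}
        for base in _RATIO_OF:
            row[base + "S"] = avg["stress"][base]
            row[base + "C"] = avg["control"][base]
        row.update(ratio_traits(avg["stress"], avg["control"]))
        rows.append(pd.Series(row, name=acc))

    table = pd.DataFrame(rows)
    table.index.name = "accession_id"
    return table.reindex(columns=list(ALL_TRAITS))


# ---------------------------------------------------------------------------
# panel-level summaries
# ---------------------------------------------------------------------------

def summarize_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Range, mean, sample SD (ddof=1) and CV=SD/mean per trait column."""
    rows = []
    for trait in table.columns:
        vals = table[trait].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            rows.append({"trait": trait, "min": math.nan, "max": math.nan,
                         "mean": math.nan, "sd": math.nan, "cv": math.nan,
                         "n": len(vals)})
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        cv = sd / mean if mean != 0 else math.nan
        rows.append({"trait": trait, "min": float(vals.min()),
                     "max": float(vals.max()), "mean": mean, "sd": sd,
                     "cv": cv, "n": len(vals)})
    return pd.DataFrame(rows).set_index("trait")


def relative_damage(ratio_means: Mapping[str, float]) -> pd.DataFrame:
    """Percentage alkali damage per trait from mean ratio-trait values.

    MGT is *delayed* under stress, so its damage is 100*(mean RMGT - 1); the
    other six traits are *reduced*, damage 100*(1 - mean ratio).  Returns a
    table sorted by decreasing damage with columns ``base_trait``, ``kind``
    (delay/reduction) and ``percent``.
    """
    rows = []
    for base, rname in _RATIO_OF.items():
        if rname not in ratio_means:
            continue
        m = float(ratio_means[rname])
        if base == "MGT":
            rows.append({"base_trait": base, "kind": "delay",
                         "percent": 100.0 * (m - 1.0)})
        else:
            rows.append({"base_trait": base, "kind": "reduction",
                         "percent": 100.0 * (1.0 - m)})
    out = pd.DataFrame(rows).sort_values("percent", ascending=False)
    return out.reset_index(drop=True)


def correlate_traits(table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Spearman correlation matrix (tie-corrected ranks)."""
    cols = list(table.columns)
    n = len(cols)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        mat[i, i] = 1.0
        for j in range(i + 1, n):
            x = table[cols[i]].to_numpy(dtype=float)
            y = table[cols[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < min_pairs:
                continue
            rho = stats.spearmanr(x[ok], y[ok]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=cols, columns=cols)


@dataclass
class GroupComparison:
    """One-way ANOVA across groups plus two-tailed t-tests for one pair."""

    anova_f: float
    anova_p: float
    t_pooled: float
    p_pooled: float
    t_welch: float
    p_welch: float
    group_means: dict[str, float]


def compare_subpopulations(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    trait: str,
    pair: tuple[str, str] = ("Xian", "Geng"),
) -> GroupComparison:
    """ANOVA across all subpopulations and t-tests for one stated pair.

    ``metadata`` must have columns ``accession_id`` and ``subpopulation``.
    Groups with fewer than 2 non-missing values are excluded from the ANOVA.
    """
    sub = metadata.set_index("accession_id")["subpopulation"]
    vals = table[trait].dropna()
    groups: dict[str, np.ndarray] = {}
    for name, grp in vals.groupby(sub.reindex(vals.index)):
        if len(grp) >= 2:
            groups[str(name)] = grp.to_numpy(dtype=float)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >=2 members each")
    f, p = stats.f_oneway(*groups.values())
    a, b = pair
    if a not in groups or b not in groups:
        raise ValueError(f"pair {pair} not present among groups {sorted(groups)}")
    if np.array_equal(groups[a], groups[b]):
        tp, pp = 0.0, 1.0
        tw, pw = 0.0, 1.0
    else:
        tp, pp = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        tw, pw = stats.ttest_ind(groups[a], groups[b], equal_var=False)
    return GroupComparison(
        anova_f=float(f), anova_p=float(p),
        t_pooled=float(tp), p_pooled=float(pp),
        t_welch=float(tw), p_welch=float(pw),
        group_means={k: float(v.mean()) for k, v in groups.items()},
    )
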