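"""Extreme-phenotype group construction and high-vs-low comparisons.

Animals are ranked by a fiber degradation phenotype after a single
mean +/- k*SD outlier exclusion; the top and bottom n form the high and
low groups.  Traits and genus abundances are then compared between the
groups with two-sample t-tests: traits at p < 0.05, genus-level
differential abundance at p < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CompositionMatrix

__all__ = [
    "GroupAssignment",
    "trim_outliers",
    "extreme_groups",
    "group_ttest",
    "group_overlap",
    "differential_abundance",
    "compare_traits",
]


@dataclass(frozen=True)
class GroupAssignment:
    """High/low extreme groups for one phenotype.

    ``excluded_ids`` are the outlier-trimmed samples; ``high_ids`` and
    ``low_ids`` are disjoint and each of size ``n_per_group``.
    """

    phenotype: str
    high_ids: Tuple[str, ...]
    low_ids: Tuple[str, ...]
    excluded_ids: Tuple[str, ...] = ()
    n_per_group: int = 10
    sd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if set(self.high_ids) & set(self.low_ids):
            raise ValueError("high and low groups must be disjoint")
        if len(self.high_ids) != self.n_per_group or len(self.low_ids) != self.n_per_group:
            raise ValueError("group sizes must equal n_per_group")


def trim_outliers(values: pd.Series, k: float = 2.0) -> pd.Series:
    """Boolean keep-mask excluding values beyond mean +/- k * sample SD.

    A single pass: mean and SD (ddof=1) are computed once on all values;
    no iterative re-trimming.  All-equal input keeps everything.
    """
    v = values.to_numpy(dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 values to trim outliers")
    mu, sd = v.mean(), v.std(ddof=1)
    mask = (v >= mu - k * sd) & (v <= mu + k * sd)
    return pd.Series(mask, index=values.index)


def extreme_groups(values: pd.Series, n: int = 10, phenotype: str = "phenotype",
                   excluded: Tuple[str, ...] = (), sd_multiplier: float = 2.0) -> GroupAssignment:
    """Assign the n highest and n lowest samples to high/low groups.

    ``values`` is an already-trimmed phenotype vector indexed by sample ID.
    Ties straddling either cut are broken deterministically by
    lexicographic sample ID.
    """
    if len(values) < 2 * n:
        raise ValueError(f"need at least {2 * n} samples after trimming, have {len(values)}")
    order = sorted(values.items(), key=lambda kv: (-kv[1], str(kv[0])))
    high = tuple(sid for sid, _ in order[:n])
    low = tuple(sid for sid, _ in sorted(order[-n:], key=lambda kv: (kv[1], str(kv[0]))))
    return GroupAssignment(
        phenotype=phenotype,
        high_ids=high,
        low_ids=low,
        excluded_ids=tuple(excluded),
        n_per_group=n,
        sd_multiplier=sd_multiplier,
    )


def group_ttest(
    high: np.ndarray, low: np.ndarray, variant: str = "student"
) -> Tuple[float, float]:
    """Two-sided two-sample t-test between the high and low groups.

    ``variant="student"`` (default) pools variances; ``"welch"`` does not.
    Degenerate cases: both groups constant with equal means -> (0, 1);
    both constant with different means -> infinite t, smallest
    representable p (the separation is perfect, not missing).
    """
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    if high.std(ddof=1) == 0 and low.std(ddof=1) == 0:
        if high.mean() == low.mean():
            return 0.0, 1.0
        sign = 1.0 if high.mean() > low.mean() else -1.0
        return sign * math.inf, float(np.finfo(float).tiny)
    t, p = stats.ttest_ind(high, low, equal_var=(variant == "student"))
    return float(t), float(p)


def group_overlap(a: GroupAssignment, b: GroupAssignment) -> Dict[str, int]:
    """Shared sample counts between two assignments: high∩high and low∩low."""
    return {
        "high": len(set(a.high_ids) & set(b.high_ids)),
        "low": len(set(a.low_ids) & set(b.low_ids)),
    }


def _two_group_frame(values: pd.DataFrame, assignment: GroupAssignment,
                     variant: str, alpha: float) -> pd.DataFrame:
    rows: List[dict] = []
    hi = values.loc[list(assignment.high_ids)]
    lo = values.loc[list(assignment.low_ids)]
    for col in values.columns:
        h = hi[col].to_numpy(dtype=float)
        l = lo[col].to_numpy(dtype=float)
        t, p = group_ttest(h, l, variant=variant)
        n1, n2 = len(h), len(l)
        sp = math.sqrt(
            ((n1 - 1) * h.var(ddof=1) + (n2 - 1) * l.var(ddof=1)) / (n1 + n2 - 2)
        ) if n1 + n2 > 2 else math.nan
        rows.append(
            {
                "feature": col,
                "mean_high": h.mean(),
                "mean_low": l.mean(),
                "sem_high": h.std(ddof=1) / math.sqrt(n1),
                "sem_low": l.std(ddof=1) / math.sqrt(n2),
                # pooled-model SEM as tabulated alongside per-group SEMs,
                # since either convention appears in livestock tables
                "sem_pooled": sp / math.sqrt(n1),
                "t": t,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def differential_abundance(
    abundance: CompositionMatrix,
    assignment: GroupAssignment,
    alpha: float = 0.01,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-genus high-vs-low t-tests; the hit set is ``p < alpha`` (default 0.01).

    Tests are run on the matrix as given (the pipeline passes CLR values so
    that group contrasts live on the same scale as the quantitative
    association model).
    """
    df = abundance.values if isinstance(abundance, CompositionMatrix) else abundance
    out = _two_group_frame(df, assignment, variant, alpha)
    out.insert(1, "phenotype", assignment.phenotype)
    return out


def compare_traits(
    phenotypes: pd.DataFrame,
    assignment: GroupAssignment,
    traits: List[str],
    alpha: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """High-vs-low comparison of phenotypic traits at p < alpha (default 0.05)."""
    out = _two_group_frame(phenotypes[traits], assignment, variant, alpha)
    out.insert(1, "phenotype", assignment.phenotype)
    return out
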