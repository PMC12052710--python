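"""Spearman rank-correlation screening with strength classification.

The screen labels each genus-phenotype pair as *moderate* (p < 0.01 and
|rho| > 0.40), *weak* (p < 0.01 and 0.20 < |rho| <= 0.40) or *none*.
Genera classified other than *none* form the Spearman hit set that feeds
the three-method consensus.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CompositionMatrix

__all__ = [
    "AssociationResult",
    "spearman",
    "classify_correlation",
    "correlation_screen",
]

#: exact permutation p-values are used at or below this sample size
EXACT_N_MAX = 9


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of one feature-phenotype screening test.

    ``method`` is one of ``spearman``, ``mwas_binary``, ``mwas_quantitative``
    or ``ttest``; ``classification`` (moderate/weak/none) is populated for
    Spearman results only.
    """

    feature: str
    target: str
    statistic: float
    p: float
    method: str
    p_adjusted: Optional[float] = None
    classification: Optional[str] = None


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p over all n! orderings of one vector."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(rxc) * np.linalg.norm(pc, axis=1)
    rhos = pc @ rxc / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Spearman rank correlation with mid-rank ties and two-sided p.

    rho is the Pearson correlation of mid-ranks.  The p-value uses the
    t approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` for n > 9 and an
    exact permutation enumeration for n <= 9, where the approximation is
    poor.  Constant input yields ``(nan, nan)`` (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rx, ry = _midranks(x), _midranks(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    rho = float(rxc @ ryc / (np.linalg.norm(rxc) * np.linalg.norm(ryc)))
    if n <= EXACT_N_MAX:
        return rho, _exact_spearman_p(rx, ry, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def classify_correlation(rho: float, p: float, strict_bounds: bool = False) -> str:
    """Classify a correlation as ``moderate``, ``weak`` or ``none``.

    moderate: p < 0.01 and |rho| > 0.40
    weak:     p < 0.01 and 0.20 < |rho| <= 0.40

    With ``strict_bounds=True`` the weak band is the open interval
    (0.20, 0.40) and |rho| exactly 0.40 is unclassified, matching a
    literal reading of strict inequalities on both sides; the default
    closes the band at 0.40 so no significant result with |rho| > 0.20
    is silently dropped.
    """
    if math.isnan(rho) or math.isnan(p):
        return "none"
    a = abs(rho)
    if p < 0.01:
        if a > 0.40:
            return "moderate"
        upper_ok = a < 0.40 if strict_bounds else a <= 0.40
        if 0.20 < a and upper_ok:
            return "weak"
    return "none"


def correlation_screen(
    abundance,
    phenotype: pd.Series,
    target: str = "phenotype",
    strict_bounds: bool = False,
) -> pd.DataFrame:
    """Screen every genus against one phenotype by Spearman correlation.

    ``abundance`` is a :class:`~fibermwas.preprocess.CompositionMatrix`
    (any kind; ranks are scale-invariant within samples of a single genus
    column).  Returns a DataFrame with columns feature, target, method,
    statistic (rho), p, classification.  Genera with undefined correlation
    (constant columns) carry NaN statistics and classify as ``none``; the
    hit set is ``classification != 'none'``.
    """
    df = abundance.values if isinstance(abundance, CompositionMatrix) else abundance
    if not df.index.equals(phenotype.index):
        if set(df.index) != set(phenotype.index):
            raise ValueError("abundance and phenotype sample sets differ")
        phenotype = phenotype.loc[df.index]
    y = phenotype.to_numpy(dtype=float)
    rows = []
    for genus in df.columns:
        rho, p = spearman(df[genus].to_numpy(dtype=float), y)
        rows.append(
            {
                "feature": genus,
                "target": target,
                "method": "spearman",
                "statistic": rho,
                "p": p,
                "classification": classify_correlation(rho, p, strict_bounds),
            }
        )
    return pd.DataFrame(rows)
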