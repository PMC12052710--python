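"""Two-part microbiome-wide association model with permutation p-values.

Each genus is tested against the phenotype in one of two model parts,
routed by its sample prevalence:

* prevalence < 60%  -> binary part:        y = b0 + PCs + beta1 * 1[x > 0] + e
* prevalence >= 60% -> quantitative part:  y = b0 + PCs + beta2 * clr(x) + e

The genus term's two-sided significance is assessed by permutation: the
genus predictor is shuffled against the fixed (phenotype, covariate)
frame and the absolute partial statistic is recomputed for every
rearrangement.  When the number of distinct arrangements of the predictor
is small enough, the full permutation distribution is enumerated exactly;
otherwise Monte-Carlo sampling with the add-one estimator
``p = (1 + #{stat >= observed}) / (1 + N)`` guarantees p > 0.  Family-wise
error across all tested genera (both parts combined) is controlled by
Bonferroni.

Permutation resolution and Bonferroni interact: with m genera and
threshold alpha, a genus can only reach adjusted significance when
``N > m / alpha - 1`` (the smallest achievable adjusted p is
``m / (1 + N)``).  The default of 100,000 permutations leaves headroom
for a family of 292 genera at alpha = 0.01; a two-stage scheme keeps the
cost low by escalating only genera that survive a cheap first pass.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import (
    CompositionMatrix,
    clr_transform,
    normalize_to_min_depth,
    prevalence,
    principal_components,
)

__all__ = [
    "MwasModelSpec",
    "PermutationResult",
    "route_genera",
    "permutation_association",
    "bonferroni_select",
    "mwas_screen",
]

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class MwasModelSpec:
    """Configuration of the two-part association screen.

    Attributes
    ----------
    prevalence_threshold : float
        Genera below this prevalence go to the binary part, at or above it
        to the quantitative part (default 0.60).
    n_pcs : int
        Number of CLR principal components used as covariates (default 3).
    n_permutations : int
        Permutations for the Monte-Carlo p-value.  Must exceed
        ``m / alpha - 1`` for Bonferroni-adjusted significance to be
        achievable at all (default 100,000).
    alpha : float
        Family-wise significance threshold on Bonferroni-adjusted p.
    seed : int
        Base seed; per-genus streams are derived from it and the genus
        name, so results do not depend on column order.
    two_stage : bool
        If True, screen every genus at ``stage1_permutations`` first and
        re-test at full resolution only those with stage-1
        p <= ``escalate_p``.  Genera that could never reach significance
        at stage-1 resolution keep their stage-1 p.
    scheme : str
        ``"predictor"`` shuffles the genus vector against fixed (y, PCs);
        ``"freedman_lane"`` permutes covariate-adjusted phenotype
        residuals instead.
    """

    prevalence_threshold: float = 0.60
    n_pcs: int = 3
    n_permutations: int = 100_000
    alpha: float = 0.01
    seed: int = 0
    two_stage: bool = True
    stage1_permutations: int = 999
    escalate_p: float = 0.02
    scheme: str = "predictor"

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_threshold <= 1):
            raise ValueError("prevalence_threshold must be in (0, 1]")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.scheme not in ("predictor", "freedman_lane"):
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")


@dataclass(frozen=True)
class PermutationResult:
    """Coefficient, partial t and permutation p for one genus term."""

    coefficient: float
    t: float
    p: float
    n_permutations: int
    exhaustive: bool
    estimable: bool = True


def route_genera(
    prev: pd.Series, threshold: float = 0.60
) -> Tuple[pd.Index, pd.Index]:
    """Partition genera into (binary_set, quantitative_set) by prevalence.

    ``prev < threshold`` routes to the binary (presence/absence) part,
    ``prev >= threshold`` to the quantitative (CLR abundance) part.  The
    two sets are disjoint and jointly exhaustive.
    """
    p = prev.to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("prevalence values must lie in [0, 1]")
    binary = prev.index[p < threshold]
    quantitative = prev.index[p >= threshold]
    return binary, quantitative


def _n_distinct_arrangements(g: np.ndarray, limit: int) -> Optional[int]:
    """Distinct multiset permutations of g, or None once the count exceeds limit."""
    _, counts = np.unique(g, return_counts=True)
    total = 1
    remaining = len(g)
    for c in counts:
        total *= math.comb(remaining, int(c))
        remaining -= int(c)
        if total > limit:
            return None
    return total


def _multiset_permutations(values: Sequence[float]) -> Iterator[List[float]]:
    """Yield every distinct arrangement of a multiset (lexicographic)."""
    items = sorted(values)
    n = len(items)
    out: List[float] = [0.0] * n

    def rec(pool: List[float], depth: int) -> Iterator[List[float]]:
        if depth == n:
            yield list(out)
            return
        prev = None
        for i, v in enumerate(pool):
            if prev is not None and v == prev:
                continue
            prev = v
            out[depth] = v
            yield from rec(pool[:i] + pool[i + 1 :], depth + 1)

    yield from rec(items, 0)


def _qr_basis(n: int, pcs: Optional[np.ndarray]) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if pcs is not None and pcs.size:
        cols.append(np.asarray(pcs, dtype=float).reshape(n, -1))
    X = np.hstack(cols)
    q, _ = np.linalg.qr(X)
    return q


def _abs_partial_r(
    G: np.ndarray, y_hat: np.ndarray, Q: np.ndarray, g_sq: float, ny: float
) -> np.ndarray:
    """|partial correlation| of each row of G with y, given covariates Q.

    Uses the identity ||g - QQ'g||^2 = ||g||^2 - ||Q'g||^2 and the fact
    that y_hat is already orthogonal to Q, so each permutation costs
    O(n * n_covariates) instead of a full refit.
    """
    num = G @ y_hat
    ng2 = g_sq - np.square(G @ Q).sum(axis=1)
    ng2 = np.maximum(ng2, 0.0)
    denom = np.sqrt(ng2) * ny
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > _TIE_EPS, num / np.maximum(denom, _TIE_EPS), 0.0)
    return np.abs(r)


def permutation_association(
    y: np.ndarray,
    g: np.ndarray,
    pcs: Optional[np.ndarray] = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    method: str = "auto",
    scheme: str = "predictor",
    rng: Optional[np.random.Generator] = None,
) -> PermutationResult:
    """Permutation test for the genus term in ``y ~ 1 + PCs + g``.

    The observed statistic is the absolute partial t of ``g`` (equivalently
    the absolute partial correlation, which is monotone in |t| at fixed
    degrees of freedom).  ``method`` is ``"auto"`` (exhaustive enumeration
    whenever the number of distinct arrangements of ``g`` does not exceed
    ``n_permutations``, else Monte-Carlo), ``"exhaustive"`` or
    ``"sampled"``.

    Returns a :class:`PermutationResult`; a predictor collinear with the
    covariates (or constant) is reported unestimable with NaN statistics.
    A phenotype constant after covariate adjustment makes every
    permutation statistic tie at zero, giving p = 1.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("y and g must be 1-D vectors of equal length")
    n = len(y)
    if np.ptp(g) == 0:
        return PermutationResult(math.nan, math.nan, math.nan, 0, False, estimable=False)

    Q = _qr_basis(n, pcs)
    k = Q.shape[1]
    df = n - k - 1
    if df < 1:
        raise ValueError(f"not enough residual degrees of freedom (n={n}, covariates={k})")
    y_hat = y - Q @ (Q.T @ y)
    g_hat = g - Q @ (Q.T @ g)
    ny = float(np.linalg.norm(y_hat))
    ng2_obs = float(g_hat @ g_hat)
    if ng2_obs <= _TIE_EPS * max(1.0, float(g @ g)):
        return PermutationResult(math.nan, math.nan, math.nan, 0, False, estimable=False)

    if ny <= _TIE_EPS:
        # degenerate phenotype: every statistic (observed and permuted) is 0
        return PermutationResult(0.0, 0.0, 1.0, n_permutations, False)

    r_obs = float(g_hat @ y_hat / (math.sqrt(ng2_obs) * ny))
    r_obs = max(min(r_obs, 1.0), -1.0)
    coef = float(g_hat @ y_hat / ng2_obs)
    if abs(r_obs) >= 1.0:
        t_obs = math.inf if r_obs > 0 else -math.inf
    else:
        t_obs = r_obs * math.sqrt(df / (1.0 - r_obs * r_obs))
    g_sq = float(g @ g)

    n_arr = _n_distinct_arrangements(g, n_permutations)
    exhaustive = method == "exhaustive" or (method == "auto" and n_arr is not None)
    if method == "exhaustive" and n_arr is None:
        raise ValueError("too many distinct arrangements for exhaustive enumeration")

    if scheme == "freedman_lane":
        # Freedman-Lane permutes the covariate-adjusted phenotype residuals;
        # the residual multiset is continuous, so enumeration is not offered.
        exhaustive = False
        stats_fn = lambda P: _abs_partial_r(  # noqa: E731
            P, g_hat, Q, ny * ny, math.sqrt(ng2_obs)
        )
        base = y_hat
    else:
        stats_fn = lambda P: _abs_partial_r(P, y_hat, Q, g_sq, ny)  # noqa: E731
        base = g

    if exhaustive and scheme == "predictor":
        G = np.array(list(_multiset_permutations(g)))
        stat = stats_fn(G)
        p = float(np.mean(stat >= abs(r_obs) - _TIE_EPS))
        return PermutationResult(coef, t_obs, p, len(G), True)

    if rng is None:
        rng = np.random.default_rng(seed)
    G = np.tile(base, (n_permutations, 1))
    rng.permuted(G, axis=1, out=G)
    stat = stats_fn(G)
    exceed = int(np.sum(stat >= abs(r_obs) - _TIE_EPS))
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationResult(coef, t_obs, p, n_permutations, False)


def bonferroni_select(
    p_values: pd.Series, m: Optional[int] = None, alpha: float = 0.01
) -> pd.DataFrame:
    """Bonferroni adjustment ``p_adj = min(1, m * p)`` and selection at alpha.

    ``m`` defaults to the number of non-missing p-values and must be at
    least that number.  Returns a DataFrame with columns ``p_adjusted``
    and ``significant`` indexed like the input; missing p-values stay
    missing and are never significant.
    """
    n_tested = int(p_values.notna().sum())
    if m is None:
        m = n_tested
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < n_tested:
        raise ValueError(f"family size m={m} smaller than number of tests {n_tested}")
    p_adj = (p_values * m).clip(upper=1.0)
    return pd.DataFrame(
        {"p_adjusted": p_adj, "significant": p_adj.notna() & (p_adj < alpha)}
    )


def _genus_seed(base_seed: int, name: str, stage: int) -> list:
    return [int(base_seed) & 0x7FFFFFFF, zlib.crc32(name.encode()) & 0x7FFFFFFF, stage]


def mwas_screen(
    abundance: CompositionMatrix,
    phenotype: pd.Series,
    spec: MwasModelSpec = MwasModelSpec(),
    target: str = "phenotype",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Run the full two-part screen of every genus against one phenotype.

    Pipeline: per-genus prevalence on the count table -> routing ->
    depth normalization -> CLR -> top PCs as covariates -> per-genus
    permutation test (presence vector in the binary part, CLR column in
    the quantitative part) -> Bonferroni across the combined family.

    Returns one row per genus with columns: feature, target, method, part,
    prevalence, coefficient, statistic (partial t), p, n_permutations,
    exhaustive, p_adjusted, significant.  All-zero or otherwise constant
    predictors are reported with missing statistics and excluded from the
    family.
    """
    if abundance.kind != "raw_counts":
        raise ValueError("mwas_screen expects a raw count matrix")
    if not abundance.values.index.equals(phenotype.index):
        if set(abundance.values.index) != set(phenotype.index):
            raise ValueError("abundance and phenotype sample sets differ")
        phenotype = phenotype.loc[abundance.values.index]
    y = phenotype.to_numpy(dtype=float)

    prev = prevalence(abundance)
    norm = normalize_to_min_depth(abundance)
    clr = clr_transform(norm, pseudocount=pseudocount)
    pcs = (
        principal_components(clr, spec.n_pcs).to_numpy()
        if spec.n_pcs > 0
        else None
    )
    binary_set, _ = route_genera(prev, spec.prevalence_threshold)
    binary = set(binary_set)

    presence = (abundance.values > 0).astype(float)
    stage1_n = min(spec.stage1_permutations, spec.n_permutations)

    rows = []
    for genus in abundance.values.columns:
        is_binary = genus in binary
        gvec = (
            presence[genus].to_numpy()
            if is_binary
            else clr.values[genus].to_numpy()
        )
        if spec.two_stage and spec.n_permutations > stage1_n:
            res = permutation_association(
                y, gvec, pcs,
                n_permutations=stage1_n,
                rng=np.random.default_rng(_genus_seed(spec.seed, genus, 1)),
                scheme=spec.scheme,
            )
            if res.estimable and not res.exhaustive and res.p <= spec.escalate_p:
                res = permutation_association(
                    y, gvec, pcs,
                    n_permutations=spec.n_permutations,
                    rng=np.random.default_rng(_genus_seed(spec.seed, genus, 2)),
                    scheme=spec.scheme,
                )
        else:
            res = permutation_association(
                y, gvec, pcs,
                n_permutations=spec.n_permutations,
                rng=np.random.default_rng(_genus_seed(spec.seed, genus, 1)),
                scheme=spec.scheme,
            )
        rows.append(
            {
                "feature": genus,
                "target": target,
                "method": "mwas_binary" if is_binary else "mwas_quantitative",
                "part": "binary" if is_binary else "quantitative",
                "prevalence": float(prev[genus]),
                "coefficient": res.coefficient,
                "statistic": res.t,
                "p": res.p,
                "n_permutations": res.n_permutations,
                "exhaustive": res.exhaustive,
            }
        )
    out = pd.DataFrame(rows)
    sel = bonferroni_select(out["p"], alpha=spec.alpha)
    out["p_adjusted"] = sel["p_adjusted"]
    out["significant"] = sel["significant"]
    return out
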