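"""Depth normalization, prevalence, CLR transform and principal components.

Genus tables are compositional: within a sample only relative information
is meaningful.  The centered log-ratio (CLR) transform maps each sample's
composition to an unconstrained real vector (log of each part over the
sample's geometric mean), which is the scale on which the quantitative
association model operates.  Principal components of the CLR matrix serve
as covariates against community-level structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompositionMatrix",
    "normalize_to_min_depth",
    "prevalence",
    "clr_transform",
    "principal_components",
]

_KINDS = ("raw_counts", "depth_normalized", "relative", "clr")


@dataclass
class CompositionMatrix:
    """A samples x genera abundance matrix with an explicit scale tag.

    ``kind`` is one of ``raw_counts``, ``depth_normalized``, ``relative``
    or ``clr`` and gates which operations apply.  Rows are samples and
    columns genera throughout the package.
    """

    values: pd.DataFrame
    kind: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        v = self.values.to_numpy(dtype=float)
        if self.kind != "clr" and (v < 0).any():
            raise ValueError(f"{self.kind} matrix must be non-negative")
        if self.kind == "relative" and not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("relative matrix rows must sum to 1")
        if self.kind == "clr" and not np.allclose(v.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("clr matrix rows must sum to 0")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def genera(self) -> pd.Index:
        return self.values.columns


def normalize_to_min_depth(counts: CompositionMatrix) -> CompositionMatrix:
    """Scale every sample to the sequencing depth of the shallowest sample.

    Each row is multiplied by ``min_total / own_total`` so that all row
    totals equal the minimum input total.  Within-sample proportions are
    preserved exactly; the operation is deterministic (no subsampling).
    """
    if counts.kind != "raw_counts":
        raise ValueError(f"expected raw_counts, got {counts.kind!r}")
    totals = counts.values.sum(axis=1)
    if (totals <= 0).any():
        empty = list(counts.values.index[totals <= 0])
        raise ValueError(f"samples with zero total abundance: {empty}")
    scaled = counts.values.mul(totals.min() / totals, axis=0)
    return CompositionMatrix(scaled, kind="depth_normalized")


def prevalence(x: CompositionMatrix) -> pd.Series:
    """Per-genus fraction of samples with strictly positive abundance.

    Defined on any non-CLR matrix; the >0 predicate is invariant to the
    deterministic depth scaling, so raw and normalized tables give the
    same answer.
    """
    if x.kind == "clr":
        raise ValueError("prevalence is undefined on a CLR matrix")
    return (x.values > 0).mean(axis=0)


def clr_transform(x: CompositionMatrix, pseudocount: float = 0.5) -> CompositionMatrix:
    """Centered log-ratio transform with additive pseudocount zero handling.

    Per sample: add ``pseudocount`` to every entry, close to proportions,
    and return ``ln(p_j / g(p))`` with ``g`` the geometric mean.  Rows of
    the result sum to zero by construction.

    The default pseudocount of 0.5 (on depth-normalized counts) is the
    standard additive replacement for compositional zeros.
    """
    if x.kind not in ("raw_counts", "depth_normalized"):
        raise ValueError(f"CLR expects counts, got {x.kind!r}")
    if not pseudocount > 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    v = x.values.to_numpy(dtype=float) + pseudocount
    logp = np.log(v / v.sum(axis=1, keepdims=True))
    clr = logp - logp.mean(axis=1, keepdims=True)
    out = pd.DataFrame(clr, index=x.values.index, columns=x.values.columns)
    return CompositionMatrix(out, kind="clr")


def principal_components(clr: CompositionMatrix, k: int = 3) -> pd.DataFrame:
    """Top-k principal-component scores of the column-centered CLR matrix.

    Scores are ordered by decreasing explained variance.  The sign of each
    component is fixed by requiring the largest-magnitude loading to be
    positive, so results are reproducible across SVD implementations.
    """
    if clr.kind != "clr":
        raise ValueError(f"expected a clr matrix, got {clr.kind!r}")
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    n, g = clr.values.shape
    if k >= min(n, g):
        raise ValueError(f"k={k} must be < min(n_samples, n_genera)={min(n, g)}")
    centered = clr.values.to_numpy(dtype=float)
    centered = centered - centered.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # fix sign: largest-|loading| positive in each retained component
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=clr.values.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
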