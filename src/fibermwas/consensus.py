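"""Three-method consensus of association hits and phylum tallies.

A genus counts as a *key genus* for a phenotype when it is flagged by all
three screens: Spearman correlation (p < 0.01 and |rho| > 0.20), the
Bonferroni-significant two-part association model, and high-vs-low
differential abundance (p < 0.01).  The consensus is a pure three-way set
intersection, so it is invariant to the order in which the methods are
combined, and relaxing any single threshold can only grow it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Set

import pandas as pd

__all__ = [
    "ConsensusReport",
    "intersect_hits",
    "phylum_tally",
    "membership_table",
    "NDFD_KEY_GENERA",
    "ADFD_KEY_GENERA",
]

#: Key genera reported for ruminal NDF degradation rate in fattening Hu
#: sheep, with phylum membership (reference worked example for tallies).
NDFD_KEY_GENERA: Dict[str, str] = {
    "Anaerotruncus": "Firmicutes",
    "Family_XIII_UCG-002": "Firmicutes",
    "Lachnoclostridium_1": "Firmicutes",
    "Moryella": "Firmicutes",
    "Ruminococcaceae_NK4A214_group": "Firmicutes",
    "Veillonellaceae_UCG-001": "Firmicutes",
    "Prevotellaceae_UCG-003": "Bacteroidetes",
}

#: Key genera reported for ruminal ADF degradation rate, as above.
ADFD_KEY_GENERA: Dict[str, str] = {
    "Lachnospiraceae_ND3007_group": "Firmicutes",
    "Family_XIII_UCG-002": "Firmicutes",
    "Lachnoclostridium_1": "Firmicutes",
    "Lachnospiraceae_UCG-002": "Firmicutes",
    "Moryella": "Firmicutes",
    "Ruminococcaceae_NK4A214_group": "Firmicutes",
    "Prevotellaceae_UCG-003": "Bacteroidetes",
    "Olsenella": "Actinobacteria",
}


@dataclass(frozen=True)
class ConsensusReport:
    """Hit sets of the three screens and their intersection for one phenotype."""

    phenotype: str
    spearman_hits: FrozenSet[str]
    mwas_hits: FrozenSet[str]
    diff_hits: FrozenSet[str]
    consensus: FrozenSet[str] = field(default=frozenset())
    phylum_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = self.spearman_hits & self.mwas_hits & self.diff_hits
        if self.consensus != expected:
            raise ValueError("consensus must equal the three-way intersection")


def intersect_hits(
    spearman: Iterable[str], mwas: Iterable[str], diff: Iterable[str]
) -> FrozenSet[str]:
    """Three-way intersection of genus hit sets."""
    return frozenset(spearman) & frozenset(mwas) & frozenset(diff)


def phylum_tally(
    consensus: Iterable[str], taxonomy: Mapping[str, str]
) -> Dict[str, int]:
    """Count consensus genera per phylum; unknown genera tally as Unclassified."""
    counts: Counter = Counter(
        taxonomy.get(genus, "Unclassified") for genus in consensus
    )
    return dict(counts)


def membership_table(
    universe: Iterable[str], hits: Mapping[str, Set[str]]
) -> pd.DataFrame:
    """Genus x method boolean membership matrix (upset-style plot input)."""
    genera = list(universe)
    data = {method: [g in s for g in genera] for method, s in hits.items()}
    return pd.DataFrame(data, index=pd.Index(genera, name="feature"))


def build_report(
    phenotype: str,
    spearman_hits: Iterable[str],
    mwas_hits: Iterable[str],
    diff_hits: Iterable[str],
    taxonomy: Mapping[str, str],
) -> ConsensusReport:
    """Assemble a :class:`ConsensusReport` with its phylum tally."""
    s, m, d = frozenset(spearman_hits), frozenset(mwas_hits), frozenset(diff_hits)
    consensus = s & m & d
    return ConsensusReport(
        phenotype=phenotype,
        spearman_hits=s,
        mwas_hits=m,
        diff_hits=d,
        consensus=consensus,
        phylum_counts=phylum_tally(consensus, taxonomy),
    )
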