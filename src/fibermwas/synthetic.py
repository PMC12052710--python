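"""Synthetic rumen cohort generator with planted causal structure.

Emulates the statistical shape of a genus-level 16S survey of ~190
fattening lambs: ~292 genera with heterogeneous prevalence (structural
zero-inflation plus multinomial sampling zeros), compositional counts at
realistic sequencing depths, a fiber degradation phenotype driven by a
small set of causal genera (linear in CLR abundance for common genera,
presence/absence for rare ones), a negatively correlated feed conversion
ratio, and internal-marker panels constructed to reproduce each animal's
degradation rate exactly.  A :class:`TruthRecord` carries all planted
structure for recovery testing.

Randomness comes from a single generator stream per cohort, consumed in a
fixed documented order (genus log-means, genus prevalences, presence
matrix, depths, cell noise, counts, causal choice, phenotype noise, FCR
noise, ADF noise, marker panels, growth, fermentation/morphology traits),
so identical configurations reproduce identical cohorts element-wise.
Genus-wise parameter arrays are drawn genus-major, so enlarging
``n_genera`` extends rather than reshuffles the earlier columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .digestibility import MarkerMeasurement
from .preprocess import CompositionMatrix, clr_transform, normalize_to_min_depth, prevalence

__all__ = [
    "SimConfig",
    "TruthRecord",
    "generate_abundance",
    "generate_marker_panel",
    "generate_cohort",
    "generate_taxonomy",
]

#: phylum labels and weights used for synthetic taxonomy tables, roughly
#: matching the phylum spectrum of rumen 16S surveys
_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
          "Spirochaetes", "Unclassified")
_PHYLUM_WEIGHTS = (0.58, 0.25, 0.08, 0.05, 0.02, 0.02)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the cohort generator.

    The defaults mirror the scale of the emulated study: 190 animals,
    292 genera, 4 quantitative + 1 binary causal genus, a phenotype
    (NDF degradation rate, percent) around 55 with residual SD
    ``noise_sd``, and a feed conversion ratio linked linearly and
    negatively to the phenotype.  ``effect_sizes`` may list explicit
    per-causal-genus weights (quantitative genera first, phenotype units
    per CLR unit; then binary genera, units per presence); when None,
    quantitative effects are calibrated so each causal genus explains
    ``quant_r2`` of total phenotype variance and each binary genus shifts
    the phenotype by ``binary_shift`` residual SDs when present.
    """

    n_samples: int = 190
    n_genera: int = 292
    n_causal_quant: int = 4
    n_causal_binary: int = 1
    effect_sizes: Optional[Sequence[float]] = None
    quant_r2: float = 0.15
    binary_shift: float = 2.0
    noise_sd: float = 3.0
    fcr_slope: float = -0.1
    fcr_noise_sd: float = 1.0
    fcr_intercept: float = 12.0
    depth_range: Tuple[int, int] = (30_000, 60_000)
    prevalence_range: Tuple[float, float] = (0.2, 1.0)
    mean_ndfd: float = 55.0
    adfd_offset: float = 10.0
    adfd_noise_sd: float = 2.0
    genus_logmean_sd: float = 1.5
    cell_noise_sd: float = 1.0
    feed_ndf: float = 400.0
    feed_adf: float = 220.0
    feed_marker_range: Tuple[float, float] = (8.0, 12.0)
    marker_enrichment_range: Tuple[float, float] = (1.5, 2.5)
    pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genera <= 0:
            raise ValueError("n_samples and n_genera must be positive")
        if self.n_causal_quant + self.n_causal_binary > self.n_genera:
            raise ValueError("more causal genera than genera")
        if self.n_causal_quant < 0 or self.n_causal_binary < 0:
            raise ValueError("causal genus counts must be >= 0")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must satisfy 1 <= min <= max")
        lo, hi = self.prevalence_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("prevalence bounds must lie in (0, 1]")
        if self.effect_sizes is not None and len(self.effect_sizes) != (
            self.n_causal_quant + self.n_causal_binary
        ):
            raise ValueError("effect_sizes must have one entry per causal genus")
        if self.effect_sizes is None and self.n_causal_quant * self.quant_r2 >= 1:
            raise ValueError("n_causal_quant * quant_r2 must be < 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth planted by :func:`generate_cohort`.

    ``causal`` has one row per causal genus (genus, part, effect,
    prevalence); ``true_rate_per_sample`` holds the NDFD/ADFD values (in
    percent) from which the marker panels were built, so the marker
    formula recovers them exactly.
    """

    causal: pd.DataFrame
    true_rate_per_sample: pd.DataFrame
    fcr_slope: float
    fcr_intercept: float


def _sample_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id")


def _genus_ids(g: int) -> pd.Index:
    return pd.Index([f"Genus_{j + 1:03d}" for j in range(g)], name="feature")


def generate_abundance(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> CompositionMatrix:
    """Zero-inflated compositional count table (samples x genera).

    Mechanism: per-genus log-normal mean abundances, per-genus Bernoulli
    zero-inflation applied *before* sampling (structural zeros, so rare
    genera are genuinely absent rather than merely undersampled), and a
    per-sample multinomial draw at a depth sampled from ``depth_range``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genera
    log_means = rng.normal(0.0, config.genus_logmean_sd, size=g)
    lo, hi = config.prevalence_range
    prev = rng.uniform(lo, hi, size=g)
    presence = (rng.random(size=(g, n)) < prev[:, None]).T.astype(float)
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=n)
    noise = rng.normal(0.0, config.cell_noise_sd, size=(g, n)).T
    weights = presence * np.exp(log_means[None, :] + noise)
    # a sample with no present genus cannot be drawn; force its densest genus
    dead = weights.sum(axis=1) == 0
    if dead.any():
        weights[dead, int(np.argmax(log_means))] = 1.0
    probs = weights / weights.sum(axis=1, keepdims=True)
    counts = np.empty((n, g), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], probs[i])
    table = pd.DataFrame(counts, index=_sample_ids(n), columns=_genus_ids(g))
    return CompositionMatrix(table, kind="raw_counts")


def generate_marker_panel(
    true_rate: float,
    feed_marker_conc: float,
    digesta_marker_conc: float,
    feed_fiber_conc: float,
    fiber_kind: str = "NDF",
) -> MarkerMeasurement:
    """Marker panel whose concentrations encode a known degradation rate.

    Inverts the internal-marker digestibility formula: given the true
    degraded fraction ``d`` and the marker concentrations A (feed) and
    B (digesta), the digesta fiber concentration is set to
    ``FB = FA * (1 - d) * (B / A)`` so that the rate computed from the
    panel equals ``d`` exactly.
    """
    if not 0.0 <= true_rate <= 1.0:
        raise ValueError(f"true_rate must be in [0, 1], got {true_rate}")
    if not feed_marker_conc > 0:
        raise ValueError("feed marker concentration must be positive")
    if digesta_marker_conc <= feed_marker_conc:
        raise ValueError(
            "indigestible marker must concentrate in digesta "
            f"(B={digesta_marker_conc} <= A={feed_marker_conc})"
        )
    if not feed_fiber_conc > 0:
        raise ValueError("feed fiber concentration must be positive")
    fb = feed_fiber_conc * (1.0 - true_rate) * (digesta_marker_conc / feed_marker_conc)
    return MarkerMeasurement(
        A=feed_marker_conc,
        B=digesta_marker_conc,
        FA=feed_fiber_conc,
        FB=fb,
        fiber_kind=fiber_kind,
    )


def _select_causal(
    prev: pd.Series, config: SimConfig, rng: np.random.Generator
) -> Tuple[list, list]:
    """Pick causal genera whose observed prevalence matches their routing class."""
    quant_pool = list(prev.index[prev >= 0.70])
    if len(quant_pool) < config.n_causal_quant:
        quant_pool = list(prev.index[prev >= 0.60])
    binary_pool = list(prev.index[(prev >= 0.25) & (prev <= 0.55)])
    if len(binary_pool) < config.n_causal_binary:
        binary_pool = list(prev.index[(prev > 0.05) & (prev < 0.60)])
    if len(quant_pool) < config.n_causal_quant:
        raise ValueError("not enough high-prevalence genera for quantitative effects")
    if len(binary_pool) < config.n_causal_binary:
        raise ValueError("not enough low-prevalence genera for binary effects")
    quant = list(rng.choice(quant_pool, size=config.n_causal_quant, replace=False))
    binary_pool = [g_ for g_ in binary_pool if g_ not in set(quant)]
    binary = list(rng.choice(binary_pool, size=config.n_causal_binary, replace=False))
    return quant, binary


def generate_cohort(
    config: SimConfig,
) -> Tuple[CompositionMatrix, pd.DataFrame, TruthRecord]:
    """Full synthetic cohort: counts, phenotype table and ground truth.

    The phenotype model is
    ``NDFD_i = mu + sum_j beta_j clr_ij + sum_j gamma_j 1[x_ij > 0] + eps_i``
    with the causal CLR columns and presence indicators centered, then
    ``FCR_i = a + fcr_slope * NDFD_i + eta_i``.  ADFD tracks NDFD minus a
    fixed offset plus noise.  Marker panels, a linear body-weight series
    and nuisance fermentation/morphology traits complete the phenotype
    table; ``growth_metrics`` on the emitted columns recovers ADG and FCR
    exactly, and ``degradation_rate`` on the marker columns recovers
    NDFD/ADFD exactly.
    """
    rng = np.random.default_rng(config.seed)
    counts = generate_abundance(config, rng)
    n = config.n_samples
    prev = prevalence(counts)
    clr = clr_transform(normalize_to_min_depth(counts), config.pseudocount)
    presence = (counts.values > 0).astype(float)

    quant, binary = ([], []) if config.n_causal_quant + config.n_causal_binary == 0 \
        else _select_causal(prev, config, rng)
    # routing-class invariant by construction; verify against observed prevalence
    assert all(prev[g_] >= 0.60 for g_ in quant)
    assert all(prev[g_] < 0.60 for g_ in binary)

    sigma = config.noise_sd
    if config.effect_sizes is not None:
        betas = list(config.effect_sizes[: len(quant)])
        gammas = list(config.effect_sizes[len(quant):])
    else:
        gammas = [config.binary_shift * sigma] * len(binary)
        binary_var = sum(
            gam ** 2 * prev[g_] * (1 - prev[g_]) for gam, g_ in zip(gammas, binary)
        )
        total_var = (sigma ** 2 + binary_var) / (1.0 - len(quant) * config.quant_r2)
        betas = [
            math.sqrt(config.quant_r2 * total_var) / clr.values[g_].std()
            for g_ in quant
        ]

    signal = np.zeros(n)
    for beta, g_ in zip(betas, quant):
        col = clr.values[g_].to_numpy()
        signal += beta * (col - col.mean())
    for gam, g_ in zip(gammas, binary):
        col = presence[g_].to_numpy()
        signal += gam * (col - col.mean())

    eps = rng.normal(0.0, sigma, size=n)
    ndfd = np.clip(config.mean_ndfd + signal + eps, 0.5, 99.5)
    eta = rng.normal(0.0, config.fcr_noise_sd, size=n)
    fcr = np.clip(config.fcr_intercept + config.fcr_slope * ndfd + eta, 1.0, None)
    adfd = np.clip(
        ndfd - config.adfd_offset + rng.normal(0.0, config.adfd_noise_sd, size=n),
        0.5, 99.5,
    )

    feed_aia = rng.uniform(*config.feed_marker_range, size=n)
    enrich = rng.uniform(*config.marker_enrichment_range, size=n)
    digesta_aia = feed_aia * enrich
    fb_ndf = config.feed_ndf * (1.0 - ndfd / 100.0) * enrich
    fb_adf = config.feed_adf * (1.0 - adfd / 100.0) * enrich

    adfi = np.clip(rng.normal(1.5, 0.15, size=n), 0.8, None)
    adg = adfi / fcr
    bw80 = np.clip(rng.normal(20.0, 2.5, size=n), 12.0, None)

    ph = rng.normal(6.3, 0.25, size=n)
    vfa = np.clip(rng.normal(90.0, 15.0, size=n), 30.0, None)
    acetate = np.clip(rng.normal(60.0, 8.0, size=n), 20.0, None)
    propionate = np.clip(rng.normal(20.0, 4.0, size=n), 5.0, None)
    butyrate = np.clip(rng.normal(10.0, 2.0, size=n), 2.0, None)
    pap_h = np.clip(rng.normal(2.5, 0.4, size=n), 0.8, None)
    pap_w = np.clip(rng.normal(1.2, 0.2, size=n), 0.4, None)

    pheno = pd.DataFrame(index=counts.values.index)
    for day in range(80, 181, 20):
        pheno[f"BW_{day}"] = bw80 + adg * (day - 80)
    for col in ("ADFI_80_100", "ADFI_120_140", "ADFI_160_180", "ADFI_80_180"):
        pheno[col] = adfi
    pheno["FCR"] = fcr
    pheno["A"] = feed_aia
    pheno["B"] = digesta_aia
    pheno["FA_NDF"] = config.feed_ndf
    pheno["FB_NDF"] = fb_ndf
    pheno["FA_ADF"] = config.feed_adf
    pheno["FB_ADF"] = fb_adf
    pheno["pH"] = ph
    pheno["total_VFA"] = vfa
    pheno["acetate"] = acetate
    pheno["propionate"] = propionate
    pheno["butyrate"] = butyrate
    pheno["papilla_height"] = pap_h
    pheno["papilla_width"] = pap_w

    causal = pd.DataFrame(
        {
            "feature": quant + binary,
            "part": ["quantitative"] * len(quant) + ["binary"] * len(binary),
            "effect": betas + gammas,
            "prevalence": [float(prev[g_]) for g_ in quant + binary],
        }
    )
    truth = TruthRecord(
        causal=causal,
        true_rate_per_sample=pd.DataFrame(
            {"NDFD": ndfd, "ADFD": adfd}, index=counts.values.index
        ),
        fcr_slope=config.fcr_slope,
        fcr_intercept=config.fcr_intercept,
    )
    return counts, pheno, truth


def generate_taxonomy(
    genera: pd.Index, seed: int = 0, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Synthetic genus -> phylum table with a SILVA-style lineage column."""
    if rng is None:
        rng = np.random.default_rng(seed)
    phyla = rng.choice(_PHYLA, size=len(genera), p=_PHYLUM_WEIGHTS)
    lineage = [
        f"d__Bacteria;p__{p};c__;o__;f__;g__{g_}" for p, g_ in zip(phyla, genera)
    ]
    return pd.DataFrame(
        {"phylum": phyla, "lineage": lineage}, index=pd.Index(genera, name="feature")
    )
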