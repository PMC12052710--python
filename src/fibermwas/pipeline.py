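"""End-to-end workflow: TSV I/O, configuration, and stage orchestration.

The pipeline consumes three TSVs (genus abundance, per-animal phenotypes,
genus taxonomy), computes marker-based degradation rates, builds extreme
groups, runs the three screens (Spearman, two-part MWAS, differential
abundance) per phenotype, and intersects the hit sets into the consensus
key-genus report.  Every intermediate table is written as TSV and a run
manifest records configuration, seed and package version, so a fixed
config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import ConsensusReport, build_report, membership_table
from .digestibility import MarkerMeasurement, degradation_rate
from .groups import compare_traits, differential_abundance, extreme_groups, group_overlap, trim_outliers
from .mwas import MwasModelSpec, mwas_screen
from .preprocess import CompositionMatrix, clr_transform, normalize_to_min_depth, prevalence
from .spearman import correlation_screen
from .synthetic import SimConfig

log = logging.getLogger("fibermwas")

__all__ = [
    "PipelineConfig",
    "read_abundance",
    "read_phenotypes",
    "read_taxonomy",
    "write_tsv",
    "add_degradation_rates",
    "run_pipeline",
]

#: marker-panel column pairs expected in the phenotype table
_MARKER_COLUMNS = ("A", "B", "FA_NDF", "FB_NDF", "FA_ADF", "FB_ADF")


@dataclass
class Thresholds:
    """Significance and grouping thresholds of the published workflow."""

    trait_alpha: float = 0.05
    genus_alpha: float = 0.01
    group_size: int = 10
    sd_multiplier: float = 2.0
    strict_bounds: bool = False
    welch: bool = False

    def __post_init__(self) -> None:
        for name in ("trait_alpha", "genus_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class PipelineConfig:
    """Paths, sub-configurations and thresholds for one pipeline run."""

    abundance_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    taxonomy_path: Optional[str] = None
    out_dir: str = "fibermwas_out"
    phenotypes: List[str] = field(default_factory=lambda: ["NDFD", "ADFD"])
    pseudocount: float = 0.5
    sim: SimConfig = field(default_factory=SimConfig)
    mwas: MwasModelSpec = field(default_factory=MwasModelSpec)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, overrides: Optional[Dict[str, str]] = None) -> "PipelineConfig":
        """Load a config from a YAML file, applying ``--set key=value`` overrides.

        Override keys use dotted paths into the nested blocks, e.g.
        ``mwas.n_permutations=9999`` or ``thresholds.group_size=8``.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, overrides)

    @classmethod
    def from_dict(cls, raw: dict, overrides: Optional[Dict[str, str]] = None) -> "PipelineConfig":
        raw = dict(raw)
        for key, value in (overrides or {}).items():
            parts = key.split(".")
            node = raw
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = yaml.safe_load(value)
        sim = SimConfig(**raw.pop("sim", {}))
        mwas = MwasModelSpec(**raw.pop("mwas", {}))
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        return cls(sim=sim, mwas=mwas, thresholds=thresholds, **raw)


def write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def _read_table(path: str, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except FileNotFoundError:
        raise FileNotFoundError(f"{what} table not found: {path}")
    except Exception as exc:  # surface file name with the parse failure
        raise ValueError(f"failed to parse {what} table {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{what} table {path}: duplicate row identifiers {dups[:5]}")
    return df


def read_abundance(path: str) -> CompositionMatrix:
    """Read a samples x genera abundance TSV (first column sample IDs)."""
    df = _read_table(path, "abundance")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(
            f"abundance table {path}: non-numeric columns {non_numeric[:5]}"
        )
    return CompositionMatrix(df, kind="raw_counts")


def read_phenotypes(path: str) -> pd.DataFrame:
    return _read_table(path, "phenotype")


def read_taxonomy(path: str) -> pd.DataFrame:
    df = _read_table(path, "taxonomy")
    if "phylum" not in df.columns:
        raise ValueError(f"taxonomy table {path}: missing required column 'phylum'")
    return df


def _check_samples(abundance: CompositionMatrix, phenotypes: pd.DataFrame) -> None:
    a, p = set(abundance.values.index), set(phenotypes.index)
    if a != p:
        missing = sorted(a ^ p)
        raise ValueError(
            "sample IDs differ between abundance and phenotype tables; "
            f"offenders: {missing[:10]}"
        )


def add_degradation_rates(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Compute NDFD/ADFD (percent) from the marker columns, appending them.

    Requires the six marker columns A, B, FA_NDF, FB_NDF, FA_ADF, FB_ADF;
    raises a clear error naming any that are absent.
    """
    missing = [c for c in _MARKER_COLUMNS if c not in phenotypes.columns]
    if missing:
        raise ValueError(
            f"phenotype table lacks marker columns required for degradation "
            f"rates: {missing}"
        )
    out = phenotypes.copy()
    for kind in ("NDF", "ADF"):
        rates = [
            degradation_rate(
                MarkerMeasurement(
                    A=row["A"], B=row["B"],
                    FA=row[f"FA_{kind}"], FB=row[f"FB_{kind}"],
                    fiber_kind=kind,
                )
            )
            for _, row in phenotypes.iterrows()
        ]
        out[f"{kind}D"] = rates
    return out


def run_pipeline(
    config: PipelineConfig,
    abundance: Optional[CompositionMatrix] = None,
    phenotypes: Optional[pd.DataFrame] = None,
    taxonomy: Optional[pd.DataFrame] = None,
    write: bool = True,
) -> Dict[str, ConsensusReport]:
    """Execute the full workflow and return one ConsensusReport per phenotype.

    Inputs may be passed in memory or read from the configured TSV paths.
    With ``write=True`` every intermediate table plus a manifest goes to
    ``config.out_dir``.
    """
    if abundance is None:
        if config.abundance_path is None:
            raise ValueError("no abundance table given (path or in-memory)")
        abundance = read_abundance(config.abundance_path)
    if phenotypes is None:
        if config.phenotype_path is None:
            raise ValueError("no phenotype table given (path or in-memory)")
        phenotypes = read_phenotypes(config.phenotype_path)
    if taxonomy is None and config.taxonomy_path is not None:
        taxonomy = read_taxonomy(config.taxonomy_path)
    _check_samples(abundance, phenotypes)
    phenotypes = phenotypes.loc[abundance.values.index]
    out = Path(config.out_dir)
    th = config.thresholds
    variant = "welch" if th.welch else "student"

    needed = [p for p in config.phenotypes if p not in phenotypes.columns]
    if needed:
        log.info("computing degradation rates for %s from marker columns", needed)
        phenotypes = add_degradation_rates(phenotypes)
        still = [p for p in config.phenotypes if p not in phenotypes.columns]
        if still:
            raise ValueError(f"phenotype columns not derivable from inputs: {still}")
    log.info("inputs: %d samples, %d genera", *abundance.values.shape)

    norm = normalize_to_min_depth(abundance)
    clr = clr_transform(norm, config.pseudocount)
    prev = prevalence(abundance)
    log.info("preprocess: min depth %s, median prevalence %.2f",
             f"{abundance.values.sum(axis=1).min():g}", prev.median())
    if write:
        write_tsv(phenotypes, out / "phenotypes_with_rates.tsv")
        write_tsv(clr.values, out / "clr.tsv")

    trait_candidates = [
        c for c in phenotypes.columns
        if c not in config.phenotypes and np.issubdtype(phenotypes[c].dtype, np.number)
    ]

    reports: Dict[str, ConsensusReport] = {}
    assignments = {}
    tax_map = dict(taxonomy["phylum"]) if taxonomy is not None else {}
    for pheno in config.phenotypes:
        y_full = phenotypes[pheno]
        keep = trim_outliers(y_full, th.sd_multiplier)
        excluded = tuple(y_full.index[~keep])
        assignment = extreme_groups(
            y_full[keep], n=th.group_size, phenotype=pheno,
            excluded=excluded, sd_multiplier=th.sd_multiplier,
        )
        assignments[pheno] = assignment
        log.info("%s groups: %d excluded as outliers, %d per group",
                 pheno, len(excluded), th.group_size)

        traits = compare_traits(
            phenotypes, assignment, trait_candidates, alpha=th.trait_alpha,
            variant=variant,
        )
        diff = differential_abundance(
            clr, assignment, alpha=th.genus_alpha, variant=variant
        )
        diff_hits = set(diff.loc[diff["significant"], "feature"])

        spear = correlation_screen(
            abundance, y_full, target=pheno, strict_bounds=th.strict_bounds
        )
        spearman_hits = set(spear.loc[spear["classification"] != "none", "feature"])

        mwas = mwas_screen(
            abundance, y_full, config.mwas, target=pheno,
            pseudocount=config.pseudocount,
        )
        mwas_hits = set(mwas.loc[mwas["significant"], "feature"])
        log.info("%s hits: spearman=%d mwas=%d differential=%d",
                 pheno, len(spearman_hits), len(mwas_hits), len(diff_hits))

        report = build_report(pheno, spearman_hits, mwas_hits, diff_hits, tax_map)
        reports[pheno] = report
        log.info("%s consensus: %d genera %s", pheno, len(report.consensus),
                 dict(report.phylum_counts))

        if write:
            groups_df = pd.DataFrame(
                {
                    "sample_id": list(assignment.high_ids) + list(assignment.low_ids),
                    "group": ["high"] * th.group_size + ["low"] * th.group_size,
                }
            ).set_index("sample_id")
            groups_df[pheno] = y_full[groups_df.index]
            write_tsv(groups_df, out / f"{pheno}_groups.tsv")
            write_tsv(traits, out / f"{pheno}_trait_comparison.tsv", index=False)
            write_tsv(diff, out / f"{pheno}_differential.tsv", index=False)
            write_tsv(spear, out / f"{pheno}_spearman.tsv", index=False)
            write_tsv(mwas, out / f"{pheno}_mwas.tsv", index=False)
            cons_df = pd.DataFrame({"feature": sorted(report.consensus)})
            cons_df["phylum"] = [tax_map.get(g, "Unclassified") for g in cons_df["feature"]]
            write_tsv(cons_df, out / f"{pheno}_consensus.tsv", index=False)
            tally = pd.DataFrame(
                sorted(report.phylum_counts.items()), columns=["phylum", "count"]
            )
            write_tsv(tally, out / f"{pheno}_phylum_tally.tsv", index=False)
            member = membership_table(
                abundance.values.columns,
                {"spearman": spearman_hits, "mwas": mwas_hits, "differential": diff_hits},
            )
            write_tsv(member, out / f"{pheno}_membership.tsv")

    if write and len(config.phenotypes) == 2:
        a, b = (assignments[p] for p in config.phenotypes)
        overlap = group_overlap(a, b)
        (out / "group_overlap.json").write_text(json.dumps(overlap, indent=2))
    if write:
        manifest = {
            "package": "fibermwas",
            "version": __version__,
            "seed": config.seed,
            "config": _config_to_jsonable(config),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return reports


def _config_to_jsonable(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)
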