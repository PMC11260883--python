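"""End-to-end orchestration: from alignments (real or simulated) to report tables.

The full analysis runs, per genus: ingestion/simulation -> end trimming ->
haplotype collapsing -> inclusion filtering into the unique-haplotype (N_H)
and all-sequences (N_S) views -> K2P distance matrices -> local and global
gap detection per view -> permutation comparison of the two views ->
distance-based delimitation (on the unique-haplotype view, where redundant
haplotypes would only add zero distances) -> five-category concordance
against the recognized species labels.

Three summary tables mirror the shape of a barcoding-gap audit report:

* local-gap table: per genus, species counts and integer percentages with a
  local gap in each view, plus a "total examined" union column where a
  species counts as gap-present if it has a gap in either view;
* global-gap table: per-genus mean intra/inter distances (% sequence
  divergence, 1 decimal), gap presence, threshold ratio, and the
  permutation-test p-values comparing the views;
* concordance table: per genus, the five-category counts.

Every stochastic stage records its seed, and rerunning with the same
configuration writes byte-identical TSVs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .comparison import PermutationResult, permutation_test
from .concordance import (
    ConcordanceRecord,
    ConcordanceSummary,
    classify_species,
    records_dataframe,
    recognized_from_labels,
    summarize_concordance,
)
from .delimitation import (
    Partition,
    RankedPartitions,
    candidate_partitions,
    rank_partitions,
    score_partition,
)
from .distances import DistanceMatrix, SpeciesDistanceSummary, pairwise_matrix, summarize_by_species
from .gap_analysis import (
    GenusGapRecord,
    SpeciesGapRecord,
    global_gap,
    global_gap_dataframe,
    histogram_dataframe,
    local_gaps,
    local_gaps_dataframe,
)
from .haplotypes import DatasetViews, HaplotypeTable, InclusionConfig, build_datasets, collapse_haplotypes
from .seq_io import GenusDataset, read_alignment, trim_alignment
from .simulate import SimConfig, simulate_genus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    sim_configs: tuple[SimConfig, ...] = ()
    inputs: tuple[tuple[str, str], ...] = ()  # (fasta, metadata) path pairs
    inclusion: InclusionConfig = InclusionConfig()
    multipliers: tuple[float, ...] = (10.0, 5.0)
    min_col_coverage: float = 0.9
    min_seq_bp: int = 200
    permutation_iterations: int = 10_000
    delimit_n_perm: int = 999
    plausibility_cap: float = 0.9
    pooling: str = "species_means"
    seed: int = 0
    outdir: str | None = None


@dataclass
class ViewResult:
    """Distance and gap results for one genus in one dataset view."""

    matrix: DistanceMatrix
    summaries: list[SpeciesDistanceSummary]
    local: list[SpeciesGapRecord]
    global_: GenusGapRecord


@dataclass
class GenusComparison:
    intra: PermutationResult | None
    inter: PermutationResult | None


@dataclass
class RunResult:
    config: RunConfig
    tables: dict[str, HaplotypeTable]
    views: DatasetViews
    nh_results: dict[str, ViewResult] = field(default_factory=dict)
    ns_results: dict[str, ViewResult] = field(default_factory=dict)
    comparisons: dict[str, GenusComparison] = field(default_factory=dict)
    delimitations: dict[str, RankedPartitions] = field(default_factory=dict)
    concordance_records: dict[str, list[ConcordanceRecord]] = field(default_factory=dict)
    concordance_summaries: dict[str, ConcordanceSummary] = field(default_factory=dict)
    local_gap_table: pd.DataFrame | None = None
    global_gap_table: pd.DataFrame | None = None
    concordance_table: pd.DataFrame | None = None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _analyze_view(ds: GenusDataset, cfg: RunConfig) -> ViewResult:
    m = pairwise_matrix(ds)
    summaries = summarize_by_species(m, ds.species_labels)
    return ViewResult(
        matrix=m,
        summaries=summaries,
        local=local_gaps(summaries),
        global_=global_gap(
            summaries, ds.genus, multipliers=cfg.multipliers,
            pooling=cfg.pooling, matrix=m, labels=ds.species_labels,
        ),
    )


def run_full_analysis(cfg: RunConfig) -> RunResult:
    """Execute the whole pipeline; write per-stage TSVs when an outdir is set."""
    datasets: dict[str, GenusDataset] = {}
    for sim in cfg.sim_configs:
        ds, _truth = simulate_genus(sim)
        datasets[ds.genus] = ds
    for fasta, meta in cfg.inputs:
        ds = read_alignment(fasta, meta)
        if ds.genus in datasets:
            raise ValueError(f"genus {ds.genus} appears twice in inputs")
        datasets[ds.genus] = ds

    if not datasets:
        raise ValueError("no input datasets configured")

    tables: dict[str, HaplotypeTable] = {}
    for genus, ds in datasets.items():
        trimmed = trim_alignment(ds, cfg.min_col_coverage, cfg.min_seq_bp).dataset
        tables[genus] = collapse_haplotypes(trimmed)

    views = build_datasets(tables, cfg.inclusion)
    result = RunResult(config=cfg, tables=tables, views=views)

    for genus, ds in views.nh.items():
        result.nh_results[genus] = _analyze_view(ds, cfg)
    for genus, ds in views.ns.items():
        result.ns_results[genus] = _analyze_view(ds, cfg)

    # permutation comparison of the two views, genus by genus
    for k, genus in enumerate(sorted(set(result.nh_results) & set(result.ns_results))):
        nh, ns = result.nh_results[genus], result.ns_results[genus]
        intra_a = [s.mean_intra for s in nh.summaries if s.n_intra_pairs > 0]
        intra_b = [s.mean_intra for s in ns.summaries if s.n_intra_pairs > 0]
        inter_a = list(nh.global_.inter_means.values())
        inter_b = list(ns.global_.inter_means.values())
        intra = inter = None
        if len(intra_a) >= 2 and len(intra_b) >= 2:
            intra = permutation_test(
                intra_a, intra_b, cfg.permutation_iterations, seed=cfg.seed * 1000 + 2 * k
            )
        if len(inter_a) >= 2 and len(inter_b) >= 2:
            inter = permutation_test(
                inter_a, inter_b, cfg.permutation_iterations, seed=cfg.seed * 1000 + 2 * k + 1
            )
        result.comparisons[genus] = GenusComparison(intra=intra, inter=inter)

    # delimitation + concordance on the unique-haplotype view
    for k, (genus, ds) in enumerate(sorted(views.nh.items())):
        vr = result.nh_results[genus]
        cands = candidate_partitions(vr.matrix)
        scored = [
            (p, score_partition(p, vr.matrix, cfg.delimit_n_perm, seed=cfg.seed * 1000 + 500 + k))
            for p in cands
            if 2 <= p.n_clusters <= len(vr.matrix.ids)
        ]
        ranked = rank_partitions(scored, cfg.plausibility_cap)
        result.delimitations[genus] = ranked
        recognized = recognized_from_labels(ds.species_labels)
        records = classify_species(recognized, ranked.selected)
        result.concordance_records[genus] = records
        result.concordance_summaries[genus] = summarize_concordance(records, ranked.selected)

    result.local_gap_table = _local_gap_table(result)
    result.global_gap_table = _global_gap_table(result)
    result.concordance_table = _concordance_table(result)

    if cfg.outdir is not None:
        _write_outputs(result, Path(cfg.outdir))
    return result


def _gap_species(vr: ViewResult | None) -> tuple[set[str], set[str]]:
    """(examined species, gap-present species) for a view, or empty sets."""
    if vr is None:
        return set(), set()
    examined = {r.species for r in vr.local}
    present = {r.species for r in vr.local if r.gap_present}
    return examined, present


def _local_gap_table(result: RunResult) -> pd.DataFrame:
    rows = []
    genera = sorted(set(result.nh_results) | set(result.ns_results))
    for genus in genera:
        nh_ex, nh_gap = _gap_species(result.nh_results.get(genus))
        ns_ex, ns_gap = _gap_species(result.ns_results.get(genus))
        tot_ex = nh_ex | ns_ex  # union semantics: gap in either view counts
        tot_gap = nh_gap | ns_gap
        discrepant = (nh_gap ^ ns_gap) & nh_ex & ns_ex
        rows.append(
            {
                "genus": genus,
                "nh_species": len(nh_ex) or None,
                "nh_gap_pct": _round_half_up(100 * len(nh_gap) / len(nh_ex)) if nh_ex else None,
                "ns_species": len(ns_ex) or None,
                "ns_gap_pct": _round_half_up(100 * len(ns_gap) / len(ns_ex)) if ns_ex else None,
                "total_species": len(tot_ex),
                "total_gap_pct": _round_half_up(100 * len(tot_gap) / len(tot_ex)) if tot_ex else None,
                "discrepant_species": ",".join(sorted(discrepant)),
            }
        )
    return pd.DataFrame(rows)


def _fmt_ratio(r: float | None) -> str:
    return f"{r:.1f}x" if r is not None else ""


def _global_gap_table(result: RunResult) -> pd.DataFrame:
    rows = []
    genera = sorted(set(result.nh_results) | set(result.ns_results))
    for genus in genera:
        nh = result.nh_results.get(genus)
        ns = result.ns_results.get(genus)
        cmp_ = result.comparisons.get(genus)
        rows.append(
            {
                "genus": genus,
                "nh_intra_pct": round(nh.global_.mean_intra * 100, 1) if nh else None,
                "nh_inter_pct": round(nh.global_.mean_inter * 100, 1) if nh else None,
                "nh_threshold": _fmt_ratio(nh.global_.threshold_ratio) if nh else "",
                "ns_intra_pct": round(ns.global_.mean_intra * 100, 1) if ns else None,
                "ns_inter_pct": round(ns.global_.mean_inter * 100, 1) if ns else None,
                "ns_threshold": _fmt_ratio(ns.global_.threshold_ratio) if ns else "",
                "p_intra": round(cmp_.intra.p_value, 3) if cmp_ and cmp_.intra else None,
                "p_inter": round(cmp_.inter.p_value, 3) if cmp_ and cmp_.inter else None,
            }
        )
    return pd.DataFrame(rows)


def _concordance_table(result: RunResult) -> pd.DataFrame:
    rows = []
    for genus in sorted(result.concordance_records):
        records = result.concordance_records[genus]
        vr = result.nh_results[genus]
        gap_present = {r.species for r in vr.local if r.gap_present}
        counts = {c: 0 for c in ("PT", "PU", "IU", "PO", "IO")}
        from .concordance import CATEGORY_CODES

        for r in records:
            counts[CATEGORY_CODES[r.category]] += 1
        rows.append(
            {
                "genus": genus,
                "local_gaps": len(gap_present),
                "n_species": len(records),
                **counts,
                "n_delimited": result.concordance_summaries[genus].n_delimited,
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for genus, table in result.tables.items():
        table.write_tsv(outdir / f"haplotypes_{genus}.tsv")
    for view, results in (("nh", result.nh_results), ("ns", result.ns_results)):
        for genus, vr in results.items():
            vr.matrix.write_tsv(outdir / f"distances_{view}_{genus}.tsv")
            local_gaps_dataframe(vr.local).to_csv(
                outdir / f"local_gaps_{view}_{genus}.tsv", sep="\t", index=False,
                float_format="%.8f",
            )
            global_gap_dataframe(vr.global_).to_csv(
                outdir / f"global_gap_{view}_{genus}.tsv", sep="\t", index=False
            )
            histogram_dataframe(vr.global_).to_csv(
                outdir / f"gap_histogram_{view}_{genus}.tsv", sep="\t", index=False,
                float_format="%.8f",
            )
    cmp_rows = []
    for genus, c in sorted(result.comparisons.items()):
        for kind, res in (("intra", c.intra), ("inter", c.inter)):
            if res is None:
                continue
            cmp_rows.append(
                {
                    "genus": genus,
                    "test": kind,
                    "statistic": "inf" if math.isinf(res.statistic) else f"{res.statistic:.6f}",
                    "p_value": f"{res.p_value:.6f}",
                    "iterations": res.iterations,
                    "seed": res.seed,
                }
            )
    pd.DataFrame(cmp_rows).to_csv(outdir / "comparison.tsv", sep="\t", index=False)
    for genus, ranked in result.delimitations.items():
        ranked.selected.write_tsv(outdir / f"partition_{genus}.tsv")
        ranked.to_dataframe().to_csv(
            outdir / f"partition_scores_{genus}.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
    for genus, records in result.concordance_records.items():
        records_dataframe(records).to_csv(
            outdir / f"concordance_{genus}.tsv", sep="\t", index=False
        )
        result.concordance_summaries[genus].to_dataframe().to_csv(
            outdir / f"concordance_summary_{genus}.tsv", sep="\t", index=False
        )
    result.local_gap_table.to_csv(outdir / "local_gap_table.tsv", sep="\t", index=False)
    result.global_gap_table.to_csv(outdir / "global_gap_table.tsv", sep="\t", index=False)
    result.concordance_table.to_csv(outdir / "concordance_table.tsv", sep="\t", index=False)

    log = {
        "version": __version__,
        "seed": result.config.seed,
        "inclusion": {
            "min_n_h": result.config.inclusion.min_n_h,
            "min_n_s": result.config.inclusion.min_n_s,
            "min_species_per_genus": result.config.inclusion.min_species_per_genus,
        },
        "trim": {
            "min_col_coverage": result.config.min_col_coverage,
            "min_seq_bp": result.config.min_seq_bp,
        },
        "multipliers": list(result.config.multipliers),
        "permutation_iterations": result.config.permutation_iterations,
        "delimit_n_perm": result.config.delimit_n_perm,
        "plausibility_cap": result.config.plausibility_cap,
        "pooling": result.config.pooling,
        "genera_nh": sorted(result.views.nh),
        "genera_ns": sorted(result.views.ns),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
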