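"""Full refinement pipeline: LCA filter -> median filter -> split -> z-score purify.

Stages run per bin in that order; sub-bins created by the inverse-profile
split are processed independently downstream. The pipeline produces a
machine-readable run report (per stage: members in, removed, members out,
parameters), a row-per-event trace, and the refined bins. Reports carry no
timestamps or hostnames — those go to a sidecar — so identical configs and
inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import coverage_refine, taxonomy_lca
from .formats_io import (
    Bin,
    CoverageMatrix,
    HitTable,
    TaxonomyTree,
    TraceRecord,
    read_bins,
    read_coverage,
    read_hits,
    read_taxonomy,
    write_refined_bins,
    write_trace,
)


@dataclass
class RunConfig:
    """Every tunable of the refinement, serializable to a flat YAML file."""

    # inputs (optional here; in-memory use supplies objects directly)
    fasta: list[str] = field(default_factory=list)
    contig2bin: str | None = None
    depth_tsv: str | None = None
    hits: list[str] = field(default_factory=list)
    taxonomy: str | None = None
    taxonomy_names: str | None = None
    target_phyla: dict[str, str] = field(default_factory=dict)  # bin -> node id
    out_dir: str = "refined"

    # dataset pair used for differencing
    dataset_a: str = ""
    dataset_b: str = ""

    # thresholds (defaults follow the published procedure where one exists)
    evalue_max: float = 1e-20
    top_percent: float = 10.0
    median_factor: float = 3.0
    min_gap_log2: float = 2.0
    min_side: int = 5
    start_cutoff: float = 4.0
    end_cutoff: float = 2.0
    step: float = 1.0
    min_members: int = 4
    ambiguity_factor: float = 2.0

    seed: int = 0
    overwrite: bool = False
    write_fasta: bool = True

    def __post_init__(self) -> None:
        if not (self.start_cutoff >= self.end_cutoff > 0):
            raise ValueError("need start_cutoff >= end_cutoff > 0")
        if self.step <= 0 or self.median_factor <= 0 or self.min_side < 1:
            raise ValueError("thresholds out of range")
        if not 0 < self.top_percent <= 100:
            raise ValueError("top_percent must be in (0, 100]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class StageReport:
    stage: str
    bin_id: str
    members_in: int
    removed: int
    members_out: int
    params: dict
    flags: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    config: dict
    stages: list[StageReport]
    final_bins: dict[str, list[str]]       # bin id -> sorted member list
    removed_total: int

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "stages": [dataclasses.asdict(s) for s in self.stages],
            "final_bins": self.final_bins,
            "removed_total": self.removed_total,
        }


def refine_bins(
    bins: Mapping[str, Bin],
    coverage: CoverageMatrix,
    config: RunConfig,
    hits: HitTable | None = None,
    taxonomy: TaxonomyTree | None = None,
) -> tuple[dict[str, Bin], list[TraceRecord], RunReport]:
    """Run the refinement stages in order on in-memory objects.

    The LCA stage runs only when both hits and a taxonomy are supplied
    (and a bin has a target taxon). Returns the final bins (keyed by
    possibly suffixed sub-bin ids), the full trace, and the run report.
    """
    d_a = config.dataset_a or coverage.datasets[0]
    d_b = config.dataset_b or (coverage.datasets[1] if len(coverage.datasets) > 1
                               else coverage.datasets[0])
    trace: list[TraceRecord] = []
    stages: list[StageReport] = []
    final: dict[str, Bin] = {}
    removed_total = 0

    for bid in sorted(bins):
        current = Bin(bid, set(bins[bid].members), bins[bid].target_taxon)

        # 1) taxonomic (LCA) filter
        if hits is not None and taxonomy is not None and current.target_taxon:
            assignments = taxonomy_lca.assign_bin_lca(
                hits, current, taxonomy,
                evalue_max=config.evalue_max, top_percent=config.top_percent)
            res = taxonomy_lca.filter_bin_by_taxonomy(current, assignments, taxonomy)
            trace.extend(res.trace)
            stages.append(StageReport(
                "lca_filter", bid, len(current), len(res.removed), len(res.kept),
                {"evalue_max": config.evalue_max, "top_percent": config.top_percent}))
            removed_total += len(res.removed)
            current = res.kept
            if not current.members:
                final[bid] = current
                continue

        # 2) median-outlier removal
        med = coverage_refine.median_outlier_filter(
            current, coverage, factor=config.median_factor, datasets=[d_a, d_b])
        trace.extend(med.trace)
        stages.append(StageReport(
            "median_filter", bid, len(current), len(med.removed), len(med.kept),
            {"factor": config.median_factor},
            flags=[f"zero_median:{d}" for d in med.skipped_datasets]))
        removed_total += len(med.removed)
        current = med.kept
        if not current.members:
            final[bid] = current
            continue

        # 3) inverse-profile split
        split = coverage_refine.split_inverse_profiles(
            current, coverage, d_a, d_b,
            min_gap_log2=config.min_gap_log2, min_side=config.min_side)
        if split.was_split:
            for sub in split.sub_bins:
                for sid in sub.sorted_members():
                    trace.append(TraceRecord(
                        stage="split", bin_id=bid, scaffold_id=sid,
                        action="split", reason="inverse_profile",
                        cutoff=config.min_gap_log2,
                        values=f"sub_bin={sub.bin_id};gap={split.split_statistic:.4f}"))
        stages.append(StageReport(
            "split", bid, len(current), 0,
            sum(len(s) for s in split.sub_bins),
            {"min_gap_log2": config.min_gap_log2, "min_side": config.min_side,
             "was_split": split.was_split, "gap": split.split_statistic}))

        # 4) z-score purification, per sub-bin
        for sub in split.sub_bins:
            if len(sub) < config.min_members:
                trace.append(TraceRecord(
                    stage="zscore_purify", bin_id=sub.bin_id, scaffold_id="*",
                    action="flag", reason="too_few_members_for_purify",
                    values=f"members={len(sub)}"))
                final[sub.bin_id] = sub
                continue
            pur = coverage_refine.zscore_purify(
                sub, coverage, d_a, d_b,
                start_cutoff=config.start_cutoff, end_cutoff=config.end_cutoff,
                step=config.step, min_members=config.min_members)
            trace.extend(pur.trace)
            flags = []
            if pur.early_stopped:
                flags.append("min_members_guard")
            if pur.zero_variance_seen:
                flags.append("zero_variance")
            stages.append(StageReport(
                "zscore_purify", sub.bin_id, len(sub), len(pur.removed),
                len(pur.kept),
                {"start_cutoff": config.start_cutoff,
                 "end_cutoff": config.end_cutoff, "step": config.step,
                 "min_members": config.min_members}, flags=flags))
            removed_total += len(pur.removed)
            final[sub.bin_id] = pur.kept

    # the report records what was computed, not where files lived: path
    # fields are dropped so identical runs from different dirs diff clean
    _path_fields = {"fasta", "contig2bin", "depth_tsv", "hits", "taxonomy",
                    "taxonomy_names", "out_dir"}
    config_dict = {k: v for k, v in dataclasses.asdict(config).items()
                   if k not in _path_fields}
    report = RunReport(
        config=config_dict,
        stages=stages,
        final_bins={b: final[b].sorted_members() for b in sorted(final)},
        removed_total=removed_total,
    )
    return final, trace, report


def run_refinement(config: RunConfig) -> RunReport:
    """File-to-file refinement driven entirely by a :class:`RunConfig`.

    Reads the configured inputs, runs :func:`refine_bins`, and writes the
    refined bins, the trace TSV, and ``report.json`` (plus a
    ``run_meta.json`` sidecar holding the wall-clock timestamp) into
    ``config.out_dir``. On stage failure a ``FAILED`` marker file is left
    next to any partial outputs and the exception propagates.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        scaffolds, bins = read_bins(config.fasta, config.contig2bin,
                                    target_taxa=config.target_phyla)
        coverage = read_coverage(depth_tsv=config.depth_tsv, scaffolds=scaffolds)
        taxonomy = hits = None
        if config.taxonomy:
            taxonomy = read_taxonomy(config.taxonomy, config.taxonomy_names)
        if config.hits and taxonomy is not None:
            hits, _ = read_hits(config.hits, taxonomy)
        final, trace, report = refine_bins(bins, coverage, config,
                                           hits=hits, taxonomy=taxonomy)
        non_empty = {b: v for b, v in final.items() if v.members}
        write_refined_bins(non_empty, scaffolds, out_dir,
                           fasta=config.write_fasta, overwrite=config.overwrite)
        write_trace(trace, out_dir / "trace.tsv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out_dir / "run_meta.json", "w") as fh:
            json.dump({"completed_at": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
                       "out_dir": str(out_dir)}, fh)
            fh.write("\n")
        return report
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
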