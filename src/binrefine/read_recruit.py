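"""Strict read recruitment for targeted reassembly.

Reads are recruited to a bin for external reassembly only under
end-to-end acceptance rules: an alignment counts only when it spans the
entire read (no soft or hard clipping; mismatches and indels are
allowed), and a read pair is accepted only when *both* mates align
full-length to scaffolds of the *same* bin. Merged read pairs and
orphaned reads are accepted individually under the same full-length
rule. Pairs whose mates land on two different bins are rejected for both
bins — a cross-bin pair is evidence of ambiguity, not membership.

The recruited read-id sets are exported as manifests (and optionally as
FASTQ subsets); assembly itself is delegated to an external assembler,
with the purified bin FASTA passed along as its untrusted reference.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pysam
from Bio import SeqIO

from .formats_io import Bin

MATE_FLAGS = ("single", "mate1", "mate2", "merged")


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal view of one primary alignment."""

    read_id: str
    mate_flag: str            # single | mate1 | mate2 | merged
    scaffold_id: str | None   # None when unmapped
    full_length: bool         # spans the entire read: no soft/hard clipping
    mapped: bool

    def __post_init__(self) -> None:
        if self.mate_flag not in MATE_FLAGS:
            raise ValueError(f"bad mate_flag {self.mate_flag!r}")
        if self.full_length and not self.mapped:
            raise ValueError("full_length alignment must be mapped")


def _is_full_length(aln: pysam.AlignedSegment) -> bool:
    if aln.is_unmapped or not aln.cigartuples:
        return False
    return all(op not in (4, 5) for op, _ in aln.cigartuples)  # S, H


def load_alignments_sam(
    path: str | Path,
    merged_marker: Callable[[str], bool] | str | None = None,
) -> list[AlignmentRecord]:
    """Read primary alignments from a SAM/BAM file.

    ``merged_marker`` identifies merged (overlap-joined) read pairs among
    unpaired records, either as a callable on the read name or a substring
    of it; unpaired reads without the marker are classed ``single``.
    """
    if isinstance(merged_marker, str):
        marker = merged_marker
        merged_marker = lambda name: marker in name  # noqa: E731
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_paired:
                mate = "mate1" if aln.is_read1 else "mate2"
            elif merged_marker is not None and merged_marker(aln.query_name):
                mate = "merged"
            else:
                mate = "single"
            mapped = not aln.is_unmapped
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    mate_flag=mate,
                    scaffold_id=aln.reference_name if mapped else None,
                    full_length=_is_full_length(aln),
                    mapped=mapped,
                )
            )
    return records


@dataclass
class RecruitResult:
    bin_id: str
    accepted: dict[str, str]            # read id -> category (pair|merged|orphan)
    counts: Counter = field(default_factory=Counter)
    n_missing_mate: int = 0             # mate1 seen without its mate2 record (or v.v.)

    @property
    def read_ids(self) -> set[str]:
        return set(self.accepted)

    @property
    def n_reads(self) -> int:
        """Total accepted reads; an accepted pair contributes two."""
        return sum(self.counts.values())


def recruit_reads(alignments: Iterable[AlignmentRecord], bin_: Bin) -> RecruitResult:
    """Select the read ids recruited to one bin.

    Acceptance: paired reads require both mates mapped full-length to
    scaffolds of this bin; merged and single-end (orphan) reads require a
    full-length alignment to a bin scaffold. A mate record missing
    entirely from the input demotes the present mate to an orphan, with a
    warning count. The result is independent of record order.
    """
    members = bin_.members
    pairs: dict[str, dict[str, AlignmentRecord]] = {}
    singles: list[AlignmentRecord] = []
    for rec in alignments:
        if rec.mate_flag in ("mate1", "mate2"):
            slot = pairs.setdefault(rec.read_id, {})
            # keep the first record per mate deterministically; duplicates
            # of the same mate should not occur once secondaries are gone
            slot.setdefault(rec.mate_flag, rec)
        else:
            singles.append(rec)

    accepted: dict[str, str] = {}
    counts: Counter = Counter()
    missing_mate = 0
    for read_id in sorted(pairs):
        slot = pairs[read_id]
        m1, m2 = slot.get("mate1"), slot.get("mate2")
        if m1 is None or m2 is None:
            missing_mate += 1
            present = m1 or m2
            if present.full_length and present.scaffold_id in members:
                accepted[read_id] = "orphan"
                counts["orphan"] += 1
            continue
        ok = (
            m1.full_length and m2.full_length
            and m1.scaffold_id in members and m2.scaffold_id in members
        )
        if ok:
            accepted[read_id] = "pair"
            counts["pair"] += 2    # both mates are recruited
    for rec in sorted(singles, key=lambda r: r.read_id):
        if rec.full_length and rec.scaffold_id in members:
            category = "merged" if rec.mate_flag == "merged" else "orphan"
            accepted[rec.read_id] = category
            counts[category] += 1
    return RecruitResult(bin_id=bin_.bin_id, accepted=accepted, counts=counts,
                         n_missing_mate=missing_mate)


def export_read_manifest(
    results: Mapping[str, RecruitResult] | Iterable[RecruitResult],
    out_dir: str | Path,
    fastq_sources: Mapping[str, str | Path] | None = None,
    bin_fasta_paths: Mapping[str, str] | None = None,
) -> dict:
    """Write per-bin read-id manifests (and optional FASTQ subsets).

    Each bin gets ``<bin>.reads.txt`` with one ``read_id<TAB>category``
    row, sorted by read id. When ``fastq_sources`` (label -> FASTQ path)
    is supplied, per-bin FASTQ subsets are written too; an accepted read
    id absent from every source is an error. ``bin_fasta_paths`` records,
    per bin, the purified bin FASTA to hand to the external assembler as
    its untrusted reference. Returns the JSON-serializable manifest.
    """
    if isinstance(results, Mapping):
        results = list(results.values())
    else:
        results = list(results)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, dict] = {}
    for res in sorted(results, key=lambda r: r.bin_id):
        list_path = out_dir / f"{res.bin_id}.reads.txt"
        with open(list_path, "w") as fh:
            for rid in sorted(res.accepted):
                cat = res.accepted[rid]
                if cat == "pair":    # one row per mate
                    fh.write(f"{rid}/1\tpair\n{rid}/2\tpair\n")
                else:
                    fh.write(f"{rid}\t{cat}\n")
        entry: dict = {
            "read_list": str(list_path),
            "n_reads": res.n_reads,
            "counts": dict(res.counts),
            "n_missing_mate": res.n_missing_mate,
        }
        if bin_fasta_paths and res.bin_id in bin_fasta_paths:
            entry["untrusted_reference"] = bin_fasta_paths[res.bin_id]
        if fastq_sources:
            wanted = set(res.accepted)
            found: set[str] = set()
            fq_path = out_dir / f"{res.bin_id}.reads.fastq"
            n_written = 0
            with open(fq_path, "w") as out:
                for _, src in sorted(fastq_sources.items()):
                    for rec in SeqIO.parse(str(src), "fastq"):
                        if rec.id in wanted:
                            SeqIO.write(rec, out, "fastq")
                            found.add(rec.id)
                            n_written += 1
            missing = wanted - found
            if missing:
                raise ValueError(
                    f"{len(missing)} accepted read id(s) absent from the FASTQ "
                    f"sources for bin {res.bin_id!r} (e.g. {sorted(missing)[:5]})"
                )
            entry["fastq"] = str(fq_path)
            entry["n_fastq_records"] = n_written
        manifest[res.bin_id] = entry

    manifest_path = out_dir / "recruitment.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
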