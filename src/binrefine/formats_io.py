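"""Standard-format readers/writers and the internal data model.

Everything downstream operates on four in-memory containers:

* :class:`Scaffold` — an assembled contig/scaffold with optional sequence.
* :class:`Bin` — a named set of scaffold ids with an optional expected
  (target) phylum.
* :class:`CoverageMatrix` — mean per-base read depth per scaffold per
  sequencing dataset, backed by a pandas DataFrame.
* :class:`TaxonomyTree` / :class:`HitTable` — an NCBI-style taxonomy and
  BLAST-tabular homology hits used for LCA classification.

Supported external formats: FASTA (Biopython), SAM (pysam), the common
contig-depth summary TSV (``contigName  contigLen  totalAvgDepth
sample1 [sample1-var] ...``), per-base depth dumps, BED-like interval
depth, BLAST outfmt-6-like tables with a taxid column, 4-column taxonomy
TSV or NCBI nodes/names dumps, and a tab-separated refinement trace.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("binrefine")

_GC_BASES = frozenset("GCgc")
_VALID_BASES = frozenset("ACGTNacgtn")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaffold:
    """A contiguous assembled sequence; the unit of binning and coverage.

    ``gc`` is the G+C fraction over non-N positions, ``None`` when no
    sequence is attached or every position is N (undefined, never 0).
    """

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"scaffold {self.id!r}: length must be > 0, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"scaffold {self.id!r}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )

    @property
    def gc(self) -> float | None:
        if self.sequence is None:
            return None
        non_n = sum(1 for b in self.sequence if b in "ACGTacgt")
        if non_n == 0:
            return None
        gc = sum(1 for b in self.sequence if b in _GC_BASES)
        return gc / non_n


@dataclass
class Bin:
    """A named set of scaffolds putatively from one genome.

    ``target_taxon`` is the taxonomy node id of the expected phylum; it is
    required by the taxonomic (LCA) filter and optional elsewhere.
    """

    bin_id: str
    members: set[str]
    target_taxon: str | None = None

    def __post_init__(self) -> None:
        self.members = set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


class CoverageMatrix:
    """Mean per-base depth per (scaffold, dataset), dense with 0 for absent."""

    def __init__(self, df: pd.DataFrame):
        if df.isna().any().any():
            raise ValueError("coverage matrix contains NaN")
        if (df.values < 0).any():
            raise ValueError("coverage matrix contains negative depth")
        if not np.isfinite(df.values).all():
            raise ValueError("coverage matrix contains non-finite depth")
        self.df = df.astype(float)

    @classmethod
    def from_dict(cls, depth: Mapping[str, Mapping[str, float]],
                  datasets: Sequence[str] | None = None) -> "CoverageMatrix":
        """Build from ``{scaffold: {dataset: depth}}``."""
        df = pd.DataFrame.from_dict(depth, orient="index").fillna(0.0)
        if datasets is not None:
            for d in datasets:
                if d not in df.columns:
                    df[d] = 0.0
            df = df[list(datasets)]
        return cls(df)

    @property
    def datasets(self) -> list[str]:
        return list(self.df.columns)

    @property
    def scaffolds(self) -> list[str]:
        return list(self.df.index)

    def depth(self, scaffold_id: str, dataset: str) -> float:
        if scaffold_id in self.df.index:
            return float(self.df.at[scaffold_id, dataset])
        return 0.0

    def vector(self, scaffold_id: str) -> np.ndarray:
        """Depth across all datasets, zeros when the scaffold has no rows."""
        if scaffold_id in self.df.index:
            return self.df.loc[scaffold_id].to_numpy(dtype=float)
        return np.zeros(len(self.df.columns))

    def submatrix(self, scaffold_ids: Iterable[str]) -> pd.DataFrame:
        ids = list(scaffold_ids)
        sub = self.df.reindex(ids).fillna(0.0)
        return sub


@dataclass(frozen=True)
class HitRecord:
    """One homology hit of a scaffold against a reference taxon."""

    scaffold_id: str
    taxon_id: str
    evalue: float
    bitscore: float
    source: str = "blast"


class HitTable:
    """Homology hits indexed by scaffold, backed by a DataFrame."""

    COLUMNS = ["scaffold_id", "taxon_id", "evalue", "bitscore", "source"]

    def __init__(self, records: Iterable[HitRecord] | pd.DataFrame = ()):
        if isinstance(records, pd.DataFrame):
            df = records[self.COLUMNS].copy()
        else:
            df = pd.DataFrame([r.__dict__ for r in records], columns=self.COLUMNS)
        df["evalue"] = df["evalue"].astype(float)
        df["bitscore"] = df["bitscore"].astype(float)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def for_scaffold(self, scaffold_id: str) -> pd.DataFrame:
        return self.df[self.df["scaffold_id"] == scaffold_id]

    def scaffold_ids(self) -> list[str]:
        return sorted(self.df["scaffold_id"].unique())


class TaxonomyTree:
    """Rooted taxonomy: node id -> (parent id, rank, name).

    The root's parent is itself (NCBI convention). Every node must reach
    the root by parent-following.
    """

    def __init__(self, nodes: Mapping[str, tuple[str, str, str]]):
        self.nodes = {str(k): (str(p), r, n) for k, (p, r, n) in nodes.items()}
        roots = [k for k, (p, _, _) in self.nodes.items() if p == k or p not in self.nodes]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {sorted(roots)}")
        self.root = roots[0]
        for node in self.nodes:
            self.path_to_root(node)  # validates connectivity / acyclicity

    def __contains__(self, node_id: str) -> bool:
        return str(node_id) in self.nodes

    def parent(self, node_id: str) -> str:
        return self.nodes[node_id][0]

    def rank(self, node_id: str) -> str:
        return self.nodes[node_id][1]

    def name(self, node_id: str) -> str:
        return self.nodes[node_id][2]

    def path_to_root(self, node_id: str) -> list[str]:
        """Nodes from ``node_id`` up to and including the root."""
        node_id = str(node_id)
        path = [node_id]
        seen = {node_id}
        cur = node_id
        while True:
            if cur not in self.nodes:
                raise KeyError(f"taxon {cur!r} not in taxonomy")
            parent = self.nodes[cur][0]
            if parent == cur or parent not in self.nodes:
                break
            if parent in seen:
                raise ValueError(f"taxonomy cycle at node {parent!r}")
            path.append(parent)
            seen.add(parent)
            cur = parent
        return path

    def depth(self, node_id: str) -> int:
        return len(self.path_to_root(node_id)) - 1

    def ancestor_at_rank(self, node_id: str, rank: str) -> str | None:
        """Ancestor-or-self of ``node_id`` with the given rank, else None."""
        for anc in self.path_to_root(node_id):
            if self.rank(anc) == rank:
                return anc
        return None

    def is_ancestor(self, ancestor: str, node_id: str) -> bool:
        return str(ancestor) in self.path_to_root(node_id)


@dataclass
class TraceRecord:
    """One refinement event (removal, split, flag) for the audit trail."""

    stage: str
    bin_id: str
    scaffold_id: str
    action: str          # remove | split | keep | flag
    reason: str
    cutoff: float | None = None
    values: str = ""


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_fasta_scaffolds(path: str | Path) -> dict[str, Scaffold]:
    """Read one FASTA into ``{id: Scaffold}``, rejecting duplicate ids."""
    scaffolds: dict[str, Scaffold] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in scaffolds:
            raise ValueError(f"duplicate scaffold id {rec.id!r} within {path}")
        seq = str(rec.seq).upper()
        scaffolds[rec.id] = Scaffold(id=rec.id, length=len(seq), sequence=seq)
    return scaffolds


def read_bins(
    fasta_paths: Sequence[str | Path],
    contig2bin: str | Path | None = None,
    target_taxa: Mapping[str, str] | None = None,
) -> tuple[dict[str, Scaffold], dict[str, Bin]]:
    """Load preliminary bins from FASTA files and/or a contig-to-bin table.

    Without a table, each FASTA file becomes one bin named after the file
    stem. With a table (two tab- or whitespace-separated columns: scaffold
    id, bin id), bin membership comes from the table and the FASTA files
    only supply sequences. Duplicate scaffold ids across files are a hard
    error; a table row naming an unknown scaffold is a hard error; a bin
    that ends up empty is dropped with a warning.
    """
    scaffolds: dict[str, Scaffold] = {}
    origin: dict[str, str] = {}
    per_file: dict[str, list[str]] = {}
    for path in fasta_paths:
        path = Path(path)
        batch = read_fasta_scaffolds(path)
        for sid in batch:
            if sid in scaffolds:
                raise ValueError(
                    f"duplicate scaffold id {sid!r} in {path} (already seen in "
                    f"{origin[sid]})"
                )
            origin[sid] = str(path)
        scaffolds.update(batch)
        per_file[path.stem] = list(batch)

    bins: dict[str, Bin] = {}
    if contig2bin is None:
        for stem, ids in per_file.items():
            if not ids:
                warnings.warn(f"bin {stem!r} is empty and was dropped")
                continue
            bins[stem] = Bin(bin_id=stem, members=set(ids))
    else:
        assignment: dict[str, set[str]] = {}
        orphans: list[str] = []
        with open(contig2bin) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 2:
                    raise ValueError(f"malformed contig2bin line: {line!r}")
                sid, bid = parts[0], parts[1]
                if sid not in scaffolds:
                    orphans.append(sid)
                    continue
                assignment.setdefault(bid, set()).add(sid)
        if orphans:
            raise ValueError(
                "contig2bin table references scaffolds absent from the FASTA "
                f"input: {sorted(set(orphans))}"
            )
        seen: dict[str, str] = {}
        for bid, members in assignment.items():
            for sid in members:
                if sid in seen:
                    raise ValueError(
                        f"scaffold {sid!r} assigned to both {seen[sid]!r} and {bid!r}"
                    )
                seen[sid] = bid
            if not members:
                warnings.warn(f"bin {bid!r} is empty and was dropped")
                continue
            bins[bid] = Bin(bin_id=bid, members=members)

    if target_taxa:
        for bid, taxon in target_taxa.items():
            if bid in bins:
                bins[bid].target_taxon = str(taxon)
    return scaffolds, bins


def read_coverage_tsv(path: str | Path) -> CoverageMatrix:
    """Read the common contig-depth summary table.

    Layout: header, then one row per contig with columns ``name, length,
    totalAvgDepth, <sample> [, <sample>-var] ...``. Variance columns
    (header ending in ``-var``) are ignored, as is the total-average
    column. A plainer ``name, length, <sample>...`` layout (no
    total-average column) is accepted when the third header does not look
    like a total-average column.
    """
    df = pd.read_csv(path, sep=r"\s+", engine="python")
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError("depth table needs at least name, length and one sample column")
    data_cols = cols[2:]
    if data_cols and data_cols[0].lower().replace("_", "") in {"totalavgdepth", "totalavg", "total"}:
        data_cols = data_cols[1:]
    data_cols = [c for c in data_cols if not c.endswith("-var")]
    if not data_cols:
        raise ValueError("depth table has no per-sample depth columns")
    sub = df.set_index(cols[0])[data_cols]
    if (sub.values < 0).any():
        raise ValueError("negative depth in depth table")
    return CoverageMatrix(sub)


def read_coverage_perbase(
    path: str | Path, scaffolds: Mapping[str, Scaffold], dataset: str = "depth"
) -> CoverageMatrix:
    """Mean depth from 1-based (scaffold, position, depth) rows.

    Positions not listed count as depth 0; the denominator is the scaffold
    length, so partial dumps average correctly.
    """
    totals: dict[str, float] = {sid: 0.0 for sid in scaffolds}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, pos, depth = line.split("\t")[:3]
            d = float(depth)
            if d < 0:
                raise ValueError(f"negative depth for {sid}:{pos}")
            if sid not in totals:
                raise ValueError(f"per-base depth names unknown scaffold {sid!r}")
            totals[sid] += d
    means = {sid: {dataset: totals[sid] / scaffolds[sid].length} for sid in scaffolds}
    return CoverageMatrix.from_dict(means, datasets=[dataset])


def read_coverage_intervals(
    path: str | Path, scaffolds: Mapping[str, Scaffold], dataset: str = "depth"
) -> CoverageMatrix:
    """Mean depth from BED-style rows (scaffold, start, end, depth).

    Intervals are half-open, 0-based; converted to mean depth by summing
    depth x interval length over the scaffold length.
    """
    totals: dict[str, float] = {sid: 0.0 for sid in scaffolds}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, start, end, depth = line.split("\t")[:4]
            d = float(depth)
            if d < 0:
                raise ValueError(f"negative depth for {sid}:{start}-{end}")
            if sid not in totals:
                raise ValueError(f"interval depth names unknown scaffold {sid!r}")
            totals[sid] += d * (int(end) - int(start))
    means = {sid: {dataset: totals[sid] / scaffolds[sid].length} for sid in scaffolds}
    return CoverageMatrix.from_dict(means, datasets=[dataset])


def _aligned_ref_length(aln: pysam.AlignedSegment) -> int:
    """Reference positions where a read base is aligned (cigar M/=/X)."""
    n = 0
    for op, ln in aln.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            n += ln
    return n


def read_coverage_sam(
    sam_paths: Mapping[str, str | Path], scaffolds: Mapping[str, Scaffold]
) -> CoverageMatrix:
    """Mean depth per dataset from SAM/BAM alignments.

    One SAM per dataset label. Mean depth = aligned bases / scaffold
    length, counting primary alignments only (secondary and supplementary
    records are skipped so each read contributes one placement). Records
    on scaffolds absent from ``scaffolds`` are skipped with a warning.
    """
    depth: dict[str, dict[str, float]] = {sid: {} for sid in scaffolds}
    for dataset, path in sam_paths.items():
        totals = {sid: 0.0 for sid in scaffolds}
        skipped = 0
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                ref = aln.reference_name
                if ref not in totals:
                    skipped += 1
                    continue
                totals[ref] += _aligned_ref_length(aln)
        if skipped:
            warnings.warn(
                f"{skipped} alignment(s) in {path} reference scaffolds outside "
                "the assembly and were skipped"
            )
        for sid in scaffolds:
            depth[sid][dataset] = totals[sid] / scaffolds[sid].length
    return CoverageMatrix.from_dict(depth, datasets=list(sam_paths))


def read_coverage(
    *,
    depth_tsv: str | Path | None = None,
    per_base: Mapping[str, str | Path] | None = None,
    sam: Mapping[str, str | Path] | None = None,
    scaffolds: Mapping[str, Scaffold] | None = None,
) -> CoverageMatrix:
    """Dispatch to one of the coverage readers (exactly one source)."""
    given = [x is not None for x in (depth_tsv, per_base, sam)]
    if sum(given) != 1:
        raise ValueError("provide exactly one of depth_tsv, per_base or sam")
    if depth_tsv is not None:
        return read_coverage_tsv(depth_tsv)
    if scaffolds is None:
        raise ValueError("per-base and SAM routes need scaffold lengths")
    if per_base is not None:
        mats = [read_coverage_perbase(p, scaffolds, dataset=d) for d, p in per_base.items()]
        df = pd.concat([m.df for m in mats], axis=1)
        return CoverageMatrix(df)
    return read_coverage_sam(sam, scaffolds)  # type: ignore[arg-type]


def read_taxonomy(
    path: str | Path, names_path: str | Path | None = None
) -> TaxonomyTree:
    """Read a taxonomy from a 4-column TSV or NCBI-style dump files.

    The TSV layout is ``id<TAB>parent<TAB>rank<TAB>name``. When
    ``names_path`` is given, ``path`` is parsed as a ``nodes.dmp`` (fields
    separated by ``\t|\t``) and names come from ``names.dmp`` (scientific
    names only).
    """
    nodes: dict[str, tuple[str, str, str]] = {}
    if names_path is not None:
        names: dict[str, str] = {}
        with open(names_path) as fh:
            for line in fh:
                parts = [p.strip() for p in line.rstrip("\t|\n").split("\t|\t")]
                if len(parts) >= 4 and parts[3] == "scientific name":
                    names[parts[0]] = parts[1]
                elif len(parts) >= 2 and parts[0] not in names:
                    names[parts[0]] = parts[1]
        with open(path) as fh:
            for line in fh:
                parts = [p.strip() for p in line.rstrip("\t|\n").split("\t|\t")]
                nid, parent, rank = parts[0], parts[1], parts[2]
                nodes[nid] = (parent, rank, names.get(nid, nid))
    else:
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed taxonomy line: {line!r}")
                nid, parent, rank = parts[0], parts[1], parts[2]
                name = parts[3] if len(parts) > 3 else nid
                nodes[nid] = (parent, rank, name)
    return TaxonomyTree(nodes)


def read_hits(
    paths: Sequence[str | Path] | str | Path,
    taxonomy: TaxonomyTree,
    taxid_column: int = 12,
    source_labels: Sequence[str] | None = None,
    strict: bool = False,
) -> tuple[HitTable, int]:
    """Read BLAST outfmt-6-like tables into a :class:`HitTable`.

    Columns follow the standard 12-column tabular layout (query, subject,
    identity, length, mismatches, gaps, qstart, qend, sstart, send,
    evalue, bitscore) with a taxon-id column appended; ``taxid_column`` is
    its 0-based index (default 12, i.e. a 13th column). Hits whose taxon
    is not in the taxonomy are dropped and counted; the e-value cutoff is
    *not* applied here (that belongs to the LCA stage). Returns
    ``(table, n_dropped)``.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if source_labels is None:
        source_labels = [Path(p).stem for p in paths]
    records: list[HitRecord] = []
    dropped = 0
    for path, source in zip(paths, source_labels):
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                try:
                    sid = parts[0]
                    evalue = float(parts[10])
                    bitscore = float(parts[11])
                    taxid = parts[taxid_column].split(";")[0]
                except (IndexError, ValueError) as exc:
                    if strict:
                        raise ValueError(f"{path}:{lineno}: malformed hit line") from exc
                    logger.warning("%s:%d: malformed hit line skipped", path, lineno)
                    continue
                if taxid not in taxonomy:
                    dropped += 1
                    continue
                records.append(HitRecord(sid, taxid, evalue, bitscore, source))
    if dropped:
        logger.info("dropped %d hit(s) with unresolvable taxa", dropped)
    return HitTable(records), dropped


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_refined_bins(
    bins: Mapping[str, Bin] | Iterable[Bin],
    scaffolds: Mapping[str, Scaffold],
    out_dir: str | Path,
    fasta: bool = True,
    overwrite: bool = False,
) -> dict:
    """Write one FASTA (or contig2bin TSV) per bin plus a JSON manifest.

    Returns the manifest mapping. Round-trips through :func:`read_bins`.
    """
    if isinstance(bins, Mapping):
        bins = list(bins.values())
    else:
        bins = list(bins)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    if fasta:
        missing = {
            b.bin_id: [s for s in b.sorted_members() if scaffolds[s].sequence is None]
            for b in bins
        }
        missing = {k: v for k, v in missing.items() if v}
        if missing:
            raise ValueError(f"FASTA output requested but sequences missing: {missing}")
    for b in sorted(bins, key=lambda x: x.bin_id):
        suffix = ".fasta" if fasta else ".contig2bin.tsv"
        path = out_dir / f"{b.bin_id}{suffix}"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
        if fasta:
            recs = [
                SeqRecord(Seq(scaffolds[s].sequence), id=s, description="")
                for s in b.sorted_members()
            ]
            SeqIO.write(recs, str(path), "fasta")
        else:
            with open(path, "w") as fh:
                for s in b.sorted_members():
                    fh.write(f"{s}\t{b.bin_id}\n")
        # path is stored relative to out_dir so manifests are relocatable
        # (and identical runs into different directories compare equal)
        manifest[b.bin_id] = {
            "path": path.name,
            "n_scaffolds": len(b),
            "target_taxon": b.target_taxon,
        }
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists (pass overwrite=True to replace)")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


TRACE_COLUMNS = ["stage", "bin", "scaffold", "action", "reason", "cutoff", "values"]


def write_trace(trace: Iterable[TraceRecord], path: str | Path) -> Path:
    """Write the refinement trace as TSV in event order."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        for rec in trace:
            cutoff = "" if rec.cutoff is None else f"{rec.cutoff:g}"
            fh.write(
                "\t".join(
                    [rec.stage, rec.bin_id, rec.scaffold_id, rec.action,
                     rec.reason, cutoff, rec.values]
                )
                + "\n"
            )
    return path


def read_trace(path: str | Path) -> list[TraceRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRACE_COLUMNS:
            raise ValueError(f"unexpected trace header: {header}")
        for line in fh:
            stage, bid, sid, action, reason, cutoff, values = line.rstrip("\n").split("\t")
            records.append(
                TraceRecord(stage, bid, sid, action, reason,
                            float(cutoff) if cutoff else None, values)
            )
    return records
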