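"""Lowest-common-ancestor classification of scaffolds and taxonomic filtering.

A scaffold inherits the deepest taxonomy node that is an ancestor of every
qualifying homology hit (MEGAN-style LCA). Qualifying means e-value at or
below a cutoff (default 1e-20) and bitscore within a top-percent window of
the best hit, applied per hit source (protein- and nucleotide-level
searches are filtered separately, then pooled for one decision).

A scaffold is flagged as a conflict — a putative contaminant — only when
its LCA falls *unambiguously* inside a phylum different from the bin's
target phylum: the LCA must sit at or below rank "phylum". Scaffolds whose
LCA resolves above phylum level (hits split across phyla) and scaffolds
without qualifying hits are kept; absence of evidence is never treated as
contamination.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Mapping

from .formats_io import Bin, HitTable, TaxonomyTree, TraceRecord

UNASSIGNED = "unassigned"

DEFAULT_EVALUE_MAX = 1e-20
DEFAULT_TOP_PERCENT = 10.0


@dataclass(frozen=True)
class LcaAssignment:
    scaffold_id: str
    lca_node: str          # taxonomy node id, or UNASSIGNED
    n_hits_used: int
    conflict: bool = False


def _pairwise_lca(a: str, b: str, taxonomy: TaxonomyTree) -> str:
    """Classic two-pointer LCA: lift the deeper node, then walk up together."""
    da, db = taxonomy.depth(a), taxonomy.depth(b)
    while da > db:
        a = taxonomy.parent(a)
        da -= 1
    while db > da:
        b = taxonomy.parent(b)
        db -= 1
    while a != b:
        a = taxonomy.parent(a)
        b = taxonomy.parent(b)
    return a


def lca(taxon_ids: Iterable[str], taxonomy: TaxonomyTree) -> str:
    """Deepest node that is an ancestor-or-self of every input taxon."""
    ids = [str(t) for t in taxon_ids]
    if not ids:
        raise ValueError("lca of an empty taxon set is undefined")
    for t in ids:
        if t not in taxonomy:
            raise KeyError(f"taxon {t!r} not in taxonomy")
    return reduce(lambda a, b: _pairwise_lca(a, b, taxonomy), ids)


def phylum_of(node_id: str, taxonomy: TaxonomyTree) -> str | None:
    """Phylum-rank ancestor-or-self of a node, or None above phylum level."""
    return taxonomy.ancestor_at_rank(node_id, "phylum")


def qualifying_taxa(
    hits: HitTable,
    scaffold_id: str,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    top_percent: float = DEFAULT_TOP_PERCENT,
) -> list[str]:
    """Taxa of hits passing the e-value cutoff and per-source bitscore window.

    Within each hit source, only hits with bitscore >= (1 - top_percent/100)
    x the best passing bitscore of that source survive; survivors from all
    sources are pooled. Sorted for determinism.
    """
    sub = hits.for_scaffold(scaffold_id)
    sub = sub[sub["evalue"] <= evalue_max]
    if sub.empty:
        return []
    frac = 1.0 - top_percent / 100.0
    taxa: set[str] = set()
    for _, group in sub.groupby("source"):
        best = group["bitscore"].max()
        keep = group[group["bitscore"] >= frac * best]
        taxa.update(keep["taxon_id"])
    return sorted(taxa)


def assign_scaffold_lca(
    hits: HitTable,
    scaffold_id: str,
    taxonomy: TaxonomyTree,
    target_phylum: str | None = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    top_percent: float = DEFAULT_TOP_PERCENT,
) -> LcaAssignment:
    """LCA-classify one scaffold from its hit table.

    With no qualifying hits the scaffold is "unassigned" (a valid state,
    never a conflict). ``conflict`` is filled only when ``target_phylum``
    is given.
    """
    taxa = qualifying_taxa(hits, scaffold_id, evalue_max, top_percent)
    if not taxa:
        return LcaAssignment(scaffold_id, UNASSIGNED, 0, False)
    node = lca(taxa, taxonomy)
    conflict = False
    if target_phylum is not None:
        conflict = is_conflict(node, target_phylum, taxonomy)
    return LcaAssignment(scaffold_id, node, len(taxa), conflict)


def is_conflict(lca_node: str, target_phylum: str, taxonomy: TaxonomyTree) -> bool:
    """True iff the LCA lies unambiguously within a non-target phylum."""
    if lca_node == UNASSIGNED:
        return False
    phylum = phylum_of(lca_node, taxonomy)
    return phylum is not None and phylum != str(target_phylum)


def assign_bin_lca(
    hits: HitTable,
    bin_: Bin,
    taxonomy: TaxonomyTree,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    top_percent: float = DEFAULT_TOP_PERCENT,
) -> dict[str, LcaAssignment]:
    """Assignments for every member of a bin, keyed by scaffold id."""
    if bin_.target_taxon is None:
        raise ValueError(f"bin {bin_.bin_id!r} has no target taxon")
    target = phylum_of(bin_.target_taxon, taxonomy) or bin_.target_taxon
    return {
        sid: assign_scaffold_lca(hits, sid, taxonomy, target, evalue_max, top_percent)
        for sid in bin_.sorted_members()
    }


@dataclass
class TaxonomyFilterResult:
    kept: Bin
    removed: set[str]
    trace: list[TraceRecord]


def filter_bin_by_taxonomy(
    bin_: Bin,
    assignments: Mapping[str, LcaAssignment],
    taxonomy: TaxonomyTree | None = None,
) -> TaxonomyFilterResult:
    """Remove exactly the members whose LCA conflicts with the target phylum.

    Members missing from ``assignments`` count as unassigned and are kept.
    When a taxonomy is supplied the conflict flag is recomputed from the
    stored LCA node against the bin's target, so assignments produced
    without a target are usable.
    """
    if bin_.target_taxon is None:
        raise ValueError(
            f"bin {bin_.bin_id!r} has no target taxon; conflict is undefined"
        )
    removed: set[str] = set()
    trace: list[TraceRecord] = []
    target = bin_.target_taxon
    if taxonomy is not None:
        target = phylum_of(bin_.target_taxon, taxonomy) or bin_.target_taxon
    for sid in bin_.sorted_members():
        a = assignments.get(sid)
        if a is None or a.lca_node == UNASSIGNED:
            continue
        conflict = (
            is_conflict(a.lca_node, target, taxonomy) if taxonomy is not None
            else a.conflict
        )
        if conflict:
            removed.add(sid)
            trace.append(
                TraceRecord(
                    stage="lca_filter", bin_id=bin_.bin_id, scaffold_id=sid,
                    action="remove", reason="foreign_phylum",
                    values=f"lca={a.lca_node};n_hits={a.n_hits_used}",
                )
            )
    kept = Bin(
        bin_id=bin_.bin_id,
        members=bin_.members - removed,
        target_taxon=bin_.target_taxon,
    )
    if not kept.members:
        trace.append(
            TraceRecord(
                stage="lca_filter", bin_id=bin_.bin_id, scaffold_id="*",
                action="flag", reason="bin_emptied",
            )
        )
    return TaxonomyFilterResult(kept=kept, removed=removed, trace=trace)
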