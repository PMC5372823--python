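"""Post-refinement estimators.

* Relative abundance of a bin per dataset, as the fraction of sequenced
  bacterial "mass" (mean depth x scaffold length, i.e. aligned bases)
  assigned to the bin. The denominator set — scaffolds regarded as
  bacterial — is caller-provided, and the basis string is always reported
  alongside the number so the estimator's operationalization is explicit.
* tRNA-based completeness: the fraction of the 20 standard amino-acid
  isotypes with at least one tRNA annotated, reported as ">99" when all
  20 are present (a full isotype set cannot distinguish 100% from
  near-complete).
* The unique core genome of an ortholog table: groups universally present
  in single copy across every compared genome — the input to MLSA
  concatenation.
* Coverage-profile linking of 16S-bearing scaffolds to bins: 16S genes
  typically assemble on short fragments that composition-based binning
  cannot place, but their depth profile across datasets can still point
  to the source bin. This is a coverage-only link; the phylogenetic and
  MLSA evidence the full linking argument also rests on is outside this
  toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import Bin, CoverageMatrix, Scaffold

STANDARD_ISOTYPES = frozenset(
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val".split()
)
_IGNORED_ISOTYPES = frozenset({"Sec", "SeC", "Pyl", "Sup", "Undet"})

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


# ---------------------------------------------------------------------------
# Relative abundance
# ---------------------------------------------------------------------------

@dataclass
class AbundanceEstimate:
    bin_id: str
    fractions: dict[str, float]     # dataset -> fraction in [0, 1]
    basis: str

    def percent(self, dataset: str) -> float:
        return 100.0 * self.fractions[dataset]

    def formatted(self) -> str:
        return "/".join(f"{100.0 * v:.2g}%" for v in self.fractions.values())


def _mass(scaffold_ids: Iterable[str], coverage: CoverageMatrix,
          scaffolds: Mapping[str, Scaffold], dataset: str) -> float:
    return float(sum(coverage.depth(s, dataset) * scaffolds[s].length
                     for s in scaffold_ids))


def relative_abundance(
    bin_: Bin,
    coverage: CoverageMatrix,
    scaffolds: Mapping[str, Scaffold],
    denominator_scaffolds: Iterable[str],
) -> AbundanceEstimate:
    """Bin abundance relative to the given bacterial scaffold population.

    Per dataset: sum of depth x length over bin members divided by the
    same sum over ``denominator_scaffolds`` (the scaffolds flagged
    bacterial by the caller). A zero denominator in any dataset is an
    error.
    """
    denom_ids = list(denominator_scaffolds)
    fractions: dict[str, float] = {}
    for d in coverage.datasets:
        denom = _mass(denom_ids, coverage, scaffolds, d)
        if denom == 0.0:
            raise ValueError(f"zero denominator mass in dataset {d!r}")
        fractions[d] = _mass(bin_.sorted_members(), coverage, scaffolds, d) / denom
    return AbundanceEstimate(
        bin_id=bin_.bin_id,
        fractions=fractions,
        basis="depth x length mass fraction over caller-flagged bacterial scaffolds",
    )


def grouped_abundance(estimates: Sequence[AbundanceEstimate],
                      group_id: str) -> AbundanceEstimate:
    """Abundance of a group of disjoint bins: the sum of the members'."""
    if not estimates:
        raise ValueError("no estimates to group")
    datasets = list(estimates[0].fractions)
    fractions = {d: sum(e.fractions[d] for e in estimates) for d in datasets}
    return AbundanceEstimate(bin_id=group_id, fractions=fractions,
                             basis=estimates[0].basis)


# ---------------------------------------------------------------------------
# tRNA-based completeness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrnaCompleteness:
    percent: float            # 100 x distinct standard isotypes / 20
    n_isotypes: int
    display: str              # ">99" when all 20 isotypes are present


def trna_completeness(
    annotations: Iterable[tuple[str, str]]
) -> TrnaCompleteness:
    """Completeness from tRNA isotype presence.

    ``annotations`` are (scaffold id, amino-acid isotype) rows as produced
    by common tRNA scanners; isotypes may be 3-letter names or 1-letter
    codes. Selenocysteine, pyrrolysine, suppressors and undetermined
    isotypes are ignored.
    """
    seen: set[str] = set()
    for _, isotype in annotations:
        iso = isotype.strip()
        iso = _ONE_TO_THREE.get(iso.upper(), iso.capitalize())
        if iso in _IGNORED_ISOTYPES or iso.capitalize() in {"Sec", "Pyl", "Sup", "Undet"}:
            continue
        if iso in STANDARD_ISOTYPES:
            seen.add(iso)
    n = len(seen)
    pct = 100.0 * n / 20.0
    display = ">99" if n == 20 else f"{pct:g}"
    return TrnaCompleteness(percent=pct, n_isotypes=n, display=display)


# ---------------------------------------------------------------------------
# Unique core genome
# ---------------------------------------------------------------------------

@dataclass
class OrthologTable:
    """Ortholog groups x genomes copy-count table."""

    genomes: list[str]
    counts: pd.DataFrame      # index: group id, columns: genomes, integer counts

    def __post_init__(self) -> None:
        missing = [g for g in self.counts.columns if g not in self.genomes]
        if missing:
            raise ValueError(f"groups name unknown genomes: {missing}")
        if not (self.counts.to_numpy() >= 0).all():
            raise ValueError("copy counts must be >= 0")

    @classmethod
    def from_tsv(cls, path: str) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.astype(int)
        return cls(genomes=list(df.columns), counts=df)


def unique_core_genome(table: OrthologTable) -> list[str]:
    """Groups present in exactly one copy in every genome.

    These universally single-copy orthologs form the concatenation set for
    multi-locus sequence analysis.
    """
    if table.counts.empty:
        raise ValueError("ortholog table is empty")
    mask = (table.counts[table.genomes] == 1).all(axis=1)
    return list(table.counts.index[mask])


# ---------------------------------------------------------------------------
# 16S-to-bin coverage linking
# ---------------------------------------------------------------------------

@dataclass
class LinkResult:
    sequence_id: str
    best_bin: str
    distance: float
    second_bin: str | None
    second_distance: float | None
    ambiguous: bool
    note: str = "coverage-only link; phylogenetic/MLSA evidence not considered"


def bin_profile(bin_: Bin, coverage: CoverageMatrix) -> np.ndarray:
    """Per-dataset mean depth over the bin's members."""
    sub = coverage.submatrix(bin_.sorted_members())
    return sub.mean(axis=0).to_numpy(dtype=float)


def link_16s_to_bins(
    seq_profiles: Mapping[str, Sequence[float]] | pd.DataFrame,
    bins: Mapping[str, Bin] | Sequence[Bin],
    coverage: CoverageMatrix,
    ambiguity_factor: float = 2.0,
    pseudo: float = 0.1,
) -> list[LinkResult]:
    """Assign each 16S-bearing scaffold to the bin with the nearest profile.

    Distance is Euclidean between log2(depth + pseudo) vectors of the
    sequence and of each bin's mean profile. A link is ambiguous when the
    runner-up distance is under ``ambiguity_factor`` times the best (or
    ties it exactly — two equidistant bins can never be told apart).
    """
    if isinstance(bins, Mapping):
        bin_list = [bins[k] for k in sorted(bins)]
    else:
        bin_list = sorted(bins, key=lambda b: b.bin_id)
    if not bin_list:
        raise ValueError("no bins to link against")
    if isinstance(seq_profiles, pd.DataFrame):
        seq_profiles = {sid: seq_profiles.loc[sid].to_numpy()
                        for sid in seq_profiles.index}

    profiles = {b.bin_id: np.log2(bin_profile(b, coverage) + pseudo)
                for b in bin_list}
    results: list[LinkResult] = []
    for sid in sorted(seq_profiles):
        v = np.log2(np.asarray(seq_profiles[sid], dtype=float) + pseudo)
        dists = sorted(
            ((float(np.linalg.norm(v - p)), bid) for bid, p in profiles.items()),
        )
        best_d, best_b = dists[0]
        if len(dists) > 1:
            second_d, second_b = dists[1]
            ambiguous = second_d < ambiguity_factor * best_d or second_d == best_d
        else:
            second_d, second_b, ambiguous = None, None, False
        results.append(
            LinkResult(sequence_id=sid, best_bin=best_b, distance=best_d,
                       second_bin=second_b, second_distance=second_d,
                       ambiguous=ambiguous)
        )
    return results


def link_report(results: Sequence[LinkResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_id": r.sequence_id,
                "best_bin": r.best_bin,
                "distance": r.distance,
                "second_bin": r.second_bin,
                "second_distance": r.second_distance,
                "ambiguous": r.ambiguous,
                "note": r.note,
            }
            for r in results
        ]
    )
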