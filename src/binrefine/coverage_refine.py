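"""Differential-coverage purification of genome bins.

Three steps, applied in order within the refinement pipeline:

1. **Median-outlier removal** — a scaffold whose mean depth exceeds a
   factor (default 3x) of the bin's median depth in any dataset is a
   coverage outlier and is removed. Medians are computed once on the input
   membership (single pass).

2. **Inverse-profile splitting** — a bin mixing two genomes that are
   abundant in opposite datasets shows a bimodal log2 depth ratio
   A/B. The bin is split at the largest gap in the sorted per-scaffold
   log-ratios when the gap is wide enough, both sides are big enough, and
   the two sides sit on opposite sides of ratio 0 ("high in A but low in
   B or vice versa").

3. **Iterative z-score purification** — per-dataset depths over the
   current membership are standardized to z-scores; the scaffold with the
   largest |z_A - z_B| above the cutoff is removed and the z-scores are
   recomputed after every single removal. The cutoff starts at 4 and is
   lowered by 1 each time no further offender exists, down to a final
   cutoff of 2 (i.e. a residual between-dataset difference of at most two
   standard deviations).

All operations are order-invariant (members are processed in sorted id
order, ties broken by lexicographically smallest id) and satisfy the
partition property kept ∪ removed == input with kept ∩ removed == ∅.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import Bin, CoverageMatrix, TraceRecord


# ---------------------------------------------------------------------------
# Median-outlier removal
# ---------------------------------------------------------------------------

@dataclass
class MedianFilterResult:
    kept: Bin
    removed: set[str]
    medians: dict[str, float]          # per dataset, computed on the input bin
    skipped_datasets: list[str]        # zero-median datasets excluded from the rule
    trace: list[TraceRecord] = field(default_factory=list)


def median_outlier_filter(
    bin_: Bin,
    coverage: CoverageMatrix,
    factor: float = 3.0,
    datasets: list[str] | None = None,
    require_all: bool = False,
    iterative: bool = False,
) -> MedianFilterResult:
    """Remove scaffolds with depth above ``factor`` x the bin median.

    The rule is evaluated per dataset; by default a scaffold is removed
    when it exceeds the threshold in *any* dataset (``require_all=True``
    demands every dataset). Datasets whose bin median is 0 are skipped
    with a flag — with a zero median the rule would remove every scaffold
    with positive depth, which is a degenerate reading. ``iterative=True``
    recomputes medians after each removal pass until stable (off by
    default: one filtering action, one set of medians).
    """
    if not bin_.members:
        raise ValueError(f"bin {bin_.bin_id!r} is empty")
    datasets = list(datasets) if datasets is not None else coverage.datasets
    members = bin_.sorted_members()
    sub = coverage.submatrix(members)[datasets]

    removed: set[str] = set()
    trace: list[TraceRecord] = []
    skipped: list[str] = []
    medians: dict[str, float] = {}
    current = list(members)
    while True:
        cur_sub = sub.loc[current]
        medians = {d: float(np.median(cur_sub[d].to_numpy())) for d in datasets}
        skipped = [d for d in datasets if medians[d] == 0.0]
        for d in skipped:
            trace.append(
                TraceRecord(
                    stage="median_filter", bin_id=bin_.bin_id, scaffold_id="*",
                    action="flag", reason="zero_median_dataset", values=f"dataset={d}",
                )
            )
        used = [d for d in datasets if medians[d] > 0.0]
        newly: list[str] = []
        for sid in current:
            over = [d for d in used if cur_sub.at[sid, d] > factor * medians[d]]
            hit = (len(over) == len(used) and used) if require_all else bool(over)
            if hit:
                newly.append(sid)
                trace.append(
                    TraceRecord(
                        stage="median_filter", bin_id=bin_.bin_id, scaffold_id=sid,
                        action="remove", reason="median_outlier", cutoff=factor,
                        values=";".join(
                            f"{d}={cur_sub.at[sid, d]:g}>{factor:g}x{medians[d]:g}"
                            for d in over
                        ),
                    )
                )
        removed.update(newly)
        current = [s for s in current if s not in removed]
        if not iterative or not newly or not current:
            break

    kept = Bin(bin_id=bin_.bin_id, members=set(members) - removed,
               target_taxon=bin_.target_taxon)
    return MedianFilterResult(kept=kept, removed=removed, medians=medians,
                              skipped_datasets=skipped, trace=trace)


# ---------------------------------------------------------------------------
# Inverse-profile sub-bin splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    parent: str
    sub_bins: list[Bin]
    split_statistic: float     # the largest gap in sorted log2 ratios
    was_split: bool
    reason: str = ""


def split_inverse_profiles(
    bin_: Bin,
    coverage: CoverageMatrix,
    dataset_a: str,
    dataset_b: str,
    min_gap_log2: float = 2.0,
    min_side: int = 5,
    pseudo: float = 0.1,
) -> SplitResult:
    """Split a bin whose members separate into inverse A/B coverage profiles.

    Per member, r = log2((depth_A + pseudo) / (depth_B + pseudo)). The
    split point is the largest gap between consecutive sorted ratios; the
    split fires only when the gap is at least ``min_gap_log2``, both sides
    hold at least ``min_side`` members, and the two sides' mean ratios
    have opposite signs (one sub-bin high in A, the other high in B).
    """
    members = bin_.sorted_members()
    if len(members) < 2 * min_side:
        return SplitResult(bin_.bin_id, [Bin(bin_.bin_id, set(members), bin_.target_taxon)],
                           0.0, False, reason="too_few_members")
    a = np.array([coverage.depth(s, dataset_a) for s in members])
    b = np.array([coverage.depth(s, dataset_b) for s in members])
    r = np.log2((a + pseudo) / (b + pseudo))
    order = np.argsort(r, kind="stable")
    r_sorted = r[order]
    gaps = np.diff(r_sorted)
    if len(gaps) == 0:
        return SplitResult(bin_.bin_id, [Bin(bin_.bin_id, set(members), bin_.target_taxon)],
                           0.0, False, reason="degenerate")
    k = int(np.argmax(gaps))           # first index of the largest gap
    gap = float(gaps[k])
    low_idx = order[: k + 1]
    high_idx = order[k + 1:]
    mean_low = float(np.mean(r[low_idx]))
    mean_high = float(np.mean(r[high_idx]))

    reason = ""
    if gap < min_gap_log2:
        reason = "gap_below_threshold"
    elif len(low_idx) < min_side or len(high_idx) < min_side:
        reason = "side_below_min_size"
    elif not (mean_low < 0.0 < mean_high):
        reason = "same_sign_profiles"
    if reason:
        return SplitResult(bin_.bin_id, [Bin(bin_.bin_id, set(members), bin_.target_taxon)],
                           gap, False, reason=reason)

    low = {members[i] for i in low_idx}
    high = {members[i] for i in high_idx}
    sub_bins = [
        Bin(f"{bin_.bin_id}.1", high, bin_.target_taxon),   # high in A
        Bin(f"{bin_.bin_id}.2", low, bin_.target_taxon),    # high in B
    ]
    return SplitResult(bin_.bin_id, sub_bins, gap, True)


# ---------------------------------------------------------------------------
# Iterative z-score purification
# ---------------------------------------------------------------------------

@dataclass
class ZState:
    """Z-scores of the current membership for the two differenced datasets."""

    bin_id: str
    datasets: tuple[str, str]
    members: list[str]
    z: dict[str, tuple[float, float]]   # scaffold -> (z_A, z_B)
    current_cutoff: float
    zero_variance: tuple[bool, bool]


def _zscores(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Standardize with the sample standard deviation (n-1 denominator).

    Zero variance (or n < 2) yields all-zero z-scores and a flag, so a
    constant-coverage dataset can never drive a removal.
    """
    if len(values) < 2:
        return np.zeros_like(values, dtype=float), True
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        return np.zeros_like(values, dtype=float), True
    return (values - float(np.mean(values))) / sd, False


def compute_zstate(
    bin_id: str,
    members: list[str],
    coverage: CoverageMatrix,
    dataset_a: str,
    dataset_b: str,
    cutoff: float,
) -> ZState:
    a = np.array([coverage.depth(s, dataset_a) for s in members])
    b = np.array([coverage.depth(s, dataset_b) for s in members])
    za, flat_a = _zscores(a)
    zb, flat_b = _zscores(b)
    return ZState(
        bin_id=bin_id,
        datasets=(dataset_a, dataset_b),
        members=list(members),
        z={s: (float(za[i]), float(zb[i])) for i, s in enumerate(members)},
        current_cutoff=cutoff,
        zero_variance=(flat_a, flat_b),
    )


@dataclass
class PurifyResult:
    kept: Bin
    removed: list[str]                 # in removal order
    trace: list[TraceRecord]
    early_stopped: bool = False        # min_members guard fired
    zero_variance_seen: bool = False
    final_state: ZState | None = None


def zscore_purify(
    bin_: Bin,
    coverage: CoverageMatrix,
    dataset_a: str,
    dataset_b: str,
    start_cutoff: float = 4.0,
    end_cutoff: float = 2.0,
    step: float = 1.0,
    min_members: int = 4,
    batch: bool = False,
) -> PurifyResult:
    """Iterative z-score decontamination of one bin.

    At cutoff c the per-dataset z-scores are computed over the *current*
    membership; while some member has |z_A - z_B| > c the single maximal
    offender is removed (ties broken by smallest id) and the z-scores are
    recomputed. When no offender remains the cutoff drops by ``step``;
    the procedure ends after the ``end_cutoff`` round, at which point
    every survivor satisfies |z_A - z_B| <= end_cutoff on the final
    membership. Removal halts early (flagged) rather than shrink the bin
    below ``min_members``. ``batch=True`` removes every above-cutoff
    member per recomputation instead of one at a time.
    """
    if not (start_cutoff >= end_cutoff > 0):
        raise ValueError("need start_cutoff >= end_cutoff > 0")
    if step <= 0:
        raise ValueError("step must be positive")
    if len(bin_.members) < min_members:
        raise ValueError(
            f"bin {bin_.bin_id!r} has {len(bin_.members)} members, "
            f"fewer than min_members={min_members}"
        )

    current = bin_.sorted_members()
    removed: list[str] = []
    trace: list[TraceRecord] = []
    early = False
    flat_seen = False
    state: ZState | None = None

    cutoffs: list[float] = []
    c = float(start_cutoff)
    while c > end_cutoff:
        cutoffs.append(c)
        c -= step
    cutoffs.append(float(end_cutoff))

    for cutoff in cutoffs:
        if early:
            break
        while True:
            state = compute_zstate(bin_.bin_id, current, coverage,
                                   dataset_a, dataset_b, cutoff)
            flat_seen = flat_seen or any(state.zero_variance)
            deltas = {s: abs(z[0] - z[1]) for s, z in state.z.items()}
            worst = max(deltas.values(), default=0.0)
            if worst <= cutoff:
                break
            offender = min(s for s, d in deltas.items() if d == worst)
            if len(current) - 1 < min_members:
                early = True
                trace.append(
                    TraceRecord(
                        stage="zscore_purify", bin_id=bin_.bin_id, scaffold_id="*",
                        action="flag", reason="min_members_guard", cutoff=cutoff,
                        values=f"members={len(current)}",
                    )
                )
                break
            if batch:
                batch_ids = sorted(s for s, d in deltas.items() if d > cutoff)
                if len(current) - len(batch_ids) < min_members:
                    batch_ids = [offender]   # fall back to one-at-a-time
                to_remove = batch_ids
            else:
                to_remove = [offender]
            for sid in to_remove:
                za, zb = state.z[sid]
                trace.append(
                    TraceRecord(
                        stage="zscore_purify", bin_id=bin_.bin_id, scaffold_id=sid,
                        action="remove", reason="zscore_outlier", cutoff=cutoff,
                        values=f"zA={za:.4f};zB={zb:.4f};delta={abs(za - zb):.4f}",
                    )
                )
                removed.append(sid)
            current = [s for s in current if s not in set(to_remove)]

    final_state = compute_zstate(bin_.bin_id, current, coverage,
                                 dataset_a, dataset_b, float(end_cutoff))
    kept = Bin(bin_id=bin_.bin_id, members=set(current), target_taxon=bin_.target_taxon)
    return PurifyResult(kept=kept, removed=removed, trace=trace,
                        early_stopped=early, zero_variance_seen=flat_seen,
                        final_state=final_state)
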