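# Methods

## Setting and assumptions

`binrefine` refines preliminary metagenome bins using the read-depth
profiles of scaffolds across two sequencing datasets of the same
community. The working assumption is the standard one behind
differential-coverage binning: scaffolds of one genome share an
abundance, so their depths move together across datasets, while a
scaffold mis-assigned from another genome follows a different profile.
Two datasets are the minimum that makes a *differential* signal; with
more than two, the purification operates on an explicitly configured
pair, and the remaining datasets still inform the median filter and the
linking/abundance estimators.

All depth inputs are mean per-base depths per scaffold per dataset.
Where depths are computed from SAM, only primary alignments contribute
and the mean is (aligned read bases)/(scaffold length), counting cigar
M/=/X positions; this matches a per-base depth dump of the same
alignment exactly, which the tests assert. The arithmetic mean was
chosen as the depth summary; a trimmed or median summary would be more
robust to repeats but is not what standard depth summarizers emit.

## Stage order and rationale

Stages run per bin in a fixed order: LCA filter → median-outlier
removal → inverse-profile split → (read recruitment for external
reassembly) → iterative z-score purification. Taxonomy acts first
because it is independent of coverage; the gross single-dataset
outliers are removed next so they cannot distort the ratio and z-score
statistics; splitting precedes z-score purification because a mixed bin
violates the single-population assumption the z-scores rest on.
Sub-bins produced by the split are purified independently. The LCA
filter is applied once, before reassembly, matching the narrative order
of the refinement it implements.

## The operations

**LCA filter.** Hits qualify with e-value ≤ `evalue_max` (default
1e-20) and bitscore ≥ (1 − `top_percent`/100) × the best qualifying
bitscore, the window applied within each hit source (protein- vs
nucleotide-level searches score on different scales) before pooling.
The scaffold's LCA is the deepest taxonomy node ancestral to every
qualifying hit taxon, computed by pairwise two-pointer ancestor
walking. A scaffold is removed only when the LCA lies at or below rank
"phylum" and that phylum differs from the bin's target — the
operational reading of "unambiguously assigned to another phylum". LCAs
above phylum rank (conflicting evidence) and unassigned scaffolds are
kept: absence or ambiguity of evidence is never treated as
contamination. The top-percent window (default 10%) is a choice this
package makes because MEGAN-style LCA requires one; it is exposed and
documented rather than asserted as anyone else's setting.

**Median-outlier removal.** Medians are computed once per dataset on
the input membership (single pass; an iterative variant that recomputes
after removals sits behind a flag). A scaffold is removed when it
exceeds `factor` × median (default 3) in *any* dataset — the OR reading
is the conservative contaminant-removal interpretation; AND semantics
are available by flag. Even-sized medians are the mean of the two
middle values. A dataset whose bin median is 0 is skipped with a flag:
with a zero median the rule degenerates to "remove everything with
positive depth".

**Inverse-profile split.** Ratios r = log₂((depth_A + 0.1)/(depth_B +
0.1)); the pseudocount keeps zero-depth scaffolds finite and its scale
(0.1×) is far below real depths of interest. The bin splits at the
largest gap of the sorted ratios when (i) the gap ≥ `min_gap_log2`
(default 2, i.e. a 4-fold change in relative abundance), (ii) both
sides have ≥ `min_side` members (default 5, so a sub-bin is a
population, not a straggler), and (iii) the two sides' mean ratios have
opposite signs — the sign condition encodes "high in A but low in B or
vice versa"; two groups both enriched in the same dataset are not
inverse profiles. Only the criterion, not an algorithm, is prescribed
by the refinement this implements; largest-gap-with-sign-condition is
this package's design.

**Z-score purification.** Per dataset, z-scores over the *current*
membership use the sample standard deviation (n−1): bins are small and
the purifier's test oracle must match the implementation's scale
convention exactly, so it is fixed and documented. The procedure
removes the single scaffold with the largest |z_A − z_B| above the
cutoff, then recomputes — one at a time, because the scores are defined
to be recalculated after every removal; a batch mode (all offenders per
recomputation) exists behind a flag for comparison. Cutoffs run 4 → 2
in steps of 1; after the final round every survivor satisfies
|z_A − z_B| ≤ 2 on the final membership, which the acceptance tests
assert. Ties break toward the lexicographically smallest scaffold id,
making the output independent of input order. Two guards: a dataset
with zero variance yields all-zero z-scores (flagged) so a constant
dataset cannot drive removals, and membership never drops below
`min_members` (default 4 — the smallest n where a sample standard
deviation is meaningfully stable); hitting the guard stops the loop
early with a flag rather than grinding a bin to nothing.

**Read recruitment.** "Entire length" is operationalized as an
alignment with no soft- or hard-clip cigar operations; mismatches and
indels are allowed, matching end-to-end alignment-mode semantics. Pairs
need both mates full-length on scaffolds of the same bin; a pair
spanning two bins is rejected for both, since such a pair is evidence
of ambiguity rather than of membership in either. A mate record missing
from the input demotes the present mate to an orphan with a warning
count. Secondary and supplementary records are ignored throughout.

**Estimators.** Relative abundance is the depth × length mass fraction
of the bin over a caller-supplied set of bacterial scaffolds; no
formula is standard for this quantity, so the basis string is attached
to every estimate. tRNA completeness is 100 × (distinct standard
isotypes)/20, displayed as ">99" when all 20 are present because a full
isotype set cannot distinguish complete from nearly complete.
`unique_core_genome` returns ortholog groups with copy count exactly 1
in every genome. 16S linking measures Euclidean distance between
log₂(depth + 0.1) profiles of a 16S-bearing scaffold and each bin's
mean profile; a link is flagged ambiguous when the runner-up is closer
than `ambiguity_factor` (default 2) × the best distance or exactly ties
it. The output carries an explicit coverage-only caveat: the
phylogenetic and multi-locus evidence that a full linking argument also
uses is out of scope here.

## The synthetic-data generator

`simulate_community` emulates the two-extraction study design:
depth(s, d) = A(g, d) · n_shared(s) · n_ds(s, d), with per-genome
abundance A = (between-genome lognormal, log-mean 3.0 ≈ 20×, log-sd
1.0) × (per-dataset lognormal effect, log-sd 0.7), a shared mean-one
lognormal scaffold effect (log-sd 0.25) and a small per-dataset
residual (log-sd 0.05). The split between shared and per-dataset noise
is the load-bearing modeling choice: scaffold-specific effects such as
mappability and composition bias act identically in both datasets, so
genuine members have nearly equal z-scores in A and B, while
contaminants break the equality. Defaults are 5 genomes × 50 scaffolds
(lognormal lengths, ≈3 kb), 10% planted contaminants per bin at an 8×
differential-abundance factor applied to one randomly chosen dataset,
one unbinned 16S-bearing scaffold per genome, and a toy taxonomy of one
phylum per genome with two genera × two species each. An optional
strain-pair mode makes genomes 0 and 1 near-identical in abundance and
GC, reproducing the hard case where differential coverage cannot
separate strains.

`simulate_hits` concentrates each scaffold's hits in its source phylum
(spanning two genera, so a noise-free LCA resolves to exactly the
phylum), redirects hits cross-phylum with a configurable probability at
reduced bitscore (50–95% of the best, so the top-percent window
discards most), and adds weak hits above the e-value cutoff to exercise
that filter.

What the generator does **not** model: sequence composition beyond
per-genome GC (no k-mer structure — no stage here uses composition),
assembly artifacts (chimeras, repeat-collapsed scaffolds), read-level
error profiles, and depth-versus-length covariance. Passing the
planted-contaminant tests therefore demonstrates that the statistics do
what they claim under the stated coverage model, not that real bins
from any particular habitat will be cleaned this well; on real data the
shared-noise assumption degrades when mappability differs between
library preparations.

## Numerical and I/O choices

- Depth table dialect: `name, length, totalAvgDepth, <sample>
  [, <sample>-var] …` (variance columns ignored); a plain `name,
  length, <sample>…` layout is also accepted. Per-base depth dumps are
  1-based inclusive; BED-style intervals are 0-based half-open; both
  reduce internally to mean depth only.
- GC excludes N bases from the denominator; an all-N sequence has
  undefined GC (`None`), never 0.
- Taxonomies load from a 4-column TSV or NCBI-style nodes/names dumps;
  exactly one root is required and connectivity is validated at load.
- Run reports contain parameters and results only; timestamps and
  file-system paths live in a sidecar so identically seeded runs are
  byte-identical and diffable.
- All iteration orders are sorted; every pseudo-random draw flows from
  a single integer seed through one generator, giving byte-identical
  FASTA/TSV/JSON outputs for identical specs.

## Problem sizes used in validation

The test suite and the acceptance script validate on: 100 random
unstructured fixtures of 10–200 scaffolds for the purifier-vs-oracle
check, a 200-node random taxonomy with 50 node pairs for the LCA
oracle, 50 fixtures for the median-filter oracle and the termination
contract, 20 simulated communities (the default spec above) for
planted-contaminant recovery, 3 communities at 10% hit noise for
conflict-flag agreement, 8 wide-spread communities for 16S linking, a
20-record hand-built SAM fixture for the recruitment rules, and two
identically seeded end-to-end runs for bitwise reproducibility. These
sizes give stable pass/fail behavior at interactive runtimes.

## Known limitations

- The purifier differs exactly one dataset pair; communities sequenced
  many times would be better served by a multivariate outlier model.
- The median filter's single-pass semantics can leave secondary
  outliers that only become visible after the first removals (the
  iterative flag addresses this at the cost of departing from the
  single-action definition).
- Coverage-only 16S linking cannot separate genomes with similar
  abundance profiles; its ambiguity flag is conservative by design.
- The abundance estimator depends entirely on the caller's definition
  of the bacterial denominator set.
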