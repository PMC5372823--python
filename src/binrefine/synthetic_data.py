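"""Fully labeled synthetic two-sample metagenome communities.

The generator emulates the study design every refinement stage assumes:
two sequencing datasets of the same community (e.g. two DNA extractions
of one biofilm) whose per-genome abundances differ, so that genuine bin
members share a coverage profile across datasets while contaminants from
other genomes break it.

Model, per scaffold ``s`` of genome ``g`` in dataset ``d``::

    depth(s, d) = A(g, d) * n_shared(s) * n_ds(s, d)

where ``A(g, d)`` is the genome's per-dataset abundance (a between-genome
lognormal times a per-dataset lognormal effect) and the noise terms are
mean-one lognormals. The shared term models scaffold-specific effects
(mappability, composition bias) that act identically in both datasets —
this is what makes between-dataset z-score differences small for true
members; the per-dataset term is residual sampling noise.

Planted contaminants are extra scaffolds attributed to a donor genome
from a different phylum, with the host bin's profile scaled by the
requested differential-abundance factor in one randomly chosen dataset.
Every scaffold is labeled in a truth table (source genome, contaminant
flag, 16S flag), and identical seeds give byte-identical outputs.

Sequences are i.i.d. bases at a genome-specific GC; no k-mer structure is
simulated because no stage of this toolkit uses composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .formats_io import (
    Bin,
    CoverageMatrix,
    HitRecord,
    HitTable,
    Scaffold,
    TaxonomyTree,
)

__all__ = ["SimSpec", "Community", "simulate_community", "simulate_hits",
           "toy_taxonomy", "write_community"]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated community; defaults give the standard
    test condition of five genomes x fifty scaffolds with 10% planted
    contaminants at an 8x differential abundance."""

    n_genomes: int = 5
    scaffolds_per_genome: int = 50
    scaffold_len_log_mean: float = 8.0      # ln bp; exp(8) ~ 3 kb
    scaffold_len_log_sd: float = 0.5
    min_scaffold_len: int = 500
    datasets: tuple[str, str] = ("sampleA", "sampleB")
    abundance_log_mean: float = 3.0         # ln depth; exp(3) ~ 20x
    abundance_log_sd: float = 1.0           # spread between genomes
    dataset_effect_log_sd: float = 0.7      # per-genome between-dataset variation
    noise_shared_log_sd: float = 0.25       # scaffold effect common to both datasets
    noise_dataset_log_sd: float = 0.05      # residual per-dataset scaffold noise
    contamination_rate: float = 0.1         # planted contaminants per bin
    contaminant_delta: float = 8.0          # differential-abundance factor
    strain_pair: bool = False               # genomes 0 and 1 become near-strains
    strain_log_sd: float = 0.1              # abundance divergence of the strain pair
    n_16s_per_genome: int = 1
    len_16s: int = 1500
    gc_low: float = 0.35
    gc_high: float = 0.65
    with_sequences: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must be in [0, 1]")
        if self.contamination_rate > 0 and self.n_genomes < 2:
            raise ValueError("contaminants need at least two genomes to sample from")
        if self.min_scaffold_len <= 0 or self.len_16s <= 0:
            raise ValueError("lengths must be > 0")
        if self.contaminant_delta <= 1.0:
            raise ValueError("contaminant_delta must exceed 1")
        if self.strain_pair and self.n_genomes < 2:
            raise ValueError("a strain pair needs at least two genomes")


@dataclass
class Community:
    spec: SimSpec
    scaffolds: dict[str, Scaffold]
    true_bins: dict[str, Bin]
    contaminated_bins: dict[str, Bin]
    coverage: CoverageMatrix
    truth: pd.DataFrame
    taxonomy: TaxonomyTree
    genome_phylum: dict[str, str]           # genome -> phylum node id
    abundance: pd.DataFrame                 # genome x dataset specified abundance

    def sixteen_s_ids(self) -> list[str]:
        return sorted(self.truth.loc[self.truth["is_16s"], "scaffold_id"])


def toy_taxonomy(n_phyla: int) -> TaxonomyTree:
    """A small rooted taxonomy: root -> phyla -> 2 genera -> 2 species each."""
    n_phyla = max(3, n_phyla)
    nodes: dict[str, tuple[str, str, str]] = {"root": ("root", "no rank", "root")}
    for p in range(1, n_phyla + 1):
        pid = f"p{p}"
        nodes[pid] = ("root", "phylum", f"Phylum{p}")
        for g in (1, 2):
            gid = f"{pid}.g{g}"
            nodes[gid] = (pid, "genus", f"Genus{p}.{g}")
            for s in (1, 2):
                sid = f"{gid}.s{s}"
                nodes[sid] = (gid, "species", f"Species{p}.{g}.{s}")
    return TaxonomyTree(nodes)


def _lognormal(rng: np.random.Generator, log_sd: float, size=None) -> np.ndarray:
    """Mean-one lognormal noise (log-sd corrected so E[X] = 1)."""
    return np.exp(rng.normal(-0.5 * log_sd**2, log_sd, size=size))


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("AGCT")), size=length, p=p))


def simulate_community(spec: SimSpec) -> Community:
    """Generate one labeled community under ``spec`` (deterministic in seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    taxonomy = toy_taxonomy(spec.n_genomes)
    n_phyla = max(3, spec.n_genomes)
    d_a, d_b = spec.datasets

    genomes = [f"g{i}" for i in range(spec.n_genomes)]
    genome_phylum = {g: f"p{(i % n_phyla) + 1}" for i, g in enumerate(genomes)}
    genome_gc = {g: float(rng.uniform(spec.gc_low, spec.gc_high)) for g in genomes}

    # per-genome per-dataset abundance
    base = np.exp(rng.normal(spec.abundance_log_mean, spec.abundance_log_sd,
                             size=spec.n_genomes))
    effect = np.exp(rng.normal(0.0, spec.dataset_effect_log_sd,
                               size=(spec.n_genomes, 2)))
    abundance = base[:, None] * effect
    if spec.strain_pair and spec.n_genomes >= 2:
        # genome 1 shadows genome 0 with only slight abundance divergence
        abundance[1] = abundance[0] * np.exp(
            rng.normal(0.0, spec.strain_log_sd, size=2))
        genome_gc[genomes[1]] = genome_gc[genomes[0]]
    abundance_df = pd.DataFrame(abundance, index=genomes, columns=[d_a, d_b])

    scaffolds: dict[str, Scaffold] = {}
    depth: dict[str, dict[str, float]] = {}
    truth_rows: list[dict] = []
    true_bins: dict[str, Bin] = {}
    contaminated_bins: dict[str, Bin] = {}

    def add_scaffold(sid: str, length: int, genome: str,
                     d_vec: tuple[float, float]) -> None:
        seq = _random_sequence(rng, length, genome_gc[genome]) \
            if spec.with_sequences else None
        scaffolds[sid] = Scaffold(id=sid, length=length, sequence=seq)
        depth[sid] = {d_a: d_vec[0], d_b: d_vec[1]}

    def noisy(profile: np.ndarray) -> tuple[float, float]:
        shared = _lognormal(rng, spec.noise_shared_log_sd)
        ds = _lognormal(rng, spec.noise_dataset_log_sd, size=2)
        v = profile * shared * ds
        return float(v[0]), float(v[1])

    for gi, genome in enumerate(genomes):
        bin_id = f"bin_{genome}"
        members: set[str] = set()
        lengths = np.exp(rng.normal(spec.scaffold_len_log_mean,
                                    spec.scaffold_len_log_sd,
                                    size=spec.scaffolds_per_genome))
        lengths = np.maximum(lengths.astype(int), spec.min_scaffold_len)
        for j in range(spec.scaffolds_per_genome):
            sid = f"{genome}_s{j:03d}"
            add_scaffold(sid, int(lengths[j]), genome, noisy(abundance[gi]))
            members.add(sid)
            truth_rows.append(dict(scaffold_id=sid, source_genome=genome,
                                   true_bin=bin_id, planted_bin=bin_id,
                                   is_contaminant=False, is_16s=False))
        for k in range(spec.n_16s_per_genome):
            sid = f"{genome}_16s_{k}"
            add_scaffold(sid, spec.len_16s, genome, noisy(abundance[gi]))
            truth_rows.append(dict(scaffold_id=sid, source_genome=genome,
                                   true_bin="", planted_bin="",
                                   is_contaminant=False, is_16s=True))
        true_bins[bin_id] = Bin(bin_id=bin_id, members=set(members),
                                target_taxon=genome_phylum[genome])

    # planted contaminants: extra donor-genome scaffolds whose profile is the
    # host's scaled by the differential factor in one random dataset
    for gi, genome in enumerate(genomes):
        bin_id = f"bin_{genome}"
        members = set(true_bins[bin_id].members)
        n_cont = int(round(spec.contamination_rate * spec.scaffolds_per_genome))
        for k in range(n_cont):
            donors = [g for g in genomes if g != genome]
            donor = donors[int(rng.integers(len(donors)))]
            direction = int(rng.integers(2))        # 0: boost A, 1: boost B
            profile = abundance[gi].copy()
            profile[direction] *= spec.contaminant_delta
            sid = f"{genome}_cont{k:02d}"
            length = max(spec.min_scaffold_len,
                         int(np.exp(rng.normal(spec.scaffold_len_log_mean,
                                               spec.scaffold_len_log_sd))))
            add_scaffold(sid, length, donor, noisy(profile))
            members.add(sid)
            truth_rows.append(dict(scaffold_id=sid, source_genome=donor,
                                   true_bin="", planted_bin=bin_id,
                                   is_contaminant=True, is_16s=False))
        contaminated_bins[bin_id] = Bin(bin_id=bin_id, members=members,
                                        target_taxon=genome_phylum[genome])

    truth = pd.DataFrame(truth_rows).sort_values("scaffold_id").reset_index(drop=True)
    coverage = CoverageMatrix.from_dict(depth, datasets=[d_a, d_b])
    return Community(spec=spec, scaffolds=scaffolds, true_bins=true_bins,
                     contaminated_bins=contaminated_bins, coverage=coverage,
                     truth=truth, taxonomy=taxonomy,
                     genome_phylum=genome_phylum, abundance=abundance_df)


def simulate_hits(
    community: Community,
    cross_phylum_noise: float = 0.1,
    hits_per_scaffold: int = 6,
    evalue_exponent_range: tuple[float, float] = (25.0, 40.0),
    weak_hits: int = 1,
    seed: int | None = None,
) -> HitTable:
    """Homology hits concentrated in each scaffold's true phylum.

    Each scaffold receives ``hits_per_scaffold`` hits. The first two go to
    species in different genera of the source phylum (so a noise-free LCA
    resolves to exactly the phylum), the rest to random species of the
    phylum. With probability ``cross_phylum_noise`` a hit is redirected to
    a random species of a *different* phylum at a reduced bitscore (50-95%
    of the best), mimicking spurious cross-phylum homology that a
    top-percent window mostly discards. ``weak_hits`` extra hits per
    scaffold carry e-values above the usual 1e-20 cutoff and exercise the
    e-value filter.
    """
    spec = community.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    taxonomy = community.taxonomy
    phyla = sorted({p for p in community.genome_phylum.values()})
    all_phyla = sorted({n for n in taxonomy.nodes if taxonomy.rank(n) == "phylum"})
    lo, hi = evalue_exponent_range

    def species_of(phylum: str, genus: int, sp: int) -> str:
        return f"{phylum}.g{genus}.s{sp}"

    records: list[HitRecord] = []
    truth = community.truth.set_index("scaffold_id")
    for sid in sorted(community.scaffolds):
        genome = truth.at[sid, "source_genome"]
        phylum = community.genome_phylum[genome]
        best = float(rng.uniform(200.0, 400.0))
        for h in range(hits_per_scaffold):
            if h == 0:
                taxon = species_of(phylum, 1, 1)
            elif h == 1:
                taxon = species_of(phylum, 2, 1)
            else:
                taxon = species_of(phylum, int(rng.integers(1, 3)),
                                   int(rng.integers(1, 3)))
            score = best * float(rng.uniform(0.96, 1.0))
            if rng.random() < cross_phylum_noise:
                foreign = [p for p in all_phyla if p != phylum]
                taxon = species_of(foreign[int(rng.integers(len(foreign)))],
                                   int(rng.integers(1, 3)), int(rng.integers(1, 3)))
                score = best * float(rng.uniform(0.50, 0.95))
            evalue = 10.0 ** (-float(rng.uniform(lo, hi)))
            source = "blastx" if h % 2 == 0 else "blastn"
            records.append(HitRecord(sid, taxon, evalue, score, source))
        for _ in range(weak_hits):
            taxon = species_of(all_phyla[int(rng.integers(len(all_phyla)))],
                               int(rng.integers(1, 3)), int(rng.integers(1, 3)))
            records.append(HitRecord(sid, taxon, 1e-10, best * 0.99, "blastn"))
    return HitTable(records)


# ---------------------------------------------------------------------------
# File emission (exact formats the readers consume)
# ---------------------------------------------------------------------------

def write_community(
    community: Community,
    out_dir: str | Path,
    hits: HitTable | None = None,
) -> dict[str, str]:
    """Emit the community as the plain-text formats the toolkit reads.

    Writes scaffold FASTA (when sequences were generated), true and
    contaminated contig2bin tables, a contig-depth summary TSV, the toy
    taxonomy, the truth table, and optionally a BLAST-like hit table.
    Output is byte-identical for identical specs (fixed orderings, fixed
    float formatting).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    if community.spec.with_sequences:
        fasta = out / "scaffolds.fasta"
        with open(fasta, "w") as fh:
            for sid in sorted(community.scaffolds):
                fh.write(f">{sid}\n{community.scaffolds[sid].sequence}\n")
        paths["scaffolds_fasta"] = str(fasta)

    for label, bins in (("true", community.true_bins),
                        ("contaminated", community.contaminated_bins)):
        path = out / f"contig2bin_{label}.tsv"
        with open(path, "w") as fh:
            for bid in sorted(bins):
                for sid in bins[bid].sorted_members():
                    fh.write(f"{sid}\t{bid}\n")
        paths[f"contig2bin_{label}"] = str(path)

    d_a, d_b = community.spec.datasets
    depth_path = out / "depth.tsv"
    with open(depth_path, "w") as fh:
        fh.write(f"contigName\tcontigLen\ttotalAvgDepth\t{d_a}\t{d_b}\n")
        for sid in sorted(community.scaffolds):
            a = community.coverage.depth(sid, d_a)
            b = community.coverage.depth(sid, d_b)
            fh.write(f"{sid}\t{community.scaffolds[sid].length}\t"
                     f"{(a + b) / 2:.6f}\t{a:.6f}\t{b:.6f}\n")
    paths["depth_tsv"] = str(depth_path)

    tax_path = out / "taxonomy.tsv"
    with open(tax_path, "w") as fh:
        for nid in sorted(community.taxonomy.nodes):
            parent, rank, name = community.taxonomy.nodes[nid]
            fh.write(f"{nid}\t{parent}\t{rank}\t{name}\n")
    paths["taxonomy_tsv"] = str(tax_path)

    truth_path = out / "truth.tsv"
    community.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth_tsv"] = str(truth_path)

    targets_path = out / "target_phyla.tsv"
    with open(targets_path, "w") as fh:
        for bid in sorted(community.contaminated_bins):
            fh.write(f"{bid}\t{community.contaminated_bins[bid].target_taxon}\n")
    paths["target_phyla_tsv"] = str(targets_path)

    if hits is not None:
        hits_path = out / "hits.tsv"
        with open(hits_path, "w") as fh:
            df = hits.df.sort_values(
                ["scaffold_id", "source", "taxon_id", "bitscore"]
            ).reset_index(drop=True)
            for row in df.itertuples(index=False):
                # outfmt-6-like: 12 standard columns + taxid; unused fields 0
                fh.write(
                    f"{row.scaffold_id}\t{row.source}_subject\t0\t0\t0\t0\t0\t0\t0\t0\t"
                    f"{row.evalue:.3e}\t{row.bitscore:.2f}\t{row.taxon_id}\n"
                )
        paths["hits_tsv"] = str(hits_path)
    return paths
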