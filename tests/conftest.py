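"""Shared fixtures: tiny taxonomies, toy coverage matrices, random fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from binrefine.formats_io import Bin, CoverageMatrix, TaxonomyTree


@pytest.fixture
def small_taxonomy() -> TaxonomyTree:
    """root -> 3 phyla; pA has two genera with two species each."""
    nodes = {
        "root": ("root", "no rank", "root"),
        "pA": ("root", "phylum", "PhylumA"),
        "pB": ("root", "phylum", "PhylumB"),
        "pC": ("root", "phylum", "PhylumC"),
        "pA.g1": ("pA", "genus", "GenusA1"),
        "pA.g2": ("pA", "genus", "GenusA2"),
        "pA.g1.s1": ("pA.g1", "species", "SpA11"),
        "pA.g1.s2": ("pA.g1", "species", "SpA12"),
        "pA.g2.s1": ("pA.g2", "species", "SpA21"),
        "pB.g1": ("pB", "genus", "GenusB1"),
        "pB.g1.s1": ("pB.g1", "species", "SpB11"),
        "pC.g1": ("pC", "genus", "GenusC1"),
        "pC.g1.s1": ("pC.g1", "species", "SpC11"),
    }
    return TaxonomyTree(nodes)


def make_coverage(depths: dict[str, tuple[float, ...]],
                  datasets: tuple[str, ...] = ("A", "B")) -> CoverageMatrix:
    """Coverage matrix from {scaffold: per-dataset depth tuple}."""
    return CoverageMatrix.from_dict(
        {sid: dict(zip(datasets, v)) for sid, v in depths.items()},
        datasets=list(datasets),
    )


def make_bin(depths: dict[str, tuple[float, ...]], bin_id: str = "b1",
             target: str | None = None) -> Bin:
    return Bin(bin_id=bin_id, members=set(depths), target_taxon=target)


def random_taxonomy(rng: np.random.Generator, n_nodes: int = 200) -> TaxonomyTree:
    """Random tree: each node's parent drawn among earlier nodes.

    Second-level nodes get rank "phylum", deeper nodes cycle through
    lower ranks; node ids are zero-padded so ordering is stable.
    """
    ranks = ["class", "order", "family", "genus", "species"]
    nodes: dict[str, tuple[str, str, str]] = {"n000": ("n000", "no rank", "root")}
    depths = {"n000": 0}
    for i in range(1, n_nodes):
        nid = f"n{i:03d}"
        parent = f"n{int(rng.integers(i)):03d}"
        d = depths[parent] + 1
        depths[nid] = d
        rank = "phylum" if d == 1 else ranks[min(d - 2, len(ranks) - 1)]
        nodes[nid] = (parent, rank, nid)
    return TaxonomyTree(nodes)


def random_coverage_fixture(rng: np.random.Generator, n: int,
                            datasets: tuple[str, str] = ("A", "B")):
    """A random bin + coverage with uniform depths (unstructured fixture)."""
    depths = {f"s{i:03d}": (float(rng.uniform(0, 50)), float(rng.uniform(0, 50)))
              for i in range(n)}
    return make_bin(depths), make_coverage(depths, datasets)
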