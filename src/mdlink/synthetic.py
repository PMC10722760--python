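"""Synthetic bipartite networks with planted block structure, and random disease DAGs.

The generator emulates the statistical regime of curated microbe-disease
association catalogues: a sparse binary bipartite matrix (a few percent
density), many more microbes than diseases, and community structure in
which groups of microbes co-associate with groups of diseases.  Microbes
and diseases are assigned to ``n_blocks`` co-clusters; a (microbe, disease)
edge appears with probability ``p_in`` when the two blocks are paired and
``p_out`` otherwise.

``make_benchmark`` additionally builds a disease ontology DAG in which
block-mate diseases share a block-level ancestor, so DAG semantic
similarity correlates with the planted structure the way real ontologies
correlate with real co-association patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import AssociationNetwork, DiseaseOntologyGraph

__all__ = [
    "SyntheticSpec",
    "generate_block_bipartite",
    "generate_random_dag",
    "make_benchmark",
    "BENCHMARK_SPEC",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block bipartite generator.

    Defaults give a 200 x 40 network with 4 blocks at p_in = 0.3,
    p_out = 0.01 (overall density a few percent, microbe:disease ratio 5:1),
    small enough that a full masked-mode 10-fold cross-validation runs in
    minutes on one CPU while preserving the scale imbalance of real
    association catalogues.
    """

    n_microbes: int = 200
    n_diseases: int = 40
    n_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.01
    dag_depth: int = 3
    dag_branching: int = 2
    min_degree: int = 0
    seed: int = 13

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_blocks > min(self.n_microbes, self.n_diseases):
            raise ValueError("n_blocks cannot exceed the smaller node set")
        if self.n_blocks < 1 or self.dag_depth < 1:
            raise ValueError("n_blocks and dag_depth must be >= 1")


#: The reference benchmark instance used throughout the test-suite.
BENCHMARK_SPEC = SyntheticSpec()


def _block_assignment(n: int, n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform block labels, with every block guaranteed non-empty."""
    labels = rng.integers(0, n_blocks, size=n)
    labels[:n_blocks] = np.arange(n_blocks)  # pin one member per block
    rng.shuffle(labels)
    return labels


def generate_block_bipartite(
    spec: SyntheticSpec,
) -> tuple[AssociationNetwork, np.ndarray, np.ndarray]:
    """Sample a planted-block network; returns (network, microbe_blocks, disease_blocks).

    Edge (i, j) ~ Bernoulli(p_in) when microbe block i equals disease block j,
    else Bernoulli(p_out).  With ``min_degree=1`` each isolated node is
    repaired with one random edge into its own paired block.
    """
    rng = np.random.default_rng(spec.seed)
    mb = _block_assignment(spec.n_microbes, spec.n_blocks, rng)
    db = _block_assignment(spec.n_diseases, spec.n_blocks, rng)
    paired = mb[:, None] == db[None, :]
    p = np.where(paired, spec.p_in, spec.p_out)
    Y = (rng.random((spec.n_microbes, spec.n_diseases)) < p).astype(np.int8)

    if spec.min_degree >= 1:
        for i in np.flatnonzero(Y.sum(axis=1) == 0):
            js = np.flatnonzero(db == mb[i])
            Y[i, rng.choice(js)] = 1
        for j in np.flatnonzero(Y.sum(axis=0) == 0):
            is_ = np.flatnonzero(mb == db[j])
            Y[rng.choice(is_), j] = 1

    microbe_ids = tuple(f"m{i:04d}" for i in range(spec.n_microbes))
    disease_ids = tuple(f"d{j:03d}" for j in range(spec.n_diseases))
    return AssociationNetwork(microbe_ids, disease_ids, Y), mb, db


def generate_random_dag(
    n_terms: int, depth: int, branching: int, seed: int
) -> DiseaseOntologyGraph:
    """Layered random DAG: terms on levels 0..depth-1, each non-root term
    drawing 1..branching parents from strictly higher (smaller-index) levels.

    Acyclic by construction; depth=1 yields an edgeless forest of roots.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    depth = min(depth, n_terms)
    levels = rng.integers(0, depth, size=n_terms)
    levels[:depth] = np.arange(depth)  # every level non-empty
    rng.shuffle(levels)
    # ensure term order is irrelevant: name terms t000..; parents from lower levels
    terms = [f"t{i:03d}" for i in range(n_terms)]
    c2p: dict[str, set[str]] = {}
    for i in range(n_terms):
        if levels[i] == 0:
            continue
        pool = np.flatnonzero(levels < levels[i])
        k = int(rng.integers(1, branching + 1))
        parents = rng.choice(pool, size=min(k, pool.size), replace=False)
        c2p[terms[i]] = {terms[int(p)] for p in parents}
    return DiseaseOntologyGraph(
        frozenset(terms), {c: frozenset(p) for c, p in c2p.items()}
    )


def make_benchmark(
    spec: SyntheticSpec = BENCHMARK_SPEC,
) -> tuple[AssociationNetwork, DiseaseOntologyGraph, dict]:
    """Network + block-aligned disease DAG + planted truth.

    The DAG has a single synthetic root, one ancestor term per block, and
    each disease as a leaf under its block ancestor (with a within-block
    chain of depth up to ``dag_depth`` so contributions vary).  Block-mate
    diseases therefore share more ancestor mass than cross-block pairs.

    Returns ``(network, dag, truth)`` where truth maps node ids to planted
    block labels and records the spec.
    """
    net, mb, db = generate_block_bipartite(spec)
    rng = np.random.default_rng(spec.seed + 1)

    root = "ROOT"
    terms: set[str] = {root}
    c2p: dict[str, set[str]] = {}
    for b in range(spec.n_blocks):
        anc = f"BLOCK{b}"
        terms.add(anc)
        c2p[anc] = {root}
        members = [net.disease_ids[j] for j in np.flatnonzero(db == b)]
        # chain a few diseases under the block ancestor to vary DAG depth
        for pos, d in enumerate(members):
            terms.add(d)
            if pos == 0 or spec.dag_depth <= 2:
                c2p[d] = {anc}
            else:
                # attach to a random earlier block-mate or the ancestor
                parent = members[int(rng.integers(0, pos))] if rng.random() < 0.5 else anc
                c2p[d] = {parent}
    dag = DiseaseOntologyGraph(
        frozenset(terms), {c: frozenset(p) for c, p in c2p.items()}
    )
    truth = {
        "microbe_blocks": {net.microbe_ids[i]: int(mb[i]) for i in range(net.n_microbes)},
        "disease_blocks": {net.disease_ids[j]: int(db[j]) for j in range(net.n_diseases)},
        "spec": spec,
    }
    return net, dag, truth
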