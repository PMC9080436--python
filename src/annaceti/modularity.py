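"""Connectivity-module detection and the parcellation descriptor.

Modules are detected by seeded Louvain modularity maximization with restarts;
the partition with the highest Newman modularity Q is kept, with deterministic
tie-breaking (fewer blocks, then lexicographically smallest block
fingerprint).  Parcellation P = 1 - sum_i (n_i/N)^2 summarizes how evenly the
bones spread over the recovered modules.  Because module detection in
anatomical networks is unstable, a consensus variant re-clusters the
co-assignment matrix over many runs and scores per-bone stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network_model import AnatomicalNetwork


@dataclass
class ModulePartition:
    """Disjoint bone blocks covering the network, with modularity score Q."""

    taxon: str
    blocks: list[frozenset[str]]
    Q: float
    method_seed: int
    n_restarts: int
    resolution: float = 1.0
    stability: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.blocks or any(not b for b in self.blocks):
            raise ValueError("partition blocks must be non-empty")
        all_nodes = [n for b in self.blocks for n in b]
        if len(all_nodes) != len(set(all_nodes)):
            raise ValueError("partition blocks must be disjoint")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def nodes(self) -> set[str]:
        return {n for b in self.blocks for n in b}

    def block_of(self, name: str) -> int:
        for i, b in enumerate(self.blocks):
            if name in b:
                return i
        raise KeyError(name)

    def fingerprint(self) -> tuple:
        """Canonical order-free representation for deterministic tie-breaking."""
        return tuple(sorted(tuple(sorted(b)) for b in self.blocks))

    def to_dict(self) -> dict:
        d = {
            "taxon": self.taxon,
            "Q": self.Q,
            "blocks": [sorted(b) for b in self.fingerprint()],
            "method_seed": self.method_seed,
            "n_restarts": self.n_restarts,
            "resolution": self.resolution,
        }
        if self.stability is not None:
            d["stability"] = dict(sorted(self.stability.items()))
        return d


def _louvain_once(g: nx.Graph, resolution: float, seed: int) -> list[frozenset[str]]:
    comms = nx.community.louvain_communities(g, resolution=resolution, seed=seed)
    return [frozenset(c) for c in comms]


def _partition_key(g: nx.Graph, blocks: list[frozenset[str]], resolution: float,
                   ) -> tuple:
    q = nx.community.modularity(g, blocks, resolution=resolution)
    fingerprint = tuple(sorted(tuple(sorted(b)) for b in blocks))
    # maximize Q, then fewer blocks, then smallest fingerprint
    return (-q, len(blocks), fingerprint)


def detect_modules(net: AnatomicalNetwork, resolution: float = 1.0,
                   n_restarts: int = 100, seed: int = 0) -> ModulePartition:
    """Best-Q Louvain partition over ``n_restarts`` seeded restarts.

    Restart r uses the derived seed ``seed + r``; the result is
    bit-reproducible for a fixed (seed, n_restarts, resolution).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    g = net.to_networkx()
    best_blocks: list[frozenset[str]] | None = None
    best_key: tuple | None = None
    for r in range(n_restarts):
        blocks = _louvain_once(g, resolution, seed + r)
        key = _partition_key(g, blocks, resolution)
        if best_key is None or key < best_key:
            best_key, best_blocks = key, blocks
    assert best_blocks is not None and best_key is not None
    return ModulePartition(
        taxon=net.taxon,
        blocks=sorted(best_blocks, key=lambda b: sorted(b)),
        Q=-best_key[0],
        method_seed=seed,
        n_restarts=n_restarts,
        resolution=resolution,
    )


def parcellation(partition: ModulePartition) -> float:
    """Parcellation P = 1 - sum over blocks of (block size / N)^2."""
    sizes = np.array([len(b) for b in partition.blocks], dtype=float)
    n = sizes.sum()
    if n == 0:
        raise ValueError("empty partition")
    return float(1.0 - np.sum((sizes / n) ** 2))


def parcellation_from_sizes(sizes: list[int]) -> float:
    """P from block sizes alone (no partition object needed)."""
    arr = np.array(sizes, dtype=float)
    if arr.sum() == 0 or (arr <= 0).any():
        raise ValueError("block sizes must be positive")
    return float(1.0 - np.sum((arr / arr.sum()) ** 2))


def merge_pairs(partition: ModulePartition, net: AnatomicalNetwork) -> ModulePartition:
    """Merge any two blocks that are left/right images of each other.

    Lets P be computed with mirrored left/right modules counted as one,
    for networks whose best partition splits a region into side halves.
    """
    blocks = list(partition.blocks)
    merged = True
    while merged:
        merged = False
        for i in range(len(blocks)):
            mirror_i = {net.mirror_of(n) or n for n in blocks[i]}
            for j in range(i + 1, len(blocks)):
                if mirror_i == set(blocks[j]):
                    blocks[i] = blocks[i] | blocks[j]
                    del blocks[j]
                    merged = True
                    break
            if merged:
                break
    g = net.to_networkx()
    return ModulePartition(
        taxon=partition.taxon,
        blocks=sorted(blocks, key=lambda b: sorted(b)),
        Q=nx.community.modularity(g, blocks, resolution=partition.resolution),
        method_seed=partition.method_seed,
        n_restarts=partition.n_restarts,
        resolution=partition.resolution,
    )


def consensus_modules(net: AnatomicalNetwork, n_runs: int = 100, seed: int = 0,
                      resolution: float = 1.0) -> ModulePartition:
    """Consensus partition over ``n_runs`` Louvain runs, with node stability.

    The fraction of runs co-assigning each bone pair forms a weighted
    co-assignment graph, which is re-clustered (Louvain, derived seed) to give
    the consensus blocks.  A bone's stability is the mean, over runs, of the
    Jaccard overlap between its run block and its consensus block — 1.0 when
    every run reproduces the consensus exactly.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    g = net.to_networkx()
    names = sorted(g.nodes)
    index = {n: i for i, n in enumerate(names)}
    co = np.zeros((len(names), len(names)))
    run_blocks: list[list[frozenset[str]]] = []
    for r in range(n_runs):
        blocks = _louvain_once(g, resolution, seed + r)
        run_blocks.append(blocks)
        for block in blocks:
            idx = [index[n] for n in block]
            co[np.ix_(idx, idx)] += 1
    co /= n_runs
    cg = nx.Graph()
    cg.add_nodes_from(names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            if co[i, j] > 0:
                cg.add_edge(a, names[j], weight=co[i, j])
    consensus = [frozenset(c) for c in
                 nx.community.louvain_communities(cg, weight="weight",
                                                  seed=seed + n_runs)]
    member: dict[str, frozenset[str]] = {}
    for block in consensus:
        for n in block:
            member[n] = block
    stability = {}
    for n in names:
        cons_block = member[n]
        overlaps = []
        for blocks in run_blocks:
            run_block = next(b for b in blocks if n in b)
            inter = len(run_block & cons_block)
            union = len(run_block | cons_block)
            overlaps.append(inter / union)
        stability[n] = float(np.mean(overlaps))
    return ModulePartition(
        taxon=net.taxon,
        blocks=sorted(consensus, key=lambda b: sorted(b)),
        Q=nx.community.modularity(g, consensus, resolution=resolution),
        method_seed=seed,
        n_restarts=n_runs,
        resolution=resolution,
        stability=stability,
    )
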