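"""Whole-network descriptors of skull organization.

Eight quantities characterize each skull network: node count N, link count K,
density D (complexity: realized over maximum possible contacts), average path
length L (integration by proximity), average clustering coefficient C
(integration with the immediate surroundings), heterogeneity H (anisomerism:
coefficient of variation of the degrees), parcellation P (modularity of the
best node partition, see :mod:`annaceti.modularity`) and the unpaired-bone
ratio UBR (fraction of midline bones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network_model import AnatomicalNetwork

logger = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = ["taxon", "N", "K", "D", "L", "C", "H", "P", "UBR"]


class UndefinedDescriptorError(ValueError):
    """A descriptor is undefined for this network (too small or disconnected)."""


@dataclass
class DescriptorSet:
    """The per-taxon descriptor vector (N, K, D, L, C, H, P, UBR)."""

    taxon: str
    N: int
    K: int
    D: float
    L: float
    C: float
    H: float
    P: float | None
    UBR: float

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in DESCRIPTOR_COLUMNS}


def density(net: AnatomicalNetwork) -> float:
    """Density D = K / (N(N-1)/2): realized fraction of possible bone contacts."""
    n, k = net.n_bones, net.n_links
    if n < 2:
        raise UndefinedDescriptorError("density undefined for N < 2")
    return 2.0 * k / (n * (n - 1))


def heterogeneity(net: AnatomicalNetwork, population_sd: bool = False) -> float:
    """Heterogeneity H = sd(degrees) / mean(degrees).

    The coefficient of variation of the degree sequence; 0 iff the graph is
    regular.  Sample sd (n-1 denominator) by default, population sd on request.
    """
    if net.n_bones < 2:
        raise UndefinedDescriptorError("heterogeneity undefined for N < 2")
    degrees = np.array([net.degree(b) for b in net.bones], dtype=float)
    mean = degrees.mean()
    if mean == 0:
        raise UndefinedDescriptorError("heterogeneity undefined for a linkless network")
    return float(degrees.std(ddof=0 if population_sd else 1) / mean)


def average_clustering(net: AnatomicalNetwork, exclude_low_degree: bool = False) -> float:
    """Average clustering coefficient C.

    Unweighted mean of the local clustering coefficient over all bones;
    degree<2 bones contribute 0.  With ``exclude_low_degree`` the mean runs
    over degree>=2 bones only.
    """
    g = net.to_networkx()
    local = nx.clustering(g)
    if exclude_low_degree:
        vals = [c for n, c in local.items() if g.degree(n) >= 2]
        if not vals:
            return 0.0
        return float(np.mean(vals))
    return float(np.mean(list(local.values())))


def average_path_length(net: AnatomicalNetwork, largest_component: bool = False) -> float:
    """Average path length L: mean geodesic distance over unordered bone pairs.

    Errors on disconnected networks unless ``largest_component`` is set, in
    which case L is computed on the giant component with a logged warning.
    """
    g = net.to_networkx()
    if not nx.is_connected(g):
        if not largest_component:
            comps = sorted((sorted(c) for c in nx.connected_components(g)), key=len,
                           reverse=True)
            raise UndefinedDescriptorError(
                f"average path length undefined: network has {len(comps)} components "
                f"(sizes {[len(c) for c in comps]})")
        giant = max(nx.connected_components(g), key=len)
        logger.warning(
            "%s: disconnected network; L computed on the largest component "
            "(%d of %d bones)", net.taxon, len(giant), g.number_of_nodes())
        g = g.subgraph(giant)
    if g.number_of_nodes() < 2:
        raise UndefinedDescriptorError("average path length undefined for N < 2")
    return float(nx.average_shortest_path_length(g))


def unpaired_bone_ratio(net: AnatomicalNetwork) -> float:
    """UBR: fraction of bones that are midline (unpaired)."""
    n_mid = sum(1 for b in net.bones.values() if b.laterality == "midline")
    return n_mid / net.n_bones


def compute_descriptors(
    net: AnatomicalNetwork,
    P: float | None = None,
    population_sd: bool = False,
    exclude_low_degree: bool = False,
    largest_component: bool = False,
) -> DescriptorSet:
    """All eight descriptors for one network; P is supplied from a partition."""
    return DescriptorSet(
        taxon=net.taxon,
        N=net.n_bones,
        K=net.n_links,
        D=density(net),
        L=average_path_length(net, largest_component=largest_component),
        C=average_clustering(net, exclude_low_degree=exclude_low_degree),
        H=heterogeneity(net, population_sd=population_sd),
        P=P,
        UBR=unpaired_bone_ratio(net),
    )


def descriptor_table(
    networks: list[AnatomicalNetwork],
    partitions: list | None = None,
    **options,
) -> pd.DataFrame:
    """One descriptor row per taxon, in input order.

    ``partitions`` supplies one :class:`~annaceti.modularity.ModulePartition`
    per network for the P column (or None to leave P unset).
    """
    from .modularity import parcellation

    rows = []
    for i, net in enumerate(networks):
        p_value = None
        if partitions is not None:
            part = partitions[i]
            p_value = parcellation(part) if part is not None else None
        rows.append(compute_descriptors(net, P=p_value, **options).as_row())
    return pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS)


def round_for_report(value: float, decimals: int = 3) -> float:
    """Round half-to-even for table comparison; never applied internally."""
    return float(np.round(value, decimals))
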