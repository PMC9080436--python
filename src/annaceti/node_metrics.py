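"""Per-bone network metrics: degree, clustering, closeness, betweenness.

Conventions: betweenness (BetC) is computed on the undirected graph with each
unordered pair counted once, endpoints excluded, credit split equally among
the shortest paths, and no normalization — so values are shortest-path pair
counts (possibly fractional).  Closeness (CloC) is primarily harmonic,
(1/(N-1)) * sum of reciprocal distances, which stays defined on disconnected
graphs; the classic (N-1)/sum-of-distances form is also emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network_model import AnatomicalNetwork

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["taxon", "bone", "DeC", "CluC", "CloC", "CloC_classic", "BetC"]


@dataclass
class NodeMetricsRow:
    taxon: str
    bone: str
    DeC: int
    CluC: float
    CloC: float
    CloC_classic: float | None
    BetC: float


def node_metrics(net: AnatomicalNetwork, normalize_betweenness: bool = False,
                 ) -> list[NodeMetricsRow]:
    """One metrics row per bone, in sorted bone-name order.

    On a disconnected network the harmonic closeness remains defined
    (unreachable bones contribute 0) with a logged warning, while classic
    closeness is reported as None.
    """
    g = net.to_networkx()
    n = g.number_of_nodes()
    connected = nx.is_connected(g)
    if not connected:
        logger.warning("%s: network disconnected; classic closeness undefined, "
                       "harmonic closeness uses reachable bones only", net.taxon)
    clustering = nx.clustering(g)
    betweenness = nx.betweenness_centrality(g, normalized=normalize_betweenness)
    harmonic = nx.harmonic_centrality(g)  # sum of 1/d; normalized below
    rows = []
    for bone in sorted(net.bones):
        cloc = harmonic[bone] / (n - 1) if n > 1 else 0.0
        if connected:
            total = sum(nx.single_source_shortest_path_length(g, bone).values())
            classic = (n - 1) / total if total > 0 else 0.0
        else:
            classic = None
        rows.append(NodeMetricsRow(
            taxon=net.taxon,
            bone=bone,
            DeC=int(g.degree(bone)),
            CluC=float(clustering[bone]),
            CloC=float(cloc),
            CloC_classic=None if classic is None else float(classic),
            BetC=float(betweenness[bone]),
        ))
    return rows


def node_metrics_table(networks: list[AnatomicalNetwork], **options) -> pd.DataFrame:
    """Long-format metrics table over several taxa (handshake lemma asserted)."""
    all_rows = []
    for net in networks:
        rows = node_metrics(net, **options)
        assert sum(r.DeC for r in rows) == 2 * net.n_links, \
            f"{net.taxon}: degree sum does not match twice the link count"
        all_rows.extend(rows)
    return pd.DataFrame([r.__dict__ for r in all_rows], columns=METRIC_COLUMNS)


def group_metric_distributions(rows: pd.DataFrame, grouping: dict[str, str],
                               ) -> pd.DataFrame:
    """Per-group summary (median, quartiles, min, max) of each bone metric.

    ``grouping`` maps taxon -> group label (e.g. stem cetacean / odontocete /
    mysticete).  Quartiles use linear interpolation.  Unknown taxa error.
    """
    unknown = sorted(set(rows["taxon"]) - set(grouping))
    if unknown:
        raise ValueError(f"taxa missing from grouping: {unknown}")
    df = rows.copy()
    df["group"] = df["taxon"].map(grouping)
    metrics = [c for c in ("DeC", "CluC", "CloC", "CloC_classic", "BetC")
               if c in df.columns]
    records = []
    for group, sub in df.groupby("group", sort=True):
        for metric in metrics:
            vals = sub[metric].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            records.append({
                "group": group, "metric": metric,
                "min": float(vals.min()), "q1": float(q1), "median": float(med),
                "q3": float(q3), "max": float(vals.max()), "n": int(len(vals)),
            })
    return pd.DataFrame(records,
                        columns=["group", "metric", "min", "q1", "median", "q3",
                                 "max", "n"])
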