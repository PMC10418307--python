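"""CDR3 Hamming-distance similarity graphs and cluster statistics.

Clonotypes whose CDR3 loops have common length and differ by exactly one
amino acid (Hamming distance 1) are predicted to recognize the same
antigen; connecting all such pairs yields a similarity graph whose
connected components ("clusters") expose the convergent structure of a
repertoire. The graph is built by length-bucketed masked-position hashing
(each CDR3 of length L emits L masked variants; candidate pairs colliding
on a mask are verified), which is O(n * L) expected rather than O(n^2).

Cluster statistics summarize the large components: their number, maximum
and mean size (+/- SEM), and the edges/vertices ratio of the displayed
subgraph — a tree has ratio (n-1)/n < 1 and every extra cycle raises it,
so the ratio measures interconnectedness.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np


def hamming1_neighbors(cdr3_a: str, cdr3_b: str) -> bool:
    """True iff the two sequences have equal length and differ at exactly one position."""
    if len(cdr3_a) != len(cdr3_b):
        return False
    mismatches = 0
    for a, b in zip(cdr3_a, cdr3_b):
        if a != b:
            mismatches += 1
            if mismatches > 1:
                return False
    return mismatches == 1


def build_graph(clonotypes, sample_of: dict[str, str] | None = None) -> nx.Graph:
    """Build the HD=1 similarity graph over unique CDR3 keys.

    ``clonotypes`` is an iterable of objects with ``cdr3_aa`` and ``count``
    (Clonotype) or plain strings. Vertices carry a ``size`` attribute (clone
    size, summed over duplicates) and optionally ``sample`` from
    ``sample_of``. All and only HD=1 pairs are connected.
    """
    sizes: dict[str, float] = {}
    order: list[str] = []
    for c in clonotypes:
        if isinstance(c, str):
            key, cnt = c, 1.0
        else:
            key, cnt = c.cdr3_aa, float(c.count)
        if key not in sizes:
            sizes[key] = 0.0
            order.append(key)
        sizes[key] += cnt

    g = nx.Graph()
    for key in order:
        attrs = {"size": sizes[key]}
        if sample_of is not None and key in sample_of:
            attrs["sample"] = sample_of[key]
        g.add_node(key, **attrs)

    # masked-position hashing within each length bucket
    by_length: dict[int, list[str]] = defaultdict(list)
    for key in order:
        by_length[len(key)].append(key)
    for length, bucket in by_length.items():
        for pos in range(length):
            collisions: dict[str, list[str]] = defaultdict(list)
            for key in bucket:
                collisions[key[:pos] + key[pos + 1:]].append(key)
            for group in collisions.values():
                if len(group) < 2:
                    continue
                for i, a in enumerate(group):
                    for b in group[i + 1:]:
                        # same mask => differ only at pos (or identical, impossible
                        # for unique keys), so the pair is HD=1 by construction
                        if a[pos] != b[pos]:
                            g.add_edge(a, b)
    return g


@dataclass
class ClusterStats:
    """Summary of the large connected components of a similarity graph."""

    n_large_clusters: int
    max_size: int
    mean_size: float
    sem_size: float
    edges_vertices_ratio: float
    cluster_sizes: list[int]


def cluster_stats(graph: nx.Graph, min_size: int = 5, strict: bool = True) -> ClusterStats:
    """Statistics over the graph's large connected components.

    ``strict=True`` keeps components with > min_size members (the statistic
    convention); ``strict=False`` keeps >= min_size (the display
    convention). The edges/vertices ratio is computed over the union of the
    retained components. All-singleton graphs give NaN statistics.
    """
    components = [set(c) for c in nx.connected_components(graph)]
    if strict:
        large = [c for c in components if len(c) > min_size]
    else:
        large = [c for c in components if len(c) >= min_size]
    if not large:
        return ClusterStats(0, 0, math.nan, math.nan, math.nan, [])
    sizes = sorted((len(c) for c in large), reverse=True)
    arr = np.array(sizes, dtype=float)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    displayed = set().union(*large)
    sub = graph.subgraph(displayed)
    ratio = sub.number_of_edges() / sub.number_of_nodes()
    return ClusterStats(
        n_large_clusters=len(large),
        max_size=sizes[0],
        mean_size=float(arr.mean()),
        sem_size=sem,
        edges_vertices_ratio=ratio,
        cluster_sizes=sizes,
    )


def export_graph(graph: nx.Graph, path) -> None:
    """Write the graph to GraphML with log2(clone size) as the display size."""
    out = graph.copy()
    for node, data in out.nodes(data=True):
        size = data.get("size", 1.0)
        data["log2_size"] = math.log2(size) if size > 0 else 0.0
    nx.write_graphml(out, path)
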