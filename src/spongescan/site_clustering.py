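"""Distance-weighted site graph and Markov clustering (MCL) of binding sites.

Edges connect predicted sites on the same strand of the same chromosome with
weight sim(x) = C - x for inter-site gap x < C (0 otherwise, so such pairs
carry no edge); C defaults to 1000 nt.  The graph decomposes into blocks of
sites chained by gaps < C, and standard MCL (expansion, inflation, pruning)
runs independently per block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .target_scan import BindingSite

__all__ = ["SiteGraph", "Cluster", "build_site_graph", "mcl_cluster", "cluster_genome"]


@dataclass
class SiteGraph:
    nodes: list[BindingSite]
    edges: list[tuple[int, int, float]]
    edge_weight_C: int = 1000


@dataclass
class Cluster:
    mirna_id: str
    members: list[int]
    chrom: str
    strand: str
    start: int
    end: int
    sites: list[BindingSite] = field(default_factory=list, repr=False)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


def _gap(a: BindingSite, b: BindingSite) -> int:
    """Gap between nearest ends of two sorted sites, floored at 0."""
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end)


def build_site_graph(sites: list[BindingSite], C: int = 1000) -> SiteGraph:
    """Edges between same-chrom same-strand site pairs closer than C nt."""
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].strand, sites[i].start))
    edges: list[tuple[int, int, float]] = []
    for a_pos, i in enumerate(order):
        si = sites[i]
        for j in order[a_pos + 1 :]:
            sj = sites[j]
            if (sj.chrom, sj.strand) != (si.chrom, si.strand):
                break
            x = _gap(si, sj)
            if x >= C:
                # sites are sorted by start; later ones are at least this far
                if sj.start - si.end >= C:
                    break
                continue
            edges.append((min(i, j), max(i, j), float(C - x)))
    return SiteGraph(nodes=list(sites), edges=edges, edge_weight_C=C)


def _mcl_matrix(A: np.ndarray, inflation: float, expansion: int,
                prune_threshold: float, max_iter: int, tol: float) -> np.ndarray:
    n = A.shape[0]
    A = A.astype(float).copy()
    # self-loops: node's max incident weight (1 for isolated nodes)
    loops = A.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(A, loops)
    M = A / A.sum(axis=0)
    for _ in range(max_iter):
        new = np.linalg.matrix_power(M, expansion)
        new = np.power(new, inflation)
        new[new < prune_threshold] = 0.0
        colsum = new.sum(axis=0)
        colsum[colsum == 0] = 1.0
        new /= colsum
        diff = np.abs(new - M).max()
        M = new
        if diff < tol:
            break
    else:
        warnings.warn("MCL did not converge; interpreting current matrix", stacklevel=2)
    return M


def _interpret_mcl(M: np.ndarray) -> list[list[int]]:
    """Read clusters from a (near-)converged MCL matrix as attractor systems.

    Attractors are nodes with positive diagonal; attractors sharing support in
    any column belong to one system; every node joins the system of the
    attractor with the largest flow into it (ties: lowest attractor index).
    """
    n = M.shape[0]
    attractors = [i for i in range(n) if M[i, i] > 0]
    if not attractors:  # fully degenerate matrix; every node on its own
        return [[i] for i in range(n)]
    parent = {a: a for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(n):
        support = [a for a in attractors if M[a, j] > 0]
        for a in support[1:]:
            ra, rb = find(support[0]), find(a)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    systems: dict[int, list[int]] = {}
    assigned = set()
    for j in range(n):
        flows = [(M[a, j], -a) for a in attractors]
        best_flow, neg_a = max(flows)
        if best_flow <= 0:
            continue
        systems.setdefault(find(-neg_a), []).append(j)
        assigned.add(j)
    for j in range(n):
        if j not in assigned:
            systems[-j - 1] = [j]
    return [sorted(m) for _, m in sorted(systems.items(), key=lambda kv: min(kv[1]))]


def mcl_cluster(graph: SiteGraph, inflation: float = 3.5, expansion: int = 2,
                prune_threshold: float = 1e-5, max_iter: int = 100,
                tol: float = 1e-6, mirna_id: str | None = None) -> list[Cluster]:
    """Partition a site graph with MCL; isolated nodes become singletons."""
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    n = len(graph.nodes)
    if n == 0:
        return []
    A = np.zeros((n, n))
    for i, j, w in graph.edges:
        A[i, j] = A[j, i] = w
    M = _mcl_matrix(A, inflation, expansion, prune_threshold, max_iter, tol)
    clusters = []
    for members in _interpret_mcl(M):
        sites = [graph.nodes[i] for i in members]
        clusters.append(
            Cluster(
                mirna_id=mirna_id or (sites[0].mirna_id if sites else ""),
                members=members,
                chrom=sites[0].chrom,
                strand=sites[0].strand,
                start=min(s.start for s in sites),
                end=max(s.end for s in sites),
                sites=sites,
            )
        )
    return clusters


def cluster_genome(sites: list[BindingSite], inflation: float = 3.5, C: int = 1000,
                   mirna_id: str | None = None, **mcl_kwargs) -> list[Cluster]:
    """Cluster all sites of one miRNA, block by block.

    Connected components of the site graph are exactly maximal chains of
    sorted same-chrom same-strand sites with consecutive gaps < C, so each
    chain is clustered independently (block-diagonal exactness).
    """
    if not sites:
        return []
    sites = sorted(sites, key=lambda s: (s.chrom, s.strand, s.start))
    blocks: list[list[BindingSite]] = [[sites[0]]]
    for prev, cur in zip(sites, sites[1:]):
        if (cur.chrom, cur.strand) == (prev.chrom, prev.strand) and _gap(prev, cur) < C:
            blocks[-1].append(cur)
        else:
            blocks.append([cur])
    clusters: list[Cluster] = []
    for block in blocks:
        graph = build_site_graph(block, C=C)
        clusters.extend(mcl_cluster(graph, inflation=inflation, mirna_id=mirna_id, **mcl_kwargs))
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.start))
    return clusters
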