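"""Dinucleotide-preserving shuffling of genome sequence in fixed windows.

The background genome for significance estimation is produced by shuffling
every maximal unmasked segment in non-overlapping 120-nt windows, each window
permuted so that its 16 dinucleotide counts (hence mononucleotide counts and
the first and last base) are exactly preserved.  Sampling uses the classic
Euler-path construction on the dinucleotide transition multigraph
(Altschul-Erickson, as implemented in uShuffle for k = 2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .genomic_io import GenomeSequence

__all__ = ["ShuffleConfig", "dinucleotide_shuffle", "shuffle_genome"]

_UNMASKED_SEGMENT = re.compile(r"[ACGT]+")


@dataclass
class ShuffleConfig:
    window: int = 120
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("shuffle window must be >= 2")


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random sequence with exactly the dinucleotide count multiset of ``seq``.

    Draws a uniform-ish sample by picking random last-exit edges that form an
    arborescence toward the final vertex, shuffling the remaining out-edges,
    and walking the resulting Euler path.
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters {sorted(bad)}; pass unmasked segments only")
    if len(seq) <= 2:
        return seq

    first, last = seq[0], seq[-1]
    out_edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        out_edges.setdefault(a, []).append(b)
    vertices = list(out_edges)

    # choose a random last-exit edge per vertex (except `last`) such that
    # following last edges always reaches `last`; rejection is cheap on <= 4 vertices
    need = [v for v in vertices if v != last]
    while True:
        last_edge = {v: out_edges[v][rng.integers(len(out_edges[v]))] for v in need}
        ok = True
        for v in need:
            seen, cur = set(), v
            while cur != last and cur in last_edge and cur not in seen:
                seen.add(cur)
                cur = last_edge[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break

    walk_lists: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(out_edges[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        idx = rng.permutation(len(edges))
        edges = [edges[i] for i in idx]
        if v in last_edge:
            edges.append(last_edge[v])
        walk_lists[v] = edges

    out = [first]
    ptr = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = walk_lists[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_genome(genome: GenomeSequence, config: ShuffleConfig) -> GenomeSequence:
    """Shuffle each unmasked segment of the genome in non-overlapping windows.

    Masked positions (lowercase or N) are untouched; each window, including a
    shorter final remainder, is shuffled independently; a length-1 remainder
    is left as is.
    """
    rng = np.random.default_rng(config.rng_seed)
    seq = genome.sequence
    parts: list[str] = []
    pos = 0
    for m in _UNMASKED_SEGMENT.finditer(seq):
        parts.append(seq[pos : m.start()])
        segment = m.group(0)
        for w0 in range(0, len(segment), config.window):
            window = segment[w0 : w0 + config.window]
            parts.append(window if len(window) < 2 else dinucleotide_shuffle(window, rng))
        pos = m.end()
    parts.append(seq[pos:])
    return GenomeSequence(genome.chrom_id, "".join(parts))
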