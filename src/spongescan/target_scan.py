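"""Seed-and-extend prediction of miRNA binding sites on a genome.

The scanner locates every stretch of six consecutive query bases within the
first eight that can pair (antiparallel, G-U wobble allowed) with the target
sense sequence, extends each seed match by dynamic programming under a
simplified nearest-neighbour duplex energy model, keeps sites at or below an
energy cutoff and merges overlapping sites per strand.

Pair notation throughout: a pair is (query base, target sense base) written
as a 2-letter RNA string, one of AU, UA, CG, GC, GU, UG.  A stack step is
keyed (pair at lower query index, pair at next query index); the physical
duplex step is 5'-q1 q2-3' over 3'-t1 t2-5'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import product

import numpy as np

from .genomic_io import GenomeSequence, MatureMirna

__all__ = [
    "EnergyModel",
    "DuplexAlignment",
    "BindingSite",
    "find_seed_matches",
    "duplex_energy",
    "extend_site",
    "scan_targets",
    "merge_overlapping_sites",
    "paired_fraction",
    "revcomp",
]

ADMISSIBLE_PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})

# DNA letters on the target sense strand that can pair a given query RNA base
_TARGET_LETTERS = {"A": "T", "C": "G", "G": "CT", "U": "AG"}

_DNA_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DNA2RNA = str.maketrans("T", "U")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

INF = math.inf


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence, preserving case."""
    return seq.translate(_COMPLEMENT)[::-1]


def _pair(q: str, t: str) -> str | None:
    """Pair string for query RNA base q vs target DNA sense base t, or None."""
    p = q + t.translate(_DNA2RNA)
    return p if p in ADMISSIBLE_PAIRS else None


@dataclass
class EnergyModel:
    """Simplified duplex energy model: stack table + affine loop penalties."""

    stack: dict[tuple[str, str], float]
    loop_open: float = 4.0
    loop_extend: float = 0.3
    init_penalty: float = 0.0

    def __post_init__(self) -> None:
        missing = [
            (p1, p2)
            for p1 in ADMISSIBLE_PAIRS
            for p2 in ADMISSIBLE_PAIRS
            if (p1, p2) not in self.stack
        ]
        if missing:
            raise ValueError(f"stack table missing {len(missing)} entries, e.g. {missing[0]}")
        for v in self.stack.values():
            if not math.isfinite(v):
                raise ValueError("non-finite stack energy")

    @classmethod
    def from_file(cls, path) -> "EnergyModel":
        stack: dict[tuple[str, str], float] = {}
        params: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if f[0] == "param":
                    params[f[1]] = float(f[2])
                elif f[0] == "stack":
                    stack[(f[1], f[2])] = float(f[3])
        return cls(stack=stack, **params)

    @classmethod
    def default(cls) -> "EnergyModel":
        ref = resources.files("spongescan").joinpath("data/stack_energies.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    @classmethod
    def uniform(cls, stack_energy: float = -2.0, loop_open: float = 3.0,
                loop_extend: float = 0.5, init_penalty: float = 0.0) -> "EnergyModel":
        """Toy model with one stack energy for every step (handy in tests/docs)."""
        table = {(p1, p2): stack_energy for p1 in ADMISSIBLE_PAIRS for p2 in ADMISSIBLE_PAIRS}
        return cls(table, loop_open, loop_extend, init_penalty)


@dataclass
class DuplexAlignment:
    """An antiparallel duplex: query positions increase, target positions decrease."""

    pairs: list[tuple[int, int]]  # (query index, target sense position)
    energy: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(order=True)
class BindingSite:
    chrom: str
    strand: str
    start: int
    end: int
    energy: float = field(compare=False)
    seed_start: int = field(compare=False)
    seed_end: int = field(compare=False)
    paired_fraction: float = field(compare=False)
    mirna_id: str = field(compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SeedMatch:
    strand: str
    start: int  # sense coordinates of the 6-nt target window
    end: int
    offset: int  # query offset of the seed window


# ---------------------------------------------------------------------------
# seed matching


def _admissible_kmers(mirna_seq: str, offset: int, seed_len: int) -> list[int]:
    """Integer codes of all target sense k-mers pairing the seed window."""
    window = mirna_seq[offset : offset + seed_len]
    # target position j+k pairs query base at offset+seed_len-1-k
    letter_sets = [_TARGET_LETTERS[window[seed_len - 1 - k]] for k in range(seed_len)]
    codes = []
    for combo in product(*letter_sets):
        v = 0
        for ch in combo:
            v = v * 4 + _DNA_CODE[ch]
        codes.append(v)
    return codes


def _encode(sense: str) -> np.ndarray:
    """Base codes 0-3; masked (lowercase or N) and non-ACGT become 4."""
    arr = np.frombuffer(sense.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for ch, code in _DNA_CODE.items():
        out[arr == ord(ch)] = code
    return out


def _rolling_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    kv = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        kv = kv * 4 + codes[i : n + i]
        valid &= codes[i : n + i] < 4
    return kv, valid


def find_seed_matches(
    genome: GenomeSequence,
    mirna: MatureMirna,
    seed_len: int = 6,
    seed_region: int = 8,
) -> list[SeedMatch]:
    """All seed matches on both strands, in sense coordinates per strand."""
    if mirna.length < seed_region:
        raise ValueError(f"{mirna.mirna_id}: shorter than seed region {seed_region}")
    if seed_len > seed_region:
        raise ValueError("seed_len must be <= seed_region")
    matches: list[SeedMatch] = []
    for strand in "+-":
        sense = genome.sequence if strand == "+" else revcomp(genome.sequence)
        codes = _encode(sense)
        kv, valid = _rolling_kmers(codes, seed_len)
        for offset in range(seed_region - seed_len + 1):
            mers = np.array(_admissible_kmers(mirna.sequence, offset, seed_len), dtype=np.int64)
            hits = np.flatnonzero(np.isin(kv, mers) & valid)
            matches.extend(SeedMatch(strand, int(j), int(j) + seed_len, offset) for j in hits)
    return matches


# ---------------------------------------------------------------------------
# energies


def duplex_energy(pairs: list[tuple[int, int]], mirna: MatureMirna, target_seq: str,
                  model: EnergyModel) -> float:
    """Energy of an explicit alignment: init + stacks + affine loop terms.

    ``pairs`` are (query index, position in target_seq), query increasing and
    target decreasing (antiparallel); target_seq is the sense sequence.
    """
    e = model.init_penalty
    if not pairs:
        return e
    prev = None
    for qi, tj in pairs:
        p = _pair(mirna.sequence[qi], target_seq[tj].upper())
        if p is None:
            raise ValueError(f"inadmissible pair {mirna.sequence[qi]}-{target_seq[tj]}")
        if prev is not None:
            pq, pt, pp = prev
            if qi <= pq or tj >= pt:
                raise ValueError("pairs must increase in query and decrease in target")
            gap = (qi - pq - 1) + (pt - tj - 1)
            if gap == 0:
                e += model.stack[(pp, p)]
            else:
                e += model.loop_open + model.loop_extend * gap
        prev = (qi, tj, p)
    return e


def _extend_one_side(u: list[str], v: list[str], boundary_pair: str, side: str,
                     model: EnergyModel) -> tuple[float, list[tuple[int, int]]]:
    """Minimum-energy extension on one side of a fixed seed duplex.

    u: query bases outward from the seed; v: target sense bases outward.
    Returns (energy delta <= 0, chosen (u index, v index) pairs).  ``side``
    fixes stack orientation: 'three' stacks (inner, outer) along the query,
    'five' stacks (outer, inner).
    """
    n, m = len(u), len(v)
    if n == 0 or m == 0:
        return 0.0, []
    open_, ext = model.loop_open, model.loop_extend
    # index 0 = virtual boundary (seed terminal pair); pair k at (i=k+1, j=k'+1)
    M = [[INF] * (m + 1) for _ in range(n + 1)]
    G = [[INF] * (m + 1) for _ in range(n + 1)]
    Mptr: dict[tuple[int, int], tuple] = {}
    Gptr: dict[tuple[int, int], tuple] = {}
    M[0][0] = 0.0
    pair_at = [[None] * (m + 1) for _ in range(n + 1)]
    pair_at[0][0] = boundary_pair
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            # gap state
            best, ptr = INF, None
            if i > 0 and G[i - 1][j] + ext < best:
                best, ptr = G[i - 1][j] + ext, ("G", i - 1, j)
            if j > 0 and G[i][j - 1] + ext < best:
                best, ptr = G[i][j - 1] + ext, ("G", i, j - 1)
            if i > 0 and M[i - 1][j] + open_ + ext < best:
                best, ptr = M[i - 1][j] + open_ + ext, ("M", i - 1, j)
            if j > 0 and M[i][j - 1] + open_ + ext < best:
                best, ptr = M[i][j - 1] + open_ + ext, ("M", i, j - 1)
            G[i][j], Gptr[(i, j)] = best, ptr
            # match state
            if i > 0 and j > 0:
                p = _pair(u[i - 1], v[j - 1])
                if p is not None:
                    pair_at[i][j] = p
                    best, ptr = INF, None
                    prev_p = pair_at[i - 1][j - 1]
                    if prev_p is not None and M[i - 1][j - 1] < INF:
                        key = (prev_p, p) if side == "three" else (p, prev_p)
                        cand = M[i - 1][j - 1] + model.stack[key]
                        if cand < best:
                            best, ptr = cand, ("M", i - 1, j - 1)
                    if G[i - 1][j - 1] < best:
                        best, ptr = G[i - 1][j - 1], ("G", i - 1, j - 1)
                    M[i][j], Mptr[(i, j)] = best, ptr
    # best stopping point (trailing unpaired bases are free)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i][j] < best:
                best, bi, bj = M[i][j], i, j
    pairs: list[tuple[int, int]] = []
    state, i, j = "M", bi, bj
    while (i, j) != (0, 0):
        if state == "M":
            pairs.append((i - 1, j - 1))
            state, i, j = Mptr[(i, j)]
        else:
            state, i, j = Gptr[(i, j)]
    pairs.reverse()
    return best, pairs


def _seed_pairs_and_energy(match: SeedMatch, sense: str, mirna: MatureMirna,
                           model: EnergyModel, seed_len: int) -> tuple[list, float]:
    o, j = match.offset, match.start
    pairs = [(o + k, j + seed_len - 1 - k) for k in range(seed_len)]
    e = 0.0
    for k in range(seed_len - 1):
        p1 = _pair(mirna.sequence[o + k], sense[j + seed_len - 1 - k])
        p2 = _pair(mirna.sequence[o + k + 1], sense[j + seed_len - 2 - k])
        e += model.stack[(p1, p2)]
    return pairs, e


def _truncate_at_mask(sense: str, start: int, stop: int, step: int) -> int:
    """Number of usable bases walking from start (inclusive) toward stop by step."""
    count = 0
    p = start
    while p != stop:
        ch = sense[p]
        if ch.islower() or ch not in "ACGT":
            break
        count += 1
        p += step
    return count


def extend_site(match: SeedMatch, sense: str, mirna: MatureMirna, model: EnergyModel,
                window_pad: int = 5, seed_len: int = 6) -> DuplexAlignment:
    """DP extension of one seed match; seed pairs stay fixed.

    ``sense`` is the transcript sense sequence of the matched strand; returned
    target positions are sense coordinates.
    """
    L = len(sense)
    o, j = match.offset, match.start
    seed_pairs, seed_e = _seed_pairs_and_energy(match, sense, mirna, model, seed_len)

    # 3' side of the query pairs sense positions < j (antiparallel)
    n3 = mirna.length - (o + seed_len)
    u3 = list(mirna.sequence[o + seed_len :])
    m3 = min(n3 + window_pad, _truncate_at_mask(sense, j - 1, -1, -1))
    v3 = [sense[j - 1 - k] for k in range(m3)]
    b3 = _pair(mirna.sequence[o + seed_len - 1], sense[j])  # seed pair at highest q
    e3, p3 = _extend_one_side(u3, v3, b3, "three", model)

    # 5' side of the query pairs sense positions >= j + seed_len
    u5 = [mirna.sequence[o - 1 - k] for k in range(o)]
    m5 = min(o + window_pad, _truncate_at_mask(sense, j + seed_len, L, 1))
    v5 = [sense[j + seed_len + k] for k in range(m5)]
    b5 = _pair(mirna.sequence[o], sense[j + seed_len - 1])  # seed pair at lowest q
    e5, p5 = _extend_one_side(u5, v5, b5, "five", model)

    pairs = (
        [(o - 1 - i, j + seed_len + k) for i, k in reversed(p5)]
        + seed_pairs
        + [(o + seed_len + i, j - 1 - k) for i, k in p3]
    )
    pairs.sort()
    energy = model.init_penalty + seed_e + e3 + e5
    return DuplexAlignment(pairs=pairs, energy=energy)


def paired_fraction(alignment: DuplexAlignment, mirna: MatureMirna) -> float:
    return alignment.n_pairs / mirna.length


# ---------------------------------------------------------------------------
# site assembly


def _site_from_alignment(match: SeedMatch, aln: DuplexAlignment, L: int, chrom: str,
                         mirna: MatureMirna, seed_len: int = 6) -> BindingSite:
    o, j = match.offset, match.start
    tpos = [t for _, t in aln.pairs]
    s_start, s_end = min(tpos), max(tpos) + 1
    # seed site: the 7 sense positions opposite query positions 1..7 (0-based),
    # laid out without gaps from the seed window: t(q) = j + (o + seed_len - 1 - q)
    seed_hi = j + o + seed_len - 2  # q = 1
    seed_lo = j + o + seed_len - 8  # q = 7
    seed_s, seed_e = max(0, seed_lo), min(L, seed_hi + 1)
    s_start, s_end = min(s_start, seed_s), max(s_end, seed_e)
    if match.strand == "+":
        start, end = s_start, s_end
        sd_s, sd_e = seed_s, seed_e
    else:
        start, end = L - s_end, L - s_start
        sd_s, sd_e = L - seed_e, L - seed_s
    return BindingSite(
        chrom=chrom,
        strand=match.strand,
        start=start,
        end=end,
        energy=aln.energy,
        seed_start=sd_s,
        seed_end=sd_e,
        paired_fraction=round(aln.n_pairs / mirna.length, 6),
        mirna_id=mirna.mirna_id,
    )


def merge_overlapping_sites(sites: list[BindingSite]) -> list[BindingSite]:
    """Transitively merge same-chrom same-strand sites sharing >= 1 bp.

    The merged site keeps the minimum constituent energy; seed interval and
    paired fraction come from that constituent (ties: leftmost seed).
    """
    out: list[BindingSite] = []
    for site in sorted(sites, key=lambda s: (s.chrom, s.strand, s.start, s.end)):
        cur = out[-1] if out else None
        if (
            cur is not None
            and site.chrom == cur.chrom
            and site.strand == cur.strand
            and site.start < cur.end
        ):
            cur.end = max(cur.end, site.end)
            better = site.energy < cur.energy or (
                site.energy == cur.energy and site.seed_start < cur.seed_start
            )
            if better:
                cur.energy = site.energy
                cur.seed_start, cur.seed_end = site.seed_start, site.seed_end
                cur.paired_fraction = site.paired_fraction
        else:
            out.append(
                BindingSite(
                    site.chrom, site.strand, site.start, site.end, site.energy,
                    site.seed_start, site.seed_end, site.paired_fraction, site.mirna_id,
                )
            )
    return out


def scan_targets(
    genome: GenomeSequence,
    mirna: MatureMirna,
    model: EnergyModel | None = None,
    energy_cutoff: float = -10.0,
    seed_len: int = 6,
    seed_region: int = 8,
    window_pad: int = 5,
) -> list[BindingSite]:
    """Predict, filter and merge binding sites for one miRNA on one chromosome."""
    if model is None:
        model = EnergyModel.default()
    L = genome.length
    sense_by_strand = {"+": genome.sequence, "-": revcomp(genome.sequence)}
    raw: list[BindingSite] = []
    for strand, sense in sense_by_strand.items():
        codes = _encode(sense)
        kv, valid = _rolling_kmers(codes, seed_len)
        for offset in range(seed_region - seed_len + 1):
            mers = np.array(_admissible_kmers(mirna.sequence, offset, seed_len), dtype=np.int64)
            for j in np.flatnonzero(np.isin(kv, mers) & valid):
                m = SeedMatch(strand, int(j), int(j) + seed_len, offset)
                aln = extend_site(m, sense, mirna, model, window_pad, seed_len)
                if aln.energy <= energy_cutoff:
                    raw.append(_site_from_alignment(m, aln, L, genome.chrom_id, mirna, seed_len))
    return merge_overlapping_sites(raw)
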