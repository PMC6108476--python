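"""Annotation and characterization of significant, filtered clusters.

A candidate is annotated to an overlapping same-strand gene when the larger
of the two regions covers at least half of the smaller one (GENCODE records
take priority over circBase).  Per candidate we compute FBSE (fraction of
member sites fully inside annotated exons), the SNP density ratio between
seed sites and the gaps separating them, the energy entropy, and the
conserved-site fraction; a high-confidence shortlist keeps annotated
candidates exceeding their significance cutoff by at least 10 sites with
FBSE > 0.09.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, GenomeSequence, SnpTable
from .significance import TailFit
from .site_clustering import Cluster

__all__ = [
    "SpongeCandidate",
    "annotate_candidate",
    "fbse",
    "sdr",
    "shortlist_high_confidence",
    "genomic_context_summary",
]

CONTEXT_CLASSES = [
    "PCG_not_circRNA",
    "circRNA_not_PCG",
    "circRNA_and_PCG",
    "lincRNA",
    "antisense",
    "pseudogene",
    "processed_transcript",
    "unannotated",
]


@dataclass
class SpongeCandidate:
    cluster: Cluster
    fit: TailFit
    annotation: tuple[str, str, str] | None  # (gene_id, biotype, source)
    fbse: float
    sdr: float | None
    entropy: float
    conserved_fraction: float

    @property
    def mirna_id(self) -> str:
        return self.cluster.mirna_id

    @property
    def excess_size(self) -> int:
        return self.cluster.size - self.fit.x_cutoff

    def as_row(self) -> list:
        cl = self.cluster
        ann = self.annotation
        return [
            self.mirna_id,
            cl.size,
            self.fit.x_cutoff,
            cl.chrom,
            cl.start,
            cl.end,
            cl.strand,
            ann[0] if ann else "NA",
            ann[1] if ann else "NA",
            round(self.fbse, 6),
            "NA" if self.sdr is None else round(self.sdr, 6),
            round(self.entropy, 6),
            round(self.conserved_fraction, 6),
        ]


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def annotate_candidate(cluster: Cluster, genes: list[GeneModel]) -> tuple[str, str, str] | None:
    """Best overlapping same-strand gene, or None.

    Qualifying genes overlap the cluster span by at least 50% of the smaller
    of the two regions; ties break by source priority (gencode before
    circbase), then larger overlap, then lexicographically lowest gene id.
    """
    hits = []
    for g in genes:
        if g.chrom != cluster.chrom or g.strand != cluster.strand:
            continue
        ov = _overlap(cluster.start, cluster.end, g.start, g.end)
        smaller = min(cluster.end - cluster.start, g.span_length)
        if smaller > 0 and ov >= 0.5 * smaller:
            hits.append((0 if g.source == "gencode" else 1, -ov, g.gene_id, g))
    if not hits:
        return None
    _, _, _, best = min(hits)
    return (best.gene_id, best.biotype, best.source)


def fbse(cluster: Cluster, genes: list[GeneModel]) -> float:
    """Fraction of member sites whose full interval lies in a same-strand exon."""
    exons = [
        ex
        for g in genes
        if g.chrom == cluster.chrom and g.strand == cluster.strand
        for ex in g.exons
    ]
    if cluster.size == 0:
        return 0.0
    inside = 0
    for site in cluster.sites:
        if any(es <= site.start and site.end <= ee for es, ee in exons):
            inside += 1
    return inside / cluster.size


def _merged_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def sdr(cluster: Cluster, snps: SnpTable) -> float | None:
    """SNP density in seed sites over SNP density in the gaps between them.

    The seed region is the union of the member 7-nt seed sites; the flanking
    region is the gaps between consecutive seed sites within the cluster
    span.  Zero flanking length or zero flanking SNPs yields None (undefined).
    """
    seeds = _merged_intervals([(s.seed_start, s.seed_end) for s in cluster.sites])
    seed_nt = sum(e - s for s, e in seeds)
    seed_snps = sum(snps.count(cluster.chrom, s, e) for s, e in seeds)
    flank_nt = flank_snps = 0
    for (_, e1), (s2, _) in zip(seeds, seeds[1:]):
        flank_nt += s2 - e1
        flank_snps += snps.count(cluster.chrom, e1, s2)
    if flank_nt == 0 or flank_snps == 0 or seed_nt == 0:
        return None
    return (seed_snps / seed_nt) / (flank_snps / flank_nt)


def shortlist_high_confidence(candidates: list[SpongeCandidate], min_excess: int = 10,
                              min_fbse: float = 0.09) -> list[SpongeCandidate]:
    """Annotated candidates with excess size >= min_excess and FBSE > min_fbse,
    sorted by excess size descending."""
    kept = [
        c
        for c in candidates
        if c.excess_size >= min_excess and c.annotation is not None and c.fbse > min_fbse
    ]
    return sorted(kept, key=lambda c: (-c.excess_size, c.mirna_id, c.cluster.chrom, c.cluster.start))


def _class_arrays(genes: list[GeneModel], chrom: str, strand: str, length: int) -> np.ndarray:
    """Per-position context class index for one chrom+strand (priority order)."""
    cover = {name: np.zeros(length, dtype=bool) for name in
             ("protein_coding", "circRNA", "lincRNA", "antisense", "pseudogene",
              "processed_transcript")}
    for g in genes:
        if g.chrom != chrom or g.strand != strand or g.biotype not in cover:
            continue
        cover[g.biotype][g.start : g.end] = True
    cls = np.full(length, CONTEXT_CLASSES.index("unannotated"), dtype=np.int8)
    order = [
        ("lincRNA", "lincRNA"),
        ("antisense", "antisense"),
        ("pseudogene", "pseudogene"),
        ("processed_transcript", "processed_transcript"),
    ]
    for biotype, name in reversed(order):
        cls[cover[biotype]] = CONTEXT_CLASSES.index(name)
    pcg, circ = cover["protein_coding"], cover["circRNA"]
    cls[pcg & ~circ] = CONTEXT_CLASSES.index("PCG_not_circRNA")
    cls[circ & ~pcg] = CONTEXT_CLASSES.index("circRNA_not_PCG")
    cls[circ & pcg] = CONTEXT_CLASSES.index("circRNA_and_PCG")
    return cls


def genomic_context_summary(candidates: list[SpongeCandidate], genes: list[GeneModel],
                            genome: dict[str, GenomeSequence]) -> pd.DataFrame:
    """Strand-sensitive nucleotide percentages per context class.

    Percentages are over unmasked nucleotides, for the whole genome (both
    strands) and for the candidate spans; enrichment is their ratio.
    """
    n_classes = len(CONTEXT_CLASSES)
    genome_counts = np.zeros(n_classes, dtype=np.int64)
    cand_counts = np.zeros(n_classes, dtype=np.int64)
    for chrom, gseq in genome.items():
        unmasked = ~gseq.mask
        for strand in "+-":
            cls = _class_arrays(genes, chrom, strand, gseq.length)
            genome_counts += np.bincount(cls[unmasked], minlength=n_classes)
            covered = np.zeros(gseq.length, dtype=bool)
            for c in candidates:
                if c.cluster.chrom == chrom and c.cluster.strand == strand:
                    covered[c.cluster.start : c.cluster.end] = True
            sel = covered & unmasked
            if sel.any():
                cand_counts += np.bincount(cls[sel], minlength=n_classes)
    df = pd.DataFrame(index=CONTEXT_CLASSES)
    g_total, c_total = genome_counts.sum(), cand_counts.sum()
    df["genome_pct"] = 100.0 * genome_counts / g_total if g_total else 0.0
    df["candidate_pct"] = 100.0 * cand_counts / c_total if c_total else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        df["enrichment"] = df["candidate_pct"] / df["genome_pct"]
    return df
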