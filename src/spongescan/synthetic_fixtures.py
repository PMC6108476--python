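"""Synthetic genomes, miRNAs, tracks and gene models with planted sponges.

Every pipeline stage is testable offline: an i.i.d. background genome with
soft-masked stretches stands in for a repeat-masked genome, planted
near-reverse-complement site arrays emulate natural sponge loci (the seed
7-mer is always a perfect match, so recovery failures isolate clustering or
statistics problems rather than scanner sensitivity), and matching
conservation, SNP and gene-model fixtures are constructed to exercise the
downstream filters.  All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genomic_io import ConservationTrack, GeneModel, GenomeSequence, MatureMirna, SnpTable, write_fasta
from .target_scan import revcomp

__all__ = [
    "Scenario",
    "PlantedSite",
    "ScenarioData",
    "DEFAULT_MIRNA",
    "random_genome",
    "plant_sponge",
    "synth_tracks",
    "make_benchmark_scenario",
]

# AC-rich seed region keeps seed-match degeneracy (and hence scan time) low
# while the full 22-mer still forms a strongly bound duplex when planted.
DEFAULT_MIRNA = MatureMirna("syn-miR-1", "UACCAACACUCAGUCUUAACGU")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Scenario:
    rng_seed: int
    genome_length: int = 600_000
    gc_content: float = 0.41
    mask_fraction: float = 0.30
    n_sites: int = 30
    gap_range: tuple[int, int] = (2, 40)
    mismatches: int = 2
    conserved: bool = True
    exon_fraction: float = 0.5
    snp_rate: float = 0.001
    decoy_repeat: bool = False
    preset: str = "custom"


@dataclass
class PlantedSite:
    start: int
    end: int
    seed_start: int
    seed_end: int
    strand: str = "+"


@dataclass
class ScenarioData:
    scenario: Scenario
    genome: dict[str, GenomeSequence]
    mirna: MatureMirna
    planted: list[PlantedSite]
    track: ConservationTrack
    snps: SnpTable
    genes: list[GeneModel]


def random_genome(length: int, gc: float, mask_fraction: float,
                  rng: np.random.Generator, chrom_id: str = "chr1",
                  mean_mask_run: int = 300) -> GenomeSequence:
    """i.i.d. genome with P(G)+P(C)=gc and soft-masked geometric stretches."""
    if not (0 < gc < 1) or not (0 <= mask_fraction < 1):
        raise ValueError("gc in (0,1) and mask_fraction in [0,1) required")
    at, cg = (1 - gc) / 2, gc / 2
    codes = rng.choice(4, size=length, p=[at, cg, cg, at])
    arr = _BASES[codes].copy()
    masked = np.zeros(length, dtype=bool)
    target = int(mask_fraction * length)
    while masked.sum() < target:
        run = max(1, int(rng.geometric(1.0 / mean_mask_run)))
        start = int(rng.integers(0, max(1, length - run)))
        masked[start : start + run] = True
    arr[masked] += 32  # lowercase
    return GenomeSequence(chrom_id, arr.tobytes().decode("ascii"))


def _mutate_site(site_seq: str, n_mut: int, rng: np.random.Generator) -> str:
    """Substitute n_mut bases outside the region pairing the first 8 query bases.

    Site position k pairs query position L-1-k, so the last 8 site positions
    are protected (they carry the perfect seed).
    """
    L = len(site_seq)
    editable = np.arange(0, L - 8)
    chosen = rng.choice(editable, size=min(n_mut, len(editable)), replace=False)
    seq = list(site_seq)
    for k in chosen:
        alternatives = [b for b in "ACGT" if b != seq[k]]
        seq[k] = alternatives[rng.integers(3)]
    return "".join(seq)


def plant_sponge(genome: GenomeSequence, mirna: MatureMirna, n_sites: int,
                 rng: np.random.Generator, gap_range: tuple[int, int] = (2, 40),
                 mismatches: int = 0, identical_copies: bool = False,
                 anchor: int | None = None) -> tuple[GenomeSequence, list[PlantedSite]]:
    """Write n_sites near-reverse-complements of the miRNA into the genome.

    Sites are separated by gaps sampled from gap_range (< 1000 nt so they
    co-cluster); with identical_copies one mutated copy is replicated
    verbatim (repeat-decoy construction).  Returns the modified genome and
    ground-truth intervals.
    """
    if n_sites == 0:
        return genome, []
    L = mirna.length
    perfect = revcomp(mirna.sequence.replace("U", "T"))
    gaps = [int(rng.integers(gap_range[0], gap_range[1] + 1)) for _ in range(n_sites - 1)]
    needed = n_sites * L + sum(gaps)
    if needed > genome.length - 2 * L:
        raise ValueError(f"not enough room to plant {n_sites} sites ({needed} nt needed)")
    if anchor is None:
        anchor = int(rng.integers(L, genome.length - needed - L))
    fixed_copy = _mutate_site(perfect, mismatches, rng) if identical_copies else None

    seq = list(genome.sequence)
    planted: list[PlantedSite] = []
    pos = anchor
    for i in range(n_sites):
        site_seq = fixed_copy if identical_copies else _mutate_site(perfect, mismatches, rng)
        seq[pos : pos + L] = site_seq
        planted.append(PlantedSite(pos, pos + L, pos + L - 8, pos + L - 1))
        pos += L + (gaps[i] if i < len(gaps) else 0)
    return GenomeSequence(genome.chrom_id, "".join(seq)), planted


def synth_tracks(genome: GenomeSequence, planted: list[PlantedSite], snp_rate: float,
                 rng: np.random.Generator, conserved: bool = True,
                 exon_fraction: float = 0.5, seed_snp_factor: float = 1.0,
                 gene_biotype: str = "protein_coding", gene_source: str = "gencode",
                 conserved_score: float = 0.5) -> tuple[ConservationTrack, SnpTable, list[GeneModel]]:
    """Conservation, SNPs and a wrapping gene model matching the planted sponge.

    Conserved planted seed sites get 7 consecutive scores above the phyloP
    threshold; SNPs fall as Bernoulli(snp_rate) per unmasked base, optionally
    rescaled inside seed sites (seed_snp_factor < 1 plants depletion); exons
    cover the first ceil(exon_fraction * n) planted sites.
    """
    chrom = genome.chrom_id
    track = ConservationTrack()
    if conserved:
        for p in planted:
            for pos in range(p.seed_start, p.seed_end):
                track.set_score(chrom, pos, conserved_score)

    snps = SnpTable()
    if snp_rate > 0:
        unmasked = np.flatnonzero(~genome.mask)
        in_seed = np.zeros(genome.length, dtype=bool)
        for p in planted:
            in_seed[p.seed_start : p.seed_end] = True
        draws = rng.random(len(unmasked))
        rates = np.where(in_seed[unmasked], snp_rate * seed_snp_factor, snp_rate)
        for pos in unmasked[draws < rates]:
            snps.add(chrom, int(pos))

    genes: list[GeneModel] = []
    if planted:
        span_start = max(0, planted[0].start - 50)
        span_end = min(genome.length, planted[-1].end + 50)
        n_exonic = int(np.ceil(exon_fraction * len(planted)))
        exons = [(p.start, p.end) for p in planted[:n_exonic]]
        genes.append(
            GeneModel(
                gene_id="SYNGENE1",
                biotype=gene_biotype,
                source=gene_source,
                chrom=chrom,
                strand="+",
                start=span_start,
                end=span_end,
                exons=exons,
            )
        )
    return track, snps, genes


def make_benchmark_scenario(preset: str, rng_seed: int, out_dir: str | Path | None = None,
                            **overrides) -> ScenarioData:
    """Materialize a named benchmark scenario.

    Presets: ``recovery`` (one strong planted sponge), ``null`` (background
    only), ``repeat_decoy`` (one cluster of identical copies, the entropy
    filter's target), ``parity`` (5-Mb background for real/shuffled site
    volume comparison).
    """
    params: dict = {"rng_seed": rng_seed, "preset": preset}
    if preset == "recovery":
        pass
    elif preset == "null":
        params["n_sites"] = 0
    elif preset == "repeat_decoy":
        params["decoy_repeat"] = True
    elif preset == "parity":
        params.update(genome_length=5_000_000, n_sites=0)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    params.update(overrides)
    sc = Scenario(**params)

    rng = np.random.default_rng(sc.rng_seed)
    genome = random_genome(sc.genome_length, sc.gc_content, sc.mask_fraction, rng)
    mirna = DEFAULT_MIRNA
    genome, planted = plant_sponge(
        genome, mirna, sc.n_sites, rng, sc.gap_range, sc.mismatches,
        identical_copies=sc.decoy_repeat,
    )
    track, snps, genes = synth_tracks(
        genome, planted, sc.snp_rate, rng, conserved=sc.conserved,
        exon_fraction=sc.exon_fraction,
    )
    data = ScenarioData(sc, {genome.chrom_id: genome}, mirna, planted, track, snps, genes)
    if out_dir is not None:
        materialize(data, out_dir)
    return data


def materialize(data: ScenarioData, out_dir: str | Path) -> dict[str, Path]:
    """Write scenario fixtures as standard text files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "mirnas": out / "mirnas.fa",
        "genes": out / "genes.gtf",
        "conservation": out / "conservation.wig",
        "snps": out / "snps.tsv",
        "truth": out / "truth.bed",
        "scenario": out / "scenario.tsv",
    }
    write_fasta(data.genome.values(), paths["genome"])
    write_fasta([data.mirna], paths["mirnas"])
    with open(paths["genes"], "w") as fh:
        for g in data.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\t{g.source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for es, ee in g.exons:
                fh.write(
                    f"{g.chrom}\t{g.source}\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{attrs}\n"
                )
    with open(paths["conservation"], "w") as fh:
        for chrom in data.genome:
            scores = data.track._scores.get(chrom, {})
            prev = None
            for pos in sorted(scores):
                if prev is None or pos != prev + 1:
                    fh.write(f"fixedStep chrom={chrom} start={pos + 1} step=1\n")
                fh.write(f"{scores[pos]}\n")
                prev = pos
    with open(paths["snps"], "w") as fh:
        for chrom in data.genome:
            for pos in sorted(data.snps._pos.get(chrom, ())):
                fh.write(f"{chrom}\t{pos}\n")
    with open(paths["truth"], "w") as fh:
        for chrom in data.genome:
            for p in data.planted:
                fh.write(f"{chrom}\t{p.start}\t{p.end}\tplanted\t0\t{p.strand}\n")
    with open(paths["scenario"], "w") as fh:
        for k, v in asdict(data.scenario).items():
            fh.write(f"{k}\t{v}\n")
    return paths
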