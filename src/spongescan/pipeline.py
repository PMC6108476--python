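"""End-to-end orchestration: scan -> shuffle -> scan shuffled -> cluster both
-> fit tail -> select significant -> filter -> annotate -> report.

Each miRNA is processed independently with a shared shuffled genome; outputs
are canonically sorted so any per-miRNA scheduling yields identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .cluster_filters import (
    FilterConfig,
    cluster_entropy,
    conservation_filter,
    conserved_fraction,
    entropy_filter,
)
from .genomic_io import (
    ConservationTrack,
    GeneModel,
    GenomeSequence,
    MatureMirna,
    SnpTable,
    write_candidates,
)
from .genome_shuffle import ShuffleConfig, shuffle_genome
from .significance import TailFit, fit_tail, significant_clusters
from .site_clustering import Cluster, cluster_genome
from .sponge_annotation import SpongeCandidate, annotate_candidate, fbse, sdr, shortlist_high_confidence
from .target_scan import BindingSite, EnergyModel, scan_targets

__all__ = ["PipelineConfig", "MirnaResult", "PipelineResult", "run_pipeline",
           "write_sites_tsv", "read_sites_tsv", "write_clusters_tsv", "read_clusters_tsv",
           "write_fits_tsv", "read_fits_tsv"]


@dataclass
class PipelineConfig:
    """All tunables, with the pipeline's standard defaults."""

    seed_len: int = 6
    seed_region: int = 8
    energy_cutoff: float = -10.0
    window_pad: int = 5
    C: int = 1000
    inflation: float = 3.5
    shuffle_window: int = 120
    p: float = 0.001
    top_frac: float = 0.10
    min_cluster_size: int = 2
    phylop_threshold: float = 0.3
    run_length: int = 5
    enrichment_factor: float = 2.0
    entropy_threshold: float = 0.6
    min_excess: int = 10
    min_fbse: float = 0.09
    rng_seed: int = 0

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            phylop_threshold=self.phylop_threshold,
            run_length=self.run_length,
            enrichment_factor=self.enrichment_factor,
            entropy_threshold=self.entropy_threshold,
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key=value (or key<TAB>value) config; unknown keys rejected."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.replace("\t", "=", 1).partition("=")
                key, value = key.strip(), value.strip()
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                current = getattr(cls(), key)
                kwargs[key] = type(current)(value) if not isinstance(current, int) else int(value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")


@dataclass
class MirnaResult:
    mirna_id: str
    sites_real: list[BindingSite]
    sites_shuffled: list[BindingSite]
    clusters_real: list[Cluster]
    clusters_shuffled: list[Cluster]
    fit: TailFit
    significant: list[Cluster]
    filtered: list[Cluster]
    candidates: list[SpongeCandidate]
    shortlist: list[SpongeCandidate]


@dataclass
class PipelineResult:
    config: PipelineConfig
    per_mirna: dict[str, MirnaResult] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _scan_all(genome: dict[str, GenomeSequence], mirna: MatureMirna, model: EnergyModel,
              cfg: PipelineConfig) -> list[BindingSite]:
    sites: list[BindingSite] = []
    for chrom in sorted(genome):
        sites.extend(
            scan_targets(
                genome[chrom], mirna, model,
                energy_cutoff=cfg.energy_cutoff, seed_len=cfg.seed_len,
                seed_region=cfg.seed_region, window_pad=cfg.window_pad,
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.strand, s.start))
    return sites


def run_pipeline(config: PipelineConfig, genome: dict[str, GenomeSequence],
                 mirnas: list[MatureMirna], genes: list[GeneModel] | None = None,
                 conservation: ConservationTrack | None = None,
                 snps: SnpTable | None = None,
                 model: EnergyModel | None = None,
                 shuffled: dict[str, GenomeSequence] | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the whole pipeline for every miRNA against one genome.

    Conservation, SNP and annotation inputs are optional: stages that need a
    missing input are skipped and the corresponding metrics set to NA (the
    conservation filter passes everything through, SDR is undefined).
    """
    if model is None:
        model = EnergyModel.default()
    fcfg = config.filter_config()
    if shuffled is None:
        shuffled = {
            chrom: shuffle_genome(g, ShuffleConfig(config.shuffle_window, config.rng_seed))
            for chrom, g in genome.items()
        }
    result = PipelineResult(config=config)
    stage_counts: dict[str, dict] = {}
    warnings_log: list[str] = []
    if conservation is None:
        warnings_log.append("no conservation track: conservation filter skipped")
    if snps is None:
        warnings_log.append("no SNP table: SDR set to NA")
    if genes is None:
        warnings_log.append("no gene models: candidates left unannotated, FBSE = 0")

    for mirna in mirnas:
        sites_real = _scan_all(genome, mirna, model, config)
        sites_shuf = _scan_all(shuffled, mirna, model, config)
        clusters_real = cluster_genome(sites_real, config.inflation, config.C, mirna.mirna_id)
        clusters_shuf = cluster_genome(sites_shuf, config.inflation, config.C, mirna.mirna_id)
        fit = fit_tail(clusters_shuf, config.top_frac, config.p,
                       config.min_cluster_size, mirna.mirna_id)
        if fit.valid:
            sig = significant_clusters(clusters_real, fit)
        else:
            sig = []
            warnings_log.append(f"{mirna.mirna_id}: no significance cutoff (NoCutoff)")

        if conservation is not None:
            genome_frac = conserved_fraction(sites_real, conservation, fcfg)
            kept = conservation_filter(sig, conservation, genome_frac, fcfg)
        else:
            genome_frac = 0.0
            kept = list(sig)
        kept = entropy_filter(kept, fcfg)

        candidates = []
        for cl in kept:
            ann = annotate_candidate(cl, genes) if genes else None
            candidates.append(
                SpongeCandidate(
                    cluster=cl,
                    fit=fit,
                    annotation=ann,
                    fbse=fbse(cl, genes) if genes else 0.0,
                    sdr=sdr(cl, snps) if snps is not None else None,
                    entropy=cluster_entropy(cl),
                    conserved_fraction=(
                        conserved_fraction(cl.sites, conservation, fcfg)
                        if conservation is not None
                        else 0.0
                    ),
                )
            )
        shortlist = shortlist_high_confidence(candidates, config.min_excess, config.min_fbse)
        result.per_mirna[mirna.mirna_id] = MirnaResult(
            mirna.mirna_id, sites_real, sites_shuf, clusters_real, clusters_shuf,
            fit, sig, kept, candidates, shortlist,
        )
        stage_counts[mirna.mirna_id] = {
            "sites_real": len(sites_real),
            "sites_shuffled": len(sites_shuf),
            "clusters_real": len(clusters_real),
            "clusters_shuffled": len(clusters_shuf),
            "cutoff": fit.x_cutoff,
            "significant": len(sig),
            "post_filter": len(kept),
            "shortlist": len(shortlist),
        }

    cfg_text = json.dumps(dataclasses.asdict(config), sort_keys=True)
    result.manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "input_checksums": {
            chrom: hashlib.sha256(g.sequence.encode()).hexdigest()[:16]
            for chrom, g in sorted(genome.items())
        },
        "stage_counts": stage_counts,
        "warnings": warnings_log,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_candidates = [c for r in result.per_mirna.values() for c in r.candidates]
        all_shortlist = [c for r in result.per_mirna.values() for c in r.shortlist]
        write_candidates(all_candidates, out / "candidates.tsv", "tsv")
        write_candidates(
            sorted(all_shortlist, key=lambda c: -c.excess_size), out / "shortlist.tsv", "tsv"
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(result.manifest, fh, indent=2, default=str)
    return result


# ---------------------------------------------------------------------------
# stage TSV formats (used by the CLI subcommands)

_SITE_COLS = ["mirna_id", "chrom", "strand", "start", "end", "energy",
              "seed_start", "seed_end", "paired_fraction"]


def write_sites_tsv(sites: list[BindingSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SITE_COLS) + "\n")
        for s in sites:
            fh.write(
                f"{s.mirna_id}\t{s.chrom}\t{s.strand}\t{s.start}\t{s.end}"
                f"\t{s.energy:.4f}\t{s.seed_start}\t{s.seed_end}\t{s.paired_fraction}\n"
            )


def read_sites_tsv(path) -> list[BindingSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == _SITE_COLS, f"unexpected sites header in {path}"
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(
                BindingSite(f[1], f[2], int(f[3]), int(f[4]), float(f[5]),
                            int(f[6]), int(f[7]), float(f[8]), f[0])
            )
    return sites


def write_sites_bed(sites: list[BindingSite], path) -> None:
    """BED6 export: name = miRNA id, score = round(-energy * 100)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.mirna_id}"
                f"\t{round(-s.energy * 100)}\t{s.strand}\n"
            )


def write_clusters_bed(clusters: list[Cluster], path) -> None:
    """BED6 export of cluster spans: name = mirna_id:index, score = size."""
    with open(path, "w") as fh:
        for idx, c in enumerate(clusters):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.mirna_id}:{idx}\t{c.size}\t{c.strand}\n"
            )


def write_clusters_tsv(clusters: list[Cluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tchrom\tstrand\tstart\tend\tsize\tmember_sites\n")
        for c in clusters:
            members = ";".join(
                f"{s.start}-{s.end}:{s.energy:.4f}:{s.seed_start}-{s.seed_end}:{s.paired_fraction}"
                for s in c.sites
            )
            fh.write(f"{c.mirna_id}\t{c.chrom}\t{c.strand}\t{c.start}\t{c.end}\t{c.size}\t{members}\n")


def read_clusters_tsv(path) -> list[Cluster]:
    clusters = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites = []
            for tok in f[6].split(";"):
                span, energy, seed, pf = tok.split(":")
                s0, e0 = span.split("-")
                ss, se = seed.split("-")
                sites.append(
                    BindingSite(f[1], f[2], int(s0), int(e0), float(energy),
                                int(ss), int(se), float(pf), f[0])
                )
            clusters.append(
                Cluster(f[0], list(range(len(sites))), f[1], f[2], int(f[3]), int(f[4]), sites)
            )
    return clusters


def write_fits_tsv(fits: list[TailFit], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\ta\tb\tcutoff\tp\tn_clusters_fit\n")
        for t in fits:
            a = "NA" if t.a is None else f"{t.a:.6f}"
            b = "NA" if t.b is None else f"{t.b:.6f}"
            cut = "NA" if t.x_cutoff is None else t.x_cutoff
            fh.write(f"{t.mirna_id}\t{a}\t{b}\t{cut}\t{t.p}\t{t.n_clusters_fit}\n")


def read_fits_tsv(path) -> dict[str, TailFit]:
    fits = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            fits[f[0]] = TailFit(
                f[0],
                None if f[1] == "NA" else float(f[1]),
                None if f[2] == "NA" else float(f[2]),
                None if f[3] == "NA" else int(f[3]),
                float(f[4]),
                int(f[5]),
            )
    return fits
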