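"""Post-significance cluster filters: seed conservation enrichment and
binding-energy entropy.

A site counts as conserved when its 7-nt seed site contains a run of at
least five consecutive positions with conservation score strictly above 0.3.
Clusters are kept when their conserved-site fraction is at least twice the
genome-wide conserved fraction for the same miRNA, and when the normalized
Shannon entropy of their (2-decimal) binding energies is at least 0.6 —
near-zero entropy marks clusters built from identical repeat copies.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .genomic_io import ConservationTrack
from .site_clustering import Cluster
from .target_scan import BindingSite

__all__ = [
    "FilterConfig",
    "site_is_conserved",
    "conserved_fraction",
    "conservation_filter",
    "energy_entropy",
    "entropy_filter",
]


@dataclass
class FilterConfig:
    phylop_threshold: float = 0.3
    run_length: int = 5
    enrichment_factor: float = 2.0
    entropy_threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.run_length > 7:
            raise ValueError("run_length cannot exceed the 7-nt seed site")


def site_is_conserved(site: BindingSite, track: ConservationTrack,
                      cfg: FilterConfig | None = None) -> bool:
    """True iff the seed site holds a run of >= run_length scores > threshold.

    Positions without data count as non-conserved.
    """
    cfg = cfg or FilterConfig()
    run = best = 0
    for score in track.scores(site.chrom, site.seed_start, site.seed_end):
        if score is not None and score > cfg.phylop_threshold:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best >= cfg.run_length


def conserved_fraction(sites: list[BindingSite], track: ConservationTrack,
                       cfg: FilterConfig | None = None) -> float:
    if not sites:
        return 0.0
    return sum(site_is_conserved(s, track, cfg) for s in sites) / len(sites)


def conservation_filter(clusters: list[Cluster], track: ConservationTrack,
                        all_sites_conserved_fraction: float,
                        cfg: FilterConfig | None = None) -> list[Cluster]:
    """Keep clusters whose conserved fraction >= factor x genome-wide fraction.

    A genome-wide fraction of 0 keeps everything (threshold degenerates to 0).
    """
    cfg = cfg or FilterConfig()
    threshold = cfg.enrichment_factor * all_sites_conserved_fraction
    return [c for c in clusters if conserved_fraction(c.sites, track, cfg) >= threshold]


def energy_entropy(energies: list[float]) -> float:
    """Normalized Shannon entropy of binding energies, in [0, 1].

    Energies are compared after rounding to 2 decimals; a single site (or a
    single distinct energy) gives 0 by convention.
    """
    n = len(energies)
    if n <= 1:
        return 0.0
    counts = Counter(round(e, 2) for e in energies)
    if len(counts) == 1:
        return 0.0
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return h / math.log2(n)


def cluster_entropy(cluster: Cluster) -> float:
    return energy_entropy([s.energy for s in cluster.sites])


def entropy_filter(clusters: list[Cluster], cfg: FilterConfig | None = None) -> list[Cluster]:
    """Keep clusters with energy entropy >= entropy_threshold (inclusive)."""
    cfg = cfg or FilterConfig()
    return [c for c in clusters if cluster_entropy(c) >= cfg.entropy_threshold]


def write_filter_report(clusters: list[Cluster], track: ConservationTrack | None,
                        genome_fraction: float, path, cfg: FilterConfig | None = None) -> None:
    """Per-cluster TSV of both filter statistics and pass/fail flags."""
    cfg = cfg or FilterConfig()
    with open(path, "w") as fh:
        fh.write(
            "mirna_id\tchrom\tstrand\tstart\tend\tsize\tconserved_fraction"
            "\tgenome_fraction\tentropy\tpass_conservation\tpass_entropy\n"
        )
        for c in clusters:
            frac = conserved_fraction(c.sites, track, cfg) if track is not None else 0.0
            ent = cluster_entropy(c)
            ok_cons = track is None or frac >= cfg.enrichment_factor * genome_fraction
            ok_ent = ent >= cfg.entropy_threshold
            fh.write(
                f"{c.mirna_id}\t{c.chrom}\t{c.strand}\t{c.start}\t{c.end}\t{c.size}"
                f"\t{frac:.4f}\t{genome_fraction:.4f}\t{ent:.4f}"
                f"\t{int(ok_cons)}\t{int(ok_ent)}\n"
            )
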