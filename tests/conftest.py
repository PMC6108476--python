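from __future__ import annotations

import numpy as np
import pytest

from spongescan.genomic_io import GenomeSequence, MatureMirna
from spongescan.site_clustering import Cluster
from spongescan.target_scan import BindingSite, EnergyModel


@pytest.fixture(scope="session")
def default_model() -> EnergyModel:
    return EnergyModel.default()


@pytest.fixture
def toy_model() -> EnergyModel:
    return EnergyModel.uniform(stack_energy=-2.0, loop_open=3.0, loop_extend=0.5)


def make_site(start: int, end: int, energy: float = -12.0, strand: str = "+",
              chrom: str = "chr1", seed_start: int | None = None,
              mirna_id: str = "mir-x") -> BindingSite:
    ss = start if seed_start is None else seed_start
    return BindingSite(chrom, strand, start, end, energy, ss, min(ss + 7, end),
                       0.5, mirna_id)


def make_cluster(sites: list[BindingSite], mirna_id: str = "mir-x") -> Cluster:
    return Cluster(
        mirna_id=mirna_id,
        members=list(range(len(sites))),
        chrom=sites[0].chrom,
        strand=sites[0].strand,
        start=min(s.start for s in sites),
        end=max(s.end for s in sites),
        sites=sites,
    )


def cluster_of_size(n: int, start: int = 0, energy_fn=lambda i: -12.0 - i,
                    chrom: str = "chr1") -> Cluster:
    sites = [
        make_site(start + i * 40, start + i * 40 + 22, energy_fn(i), chrom=chrom)
        for i in range(n)
    ]
    return make_cluster(sites)


def random_mirna(rng: np.random.Generator, length: int = 21, name: str = "mir-r") -> MatureMirna:
    return MatureMirna(name, "".join(rng.choice(list("ACGU"), size=length)))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def unmasked_genome():
    def _make(seq: str, chrom: str = "chr1") -> GenomeSequence:
        return GenomeSequence(chrom, seq)

    return _make
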