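import numpy as np
import pytest

from spongescan.genomic_io import GeneModel, GenomeSequence, SnpTable
from spongescan.significance import TailFit
from spongescan.sponge_annotation import (
    SpongeCandidate,
    annotate_candidate,
    fbse,
    genomic_context_summary,
    sdr,
    shortlist_high_confidence,
)

from .conftest import cluster_of_size, make_cluster, make_site


def gene(gene_id="g1", biotype="protein_coding", source="gencode", start=0, end=10_000,
         strand="+", chrom="chr1", exons=()):
    return GeneModel(gene_id, biotype, source, chrom, strand, start, end, list(exons))


def candidate(cluster, cutoff=20, annotation=("g1", "protein_coding", "gencode"),
              fbse_val=0.2, sdr_val=1.0, entropy=0.9, cons=0.5):
    fit = TailFit(cluster.mirna_id, -1.0, 4.0, cutoff)
    return SpongeCandidate(cluster, fit, annotation, fbse_val, sdr_val, entropy, cons)


class TestAnnotateCandidate:
    def test_candidate_inside_larger_gene(self):
        cl = cluster_of_size(5)  # span [0, 182)
        assert annotate_candidate(cl, [gene()]) == ("g1", "protein_coding", "gencode")

    def test_49_percent_overlap_rejected(self):
        cl = make_cluster([make_site(0, 100)])
        g = gene(start=51, end=10_000)  # overlap 49 of smaller region 100
        assert annotate_candidate(cl, [g]) is None

    def test_gencode_priority_over_circbase(self):
        cl = cluster_of_size(5)
        circ = gene("circ1", "circRNA", "circbase")
        coding = gene("zzz", "protein_coding", "gencode")
        assert annotate_candidate(cl, [circ, coding])[0] == "zzz"

    def test_strand_must_match(self):
        cl = cluster_of_size(5)
        assert annotate_candidate(cl, [gene(strand="-")]) is None


class TestFbse:
    def test_fraction_of_contained_sites(self):
        cl = cluster_of_size(10)
        exons = [(s.start, s.end) for s in cl.sites[:3]]
        assert fbse(cl, [gene(exons=exons)]) == pytest.approx(0.3)

    def test_no_gene_overlap_is_zero(self):
        assert fbse(cluster_of_size(10), []) == 0.0

    def test_junction_straddling_site_not_counted(self):
        cl = make_cluster([make_site(0, 22)])
        g = gene(exons=[(0, 10)])  # exon ends inside the site
        assert fbse(cl, [g]) == 0.0


class TestSdr:
    def test_direct_evaluation(self):
        # 2 seed sites of 7 nt, 100-nt gap between them; 2 SNPs in seeds, 1 in gap
        s1 = make_site(0, 22, seed_start=0)
        s2 = make_site(107, 129, seed_start=107)
        cl = make_cluster([s1, s2])
        snps = SnpTable()
        snps.add("chr1", 1)
        snps.add("chr1", 108)
        snps.add("chr1", 50)
        assert sdr(cl, snps) == pytest.approx((2 / 14) / (1 / 100))

    def test_zero_seed_snps_is_zero(self):
        cl = make_cluster([make_site(0, 22, seed_start=0), make_site(107, 129, seed_start=107)])
        snps = SnpTable()
        snps.add("chr1", 50)
        assert sdr(cl, snps) == 0.0

    def test_zero_flanking_snps_undefined(self):
        cl = make_cluster([make_site(0, 22, seed_start=0), make_site(107, 129, seed_start=107)])
        snps = SnpTable()
        snps.add("chr1", 1)
        assert sdr(cl, snps) is None

    def test_uniform_snps_median_near_one_and_depletion_detected(self):
        medians = {}
        for factor in (1.0, 0.1):
            ratios = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                sites = [make_site(i * 40, i * 40 + 22, seed_start=i * 40 + 10) for i in range(40)]
                cl = make_cluster(sites)
                snps = SnpTable()
                in_seed = np.zeros(cl.end, dtype=bool)
                for s in sites:
                    in_seed[s.seed_start : s.seed_end] = True
                for pos in range(cl.end):
                    rate = 0.05 * (factor if in_seed[pos] else 1.0)
                    if rng.random() < rate:
                        snps.add("chr1", pos)
                val = sdr(cl, snps)
                if val is not None:
                    ratios.append(val)
            medians[factor] = float(np.median(ratios))
        assert 0.5 <= medians[1.0] <= 2.0
        assert medians[0.1] < medians[1.0]


class TestShortlist:
    def test_table_style_entry_included(self):
        cl = cluster_of_size(76)
        c = candidate(cl, cutoff=20, fbse_val=0.2)
        (kept,) = shortlist_high_confidence([c])
        assert kept.excess_size == 56

    def test_excess_below_10_excluded(self):
        c = candidate(cluster_of_size(29), cutoff=20)
        assert shortlist_high_confidence([c]) == []

    def test_unannotated_excluded(self):
        c = candidate(cluster_of_size(76), annotation=None)
        assert shortlist_high_confidence([c]) == []

    def test_fbse_strictly_greater(self):
        at = candidate(cluster_of_size(76), fbse_val=0.09)
        above = candidate(cluster_of_size(40), fbse_val=0.091)
        assert shortlist_high_confidence([at, above]) == [above]

    def test_sorted_by_excess_descending(self):
        small = candidate(cluster_of_size(35))
        big = candidate(cluster_of_size(90, start=500_000))
        out = shortlist_high_confidence([small, big])
        assert [c.cluster.size for c in out] == [90, 35]


class TestGenomicContext:
    def test_toy_enrichment_of_two(self):
        genome = {"chr1": GenomeSequence("chr1", "A" * 1000)}
        genes = [gene(start=0, end=500, strand=s) for s in "+-"]
        cl = make_cluster([make_site(100, 200)])
        c = candidate(cl, cutoff=1)
        df = genomic_context_summary([c], genes, genome)
        assert df.loc["PCG_not_circRNA", "genome_pct"] == pytest.approx(50.0)
        assert df.loc["PCG_not_circRNA", "candidate_pct"] == pytest.approx(100.0)
        assert df.loc["PCG_not_circRNA", "enrichment"] == pytest.approx(2.0)

    def test_no_candidates_keeps_genome_column(self):
        genome = {"chr1": GenomeSequence("chr1", "A" * 100)}
        df = genomic_context_summary([], [gene(start=0, end=50)], genome)
        assert df["genome_pct"].sum() == pytest.approx(100.0)
        assert df["candidate_pct"].isna().all()

    def test_columns_partition_to_100(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGTacgt"), size=5000))
        genome = {"chr1": GenomeSequence("chr1", seq)}
        genes = [
            gene("g1", "protein_coding", start=0, end=2000),
            gene("c1", "circRNA", "circbase", start=1500, end=2500),
            gene("l1", "lincRNA", start=3000, end=3500, strand="-"),
        ]
        cl = make_cluster([make_site(1600, 1900)])
        df = genomic_context_summary([candidate(cl, cutoff=1)], genes, genome)
        assert df["genome_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        assert df["candidate_pct"].sum() == pytest.approx(100.0, abs=1e-9)
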