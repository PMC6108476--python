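import itertools

import numpy as np
import pytest

from spongescan.genomic_io import GenomeSequence, MatureMirna
from spongescan.target_scan import (
    BindingSite,
    DuplexAlignment,
    EnergyModel,
    SeedMatch,
    _admissible_kmers,
    duplex_energy,
    extend_site,
    find_seed_matches,
    merge_overlapping_sites,
    paired_fraction,
    revcomp,
    scan_targets,
)

from .conftest import make_site, random_dna, random_mirna
from .oracles import brute_force_scan, pairs_ok


class TestSeedMatching:
    def test_perfect_watson_crick_seed(self):
        # miRNA positions 1-6 "AAAAAA" pair a genomic TTTTTT stretch
        mirna = MatureMirna("m", "CAAAAAAC" + "A" * 14)
        genome = GenomeSequence("chr1", "GCGC" + "TTTTTT" + "GCGCGCGC")
        matches = [m for m in find_seed_matches(genome, mirna) if m.strand == "+"]
        assert any(m.start == 4 and m.offset == 1 for m in matches)

    def test_g_seed_matches_64_distinct_kmers(self):
        # G pairs C or U, so a GGGGGG seed admits 2^6 target 6-mers;
        # verified independently by enumerating all 4^6 6-mers
        mirna_seq = "GGGGGGGG"
        kmers = _admissible_kmers(mirna_seq, 0, 6)
        assert len(set(kmers)) == 64
        brute = sum(
            all(pairs_ok(mirna_seq[5 - k], "".join(combo)[k]) for k in range(6))
            for combo in itertools.product("ACGT", repeat=6)
        )
        assert brute == 64

    def test_poly_a_genome_matches_only_on_minus_strand(self):
        mirna = MatureMirna("m", "AAAAAAAA")
        genome = GenomeSequence("chr1", "A" * 50)
        matches = find_seed_matches(genome, mirna)
        assert all(m.strand == "-" for m in matches)
        # minus-strand sense is poly-T: every offset of every position matches
        assert len(matches) == 3 * (50 - 5)

    def test_masked_seed_windows_excluded(self):
        mirna = MatureMirna("m", "CAAAAAAC" + "A" * 14)
        genome = GenomeSequence("chr1", "GCGC" + "TTTtTT" + "GCGCGCGC")
        assert not [m for m in find_seed_matches(genome, mirna) if m.strand == "+"]

    def test_short_mirna_rejected(self):
        with pytest.raises(Exception):
            find_seed_matches(GenomeSequence("c", "ACGT" * 10), MatureMirna("m", "AAAAAAAA"),
                              seed_region=10)


class TestDuplexEnergy:
    def test_empty_alignment_is_init_penalty(self, toy_model):
        toy_model.init_penalty = 1.5
        mirna = MatureMirna("m", "A" * 10)
        assert duplex_energy([], mirna, "T" * 10, toy_model) == 1.5

    def test_contiguous_11_pairs_sum_10_stacks(self, toy_model):
        mirna = MatureMirna("m", "A" * 11)
        target = "T" * 11
        pairs = [(i, 10 - i) for i in range(11)]
        assert duplex_energy(pairs, mirna, target, toy_model) == pytest.approx(-20.0)

    def test_bulge_charged_open_plus_extends(self, toy_model):
        # two 5-pair helices around a 2-nt bulge on the target side:
        # 8 stacks * -2.0 + (3.0 + 2 * 0.5) = -12.0
        mirna = MatureMirna("m", "A" * 10)
        target = "T" * 21
        pairs = [(i, 20 - i) for i in range(5)] + [(5 + k, 13 - k) for k in range(5)]
        assert duplex_energy(pairs, mirna, target, toy_model) == pytest.approx(-12.0)

    def test_inadmissible_pair_rejected(self, toy_model):
        mirna = MatureMirna("m", "A" * 10)
        with pytest.raises(ValueError, match="inadmissible"):
            duplex_energy([(0, 0)], mirna, "A" * 10, toy_model)


class TestExtension:
    def test_full_complement_pairs_every_base(self, default_model):
        mirna = MatureMirna("m", "UACCAACACUCAGUCUUAACGU")
        target = revcomp(mirna.sequence.replace("U", "T"))
        sense = "GGGG" + target + "GGGG"
        j = 4 + len(target) - 6  # seed window at offset 0 sits at the 3' end
        aln = extend_site(SeedMatch("+", j, j + 6, 0), sense, mirna, default_model)
        assert aln.n_pairs == mirna.length
        assert paired_fraction(aln, mirna) == 1.0

    def test_masked_flanks_give_seed_only_duplex(self, default_model):
        mirna = MatureMirna("m", "CAAAAAAC" + "A" * 14)
        sense = "gcgc" + "TTTTTT" + "gcgcgcgc"
        aln = extend_site(SeedMatch("+", 4, 10, 1), sense, mirna, default_model)
        assert aln.n_pairs == 6

    def test_extension_never_worse_than_seed_alone(self, default_model):
        rng = np.random.default_rng(11)
        for _ in range(50):
            mirna = random_mirna(rng)
            sense = random_dna(rng, 80)
            for o, j in [(0, 30), (1, 30), (2, 30)]:
                window = sense[j : j + 6]
                if not all(pairs_ok(mirna.sequence[o + 5 - k], window[k]) for k in range(6)):
                    continue
                aln = extend_site(SeedMatch("+", j, j + 6, o), sense, mirna, default_model)
                seed_only = extend_site(
                    SeedMatch("+", j, j + 6, o),
                    sense[:j].lower() + window + sense[j + 6 :].lower(),
                    mirna, default_model,
                )
                assert aln.energy <= seed_only.energy + 1e-9


class TestMerging:
    def test_overlapping_sites_merge_to_min_energy(self):
        a = make_site(100, 121, -12.0)
        b = make_site(110, 131, -15.0, seed_start=112)
        (m,) = merge_overlapping_sites([a, b])
        assert (m.start, m.end, m.energy) == (100, 131, -15.0)
        assert m.seed_start == 112  # seed follows the best constituent

    def test_book_ended_half_open_intervals_not_merged(self):
        out = merge_overlapping_sites([make_site(100, 120), make_site(120, 140)])
        assert len(out) == 2

    def test_opposite_strands_not_merged(self):
        out = merge_overlapping_sites([make_site(100, 120, strand="+"),
                                       make_site(110, 130, strand="-")])
        assert len(out) == 2


class TestPairedFraction:
    @pytest.mark.parametrize("n_pairs,length,expected", [(11, 22, 0.5), (22, 22, 1.0), (6, 20, 0.3)])
    def test_values(self, n_pairs, length, expected):
        mirna = MatureMirna("m", "A" * length)
        aln = DuplexAlignment([(i, length - i) for i in range(n_pairs)], -20.0)
        assert paired_fraction(aln, mirna) == pytest.approx(expected)


class TestScan:
    def test_planted_complement_found_below_cutoff(self, default_model):
        mirna = MatureMirna("m", "UACCAACACUCAGUCUUAACGU")
        target = revcomp(mirna.sequence.replace("U", "T"))
        genome = GenomeSequence("chr1", "A" * 60 + target + "A" * 60)
        sites = scan_targets(genome, mirna, default_model)
        hit = [s for s in sites if s.start <= 60 and s.end >= 60 + len(target)]
        assert hit and hit[0].energy <= -10.0

    def test_no_admissible_seed_gives_empty(self, default_model):
        # genome of G on both strands senses (G/C): seed needs T or A somewhere
        mirna = MatureMirna("m", "AAAAAAAA")
        genome = GenomeSequence("chr1", "G" * 100)
        assert scan_targets(genome, mirna, default_model) == []

    def test_strand_symmetry(self, default_model):
        rng = np.random.default_rng(5)
        mirna = random_mirna(rng, name="mir-sym")
        seq = random_dna(rng, 600)
        fwd = scan_targets(GenomeSequence("chr1", seq), mirna, default_model)
        rev = scan_targets(GenomeSequence("chr1", revcomp(seq)), mirna, default_model)
        L = len(seq)
        mirrored = sorted(
            (s.chrom, "+" if s.strand == "-" else "-", L - s.end, L - s.start,
             round(s.energy, 6))
            for s in rev
        )
        assert mirrored == sorted((s.chrom, s.strand, s.start, s.end, round(s.energy, 6))
                                  for s in fwd)

    def test_cutoff_monotonicity(self, default_model):
        rng = np.random.default_rng(6)
        mirna = random_mirna(rng, name="mir-mono")
        genome = GenomeSequence("chr1", random_dna(rng, 2000))
        strict = scan_targets(genome, mirna, default_model, energy_cutoff=-10.0)
        loose = scan_targets(genome, mirna, default_model, energy_cutoff=-5.0)
        assert len(loose) >= len(strict)

    def test_determinism(self, default_model):
        rng = np.random.default_rng(7)
        mirna = random_mirna(rng, name="mir-det")
        genome = GenomeSequence("chr1", random_dna(rng, 1500))
        assert scan_targets(genome, mirna, default_model) == scan_targets(
            genome, mirna, default_model
        )

    def test_agrees_with_brute_force_oracle(self, default_model):
        rng = np.random.default_rng(8)
        for i in range(5):
            mirna = random_mirna(rng, name=f"mir-{i}")
            genome = GenomeSequence("chr1", random_dna(rng, 400))
            fast = scan_targets(genome, mirna, default_model)
            slow = brute_force_scan(genome, mirna, default_model)
            assert fast == slow
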