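"""Junction-read filtering, consensus, site calling, loci and enrichment."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from attforge import fixtures, integration_mapping as im
from attforge._seq import revcomp


@pytest.fixture(scope="module")
def small_setup():
    genome = fixtures.make_genome(50_000, 0.45, seed=21)
    attd = fixtures.make_genome(50, 0.5, seed=22)
    donor = fixtures.build_donor(attd, core_offset=24, seed=23)
    config = im.SiteConfig(donor_seq=donor.sequence, primer=donor.primer,
                           attd_interval=donor.attd_interval,
                           core_offset=donor.core_offset)
    return genome, donor, config


def sam_line(name, flag, chrom, pos, mapq, cigar, seq, mate_pos=None,
             tlen=0):
    qual = "F" * len(seq)
    mate = str((mate_pos or pos) + 1)
    return (f"{name}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t{cigar}\t="
            f"\t{mate}\t{tlen}\t{seq}\t{qual}")


def make_sam(genome, donor, config, records):
    header = (f"@HD\tVN:1.6\tSO:unsorted\n"
              f"@SQ\tSN:donor\tLN:{len(donor.sequence)}\n"
              f"@SQ\tSN:chr1\tLN:{len(genome)}\n")
    return header + "\n".join(records) + "\n"


def junction_read(genome, donor, config, pos, mapq=60, tlen=400,
                  clip_override=None, name="r1"):
    """A forward-strand junction read planted at genomic core position pos."""
    attd_lo, _ = config.attd_interval
    clip = clip_override if clip_override is not None else \
        donor.sequence[config.primer_start : attd_lo + config.core_offset]
    glen = 150 - len(clip)
    seq = clip + genome[pos : pos + glen]
    flag = 0x1 | 0x2 | 0x40 | 0x20
    return sam_line(name, flag, "chr1", pos, mapq,
                    f"{len(clip)}S{glen}M", seq, tlen=tlen)


class TestFilterReads:
    @pytest.mark.parametrize("mapq,kept", [(29, 0), (30, 1)])
    def test_mapq_boundary(self, small_setup, mapq, kept):
        genome, donor, config = small_setup
        sam = make_sam(genome, donor, config,
                       [junction_read(genome, donor, config, 10_000, mapq=mapq)])
        assert len(im.filter_reads(sam, config)) == kept

    @pytest.mark.parametrize("tlen,kept", [(1501, 0), (1500, 1)])
    def test_insert_size_boundary(self, small_setup, tlen, kept):
        genome, donor, config = small_setup
        sam = make_sam(genome, donor, config,
                       [junction_read(genome, donor, config, 10_000, tlen=tlen)])
        assert len(im.filter_reads(sam, config)) == kept

    def test_intact_attd_read_removed(self, small_setup):
        genome, donor, config = small_setup
        # Read runs through the entire attD (no junction): intact, dropped.
        lo, hi = config.attd_interval
        clip = donor.sequence[config.primer_start : hi + 10]
        sam = make_sam(genome, donor, config,
                       [junction_read(genome, donor, config, 10_000,
                                      clip_override=clip)])
        assert im.filter_reads(sam, config) == []

    def test_read_without_primer_clip_removed(self, small_setup):
        genome, donor, config = small_setup
        clip = fixtures.make_genome(59, 0.5, 99)   # unrelated clip
        sam = make_sam(genome, donor, config,
                       [junction_read(genome, donor, config, 10_000,
                                      clip_override=clip)])
        assert im.filter_reads(sam, config) == []

    def test_donor_only_read_removed(self, small_setup):
        genome, donor, config = small_setup
        seq = donor.sequence[:150]
        rec = sam_line("d1", 0x1 | 0x2 | 0x40 | 0x20, "donor", 0, 60,
                       "150M", seq)
        sam = make_sam(genome, donor, config, [rec])
        assert im.filter_reads(sam, config) == []

    def test_positional_duplicates_collapse_and_idempotence(self, small_setup):
        genome, donor, config = small_setup
        reads = [junction_read(genome, donor, config, 10_000, name=f"r{i}")
                 for i in range(3)]
        reads.append(junction_read(genome, donor, config, 20_000, name="r9"))
        sam = make_sam(genome, donor, config, reads)
        kept = im.filter_reads(sam, config)
        assert len(kept) == 2            # one per distinct position
        # Dedup is idempotent: filtering the survivors changes nothing.
        again_keys = {(r.chrom, r.anchor, r.strand) for r in kept}
        assert len(again_keys) == 2

    def test_umi_distinguishes_same_position_events(self, small_setup):
        genome, donor, config = small_setup
        r1 = junction_read(genome, donor, config, 10_000, name="u1") + "\tRX:Z:AAAA"
        r2 = junction_read(genome, donor, config, 10_000, name="u2") + "\tRX:Z:CCCC"
        r3 = junction_read(genome, donor, config, 10_000, name="u3") + "\tRX:Z:AAAA"
        sam = make_sam(genome, donor, config, [r1, r2, r3])
        assert len(im.filter_reads(sam, config)) == 2


class TestConsensusClips:
    def test_identical_clips_reproduce_clip(self, small_setup):
        _, donor, config = small_setup
        clip = donor.sequence[config.primer_start :
                              config.attd_interval[0] + 24]
        recs = [im.JunctionReadRecord(f"r{i}", "chr1", 100, "+", clip, 60,
                                      300, True, True, True, "disrupted")
                for i in range(3)]
        cons = im.consensus_clips(recs, config)
        assert cons[("chr1", 100, "+")] == clip

    def test_majority_base_wins(self, small_setup):
        _, donor, config = small_setup
        clip = donor.sequence[config.primer_start :
                              config.attd_interval[0] + 24]
        variant = clip[:30] + ("A" if clip[30] != "A" else "C") + clip[31:]
        recs = [im.JunctionReadRecord(f"r{i}", "chr1", 100, "+", s, 60,
                                      300, True, True, True, "disrupted")
                for i, s in enumerate([clip, clip, variant])]
        cons = im.consensus_clips(recs, config)
        assert cons[("chr1", 100, "+")] == clip

    def test_even_tie_becomes_n(self, small_setup):
        _, donor, config = small_setup
        clip = donor.sequence[config.primer_start :
                              config.attd_interval[0] + 24]
        variant = clip[:30] + ("A" if clip[30] != "A" else "C") + clip[31:]
        recs = [im.JunctionReadRecord(f"r{i}", "chr1", 100, "+", s, 60,
                                      300, True, True, True, "disrupted")
                for i, s in enumerate([clip, variant])]
        cons = im.consensus_clips(recs, config)
        assert cons[("chr1", 100, "+")][30] == "N"


class TestCallSites:
    def consensus_for(self, config, mutate=0, crossover_shift=0):
        lo = config.attd_interval[0]
        end = lo + config.core_offset + crossover_shift
        cons = config.donor_seq[config.primer_start : end]
        if mutate:
            rng = np.random.default_rng(1)
            cons = list(cons)
            for pos in rng.choice(len(cons) - 10, size=mutate, replace=False):
                cons[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[cons[pos]]
            cons = "".join(cons)
        return cons

    def test_valid_consensus_called_at_anchor(self, small_setup):
        _, _, config = small_setup
        cons = {("chr1", 5000, "+"): self.consensus_for(config)}
        sites, rejections = im.call_sites(cons, config)
        assert len(sites) == 1 and not rejections
        assert sites[0].position == 5000

    def test_minus_strand_position_is_core_start(self, small_setup):
        _, _, config = small_setup
        cons = {("chr1", 5002, "-"): self.consensus_for(config)}
        sites, _ = im.call_sites(cons, config)
        assert sites[0].position == 5000

    def test_unrelated_consensus_rejected_for_missing_9mer(self, small_setup):
        _, _, config = small_setup
        cons = {("chr1", 5000, "+"): fixtures.make_genome(60, 0.5, 77)}
        sites, rejections = im.call_sites(cons, config)
        assert not sites and "9-mer" in rejections[0].reason

    def test_identity_gate(self, small_setup):
        _, _, config = small_setup
        # Heavily mutated consensus falls below 80% in both alignments.
        cons = {("chr1", 5000, "+"): self.consensus_for(config, mutate=20)}
        sites, rejections = im.call_sites(cons, config)
        assert not sites and "identity" in rejections[0].reason

    @pytest.mark.parametrize("shift,ok", [(-15, True), (-16, False)])
    def test_crossover_distance_boundary(self, small_setup, shift, ok):
        _, _, config = small_setup
        cons = {("chr1", 5000, "+"): self.consensus_for(config,
                                                        crossover_shift=shift)}
        sites, rejections = im.call_sites(cons, config)
        assert bool(sites) is ok


class TestMergeLoci:
    def make_site(self, pos, strand="+", support=1):
        return im.IntegrationSite(chrom="chr1", position=pos,
                                  orientation=strand, support=support)

    def test_sites_within_500_merge(self):
        loci = im.merge_loci([self.make_site(100), self.make_site(550),
                              self.make_site(1200)])
        assert len(loci) == 2
        assert [len(l.sites) for l in loci] == [2, 1]

    def test_opposite_orientations_merge(self):
        loci = im.merge_loci([self.make_site(100, "+"),
                              self.make_site(110, "-")])
        assert len(loci) == 1

    def test_share_normalization(self):
        loci = im.merge_loci([self.make_site(100, support=6),
                              self.make_site(5000, support=3),
                              self.make_site(20_000, support=1)])
        assert [l.percent_of_total for l in loci] == [60.0, 30.0, 10.0]
        assert sum(l.percent_of_total for l in loci) == pytest.approx(100.0)

    def test_counting_conservation(self):
        sites = [self.make_site(p, support=s)
                 for p, s in [(10, 2), (400, 3), (5000, 4)]]
        loci = im.merge_loci(sites)
        assert sum(l.unique_reads for l in loci) == sum(s.support for s in sites)


class TestLocusMotif:
    def test_single_site_motif_is_one_hot_of_window(self):
        genome = {"chr1": fixtures.make_genome(1000, 0.5, 31)}
        site = im.IntegrationSite("chr1", 500, "+", support=3)
        locus = im.IntegrationLocus("chr1", 500, 502, [site], 3, None, 100.0)
        m = im.locus_motif([locus], genome, flank_bp=10)
        window = genome["chr1"][490:512]
        assert m.consensus() == window

    def test_minus_strand_window_reverse_complemented(self):
        genome = {"chr1": fixtures.make_genome(1000, 0.5, 32)}
        site = im.IntegrationSite("chr1", 500, "-", support=3)
        locus = im.IntegrationLocus("chr1", 500, 502, [site], 3, None, 100.0)
        m = im.locus_motif([locus], genome, flank_bp=10)
        assert m.consensus() == revcomp(genome["chr1"][490:512])

    def test_out_of_bounds_window_skipped_with_warning(self):
        genome = {"chr1": fixtures.make_genome(100, 0.5, 33)}
        near_edge = im.IntegrationSite("chr1", 2, "+", support=1)
        inner = im.IntegrationSite("chr1", 50, "+", support=1)
        loci = [im.IntegrationLocus("chr1", 2, 4, [near_edge], 1, None, 50.0),
                im.IntegrationLocus("chr1", 50, 52, [inner], 1, None, 50.0)]
        with pytest.warns(UserWarning):
            m = im.locus_motif(loci, genome, flank_bp=10)
        assert m.width == 22

    def test_planted_target_motif_recovered(self):
        """Sites drawn from a planted base-preference profile are recovered."""
        rng = np.random.default_rng(34)
        width = 20
        profile = np.full((width, 4), 0.1)
        pref = rng.integers(0, 4, size=width)
        profile[np.arange(width), pref] = 0.7
        chrom = []
        positions = []
        for i in range(50):
            chrom.append(fixtures.make_genome(200, 0.5, 600 + i))
            draw = "".join("ACGT"[rng.choice(4, p=profile[j])]
                           for j in range(width))
            chrom.append(draw)
            positions.append(sum(len(c) for c in chrom) - width + 9)
        genome = {"chr1": "".join(chrom) + "ACGT" * 30}
        loci = []
        for p in positions:
            s = im.IntegrationSite("chr1", p, "+", support=1)
            loci.append(im.IntegrationLocus("chr1", p, p + 2, [s], 1, None,
                                            2.0))
        m = im.locus_motif(loci, genome, flank_bp=9)
        assert m.width == width
        assert np.abs(m.frequencies - profile).max() < 0.25
        # Preferred base identified at a large majority of positions.
        agree = (m.frequencies.argmax(1) == pref).mean()
        assert agree > 0.8


class TestAccessibilityEnrichment:
    def test_all_sites_in_peaks_enriched(self):
        sites = [im.IntegrationSite("chr1", 1000 + 10_000 * i, "+", 1)
                 for i in range(10)]
        peaks = {"chr1": [(s.position - 5, s.position + 5)
                          for s in sites]}
        odds, p = im.accessibility_enrichment(sites, peaks, seed=1)
        assert odds == float("inf")
        assert p < 0.01

    def test_identical_rates_give_or_near_one(self):
        # Peaks covering everything: both columns fully in-peak.
        sites = [im.IntegrationSite("chr1", 200_000 + i * 1000, "+", 1)
                 for i in range(20)]
        peaks = {"chr1": [(0, 10_000_000)]}
        odds, p = im.accessibility_enrichment(sites, peaks, seed=2)
        assert p == pytest.approx(1.0)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        from scipy.stats import fisher_exact
        table = [[2, 0], [0, 2]]
        _, p = fisher_exact(table)
        # Enumerate x successes among draws: p = sum of P(tables) <= P(obs).
        probs = [hypergeom.pmf(x, 4, 2, 2) for x in range(3)]
        obs = hypergeom.pmf(2, 4, 2, 2)
        expected = sum(q for q in probs if q <= obs + 1e-12)
        assert p == pytest.approx(expected) == pytest.approx(1 / 3)

    def test_background_is_seeded(self):
        sites = [im.IntegrationSite("chr1", 50_000, "+", 1)]
        peaks = {"chr1": [(49_000, 51_000)]}
        r1 = im.accessibility_enrichment(sites, peaks, seed=7)
        r2 = im.accessibility_enrichment(sites, peaks, seed=7)
        assert r1 == r2


class TestEndToEnd:
    def test_pipeline_recovers_planted_sites(self, junction_run):
        sim, config = junction_run
        result = im.map_integration_sites(sim.sam_text, config)
        planted = {s.position for s in sim.sites}
        recovered = sum(
            any(abs(s.position - p) <= 1 for s in result.sites)
            for p in planted)
        assert recovered / len(planted) >= 0.95
        for site in result.sites:
            assert min(abs(site.position - p) for p in planted) <= 15
        assert sum(l.percent_of_total for l in result.loci) == \
            pytest.approx(100.0, abs=0.01)

    def test_counting_conservation_end_to_end(self, junction_run):
        sim, config = junction_run
        result = im.map_integration_sites(sim.sam_text, config)
        called = {(s.chrom, s.position) for s in result.sites}
        assigned = sum(l.unique_reads for l in result.loci)
        assert assigned == sum(s.support for s in result.sites)
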