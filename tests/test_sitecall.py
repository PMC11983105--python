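import numpy as np
import pytest

from conftest import empty_pileups, make_read, signal_read
from selictseq.io import PipelineConfig, ReferenceGenome, SiteExclusionList
from selictseq.sitecall import (
    SamplePileup,
    build_pileup,
    call_candidates,
    selict_score,
)


def find_a(genome, start=100):
    """First reference position >= start whose base is A."""
    seq = next(iter(genome.sequences.values()))
    return seq.index("A", start)


def find_t(genome, start=100):
    seq = next(iter(genome.sequences.values()))
    return seq.index("T", start)


class TestPileupDefinitions:
    def test_plus_strand_second_base_mutant(self, tiny_genome):
        pos = find_a(tiny_genome)
        pileup = build_pileup([signal_read(tiny_genome, pos, "+")], tiny_genome)
        col = pileup.column("chrT", pos)
        assert col.trunc_mut_count["+"] == 1
        assert col.trunc_total_count["+"] == 1
        assert col.base_counts["+"]["G"] == 1
        # the first base of the read is NOT a truncation-signal position
        first = pileup.column("chrT", pos - 1)
        assert first.trunc_total_count["+"] == 0

    def test_minus_strand_second_from_right(self, tiny_genome):
        pos = find_t(tiny_genome)
        read = signal_read(tiny_genome, pos, "-", length=50)
        pileup = build_pileup([read], tiny_genome)
        col = pileup.column("chrT", pos)
        assert col.trunc_mut_count["-"] == 1
        assert col.base_counts["-"]["C"] == 1
        # rightmost aligned base is pos+1; it is not the signal position
        assert pileup.column("chrT", pos + 1).trunc_mut_count["-"] == 0

    def test_low_mapq_read_contributes_nothing(self, tiny_genome):
        pos = find_a(tiny_genome)
        read = signal_read(tiny_genome, pos, "+", mapq=4)
        pileup = build_pileup([read], tiny_genome, min_mapq=5)
        col = pileup.column("chrT", pos)
        assert col.depth == {"+": 0, "-": 0}
        assert pileup.n_reads == 0

    def test_mapq_five_is_included(self, tiny_genome):
        pos = find_a(tiny_genome)
        pileup = build_pileup([signal_read(tiny_genome, pos, "+", mapq=5)],
                              tiny_genome, min_mapq=5)
        assert pileup.column("chrT", pos).trunc_mut_count["+"] == 1

    def test_soft_clips_do_not_contribute(self, tiny_genome):
        # 5S45M: the second *aligned* base is query offset 6
        start = 300
        seq = "NNNNN" + tiny_genome.sequences["chrT"][start : start + 45]
        read = make_read(tiny_genome, start, 45, "+")
        read = type(read)(
            name="sc", contig="chrT", start=start, strand="+", mapq=60,
            cigar=[("S", 5), ("M", 45)], seq=seq, sample="sgrna_pos_rep1",
        )
        pileup = build_pileup([read], tiny_genome)
        col = pileup.column("chrT", start)
        assert col.depth["+"] == 1
        assert col.base_counts["+"]["N"] == 0  # clipped N never counted
        assert pileup.column("chrT", start + 1).trunc_total_count["+"] == 1

    def test_column_invariants(self, small_sim):
        pileup = small_sim["pileups"]["sgrna_pos_rep1"]
        rng = np.random.default_rng(0)
        contig = next(iter(small_sim["genome"].sequences))
        for pos in rng.integers(0, 99_000, 50):
            col = pileup.column(contig, int(pos))
            for strand in "+-":
                assert col.trunc_mut_count[strand] <= col.trunc_total_count[strand]
                assert col.trunc_total_count[strand] <= col.depth[strand]
                assert sum(col.base_counts[strand].values()) == col.depth[strand]

    def test_unknown_contig_rejected(self, tiny_genome):
        read = make_read(tiny_genome, 0, 10)
        read.contig = "chrMissing"
        with pytest.raises(KeyError):
            build_pileup([read], tiny_genome)


class TestSelictScore:
    @pytest.mark.parametrize("trunc,depth,expected",
                             [(6, 10, 0.6), (0, 10, 0.0), (10, 10, 1.0)])
    def test_fraction_of_depth(self, trunc, depth, expected):
        assert selict_score(trunc, depth) == pytest.approx(expected)

    def test_zero_depth_undefined(self):
        with pytest.raises(ZeroDivisionError):
            selict_score(1, 0)


def _site_pileups(genome, config, pos, n_signal=(3, 3), n_background=(2, 2),
                  neg_mut=0, untreated_mut=0):
    """Build four-sample pileups with a controllable site at ``pos`` (+)."""
    pileups = empty_pileups(genome, config)
    for rep, (n_sig, n_bg) in zip(("sgrna_pos_rep1", "sgrna_pos_rep2"),
                                  zip(n_signal, n_background)):
        for i in range(n_sig):
            pileups[rep].add_read(
                signal_read(genome, pos, "+", sample=rep, name=f"s{i}"))
        for i in range(n_bg):
            pileups[rep].add_read(
                make_read(genome, pos - 10, 50, "+", sample=rep, name=f"b{i}"))
    for i in range(neg_mut):
        pileups["sgrna_neg"].add_read(
            make_read(genome, pos - 20, 50, "+", sample="sgrna_neg",
                      mutate={20: "G"}, name=f"n{i}"))
    for i in range(untreated_mut):
        pileups["untreated"].add_read(
            make_read(genome, pos - 20, 50, "+", sample="untreated",
                      mutate={20: "G"}, name=f"u{i}"))
    return pileups


@pytest.fixture()
def genome(tiny_genome):
    return tiny_genome


class TestFilterCascadeBoundaries:
    """Each rule flips pass->fail exactly at its published threshold."""

    def call_one(self, genome, config, pos, **kwargs):
        pileups = _site_pileups(genome, config, pos, **kwargs)
        sites = call_candidates(pileups, SiteExclusionList(), config)
        (site,) = [s for s in sites if s.position == pos]
        return site

    def test_depth_boundary_rule_ii(self, genome, config):
        pos = find_a(genome, 400)
        ok = self.call_one(genome, config, pos, n_signal=(3, 3),
                           n_background=(2, 2))  # depth 5 each rep
        assert ok.filters["ii"] and ok.passed
        low = self.call_one(genome, config, pos, n_signal=(3, 3),
                            n_background=(1, 1))  # depth 4
        assert not low.filters["ii"] and not low.passed

    def test_mut_count_boundary_rule_iii(self, genome, config):
        pos = find_a(genome, 400)
        ok = self.call_one(genome, config, pos, n_signal=(3, 3),
                           n_background=(7, 7))  # 3/10 = 30%
        assert ok.filters["iii"]
        low = self.call_one(genome, config, pos, n_signal=(2, 2),
                            n_background=(8, 8))  # 2 < 3 mutant reads
        assert not low.filters["iii"]

    def test_mut_proportion_boundary_rule_iii(self, genome, config):
        pos = find_a(genome, 400)
        ok = self.call_one(genome, config, pos, n_signal=(4, 4),
                           n_background=(16, 16))  # 4/20 = 20% exactly
        assert ok.filters["iii"]
        low = self.call_one(genome, config, pos, n_signal=(3, 3),
                            n_background=(17, 17))  # 3/20 = 15%
        assert not low.filters["iii"]

    def test_background_boundary_rule_iv(self, genome, config):
        pos = find_a(genome, 400)
        ok = self.call_one(genome, config, pos, untreated_mut=1)
        assert ok.filters["iv"]
        bad = self.call_one(genome, config, pos, untreated_mut=2)
        assert not bad.filters["iv"] and not bad.passed

    def test_replicate_presence_rule_v(self, genome, config):
        pos = find_a(genome, 400)
        one_rep = self.call_one(genome, config, pos, n_signal=(3, 0),
                                n_background=(2, 5))
        assert one_rep.filters["ii"] and one_rep.filters["iii"]  # in rep1
        assert not one_rep.filters["v"] and not one_rep.passed
        assert one_rep.replicate_presence == (True, False)

    def test_consecutive_artifact_rule_vi(self, genome, config):
        # pick an A whose neighbours are not A, so the three artifact
        # positions carry at least two distinct substitution types
        seq0 = genome.sequences["chrT"]
        pos = next(
            p for p in range(600, 1500)
            if seq0[p] == "A" and seq0[p - 1] != "A" and seq0[p + 1] != "A"
        )
        pileups = _site_pileups(genome, config, pos)
        # add reads mutating 3 consecutive positions (>20% rate, 2 types)
        seq = genome.sequences["chrT"]
        alt = {b: {"A": "G", "C": "T", "G": "A", "T": "C"}[b]
               for b in "ACGT"}
        for rep in ("sgrna_pos_rep1", "sgrna_pos_rep2"):
            for i in range(3):
                mutate = {
                    (pos - 1 - (pos - 30)) + k: alt[seq[pos - 1 + k]]
                    for k in range(3)
                }
                pileups[rep].add_read(
                    make_read(genome, pos - 30, 50, "+", sample=rep,
                              mutate=mutate, name=f"art{i}"))
        sites = call_candidates(pileups, SiteExclusionList(), config)
        (site,) = [s for s in sites if s.position == pos]
        assert not site.filters["vi"] and not site.passed

    def test_single_type_runs_not_excluded_rule_vi(self, genome, config):
        # the candidate's own A->G pile does not trip the artifact rule
        pos = find_a(genome, 400)
        site = self.call_one(genome, config, pos)
        assert site.filters["vi"]

    def test_exclusion_list_rule_vii(self, genome, config):
        pos = find_a(genome, 400)
        pileups = _site_pileups(genome, config, pos)
        excl = SiteExclusionList({("chrT", pos)})
        (site,) = [s for s in call_candidates(pileups, excl, config)
                   if s.position == pos]
        assert not site.filters["vii"] and not site.passed

    def test_passing_site_audit_recomputes(self, genome, config):
        site = self.call_one(genome, config, find_a(genome, 400),
                             n_signal=(3, 3), n_background=(2, 2))
        assert site.passed and all(site.filters.values())
        # recompute rules ii/iii from the stored counts
        for rep in ("sgrna_pos_rep1", "sgrna_pos_rep2"):
            stats = site.per_sample[rep]
            assert (stats["depth"] >= config.min_depth) == site.filters["ii"]
            assert (
                stats["trunc_mut_reads"] >= config.min_mut_reads
                and stats["trunc_mut_reads"] / stats["depth"] >= config.min_mut_prop
            ) == site.filters["iii"]
        assert site.selict_score == pytest.approx(6 / 10)
        assert site.edited_ratio == pytest.approx(6 / 10)


class TestStrandSymmetry:
    def test_mirrored_genome_flips_candidates(self, config):
        from selictseq._dna import revcomp

        rng = np.random.default_rng(21)
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, 1500))
        genome = ReferenceGenome({"chrT": seq})
        pos = seq.index("A", 400)
        pileups = _site_pileups(genome, config, pos)
        fwd = [s for s in call_candidates(pileups, SiteExclusionList(), config)
               if s.passed]

        mirror = ReferenceGenome({"chrT": revcomp(seq)})
        L = len(seq)
        mpileups = empty_pileups(mirror, config)
        for rep in ("sgrna_pos_rep1", "sgrna_pos_rep2"):
            for i in range(3):
                mpileups[rep].add_read(signal_read(mirror, L - 1 - pos, "-",
                                                   sample=rep, name=f"s{i}"))
            for i in range(2):
                read = make_read(genome, pos - 10, 50, "+", sample=rep)
                mirrored = type(read)(
                    name=f"b{i}", contig="chrT", start=L - (pos - 10) - 50,
                    strand="-", mapq=60, cigar=[("M", 50)],
                    seq=revcomp(read.seq), sample=rep,
                )
                mpileups[rep].add_read(mirrored)
        rev = [s for s in call_candidates(mpileups, SiteExclusionList(), config)
               if s.passed]
        assert [(s.position, s.strand) for s in fwd] == [(pos, "+")]
        assert [(s.position, s.strand) for s in rev] == [(L - 1 - pos, "-")]


class TestOnSimulatedData:
    def test_planted_sites_recovered(self, small_sim, config):
        from selictseq.simulate import exclusion_list_from_truth

        candidates = call_candidates(
            small_sim["pileups"],
            exclusion_list_from_truth(small_sim["planted"]),
            config,
        )
        passing = {(c.contig, c.position) for c in candidates if c.passed}
        planted_detectable = {
            (s.contig, s.position)
            for s in small_sim["planted"]
            if s.site_class in ("on_target", "cas9_dependent", "cas9_independent")
        }
        assert planted_detectable <= passing

    def test_missing_control_sample_rejected(self, small_sim, config):
        pileups = dict(small_sim["pileups"])
        del pileups["untreated"]
        with pytest.raises(ValueError):
            call_candidates(pileups, SiteExclusionList(), config)
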