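"""dsODN tag-integration site discovery pipeline."""

import itertools

import pytest

from _oracles import best_substring_distance_both_strands
from cutscan.simulate import (DEFAULT_DSODN, PlantedSite, gen_ttiss,
                              module_rng, random_genome)
from cutscan.ttiss import (GenomeIndex, GenomicWindow, GuideSpec, ReadPair,
                           TtissSite, align_pairs, apply_site_filters,
                           call_windows, filter_and_trim, mark_duplicates,
                           match_guide, predict_cut_site, run_ttiss,
                           summarize)

DSODN = DEFAULT_DSODN


def pair(seq1, seq2, pid="p1", q=None):
    return ReadPair(pid, seq1, q or "I" * len(seq1), seq2, "I" * len(seq2))


class TestFilterAndTrim:
    def test_primerless_read_rejected(self):
        pairs = [pair("A" * 60, "C" * 20)]
        kept, tally = filter_and_trim(pairs, DSODN)
        assert not kept and tally["no_primer"] == 1

    def test_truncation_to_25_and_15(self):
        genomic = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 40 bp
        kept, _ = filter_and_trim([pair(DSODN + genomic, "C" * 20)], DSODN)
        assert kept[0].fwd == genomic[:25]
        assert len(kept[0].rev) == 15

    def test_low_quality_rejected(self):
        genomic = "A" * 30
        bad_q = "I" * len(DSODN) + "#" * 30      # Q2 genomic portion
        pairs = [ReadPair("p", DSODN + genomic, bad_q, "C" * 20, "I" * 20)]
        _, tally = filter_and_trim(pairs, DSODN)
        assert tally["low_quality"] == 1

    def test_primerless_fraction_matches_generator_truth(self, guide):
        sim = gen_ttiss(guide, [PlantedSite(0, 100)], n_noise_singletons=0,
                        primerless_fraction=0.3, seed=3)
        _, tally = filter_and_trim(sim.pairs, DSODN)
        frac = tally["no_primer"] / (tally["no_primer"] + tally["kept"])
        assert frac == pytest.approx(0.3, abs=0.12)


class TestAlignPairs:
    def test_planted_pairs_map_to_planted_coordinates(self, guide):
        sim = gen_ttiss(guide, [PlantedSite(0, 10), PlantedSite(2, 10)],
                        n_noise_singletons=20, seed=4)
        trimmed, _ = filter_and_trim(sim.pairs, DSODN)
        alignments, tally = align_pairs(trimmed, GenomeIndex(sim.genome))
        assert tally["mapped"] == len(trimmed)
        cuts = {s.cut for s in sim.sites}
        mapped_at_cuts = [a for a in alignments if a.junction in cuts]
        assert len(mapped_at_cuts) == 20

    def test_fragment_length_cap(self):
        genome = random_genome(5000, 5)
        seq = genome["chr1"]
        index = GenomeIndex(genome)
        from cutscan.ttiss import TrimmedPair
        from cutscan.seqs import revcomp
        near = TrimmedPair("ok", seq[100:125], revcomp(seq[885:900]))
        far = TrimmedPair("far", seq[100:125], revcomp(seq[1385:1400]))
        alignments, tally = align_pairs([near, far], index)
        assert [a.pair_id for a in alignments] == ["ok"]
        assert tally["unmapped"] == 1

    def test_duplicate_marking_idempotent_and_order_invariant(self, guide):
        sim = gen_ttiss(guide, [PlantedSite(0, 6)], n_noise_singletons=0,
                        seed=6)
        trimmed, _ = filter_and_trim(sim.pairs + sim.pairs, DSODN)
        alignments, _ = align_pairs(trimmed, GenomeIndex(sim.genome))
        n_unique = sum(not a.is_duplicate for a in alignments)
        assert n_unique == 6                     # each pair duplicated once
        mark_duplicates(alignments)              # idempotent
        assert sum(not a.is_duplicate for a in alignments) == n_unique
        rng = module_rng(0, "ttiss")
        shuffled = list(alignments)
        rng.shuffle(shuffled)
        mark_duplicates(shuffled)
        assert sum(not a.is_duplicate for a in shuffled) == n_unique


class TestWindows:
    def test_singleton_yields_no_window(self, guide):
        sim = gen_ttiss(guide, [], n_noise_singletons=30, seed=7)
        trimmed, _ = filter_and_trim(sim.pairs, DSODN)
        alignments, _ = align_pairs(trimmed, GenomeIndex(sim.genome))
        assert call_windows(alignments) == []

    def test_two_reads_within_span_form_one_window(self, guide):
        sim = gen_ttiss(guide, [PlantedSite(0, 2)], n_noise_singletons=0,
                        seed=8)
        trimmed, _ = filter_and_trim(sim.pairs, DSODN)
        alignments, _ = align_pairs(trimmed, GenomeIndex(sim.genome))
        windows = call_windows(alignments)
        assert len(windows) == 1
        w = windows[0]
        assert w.end - w.start == 100 and w.unique_read_count == 2

    def test_planted_loci_recalled_no_singleton_windows(self, guide):
        plants = [PlantedSite(d, 4) for d in range(5)]
        sim = gen_ttiss(guide, plants, n_noise_singletons=100, seed=9)
        trimmed, _ = filter_and_trim(sim.pairs, DSODN)
        alignments, _ = align_pairs(trimmed, GenomeIndex(sim.genome))
        windows = call_windows(alignments)
        assert len(windows) == len(plants)
        cuts = sorted(s.cut for s in sim.sites)
        starts = sorted(w.start for w in windows)
        for cut, start in zip(cuts, starts):
            assert start <= cut < start + 100


class TestPredictCut:
    def test_modal_rule(self):
        w = GenomicWindow("chr1", 0, 100, 6,
                          [(40, "+")] * 5 + [(43, "-")])
        assert predict_cut_site(w) == 40

    def test_tie_prefers_both_strand_support(self):
        w = GenomicWindow("chr1", 0, 100, 4,
                          [(40, "+"), (40, "+"), (43, "+"), (43, "-")])
        assert predict_cut_site(w) == 43

    def test_staggered_junctions_recover_planted_cut(self):
        rng = module_rng(1, "ttiss")
        hits = 0
        for _ in range(200):
            cut = int(rng.integers(1000, 2000))
            juncs = [(cut + int(round(rng.normal(0, 1))), "+")
                     for _ in range(6)]
            w = GenomicWindow("chr1", cut - 50, cut + 50, 6, juncs)
            if abs(predict_cut_site(w) - cut) <= 3:
                hits += 1
        assert hits >= 190


class TestMatchGuide:
    def test_exact_spacer_found_at_distance_zero(self, guide, spacer):
        genome = random_genome(3000, 11)
        seq = genome["chr1"]
        genome = {"chr1": seq[:1500] + spacer + seq[1500 + 20:]}
        w = GenomicWindow("chr1", 1460, 1560, 2, [(1524, "+"), (1524, "-")])
        site = match_guide(w, genome, guide)
        assert site is not None
        assert site.edit_distance == 0
        assert site.proto_start == 1500

    def test_seven_mismatches_returns_none(self, guide, spacer):
        mutated = "TTGGA" + spacer[5:18] + "CC"   # 7 edits
        genome = random_genome(1000, 12)
        genome = {"chr1": genome["chr1"][:400] + mutated +
                  genome["chr1"][420:]}
        w = GenomicWindow("chr1", 380, 480, 2, [(424, "+")])
        site = match_guide(w, genome, guide)
        assert site is None or site.edit_distance > 6 or \
            site.proto_start != 400

    def test_best_distance_equals_substring_dp_oracle(self, guide, spacer):
        rng = module_rng(2, "ttiss")
        for trial in range(25):
            genome = random_genome(200, 100 + trial)
            seq = list(genome["chr1"])
            # embed a mutated spacer half the time
            if trial % 2 == 0:
                s = list(spacer)
                for p in rng.choice(len(s), size=trial % 7, replace=False):
                    s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
                seq[90:90 + len(s)] = s
            genome = {"chr1": "".join(seq)}
            w = GenomicWindow("chr1", 50, 150, 2, [(100, "+")])
            site = match_guide(w, genome, guide, max_ed=6)
            pad = len(spacer) + 6 + 4
            region = genome["chr1"][max(0, 50 - pad):150 + pad]
            oracle = best_substring_distance_both_strands(spacer, region)
            if oracle <= 6:
                assert site is not None and site.edit_distance == oracle
            else:
                assert site is None


class TestSiteFilters:
    def _site(self, cut_offset=0, pam="ATTC", window=None):
        w = window or GenomicWindow("chr1", 0, 100, 5, [(50, "+")])
        return TtissSite(w, 50, "A" * 20, 1, pam, "+", 26, 46,
                         50 + cut_offset, "g1")

    def test_cut_offset_filter(self):
        keep, _ = apply_site_filters(self._site(cut_offset=8))
        assert keep
        keep, reason = apply_site_filters(self._site(cut_offset=9))
        assert not keep and reason == "cut_offset"

    def test_pam_iupac_semantics(self):
        keep, _ = apply_site_filters(self._site(pam="ATTC"))
        assert keep                                 # NTTN satisfied
        keep, reason = apply_site_filters(self._site(pam="AGTC"))
        assert not keep and reason == "bad_pam"

    def test_negative_control_overlap(self):
        site = self._site()
        keep, reason = apply_site_filters(site, [("chr1", 99, 150)])
        assert not keep and reason == "negative_control"
        keep, _ = apply_site_filters(site, [("chr1", 100, 150)])
        assert keep                                 # no 1 bp overlap

    def test_filter_order_independence(self):
        # a site violating several filters is dropped under any ordering
        bad = self._site(cut_offset=9, pam="AGTC")
        checks = {
            "offset": abs(bad.match_cut - bad.predicted_cut) <= 8,
            "pam": apply_site_filters(self._site(pam="AGTC"))[0],
            "control": apply_site_filters(
                self._site(), [("chr1", 0, 100)])[0],
        }
        for order in itertools.permutations(checks.values()):
            assert not all(order)


class TestSummarize:
    def _site(self, reads, on):
        w = GenomicWindow("chr1", 0, 100, reads, [(50, "+")] * reads)
        return TtissSite(w, 50, "A" * 20, 0 if on else 3, "ATTC", "+",
                         26, 46, 50, "g1", is_on_target=on)

    def test_single_on_target(self):
        rep = summarize([self._site(10, True)], "g1")
        assert rep.on_target_read_fraction == 1.0
        assert rep.n_off_targets == 0

    def test_read_share(self):
        rep = summarize([self._site(90, True), self._site(10, False)], "g1")
        assert rep.on_target_read_fraction == pytest.approx(0.9)
        assert rep.n_off_targets == 1


class TestEndToEnd:
    def test_planted_sites_recovered_exactly(self, guide):
        plants = [PlantedSite(0, 40)] + \
            [PlantedSite(d, 8) for d in (1, 2, 3, 4, 5)] + \
            [PlantedSite(1, 6, is_negative_control=True),
             PlantedSite(2, 5, is_negative_control=True)]
        sim = gen_ttiss(guide, plants, n_noise_singletons=200, seed=5)
        report = run_ttiss(
            sim.pairs, sim.genome, guide, DSODN,
            negative_control_windows=sim.negative_control_windows)
        real = {s.proto_start for s in sim.sites
                if not s.is_negative_control}
        found = {s.proto_start for s in report.sites}
        assert found == real                    # precision = recall = 1
        assert report.on_target_read_fraction == pytest.approx(
            sim.truth.planted["on_target_read_share"], abs=0.02)
        assert report.metadata["dropped_windows"].get(
            "negative_control") == 2
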