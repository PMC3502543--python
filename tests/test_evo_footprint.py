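import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosspeak.errors import ValidationError
from crosspeak.evo_footprint import (
    IUPAC,
    MotifPattern,
    archaic_fraction,
    compare_groups,
    count_hsas,
    hsa_rates,
    motif_events,
    scan_motif,
)
from crosspeak.genomic_io import AlignmentBlock

PRIMATES = ["chimpanzee", "gorilla", "orangutan", "macaque"]


def block_of(human, comparison, archaic=None, peak_id="pk1"):
    seqs = {"human": human}
    for t in PRIMATES:
        seqs[t] = comparison
    for taxon, seq in (archaic or {}).items():
        seqs[taxon] = seq
    return AlignmentBlock(peak_id, seqs)


class TestCountHsas:
    def test_single_substitution_column(self):
        (h,) = count_hsas(block_of("ACGTT", "ACGAT"), PRIMATES)
        assert (h.kind, h.column, h.human_allele, h.outgroup_allele) == \
            ("substitution", 3, "T", "A")

    def test_identical_rows_give_nothing(self):
        assert count_hsas(block_of("ACGTT", "ACGTT"), PRIMATES) == []

    def test_human_gap_run_is_one_deletion_event(self):
        (h,) = count_hsas(block_of("AC--T", "ACGGT"), PRIMATES)
        assert (h.kind, h.column, h.length) == ("deletion", 2, 2)

    def test_unanimous_comparison_gap_is_insertion(self):
        (h,) = count_hsas(block_of("ACGGT", "AC--T"), PRIMATES)
        assert (h.kind, h.length) == ("insertion", 2)

    def test_long_indel_label_at_hundred_bp(self):
        human = "A" * 10 + "C" * 100 + "G" * 10
        comp = "A" * 10 + "-" * 100 + "G" * 10
        (h,) = count_hsas(block_of(human, comp), PRIMATES)
        assert h.kind == "long_indel" and h.length == 100

    def test_disagreeing_comparison_column_skipped(self):
        seqs = {"human": "ACGTT", "chimpanzee": "ACGAT", "gorilla": "ACGCT",
                "orangutan": "ACGAT", "macaque": "ACGAT"}
        assert count_hsas(AlignmentBlock("pk1", seqs),
                          ["chimpanzee", "gorilla", "orangutan", "macaque"]) == []

    def test_n_columns_skipped(self):
        assert count_hsas(block_of("ACGNT", "ACGAT"), PRIMATES) == []
        assert count_hsas(block_of("ACGTT", "ACGNT"), PRIMATES) == []

    def test_order_invariance_and_archaic_neutrality(self, rng):
        alphabet = np.frombuffer(b"ACGT-", np.uint8)
        cols = rng.integers(0, 5, size=(6, 80))
        rows = ["".join("ACGT-"[i] for i in cols[k]) for k in range(6)]
        seqs = {"human": rows[0], "chimpanzee": rows[1], "gorilla": rows[2],
                "orangutan": rows[3], "macaque": rows[4]}
        base = count_hsas(AlignmentBlock("pk", seqs), PRIMATES)
        shuffled = count_hsas(AlignmentBlock("pk", seqs), PRIMATES[::-1])
        assert [(r.column, r.kind) for r in base] == \
            [(r.column, r.kind) for r in shuffled]
        seqs2 = dict(seqs, neanderthal=rows[5].replace("-", "A"))
        with_arch = count_hsas(AlignmentBlock("pk", seqs2), PRIMATES,
                               ["neanderthal"])
        assert [(r.column, r.kind) for r in base] == \
            [(r.column, r.kind) for r in with_arch]


class TestArchaicFraction:
    def test_ancestral_vs_derived_alleles(self):
        block = block_of("ACGTT", "ACGAT",
                         archaic={"neanderthal": "ACGAT", "denisova": "ACGTT"})
        hsas = count_hsas(block, PRIMATES, ["neanderthal", "denisova"])
        assert archaic_fraction(hsas, "neanderthal") == 1.0
        assert archaic_fraction(hsas, "denisova") == 0.0

    def test_all_missing_is_an_error(self):
        block = block_of("ACGTT", "ACGAT", archaic={"neanderthal": "ACGNT"})
        hsas = count_hsas(block, PRIMATES, ["neanderthal"])
        with pytest.raises(ValidationError):
            archaic_fraction(hsas, "neanderthal")

    def test_matches_counting_oracle_on_random_states(self, rng):
        blocks = []
        expected_anc = expected_inf = 0
        for i in range(50):
            state = rng.choice(["anc", "der", "mis"])
            arch = {"anc": "ACGAT", "der": "ACGTT", "mis": "ACGNT"}[state]
            blocks.append(block_of("ACGTT", "ACGAT",
                                   archaic={"neanderthal": arch},
                                   peak_id=f"pk{i}"))
            expected_anc += state == "anc"
            expected_inf += state != "mis"
        hsas = [h for b in blocks for h in count_hsas(b, PRIMATES, ["neanderthal"])]
        assert archaic_fraction(hsas, "neanderthal") == \
            pytest.approx(expected_anc / expected_inf)


class TestRatesAndGroups:
    def test_three_events_per_1500bp_is_two_per_kb(self):
        human = "A" * 1500
        comp = list(human)
        for pos in (10, 500, 1200):
            comp[pos] = "G"
        block = block_of(human, "".join(comp))
        rates = hsa_rates([block], PRIMATES)
        assert rates["pk1"] == pytest.approx(2.0)

    def test_no_events_is_zero_rate(self):
        rates = hsa_rates([block_of("ACGT" * 300, "ACGT" * 300)], PRIMATES)
        assert rates["pk1"] == 0.0

    def test_identical_groups_are_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        comp = compare_groups(g, g, n_sims=400, seed=0)
        assert comp.wilcoxon_p > 0.9
        assert comp.permutation_p > 0.5

    def test_exact_wilcoxon_three_vs_three(self):
        comp = compare_groups([1, 2, 3], [4, 5, 6], n_sims=100, seed=0)
        assert comp.wilcoxon_p == pytest.approx(0.1)


class TestScanMotif:
    W = MotifPattern("GATA-1", "WGATTAG")

    def test_worked_example(self):
        assert scan_motif("CCTGATTAGCC", self.W) == [(2, "+")]

    def test_no_match(self):
        assert scan_motif("AAAA", self.W) == []

    def test_nnn_matches_everywhere_on_both_strands(self):
        hits = scan_motif("ACGT", MotifPattern("nnn", "NNN"))
        assert hits == [(0, "+"), (0, "-"), (1, "+"), (1, "-")]

    def test_reverse_strand_reported_at_forward_start(self):
        # revcomp of WGATTAG is CTAATCW
        assert scan_motif("GGCTAATCAGG", self.W) == [(2, "-")]

    def test_sequence_n_only_matches_pattern_n(self):
        assert scan_motif("TGNTTAG", self.W) == []

    def test_illegal_pattern_rejected(self):
        with pytest.raises(ValidationError):
            MotifPattern("bad", "WGAZTAG")

    @given(st.integers(0, 2**31 - 1), st.sampled_from(["WGATTAG", "RYSW", "TGA"]))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_sliding_window_oracle(self, seed, pat):
        r = np.random.default_rng(seed)
        seq = "".join(r.choice(list("ACGTN"), 300))
        pattern = MotifPattern("m", pat)

        def brute(s, p):
            hits = []
            for strand, pp in (("+", p.pattern), ("-", p.reverse_complement)):
                for i in range(len(s) - len(pp) + 1):
                    if all(s[i + k] in IUPAC[c] for k, c in enumerate(pp)):
                        hits.append((i, strand))
            return sorted(hits)

        assert scan_motif(seq, pattern) == brute(seq, pattern)


class TestMotifEvents:
    W = MotifPattern("GATA-1", "WGATTAG")

    def test_human_only_match_is_gained(self):
        ev = motif_events(block_of("CCTGATTAGCC", "CCTGATCAGCC"), self.W, PRIMATES)
        assert [(e.kind, e.column, e.strand) for e in ev] == [("gained", 2, "+")]

    def test_shared_match_is_no_event(self):
        assert motif_events(block_of("CCTGATTAGCC", "CCTGATTAGCC"),
                            self.W, PRIMATES) == []

    def test_comparison_only_match_is_lost(self):
        ev = motif_events(block_of("CCTGATCAGCC", "CCTGATTAGCC"), self.W, PRIMATES)
        assert [(e.kind, e.column) for e in ev] == [("lost", 2)]

    def test_gap_in_human_still_resolves_orthology(self):
        # human missing 2 bases inside the motif window -> no human match, lost
        ev = motif_events(block_of("CCTGA--AGCC", "CCTGATTAGCC"), self.W, PRIMATES)
        assert [e.kind for e in ev] == ["lost"]
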