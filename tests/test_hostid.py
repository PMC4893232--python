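"""In-silico primer search, amplicon extraction and host assignment.

The primer-search oracle is a deliberately naive per-offset IUPAC scan,
independent of the vectorized implementation.
"""

import numpy as np
import pytest

from bloodmeal.hostid import (
    KITANO_PAIR,
    KOCHER_PAIR,
    PrimerPair,
    ReferencePanel,
    assign_host,
    extract_amplicon,
    find_primer_site,
    reverse_complement,
    two_tier_identify,
)
from bloodmeal.synth import generate_amplicons, synthetic_reference_panel

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def oracle_scan(template, primer, max_mm):
    """All-offsets IUPAC Hamming scan, plus and minus strand."""
    hits = []
    for strand, p in (("+", primer), ("-", reverse_complement(primer))):
        for start in range(len(template) - len(p) + 1):
            window = template[start : start + len(p)]
            mm = sum(
                1
                for t, q in zip(window, p)
                if not (IUPAC_SETS[q] & IUPAC_SETS.get(t, {t}))
            )
            if mm <= max_mm:
                hits.append((start, strand, mm))
    return sorted(hits)


class TestFindPrimerSite:
    def test_verbatim_site_found_exactly(self):
        tpl = "A" * 40 + KITANO_PAIR.forward_sequence + "G" * 40
        assert find_primer_site(tpl, KITANO_PAIR.forward_sequence, 0) == [(40, "+", 0)]

    def test_reverse_complement_template_hits_minus_strand(self):
        tpl = "A" * 40 + KITANO_PAIR.forward_sequence + "G" * 40
        hits = find_primer_site(reverse_complement(tpl), KITANO_PAIR.forward_sequence, 0)
        assert hits == [(40, "-", 0)]

    def test_primer_longer_than_template_yields_empty(self):
        assert find_primer_site("ACGT", KITANO_PAIR.forward_sequence, 2) == []

    def test_degenerate_codes_match_their_sets(self):
        # R matches A/G, N everything; revcomp("RN") = "NY" and Y misses A,
        # so only plus-strand hits exist here
        assert find_primer_site("AAAA", "RN", 0) == [(i, "+", 0) for i in range(3)]
        # R never matches T on the plus strand but revcomp("RR") = "YY" does
        assert find_primer_site("TTTT", "RR", 0) == [(i, "-", 0) for i in range(3)]

    def test_agrees_with_naive_oracle_on_random_templates(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        primer = KITANO_PAIR.forward_sequence
        for _ in range(60):
            tpl = "".join(rng.choice(bases, size=rng.integers(30, 300)))
            for mm in (0, 2, 4):
                assert find_primer_site(tpl, primer, mm) == oracle_scan(tpl, primer, mm)

    def test_no_22mer_in_random_template_within_two_mismatches(self):
        rng = np.random.default_rng(4)
        tpl = "".join(rng.choice(np.array(list("ACGT")), size=400))
        assert find_primer_site(tpl, KITANO_PAIR.forward_sequence, 2) == []


class TestExtractAmplicon:
    def _construct(self, pair, insert_len):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        insert = "".join(rng.choice(bases, size=insert_len))
        return (
            "".join(rng.choice(bases, size=25))
            + pair.forward_sequence
            + insert
            + reverse_complement(pair.reverse_sequence)
            + "".join(rng.choice(bases, size=25))
        )

    def test_product_length_244(self):
        tpl = self._construct(KITANO_PAIR, 200)
        amp = extract_amplicon(tpl, KITANO_PAIR)
        assert amp is not None and len(amp) == 244

    def test_fallback_pair_product_length_358(self):
        tpl = self._construct(KOCHER_PAIR, 358 - len(KOCHER_PAIR.forward_sequence)
                              - len(KOCHER_PAIR.reverse_sequence))
        amp = extract_amplicon(tpl, KOCHER_PAIR)
        assert amp is not None and len(amp) == 358

    def test_missing_reverse_site_returns_none(self):
        tpl = "A" * 20 + KITANO_PAIR.forward_sequence + "G" * 300
        assert extract_amplicon(tpl, KITANO_PAIR) is None

    def test_reverse_complement_invariance(self):
        tpl = self._construct(KITANO_PAIR, 200)
        amp = extract_amplicon(tpl, KITANO_PAIR)
        flipped_pair = PrimerPair(
            name="flipped",
            forward_sequence=KITANO_PAIR.reverse_sequence,
            reverse_sequence=KITANO_PAIR.forward_sequence,
            expected_length=KITANO_PAIR.expected_length,
        )
        amp_rc = extract_amplicon(reverse_complement(tpl), flipped_pair)
        assert amp_rc == reverse_complement(amp)

    def test_shortest_product_chosen(self):
        inner = self._construct(KITANO_PAIR, 100)
        tpl = KITANO_PAIR.forward_sequence + "A" * 600 + inner
        amp = extract_amplicon(tpl, KITANO_PAIR)
        assert len(amp) == 144


@pytest.fixture(scope="module")
def panel():
    refs = synthetic_reference_panel()
    return ReferencePanel(
        tuple((n, extract_amplicon(s, KITANO_PAIR)) for n, s in refs.entries)
    )


@pytest.fixture(scope="module")
def tiers():
    refs = synthetic_reference_panel()
    tier1 = ReferencePanel(
        tuple((n, extract_amplicon(s, KITANO_PAIR)) for n, s in refs.entries)
    )
    tier2 = ReferencePanel(
        tuple((n, extract_amplicon(s, KOCHER_PAIR)) for n, s in refs.entries)
    )
    return [("tier1", tier1), ("tier2", tier2)]


class TestAssignHost:
    def test_exact_panel_member_assigned_at_identity_one(self, panel):
        name, seq = panel.entries[0]
        call = assign_host(seq, panel)
        assert call.status == "assigned" and call.best_taxon == name
        assert call.identity == 1.0

    def test_equidistant_query_is_ambiguous(self):
        panel = ReferencePanel((("t1", "AAAAAAAAAA"), ("t2", "AAAAAAAAAC")))
        # one mismatch to each reference
        call = assign_host("AAAAAAAAAG", panel, min_identity=0.8, min_margin=0.02)
        assert call.status == "ambiguous"

    def test_five_substitutions_identity_by_hamming(self, panel):
        name, seq = panel.entries[3]
        mutated = list(seq)
        for pos in (5, 50, 100, 150, 200):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        call = assign_host("".join(mutated), panel, min_identity=0.95)
        assert call.status == "assigned" and call.best_taxon == name
        assert call.identity == pytest.approx(239 / 244)

    def test_empty_query_rejected(self, panel):
        with pytest.raises(ValueError):
            assign_host("", panel)

    def test_recovery_rate_on_mutated_queries(self, panel):
        queries = generate_amplicons(panel, 10, 0.02, seed=21)
        correct = 0
        for qid, seq, truth in queries:
            call = assign_host(seq, panel)
            correct += call.status == "assigned" and call.best_taxon == truth
        assert correct / len(queries) >= 0.99


class TestTwoTier:
    def test_tier1_assignment_never_reaches_tier2(self, tiers):
        name, seq = tiers[0][1].entries[0]
        calls = two_tier_identify([("q0", seq)], tiers)
        assert calls[0].tier == "tier1" and calls[0].status == "assigned"

    def test_tier2_rescues_tier1_failures(self, tiers):
        name, seq2 = tiers[1][1].entries[2]
        calls = two_tier_identify([("q0", seq2)], tiers)
        assert calls[0].tier == "tier2" and calls[0].best_taxon == name

    def test_garbage_query_unassigned_at_both_tiers(self, tiers):
        calls = two_tier_identify([("q0", "ACGT" * 60)], tiers)
        assert calls[0].status == "unassigned"

    def test_order_and_count_preserved(self, tiers):
        queries = [(f"q{i}", tiers[0][1].entries[i % 3][1]) for i in range(7)]
        calls = two_tier_identify(queries, tiers)
        assert [c.query_id for c in calls] == [q for q, _ in queries]
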