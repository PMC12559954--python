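"""Signature mining: consensus, mismatch budgets, search vs brute force."""

import random

import pytest

from conftest import (
    make_alignment,
    oracle_mismatch_count,
    oracle_union,
    random_toy_alignment,
)

from sigtax.signatures import (
    SignatureSearchParams,
    allowed_mismatches,
    find_disjunctive_signature,
    find_signatures,
    mismatch_count,
    motif_ambiguity,
    verify_signature,
    window_consensus,
)


def brute_force_signatures(aln, target, params):
    """Independent enumeration of every qualifying window, using the
    set-based oracle for unions and mismatch counts."""
    seqs = {r.id: r.aligned for r in aln.records}
    member_ids = [r.id for r in aln.records
                  if target in r.lineage.values() and "reference" not in r.roles]
    other_ids = [r.id for r in aln.records
                 if target not in r.lineage.values() and "reference" not in r.roles]
    results = []
    for r_idx, region in enumerate(params.region_priority):
        if region not in aln.region_map.names:
            continue
        lo, hi = aln.region_map.interval(region)
        for length in range(params.min_len, params.max_len + 1):
            for c0 in range(lo, hi - length + 1):
                cols = slice(c0, c0 + length)
                windows = [seqs[i][cols] for i in member_ids]
                if any("-" in w for w in windows):
                    continue
                motif = "".join(
                    oracle_union("".join(w[k] for w in windows))
                    for k in range(length)
                )
                amb = sum(m not in "acgt" for m in motif)
                if amb > params.max_ambiguous:
                    continue
                d_min = min(
                    oracle_mismatch_count(motif, seqs[j][cols]) for j in other_ids
                )
                if d_min < 1:
                    continue
                results.append(
                    ((-d_min, amb, r_idx, c0, length),
                     (motif, (c0, c0 + length), max(d_min - 1, 0)))
                )
    results.sort(key=lambda t: t[0])
    return [r for _, r in results[: params.top_k]]


class TestConsensusAndMismatch:
    def test_consensus_identical_members(self):
        aln = make_alignment({"A_r1": "acgtt", "A_r2": "acgtt", "B_r1": "ttttt"})
        assert window_consensus(aln, "A", (0, 3)) == "acg"

    def test_consensus_union_at_variable_column(self):
        aln = make_alignment({"A_r1": "aagtt", "A_r2": "atgtt", "B_r1": "ttttt"})
        assert window_consensus(aln, "A", (0, 3)) == "awg"

    def test_consensus_undefined_on_member_gap(self):
        aln = make_alignment({"A_r1": "a-gtt", "A_r2": "atgtt", "B_r1": "ttttt"})
        assert window_consensus(aln, "A", (0, 3)) is None

    @pytest.mark.parametrize(
        "motif,window,expected",
        [
            ("tatcattaag", "tatcattaag", 0),
            ("tatcattaag", "tatcattaac", 1),
            ("aw", "tt", 1),       # w~t compatible; a vs t mismatch
            ("acg", "a-g", 1),     # gap in sequence is a mismatch
        ],
    )
    def test_mismatch_examples(self, motif, window, expected):
        assert mismatch_count(motif, window, (0, len(window))) == expected

    def test_mismatch_window_shape_checked(self):
        with pytest.raises(Exception, match="window shape"):
            mismatch_count("acg", "acgt", (0, 4))

    def test_motif_ambiguity_counts_degenerate_symbols(self):
        assert motif_ambiguity("acgt") == 0
        assert motif_ambiguity("acrtn") == 2


class TestAllowedMismatches:
    def test_budget_is_nearest_nontarget_minus_one(self):
        # B is 1 mismatch from A's motif -> m=0; make C 3 away -> unchanged
        aln = make_alignment({"A_r1": "aaaaaaaaaa", "B_r1": "aaaaaaaaac",
                              "C_r1": "aaaaaaattt"})
        m, rep = allowed_mismatches("aaaaaaaaaa", aln, "A", (0, 10))
        assert m == 0
        assert rep.min_nontarget_mismatches == 1
        aln2 = make_alignment({"A_r1": "aaaaaaaaaa", "C_r1": "aaaaaaattt"})
        m2, _ = allowed_mismatches("aaaaaaaaaa", aln2, "A", (0, 10))
        assert m2 == 2

    def test_budget_matches_exhaustive_scan(self):
        for seed in range(10):
            rng = random.Random(seed)
            aln = random_toy_alignment(rng, n_species=4, reads_per_species=2, width=40)
            motif = window_consensus(aln, "Species 0", (5, 17))
            if motif is None:
                continue
            m, rep = allowed_mismatches(motif, aln, "Species 0", (5, 17))
            seqs = {r.id: r.aligned for r in aln.records}
            d_min = min(
                oracle_mismatch_count(motif, seqs[r.id][5:17])
                for r in aln.records if r.taxon("species") != "Species 0"
            )
            assert rep.min_nontarget_mismatches == d_min
            assert m == max(d_min - 1, 0)


class TestFindSignatures:
    PARAMS = SignatureSearchParams(min_len=8, max_len=10, top_k=10_000)

    def test_identical_nontarget_yields_empty(self):
        aln = make_alignment({"A_r1": "acgtacgtacgt", "B_r1": "acgtacgtacgt"})
        assert find_signatures(aln, "A", self.PARAMS) == []

    def test_single_discriminating_column_toy(self):
        """Target differs from both others at exactly one shared column:
        every qualifying window covers it with m = 0."""
        base = "acgtacgtacgtacgtacgt"
        tgt = base[:10] + "c" + base[11:]  # column 10 differs
        aln = make_alignment({"A_r1": tgt, "B_r1": base, "C_r1": base})
        sigs = find_signatures(aln, "A", self.PARAMS)
        assert sigs
        for s in sigs:
            lo, hi = s.columns[0]
            assert lo <= 10 < hi
            assert s.allowed_mismatches == 0
        # by-hand oracle agrees on the full qualifying set
        oracle = brute_force_signatures(aln, "A", self.PARAMS)
        assert [(s.alternatives[0], s.columns[0], s.allowed_mismatches) for s in sigs] == oracle

    def test_matches_brute_force_on_random_alignments(self):
        for seed in range(25):
            rng = random.Random(1000 + seed)
            aln = random_toy_alignment(
                rng, n_species=rng.randint(2, 4), reads_per_species=2,
                width=rng.randint(30, 80),
            )
            params = SignatureSearchParams(min_len=8, max_len=12, top_k=10_000)
            got = find_signatures(aln, "Species 0", params)
            want = brute_force_signatures(aln, "Species 0", params)
            assert [
                (s.alternatives[0], s.columns[0], s.allowed_mismatches) for s in got
            ] == want

    def test_every_returned_signature_verifies(self):
        for seed in range(15):
            rng = random.Random(seed)
            aln = random_toy_alignment(rng, n_species=3, reads_per_species=3)
            for sig in find_signatures(aln, "Species 1", self.PARAMS):
                rep = verify_signature(aln, sig)
                assert rep.is_valid(sig.allowed_mismatches)
                assert rep.min_nontarget_mismatches == sig.allowed_mismatches + sig.margin
                assert sig.margin >= 1

    def test_deterministic_ranking(self):
        rng = random.Random(5)
        aln = random_toy_alignment(rng)
        a = find_signatures(aln, "Species 0", self.PARAMS)
        b = find_signatures(aln, "Species 0", self.PARAMS)
        assert a == b

    def test_adding_nontarget_only_lowers_or_preserves_m(self):
        rng = random.Random(11)
        aln = random_toy_alignment(rng, n_species=3, reads_per_species=2, width=50)
        before = {
            s.columns[0]: s.allowed_mismatches
            for s in find_signatures(aln, "Species 0", self.PARAMS)
        }
        seqs = {r.id: r.aligned for r in aln.records}
        species = {r.id: r.taxon("species") for r in aln.records}
        seqs["spZ_r1"] = "".join(rng.choice("acgt") for _ in range(50))
        species["spZ_r1"] = "Species Z"
        bigger = make_alignment(seqs, species)
        after = {
            s.columns[0]: s.allowed_mismatches
            for s in find_signatures(bigger, "Species 0", self.PARAMS)
        }
        for cols, m_after in after.items():
            if cols in before:
                assert m_after <= before[cols]
        assert set(after) <= set(before)  # windows can only drop out


class TestDisjunctive:
    def test_two_subclade_target(self):
        """Two internally uniform subclades, each separable: a 2-alternative
        signature whose budget is the exhaustive-scan value."""
        aln = make_alignment(
            {
                "A_r1": "aaaaaaaaaa", "A_r2": "aaaaaaaaaa",
                "A_r3": "tttttttttt", "A_r4": "tttttttttt",
                "B_r1": "ggggggcccc",
            },
            species={"A_r1": "T", "A_r2": "T", "A_r3": "T", "A_r4": "T", "B_r1": "O"},
        )
        params = SignatureSearchParams(min_len=10, max_len=10, max_alternatives=2)
        assert find_signatures(aln, "T", params) == []  # consensus too ambiguous
        sig = find_disjunctive_signature(aln, "T", params)
        assert sig is not None
        assert set(sig.alternatives) == {"aaaaaaaaaa", "tttttttttt"}
        # B is 10 mismatches from each alternative -> m = 9
        assert sig.allowed_mismatches == 9
        assert verify_signature(aln, sig).is_valid(sig.allowed_mismatches)

    def test_single_subclade_reduces_to_plain_search(self):
        aln = make_alignment({"A_r1": "aaaaaaaaaa", "A_r2": "aaaaaaaaaa",
                              "B_r1": "ttttaaaaaa"})
        params = SignatureSearchParams(min_len=10, max_len=10)
        plain = find_signatures(aln, "A", params)
        disj = find_disjunctive_signature(aln, "A", params)
        assert disj is not None and len(disj.alternatives) == 1
        assert disj.alternatives == plain[0].alternatives
        assert disj.allowed_mismatches == plain[0].allowed_mismatches

    def test_infeasible_when_nontarget_matches_an_alternative(self):
        aln = make_alignment(
            {
                "A_r1": "aaaaaaaaaa", "A_r2": "tttttttttt",
                "B_r1": "aaaaaaaaaa",  # identical to one subclade
            },
            species={"A_r1": "T", "A_r2": "T", "B_r1": "O"},
        )
        params = SignatureSearchParams(min_len=10, max_len=10, max_alternatives=2)
        assert find_disjunctive_signature(aln, "T", params) is None
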