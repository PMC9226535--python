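import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polxscan.alignment import Msa, build_anchor, ungapped_length
from polxscan.features import (
    DomainWindows,
    SiteSpec,
    TriadSpec,
    call_triads,
    classify_triad,
    measure_domains,
    profile_motifs,
    summarize_conservation,
    triad_variant_census,
)


def triad_msa(triads, ref_triad="DDD"):
    """Tiny alignment whose columns 1/3/5 are the triad positions 2/4/6
    (reference numbering from 1, ungapped reference)."""
    pairs = [("ref", f"A{ref_triad[0]}C{ref_triad[1]}E{ref_triad[2]}G")]
    for i, t in enumerate(triads):
        pairs.append((f"s{i}", f"A{t[0]}C{t[1]}E{t[2]}G"))
    return Msa.from_pairs(pairs)


SPEC = TriadSpec("ref", (2, 4, 6))


class TestCallTriads:
    @pytest.mark.parametrize(
        "triad,expected",
        [
            ("AEE", "altered"),
            ("ARE", "altered"),
            ("DDD", "canonical"),
            ("EEE", "canonical"),
            ("DED", "canonical"),
            ("DE-", "indeterminate"),
            ("XDD", "indeterminate"),
            ("A-E", "indeterminate"),
            ("KRT", "altered"),
        ],
    )
    def test_classification(self, triad, expected):
        msa = triad_msa([triad])
        calls = call_triads(msa, build_anchor(msa, "ref"), SPEC)
        assert calls[1].triad == triad
        assert calls[1].triad_class == expected

    def test_one_call_per_sequence_in_order(self):
        msa = triad_msa(["DDD", "AEE", "DE-"])
        calls = call_triads(msa, build_anchor(msa, "ref"), SPEC)
        assert [c.seq_id for c in calls] == ["ref", "s0", "s1", "s2"]

    def test_unmappable_residue_raises(self):
        msa = triad_msa(["DDD"])
        from polxscan.errors import AnchorRangeError

        with pytest.raises(AnchorRangeError):
            call_triads(msa, build_anchor(msa, "ref"), TriadSpec("ref", (2, 4, 99)))

    def test_triad_read_through_gapped_reference_columns(self):
        # insertion column between reference residues must not shift the call
        msa = Msa.from_pairs([("ref", "AD-CDED"), ("s", "AA-CRED")])
        anchor = build_anchor(msa, "ref")
        # ref residues 2/4/6 sit at columns 1/4/6 (column 2 is an insertion)
        calls = call_triads(msa, anchor, TriadSpec("ref", (2, 4, 6)))
        assert calls[1].triad == "ARD"
        assert calls[1].triad_class == "altered"


class TestTriadVariantCensus:
    def test_counts_and_order(self):
        msa = triad_msa(["AEE", "AEE", "ARE"])
        calls = call_triads(msa, build_anchor(msa, "ref"), SPEC)
        assert triad_variant_census(calls) == [("AEE", 2), ("ARE", 1)]

    def test_zero_altered(self):
        msa = triad_msa(["DDD", "DE-"])
        calls = call_triads(msa, build_anchor(msa, "ref"), SPEC)
        assert triad_variant_census(calls) == []

    def test_tie_broken_lexicographically(self):
        msa = triad_msa(["KEE", "AEE"])
        calls = call_triads(msa, build_anchor(msa, "ref"), SPEC)
        assert triad_variant_census(calls) == [("AEE", 1), ("KEE", 1)]

    def test_sum_equals_altered_count(self):
        msa = triad_msa(["AEE", "ARE", "DDD", "KKT", "DE-", "AEE"])
        calls = call_triads(msa, build_anchor(msa, "ref"), SPEC)
        census = triad_variant_census(calls)
        n_altered = sum(1 for c in calls if c.triad_class == "altered")
        assert sum(n for _, n in census) == n_altered


class TestMeasureDomains:
    def test_no_gap_palm_equals_window_size(self):
        ref = "ACDEFGHIKL" * 12  # 120 residues, ungapped
        msa = Msa.from_pairs([("ref", ref), ("s", ref)])
        anchor = build_anchor(msa, "ref")
        windows = DomainWindows(palm=(3, 104), fingers=(100, 110))
        m = measure_domains(msa, anchor, windows)[1]
        assert m.palm_length == 102
        assert m.fingers_length == 11

    def test_planted_deletion_and_strict_threshold(self):
        ref = "A" * 120
        subject = "A" * 10 + "-" * 20 + "A" * 90  # 20-residue deletion inside palm
        msa = Msa.from_pairs([("ref", ref), ("s", subject)])
        anchor = build_anchor(msa, "ref")
        windows = DomainWindows(palm=(5, 85), fingers=(86, 120), fingers_truncation_threshold=30)
        m = measure_domains(msa, anchor, windows)[1]
        assert m.palm_length == 61
        assert m.palm_truncated  # 61 < 77
        assert not m.fingers_truncated  # 35 >= 30

    def test_palm_length_exactly_77_not_truncated(self):
        ref = "A" * 100
        subject = "A" * 77 + "-" * 23
        msa = Msa.from_pairs([("ref", ref), ("s", subject)])
        anchor = build_anchor(msa, "ref")
        windows = DomainWindows(palm=(1, 100), fingers=(1, 100))
        m = measure_domains(msa, anchor, windows)[1]
        assert m.palm_length == 77
        assert not m.palm_truncated

    def test_double_truncated_is_conjunction(self):
        ref = "A" * 100
        subject = "A" * 40 + "-" * 60
        msa = Msa.from_pairs([("ref", ref), ("s", subject)])
        anchor = build_anchor(msa, "ref")
        windows = DomainWindows(palm=(1, 50), fingers=(51, 100))
        m = measure_domains(msa, anchor, windows)[1]
        assert m.palm_truncated == (m.palm_length < 77)
        assert m.fingers_truncated == (m.fingers_length < 55)
        assert m.double_truncated == (m.palm_truncated and m.fingers_truncated)

    def test_subject_insertion_lengthens_domain(self):
        # subject has residues where the reference is gapped inside the window
        msa = Msa.from_pairs([("ref", "ACD--EFG"), ("s", "ACDKKEFG")])
        anchor = build_anchor(msa, "ref")
        windows = DomainWindows(palm=(1, 6), fingers=(1, 6))
        m = measure_domains(msa, anchor, windows)[1]
        assert m.palm_length == 8  # 6 reference residues + 2 insertions

    def test_brute_force_oracle_on_random_msas(self):
        rng = random.Random(42)
        alphabet = "ACDEFGHIKLMNPQRSTVWY-"
        for _ in range(50):
            n_cols = rng.randint(10, 60)
            ref = "".join(rng.choice(alphabet) for _ in range(n_cols))
            if ungapped_length(ref) < 4:
                continue
            n_seqs = rng.randint(1, 20)
            pairs = [("ref", ref)] + [
                (f"s{i}", "".join(rng.choice(alphabet) for _ in range(n_cols)))
                for i in range(n_seqs)
            ]
            msa = Msa.from_pairs(pairs)
            anchor = build_anchor(msa, "ref")
            n_res = ungapped_length(ref)
            lo = rng.randint(1, n_res)
            hi = rng.randint(lo, n_res)
            windows = DomainWindows(palm=(lo, hi), fingers=(lo, hi))
            metrics = measure_domains(msa, anchor, windows)
            # oracle: explicitly enumerate the columns of the window
            cols = [
                c
                for c in range(anchor.residue_to_column[lo], anchor.residue_to_column[hi] + 1)
            ]
            for (sid, seq), m in zip(pairs, metrics):
                expected = sum(1 for c in cols if seq[c] != "-")
                assert m.palm_length == expected, (sid, lo, hi)


class TestProfileMotifs:
    def test_reference_states(self):
        # residues 179-183 = GSFRR, residues 271-279 = YFTGSDIFN
        row = "GSFRR" + "A" * 87 + "YFTGSDIFN"
        msa = Msa.from_pairs([("ref", row)])
        anchor = build_anchor(msa, "ref", 179)  # row starts at reference residue 179
        sites = SiteSpec()
        p = profile_motifs(msa, anchor, sites)[0]
        assert p.states["gs_motif"] == "GS"
        assert p.states["palm_R"] == "R"
        assert p.states["dntp_N"] == "N"
        assert p.states["dntp_basic"] == "D"
        assert p.states["steric_gate"] == "YF"

    def test_gapped_site_contains_gap(self):
        msa = Msa.from_pairs([("ref", "ACDE"), ("s", "A-DE")])
        anchor = build_anchor(msa, "ref")
        sites = SiteSpec(sites={"site": (2,)})
        p = profile_motifs(msa, anchor, sites)[1]
        assert p.states["site"] == "-"

    def test_insertion_columns_between_site_residues_ignored(self):
        # reference gapped between the two site residues; subject has an
        # insertion there which must not appear in the state
        msa = Msa.from_pairs([("ref", "AG--SC"), ("s", "AGKKNC")])
        anchor = build_anchor(msa, "ref")
        sites = SiteSpec(sites={"gs": (2, 3)})
        profiles = profile_motifs(msa, anchor, sites)
        assert profiles[0].states["gs"] == "GS"
        assert profiles[1].states["gs"] == "GN"

    def test_state_width_equals_site_width(self):
        msa = Msa.from_pairs([("ref", "ACDEFGH")])
        anchor = build_anchor(msa, "ref")
        sites = SiteSpec(sites={"one": (3,), "three": (2, 4, 6)})
        p = profile_motifs(msa, anchor, sites)[0]
        assert len(p.states["one"]) == 1
        assert len(p.states["three"]) == 3


class TestSummarizeConservation:
    def _inputs(self, triads, n_states):
        msa = triad_msa(triads)
        anchor = build_anchor(msa, "ref")
        calls = call_triads(msa, anchor, SPEC)
        sites = SiteSpec(sites={"dntp_N": (1,)})
        profiles = profile_motifs(msa, anchor, sites)
        metrics = measure_domains(msa, anchor, DomainWindows(palm=(1, 7), fingers=(1, 7)))
        return calls, profiles, metrics

    def test_simple_percentage(self):
        # 10 canonical + ref; plant 9 'N' at a site by hand
        triads = ["DDD"] * 10
        msa_pairs = [("ref", "ADCDEDG")]
        for i in range(10):
            first = "N" if i < 9 else "Q"
            msa_pairs.append((f"s{i}", first + "DCDEDG"))
        msa = Msa.from_pairs(msa_pairs)
        anchor = build_anchor(msa, "ref")
        calls = call_triads(msa, anchor, SPEC)
        sites = SiteSpec(sites={"dntp_N": (1,)})
        profiles = profile_motifs(msa, anchor, sites)
        metrics = measure_domains(msa, anchor, DomainWindows(palm=(1, 7), fingers=(1, 7)))
        report = summarize_conservation(calls, profiles, metrics)
        per = report["sites"]["dntp_N"]["canonical"]
        assert per["n"] == 11  # ref itself is canonical
        # 9 of the 10 planted plus the reference 'A' → N at 9/11
        assert per["state_percent"]["N"] == pytest.approx(100 * 9 / 11)

    def test_empty_class_reports_n0(self):
        calls, profiles, metrics = self._inputs(["DDD", "DDD"], 2)
        report = summarize_conservation(calls, profiles, metrics)
        assert report["sites"]["dntp_N"]["altered"]["n"] == 0
        assert report["sites"]["dntp_N"]["altered"]["state_percent"] == {}
        assert report["lengths"]["altered"]["palm_length"]["n"] == 0

    def test_mismatched_ids_rejected(self):
        calls, profiles, metrics = self._inputs(["DDD"], 1)
        with pytest.raises(ValueError):
            summarize_conservation(calls[:-1], profiles, metrics)

    def test_ci_tightens_with_n(self):
        calls, profiles, metrics = self._inputs(["DDD"] * 5, 5)
        report = summarize_conservation(calls, profiles, metrics)
        summ = report["lengths"]["canonical"]["full_length"]
        assert summ["ci95_low"] <= summ["mean"] <= summ["ci95_high"]


# --- properties ---------------------------------------------------------

TRIAD_CHARS = "DEAKRTX-"


@given(st.lists(st.text(alphabet=TRIAD_CHARS, min_size=3, max_size=3), min_size=1, max_size=30))
@settings(max_examples=50)
def test_partition_property(triads):
    triads = [t for t in triads]
    msa = triad_msa(triads)
    calls = call_triads(msa, build_anchor(msa, "ref"), SPEC)
    counts = {"canonical": 0, "altered": 0, "indeterminate": 0}
    for c in calls:
        counts[c.triad_class] += 1
    assert sum(counts.values()) == len(msa)


@given(st.permutations(["DDD", "AEE", "DE-", "KRT", "EEE"]))
def test_permutation_invariance(order):
    msa = triad_msa(list(order))
    calls = call_triads(msa, build_anchor(msa, "ref"), SPEC)
    by_id = {c.seq_id: c.triad_class for c in calls}
    baseline = triad_msa(["DDD", "AEE", "DE-", "KRT", "EEE"])
    base_calls = call_triads(baseline, build_anchor(baseline, "ref"), SPEC)
    # the same triad string always yields the same class, wherever it sits
    for c in base_calls:
        assert classify_triad(c.triad) == c.triad_class
    for c in calls:
        assert classify_triad(c.triad) == by_id[c.seq_id]


@given(st.integers(min_value=0, max_value=50))
def test_deletion_monotonicity(n_deleted):
    ref = "A" * 60
    subject = "-" * n_deleted + "A" * (60 - n_deleted)
    msa = Msa.from_pairs([("ref", ref), ("s", subject)])
    anchor = build_anchor(msa, "ref")
    windows = DomainWindows(palm=(1, 60), fingers=(1, 60))
    m = measure_domains(msa, anchor, windows)[1]
    assert m.palm_length == 60 - n_deleted
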