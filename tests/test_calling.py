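import math

import numpy as np
import pytest

import ampledit as a
from ampledit.align import revcomp
from ampledit.calling import CallingError

from conftest import delete_at, insert_at, substitute_at


@pytest.fixture(scope="module")
def pair1(locus):
    return a.indicator_pair(locus, "sgRNA1")


@pytest.fixture(scope="module")
def pair2(locus):
    return a.indicator_pair(locus, "sgRNA2")


# ---------------------------------------------------------------------------
# filtering


def test_reference_read_is_used(locus, pair2):
    used, excluded = a.filter_reads([("r", locus.reference)], pair2)
    assert len(used) == 1 and excluded == 0


def test_reverse_complement_read_is_normalized(locus, pair2):
    used, _ = a.filter_reads([("r", revcomp(locus.reference))], pair2)
    assert used == [("r", locus.reference)]


def test_read_missing_right_indicator_is_excluded(locus, sg2, pair2):
    truncated = locus.reference[:sg2.cut_site + 10]
    used, excluded = a.filter_reads([("r", truncated)], pair2)
    assert used == [] and excluded == 1


def test_truncation_rate_recovered(locus, sg2, pair2):
    rng = np.random.default_rng(8)
    n = 10000
    reads = []
    truncated = 0
    for i in range(n):
        if rng.random() < 0.05:
            reads.append((f"r{i}", locus.reference[:sg2.cut_site + 10]))
            truncated += 1
        else:
            reads.append((f"r{i}", locus.reference))
    _, excluded = a.filter_reads(reads, pair2)
    assert excluded == truncated
    sigma = math.sqrt(n * 0.05 * 0.95)
    assert abs(excluded - 500) < 3 * sigma


def test_indicator_pair_requires_uniqueness(locus):
    with pytest.raises(CallingError):
        a.indicator_pair(locus, "sgRNA1", gap=30, length=2)


# ---------------------------------------------------------------------------
# call_read


def test_reference_read_called_wt(locus, pair2):
    call = a.call_read(("r", locus.reference), locus, "sgRNA2", pair=pair2)
    assert call.status == "WT" and call.events == []
    assert call.pattern == "WT"


def test_single_g_insertion_three_bp_upstream_of_pam(locus, sg1, pair1):
    read = insert_at(locus.reference, sg1.cut_site, "G")
    call = a.call_read(("r", read), locus, "sgRNA1", pair=pair1)
    assert call.status == "edited"
    assert len(call.events) == 1
    ev = call.events[0]
    assert (ev.kind, ev.size, ev.bases) == ("insertion", 1, "G")
    assert call.net_indel == 1 and call.frameshift


def test_three_bp_deletion_not_frameshift(locus, sg2, pair2):
    read = delete_at(locus.reference, sg2.cut_site - 2, 3)
    call = a.call_read(("r", read), locus, "sgRNA2", pair=pair2)
    assert call.status == "edited"
    assert call.net_indel == -3 and not call.frameshift


def test_substitution_only_read_edited_with_zero_net(locus, sg2, pair2):
    read = substitute_at(locus.reference, sg2.cut_site + 1, {
        "A": "C", "C": "A", "G": "T", "T": "G"}[locus.reference[sg2.cut_site + 1]])
    call = a.call_read(("r", read), locus, "sgRNA2", pair=pair2)
    assert call.status == "edited"
    assert call.net_indel == 0 and not call.frameshift
    assert not call.has_indel


def test_event_outside_comparison_range_ignored(locus, sg2):
    pair = a.indicator_pair(locus, "sgRNA2", gap=45)
    read = delete_at(locus.reference, sg2.cut_site - 40, 2)
    params = a.CallParams(comparison_range=30)
    call = a.call_read(("r", read), locus, "sgRNA2", params, pair=pair)
    assert call.status == "WT"


def test_left_alignment_of_equivalent_indels(locus, sg2, pair2):
    # find a dinucleotide repeat near the cut: deleting either copy of the
    # repeated base must normalize to the identical event
    ref = locus.reference
    pos = next(p for p in range(sg2.cut_site - 12, sg2.cut_site + 12)
               if ref[p] == ref[p + 1])
    read_a = delete_at(ref, pos, 1)
    read_b = delete_at(ref, pos + 1, 1)
    assert read_a == read_b  # sequences are identical by construction
    params = a.CallParams(wt_marker=15)  # marker window covers the repeat
    call_a = a.call_read(("a", read_a), locus, "sgRNA2", params, pair=pair2)
    call_b = a.call_read(("b", read_b), locus, "sgRNA2", params, pair=pair2)
    assert call_a.events == call_b.events
    assert call_a.events[0].position == pos  # leftmost placement


def test_wt_marker_monotonicity(locus, edited_pool, pair2):
    reads, _ = edited_pool
    sample = reads[:400]
    wt_sets = {}
    for r in (2, 5):
        params = a.CallParams(wt_marker=r)
        calls, _ = a.call_pool(sample, locus, "sgRNA2", params, pair2)
        wt_sets[r] = {c.read_id for c in calls if c.status == "WT"}
    # a larger exact-match window is stricter
    assert wt_sets[5] <= wt_sets[2]


def test_frameshift_flag_recomputed(locus, edited_pool, pair2):
    reads, _ = edited_pool
    calls, _ = a.call_pool(reads[:500], locus, "sgRNA2", pair=pair2)
    for c in calls:
        assert c.frameshift == (c.net_indel != 0 and c.net_indel % 3 != 0)


def test_partition_used_plus_excluded(locus, sg2, pair2):
    reads = [("r0", locus.reference),
             ("r1", insert_at(locus.reference, sg2.cut_site, "T")),
             ("r2", locus.reference[:sg2.cut_site])]
    calls, excluded = a.call_pool(reads, locus, "sgRNA2", pair=pair2)
    statuses = [c.status for c in calls]
    assert excluded == 1
    assert statuses.count("WT") + statuses.count("edited") == len(calls)
    assert len(calls) + excluded == len(reads)


# ---------------------------------------------------------------------------
# brute-force single-indel oracle


def oracle_single_indel(ref, read):
    """Enumerate every single-indel edit transforming ref into read; return
    the leftmost as (kind, position, size, bases), or None."""
    delta = len(read) - len(ref)
    hits = []
    if delta < 0:
        size = -delta
        for s in range(len(ref) - size + 1):
            if ref[:s] + ref[s + size:] == read:
                hits.append(("deletion", s, size, ref[s:s + size]))
    elif delta > 0:
        for p in range(len(ref) + 1):
            if ref[:p] + read[p:p + delta] + ref[p:] == read:
                hits.append(("insertion", p, delta, read[p:p + delta]))
    return min(hits) if hits else None


def test_call_matches_single_indel_oracle(locus, sg2):
    # 80 bp analysis segments; every single indel of size <= 3 near the cut.
    # The pair is built directly from the reference (reads here are
    # reference-derived, so SNP-free flanks are not required).
    ref = locus.reference
    cut = sg2.cut_site
    pair = a.IndicatorPair("sgRNA2", ref[cut - 40:cut - 28],
                           ref[cut + 28:cut + 40])
    assert ref.count(pair.left) == 1 and ref.count(pair.right) == 1
    seg_start = ref.find(pair.left)
    seg_end = ref.find(pair.right) + len(pair.right)
    ref_seg = ref[seg_start:seg_end]
    assert len(ref_seg) == 80
    rng = np.random.default_rng(13)
    # wide WT marker so every constructed indel defeats the exact-match
    # shortcut and exercises the alignment path the oracle checks
    params = a.CallParams(comparison_range=28, wt_marker=28)
    checked = 0
    for size in (1, 2, 3):
        for offset in range(-20, 21):
            pos = sg2.cut_site + offset
            for kind in ("deletion", "insertion"):
                if kind == "deletion":
                    read = delete_at(ref, pos, size)
                else:
                    bases = "".join(rng.choice(list("ACGT"), size=size))
                    read = insert_at(ref, pos, bases)
                call = a.call_read(("r", read), locus, "sgRNA2", params, pair)
                read_seg = read[seg_start:seg_end + (len(read) - len(ref))]
                expected = oracle_single_indel(ref_seg, read_seg)
                assert expected is not None
                kind_e, pos_e, size_e, bases_e = expected
                assert call.status == "edited"
                assert len(call.events) == 1
                ev = call.events[0]
                assert ev.kind == kind_e
                assert ev.position == pos_e + seg_start
                assert ev.size == size_e
                if kind_e == "insertion":
                    assert ev.bases == bases_e
                checked += 1
    assert checked == 246


# ---------------------------------------------------------------------------
# large deletions


def test_large_deletion_detected(locus, sg1, sg2):
    read = delete_at(locus.reference, sg1.cut_site,
                     sg2.cut_site - sg1.cut_site)
    assert a.detect_large_deletion(("r", read), locus)


def test_small_deletion_not_large(locus, sg2):
    read = delete_at(locus.reference, sg2.cut_site - 1, 1)
    assert not a.detect_large_deletion(("r", read), locus)


def test_dropout_fraction_recovered(locus, sg1, sg2):
    from ampledit.simulate import CopyState, EditEvent
    size = sg2.cut_site - sg1.cut_site
    states = {}
    for i in range(20):
        ev = ([EditEvent("sgRNA1+sgRNA2", "large_deletion", size,
                         sg1.cut_site)] if i < 7 else [])
        states[f"copy1/{i}"] = CopyState("copy1", ev)
    lineages = [a.CellLineage("L", 1.0, states)]
    cfg = a.SimConfig(n_reads=400, allocation="exact")
    reads, truth = a.generate_reads(lineages, cfg, locus,
                                    np.random.default_rng(3))
    detected = sum(a.detect_large_deletion(r, locus) for r in reads)
    assert detected == truth.large_deletion.sum() == 140  # exactly 35 %


# ---------------------------------------------------------------------------
# site summaries


def make_calls(n_indel, n_wt, net=1):
    calls = []
    for i in range(n_indel):
        ev = a.calling.CallEvent("insertion", abs(net), 100, "-3", "G")
        calls.append(a.IndelCall(f"e{i}", "sgRNA2", "edited", [ev], net,
                                 frameshift=net % 3 != 0))
    for i in range(n_wt):
        calls.append(a.IndelCall(f"w{i}", "sgRNA2", "WT"))
    return calls


def test_summary_reproduces_printed_row():
    summary = a.summarize_site(make_calls(3596, 4905 - 3596))
    assert summary.reads_used == 4905
    assert summary.indel_reads == 3596
    assert summary.indel_pct == 73


def test_summary_zero_edited():
    summary = a.summarize_site(make_calls(0, 50))
    assert summary.indel_pct == 0.0


def test_summary_no_reads_gives_missing_pct():
    summary = a.summarize_site([])
    assert summary.indel_pct is None and summary.frameshift_pct is None


def test_summary_low_pct_one_decimal():
    summary = a.summarize_site(make_calls(9, 991))
    assert summary.indel_pct == 0.9


def test_min_frequency_drops_rare_patterns_not_totals(locus, sg2, pair2):
    reads = ([("a%d" % i, insert_at(locus.reference, sg2.cut_site, "G"))
              for i in range(5)]
             + [("b", insert_at(locus.reference, sg2.cut_site, "TT"))])
    params = a.CallParams(min_frequency=2)
    calls, _ = a.call_pool(reads, locus, "sgRNA2", params, pair2)
    summary = a.summarize_site(calls, params)
    assert summary.indel_reads == 6           # rare pattern still counted
    assert len(summary.patterns) == 1          # but dropped from the table
    assert list(summary.patterns.values()) == [5]


def test_exact_round_trip_at_90_percent(locus, sg2, pair2):
    from ampledit.simulate import CopyState, EditEvent
    states = {}
    for i in range(10):
        ev = ([EditEvent("sgRNA2", "deletion", 1, sg2.cut_site - 1)]
              if i < 9 else [])
        states[f"copy1/{i}"] = CopyState("copy1", ev)
    lineages = [a.CellLineage("L", 1.0, states)]
    cfg = a.SimConfig(n_reads=10000, allocation="exact")
    reads, _ = a.generate_reads(lineages, cfg, locus, np.random.default_rng(2))
    calls, _ = a.call_pool(reads, locus, "sgRNA2", pair=pair2)
    summary = a.summarize_site(calls)
    assert summary.indel_pct == 90
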