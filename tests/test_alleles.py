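import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ampledit as a
from ampledit.simulate import CopyState, EditEvent

from conftest import delete_at, insert_at


# ---------------------------------------------------------------------------
# allele assignment


def test_error_free_clone_read_assigned(locus):
    read = a.haplotype_sequence(locus, "copy6")
    asn = a.assign_allele(("r", read), locus, max_mismatch=0)
    assert asn.hap_id == "copy6" and asn.mismatches == 0


def test_edited_clone_read_still_assigned(locus, sg2):
    read = insert_at(a.haplotype_sequence(locus, "copy4"), sg2.cut_site, "G")
    asn = a.assign_allele(("r", read), locus, max_mismatch=0)
    assert asn.hap_id == "copy4"


def test_equidistant_read_unassigned(locus):
    # halfway between copy1 (reference) and another haplotype with an even
    # SNP count: apply exactly half of its profile
    hap = next(h for h in locus.haplotypes
               if len(h.snp_profile) >= 4 and len(h.snp_profile) % 2 == 0
               and h.id != "copy6")
    positions = sorted(hap.snp_profile)
    half = positions[:len(positions) // 2]
    seq = list(locus.reference)
    for p in half:
        seq[p] = hap.snp_profile[p]
    asn = a.assign_allele(("r", "".join(seq)), locus, max_mismatch=20)
    assert asn.hap_id == "unassigned" and asn.reason == "tie"


def test_low_coverage_read_unassigned(locus):
    read = locus.reference[:150]
    asn = a.assign_allele(("r", read), locus)
    assert asn.hap_id == "unassigned"
    assert "coverage" in asn.reason


def test_mismatch_budget(locus):
    seq = list(a.haplotype_sequence(locus, "copy2"))
    informative = a.informative_positions(locus)
    touched = [p for p in informative
               if p not in locus.haplotype("copy2").snp_profile][:2]
    for p in touched:
        seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
    read = "".join(seq)
    assert a.assign_allele(("r", read), locus, max_mismatch=1).hap_id == "unassigned"
    assert a.assign_allele(("r", read), locus, max_mismatch=2).hap_id == "copy2"


def test_eighty_error_free_clones_all_correct(locus):
    cfg = a.SimConfig(seed=21, cut_prob=0.5, n_clone_reads=80)
    rng = np.random.default_rng(cfg.seed)
    lineages = a.simulate_lineages(cfg, locus, rng)
    clones, truth = a.generate_clone_reads(lineages, cfg, locus, rng)
    hap_of = dict(zip(truth.read_id, truth.hap_id))
    for rid, seq in clones:
        asn = a.assign_allele((rid, seq), locus, max_mismatch=0)
        assert asn.hap_id == hap_of[rid]


# ---------------------------------------------------------------------------
# HDR detection


def hdr_read(locus, tract):
    """copy1 backbone carrying a copy6 conversion tract."""
    state = CopyState("copy1", [EditEvent("sgRNA2", "hdr_conversion", 0,
                                          tract[0], donor_hap="copy6",
                                          tract=tract)])
    from ampledit.simulate import apply_events
    return apply_events(locus, state)


def test_recombinant_read_is_candidate(locus, sg2):
    ws, we = sg2.site_interval
    cands = a.detect_hdr([("r", hdr_read(locus, (ws - 5, we + 5)))], locus)
    assert len(cands) == 1
    c = cands[0]
    assert c.donor_hap == "copy6" and c.flanking_hap == "copy1"
    assert c.conservative


def test_pure_donor_read_not_candidate(locus):
    read = a.haplotype_sequence(locus, "copy6")
    assert a.detect_hdr([("r", read)], locus) == []


def test_tract_bounds_bracket_truth(locus, sg2):
    ws, we = sg2.site_interval
    tract = (250, 420)
    cands = a.detect_hdr([("r", hdr_read(locus, tract))], locus)
    c = cands[0]
    assert c.tract_min[0] >= tract[0] and c.tract_min[1] <= tract[1]
    assert c.tract_max[0] <= tract[0] and c.tract_max[1] >= tract[1]
    assert ws >= c.tract_min[0] and we <= c.tract_min[1]
    assert c.tract_min[0] >= c.tract_max[0] and c.tract_min[1] <= c.tract_max[1]
    assert not c.unbounded


def test_specificity_on_non_recombinant_pool(locus):
    cfg = a.SimConfig(seed=23, cut_prob=0.7, large_del_prob=0.1,
                      n_clone_reads=80)
    rng = np.random.default_rng(cfg.seed)
    lineages = a.simulate_lineages(cfg, locus, rng)
    clones, truth = a.generate_clone_reads(lineages, cfg, locus, rng)
    assert (truth.class_sgRNA2 != "hdr").all()
    assert a.detect_hdr(clones, locus, max_mismatch=0) == []


def test_simulated_hdr_reads_all_detected_with_bounds(locus):
    import re
    cfg = a.SimConfig(seed=29, cut_prob={"sgRNA2": 1.0}, hdr_prob=0.5,
                      n_clone_reads=80, allocation="exact")
    rng = np.random.default_rng(cfg.seed)
    lineages = a.simulate_lineages(cfg, locus, rng)
    clones, truth = a.generate_clone_reads(lineages, cfg, locus, rng)
    cands = a.detect_hdr(clones, locus, max_mismatch=0)
    true_ids = set(truth[truth.class_sgRNA2 == "hdr"].read_id)
    assert {c.read_id for c in cands} == true_ids
    events = dict(zip(truth.read_id, truth.events))
    for c in cands:
        m = re.search(r"hdr\[\w+:(\d+)-(\d+)\]", events[c.read_id])
        s, e = int(m.group(1)), int(m.group(2))
        assert c.tract_max[0] <= s <= c.tract_min[0]
        assert c.tract_min[1] <= e <= c.tract_max[1]


def test_edited_pattern_candidates_are_extended_class(locus, sg2):
    # the same NHEJ mutation on two different haplotype backbones
    ws, we = sg2.site_interval
    edited = insert_at(locus.reference, sg2.cut_site, "G")
    pattern = a.EditedPattern("plus1G", "copy1",
                              {"sgRNA2": edited[ws:we + 1]})
    backbone = a.haplotype_sequence(locus, "copy4")
    read = insert_at(backbone, sg2.cut_site, "G")
    cands = a.detect_hdr([("r", read)], locus, edited_patterns=[pattern])
    assert len(cands) == 1
    assert not cands[0].conservative
    assert cands[0].flanking_hap == "copy4"
    # the pattern's own backbone is not a candidate
    assert a.detect_hdr([("o", insert_at(locus.reference, sg2.cut_site, "G"))],
                        locus, edited_patterns=[pattern]) == []


def test_no_flanking_snps_flags_unbounded(locus):
    # a donor/recipient pair differing nowhere outside the window cannot
    # bound the tract; emulate by restricting to a two-haplotype locus
    mini = a.LocusModel(
        reference=locus.reference,
        haplotypes=[a.Haplotype("copy1"),
                    a.Haplotype("hapX", {215: locus.haplotype("copy6").snp_profile[215],
                                         315: locus.haplotype("copy6").snp_profile[315]})],
        targets=locus.targets,
        variable_positions=locus.variable_positions,
    )
    seq = list(locus.reference)
    seq[215] = locus.haplotype("copy6").snp_profile[215]
    seq[315] = locus.haplotype("copy6").snp_profile[315]
    cands = a.detect_hdr([("r", "".join(seq))], mini, donors=["hapX"])
    assert len(cands) == 1 and cands[0].unbounded


# ---------------------------------------------------------------------------
# HDR frequency estimate


def test_worked_example():
    est = a.estimate_hdr_frequency([26.25, 1.25], 0.7)
    assert est.total_pct == 27.5
    assert est.corrected_pct == 26.8


def test_zero_components():
    est = a.estimate_hdr_frequency([0.0], 0.0)
    assert est.corrected_pct == 0.0


def test_background_exceeding_total_clamped():
    with pytest.warns(UserWarning):
        est = a.estimate_hdr_frequency([1.0], 2.0)
    assert est.corrected_pct == 0.0


def test_out_of_range_percentage_rejected():
    with pytest.raises(ValueError):
        a.estimate_hdr_frequency([120.0], 0.0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 20), min_size=1, max_size=4),
       st.floats(0, 5))
def test_estimate_linear_in_components(components, background):
    est = a.estimate_hdr_frequency(components, background)
    expected = max(sum(components) - background, 0.0)
    assert est.corrected_pct == pytest.approx(expected, abs=0.051)


def test_estimator_recovery_small(locus):
    """Corrected estimate near truth over a handful of replicates (the full
    200-replicate recovery check lives in the acceptance suite)."""
    h = 0.27
    estimates = []
    for rep in range(20):
        cfg = a.SimConfig(seed=1000 + rep, cut_prob={"sgRNA2": h * 4 / 3},
                          hdr_prob=1.0, n_clone_reads=80)
        rng = np.random.default_rng(cfg.seed)
        lineages = a.simulate_lineages(cfg, locus, rng)
        clones, _ = a.generate_clone_reads(lineages, cfg, locus, rng)
        cands = [c for c in a.detect_hdr(clones, locus, max_mismatch=0)
                 if c.conservative]
        pct = 100.0 * len(cands) / len(clones)
        estimates.append(a.estimate_hdr_frequency([pct], 0.0).corrected_pct)
    assert abs(np.mean(estimates) - 100 * h) < 5.0
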