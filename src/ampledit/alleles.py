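"""Haplotype assignment of clone reads, HDR-signature detection, and the
background-corrected HDR frequency estimate.

Reads are profiled at the locus's variable positions after global alignment
to the reference; positions inside the target windows are excluded from
profiling so edits cannot masquerade as haplotype differences. A read whose
target-window genotype equals a donor haplotype's while its flanking SNP
profile matches a different haplotype is an HDR candidate; conversion-tract
bounds follow from the nearest informative SNPs on each side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .align import AlignScores, DEFAULT_SCORES, ReadAlignment
from .locus import LocusModel, haplotype_sequence
from .rounding import round_half_up


@dataclass
class AlleleAssignment:
    read_id: str
    hap_id: str                  # haplotype id or "unassigned"
    mismatches: int
    informative_used: int
    reason: str = ""


def informative_positions(locus: LocusModel, exclude_radius: int = 30) -> List[int]:
    """Variable positions outside every target window (cut +/- radius)."""
    windows = [t.window(exclude_radius) for t in locus.targets]
    return [p for p in locus.variable_positions
            if not any(s <= p < e for s, e in windows)]


def _profile_read(read_seq: str, locus: LocusModel, positions: Sequence[int],
                  scores: AlignScores) -> Tuple[Dict[int, Optional[str]], ReadAlignment]:
    aln = ReadAlignment(locus.reference, read_seq, scores)
    return {p: aln.base_at(p) for p in positions}, aln


def _nearest_haplotype(locus: LocusModel, prof: Dict[int, Optional[str]]):
    covered = [p for p, b in prof.items() if b is not None]
    dists = []
    for hap in locus.haplotypes:
        d = sum(1 for p in covered
                if prof[p] != hap.base_at(p, locus.reference))
        dists.append((d, hap.id))
    dists.sort()
    best_d, best_h = dists[0]
    tie = len(dists) > 1 and dists[1][0] == best_d
    return best_h, best_d, len(covered), tie


def assign_allele(read, locus: LocusModel, max_mismatch: int = 1,
                  exclude_radius: int = 30, min_coverage: float = 0.8,
                  scores: AlignScores = DEFAULT_SCORES) -> AlleleAssignment:
    rid, seq = read if isinstance(read, tuple) else ("read", read)
    seq = str(seq).upper()
    positions = informative_positions(locus, exclude_radius)
    prof, _aln = _profile_read(seq, locus, positions, scores)
    covered = sum(1 for b in prof.values() if b is not None)
    if positions and covered < min_coverage * len(positions):
        return AlleleAssignment(rid, "unassigned", 0, covered,
                                reason="insufficient coverage of variable positions")
    hap_id, d, used, tie = _nearest_haplotype(locus, prof)
    if tie:
        return AlleleAssignment(rid, "unassigned", d, used, reason="tie")
    if d > max_mismatch:
        return AlleleAssignment(rid, "unassigned", d, used,
                                reason="exceeds mismatch budget")
    return AlleleAssignment(rid, hap_id, d, used)


@dataclass(frozen=True)
class EditedPattern:
    """A named edited target genotype usable as an HDR 'donor' signature."""
    label: str
    origin_hap: str
    windows: Dict[str, str]  # target_id -> expected window sequence

    def __hash__(self):
        return hash((self.label, self.origin_hap))


@dataclass
class HdrCandidate:
    read_id: str
    genotype_class: str
    flanking_hap: str
    donor_hap: str
    tract_min: Tuple[int, int]
    tract_max: Tuple[int, int]
    unbounded: bool = False
    conservative: bool = True   # donor-genotype class (not an edited pattern)


def _hap_window(locus: LocusModel, hap_id: str, interval: Tuple[int, int]) -> str:
    return haplotype_sequence(locus, hap_id)[interval[0]:interval[1]]


def _mosaic_fit(dseq: str, rseq: str, prof: Dict[int, Optional[str]],
                span: Tuple[int, int],
                max_mismatch: int) -> Optional[Tuple[int, List[int], List[int]]]:
    """Test whether the read profile decomposes into a single donor-matching
    tract around ``span`` with the recipient everywhere else.

    Returns (mismatches, donor_positions, recipient_positions) or None when
    the decomposition fails (two tracts, no recipient evidence, or too many
    positions matching neither haplotype).
    """
    mism = 0
    labels = []  # (position, 'd'|'r'|'x') at donor/recipient-distinguishing SNPs
    for p, base in prof.items():
        if dseq[p] == rseq[p]:
            if base != dseq[p]:
                mism += 1
        elif base == dseq[p]:
            labels.append((p, "d"))
        elif base == rseq[p]:
            labels.append((p, "r"))
        else:
            labels.append((p, "x"))
            mism += 1
    if labels and not any(lab == "r" for _p, lab in labels):
        return None  # indistinguishable from the donor itself
    # (no distinguishing flank SNPs at all -> accepted, tract unbounded)
    # grow the donor tract outward from the converted window
    ws, we = span
    informative = [(p, lab) for p, lab in sorted(labels) if lab != "x"]
    left = [i for i, (p, _l) in enumerate(informative) if p < ws]
    lo = len(left)
    hi = lo  # informative[lo:hi) sits inside the window span (normally empty)
    while hi < len(informative) and informative[hi][0] < we:
        hi += 1
    i = lo
    while i > 0 and informative[i - 1][1] == "d":
        i -= 1
    j = hi
    while j < len(informative) and informative[j][1] == "d":
        j += 1
    donor_pos = [p for p, lab in informative[i:j] if lab == "d"]
    # everything outside the tract must match the recipient
    mism += sum(1 for p, lab in informative[lo:hi] if lab == "r")
    mism += sum(1 for p, lab in informative[:i] + informative[j:] if lab == "d")
    if mism > max_mismatch:
        return None
    recip_pos = [p for p, lab in informative[:i] + informative[j:] if lab == "r"]
    return mism, donor_pos, recip_pos


def detect_hdr(reads: Iterable, locus: LocusModel,
               donors: Optional[Sequence[str]] = None,
               edited_patterns: Sequence[EditedPattern] = (),
               max_mismatch: int = 0, exclude_radius: int = 30,
               scores: AlignScores = DEFAULT_SCORES) -> List[HdrCandidate]:
    """Scan clone reads for recombinant (HDR-signature) molecules.

    Default donors are the haplotypes protected by target-region SNPs
    (uneditable at one or both targets). A read qualifies when its target
    window reproduces a donor genotype that differs from the flanking
    haplotype's, and its SNP profile decomposes into one donor tract on an
    otherwise recipient background.
    """
    if donors is None:
        donors = [h.id for h in locus.haplotypes
                  if h.snp_profile and not all(h.editable.values())]
    windows = {t.id: t.site_interval for t in locus.targets}
    positions = informative_positions(locus, exclude_radius)
    hapseqs = {h.id: haplotype_sequence(locus, h.id) for h in locus.haplotypes}
    win_of = {(hid, tid): seq[iv[0]:iv[1]]
              for hid, seq in hapseqs.items()
              for tid, iv in windows.items()}
    out: List[HdrCandidate] = []
    for read in reads:
        rid, seq = read if isinstance(read, tuple) else ("read", read)
        seq = str(seq).upper()
        prof, aln = _profile_read(seq, locus, positions, scores)
        covered = sum(1 for b in prof.values() if b is not None)
        if positions and covered < 0.8 * len(positions):
            continue
        read_windows = {tid: aln.slice(*iv) for tid, iv in windows.items()}

        best = None  # (mismatches, candidate)
        for donor in donors:
            for hap in locus.haplotypes:
                if hap.id == donor:
                    continue
                matched = [
                    tid for tid in windows
                    if (win_of[donor, tid] != win_of[hap.id, tid]
                        and read_windows[tid] == win_of[donor, tid])
                ]
                if not matched:
                    continue
                span = (min(windows[t][0] for t in matched),
                        max(windows[t][1] for t in matched))
                fit = _mosaic_fit(hapseqs[donor], hapseqs[hap.id], prof,
                                  span, max_mismatch)
                if fit is None:
                    continue
                mism, donor_pos, recip_pos = fit
                tmin, tmax, unbounded = _tract_bounds(
                    span, donor_pos, recip_pos, len(locus.reference))
                cand = HdrCandidate(
                    rid, f"{donor}-type@{'+'.join(matched)}", hap.id, donor,
                    tmin, tmax, unbounded, conservative=True)
                if best is None or mism < best[0]:
                    best = (mism, cand)
        if best is None:
            for pat in edited_patterns:
                want_ok = all(read_windows.get(tid) == want
                              for tid, want in pat.windows.items())
                if not want_ok:
                    continue
                span_ivs = [windows[t] for t in pat.windows]
                span = (min(s for s, _ in span_ivs), max(e for _, e in span_ivs))
                for hap in locus.haplotypes:
                    if hap.id == pat.origin_hap:
                        continue
                    fit = _mosaic_fit(hapseqs[pat.origin_hap], hapseqs[hap.id],
                                      prof, span, max_mismatch)
                    if fit is None:
                        continue
                    mism, donor_pos, recip_pos = fit
                    tmin, tmax, unbounded = _tract_bounds(
                        span, donor_pos, recip_pos, len(locus.reference))
                    cand = HdrCandidate(rid, pat.label, hap.id, pat.origin_hap,
                                        tmin, tmax, unbounded,
                                        conservative=False)
                    if best is None or mism < best[0]:
                        best = (mism, cand)
        if best is not None:
            out.append(best[1])
    return out


def _tract_bounds(span: Tuple[int, int], donor_pos: Sequence[int],
                  recip_pos: Sequence[int], ref_len: int):
    """Minimal tract: converted window plus donor-matching informative SNPs.
    Maximal tract: bounded by the nearest recipient-matching SNPs that
    distinguish donor from recipient."""
    lo, hi = span
    if donor_pos:
        lo = min(lo, min(donor_pos))
        hi = max(hi, max(donor_pos) + 1)
    tract_min = (lo, hi)
    left = [p for p in recip_pos if p < lo]
    right = [p for p in recip_pos if p >= hi]
    tract_max = (max(left) + 1 if left else 0,
                 min(right) if right else ref_len)
    return tract_min, tract_max, not left and not right


@dataclass
class HdrEstimate:
    components: List[float]
    total_pct: float
    background_pct: float
    corrected_pct: float


def estimate_hdr_frequency(component_pcts: Sequence[float],
                           background_pct: float) -> HdrEstimate:
    """Sum recombinant-class percentages, subtract background, clamp at 0;
    one-decimal reporting."""
    from fractions import Fraction

    for p in list(component_pcts) + [background_pct]:
        if not 0 <= p <= 100:
            raise ValueError(f"percentage {p} outside [0,100]")
    total = sum(Fraction(str(p)) for p in component_pcts)
    corrected = total - Fraction(str(background_pct))
    if corrected < 0:
        warnings.warn("background exceeds total; corrected estimate clamped to 0")
        corrected = Fraction(0)
    return HdrEstimate(
        components=[float(p) for p in component_pcts],
        total_pct=round_half_up(total, 1),
        background_pct=float(background_pct),
        corrected_pct=round_half_up(corrected, 1),
    )
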