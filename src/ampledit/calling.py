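"""Indicator-pair read filtering and alignment-based indel calling.

A read enters analysis only when both indicator sequences flanking a target
window are present in order (either orientation). Reads carrying the exact
reference sequence over the cut-site marker window (cut +/- r) are wild
type; all other reads are globally aligned to the reference segment between
the indicators, indels are left-normalised, and events within the
comparison range (cut +/- R) are reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .align import AlignScores, DEFAULT_SCORES, AlnEvent, ReadAlignment, revcomp
from .locus import LocusModel, TargetSite
from .rounding import paper_pct


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class IndicatorPair:
    target_id: str
    left: str
    right: str


def indicator_pair(locus: LocusModel, target_id: str, gap: int = 30,
                   length: int = 12) -> IndicatorPair:
    """Derive an indicator pair from the reference, at least ``gap`` bp
    clear of the cut on each side. Each flank is the nearest ``length``-bp
    window that is unique in the reference and free of variable positions
    (so every haplotype carries it verbatim)."""
    t = locus.target(target_id)
    ref = locus.reference
    varpos = set(locus.variable_positions)

    def usable(start: int) -> bool:
        if start < 0 or start + length > len(ref):
            return False
        window = ref[start:start + length]
        return (ref.count(window) == 1
                and not any(p in varpos for p in range(start, start + length)))

    left_start = t.cut_site - gap - length
    while left_start >= 0 and not usable(left_start):
        left_start -= 1
    right_start = t.cut_site + gap
    while right_start + length <= len(ref) and not usable(right_start):
        right_start += 1
    if left_start < 0 or right_start + length > len(ref):
        raise CallingError(f"{target_id}: no usable indicator flank")
    return IndicatorPair(target_id, ref[left_start:left_start + length],
                         ref[right_start:right_start + length])


@dataclass
class CallParams:
    comparison_range: int = 30   # R
    wt_marker: int = 5           # r
    min_frequency: int = 1       # n
    scores: AlignScores = DEFAULT_SCORES

    def __post_init__(self):
        if not self.comparison_range >= self.wt_marker >= 1:
            raise CallingError("require R >= r >= 1")
        if self.min_frequency < 1:
            raise CallingError("require n >= 1")


Read = Tuple[str, str]


def _as_pairs(reads: Iterable) -> List[Read]:
    out = []
    for r in reads:
        if isinstance(r, tuple):
            out.append((r[0], str(r[1]).upper()))
        else:  # Bio.SeqRecord
            out.append((r.id, str(r.seq).upper()))
    return out


def filter_reads(reads: Iterable, pair: IndicatorPair) -> Tuple[List[Read], int]:
    """Keep reads containing both indicators in left->right order in either
    orientation; kept reads are returned in reference orientation."""
    used, excluded = [], 0
    for rid, seq in _as_pairs(reads):
        oriented = _orient(seq, pair)
        if oriented is None:
            excluded += 1
        else:
            used.append((rid, oriented))
    return used, excluded


def _orient(seq: str, pair: IndicatorPair) -> Optional[str]:
    for s in (seq, revcomp(seq)):
        li = s.find(pair.left)
        if li >= 0 and s.find(pair.right, li + len(pair.left)) >= 0:
            return s
    return None


@dataclass(frozen=True)
class CallEvent:
    kind: str        # insertion | deletion | substitution
    size: int
    position: int    # reference coordinate (insertions: inter-base)
    label: str       # PAM-relative display label
    bases: str

    def token(self) -> str:
        if self.kind == "insertion":
            return f"{self.label}:+{self.size}{self.bases}"
        if self.kind == "deletion":
            return f"{self.label}:-{self.size}"
        return f"{self.label}:{self.bases}"


@dataclass
class IndelCall:
    read_id: str
    target_id: str
    status: str                      # WT | edited | excluded
    events: List[CallEvent] = field(default_factory=list)
    net_indel: int = 0
    frameshift: bool = False
    large_deletion: bool = False
    reason: str = ""

    @property
    def pattern(self) -> str:
        if self.status == "WT":
            return "WT"
        return ",".join(ev.token() for ev in self.events) or "."

    @property
    def has_indel(self) -> bool:
        return any(ev.kind in ("insertion", "deletion") for ev in self.events)


def call_read(read: Union[Read, str], locus: LocusModel, target_id: str,
              params: CallParams = None,
              pair: Optional[IndicatorPair] = None) -> IndelCall:
    """Call one filtered, reference-oriented read at a target."""
    params = params or CallParams()
    if isinstance(read, str):
        read = ("read", read)
    rid, seq = read[0], str(read[1]).upper()
    pair = pair or indicator_pair(locus, target_id)
    t = locus.target(target_id)
    ref = locus.reference
    cut = t.cut_site

    li = seq.find(pair.left)
    ri = seq.find(pair.right, li + len(pair.left)) if li >= 0 else -1
    if li < 0 or ri < 0:
        return IndelCall(rid, target_id, "excluded", reason="missing indicator")
    segment = seq[li:ri + len(pair.right)]
    ref_l = ref.find(pair.left)
    ref_r = ref.find(pair.right)
    ref_segment = ref[ref_l:ref_r + len(pair.right)]

    r = params.wt_marker
    if ref[cut - r:cut + r] in segment:
        return IndelCall(rid, target_id, "WT")

    try:
        events = ReadAlignment(ref_segment, segment, params.scores,
                               offset=ref_l).events()
    except Exception as exc:  # pathological read
        return IndelCall(rid, target_id, "excluded",
                         reason=f"alignment failure: {exc}")

    R = params.comparison_range
    lo, hi = cut - R, cut + R
    in_range = []
    for ev in events:
        if ev.kind == "insertion":
            keep = lo <= ev.start <= hi
        elif ev.kind == "deletion":
            keep = ev.start <= hi and ev.end >= lo
        else:
            keep = ev.start < hi and ev.end > lo
        if keep:
            in_range.append(ev)

    cuts = sorted(u.cut_site for u in locus.targets)
    large = any(ev.kind == "deletion" and ev.start <= cuts[0]
                and ev.end >= cuts[-1] for ev in events) if len(cuts) > 1 else False

    if not in_range:
        return IndelCall(rid, target_id, "WT", large_deletion=large)

    call_events = [_to_call_event(ev, t) for ev in in_range]
    net = sum(ev.signed_size for ev in in_range)
    return IndelCall(rid, target_id, "edited", call_events, net,
                     frameshift=(net != 0 and net % 3 != 0),
                     large_deletion=large)


def _to_call_event(ev: AlnEvent, t: TargetSite) -> CallEvent:
    return CallEvent(ev.kind, ev.size, ev.start, t.pam_label(ev.start), ev.bases)


def call_pool(reads: Iterable, locus: LocusModel, target_id: str,
              params: CallParams = None,
              pair: Optional[IndicatorPair] = None) -> Tuple[List[IndelCall], int]:
    """Filter then call a read pool; returns (calls, excluded_count)."""
    params = params or CallParams()
    pair = pair or indicator_pair(locus, target_id)
    used, excluded = filter_reads(reads, pair)
    return [call_read(rd, locus, target_id, params, pair) for rd in used], excluded


def detect_large_deletion(obj, locus: LocusModel,
                          scores: AlignScores = DEFAULT_SCORES) -> bool:
    """True when a single deletion spans every cut site of the locus."""
    if isinstance(obj, IndelCall):
        return obj.large_deletion
    seq = str(obj[1] if isinstance(obj, tuple) else obj).upper()
    cuts = sorted(t.cut_site for t in locus.targets)
    if len(cuts) < 2:
        return False
    events = ReadAlignment(locus.reference, seq, scores).events()
    return any(ev.kind == "deletion" and ev.start <= cuts[0]
               and ev.end >= cuts[-1] for ev in events)


@dataclass
class SiteSummary:
    target_id: str
    total_reads: int
    reads_used: int
    indel_reads: int
    indel_pct: Optional[float]
    frameshift_reads: int
    frameshift_pct: Optional[float]
    substitution_only_reads: int
    patterns: Dict[str, int]


def summarize_site(calls: Sequence[IndelCall], params: CallParams = None,
                   total_reads: Optional[int] = None) -> SiteSummary:
    """Aggregate calls from one target into a site summary.

    Percentages use the printed-table precision (integer at >= 10 %, one
    decimal below); mutation patterns below the minimum frequency are
    dropped from the pattern table but still counted in the totals.
    """
    params = params or CallParams()
    target_ids = {c.target_id for c in calls}
    if len(target_ids) > 1:
        raise CallingError("calls span multiple targets")
    target_id = target_ids.pop() if target_ids else ""
    usable = [c for c in calls if c.status != "excluded"]
    reads_used = len(usable)
    indel = [c for c in usable if c.has_indel]
    frameshift = [c for c in indel if c.frameshift]
    sub_only = sum(1 for c in usable if c.status == "edited" and not c.has_indel)
    patterns = Counter(c.pattern for c in usable if c.status == "edited")
    patterns = {p: n for p, n in sorted(patterns.items(),
                                        key=lambda kv: (-kv[1], kv[0]))
                if n >= params.min_frequency}
    if reads_used:
        indel_pct = paper_pct(len(indel), reads_used)
        fs_pct = paper_pct(len(frameshift), reads_used)
    else:
        indel_pct = fs_pct = None
    return SiteSummary(
        target_id=target_id,
        total_reads=total_reads if total_reads is not None else len(calls),
        reads_used=reads_used,
        indel_reads=len(indel),
        indel_pct=indel_pct,
        frameshift_reads=len(frameshift),
        frameshift_pct=fs_pct,
        substitution_only_reads=sub_only,
        patterns=patterns,
    )
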