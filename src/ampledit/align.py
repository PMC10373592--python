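"""Pairwise alignment utilities shared by the calling and allele modules.

Wraps :class:`Bio.Align.PairwiseAligner` (global, affine gaps) and converts
alignments into discrete edit events with VCF-style left normalisation of
indels, plus a per-reference-position view of a read used for SNP profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from Bio import Align

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignScores:
    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


DEFAULT_SCORES = AlignScores()


def make_aligner(scores: AlignScores = DEFAULT_SCORES) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scores.match
    aligner.mismatch_score = scores.mismatch
    aligner.open_gap_score = scores.gap_open
    aligner.extend_gap_score = scores.gap_extend
    return aligner


@dataclass(frozen=True)
class AlnEvent:
    """One difference between reference and read.

    ``start``/``end`` are reference coordinates (half-open). For insertions
    ``start == end`` is the inter-base coordinate. ``bases`` holds inserted
    read bases, deleted reference bases, or ``ref>alt`` for substitutions.
    """

    kind: str  # insertion | deletion | substitution
    start: int
    end: int
    bases: str

    @property
    def size(self) -> int:
        if self.kind == "insertion":
            return len(self.bases)
        if self.kind == "deletion":
            return self.end - self.start
        return self.end - self.start  # substituted run length

    @property
    def signed_size(self) -> int:
        if self.kind == "insertion":
            return len(self.bases)
        if self.kind == "deletion":
            return -(self.end - self.start)
        return 0


def _left_shift(ref: str, ev: AlnEvent) -> AlnEvent:
    """Left-align an indel through repeat context (VCF-style normalisation)."""
    if ev.kind == "insertion":
        pos, bases = ev.start, ev.bases
        while pos > 0 and ref[pos - 1] == bases[-1]:
            bases = bases[-1] + bases[:-1]
            pos -= 1
        return AlnEvent("insertion", pos, pos, bases)
    if ev.kind == "deletion":
        s, e = ev.start, ev.end
        while s > 0 and ref[s - 1] == ref[e - 1]:
            s -= 1
            e -= 1
        return AlnEvent("deletion", s, e, ref[s:e])
    return ev


class ReadAlignment:
    """Global alignment of a read against a reference segment.

    Provides edit events (left-normalised) and projections from reference
    coordinates to read bases/substrings. A fast path skips the dynamic
    programme for reads that are same-length near-copies of the reference.
    """

    def __init__(self, ref: str, read: str, scores: AlignScores = DEFAULT_SCORES,
                 offset: int = 0):
        self.ref = ref
        self.read = read
        self.offset = offset  # added to all reported reference coordinates
        self._blocks: List[Tuple[int, int, int, int]] = []
        if len(ref) == len(read) and _hamming_capped(ref, read, 60) is not None:
            self._blocks = [(0, len(ref), 0, len(read))]
        else:
            aln = make_aligner(scores).align(ref, read)[0]
            ref_blocks, read_blocks = aln.aligned
            self._blocks = [
                (int(rs), int(re_), int(qs), int(qe))
                for (rs, re_), (qs, qe) in zip(ref_blocks, read_blocks)
            ]

    def events(self) -> List[AlnEvent]:
        out: List[AlnEvent] = []
        ref, read = self.ref, self.read
        prev_re, prev_qe = 0, 0
        for rs, re_, qs, qe in self._blocks:
            if rs > prev_re:
                out.append(_left_shift(ref, AlnEvent("deletion", prev_re, rs,
                                                     ref[prev_re:rs])))
            if qs > prev_qe:
                out.append(_left_shift(ref, AlnEvent("insertion", rs, rs,
                                                     read[prev_qe:qs])))
            # substitutions inside the aligned block, merged into runs
            run_start = None
            for i in range(re_ - rs):
                if ref[rs + i] != read[qs + i]:
                    if run_start is None:
                        run_start = i
                else:
                    if run_start is not None:
                        out.append(AlnEvent(
                            "substitution", rs + run_start, rs + i,
                            f"{ref[rs + run_start:rs + i]}>{read[qs + run_start:qs + i]}"))
                        run_start = None
            if run_start is not None:
                out.append(AlnEvent(
                    "substitution", rs + run_start, re_,
                    f"{ref[rs + run_start:re_]}>{read[qs + run_start:qe]}"))
            prev_re, prev_qe = re_, qe
        if prev_re < len(ref):
            out.append(_left_shift(ref, AlnEvent("deletion", prev_re, len(ref),
                                                 ref[prev_re:])))
        if prev_qe < len(read):
            out.append(AlnEvent("insertion", len(ref), len(ref), read[prev_qe:]))
        if self.offset:
            out = [AlnEvent(e.kind, e.start + self.offset, e.end + self.offset,
                            e.bases) for e in out]
        out.sort(key=lambda e: (e.start, e.kind))
        return out

    def base_at(self, ref_pos: int) -> Optional[str]:
        """Read base aligned to reference position, or None if gapped."""
        p = ref_pos - self.offset
        for rs, re_, qs, _qe in self._blocks:
            if rs <= p < re_:
                return self.read[qs + (p - rs)]
        return None

    def slice(self, ref_start: int, ref_end: int) -> Optional[str]:
        """Read substring aligned to a reference interval (insertions inside
        the interval included). None when either boundary falls in a read gap
        beyond the alignment."""
        s = self._project(ref_start - self.offset)
        e = self._project(ref_end - self.offset)
        if s is None or e is None or e < s:
            return None
        return self.read[s:e]

    def _project(self, p: int) -> Optional[int]:
        if not self._blocks:
            return None
        for rs, re_, qs, qe in self._blocks:
            if rs <= p < re_:
                return qs + (p - rs)
            if p < rs:
                return qs  # inside a deletion: clamp to block start
        rs, re_, qs, qe = self._blocks[-1]
        if p >= re_:
            return min(qe + (p - re_), len(self.read))
        return None


def _hamming_capped(a: str, b: str, cap: int) -> Optional[int]:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > cap:
                return None
    return n


def align_events(ref: str, read: str, scores: AlignScores = DEFAULT_SCORES,
                 offset: int = 0) -> List[AlnEvent]:
    return ReadAlignment(ref, read, scores, offset).events()
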