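"""Native target-region variant tracking in read pools.

Variants are catalogued as the exact target-region string (protospacer+PAM
with the variant applied, reference orientation). After indicator-pair
filtering and orientation normalisation, each read is assigned to at most
one catalogue entry by exact substring match, longest expected string
first; reads carrying the canonical string count as canonical and the rest
fall into an "other" bucket (de-novo edits included).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from .calling import IndicatorPair, filter_reads
from .locus import LocusModel
from .rounding import count_pct_cell, percentage


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantDef:
    id: str
    target_id: str
    expected: str       # full target-region string with the variant applied
    kind: str           # substitution | insertion | deletion | pam_substitution
    description: str = ""
    maybe_sequencing_error: bool = False


@dataclass
class VariantCounts:
    sample_id: str
    target_id: str
    total_reads: int
    reads_used: int
    counts: Dict[str, int]  # variant ids + "canonical" + "other"

    def pct(self, variant_id: str) -> float:
        if self.reads_used == 0:
            raise VariantError("no reads used")
        return float(percentage(self.counts.get(variant_id, 0), self.reads_used))

    def cell(self, variant_id: str) -> str:
        return count_pct_cell(self.counts.get(variant_id, 0), self.reads_used)


def _validate_catalog(catalog: Sequence[VariantDef], canonical: str):
    if not catalog:
        raise VariantError("empty variant catalog")
    seen = {}
    for v in catalog:
        if v.expected == canonical:
            raise VariantError(f"{v.id}: expected string equals canonical")
        if v.expected in seen:
            raise VariantError(
                f"{v.id} and {seen[v.expected]} share an expected string")
        seen[v.expected] = v.id


def track_variants(reads: Iterable, locus: LocusModel, target_id: str,
                   catalog: Sequence[VariantDef], pair: IndicatorPair,
                   sample_id: str = "sample") -> VariantCounts:
    canonical = locus.canonical_site_seq(target_id)
    _validate_catalog(catalog, canonical)
    ordered = sorted(enumerate(catalog),
                     key=lambda iv: (-len(iv[1].expected), iv[0]))
    reads = list(reads)
    used, _excluded = filter_reads(reads, pair)
    counts = {v.id: 0 for v in catalog}
    counts["canonical"] = 0
    counts["other"] = 0
    for _rid, seq in used:
        for _i, v in ordered:
            if v.expected in seq:
                counts[v.id] += 1
                break
        else:
            if canonical in seq:
                counts["canonical"] += 1
            else:
                counts["other"] += 1
    return VariantCounts(sample_id, target_id, total_reads=len(reads),
                         reads_used=len(used), counts=counts)


def enrichment_delta(line: VariantCounts, background: VariantCounts,
                     variant_id: str) -> float:
    """Percentage-point difference line - background for one variant."""
    for vc in (line, background):
        if variant_id not in vc.counts:
            raise VariantError(f"variant {variant_id!r} not tracked in "
                               f"sample {vc.sample_id!r}")
    return line.pct(variant_id) - background.pct(variant_id)


# ---------------------------------------------------------------------------
# catalogue construction helpers (variants defined relative to the canonical
# target-region string, PAM-relative positions as in the table footnotes)


def _site_coords(locus: LocusModel, target_id: str):
    t = locus.target(target_id)
    s, e = t.site_interval
    return t, s, e, locus.reference[s:e]


def substitution_variant(locus: LocusModel, target_id: str, vid: str,
                         position: int, alt: str,
                         description: str = "") -> VariantDef:
    """Substitution at an absolute reference coordinate inside the site."""
    t, s, e, canon = _site_coords(locus, target_id)
    if not s <= position < e:
        raise VariantError(f"{vid}: position outside target region")
    i = position - s
    if canon[i] == alt:
        raise VariantError(f"{vid}: substitution equals reference base")
    kind = "pam_substitution" if not (t.protospacer_interval[0] <= position
                                      < t.protospacer_interval[1]) else "substitution"
    return VariantDef(vid, target_id, canon[:i] + alt + canon[i + 1:], kind,
                      description)


def insertion_variant(locus: LocusModel, target_id: str, vid: str,
                      position: int, bases: str,
                      description: str = "") -> VariantDef:
    """Insertion at an inter-base reference coordinate inside the site."""
    _t, s, e, canon = _site_coords(locus, target_id)
    if not s < position < e:
        raise VariantError(f"{vid}: position outside target region")
    i = position - s
    return VariantDef(vid, target_id, canon[:i] + bases + canon[i:],
                      "insertion", description)


def deletion_variant(locus: LocusModel, target_id: str, vid: str,
                     start: int, size: int,
                     description: str = "") -> VariantDef:
    _t, s, e, canon = _site_coords(locus, target_id)
    if not (s <= start and start + size <= e):
        raise VariantError(f"{vid}: deletion outside target region")
    i = start - s
    return VariantDef(vid, target_id, canon[:i] + canon[i + size:],
                      "deletion", description)


def load_catalog(path) -> List[VariantDef]:
    """TSV columns: id, target, expected, class[, description]."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for row in reader:
            if not row or not any(c.strip() for c in row):
                continue
            desc = row[4] if len(row) > 4 else ""
            out.append(VariantDef(row[0], row[1], row[2].upper(), row[3], desc))
    return out


def save_catalog(catalog: Sequence[VariantDef], path):
    with open(path, "w") as fh:
        fh.write("id\ttarget\texpected\tclass\tdescription\n")
        for v in catalog:
            fh.write(f"{v.id}\t{v.target_id}\t{v.expected}\t{v.kind}\t"
                     f"{v.description}\n")
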