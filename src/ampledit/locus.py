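"""Multi-haplotype amplicon locus model: targets, primers, enzymes.

Coordinates are 0-based and half-open throughout; cut sites are inter-base
coordinates (the blunt Cas9 cut 3 nt 5' of the PAM). PAM-relative labels
(-1 adjacent to the PAM, P1..P3 inside it) are display-only.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

from .align import revcomp


class LocusError(ValueError):
    pass


@dataclass(frozen=True)
class TargetSite:
    id: str
    protospacer: str  # 20 nt, as read on the target strand
    pam: str          # 3 nt NGG, target strand
    strand: str       # '+' or '-'
    pam_start: int    # 0-based offset of the PAM's first base on the + strand
    cut_site: int     # inter-base coordinate on the + strand

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise LocusError(f"{self.id}: protospacer must be 20 nt")
        if not re.fullmatch("[ACGT]GG", self.pam):
            raise LocusError(f"{self.id}: PAM {self.pam!r} does not match NGG")
        if self.strand not in "+-":
            raise LocusError(f"{self.id}: strand must be '+' or '-'")

    @property
    def site_interval(self) -> tuple:
        """Protospacer+PAM footprint on the + strand (half-open)."""
        if self.strand == "+":
            return (self.pam_start - 20, self.pam_start + 3)
        return (self.pam_start - 2, self.pam_start + 21)

    @property
    def protospacer_interval(self) -> tuple:
        if self.strand == "+":
            return (self.pam_start - 20, self.pam_start)
        return (self.pam_start + 1, self.pam_start + 21)

    def window(self, radius: int) -> tuple:
        return (self.cut_site - radius, self.cut_site + radius)

    def pam_label(self, pos: int) -> str:
        """Display label for a + strand (inter-)base coordinate.

        Protospacer bases count -1..-20 away from the PAM; PAM bases are
        P1..P3. Inter-base coordinates (insertions) take the label of the
        base on their PAM-distal side.
        """
        if self.strand == "+":
            d = pos - self.pam_start
        else:
            d = self.pam_start - pos
        if d >= 0:
            return f"P{d + 1}" if d <= 2 else f"+{d - 2}"
        return str(d)


def locate_target(reference: str, target_id: str, protospacer: str, pam: str,
                  strand: str) -> TargetSite:
    """Find protospacer+PAM in the reference and derive coordinates."""
    protospacer = protospacer.upper()
    pam = pam.upper()
    if strand == "+":
        needle = protospacer + pam
        idx = reference.find(needle)
        if idx < 0:
            raise LocusError(
                f"target {target_id}: protospacer+PAM not found on + strand")
        if reference.find(needle, idx + 1) >= 0:
            raise LocusError(f"target {target_id}: multiple protospacer matches")
        pam_start = idx + 20
        cut = pam_start - 3
    else:
        needle = revcomp(protospacer + pam)
        idx = reference.find(needle)
        if idx < 0:
            raise LocusError(
                f"target {target_id}: protospacer+PAM not found on - strand")
        if reference.find(needle, idx + 1) >= 0:
            raise LocusError(f"target {target_id}: multiple protospacer matches")
        pam_start = idx + 2
        cut = idx + 6
    return TargetSite(target_id, protospacer, pam, strand, pam_start, cut)


@dataclass
class Haplotype:
    id: str
    snp_profile: Dict[int, str] = field(default_factory=dict)
    editable: Dict[str, bool] = field(default_factory=dict)

    def base_at(self, pos: int, reference: str) -> str:
        return self.snp_profile.get(pos, reference[pos])


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    labelled: bool = False


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        if len(self.recognition) < 4:
            raise LocusError(f"{self.name}: recognition site shorter than 4 nt")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise LocusError(f"{self.name}: cut offset outside recognition site")


@dataclass
class LocusModel:
    reference: str
    haplotypes: List[Haplotype] = field(default_factory=list)
    targets: List[TargetSite] = field(default_factory=list)
    variable_positions: List[int] = field(default_factory=list)
    primers: List[PrimerPair] = field(default_factory=list)
    enzymes: List[RestrictionEnzyme] = field(default_factory=list)

    def __post_init__(self):
        self.reference = self.reference.upper()
        if not self.haplotypes:
            self.haplotypes = [Haplotype("reference")]
        self._refresh_editability()
        self.validate()

    # -- lookups ----------------------------------------------------------
    def target(self, target_id: str) -> TargetSite:
        for t in self.targets:
            if t.id == target_id:
                return t
        raise LocusError(f"unknown target {target_id!r}")

    def haplotype(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.id == hap_id:
                return h
        raise LocusError(f"unknown haplotype {hap_id!r}")

    def primer_pair(self, name: str) -> PrimerPair:
        for p in self.primers:
            if p.name == name:
                return p
        raise LocusError(f"unknown primer pair {name!r}")

    def enzyme(self, name: str) -> RestrictionEnzyme:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise LocusError(f"unknown enzyme {name!r}")

    def canonical_site_seq(self, target_id: str) -> str:
        """Reference protospacer+PAM footprint in + strand orientation."""
        s, e = self.target(target_id).site_interval
        return self.reference[s:e]

    # -- validation -------------------------------------------------------
    def _refresh_editability(self):
        for hap in self.haplotypes:
            for t in self.targets:
                s, e = t.site_interval
                hap_site = "".join(hap.base_at(p, self.reference)
                                   for p in range(s, e))
                hap.editable[t.id] = hap_site == self.reference[s:e]

    def validate(self):
        n = len(self.reference)
        if n == 0:
            raise LocusError("empty reference")
        if sorted(set(self.variable_positions)) != list(self.variable_positions):
            raise LocusError("variable positions must be unique and sorted")
        for p in self.variable_positions:
            if not 0 <= p < n:
                raise LocusError(f"variable position {p} out of range")
        declared = set(self.variable_positions)
        for hap in self.haplotypes:
            for p, b in hap.snp_profile.items():
                if p not in declared:
                    raise LocusError(
                        f"haplotype {hap.id}: SNP position {p} not declared")
                if b not in "ACGT":
                    raise LocusError(f"haplotype {hap.id}: bad base {b!r}")
        ivs = sorted(t.site_interval for t in self.targets)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise LocusError("target sites overlap")
        for t in self.targets:
            s, e = t.site_interval
            if t.strand == "+":
                found = self.reference[s:e] == t.protospacer + t.pam
            else:
                found = self.reference[s:e] == revcomp(t.protospacer + t.pam)
            if not found:
                raise LocusError(
                    f"target {t.id}: protospacer+PAM absent at declared position")
        for pair in self.primers:
            if in_silico_pcr(self.reference, pair) == "":
                raise LocusError(f"primer pair {pair.name}: no product on reference")


# ---------------------------------------------------------------------------
# operations


def haplotype_sequence(locus: LocusModel, hap_id: str) -> str:
    hap = locus.haplotype(hap_id)
    seq = list(locus.reference)
    for pos, base in hap.snp_profile.items():
        seq[pos] = base
    return "".join(seq)


class AmbiguousPrimerError(LocusError):
    pass


def _find_once(template: str, needle: str, label: str) -> int:
    idx = template.find(needle)
    if idx < 0:
        return -1
    if template.find(needle, idx + 1) >= 0:
        raise AmbiguousPrimerError(f"{label}: multiple binding sites")
    return idx


def in_silico_pcr(template: str, pair: PrimerPair) -> str:
    """Exact-match PCR: product from forward start through reverse end
    (both primers included); empty string when either primer is absent."""
    template = template.upper()
    f = _find_once(template, pair.forward.upper(), f"{pair.name} forward")
    r = _find_once(template, revcomp(pair.reverse.upper()), f"{pair.name} reverse")
    if f < 0 or r < 0:
        return ""
    end = r + len(pair.reverse)
    if end <= f:
        return ""
    return template[f:end]


def _iupac_regex(recognition: str) -> re.Pattern:
    parts = []
    for ch in recognition.upper():
        opts = ambiguous_dna_values.get(ch, ch)
        parts.append(ch if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def digest(amplicon: str, enzyme: RestrictionEnzyme) -> List[int]:
    """Fragment lengths 5'->3' after cutting every top-strand site."""
    if not amplicon:
        raise LocusError("cannot digest an empty amplicon")
    amplicon = amplicon.upper()
    cuts = sorted({m.start() + enzyme.cut_offset
                   for m in _iupac_regex(enzyme.recognition).finditer(amplicon)
                   if 0 < m.start() + enzyme.cut_offset < len(amplicon)})
    bounds = [0] + cuts + [len(amplicon)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# configuration I/O
#
# A locus lives in a directory with a JSON config naming a single-record
# FASTA reference and one TSV per table:
#   haplotypes.tsv: hap_id  position  base   (position "." declares an
#                                             SNP-free haplotype)
#   targets.tsv:    id  protospacer  pam  strand
#   primers.tsv:    name  forward  reverse  labelled
#   enzymes.tsv:    name  recognition  cut_offset


def _read_tsv(path: Path) -> List[tuple]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        for lineno, row in enumerate(reader, start=2):
            if row and any(cell.strip() for cell in row):
                rows.append((lineno, row))
    return rows


def load_locus(config_path) -> LocusModel:
    config_path = Path(config_path)
    base = config_path.parent
    with open(config_path) as fh:
        cfg = json.load(fh)
    ref_path = base / cfg["reference"]
    records = list(SeqIO.parse(str(ref_path), "fasta"))
    if len(records) != 1:
        raise LocusError(f"{ref_path}: expected exactly one FASTA record")
    reference = str(records[0].seq).upper()

    targets = []
    for lineno, row in _read_tsv(base / cfg["targets"]):
        try:
            tid, protospacer, pam, strand = row[:4]
            targets.append(locate_target(reference, tid, protospacer, pam, strand))
        except (LocusError, ValueError) as exc:
            raise LocusError(f"{base / cfg['targets']}:{lineno}: {exc}") from exc

    haps: Dict[str, Haplotype] = {}
    positions = set()
    for lineno, row in _read_tsv(base / cfg["haplotypes"]):
        hap_id, pos, bp = row[0], row[1], row[2] if len(row) > 2 else "."
        hap = haps.setdefault(hap_id, Haplotype(hap_id))
        if pos == ".":
            continue
        p = int(pos)
        if not 0 <= p < len(reference):
            raise LocusError(
                f"{base / cfg['haplotypes']}:{lineno}: position {p} out of range")
        hap.snp_profile[p] = bp.upper()
        positions.add(p)

    variable_positions = cfg.get("variable_positions")
    if variable_positions is None:
        variable_positions = sorted(positions)

    primers = []
    if "primers" in cfg:
        for lineno, row in _read_tsv(base / cfg["primers"]):
            name, fwd, rev = row[:3]
            labelled = len(row) > 3 and row[3].strip().lower() in ("1", "true", "yes")
            primers.append(PrimerPair(name, fwd.upper(), rev.upper(), labelled))

    enzymes = []
    if "enzymes" in cfg:
        for lineno, row in _read_tsv(base / cfg["enzymes"]):
            try:
                enzymes.append(RestrictionEnzyme(row[0], row[1].upper(), int(row[2])))
            except (LocusError, ValueError) as exc:
                raise LocusError(f"{base / cfg['enzymes']}:{lineno}: {exc}") from exc

    return LocusModel(reference=reference, haplotypes=list(haps.values()) or [],
                      targets=targets, variable_positions=list(variable_positions),
                      primers=primers, enzymes=enzymes)


def save_locus(locus: LocusModel, out_dir) -> Path:
    """Write a loadable config directory; returns the config path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "reference.fa", "w") as fh:
        fh.write(">reference\n")
        for i in range(0, len(locus.reference), 70):
            fh.write(locus.reference[i:i + 70] + "\n")
    with open(out / "haplotypes.tsv", "w") as fh:
        fh.write("hap_id\tposition\tbase\n")
        for hap in locus.haplotypes:
            if not hap.snp_profile:
                fh.write(f"{hap.id}\t.\t.\n")
            for p in sorted(hap.snp_profile):
                fh.write(f"{hap.id}\t{p}\t{hap.snp_profile[p]}\n")
    with open(out / "targets.tsv", "w") as fh:
        fh.write("id\tprotospacer\tpam\tstrand\n")
        for t in locus.targets:
            fh.write(f"{t.id}\t{t.protospacer}\t{t.pam}\t{t.strand}\n")
    with open(out / "primers.tsv", "w") as fh:
        fh.write("name\tforward\treverse\tlabelled\n")
        for p in locus.primers:
            fh.write(f"{p.name}\t{p.forward}\t{p.reverse}\t{int(p.labelled)}\n")
    with open(out / "enzymes.tsv", "w") as fh:
        fh.write("name\trecognition\tcut_offset\n")
        for e in locus.enzymes:
            fh.write(f"{e.name}\t{e.recognition}\t{e.cut_offset}\n")
    cfg = {
        "reference": "reference.fa",
        "haplotypes": "haplotypes.tsv",
        "targets": "targets.tsv",
        "primers": "primers.tsv",
        "enzymes": "enzymes.tsv",
        "variable_positions": list(locus.variable_positions),
    }
    cfg_path = out / "locus.json"
    with open(cfg_path, "w") as fh:
        json.dump(cfg, fh, indent=1)
        fh.write("\n")
    return cfg_path
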