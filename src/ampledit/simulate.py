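"""Ground-truthed synthetic amplicon data.

Builds a demonstration multi-copy locus (two Cas9 targets with cut sites
100 bp apart on a 586 bp amplicon, 15 haplotypes over 36 variable
positions, one haplotype uneditable at both targets) and simulates edited
cell-lineage mixtures, short amplicon reads, Sanger-style clone reads, and
capillary-electrophoresis peak tables, each with a per-read truth table.

All randomness flows from one :func:`numpy.random.default_rng` stream so a
scenario is reproducible byte-for-byte from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .locus import (Haplotype, LocusModel, PrimerPair, RestrictionEnzyme,
                    haplotype_sequence, in_silico_pcr, locate_target)
from .align import revcomp

BASES = "ACGT"

DEFAULT_INDEL_DIST = {1: 0.40, -1: 0.30, -2: 0.10, -3: 0.05,
                      2: 0.05, -4: 0.05, 3: 0.05}


# ---------------------------------------------------------------------------
# demo locus


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def demo_locus(seed: int = 1) -> LocusModel:
    """586 bp two-target fixture locus.

    Geometry (all coordinates 0-based on the + strand):
      * sgRNA1: protospacer [197,217), PAM [217,220), cut at 214; a
        CAGCTG site at [211,217) is destroyed by indels at the cut.
      * sgRNA2: protospacer [297,317), PAM [317,320), cut at 314; a
        GGGACCC site at [310,317) cuts the amplicon into 314+272.
      * 36 variable positions including seed-region SNPs at 215 and 315
        carried by haplotype "copy6", which is therefore uneditable at
        both targets (the HDR-donor analogue).
    """
    attempt = 0
    while True:
        rng = np.random.default_rng((seed, attempt))
        seq = list(_random_seq(rng, 586))
        seq[211:217] = "CAGCTG"   # cut offset 3 -> cut at 214
        seq[217:220] = "TGG"      # sgRNA1 PAM
        seq[310:317] = "GGGACCC"  # cut offset 4 -> cut at 314
        seq[317:320] = "AGG"      # sgRNA2 PAM
        ref = "".join(seq)

        proto1, pam1 = ref[197:217], ref[217:220]
        proto2, pam2 = ref[297:317], ref[317:320]
        if ref.count("CAGCTG") != 1 or ref.count("GGGACCC") != 1:
            attempt += 1
            continue
        if ref.count(proto1 + pam1) != 1 or ref.count(proto2 + pam2) != 1:
            attempt += 1
            continue

        # variable positions: two target-seed SNP slots plus 34 flanking
        pool = (list(range(30, 184)) + list(range(245, 284))
                + list(range(345, 560)))
        flank = sorted(rng.choice(pool, size=34, replace=False).tolist())
        varpos = sorted(flank + [215, 315])

        def alt(p):
            choices = [b for b in BASES if b != ref[p]]
            return choices[rng.integers(len(choices))]

        haps = [Haplotype("copy1")]
        profiles = {frozenset()}
        ok = True
        for k in range(2, 16):
            profile: Dict[int, str] = {}
            if k == 6:
                profile[215] = alt(215)
                profile[315] = alt(315)
            m = int(rng.integers(3, 11))
            for p in rng.choice(flank, size=m, replace=False):
                profile[int(p)] = alt(int(p))
            key = frozenset(profile.items())
            if key in profiles:
                ok = False
                break
            profiles.add(key)
            haps.append(Haplotype(f"copy{k}", profile))
        if not ok:
            attempt += 1
            continue

        primers = [
            PrimerPair("CAPS", ref[0:22], revcomp(ref[564:586])),
            PrimerPair("CE1", ref[60:82], revcomp(ref[262:284]), labelled=True),
            PrimerPair("CE2", ref[246:268], revcomp(ref[440:462]), labelled=True),
        ]
        if any(ref.count(p.forward) != 1 or ref.count(revcomp(p.reverse)) != 1
               for p in primers):
            attempt += 1
            continue

        targets = [
            locate_target(ref, "sgRNA1", proto1, pam1, "+"),
            locate_target(ref, "sgRNA2", proto2, pam2, "+"),
        ]
        enzymes = [RestrictionEnzyme("PvuII", "CAGCTG", 3),
                   RestrictionEnzyme("KflI", "GGGACCC", 4)]
        locus = LocusModel(reference=ref, haplotypes=haps, targets=targets,
                           variable_positions=varpos, primers=primers,
                           enzymes=enzymes)
        assert targets[0].cut_site == 214 and targets[1].cut_site == 314
        assert not locus.haplotype("copy6").editable["sgRNA1"]
        assert not locus.haplotype("copy6").editable["sgRNA2"]
        return locus


# ---------------------------------------------------------------------------
# scenario configuration and ground-truth records


@dataclass(frozen=True)
class EditEvent:
    target_id: str
    kind: str                   # insertion|deletion|substitution|large_deletion|hdr_conversion
    size: int
    position: int               # 0-based; insertions use the inter-base coord
    inserted_bases: str = ""
    donor_hap: Optional[str] = None
    tract: Optional[Tuple[int, int]] = None

    def token(self) -> str:
        if self.kind == "insertion":
            return f"{self.position}:+{self.size}{self.inserted_bases}"
        if self.kind in ("deletion", "large_deletion"):
            return f"{self.position}:-{self.size}"
        if self.kind == "hdr_conversion":
            return f"hdr[{self.donor_hap}:{self.tract[0]}-{self.tract[1]}]"
        return f"{self.position}:sub"


@dataclass
class CopyState:
    hap_id: str
    events: List[EditEvent] = field(default_factory=list)


@dataclass
class CellLineage:
    id: str
    fraction: float
    copy_states: Dict[str, CopyState] = field(default_factory=dict)


@dataclass
class SimConfig:
    seed: int = 1
    dosage: Dict[str, int] = field(
        default_factory=lambda: {"copy1": 1, "copy2": 1, "copy4": 1, "copy6": 1})
    cut_prob: Dict[str, float] | float = 0.5
    indel_size_dist: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_DIST))
    large_del_prob: float = 0.0
    hdr_prob: float = 0.0
    donor_rule: str = "uneditable_both"   # or an explicit haplotype id
    error_rate: float = 0.0
    clone_error_rate: float = 0.0
    n_reads: int = 10000
    n_clone_reads: int = 80
    n_lineages: int = 1
    allocation: str = "multinomial"       # or "exact" (largest remainder)
    peak_scale: float = 30000.0

    def cut_prob_for(self, target_id: str) -> float:
        if isinstance(self.cut_prob, dict):
            return self.cut_prob.get(target_id, 0.0)
        return float(self.cut_prob)

    def validate(self):
        if not self.dosage or all(v == 0 for v in self.dosage.values()):
            raise ValueError("dosage must be positive for at least one haplotype")
        for p in ([self.large_del_prob, self.hdr_prob, self.error_rate,
                   self.clone_error_rate]
                  + (list(self.cut_prob.values())
                     if isinstance(self.cut_prob, dict) else [self.cut_prob])):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0,1]")
        total = sum(self.indel_size_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("indel size distribution must sum to 1")
        if 0 in self.indel_size_dist:
            raise ValueError("indel sizes must be nonzero")


# ---------------------------------------------------------------------------
# lineage simulation


def _choose_donor(cfg: SimConfig, locus: LocusModel) -> str:
    if cfg.donor_rule != "uneditable_both":
        return cfg.donor_rule
    for hap in locus.haplotypes:
        if hap.snp_profile and not any(hap.editable.values()):
            return hap.id
    raise ValueError("no haplotype uneditable at every target to act as donor")


def _draw_tract(rng: np.random.Generator, locus: LocusModel,
                window: Tuple[int, int]) -> Tuple[int, int]:
    """Tract containing the target window, endpoints uniform over the
    inter-SNP intervals flanking it."""
    ws, we = window
    lefts = [0] + [p + 1 for p in locus.variable_positions if p < ws]
    rights = [p for p in locus.variable_positions if p >= we] + [len(locus.reference)]
    return (int(lefts[rng.integers(len(lefts))]),
            int(rights[rng.integers(len(rights))]))


def simulate_lineages(cfg: SimConfig, locus: LocusModel,
                      rng: Optional[np.random.Generator] = None) -> List[CellLineage]:
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    if cfg.n_lineages == 1:
        fractions = [1.0]
    else:
        fractions = rng.dirichlet(np.ones(cfg.n_lineages)).tolist()
    donor = _choose_donor(cfg, locus) if cfg.hdr_prob > 0 else None
    sizes = sorted(cfg.indel_size_dist)
    size_p = np.array([cfg.indel_size_dist[s] for s in sizes], dtype=float)
    size_p /= size_p.sum()

    lineages = []
    for li, frac in enumerate(fractions):
        states: Dict[str, CopyState] = {}
        for hap_id, dose in cfg.dosage.items():
            hap = locus.haplotype(hap_id)
            for c in range(dose):
                key = f"{hap_id}/{c}"
                events: List[EditEvent] = []
                editable = dict(hap.editable)
                if (all(editable.get(t.id, False) for t in locus.targets)
                        and rng.random() < cfg.large_del_prob):
                    cut1 = min(t.cut_site for t in locus.targets)
                    cut2 = max(t.cut_site for t in locus.targets)
                    events.append(EditEvent(
                        "+".join(t.id for t in locus.targets),
                        "large_deletion", cut2 - cut1, cut1))
                else:
                    for t in locus.targets:
                        if not editable.get(t.id, False):
                            continue
                        if rng.random() >= cfg.cut_prob_for(t.id):
                            continue
                        if donor is not None and rng.random() < cfg.hdr_prob:
                            tract = _draw_tract(rng, locus, t.site_interval)
                            events.append(EditEvent(
                                t.id, "hdr_conversion", 0, tract[0],
                                donor_hap=donor, tract=tract))
                            # conversion may import the donor's protective
                            # SNPs at the other target as well
                            dhap = locus.haplotype(donor)
                            for u in locus.targets:
                                s, e = u.site_interval
                                if tract[0] <= s and e <= tract[1]:
                                    editable[u.id] = dhap.editable[u.id]
                        else:
                            size = int(sizes[rng.choice(len(sizes), p=size_p)])
                            cut = t.cut_site
                            if size > 0:
                                bases = _random_seq(rng, size)
                                events.append(EditEvent(t.id, "insertion", size,
                                                        cut, bases))
                            else:
                                s = -size
                                start = cut - (s - s // 2)
                                events.append(EditEvent(t.id, "deletion", s, start))
                states[key] = CopyState(hap_id, events)
        lineages.append(CellLineage(f"lineage{li}", frac, states))
    return lineages


def apply_events(locus: LocusModel, state: CopyState) -> str:
    """Sequence of one (possibly edited) gene copy."""
    seq = haplotype_sequence(locus, state.hap_id)
    for ev in state.events:
        if ev.kind == "hdr_conversion":
            donor_seq = haplotype_sequence(locus, ev.donor_hap)
            s, e = ev.tract
            seq = seq[:s] + donor_seq[s:e] + seq[e:]
    indels = [ev for ev in state.events
              if ev.kind in ("insertion", "deletion", "large_deletion")]
    for ev in sorted(indels, key=lambda e: e.position, reverse=True):
        if ev.kind == "insertion":
            seq = seq[:ev.position] + ev.inserted_bases + seq[ev.position:]
        else:
            seq = seq[:ev.position] + seq[ev.position + ev.size:]
    return seq


# ---------------------------------------------------------------------------
# read generation


def _truth_class(locus: LocusModel, state: CopyState, target_id: str) -> str:
    for ev in state.events:
        if ev.kind == "large_deletion":
            return "edited"
        if ev.kind == "hdr_conversion":
            s, e = locus.target(target_id).site_interval
            if ev.tract[0] <= s and e <= ev.tract[1]:
                return "hdr"
        elif ev.target_id == target_id:
            return "edited"
    if not locus.haplotype(state.hap_id).editable.get(target_id, True):
        return "variant"
    return "wt"


def _molecule_classes(lineages: Sequence[CellLineage], locus: LocusModel):
    """Flatten lineages into (lineage, copy_key, state, sequence, weight)."""
    classes = []
    for lin in lineages:
        if not lin.copy_states:
            continue
        w = lin.fraction / len(lin.copy_states)
        for key, state in lin.copy_states.items():
            classes.append((lin, key, state, apply_events(locus, state), w))
    weights = np.array([c[4] for c in classes], dtype=float)
    weights /= weights.sum()
    return classes, weights


def _allocate(rng: np.random.Generator, n: int, weights: np.ndarray,
              mode: str) -> np.ndarray:
    if mode == "multinomial":
        return rng.multinomial(n, weights)
    # largest-remainder exact allocation
    raw = weights * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for p in rng.choice(len(chars), size=n_err, replace=False):
        choices = [b for b in BASES if b != chars[p]]
        chars[p] = choices[rng.integers(3)]
    return "".join(chars)


def _generate(lineages, cfg, locus, rng, n, error_rate, id_prefix):
    classes, weights = _molecule_classes(lineages, locus)
    counts = _allocate(rng, n, weights, cfg.allocation)
    order = np.repeat(np.arange(len(classes)), counts)
    rng.shuffle(order)
    records, truth_rows = [], []
    for i, ci in enumerate(order):
        lin, key, state, seq, _w = classes[ci]
        rid = f"{id_prefix}{i:06d}"
        records.append((rid, _add_errors(rng, seq, error_rate)))
        row = {
            "read_id": rid,
            "lineage_id": lin.id,
            "hap_id": state.hap_id,
            "copy_id": key,
            "events": ";".join(ev.token() for ev in state.events) or ".",
            "large_deletion": any(ev.kind == "large_deletion"
                                  for ev in state.events),
        }
        for t in locus.targets:
            row[f"class_{t.id}"] = _truth_class(locus, state, t.id)
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return records, truth


def generate_reads(lineages: Sequence[CellLineage], cfg: SimConfig,
                   locus: LocusModel,
                   rng: Optional[np.random.Generator] = None,
                   out_fastq=None, out_truth=None):
    """Short-read pool (full-amplicon FASTQ) with its ground-truth table."""
    rng = rng or np.random.default_rng(cfg.seed)
    records, truth = _generate(lineages, cfg, locus, rng, cfg.n_reads,
                               cfg.error_rate, "read")
    if out_fastq is not None:
        with open(out_fastq, "w") as fh:
            for rid, seq in records:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    if out_truth is not None:
        truth.to_csv(out_truth, sep="\t", index=False)
    return records, truth


def generate_clone_reads(lineages: Sequence[CellLineage], cfg: SimConfig,
                         locus: LocusModel,
                         rng: Optional[np.random.Generator] = None,
                         out_fasta=None, out_truth=None):
    """Sanger-clone style reads: error-free by default, FASTA output."""
    rng = rng or np.random.default_rng(cfg.seed)
    records, truth = _generate(lineages, cfg, locus, rng, cfg.n_clone_reads,
                               cfg.clone_error_rate, "clone")
    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
    if out_truth is not None:
        truth.to_csv(out_truth, sep="\t", index=False)
    return records, truth


def generate_peak_table(lineages: Sequence[CellLineage], locus: LocusModel,
                        target_id: str, wt_size: int,
                        scale: float = 30000.0,
                        sample_id: str = "sample") -> pd.DataFrame:
    """One CE peak per net-indel class, heights proportional to abundance."""
    classes, weights = _molecule_classes(lineages, locus)
    by_net: Dict[int, float] = {}
    for (lin, key, state, seq, _w), w in zip(classes, weights):
        net = 0
        for ev in state.events:
            if ev.kind == "insertion" and ev.target_id == target_id:
                net += ev.size
            elif ev.kind == "deletion" and ev.target_id == target_id:
                net -= ev.size
            elif ev.kind == "large_deletion":
                net -= ev.size
        by_net[net] = by_net.get(net, 0.0) + w
    top = max(by_net.values())
    rows = [{"sample": sample_id, "dye": "6-FAM", "size": float(wt_size + net),
             "height": by_net[net] / top * scale}
            for net in sorted(by_net)]
    return pd.DataFrame(rows, columns=["sample", "dye", "size", "height"])
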