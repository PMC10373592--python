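"""Study-level summary statistics and table rendering.

Efficiency/recovery/reduction percentages use exact rational arithmetic and
half-up rounding at printed precision (one decimal, except the integer
editing-efficiency column). One-way ANOVA with the balanced Tukey HSD and a
compact letter display covers the group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .rounding import count_pct_cell, percentage, render_pct, round_half_up


class ReportError(ValueError):
    pass


@dataclass
class ExperimentTally:
    experiment: str
    explants: int
    transgenic: int
    edited: int
    uniform: int
    mosaic: int
    visible_phenotype: int = 0

    def __post_init__(self):
        if self.uniform + self.mosaic != self.edited:
            raise ReportError("uniform + mosaic must equal edited lines")
        if not self.edited <= self.transgenic <= self.explants:
            raise ReportError("require edited <= transgenic <= explants")


def transformation_efficiency(transgenic: int, explants: int) -> float:
    if explants <= 0:
        raise ReportError("explants must be positive")
    return round_half_up(percentage(transgenic, explants), 1)


def mean_transformation_efficiency(experiments: Sequence[Tuple[int, int]]) -> float:
    """Mean of per-experiment efficiencies (exact before final rounding)."""
    if not experiments:
        raise ReportError("no experiments")
    effs = [percentage(t, e) for t, e in experiments]
    return round_half_up(sum(effs, Fraction(0)) / len(effs), 1)


def editing_efficiency(edited: int, transgenic: int) -> int:
    if transgenic <= 0:
        raise ReportError("transgenic count must be positive")
    return round_half_up(percentage(edited, transgenic), 0)


def uniformity_rates(uniform: int, mosaic: int) -> Tuple[float, float]:
    edited = uniform + mosaic
    if edited <= 0:
        raise ReportError("no edited lines")
    return (round_half_up(percentage(uniform, edited), 1),
            round_half_up(percentage(mosaic, edited), 1))


def progeny_recovery_rate(uniform_progeny: int, germinated: int) -> float:
    if germinated <= 0:
        raise ReportError("germinated count must be positive")
    return round_half_up(percentage(uniform_progeny, germinated), 1)


def percent_reduction(reference_mean: float, line_mean: float) -> float:
    if reference_mean <= 0:
        raise ReportError("reference mean must be positive")
    ref = Fraction(str(reference_mean))
    line = Fraction(str(line_mean))
    return round_half_up(100 * (ref - line) / ref, 1)


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey HSD (balanced design)


@dataclass
class GroupMeasurements:
    label: str
    values: List[float]

    def __post_init__(self):
        if len(self.values) < 2:
            raise ReportError(f"group {self.label}: need n >= 2")


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    hsd: float
    means: Dict[str, float]
    letters: Dict[str, str]
    df_between: int
    df_within: int
    ms_within: float


def anova_tukey(groups: Sequence[GroupMeasurements],
                alpha: float = 0.05) -> AnovaResult:
    if len(groups) < 2:
        raise ReportError("need at least two groups")
    ns = {len(g.values) for g in groups}
    if len(ns) != 1:
        raise ReportError("unequal group sizes: balanced Tukey HSD only; "
                          "use an unbalanced post hoc method instead")
    n = ns.pop()
    k = len(groups)
    data = np.array([g.values for g in groups], dtype=float)
    means = data.mean(axis=1)
    grand = data.mean()
    ss_between = n * float(((means - grand) ** 2).sum())
    ss_within = float(((data - means[:, None]) ** 2).sum())
    df_between = k - 1
    df_within = k * (n - 1)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = 0.0 if ms_between == 0 else float("inf")
        p_value = 1.0 if ms_between == 0 else 0.0
        hsd = 0.0
    else:
        f_stat = ms_between / ms_within
        p_value = float(stats.f.sf(f_stat, df_between, df_within))
        q = float(stats.studentized_range.ppf(1 - alpha, k, df_within))
        hsd = q * float(np.sqrt(ms_within / n))
    mean_map = {g.label: float(m) for g, m in zip(groups, means)}
    letters = _compact_letters(mean_map, hsd)
    return AnovaResult(f_stat, p_value, hsd, mean_map, letters,
                       df_between, df_within, ms_within)


def _compact_letters(means: Dict[str, float], hsd: float) -> Dict[str, str]:
    """Compact letter display: groups within HSD of each other share a
    letter. With a single threshold the 'not distinguishable' graph on
    mean-sorted groups is an interval graph, so its maximal cliques are
    maximal runs of consecutive groups whose mean spread is <= HSD."""
    order = sorted(means, key=means.get, reverse=True)
    runs = []
    i = 0
    while i < len(order):
        j = i
        while (j + 1 < len(order)
               and abs(means[order[i]] - means[order[j + 1]]) <= hsd):
            j += 1
        runs.append((i, j))
        i += 1
    # keep only maximal runs
    maximal = [r for r in runs
               if not any(o[0] <= r[0] and r[1] <= o[1] and o != r for o in runs)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in means}
    for li, (s, e) in enumerate(maximal):
        for g in order[s:e + 1]:
            letters[g] += alphabet[li % len(alphabet)]
    return letters


# ---------------------------------------------------------------------------
# rendering


def render_tally_table(tallies: Sequence[ExperimentTally]) -> str:
    header = ("experiment\texplants\ttransgenic\ttransformation_pct\t"
              "edited\tediting_pct\tuniform\tuniform_pct\tmosaic\tmosaic_pct\n")
    lines = [header]
    for t in tallies:
        if t.edited > 0:
            u_pct, m_pct = uniformity_rates(t.uniform, t.mosaic)
            u_pct, m_pct = f"{u_pct:.1f}", f"{m_pct:.1f}"
        else:
            u_pct = m_pct = "NA"
        lines.append(
            f"{t.experiment}\t{t.explants}\t{t.transgenic}\t"
            f"{transformation_efficiency(t.transgenic, t.explants):.1f}\t"
            f"{t.edited}\t{editing_efficiency(t.edited, t.transgenic)}\t"
            f"{t.uniform}\t{u_pct}\t{t.mosaic}\t{m_pct}\n")
    return "".join(lines)


def render_site_table(summaries: Sequence) -> str:
    header = ("target\ttotal_reads\treads_used\tindel_reads\tindel_pct\t"
              "frameshift_reads\tframeshift_pct\n")
    lines = [header]
    for s in summaries:
        ip = render_pct(s.indel_pct) if s.indel_pct is not None else "NA"
        fp = (render_pct(s.frameshift_pct)
              if s.frameshift_pct is not None else "NA")
        lines.append(f"{s.target_id}\t{s.total_reads}\t{s.reads_used}\t"
                     f"{s.indel_reads}\t{ip}\t{s.frameshift_reads}\t{fp}\n")
    return "".join(lines)


def render_variant_table(counts_list: Sequence, variant_ids: Sequence[str]) -> str:
    header = ("sample\ttotal_reads\treads_used\t"
              + "\t".join(variant_ids) + "\n")
    lines = [header]
    for vc in counts_list:
        cells = "\t".join(vc.cell(v) for v in variant_ids)
        lines.append(f"{vc.sample_id}\t{vc.total_reads}\t{vc.reads_used}\t"
                     f"{cells}\n")
    return "".join(lines)


def render_reports(out_dir, tallies: Sequence[ExperimentTally] = (),
                   site_summaries: Sequence = (),
                   variant_counts: Sequence = (),
                   variant_ids: Sequence[str] = ()) -> Dict[str, Path]:
    """Write the TSV report documents; header-only files for empty inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    docs = {
        "tallies.tsv": render_tally_table(tallies),
        "site_summaries.tsv": render_site_table(site_summaries),
        "variant_counts.tsv": render_variant_table(variant_counts, variant_ids),
    }
    paths = {}
    for name, text in docs.items():
        p = out / name
        p.write_text(text)
        paths[name] = p
    return paths
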