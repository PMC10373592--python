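"""Capillary-electrophoresis peak-table genotyping.

A peak is wild type when its size lies within a tolerance of the expected
WT product size; everything else is mutant. Mutation frequency is
(sum mutant peak heights) / (sum mutant and WT peak heights) * 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import pandas as pd

from .rounding import round_half_up


class CeError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    size: float
    height: float
    dye: str = "6-FAM"

    def __post_init__(self):
        if self.size <= 0:
            raise CeError(f"non-positive peak size {self.size}")
        if self.height < 0:
            raise CeError(f"negative peak height {self.height}")


@dataclass(frozen=True)
class ClassifiedPeak:
    peak: Peak
    is_wt: bool
    net_indel: int  # size - expected WT size, rounded to the nearest integer


def read_peak_table(path) -> pd.DataFrame:
    """TSV export with columns sample, dye, size, height."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "dye", "size", "height"} - set(df.columns)
    if missing:
        raise CeError(f"peak table missing columns: {sorted(missing)}")
    return df


def peaks_from_table(table: pd.DataFrame,
                     sample_id: Optional[str] = None) -> List[Peak]:
    df = table
    if sample_id is not None:
        df = df[df["sample"] == sample_id]
    return [Peak(float(r.size), float(r.height), str(r.dye))
            for r in df.itertuples()]


def classify_peaks(peaks: Sequence[Peak], expected_wt_size: float,
                   tolerance: float = 0.5,
                   noise_floor: float = 0.01) -> List[ClassifiedPeak]:
    if not peaks:
        raise CeError("no peaks to classify")
    cutoff = noise_floor * max(p.height for p in peaks)
    kept = [p for p in peaks if p.height >= cutoff]
    if not kept:
        warnings.warn("all peaks below the noise floor")
        return []
    return [ClassifiedPeak(p, abs(p.size - expected_wt_size) <= tolerance,
                           round_half_up(p.size - expected_wt_size, 0))
            for p in kept]


@dataclass
class CeResult:
    sample_id: str
    target_id: str
    wt_height_sum: float
    mutant_height_sum: float
    mutation_frequency_pct: Optional[float]
    peaks: List[ClassifiedPeak] = field(default_factory=list)

    @property
    def mutant_net_indels(self) -> frozenset:
        return frozenset(cp.net_indel for cp in self.peaks if not cp.is_wt)


def mutation_frequency(classified: Sequence[ClassifiedPeak],
                       sample_id: str = "", target_id: str = "") -> CeResult:
    if not classified:
        raise CeError("no classified peaks")
    wt = sum(cp.peak.height for cp in classified if cp.is_wt)
    mut = sum(cp.peak.height for cp in classified if not cp.is_wt)
    total = wt + mut
    freq = round_half_up(100.0 * mut / total, 1) if total > 0 else None
    return CeResult(sample_id, target_id, wt, mut, freq, list(classified))


def assess_uniformity(results: Sequence[CeResult], freq_tol: float = 5.0,
                      require_same_peaks: bool = True) -> str:
    """'uniform' when all subsamples agree in frequency (and, optionally,
    in their mutant peak sets); 'chimeric' otherwise."""
    if len(results) < 2:
        raise CeError("need at least two subsamples to assess uniformity")
    freqs = [r.mutation_frequency_pct for r in results]
    if any(f is None for f in freqs):
        raise CeError("subsample with undefined mutation frequency")
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            if abs(freqs[i] - freqs[j]) > freq_tol:
                return "chimeric"
            if (require_same_peaks and results[i].mutant_net_indels
                    != results[j].mutant_net_indels):
                return "chimeric"
    return "uniform"
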