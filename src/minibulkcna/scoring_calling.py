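"""Genome-instability scoring (CNAscore) and gain/loss calling.

CNAscore summarizes one sample's segment profile as a sum over the 24
chromosomes of two components:

* a jump component — the mean absolute difference between successive
  segment means within the chromosome (chromosomal instability), and
* a deviation component — half the absolute difference between the mean
  segment copy number and the chromosome's neutral ploidy (``norm``: 2 for
  autosomes and female X, 1 for male X/Y, 0 for female Y).

``mean(s_i)`` in the deviation component is the unweighted mean over
segments by default; a length-weighted variant is available because a short
focal event otherwise carries the same weight as a whole-chromosome
segment.  Chromosomes absent from the data contribute 0.

Calls: on diploid chromosomes a segment is a gain when its mean copy number
exceeds 2.4 and a loss when it is below 1.7; on haploid chromosomes (male
X/Y) gain above 1.5 and loss below 0.5.  All four bounds are strict and
configurable.  Chromosomes with neutral copy number 0 are never called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CHROMOSOMES
from .preprocess import expected_ploidy
from .segmentation import SegmentProfile


class ScoringError(ValueError):
    pass


@dataclass
class ChromScore:
    jump: float
    deviation: float

    @property
    def total(self) -> float:
        return self.jump + self.deviation


@dataclass
class CNAScoreResult:
    sample_id: str
    per_chrom: dict[str, ChromScore]
    total: float


@dataclass
class CallingConfig:
    diploid_gain: float = 2.4
    diploid_loss: float = 1.7
    haploid_gain: float = 1.5
    haploid_loss: float = 0.5
    min_call_bins: int = 5

    def __post_init__(self):
        if self.diploid_gain <= self.diploid_loss or self.haploid_gain <= self.haploid_loss:
            raise ScoringError("gain threshold must exceed loss threshold")


@dataclass
class CNACall:
    sample_id: str
    chrom: str
    start_bin: int
    end_bin: int
    s: float
    state: str  # "gain" | "loss"
    ploidy_class: str  # "diploid" | "haploid"


def cna_score(
    segments: SegmentProfile, sex: str, length_weighted: bool = False
) -> CNAScoreResult:
    """Per-chromosome jump + deviation components and their genome total."""
    by_chrom = segments.by_chrom()
    if not any(by_chrom.values()):
        raise ScoringError("empty profile: no segments")
    per_chrom: dict[str, ChromScore] = {}
    total = 0.0
    for chrom in CHROMOSOMES:
        segs = by_chrom.get(chrom)
        if not segs:
            continue
        s = np.array([seg.mean for seg in segs])
        jump = float(np.mean(np.abs(np.diff(s)))) if len(s) >= 2 else 0.0
        if length_weighted:
            w = np.array([seg.n_bins for seg in segs], dtype=float)
            mean_s = float(np.average(s, weights=w))
        else:
            mean_s = float(np.mean(s))
        norm = expected_ploidy(sex, chrom)
        dev = 0.5 * abs(mean_s - norm)
        per_chrom[chrom] = ChromScore(jump=jump, deviation=dev)
        total += jump + dev
    return CNAScoreResult(sample_id=segments.sample_id, per_chrom=per_chrom, total=total)


def call_segments(
    segments: SegmentProfile, sex: str, config: CallingConfig | None = None
) -> list[CNACall]:
    """Threshold segment means into gain/loss calls by ploidy class."""
    config = config or CallingConfig()
    calls: list[CNACall] = []
    for seg in segments.segments:
        norm = expected_ploidy(sex, seg.chrom)
        if norm == 0:
            continue
        if seg.n_bins < config.min_call_bins:
            continue
        if norm == 2:
            gain_t, loss_t, klass = config.diploid_gain, config.diploid_loss, "diploid"
        else:
            gain_t, loss_t, klass = config.haploid_gain, config.haploid_loss, "haploid"
        state = None
        if seg.mean > gain_t:
            state = "gain"
        elif seg.mean < loss_t:
            state = "loss"
        if state is not None:
            calls.append(
                CNACall(
                    sample_id=segments.sample_id,
                    chrom=seg.chrom,
                    start_bin=seg.start_bin,
                    end_bin=seg.end_bin,
                    s=seg.mean,
                    state=state,
                    ploidy_class=klass,
                )
            )
    return calls


def merge_adjacent_calls(calls: list[CNACall]) -> list[CNACall]:
    """Merge contiguous same-direction calls into CNA regions.

    CBS may fragment one biological event into adjacent segments of the
    same state (its permutation test splits a fraction alpha of flat
    stretches by construction); for reporting and region matching, abutting
    calls on one chromosome with the same state are combined, with a
    bin-length-weighted mean copy number.
    """
    merged: list[CNACall] = []
    for c in sorted(calls, key=lambda c: (c.sample_id, CHROMOSOMES.index(c.chrom), c.start_bin)):
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.sample_id == c.sample_id
            and last.chrom == c.chrom
            and last.state == c.state
            and last.end_bin == c.start_bin
        ):
            w1, w2 = last.end_bin - last.start_bin, c.end_bin - c.start_bin
            merged[-1] = CNACall(
                sample_id=last.sample_id,
                chrom=last.chrom,
                start_bin=last.start_bin,
                end_bin=c.end_bin,
                s=(last.s * w1 + c.s * w2) / (w1 + w2),
                state=last.state,
                ploidy_class=last.ploidy_class,
            )
        else:
            merged.append(c)
    return merged


def sample_status(calls: list[CNACall]) -> bool:
    """True iff the sample has at least one gain/loss call."""
    return len(calls) > 0


def patient_status(
    lesional_positive: list[bool], min_positive_samples: int = 1
) -> bool | None:
    """Aggregate per-sample CNA status to patient level.

    ``lesional_positive`` holds the per-sample status of the patient's
    QC-passed *lesional* samples (normal-tissue samples must not be
    included).  Returns True when at least ``min_positive_samples`` of them
    are positive, False otherwise, and None ("indeterminate") when the
    patient has no QC-passed lesional sample at all.
    """
    if len(lesional_positive) == 0:
        return None
    return sum(bool(v) for v in lesional_positive) >= min_positive_samples


def calls_to_frame(calls: list[CNACall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "start_bin": c.start_bin,
                "end_bin": c.end_bin,
                "s": c.s,
                "state": c.state,
                "ploidy_class": c.ploidy_class,
            }
            for c in calls
        ],
        columns=["sample_id", "chrom", "start_bin", "end_bin", "s", "state", "ploidy_class"],
    )


def scores_to_frame(results: list[CNAScoreResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id, "total": r.total}
        for chrom, cs in r.per_chrom.items():
            row[f"chr{chrom}_jump"] = cs.jump
            row[f"chr{chrom}_dev"] = cs.deviation
        rows.append(row)
    return pd.DataFrame(rows)
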