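"""Sample quality control: MAPD and the inclusion rule.

MAPD (median absolute pairwise difference) is the median of |x_{i+1} - x_i|
over bins in genome order.  Because adjacent-bin differences difference away
any slowly varying true copy-number signal, MAPD measures technical noise
while staying robust to genuine CNA steps.  A sample is considered qualified
when it has more than 100 000 mapped reads and MAPD < 0.23 (both bounds
strict; both configurable).

By default, successive pairs that span a chromosome boundary are excluded:
the two bins are not genomic neighbours, and X/Y ploidy steps would inject
signal into a noise statistic.  ``cross_chromosome=True`` restores the
literal genome-wide reading.  MAPD is computed on linear copy-number values
as defined; ``log2=True`` gives the log2(x/2)-scale variant for
comparability with platforms that quote the 0.23 convention on log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import RatioProfile

READ_FLOOR = 100_000
MAPD_CEILING = 0.23

# MAPD of i.i.d. Gaussian noise of sd sigma is sqrt(2)*0.6745*sigma;
# this factor converts MAPD back to a noise-sd estimate.
MAPD_TO_SD = float(np.sqrt(2.0) * 0.674489750196082)


class QCError(ValueError):
    pass


@dataclass
class QCMetrics:
    sample_id: str
    mapped_reads: int
    mapd: float
    passed: bool
    reasons: list[str] = field(default_factory=list)


def compute_mapd(
    profile: RatioProfile,
    cross_chromosome: bool = False,
    log2: bool = False,
) -> float:
    """Median absolute successive difference of the normalized profile.

    Differences are taken over masked-in bins in genome order; pairs that
    straddle a chromosome boundary are excluded unless
    ``cross_chromosome=True``.
    """
    mask = profile.mask
    if int(mask.sum()) < 2:
        raise QCError("need >= 2 masked-in bins to compute MAPD")
    x = profile.x[mask]
    if log2:
        x = np.log2(np.maximum(x, 1e-6) / 2.0)
    diffs = np.abs(np.diff(x))
    if not cross_chromosome:
        chrom = profile.bins.chrom[mask]
        same = chrom[1:] == chrom[:-1]
        diffs = diffs[same]
    if diffs.size == 0:
        raise QCError("no successive within-chromosome bin pairs")
    return float(np.median(diffs))


def mapd_to_sd(mapd: float) -> float:
    """Noise-sd estimate implied by a MAPD value (Gaussian model)."""
    return mapd / MAPD_TO_SD


def qc_filter(
    sample_id: str,
    mapped_reads: int,
    mapd: float,
    read_floor: int = READ_FLOOR,
    mapd_ceiling: float = MAPD_CEILING,
) -> QCMetrics:
    """Apply the inclusion rule: mapped_reads > read_floor and mapd < ceiling.

    Both inequalities are strict; a sample sitting exactly on either
    boundary fails.
    """
    if not np.isfinite(mapd) or mapd < 0 or mapped_reads < 0:
        raise QCError("mapped_reads and mapd must be finite and nonnegative")
    reasons = []
    if not mapped_reads > read_floor:
        reasons.append("mapped_reads")
    if not mapd < mapd_ceiling:
        reasons.append("mapd")
    return QCMetrics(
        sample_id=sample_id,
        mapped_reads=int(mapped_reads),
        mapd=float(mapd),
        passed=not reasons,
        reasons=reasons,
    )
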