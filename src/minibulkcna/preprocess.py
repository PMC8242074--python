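"""GC normalization of bin counts into copy-number ratio profiles.

Shallow-WGS read counts carry a smooth multiplicative bias in the bin's GC
fraction.  Following standard practice for this assay class the bias is
estimated by locally weighted regression (LOWESS) of count against GC over
usable autosomal bins, each count is divided by its fitted value, and the
resulting ratios are rescaled so the autosomal median sits at the diploid
baseline of 2 copies.  The median anchor assumes a mostly-diploid genome,
which holds for the benign fibro-osseous lesions this pipeline targets.

Normalization is strictly per-sample; no panel of normals is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genome_io import AUTOSOMES, GenomeBins, BinCounts, normalize_chrom

MIN_USABLE_BINS = 200


class PreprocessError(ValueError):
    pass


@dataclass
class RatioProfile:
    """Per-bin normalized copy-number values for one sample.

    ``x`` is on linear copy-number scale (diploid baseline 2), aligned to
    the bin set; ``mask`` flags bins whose count basis is usable.  Masked-out
    bins hold NaN.
    """

    sample_id: str
    bins: GenomeBins
    x: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.bins.n_bins
        if len(self.x) != n or len(self.mask) != n:
            raise PreprocessError("profile length does not match bin set")
        good = self.x[self.mask]
        if np.any(~np.isfinite(good)) or np.any(good < 0):
            raise PreprocessError("x must be finite and >= 0 on masked-in bins")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.bins.chrom,
                "start": self.bins.start,
                "end": self.bins.end,
                "x": self.x,
                "mask": self.mask.astype(int),
            }
        )


def expected_ploidy(sex: str, chrom: str) -> int:
    """Neutral copy number of a chromosome given sex (2, 1 or 0).

    Autosomes are 2; male X and Y are 1; female X is 2 and Y is 0.  For
    unknown sex, X is treated as diploid with a logged caveat and Y is
    reported as 0 (masked out downstream).
    """
    c = normalize_chrom(chrom)
    if sex not in ("male", "female", "unknown"):
        raise PreprocessError(f"unknown sex: {sex!r}")
    if c in AUTOSOMES:
        return 2
    if c == "X":
        if sex == "male":
            return 1
        if sex == "unknown":
            warnings.warn("sex unknown: treating X as diploid")
        return 2
    # Y
    if sex == "male":
        return 1
    if sex == "unknown":
        warnings.warn("sex unknown: masking Y (neutral copy number 0)")
    return 0


def gc_normalize(
    counts: BinCounts,
    bins: GenomeBins,
    span: float = 0.3,
    iterations: int = 3,
) -> RatioProfile:
    """LOWESS-normalize bin counts against GC and scale to diploid baseline.

    The local regression of count on GC is fitted over usable autosomal
    bins (``iterations`` robustifying passes, smoothing span ``span``) and
    evaluated at every bin's GC by interpolation.  Counts are divided by the
    fitted value; bins with non-positive fit or zero weight are masked out;
    the ratios are scaled so the median over masked-in autosomal bins is
    exactly 2.
    """
    if not 0 < span <= 1:
        raise PreprocessError("span must be in (0, 1]")
    c = np.asarray(counts.counts, dtype=float)
    if len(c) != bins.n_bins:
        raise PreprocessError("count vector length does not match bin set")
    if c.sum() == 0:
        raise PreprocessError("empty sample: all bin counts are zero")
    usable = bins.weight > 0
    fit_set = usable & bins.is_autosome
    if int(fit_set.sum()) < MIN_USABLE_BINS:
        raise PreprocessError(
            f"only {int(fit_set.sum())} usable autosomal bins; "
            f"LOWESS needs >= {MIN_USABLE_BINS}"
        )
    # weight-adjust counts so the regression sees a weight-free target
    c_adj = np.divide(c, bins.weight, out=np.full_like(c, np.nan), where=usable)
    gc_fit = bins.gc[fit_set]
    y_fit = c_adj[fit_set]
    delta = 0.003 * (gc_fit.max() - gc_fit.min())
    smoothed = sm.nonparametric.lowess(
        y_fit, gc_fit, frac=span, it=iterations, delta=delta, return_sorted=True
    )
    xs, ys = smoothed[:, 0], smoothed[:, 1]
    # collapse duplicate gc values for interpolation
    if len(xs) > 1 and np.any(np.diff(xs) == 0):
        ser = pd.Series(ys).groupby(pd.Series(xs)).mean()
        xs, ys = ser.index.to_numpy(), ser.to_numpy()
    fitted = np.interp(bins.gc, xs, ys)
    mask = usable & (fitted > 0)
    ratio = np.full(bins.n_bins, np.nan)
    ratio[mask] = c_adj[mask] / fitted[mask]
    anchor = ratio[mask & bins.is_autosome]
    if anchor.size < 2:
        raise PreprocessError("too few autosomal bins survived normalization")
    med = float(np.median(anchor))
    if med <= 0:
        raise PreprocessError("autosomal median ratio is zero; sample unusable")
    x = 2.0 * ratio / med
    return RatioProfile(sample_id=counts.sample_id, bins=bins, x=x, mask=mask)


def write_profile(profile: RatioProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
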