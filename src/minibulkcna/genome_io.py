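"""Genomic coordinate model and on-disk formats.

Everything downstream of read counting is expressed on a single ordered set
of nonoverlapping genomic bins (:class:`GenomeBins`).  Coordinates are
0-based half-open internally and on disk (BED dialect); chromosome names are
accepted with or without a ``chr`` prefix and normalized to the unprefixed
form.  Genome order is chromosomes 1..22, X, Y.

Formats handled here:

* bin definitions — BED + ``gc`` column (optional ``weight`` column),
* mapped-read positions — two-column ``chrom  pos`` (or BED-like) text,
* bins x samples integer count matrix — TSV,
* sample sheet — TSV,
* segment output — SEG (``ID chrom loc.start loc.end num.mark seg.mean``)
  with the documented convention that ``seg.mean`` holds the linear
  copy-number value (diploid baseline 2), not log2 ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
CHROM_RANK: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}
AUTOSOMES: frozenset[str] = frozenset(str(i) for i in range(1, 23))


class GenomeIOError(ValueError):
    """Malformed input file or invariant violation."""


def normalize_chrom(name: str) -> str:
    """Map 'chr7'/'7'/'chrX' to the canonical unprefixed name.

    Raises :class:`GenomeIOError` for names outside 1..22, X, Y.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper() if s in ("x", "y") else s
    if s not in CHROM_RANK:
        raise GenomeIOError(f"unknown chromosome name: {name!r}")
    return s


class GenomeBins:
    """Ordered, nonoverlapping genomic bins with GC fraction.

    Parameters
    ----------
    chrom, start, end, gc
        Per-bin arrays.  Bins must be grouped by chromosome in genome order
        (1..22, X, Y), sorted and nonoverlapping within each chromosome,
        half-open ``[start, end)`` with positive width, and ``gc`` in [0, 1].
    weight
        Optional per-bin nonnegative weight (mappability-style scaling of
        the expected count); defaults to 1 everywhere.
    """

    def __init__(self, chrom, start, end, gc, weight=None):
        self.chrom = np.asarray([normalize_chrom(c) for c in chrom], dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.gc = np.asarray(gc, dtype=float)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.gc) == n):
            raise GenomeIOError("bin field lengths differ")
        if weight is None:
            self.weight = np.ones(n, dtype=float)
        else:
            self.weight = np.asarray(weight, dtype=float)
            if len(self.weight) != n or np.any(self.weight < 0):
                raise GenomeIOError("bin weights must be nonnegative, one per bin")
        self._chrom_slices: dict[str, slice] | None = None
        self._validate()

    def _validate(self) -> None:
        if len(self.chrom) == 0:
            raise GenomeIOError("empty bin set")
        if np.any(~np.isfinite(self.gc)) or np.any(self.gc < 0) or np.any(self.gc > 1):
            raise GenomeIOError("gc fraction outside [0, 1]")
        if np.any(self.end <= self.start):
            bad = int(np.argmax(self.end <= self.start))
            raise GenomeIOError(f"bin {bad}: end <= start")
        ranks = np.array([CHROM_RANK[c] for c in self.chrom])
        if np.any(np.diff(ranks) < 0):
            raise GenomeIOError("chromosome blocks out of genome order (1..22, X, Y)")
        # blocks must be contiguous: a chromosome may not reappear
        seen: set[str] = set()
        prev = None
        for c in self.chrom:
            if c != prev:
                if c in seen:
                    raise GenomeIOError(f"chromosome {c} appears in two blocks")
                seen.add(c)
                prev = c
        for c, sl in self.chrom_slices().items():
            s, e = self.start[sl], self.end[sl]
            if np.any(np.diff(s) <= 0) or np.any(s[1:] < e[:-1]):
                raise GenomeIOError(f"bins on chromosome {c} unsorted or overlapping")

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    def chrom_slices(self) -> dict[str, slice]:
        """Mapping chromosome -> slice of bin indices, in genome order."""
        if self._chrom_slices is None:
            out: dict[str, slice] = {}
            i = 0
            while i < self.n_bins:
                c = self.chrom[i]
                j = i
                while j < self.n_bins and self.chrom[j] == c:
                    j += 1
                out[c] = slice(i, j)
                i = j
            self._chrom_slices = out
        return self._chrom_slices

    @property
    def is_autosome(self) -> np.ndarray:
        return np.array([c in AUTOSOMES for c in self.chrom], dtype=bool)

    def __len__(self) -> int:
        return self.n_bins

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeBins):
            return NotImplemented
        return (
            np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
            and np.allclose(self.gc, other.gc, atol=1e-9)
            and np.allclose(self.weight, other.weight, atol=1e-9)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "gc": self.gc,
                "weight": self.weight,
            }
        )


@dataclass
class BinCounts:
    """Per-bin integer read counts for one sample.

    ``total_mapped`` is the number of reads assigned to bins; reads falling
    outside every bin (or on unknown chromosomes) are tallied in ``dropped``
    so that assigned + dropped equals the input record count.
    """

    sample_id: str
    counts: np.ndarray
    total_mapped: int
    dropped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise GenomeIOError("negative bin count")


@dataclass
class SampleSheet:
    """Sample metadata: sample_id, patient_id, tissue, sex, group[, timepoint]."""

    frame: pd.DataFrame

    TISSUES = ("fibrous", "calcified", "normal")
    SEXES = ("male", "female", "unknown")

    def __post_init__(self):
        required = {"sample_id", "patient_id", "tissue", "sex", "group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise GenomeIOError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dup = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise GenomeIOError(f"duplicate sample_id: {dup}")
        if self.frame["patient_id"].isna().any():
            raise GenomeIOError("every sample must reference a patient_id")
        bad_t = set(self.frame["tissue"]) - set(self.TISSUES)
        if bad_t:
            raise GenomeIOError(f"unknown tissue labels: {sorted(bad_t)}")
        bad_s = set(self.frame["sex"]) - set(self.SEXES)
        if bad_s:
            raise GenomeIOError(f"unknown sex labels: {sorted(bad_s)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def sex_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["sex"].iloc[0]

    def patients(self) -> dict[str, list[str]]:
        """patient_id -> list of sample_ids."""
        return {
            p: list(g["sample_id"]) for p, g in self.frame.groupby("patient_id", sort=True)
        }

    def is_lesional(self, sample_id: str) -> bool:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["tissue"].iloc[0] != "normal"


# ---------------------------------------------------------------------------
# readers / writers


def read_bins(path) -> GenomeBins:
    """Read bin definitions from a BED-like file.

    Columns (tab- or whitespace-separated): chrom, start, end, gc
    [, weight].  Lines starting with ``#`` or ``track`` are skipped.
    """
    chroms, starts, ends, gcs, weights = [], [], [], [], []
    has_weight = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise GenomeIOError(f"{path}:{lineno}: expected >=4 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                gc = float(fields[3])
            except ValueError as exc:
                raise GenomeIOError(f"{path}:{lineno}: {exc}") from exc
            if not 0.0 <= gc <= 1.0:
                raise GenomeIOError(f"{path}:{lineno}: gc {gc} outside [0, 1]")
            w = None
            if len(fields) >= 5:
                try:
                    w = float(fields[4])
                except ValueError as exc:
                    raise GenomeIOError(f"{path}:{lineno}: {exc}") from exc
            if has_weight is None:
                has_weight = w is not None
            elif has_weight != (w is not None):
                raise GenomeIOError(f"{path}:{lineno}: inconsistent weight column")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            gcs.append(gc)
            if w is not None:
                weights.append(w)
    if not chroms:
        raise GenomeIOError(f"{path}: no bins")
    return GenomeBins(chroms, starts, ends, gcs, weights if has_weight else None)


def write_bins(bins: GenomeBins, path) -> None:
    with open(path, "w") as fh:
        for c, s, e, g, w in zip(bins.chrom, bins.start, bins.end, bins.gc, bins.weight):
            fh.write(f"{c}\t{s}\t{e}\t{g:.17g}\t{w:.17g}\n")


def read_positions(path, bins: GenomeBins, sample_id: str = "sample") -> BinCounts:
    """Tabulate mapped-read positions into bins (half-open membership).

    The file holds one record per line: ``chrom  pos`` (extra columns
    ignored; a 3+-column BED line is counted at its start coordinate).
    Records on unknown chromosomes or outside every bin are dropped with a
    warning and tallied in ``BinCounts.dropped``.
    """
    counts = np.zeros(bins.n_bins, dtype=np.int64)
    dropped = 0
    slices = bins.chrom_slices()
    per_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise GenomeIOError(f"{path}:{lineno}: expected >=2 columns")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise GenomeIOError(f"{path}:{lineno}: {exc}") from exc
            try:
                c = normalize_chrom(fields[0])
            except GenomeIOError:
                dropped += 1
                continue
            if c not in slices:
                dropped += 1
                continue
            per_chrom.setdefault(c, []).append(pos)
    for c, poss in per_chrom.items():
        sl = slices[c]
        starts = bins.start[sl]
        ends = bins.end[sl]
        pos_arr = np.asarray(poss, dtype=np.int64)
        idx = np.searchsorted(starts, pos_arr, side="right") - 1
        in_bin = (idx >= 0) & (pos_arr < ends[np.clip(idx, 0, len(ends) - 1)])
        dropped += int(np.sum(~in_bin))
        good = idx[in_bin] + sl.start
        np.add.at(counts, good, 1)
    if dropped:
        warnings.warn(f"{dropped} read positions fell outside the bin set and were dropped")
    return BinCounts(sample_id=sample_id, counts=counts, total_mapped=int(counts.sum()), dropped=dropped)


def write_counts_matrix(counts: Mapping[str, BinCounts], bins: GenomeBins, path) -> None:
    """Write a bins x samples integer count matrix TSV (chrom/start/end index)."""
    df = pd.DataFrame({"chrom": bins.chrom, "start": bins.start, "end": bins.end})
    for sid, bc in counts.items():
        if len(bc.counts) != bins.n_bins:
            raise GenomeIOError(f"sample {sid}: count vector length mismatch")
        df[sid] = bc.counts
    df.to_csv(path, sep="\t", index=False)


def read_counts_matrix(path, bins: GenomeBins) -> dict[str, BinCounts]:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise GenomeIOError(f"count matrix missing column {col}")
    if len(df) != bins.n_bins:
        raise GenomeIOError(f"count matrix has {len(df)} rows, bin set has {bins.n_bins}")
    chrom_file = [normalize_chrom(c) for c in df["chrom"]]
    if list(chrom_file) != list(bins.chrom) or not (
        np.array_equal(df["start"].to_numpy(), bins.start)
        and np.array_equal(df["end"].to_numpy(), bins.end)
    ):
        raise GenomeIOError("count matrix coordinates do not match the bin set")
    out = {}
    for col in df.columns:
        if col in ("chrom", "start", "end"):
            continue
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise GenomeIOError(f"sample {col}: non-integer counts")
        out[col] = BinCounts(sample_id=col, counts=vals.astype(np.int64), total_mapped=int(vals.sum()))
    return out


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SEG


def write_segments(profiles: Sequence, path, bins: GenomeBins) -> None:
    """Write segment profiles as SEG.

    Convention: ``seg.mean`` holds the linear copy-number value of the
    segment (diploid baseline 2), with full float precision so a round trip
    restores values to <= 1e-9.
    """
    from .segmentation import SegmentProfile  # local import to avoid cycle

    with open(path, "w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
        for prof in profiles:
            if not isinstance(prof, SegmentProfile):
                raise GenomeIOError("write_segments expects SegmentProfile objects")
            prof.validate(bins)
            for seg in prof.segments:
                fh.write(
                    f"{prof.sample_id}\t{seg.chrom}\t{bins.start[seg.start_bin]}\t"
                    f"{bins.end[seg.end_bin - 1]}\t{seg.n_bins}\t{seg.mean:.17g}\n"
                )


def read_segments(path, bins: GenomeBins) -> list:
    """Read SEG written by :func:`write_segments` back into SegmentProfiles."""
    from .segmentation import Segment, SegmentProfile

    df = pd.read_csv(path, sep="\t")
    profiles = []
    slices = bins.chrom_slices()
    for sid, g in df.groupby("ID", sort=False):
        segs = []
        for _, row in g.iterrows():
            c = normalize_chrom(row["chrom"])
            sl = slices[c]
            start_bin = sl.start + int(np.searchsorted(bins.start[sl], row["loc.start"]))
            end_candidates = np.flatnonzero(bins.end[sl] == row["loc.end"])
            if len(end_candidates) == 0 or bins.start[start_bin] != row["loc.start"]:
                raise GenomeIOError(
                    f"segment {row['loc.start']}-{row['loc.end']} on {c} does not align to bins"
                )
            end_bin = sl.start + int(end_candidates[0]) + 1
            segs.append(
                Segment(
                    chrom=c,
                    start_bin=start_bin,
                    end_bin=end_bin,
                    n_bins=int(row["num.mark"]),
                    mean=float(row["seg.mean"]),
                )
            )
        profiles.append(SegmentProfile(sample_id=str(sid), segments=segs))
    return profiles
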