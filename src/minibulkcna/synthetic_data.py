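"""Synthetic minibulk shallow-WGS data with known copy-number ground truth.

The generator emulates the assay this pipeline analyses: ~30-50
microdissected cells sequenced at ~0.1x, yielding on the order of one
million mapped reads tabulated into ~2,900 one-megabase bins over
chromosomes 1..22, X, Y.  Counts follow a Gamma-Poisson (negative binomial)
law — the standard over-dispersed model for sequencing counts — whose
expectation per bin is

    depth * weight_i * (cn_i / 2) * b(gc_i) / normalizer,

where ``cn_i`` is the true copy number (sex-determined baseline overlaid
with injected CNA events) and ``b(gc)`` a smooth positive multiplicative
GC-bias curve (quadratic by default, which is exactly the shape LOWESS
normalization is built to remove).  The single dispersion parameter is the
knob that sweeps the profile's MAPD across the 0.23 quality cutoff;
``calibrate_dispersion`` inverts the map from dispersion to MAPD by
Monte-Carlo bisection.

Cohort simulation mirrors the study design this pipeline targets: per
patient, several samples (fibrous / calcified lesional tissue plus normal
tissue) share one event set; an OF-like menu draws chromosome-7 segmental
losses and chromosome-12 short-arm gains / focal supergains (copy number up
to ~10); FD-like patients are event-free; OS-like genomes carry events on
eight or more chromosomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_io import CHROMOSOMES, GenomeBins, BinCounts, SampleSheet, normalize_chrom
from .preprocess import expected_ploidy, gc_normalize
from .qc import compute_mapd

# hg19 chromosome lengths, megabases (rounded)
HG19_MB: dict[str, int] = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 103, "16": 90, "17": 81, "18": 78, "19": 59,
    "20": 63, "21": 48, "22": 51, "X": 155, "Y": 59,
}

BIN_SIZE = 1_000_000


class SimulationError(ValueError):
    pass


@dataclass
class CNAEvent:
    """One copy-number event; bin indices are chromosome-local, half-open."""

    chrom: str
    start_bin: int
    end_bin: int
    true_cn: float

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        if self.end_bin <= self.start_bin:
            raise SimulationError("event end_bin must exceed start_bin")
        if self.true_cn < 0:
            raise SimulationError("true_cn must be nonnegative")


@dataclass
class SimSpec:
    """Study conditions for one simulated sample."""

    bins: GenomeBins
    sex: str = "female"
    depth: float = 1e6
    gc_bias: tuple[float, float, float] = (1.0, 0.4, -1.5)  # b(g)=c0+c1*(g-.45)+c2*(g-.45)^2
    dispersion: float = 0.0
    events: list[CNAEvent] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        if self.depth <= 0:
            raise SimulationError("depth must be > 0")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        g = np.linspace(0.0, 1.0, 101)
        if np.any(self.bias_curve(g) <= 0):
            raise SimulationError("gc bias curve must be positive on [0, 1]")
        # events must not overlap within a chromosome
        by_chrom: dict[str, list[CNAEvent]] = {}
        for ev in self.events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start_bin)
            for a, b in zip(evs, evs[1:]):
                if b.start_bin < a.end_bin:
                    raise SimulationError(f"overlapping events on chromosome {chrom}")

    def bias_curve(self, gc) -> np.ndarray:
        c0, c1, c2 = self.gc_bias
        u = np.asarray(gc, dtype=float) - 0.45
        return c0 + c1 * u + c2 * u * u


@dataclass
class SimTruth:
    """Ground truth accompanying one simulated sample."""

    sample_id: str
    events: list[CNAEvent]
    true_cn: np.ndarray  # per-bin copy number, aligned to bins
    nominal_mapd: float  # analytic MAPD of the noise regime


def make_genome(scale: float = 1.0, seed: int = 0) -> GenomeBins:
    """hg19-proportioned 24-chromosome genome tiled into 1 Mb bins.

    ``scale`` shrinks every chromosome's bin count proportionally (scale 1
    gives ~2,900 bins).  GC per bin follows a smooth autocorrelated process
    confined to [0.3, 0.6], seeded for reproducibility.
    """
    if not 0 < scale <= 1:
        raise SimulationError("scale must be in (0, 1]")
    rng = np.random.default_rng(seed)
    chroms, starts, ends, gcs = [], [], [], []
    for chrom in CHROMOSOMES:
        n = int(round(HG19_MB[chrom] * scale))
        if n < 10:
            raise SimulationError(
                f"scale {scale} leaves chromosome {chrom} with {n} < 10 bins; "
                "CBS min width would be meaningless"
            )
        # AR(1) latent walk -> smooth GC in [0.3, 0.6]
        z = np.empty(n)
        z[0] = rng.normal(0, 1)
        phi = 0.9
        innov = rng.normal(0, np.sqrt(1 - phi**2), size=n)
        for i in range(1, n):
            z[i] = phi * z[i - 1] + innov[i]
        gc = 0.45 + 0.15 * np.tanh(z / 2.0)  # strictly inside (0.3, 0.6)
        chroms.extend([chrom] * n)
        starts.extend(range(0, n * BIN_SIZE, BIN_SIZE))
        ends.extend(range(BIN_SIZE, (n + 1) * BIN_SIZE, BIN_SIZE))
        gcs.extend(gc)
    return GenomeBins(chroms, starts, ends, gcs)


def baseline_cn(bins: GenomeBins, sex: str) -> np.ndarray:
    """Sex-determined neutral copy number per bin."""
    out = np.empty(bins.n_bins)
    for chrom, sl in bins.chrom_slices().items():
        out[sl] = expected_ploidy(sex, chrom)
    return out


def true_cn_vector(spec: SimSpec) -> np.ndarray:
    cn = baseline_cn(spec.bins, spec.sex)
    slices = spec.bins.chrom_slices()
    for ev in spec.events:
        sl = slices.get(ev.chrom)
        if sl is None:
            raise SimulationError(f"event on chromosome {ev.chrom} absent from genome")
        n_chrom = sl.stop - sl.start
        if ev.end_bin > n_chrom:
            raise SimulationError(
                f"event [{ev.start_bin}, {ev.end_bin}) exceeds chromosome {ev.chrom} "
                f"({n_chrom} bins)"
            )
        if np.all(cn[sl] == 0):
            raise SimulationError(
                f"event on chromosome {ev.chrom}, which is absent for sex {spec.sex!r}"
            )
        cn[sl.start + ev.start_bin : sl.start + ev.end_bin] = ev.true_cn
    return cn


def _nominal_mapd(mu_median: float, dispersion: float) -> float:
    # x ~ 2 * count/mu so sd(x) = 2*sqrt(1/mu + d); the adjacent difference has
    # sd sqrt(2)*sd(x) and median|N(0, t^2)| = 0.6745 t, hence
    # MAPD = 0.6745 * sqrt(2) * sd(x).
    sd_x = 2.0 * np.sqrt(1.0 / mu_median + dispersion)
    return float(np.sqrt(2.0) * 0.674489750196082 * sd_x)


def simulate_sample(
    spec: SimSpec, sample_id: str = "sim", rng: np.random.Generator | None = None
) -> tuple[BinCounts, SimTruth]:
    """Draw one sample's bin counts from the Gamma-Poisson model."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cn = true_cn_vector(spec)
    bias = spec.bias_curve(spec.bins.gc)
    raw = spec.bins.weight * (cn / 2.0) * bias
    total_raw = raw.sum()
    if total_raw <= 0:
        raise SimulationError("degenerate spec: zero total expected count")
    mu = spec.depth * raw / total_raw
    if spec.dispersion > 0:
        shape = 1.0 / spec.dispersion
        lam = rng.gamma(shape, scale=np.maximum(mu, 1e-12) * spec.dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    pos = mu[mu > 0]
    mu_med = float(np.median(pos)) if pos.size else 1.0
    truth = SimTruth(
        sample_id=sample_id,
        events=list(spec.events),
        true_cn=cn,
        nominal_mapd=_nominal_mapd(mu_med, spec.dispersion),
    )
    return (
        BinCounts(sample_id=sample_id, counts=counts, total_mapped=int(counts.sum())),
        truth,
    )


def _median_mapd(spec: SimSpec, dispersion: float, n_reps: int, rng) -> float:
    vals = []
    for _ in range(n_reps):
        counts, _ = simulate_sample(replace(spec, dispersion=dispersion, events=[]), rng=rng)
        prof = gc_normalize(counts, spec.bins)
        vals.append(compute_mapd(prof))
    return float(np.median(vals))


def calibrate_dispersion(
    target_mapd: float,
    spec: SimSpec,
    n_reps: int = 20,
    rel_tol: float = 0.05,
    max_iter: int = 25,
) -> float:
    """Find the dispersion whose median simulated MAPD matches the target.

    Monotone bisection against Monte-Carlo medians over ``n_reps``
    replicates per evaluation (events stripped from the spec).  Raises when
    the target lies below the Poisson-only MAPD floor at the spec's depth.
    """
    if target_mapd <= 0:
        raise SimulationError("target_mapd must be > 0")
    rng = np.random.default_rng(spec.seed if spec.seed is not None else 0)
    floor = _median_mapd(spec, 0.0, n_reps, rng)
    if target_mapd <= floor:
        raise SimulationError(
            f"target MAPD {target_mapd} is at or below the Poisson floor "
            f"{floor:.4f} at depth {spec.depth:g}; increase the target or lower depth"
        )
    # analytic first guess, then expand to bracket
    mu_med = spec.depth / spec.bins.n_bins
    guess = max((target_mapd / 1.908) ** 2 - 1.0 / mu_med, 1e-6)
    lo, hi = 0.0, guess
    val_hi = _median_mapd(spec, hi, n_reps, rng)
    tries = 0
    while val_hi < target_mapd:
        lo, hi = hi, hi * 2.0
        val_hi = _median_mapd(spec, hi, n_reps, rng)
        tries += 1
        if tries > 20:
            raise SimulationError("failed to bracket target MAPD")
    best_d, best_err = hi, abs(val_hi - target_mapd)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = _median_mapd(spec, mid, n_reps, rng)
        if abs(val - target_mapd) < best_err:
            best_d, best_err = mid, abs(val - target_mapd)
        if best_err <= rel_tol * target_mapd:
            break
        if val < target_mapd:
            lo = mid
        else:
            hi = mid
    return float(best_d)


# ---------------------------------------------------------------------------
# cohort simulation


def of_event_menu(rng: np.random.Generator, bins: GenomeBins) -> list[CNAEvent]:
    """OF-like event set: chromosome-7 segmental loss and/or chromosome-12
    short-arm gain, sometimes with a focal supergain (CN up to ~10)."""
    slices = bins.chrom_slices()
    n7 = slices["7"].stop - slices["7"].start
    n12 = slices["12"].stop - slices["12"].start
    events: list[CNAEvent] = []
    style = rng.integers(0, 3)  # 0: chr7 loss, 1: chr12 gains, 2: both
    if style in (0, 2):
        span = int(rng.integers(max(10, n7 // 4), max(11, n7 // 2)))
        start = int(rng.integers(0, n7 - span))
        events.append(CNAEvent("7", start, start + span, 1.0))
    if style in (1, 2):
        span = int(rng.integers(max(8, n12 // 8), max(9, n12 // 3)))
        start = int(rng.integers(0, max(1, n12 // 2 - span)))  # short arm
        events.append(CNAEvent("12", start, start + span, 3.0))
        if rng.random() < 0.5:
            sg_span = int(rng.integers(5, 9))
            sg_start = min(n12 - sg_span, start + span + int(rng.integers(2, 10)))
            if sg_start >= start + span:
                events.append(
                    CNAEvent("12", sg_start, sg_start + sg_span, float(rng.uniform(8.8, 10.0)))
                )
    return events


def os_event_menu(rng: np.random.Generator, bins: GenomeBins) -> list[CNAEvent]:
    """OS-like event set: gains and losses on >= 8 distinct chromosomes."""
    slices = bins.chrom_slices()
    autosomes = [c for c in CHROMOSOMES if c not in ("X", "Y")]
    n_chrom = int(rng.integers(8, 12))
    chosen = rng.choice(autosomes, size=n_chrom, replace=False)
    events = []
    for chrom in chosen:
        n = slices[chrom].stop - slices[chrom].start
        span = int(rng.integers(max(8, n // 5), max(9, n // 2)))
        start = int(rng.integers(0, max(1, n - span)))
        cn = float(rng.choice([1.0, 3.0, 4.0]))
        events.append(CNAEvent(chrom, start, start + span, cn))
    return events


DEFAULT_MENUS = {"OF": of_event_menu, "FD": None, "OS": os_event_menu, "normal": None}


def simulate_cohort(
    bins: GenomeBins,
    groups: dict[str, int] | None = None,
    n_fibrous: int = 1,
    n_calcified: int = 1,
    n_normal: int = 1,
    depth: float = 1e6,
    dispersion: float = 0.003,
    gc_bias: tuple[float, float, float] = (1.0, 0.4, -1.5),
    seed: int = 0,
    patient_events: dict[str, list[list[CNAEvent]]] | None = None,
) -> tuple[dict[str, BinCounts], dict[str, SimTruth], SampleSheet]:
    """Simulate a multi-patient cohort with shared per-patient truth.

    ``groups`` maps group label (OF / FD / OS / normal) to patient count.
    Every lesional sample (fibrous, calcified) of a patient carries the
    patient's event set; normal-tissue samples are always event-free.
    ``patient_events`` optionally fixes the event lists per group (cycled
    over patients) instead of drawing from the built-in menus.
    """
    groups = groups or {"OF": 3, "FD": 3}
    for g, n in groups.items():
        if n < 1:
            raise SimulationError(f"group {g} must have >= 1 patient")
    rng = np.random.default_rng(seed)
    counts: dict[str, BinCounts] = {}
    truths: dict[str, SimTruth] = {}
    rows = []
    pnum = 0
    for group in sorted(groups):
        menu = DEFAULT_MENUS.get(group, None)
        for k in range(groups[group]):
            pnum += 1
            patient_id = f"P{pnum:03d}"
            sex = "male" if rng.random() < 0.5 else "female"
            if patient_events is not None and group in patient_events:
                lists = patient_events[group]
                events = list(lists[k % len(lists)])
            elif menu is not None:
                events = menu(rng, bins)
            else:
                events = []
            tissues = (
                ["fibrous"] * n_fibrous + ["calcified"] * n_calcified + ["normal"] * n_normal
            )
            for t_idx, tissue in enumerate(tissues):
                sid = f"{patient_id}_{tissue}{t_idx}"
                ev = events if tissue != "normal" else []
                spec = SimSpec(
                    bins=bins,
                    sex=sex,
                    depth=depth,
                    gc_bias=gc_bias,
                    dispersion=dispersion,
                    events=ev,
                )
                bc, truth = simulate_sample(spec, sample_id=sid, rng=rng)
                counts[sid] = bc
                truths[sid] = truth
                rows.append(
                    {
                        "sample_id": sid,
                        "patient_id": patient_id,
                        "tissue": tissue,
                        "sex": sex,
                        "group": group,
                    }
                )
    sheet = SampleSheet(pd.DataFrame(rows))
    return counts, truths, sheet


def write_truth(truths: dict[str, SimTruth], path) -> None:
    """Truth JSON (events + per-bin copy number) for external harnesses."""
    payload = {
        sid: {
            "events": [
                {
                    "chrom": ev.chrom,
                    "start_bin": ev.start_bin,
                    "end_bin": ev.end_bin,
                    "true_cn": ev.true_cn,
                }
                for ev in t.events
            ],
            "true_cn": [float(v) for v in t.true_cn],
            "nominal_mapd": t.nominal_mapd,
        }
        for sid, t in truths.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
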