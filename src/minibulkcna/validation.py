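"""Self-validation experiments on synthetic data with known ground truth.

These routines exercise the full pipeline under controlled conditions —
changepoint benchmarks against the exhaustive oracle, permutation-test
false-positive rates, event recovery at calibrated noise, QC behaviour,
and end-to-end cohort recovery — and return summary statistics.  They back
both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome_io import GenomeBins
from .preprocess import RatioProfile, gc_normalize
from .qc import MAPD_TO_SD, compute_mapd, qc_filter
from .segmentation import SegmentationConfig, cbs_segment, oracle_segment
from .scoring_calling import (
    call_segments,
    merge_adjacent_calls,
    patient_status,
    sample_status,
)
from .cohort_report import pattern_concordance, smallest_common_region
from .synthetic_data import (
    CNAEvent,
    SimSpec,
    simulate_cohort,
    simulate_sample,
)


def _flat_profile(x: np.ndarray, sample_id: str = "s") -> RatioProfile:
    n = len(x)
    bins = GenomeBins(
        ["1"] * n,
        np.arange(n) * 1_000_000,
        (np.arange(n) + 1) * 1_000_000,
        np.full(n, 0.45),
    )
    return RatioProfile(sample_id=sample_id, bins=bins, x=x, mask=np.ones(n, bool))


def step_oracle_agreement(
    n_instances: int = 50,
    n_bins: int = 100,
    delta: float = 1.0,
    sd: float = 0.1,
    seed: int = 0,
) -> tuple[int, int]:
    """CBS vs exhaustive least-squares oracle on single-step instances.

    Each instance is a 100-bin chromosome stepping from CN 2 to 2 + delta at
    a random interior bin.  An instance agrees when the oracle's changepoint
    is matched by a CBS segment boundary within +-1 bin.
    """
    hits = 0
    rng = np.random.default_rng(seed)
    for k in range(n_instances):
        b = int(rng.integers(20, n_bins - 20))
        x = 2 + rng.normal(0, sd, n_bins)
        x[b:] += delta
        segs = cbs_segment(
            _flat_profile(x), SegmentationConfig(seed=int(rng.integers(2**31)))
        )
        oracle = oracle_segment(x, k_max=2)
        if len(oracle) != 2:
            continue
        boundary = oracle[0][1]
        cbs_bounds = {s.start_bin for s in segs.segments[1:]}
        if any(abs(bb - boundary) <= 1 for bb in cbs_bounds):
            hits += 1
    return hits, n_instances


def null_split_fraction(
    n_chromosomes: int = 200, n_bins: int = 100, sd: float = 0.1, seed: int = 0
) -> float:
    """Fraction of pure-noise chromosomes split into more than one segment."""
    rng = np.random.default_rng(seed)
    split = 0
    for _ in range(n_chromosomes):
        x = 2 + rng.normal(0, sd, n_bins)
        segs = cbs_segment(
            _flat_profile(x), SegmentationConfig(seed=int(rng.integers(2**31)))
        )
        if len(segs.segments) > 1:
            split += 1
    return split / n_chromosomes


def standard_events() -> list[CNAEvent]:
    """The benchmark event set: a one-copy segmental loss on chromosome 7,
    a CN-3 short-arm gain and a focal CN-9.4 supergain on chromosome 12."""
    return [
        CNAEvent("7", 40, 80, 1.0),
        CNAEvent("12", 5, 25, 3.0),
        CNAEvent("12", 60, 68, 9.4),
    ]


def _subset_profile(profile: RatioProfile, chroms: list[str]) -> RatioProfile:
    bins = profile.bins
    idx = np.concatenate([np.arange(bins.n_bins)[bins.chrom_slices()[c]] for c in chroms])
    sub_bins = GenomeBins(
        bins.chrom[idx], bins.start[idx], bins.end[idx], bins.gc[idx], bins.weight[idx]
    )
    return RatioProfile(
        sample_id=profile.sample_id,
        bins=sub_bins,
        x=profile.x[idx],
        mask=profile.mask[idx],
    )


def event_recovery(
    bins: GenomeBins,
    dispersion: float,
    n_reps: int = 100,
    depth: float = 1e6,
    seed: int = 0,
    mean_tol: float = 0.15,
    supergain_tol: float = 0.5,
) -> tuple[int, int]:
    """Recovery of the standard event set over seeded replicates.

    A replicate succeeds when, for every injected event, (1) the
    segmentation places boundaries at both event edges within +-1 bin,
    (2) the length-weighted mean copy number of the segments inside the
    event is within ``mean_tol`` copies of truth (``supergain_tol`` for the
    supergain), and (3) at least one call overlaps the event and every
    overlapping call has the correct direction.  Only the two event-bearing
    chromosomes are segmented per replicate.
    """
    events = standard_events()
    rng = np.random.default_rng(seed)
    n7 = bins.chrom_slices()["7"].stop - bins.chrom_slices()["7"].start
    # event coordinates in the chr7+chr12 subset frame
    targets = []
    for ev in events:
        off = 0 if ev.chrom == "7" else n7
        tol = supergain_tol if ev.true_cn > 5 else mean_tol
        direction = "gain" if ev.true_cn > 2 else "loss"
        targets.append((off + ev.start_bin, off + ev.end_bin, ev.true_cn, tol, direction))
    successes = 0
    for _ in range(n_reps):
        spec = SimSpec(bins=bins, sex="female", depth=depth, dispersion=dispersion, events=events)
        bc, _ = simulate_sample(spec, rng=rng)
        prof = gc_normalize(bc, bins)
        sub = _subset_profile(prof, ["7", "12"])
        segs = cbs_segment(sub, SegmentationConfig(seed=int(rng.integers(2**31))))
        calls = merge_adjacent_calls(call_segments(segs, "female"))
        boundaries = {s.start_bin for s in segs.segments} | {s.end_bin for s in segs.segments}
        ok = True
        for a, b, cn, tol, direction in targets:
            edges_found = any(abs(e - a) <= 1 for e in boundaries) and any(
                abs(e - b) <= 1 for e in boundaries
            )
            # length-weighted mean CN of segments over the event interval
            w_total = 0
            s_total = 0.0
            for s in segs.segments:
                ov = min(s.end_bin, b) - max(s.start_bin, a)
                if ov > 0:
                    w_total += ov
                    s_total += ov * s.mean
            mean_ok = w_total > 0 and abs(s_total / w_total - cn) <= tol
            overlapping = [c for c in calls if c.start_bin < b and a < c.end_bin]
            calls_ok = bool(overlapping) and all(
                c.state == direction for c in overlapping
            )
            ok = ok and edges_found and mean_ok and calls_ok
        if ok:
            successes += 1
    return successes, n_reps


def median_mapd_at(
    bins: GenomeBins, dispersion: float, n_reps: int = 20, depth: float = 1e6, seed: int = 0
) -> float:
    """Median MAPD of the normalized profile over simulated replicates."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_reps):
        bc, _ = simulate_sample(
            SimSpec(bins=bins, depth=depth, dispersion=dispersion), rng=rng
        )
        vals.append(compute_mapd(gc_normalize(bc, bins)))
    return float(np.median(vals))


def qc_verdict_rate(
    bins: GenomeBins, dispersion: float, n_samples: int = 5, depth: float = 1e6, seed: int = 0
) -> float:
    """Fraction of simulated samples passing the default inclusion rule."""
    rng = np.random.default_rng(seed)
    passed = 0
    for _ in range(n_samples):
        bc, _ = simulate_sample(
            SimSpec(bins=bins, depth=depth, dispersion=dispersion), rng=rng
        )
        mapd = compute_mapd(gc_normalize(bc, bins))
        if qc_filter(bc.sample_id, bc.total_mapped, mapd).passed:
            passed += 1
    return passed / n_samples


@dataclass
class CohortRecovery:
    status_accuracy: float
    fd_positive_patients: int
    hotspots_overlap_truth: bool
    events_overlap_calls: bool
    truth_concordance: float
    observed_concordance_min: float


def _truth_calls(events: list[CNAEvent], bins: GenomeBins, sid: str):
    from .scoring_calling import CNACall

    slices = bins.chrom_slices()
    out = []
    for ev in events:
        sl = slices[ev.chrom]
        out.append(
            CNACall(
                sid,
                ev.chrom,
                sl.start + ev.start_bin,
                sl.start + ev.end_bin,
                ev.true_cn,
                "gain" if ev.true_cn > 2 else "loss",
                "diploid",
            )
        )
    return out


def cohort_recovery(
    bins: GenomeBins,
    dispersion: float,
    n_of: int = 3,
    n_fd: int = 3,
    depth: float = 1e6,
    seed: int = 0,
) -> CohortRecovery:
    """End-to-end truth recovery on a small two-group cohort.

    OF-like patients share the standard event set across their fibrous and
    calcified samples; FD-like patients are event-free.  Measures
    patient-status accuracy, hotspot overlap with the injected intervals,
    per-event overlap with correct-direction calls, and fibrous/calcified
    concordance (on truth-derived and observed calls).

    Patient-level status requires the CNA pattern in both lesional samples
    (min_positive_samples = 2): the study design this emulates rests on
    several microdissected samples per patient, and a patient-level CNA
    verdict is corroborated across them rather than driven by a single
    sample's marginal call.
    """
    events = standard_events()
    counts, truths, sheet = simulate_cohort(
        bins,
        groups={"FD": n_fd, "OF": n_of},
        depth=depth,
        dispersion=dispersion,
        seed=seed,
        patient_events={"OF": [events]},
    )
    rng = np.random.default_rng(seed + 1)
    calls_by_sample: dict[str, list] = {}
    for sid in sheet.sample_ids:
        prof = gc_normalize(counts[sid], bins)
        segs = cbs_segment(prof, SegmentationConfig(seed=int(rng.integers(2**31))))
        calls_by_sample[sid] = merge_adjacent_calls(
            call_segments(segs, sheet.sex_of(sid))
        )

    # per-event recovery: every injected event must overlap a call of the
    # correct direction in every lesional sample of its patient
    slices = bins.chrom_slices()
    events_overlap = True
    for sid, truth in truths.items():
        if not sheet.is_lesional(sid):
            continue
        for ev in truth.events:
            a = slices[ev.chrom].start + ev.start_bin
            b = slices[ev.chrom].start + ev.end_bin
            direction = "gain" if ev.true_cn > 2 else "loss"
            if not any(
                c.chrom == ev.chrom
                and c.state == direction
                and c.start_bin < b
                and a < c.end_bin
                for c in calls_by_sample[sid]
            ):
                events_overlap = False

    groups = dict(zip(sheet.frame["patient_id"], sheet.frame["group"]))
    correct = 0
    fd_pos = 0
    observed_conc = []
    truth_conc = []
    for pid, sids in sheet.patients().items():
        lesional = [s for s in sids if sheet.is_lesional(s)]
        status = patient_status(
            [sample_status(calls_by_sample[s]) for s in lesional],
            min_positive_samples=min(2, len(lesional)),
        )
        expected = groups[pid] == "OF"
        if status == expected:
            correct += 1
        if groups[pid] == "FD" and status:
            fd_pos += 1
        if groups[pid] == "OF" and len(lesional) >= 2:
            a, b = lesional[0], lesional[1]
            observed_conc.append(
                pattern_concordance(calls_by_sample[a], calls_by_sample[b], bins.n_bins)
            )
            truth_conc.append(
                pattern_concordance(
                    _truth_calls(truths[a].events, bins, a),
                    _truth_calls(truths[b].events, bins, b),
                    bins.n_bins,
                )
            )

    # hotspot smallest common regions vs injected intervals (global coords)
    overlap_ok = True
    for chrom, direction in (("7", "loss"), ("12", "gain")):
        per_patient: dict[str, list[tuple[int, int]]] = {}
        for pid, sids in sheet.patients().items():
            for s in sids:
                if not sheet.is_lesional(s):
                    continue
                for c in calls_by_sample[s]:
                    if c.chrom == chrom and c.state == direction:
                        per_patient.setdefault(pid, []).append((c.start_bin, c.end_bin))
        region = smallest_common_region(per_patient, chrom, direction)
        injected = [
            (slices[ev.chrom].start + ev.start_bin, slices[ev.chrom].start + ev.end_bin)
            for ev in events
            if ev.chrom == chrom and (("gain" if ev.true_cn > 2 else "loss") == direction)
        ]
        if region is None or not any(
            region.start_bin < b and a < region.end_bin for a, b in injected
        ):
            overlap_ok = False
    return CohortRecovery(
        status_accuracy=correct / (n_of + n_fd),
        fd_positive_patients=fd_pos,
        hotspots_overlap_truth=overlap_ok,
        events_overlap_calls=events_overlap,
        truth_concordance=float(min(truth_conc)) if truth_conc else float("nan"),
        observed_concordance_min=float(min(observed_conc)) if observed_conc else float("nan"),
    )
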