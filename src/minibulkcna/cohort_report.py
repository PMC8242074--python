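"""Cohort-level aggregation: recurrence tracks, hotspot smallest common
regions, intra-patient concordance, score distributions, diagnostic-support
flags, and the end-to-end pipeline driver.

The diagnostic flags are decision support, not a diagnosis: the summary
label only says whether the molecular pattern supports an OF-like lesion
(chromosome 7 / 12 involvement), warns about osteosarcoma-like genome
complexity (events on many chromosomes or a high instability score), or
states that there is no molecular support — absence of CNAs never excludes
the diagnosis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GenomeBins,
    SampleSheet,
    BinCounts,
    read_bins,
    read_counts_matrix,
    read_sample_sheet,
    write_bins,
    write_counts_matrix,
    write_sample_sheet,
    write_segments,
)
from .preprocess import gc_normalize
from .qc import compute_mapd, qc_filter
from .segmentation import SegmentationConfig, cbs_segment
from .scoring_calling import (
    CallingConfig,
    CNACall,
    calls_to_frame,
    call_segments,
    cna_score,
    patient_status,
    sample_status,
    scores_to_frame,
)


class CohortError(ValueError):
    pass


@dataclass
class RecurrenceTrack:
    gain_frac: np.ndarray
    loss_frac: np.ndarray
    n_samples: int


@dataclass
class HotspotRegion:
    chrom: str
    start_bin: int
    end_bin: int
    direction: str
    patients: list[str]


@dataclass
class DiagnosisFlags:
    patient_id: str
    cna_positive: bool | None
    chr7_or_chr12_pattern: bool | None
    genome_complexity: bool | None
    label: str


def recurrence_profile(
    calls_by_sample: Mapping[str, Sequence[CNACall]], n_bins: int
) -> RecurrenceTrack:
    """Per-bin fraction of samples with a gain / loss call covering the bin.

    The denominator is the number of samples in ``calls_by_sample`` (pass
    the QC-passed set); samples without calls count toward it.
    """
    n_samples = len(calls_by_sample)
    if n_samples == 0:
        raise CohortError("recurrence profile needs >= 1 sample")
    gain = np.zeros(n_bins)
    loss = np.zeros(n_bins)
    for calls in calls_by_sample.values():
        g = np.zeros(n_bins, dtype=bool)
        l = np.zeros(n_bins, dtype=bool)
        for c in calls:
            (g if c.state == "gain" else l)[c.start_bin : c.end_bin] = True
        gain += g
        loss += l
    return RecurrenceTrack(
        gain_frac=gain / n_samples, loss_frac=loss / n_samples, n_samples=n_samples
    )


def smallest_common_region(
    intervals_by_patient: Mapping[str, Sequence[tuple[int, int]]],
    chrom: str,
    direction: str,
) -> HotspotRegion | None:
    """Smallest common region of recurrent CNA intervals on one chromosome.

    Sweeps interval endpoints; between consecutive endpoints the set of
    covering patients is constant.  Returns the region covered by the
    largest patient set (>= 2), ties broken toward the widest region; None
    when no bin is shared by two patients.
    """
    pts: set[int] = set()
    cover: dict[str, list[tuple[int, int]]] = {}
    for pid, ivals in intervals_by_patient.items():
        good = [(int(a), int(b)) for a, b in ivals if b > a]
        if good:
            cover[pid] = good
            for a, b in good:
                pts.update((a, b))
    if len(cover) < 2 or not pts:
        return None
    edges = sorted(pts)
    # patient set covering each elementary interval between endpoints
    elementary = []
    for a, b in zip(edges, edges[1:]):
        patients = frozenset(
            pid
            for pid, ivals in cover.items()
            if any(s <= a and b <= e for s, e in ivals)
        )
        elementary.append((a, b, patients))
    # merge maximal runs of consecutive elementary intervals with one set
    runs: list[tuple[int, int, frozenset]] = []
    for a, b, patients in elementary:
        if runs and runs[-1][2] == patients and runs[-1][1] == a:
            runs[-1] = (runs[-1][0], b, patients)
        else:
            runs.append((a, b, patients))
    candidates = [r for r in runs if len(r[2]) >= 2]
    if not candidates:
        return None
    a, b, support = max(candidates, key=lambda r: (len(r[2]), r[1] - r[0]))
    return HotspotRegion(
        chrom=chrom, start_bin=a, end_bin=b, direction=direction, patients=sorted(support)
    )


def _altered_bins(calls: Sequence[CNACall], n_bins: int) -> np.ndarray:
    """Per-bin direction code: +1 gain, -1 loss, 0 neutral."""
    v = np.zeros(n_bins, dtype=np.int8)
    for c in calls:
        v[c.start_bin : c.end_bin] = 1 if c.state == "gain" else -1
    return v


def pattern_concordance(
    calls_a: Sequence[CNACall],
    calls_b: Sequence[CNACall],
    n_bins: int,
    return_details: bool = False,
):
    """Direction-matched Jaccard index of two samples' altered-bin sets.

    A bin counts as shared only when both samples alter it in the same
    direction.  Two CNA-free samples are defined as fully concordant (1.0);
    ``return_details=True`` additionally reports that both-negative case.
    """
    va = _altered_bins(calls_a, n_bins)
    vb = _altered_bins(calls_b, n_bins)
    union = (va != 0) | (vb != 0)
    if not union.any():
        return (1.0, True) if return_details else 1.0
    agree = (va == vb) & (va != 0)
    value = float(agree.sum() / union.sum())
    return (value, False) if return_details else value


def score_distributions(
    scores_by_group: Mapping[str, Sequence[float]],
    cutoff: float | None = None,
    reference_group: str = "normal",
) -> pd.DataFrame:
    """Per-group summary of CNAscore distributions.

    ``cutoff`` defaults to the maximum score of the reference group (the
    CNA-free normal tissue), recomputed from the data at hand; the table
    reports each group's n, min, median, max and fraction above the cutoff.
    """
    groups = {}
    for g, scores in scores_by_group.items():
        vals = np.asarray(list(scores), dtype=float)
        if vals.size == 0:
            warnings.warn(f"group {g!r} is empty; omitted from the summary")
            continue
        groups[g] = vals
    if not groups:
        raise CohortError("no non-empty groups")
    if cutoff is None:
        if reference_group in groups:
            cutoff = float(groups[reference_group].max())
        else:
            warnings.warn(
                f"no {reference_group!r} group and no explicit cutoff; "
                "fraction-above column will be NaN"
            )
    rows = []
    for g, vals in groups.items():
        rows.append(
            {
                "group": g,
                "n": int(vals.size),
                "min": float(vals.min()),
                "median": float(np.median(vals)),
                "max": float(vals.max()),
                "cutoff": np.nan if cutoff is None else float(cutoff),
                "frac_above_cutoff": (
                    np.nan if cutoff is None else float(np.mean(vals > cutoff))
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ClassifyConfig:
    complexity_chromosomes: int = 8
    complexity_score_cutoff: float | None = None
    min_positive_samples: int = 1


NON_EXCLUSIONARY = "absence of CNAs does not exclude the diagnosis"


def classify_patient(
    patient_id: str,
    calls_by_sample: Mapping[str, Sequence[CNACall]],
    scores_by_sample: Mapping[str, float],
    config: ClassifyConfig | None = None,
) -> DiagnosisFlags:
    """Diagnostic-support flags for one patient.

    ``calls_by_sample`` / ``scores_by_sample`` must hold only the patient's
    QC-passed lesional samples; with none, the patient is indeterminate.
    """
    config = config or ClassifyConfig()
    if not calls_by_sample:
        return DiagnosisFlags(
            patient_id=patient_id,
            cna_positive=None,
            chr7_or_chr12_pattern=None,
            genome_complexity=None,
            label="insufficient QC-passed samples",
        )
    positives = [sample_status(list(c)) for c in calls_by_sample.values()]
    pos = bool(patient_status(positives, config.min_positive_samples))
    all_calls = [c for calls in calls_by_sample.values() for c in calls]
    pattern = any(c.chrom in ("7", "12") for c in all_calls)
    chroms_hit = {c.chrom for c in all_calls}
    complexity = len(chroms_hit) >= config.complexity_chromosomes
    if config.complexity_score_cutoff is not None and scores_by_sample:
        med = float(np.median(list(scores_by_sample.values())))
        complexity = complexity or med > config.complexity_score_cutoff
    if complexity:
        label = "complexity warning: events on many chromosomes"
    elif pos and pattern:
        label = "OF-supporting CNA pattern (Chr 7/12)"
    elif pos:
        label = "CNA present without Chr 7/12 pattern"
    else:
        label = f"no molecular support; {NON_EXCLUSIONARY}"
    return DiagnosisFlags(
        patient_id=patient_id,
        cna_positive=pos,
        chr7_or_chr12_pattern=pattern,
        genome_complexity=complexity,
        label=label,
    )


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass
class PipelineConfig:
    """Inputs + thresholds for one pipeline run.

    Either ``counts``/``bins_path``/``sample_sheet`` name on-disk inputs, or
    ``synthetic`` holds keyword arguments for
    :func:`minibulkcna.synthetic_data.simulate_cohort` (plus optional
    ``genome_scale``).  All thresholds default to the published values.
    """

    bins_path: str | None = None
    counts_path: str | None = None
    sample_sheet_path: str | None = None
    synthetic: dict | None = None
    span: float = 0.3
    lowess_iterations: int = 3
    read_floor: int = 100_000
    mapd_ceiling: float = 0.23
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    seed: int = 0


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """preprocess -> qc -> segmentation -> scoring/calling -> cohort report.

    Writes qc.tsv, segments.seg, calls.tsv, cnascore.tsv, recurrence.tsv,
    hotspots.tsv, score_summary.tsv, flags.json and run_log.json into
    ``out_dir``.  QC failures are recorded, never fatal; identical seeds
    give byte-identical outputs.
    """
    from . import synthetic_data as syn

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        kw = dict(config.synthetic)
        scale = kw.pop("genome_scale", 1.0)
        genome_seed = kw.pop("genome_seed", config.seed)
        bins = syn.make_genome(scale=scale, seed=genome_seed)
        kw.setdefault("seed", config.seed)
        counts, truths, sheet = syn.simulate_cohort(bins, **kw)
        write_bins(bins, out / "bins.bed")
        write_counts_matrix(counts, bins, out / "counts.tsv")
        write_sample_sheet(sheet, out / "sample_sheet.tsv")
        syn.write_truth(truths, out / "truth.json")
    else:
        if not (config.bins_path and config.counts_path and config.sample_sheet_path):
            raise CohortError("config must name bins, counts and sample sheet, or a synthetic spec")
        bins = read_bins(config.bins_path)
        counts = read_counts_matrix(config.counts_path, bins)
        sheet = read_sample_sheet(config.sample_sheet_path)

    missing = set(sheet.sample_ids) - set(counts)
    if missing:
        raise CohortError(f"samples in sheet without counts: {sorted(missing)}")

    qc_rows = []
    profiles = {}
    for sid in sheet.sample_ids:
        try:
            prof = gc_normalize(counts[sid], bins, span=config.span, iterations=config.lowess_iterations)
            mapd = compute_mapd(prof)
        except Exception as exc:
            raise CohortError(f"preprocess failed for sample {sid}: {exc}") from exc
        metrics = qc_filter(
            sid, counts[sid].total_mapped, mapd, config.read_floor, config.mapd_ceiling
        )
        qc_rows.append(
            {
                "sample_id": sid,
                "mapped_reads": metrics.mapped_reads,
                "mapd": metrics.mapd,
                "passed": int(metrics.passed),
                "reasons": ";".join(metrics.reasons),
            }
        )
        if metrics.passed:
            profiles[sid] = prof
    pd.DataFrame(qc_rows).to_csv(out / "qc.tsv", sep="\t", index=False, float_format="%.10g")

    seg_profiles = {}
    calls_by_sample: dict[str, list[CNACall]] = {}
    score_results = []
    base_seed = config.segmentation.seed if config.segmentation.seed is not None else config.seed
    for i, sid in enumerate(sorted(profiles)):
        seg_cfg = SegmentationConfig(
            alpha=config.segmentation.alpha,
            min_width=config.segmentation.min_width,
            undo_sd=config.segmentation.undo_sd,
            nperm=config.segmentation.nperm,
            seed=(base_seed + i) % (2**31),
            log_scale=config.segmentation.log_scale,
        )
        try:
            segs = cbs_segment(profiles[sid], seg_cfg)
        except Exception as exc:
            raise CohortError(f"segmentation failed for sample {sid}: {exc}") from exc
        seg_profiles[sid] = segs
        sex = sheet.sex_of(sid)
        calls_by_sample[sid] = call_segments(segs, sex, config.calling)
        score_results.append(cna_score(segs, sex))
    write_segments(list(seg_profiles.values()), out / "segments.seg", bins)
    calls_to_frame([c for cs in calls_by_sample.values() for c in cs]).to_csv(
        out / "calls.tsv", sep="\t", index=False, float_format="%.10g"
    )
    score_frame = scores_to_frame(score_results)
    score_frame.to_csv(out / "cnascore.tsv", sep="\t", index=False, float_format="%.10g")

    # recurrence over QC-passed lesional samples
    lesional = {
        sid: calls_by_sample[sid] for sid in calls_by_sample if sheet.is_lesional(sid)
    }
    rec_source = lesional or calls_by_sample
    track = recurrence_profile(rec_source, bins.n_bins)
    pd.DataFrame(
        {
            "chrom": bins.chrom,
            "start": bins.start,
            "end": bins.end,
            "gain_frac": track.gain_frac,
            "loss_frac": track.loss_frac,
        }
    ).to_csv(out / "recurrence.tsv", sep="\t", index=False, float_format="%.10g")

    # hotspots: per chromosome/direction, one merged interval set per patient
    patients = sheet.patients()
    hot_rows = []
    for direction in ("gain", "loss"):
        per_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
        for pid, sids in patients.items():
            for sid in sids:
                if sid not in calls_by_sample or not sheet.is_lesional(sid):
                    continue
                for c in calls_by_sample[sid]:
                    if c.state != direction:
                        continue
                    per_chrom.setdefault(c.chrom, {}).setdefault(pid, []).append(
                        (c.start_bin, c.end_bin)
                    )
        for chrom, by_patient in sorted(per_chrom.items()):
            region = smallest_common_region(by_patient, chrom, direction)
            if region is not None:
                hot_rows.append(
                    {
                        "chrom": region.chrom,
                        "start_bin": region.start_bin,
                        "end_bin": region.end_bin,
                        "direction": region.direction,
                        "n_patients": len(region.patients),
                        "patients": ";".join(region.patients),
                    }
                )
    pd.DataFrame(
        hot_rows,
        columns=["chrom", "start_bin", "end_bin", "direction", "n_patients", "patients"],
    ).to_csv(out / "hotspots.tsv", sep="\t", index=False)

    # score distributions by group
    scores_by_sid = dict(zip(score_frame["sample_id"], score_frame["total"]))
    by_group: dict[str, list[float]] = {}
    for _, row in sheet.frame.iterrows():
        sid = row["sample_id"]
        if sid not in scores_by_sid:
            continue
        group = "normal" if row["tissue"] == "normal" else row["group"]
        by_group.setdefault(group, []).append(scores_by_sid[sid])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = score_distributions(by_group)
    summary.to_csv(out / "score_summary.tsv", sep="\t", index=False, float_format="%.10g")

    # per-patient flags
    flags = []
    for pid, sids in patients.items():
        lesional_sids = [
            s for s in sids if s in calls_by_sample and sheet.is_lesional(s)
        ]
        flags.append(
            asdict(
                classify_patient(
                    pid,
                    {s: calls_by_sample[s] for s in lesional_sids},
                    {s: scores_by_sid[s] for s in lesional_sids},
                    config.classify,
                )
            )
        )
    with open(out / "flags.json", "w") as fh:
        json.dump(flags, fh, indent=2, sort_keys=True)

    log = {
        "seed": config.seed,
        "span": config.span,
        "lowess_iterations": config.lowess_iterations,
        "read_floor": config.read_floor,
        "mapd_ceiling": config.mapd_ceiling,
        "alpha": config.segmentation.alpha,
        "min_width": config.segmentation.min_width,
        "undo_sd": config.segmentation.undo_sd,
        "nperm": config.segmentation.nperm,
        "log_scale": config.segmentation.log_scale,
        "diploid_gain": config.calling.diploid_gain,
        "diploid_loss": config.calling.diploid_loss,
        "haploid_gain": config.calling.haploid_gain,
        "haploid_loss": config.calling.haploid_loss,
        "min_call_bins": config.calling.min_call_bins,
        "n_samples": len(sheet.sample_ids),
        "n_qc_passed": len(profiles),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return out
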