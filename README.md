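# minibulkcna

Copy-number-alteration (CNA) profiling for **minibulk** samples — tiny
laser-capture-microdissected tissue fragments of ~30–50 cells sequenced by
shallow whole-genome sequencing (~0.1×, on the order of 10⁶ mapped reads).
At this input scale, CNA profiles are the practical molecular readout for
distinguishing fibro-osseous jaw lesions: ossifying fibroma (OF) frequently
carries segmental gains and losses — characteristically on chromosomes 7
and 12, up to focal "supergains" near copy number 10 — while fibrous
dysplasia (FD) is almost always copy-number silent, and osteosarcoma-like
genomes show events scattered over many chromosomes. The package is aimed
at molecular-pathology analysts and methods developers who need a tested,
fully reproducible implementation of this pipeline together with a
synthetic-data generator that provides ground truth.

## Pipeline

Reads are tabulated into ~2,900 nonoverlapping 1 Mb bins over chromosomes
1..22, X, Y. From bin counts the pipeline computes:

1. **GC normalization** — LOWESS regression of count on GC fraction over
   autosomal bins; each count is divided by its fitted value and profiles
   are scaled so the autosomal median sits at copy number 2. The per-bin
   copy-number values are written `x_i`.
2. **Quality control** — MAPD, the median absolute pairwise difference
   `MAPD = median(|x_{i+1} − x_i|)` over genome-ordered bins: a noise
   statistic robust to true CNA steps. A sample is qualified when it has
   more than 100 000 mapped reads and MAPD < 0.23 (both strict).
3. **Segmentation** — circular binary segmentation (CBS) per chromosome
   with permutation testing (`alpha = 0.1`, `min_width = 5`,
   `undo_sd = 0.1`, implemented in-house and cross-checked against an
   exhaustive least-squares oracle), giving segment means `s_i`.
4. **CNAscore** — a genome-instability statistic

   CNAscore = Σ_{chr=1}^{24} [ mean(|s_i − s_{i−1}|) + 0.5 · |mean(s_i) − norm| ]

   where `norm` is the chromosome's neutral copy number given sex
   (2 for autosomes and female X, 1 for male X/Y, 0 for female Y). The
   first term measures chromosomal instability (jumps between successive
   segments), the second deviation from neutral ploidy.
5. **Calling** — diploid chromosomes: gain if CN > 2.4, loss if CN < 1.7;
   haploid chromosomes: gain if CN > 1.5, loss if CN < 0.5 (all strict).
6. **Cohort aggregation** — per-bin gain/loss recurrence tracks, smallest
   common regions of recurrent CNAs across patients (hotspots),
   direction-matched Jaccard concordance between samples (e.g. fibrous vs
   calcified tissue of one lesion), CNAscore distributions per group, and
   per-patient diagnostic-support flags (OF-supporting chromosome-7/12
   pattern; osteosarcoma-like complexity warning; explicit statement that
   absent CNAs do not exclude any diagnosis).

A synthetic-data module generates bin counts from a Gamma-Poisson model
with configurable GC bias, over-dispersion (calibratable to any target
MAPD), sex-aware baselines and injected CNA events, so every stage is
testable against known truth without any sequencing data.

## Worked example

```python
import numpy as np
from minibulkcna import (
    CNAEvent, SimSpec, SegmentationConfig, make_genome, simulate_sample,
    gc_normalize, compute_mapd, qc_filter, cbs_segment, call_segments, cna_score,
)

bins = make_genome(scale=1.0, seed=0)                  # hg19-like, 3,093 x 1 Mb bins
spec = SimSpec(
    bins=bins, sex="female", depth=1e6, dispersion=0.004,
    events=[CNAEvent("7", 40, 80, 1.0),                # one-copy loss, 40 bins
            CNAEvent("12", 60, 68, 9.4)],              # focal supergain
    seed=42,
)
counts, truth = simulate_sample(spec, sample_id="demo")
profile = gc_normalize(counts, bins)
mapd = compute_mapd(profile)
qc = qc_filter("demo", counts.total_mapped, mapd)
print(f"mapped reads: {counts.total_mapped}, MAPD: {mapd:.3f}, QC passed: {qc.passed}")

segments = cbs_segment(profile, SegmentationConfig(seed=0))
for c in call_segments(segments, sex="female"):
    print(f"chr{c.chrom}:{c.start_bin}-{c.end_bin}  CN={c.s:.2f}  {c.state}")
print(f"CNAscore: {cna_score(segments, sex='female').total:.3f}")
```

Output:

```
mapped reads: 999636, MAPD: 0.153, QC passed: True
chr7:1273-1313  CN=1.03  loss
chr12:2010-2018  CN=9.48  gain
CNAscore: 11.270
```

Both injected events are recovered at their exact bin boundaries
(chromosome 7 occupies bins 1233–1392, so local bins 40–80 are global
1273–1313) with segment means within a few percent of truth; the sample
passes QC at MAPD 0.153. The large CNAscore is driven by the supergain:
its jumps of ±7.5 copies enter the chromosome-12 instability term
directly. Coordinates are bin indices; `segments.seg` output carries
genomic coordinates.

The same stages are available from the shell via the `minibulkcna` CLI
(`simulate`, `preprocess`, `qc`, `segment`, `score`, `call`, `cohort`,
`run`); `run` drives the whole pipeline from one YAML config and writes
QC/SEG/calls/CNAscore/recurrence/hotspot tables plus per-patient flags.

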