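import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from minibulkcna import (
    classify_patient,
    pattern_concordance,
    recurrence_profile,
    score_distributions,
    smallest_common_region,
)
from minibulkcna.cohort_report import (
    ClassifyConfig,
    CohortError,
    PipelineConfig,
    run_pipeline,
)
from minibulkcna.scoring_calling import CNACall


def call(chrom, a, b, state, s=None, sid="s"):
    if s is None:
        s = 3.0 if state == "gain" else 1.0
    return CNACall(sid, chrom, a, b, s, state, "diploid")


class TestRecurrence:
    def test_no_calls_zero_track(self):
        t = recurrence_profile({"a": [], "b": []}, 50)
        assert np.all(t.gain_frac == 0) and np.all(t.loss_frac == 0)
        assert t.n_samples == 2

    def test_half_of_samples_with_gain(self):
        calls = {
            "a": [call("1", 10, 20, "gain")],
            "b": [call("1", 10, 20, "gain")],
            "c": [],
            "d": [],
        }
        t = recurrence_profile(calls, 30)
        assert np.all(t.gain_frac[10:20] == 0.5)
        assert np.all(t.gain_frac[:10] == 0) and np.all(t.gain_frac[20:] == 0)

    def test_gain_and_loss_tracks_independent(self):
        calls = {"a": [call("1", 0, 5, "gain"), call("2", 10, 15, "loss")]}
        t = recurrence_profile(calls, 20)
        assert t.gain_frac[0] == 1.0 and t.loss_frac[10] == 1.0

    def test_zero_samples_rejected(self):
        with pytest.raises(CohortError):
            recurrence_profile({}, 10)


class TestSmallestCommonRegion:
    def test_endpoint_sweep_hand_example(self):
        region = smallest_common_region(
            {"p1": [(10, 60)], "p2": [(20, 80)], "p3": [(5, 55)]}, "7", "loss"
        )
        assert (region.start_bin, region.end_bin) == (20, 55)
        assert region.patients == ["p1", "p2", "p3"]

    def test_identical_intervals(self):
        region = smallest_common_region({"p1": [(5, 30)], "p2": [(5, 30)]}, "12", "gain")
        assert (region.start_bin, region.end_bin) == (5, 30)

    def test_disjoint_intervals_give_none(self):
        assert smallest_common_region({"p1": [(0, 10)], "p2": [(20, 30)]}, "1", "gain") is None

    def test_single_patient_gives_none(self):
        assert smallest_common_region({"p1": [(0, 10)]}, "1", "gain") is None

    def test_majority_beats_width(self):
        # three patients share [40, 45); only two share the wide [0, 40)
        region = smallest_common_region(
            {"p1": [(0, 45)], "p2": [(0, 45)], "p3": [(40, 50)]}, "3", "gain"
        )
        assert (region.start_bin, region.end_bin) == (40, 45)
        assert len(region.patients) == 3


class TestConcordance:
    def test_identical_sets(self):
        a = [call("1", 0, 50, "gain")]
        assert pattern_concordance(a, a, 100) == 1.0

    def test_disjoint_sets(self):
        a = [call("1", 0, 10, "gain")]
        b = [call("1", 50, 60, "gain")]
        assert pattern_concordance(a, b, 100) == 0.0

    def test_partial_overlap_jaccard(self):
        a = [call("1", 0, 100, "gain")]
        b = [call("1", 50, 150, "gain")]
        assert abs(pattern_concordance(a, b, 200) - 50 / 150) <= 1e-12

    def test_direction_mismatch_not_shared(self):
        a = [call("1", 0, 50, "gain")]
        b = [call("1", 0, 50, "loss")]
        assert pattern_concordance(a, b, 100) == 0.0

    def test_both_negative_annotated(self):
        value, both_negative = pattern_concordance([], [], 100, return_details=True)
        assert value == 1.0 and both_negative

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.data())
    def test_symmetric_and_reflexive(self, data):
        def random_calls(label):
            n = data.draw(st.integers(0, 3), label=label)
            out = []
            for _ in range(n):
                a = data.draw(st.integers(0, 89), label=label + "a")
                w = data.draw(st.integers(1, 90 - a), label=label + "w")
                state = data.draw(st.sampled_from(["gain", "loss"]), label=label + "s")
                out.append(call("1", a, a + w, state))
            return out

        x, y = random_calls("x"), random_calls("y")
        assert pattern_concordance(x, y, 100) == pattern_concordance(y, x, 100)
        assert pattern_concordance(x, x, 100) == 1.0


class TestScoreDistributions:
    def test_identical_scores(self):
        df = score_distributions({"FD": [1.1, 1.1, 1.1]}, cutoff=2.0)
        row = df.iloc[0]
        assert row["min"] == row["median"] == row["max"] == 1.1

    def test_fraction_above_cutoff(self):
        df = score_distributions({"OF": [1, 2, 3]}, cutoff=2.5)
        assert abs(df.iloc[0]["frac_above_cutoff"] - 1 / 3) <= 1e-12

    def test_cutoff_recomputed_from_normal_group(self):
        df = score_distributions({"normal": [0.5, 1.9], "OF": [1.0, 2.0, 3.0]})
        assert np.all(df["cutoff"] == 1.9)
        of = df.set_index("group").loc["OF"]
        assert abs(of["frac_above_cutoff"] - 2 / 3) <= 1e-12

    def test_empty_group_omitted_with_warning(self):
        with pytest.warns(UserWarning):
            df = score_distributions({"OF": [1.0], "FD": []}, cutoff=2.0)
        assert list(df["group"]) == ["OF"]


class TestClassifyPatient:
    def test_chr12_supergain_supports_of(self):
        calls = {"s1": [call("12", 60, 68, "gain", s=9.4)]}
        flags = classify_patient("p", calls, {"s1": 2.5})
        assert flags.cna_positive and flags.chr7_or_chr12_pattern
        assert not flags.genome_complexity
        assert "OF-supporting" in flags.label

    def test_no_calls_non_exclusionary(self):
        flags = classify_patient("p", {"s1": []}, {"s1": 1.0})
        assert flags.cna_positive is False
        assert not flags.chr7_or_chr12_pattern and not flags.genome_complexity
        assert "does not exclude" in flags.label

    def test_many_chromosomes_flag_complexity(self):
        calls = {"s1": [call(str(c), 0, 10, "gain") for c in range(1, 10)]}
        flags = classify_patient("p", calls, {"s1": 5.0})
        assert flags.genome_complexity
        assert "complexity" in flags.label

    def test_score_cutoff_can_trigger_complexity(self):
        calls = {"s1": [call("3", 0, 10, "gain")]}
        cfg = ClassifyConfig(complexity_score_cutoff=2.0)
        flags = classify_patient("p", calls, {"s1": 4.0}, cfg)
        assert flags.genome_complexity

    def test_indeterminate_patient(self):
        flags = classify_patient("p", {}, {})
        assert flags.cna_positive is None
        assert flags.label == "insufficient QC-passed samples"


PIPELINE_CONFIG = dict(
    synthetic=dict(
        genome_scale=0.2,
        genome_seed=1,
        groups={"OF": 1, "FD": 1},
        depth=2e5,
        dispersion=0.003,
    ),
    seed=7,
)


@pytest.fixture(scope="module")
def run_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    run_pipeline(PipelineConfig(**PIPELINE_CONFIG), out)
    return out


class TestRunPipeline:

    def test_outputs_written(self, run_dir):
        for name in (
            "qc.tsv",
            "segments.seg",
            "calls.tsv",
            "cnascore.tsv",
            "recurrence.tsv",
            "hotspots.tsv",
            "score_summary.tsv",
            "flags.json",
            "run_log.json",
        ):
            assert (run_dir / name).exists(), name

    def test_qc_report_covers_all_samples(self, run_dir):
        qc = pd.read_csv(run_dir / "qc.tsv", sep="\t")
        sheet = pd.read_csv(run_dir / "sample_sheet.tsv", sep="\t")
        assert set(qc["sample_id"]) == set(sheet["sample_id"])

    def test_recurrence_fractions_bounded(self, run_dir):
        rec = pd.read_csv(run_dir / "recurrence.tsv", sep="\t")
        assert rec["gain_frac"].between(0, 1).all()
        assert rec["loss_frac"].between(0, 1).all()

    def test_flags_cover_all_patients(self, run_dir):
        flags = json.loads((run_dir / "flags.json").read_text())
        sheet = pd.read_csv(run_dir / "sample_sheet.tsv", sep="\t")
        assert {f["patient_id"] for f in flags} == set(sheet["patient_id"])

    def test_rerun_is_byte_identical(self, run_dir, tmp_path):
        out2 = tmp_path / "again"
        run_pipeline(PipelineConfig(**PIPELINE_CONFIG), out2)
        for name in ("qc.tsv", "segments.seg", "calls.tsv", "cnascore.tsv", "flags.json"):
            assert (run_dir / name).read_bytes() == (out2 / name).read_bytes(), name


class TestCLI:
    def test_simulate_then_qc(self, tmp_path):
        from click.testing import CliRunner

        from minibulkcna.cli import main

        runner = CliRunner()
        simdir = tmp_path / "sim"
        r = runner.invoke(
            main,
            [
                "simulate", "--out", str(simdir), "--scale", "0.2",
                "--of", "1", "--fd", "1", "--depth", "2e5", "--seed", "5",
            ],
        )
        assert r.exit_code == 0, r.output
        r2 = runner.invoke(
            main,
            [
                "qc", "--bins", str(simdir / "bins.bed"),
                "--counts", str(simdir / "counts.tsv"),
                "--out", str(tmp_path / "qc.tsv"),
            ],
        )
        assert r2.exit_code == 0, r2.output
        qc = pd.read_csv(tmp_path / "qc.tsv", sep="\t")
        assert len(qc) == 6  # 2 patients x (fibrous + calcified + normal)
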