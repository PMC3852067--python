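import numpy as np
import pandas as pd
import pytest

from comotif.curation import Experiment, Peak
from comotif.motifs import Background
from comotif.screen import (
    AbundanceRecord,
    EnrichmentFlag,
    PeakPartition,
    ScanContext,
    ScreenThresholds,
    SpecificCall,
    abundance_table,
    cell_type_specific_screen,
    enrichment_flags,
    experiment_presence,
    partition_peaks,
    percentile_linear,
    remove_similar,
    tf_specific_screen,
    ubiquity_filter,
    write_reports,
)
from conftest import random_pwm

TH = ScreenThresholds()


def rec(exp, motif, cls, n_present, n_peaks=100):
    return AbundanceRecord(exp_id=exp, motif_id=motif, cls=cls,
                           n_peaks=n_peaks, n_present=n_present)


def flag(exp, motif, cls, flagged=True, q95=0.05):
    return EnrichmentFlag(exp_id=exp, motif_id=motif, cls=cls, q95=q95,
                          flagged=flagged)


class TestPercentile:
    def test_matches_interpolation_formula(self):
        rng = np.random.default_rng(3)
        values = list(rng.uniform(0, 1, size=20))
        v = np.sort(values)
        pos = 0.95 * 19
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expected = v[lo] + (pos - lo) * (v[hi] - v[lo])
        assert percentile_linear(values, 95) == pytest.approx(expected)
        assert percentile_linear(values, 95) == pytest.approx(
            np.percentile(values, 95)
        )

    def test_empty_group(self):
        with pytest.raises(ValueError):
            percentile_linear([], 95)


class TestEnrichmentFlags:
    def test_single_outlier_flagged(self):
        records = [rec("e1", f"m{i}", "proximal", 2) for i in range(99)]
        records.append(rec("e1", "hot_motif", "proximal", 60))
        flags = enrichment_flags(records)
        flagged = {f.motif_id for f in flags if f.flagged}
        assert "hot_motif" in flagged

    def test_all_equal_none_flagged(self):
        records = [rec("e1", f"m{i}", "proximal", 10) for i in range(30)]
        flags = enrichment_flags(records)
        assert not any(f.flagged for f in flags)

    def test_small_group_warns(self, caplog):
        records = [rec("e1", f"m{i}", "distal", i) for i in range(5)]
        with caplog.at_level("WARNING"):
            flags = enrichment_flags(records)
        assert len(flags) == 5
        assert "only 5 motifs" in caplog.text

    def test_crafted_group_matches_oracle(self):
        rng = np.random.default_rng(11)
        abundances = rng.integers(0, 100, size=20)
        records = [rec("e1", f"m{i}", "proximal", int(a))
                   for i, a in enumerate(abundances)]
        q95 = percentile_linear([a / 100 for a in abundances], 95)
        flags = enrichment_flags(records)
        for f, r in zip(flags, records):
            assert f.flagged == (r.abundance > q95)
            assert f.q95 == pytest.approx(q95)


class TestUbiquityFilter:
    def test_25pct_proximal_discarded(self):
        flags = [flag(f"e{i}", "m", "proximal") for i in range(25)]
        assert ubiquity_filter(flags, n_exps=100, thresholds=TH) == set()

    def test_5pct_distal_retained(self):
        flags = [flag(f"e{i}", "m", "distal") for i in range(5)]
        assert ubiquity_filter(flags, n_exps=100, thresholds=TH) == {
            ("m", "distal")
        }

    def test_never_flagged_not_retained(self):
        flags = [flag("e1", "m", "proximal", flagged=False)]
        assert ubiquity_filter(flags, n_exps=10, thresholds=TH) == set()

    def test_boundary_strict(self):
        # exactly at the ceiling: 20 of 100 proximal is NOT retained
        flags = [flag(f"e{i}", "m", "proximal") for i in range(20)]
        assert ubiquity_filter(flags, n_exps=100, thresholds=TH) == set()


def make_ct_table(n_exps, n_tfs, abundance, cell_type="CT1", motif="cf",
                  cls="proximal"):
    experiments, records, flags = [], [], []
    for i in range(n_exps):
        exp_id = f"e{i}"
        experiments.append(
            Experiment(exp_id, f"TF{i % n_tfs}", cell_type, "")
        )
        records.append(rec(exp_id, motif, cls, int(abundance * 100)))
        flags.append(flag(exp_id, motif, cls))
    return flags, records, experiments


class TestCellTypeScreen:
    def test_planted_recovery(self):
        flags, records, exps = make_ct_table(12, 5, 0.60)
        calls = cell_type_specific_screen(flags, records, exps, TH)
        assert len(calls) == 1
        call = calls[0]
        assert (call.scope, call.key, call.cls) == ("cell_type", "CT1",
                                                    "proximal")
        assert len(call.supporting_exp_ids) == 12
        assert call.min_abundance == pytest.approx(0.60)

    def test_nine_experiments_fails(self):
        flags, records, exps = make_ct_table(9, 5, 0.60)
        assert cell_type_specific_screen(flags, records, exps, TH) == []

    def test_single_tf_fails_diversity(self):
        flags, records, exps = make_ct_table(12, 1, 0.60)
        assert cell_type_specific_screen(flags, records, exps, TH) == []

    def test_low_abundance_fails(self):
        flags, records, exps = make_ct_table(12, 5, 0.10)
        assert cell_type_specific_screen(flags, records, exps, TH) == []

    def test_monotone_in_abundance_threshold(self):
        rng = np.random.default_rng(8)
        flags, records, exps = [], [], []
        for i in range(30):
            exp_id = f"e{i}"
            exps.append(Experiment(exp_id, f"TF{i % 6}", f"CT{i % 2}", ""))
            records.append(rec(exp_id, "m", "proximal",
                               int(rng.integers(0, 100))))
            flags.append(flag(exp_id, "m", "proximal",
                              flagged=bool(rng.integers(2))))
        base = {
            (c.motif_id, c.key, c.cls)
            for c in cell_type_specific_screen(
                flags, records, exps, ScreenThresholds(ct_min_abund=0.15)
            )
        }
        for abund in (0.3, 0.5, 0.8):
            tighter = {
                (c.motif_id, c.key, c.cls)
                for c in cell_type_specific_screen(
                    flags, records, exps, ScreenThresholds(ct_min_abund=abund)
                )
            }
            assert tighter <= base


def make_tf_table(abundances_by_ct, tf="TFA", motif="cf", cls="proximal"):
    experiments, records, flags = [], [], []
    for i, (ct, abundance) in enumerate(abundances_by_ct.items()):
        exp_id = f"e{i}"
        experiments.append(Experiment(exp_id, tf, ct, ""))
        records.append(rec(exp_id, motif, cls, int(round(abundance * 100))))
        flags.append(flag(exp_id, motif, cls))
    return flags, records, experiments


class TestTfScreen:
    def test_planted_recovery(self):
        flags, records, exps = make_tf_table(
            {"CT1": 0.4, "CT2": 0.4, "CT3": 0.4, "CT4": 0.4}
        )
        calls = tf_specific_screen(flags, records, exps, TH)
        assert len(calls) == 1
        assert (calls[0].scope, calls[0].key) == ("tf", "TFA")

    def test_one_low_sister_fails(self):
        flags, records, exps = make_tf_table(
            {"CT1": 0.4, "CT2": 0.4, "CT3": 0.19}
        )
        assert tf_specific_screen(flags, records, exps, TH) == []

    def test_two_sisters_fail(self):
        flags, records, exps = make_tf_table({"CT1": 0.4, "CT2": 0.4})
        assert tf_specific_screen(flags, records, exps, TH) == []

    def test_sisters_must_span_cell_types(self):
        # three flagged experiments but only two distinct cell types
        exps = [
            Experiment("e0", "TFA", "CT1", ""),
            Experiment("e1", "TFA", "CT1", "drug"),
            Experiment("e2", "TFA", "CT2", ""),
        ]
        records = [rec(e.exp_id, "cf", "proximal", 40) for e in exps]
        flags = [flag(e.exp_id, "cf", "proximal") for e in exps]
        assert tf_specific_screen(flags, records, exps, TH) == []


class TestRemoveSimilar:
    def test_decoy_dropped_unrelated_kept(self, rng):
        canon_pwm = random_pwm(rng, 10, informative=True, motif_id="CANON_TFA")
        probs = canon_pwm.probs.copy()
        old = int(np.argmax(probs[:, 3]))
        new = (old + 1) % 4
        col = np.full(4, 0.02)
        col[new] = 0.94
        probs[:, 3] = col / col.sum()
        from comotif.motifs import PWM

        decoy = PWM("decoy", "decoy", "synthetic", probs)
        from comotif.similarity import similarity_pvalue, stable_seed

        unrelated = None
        for i in range(50):  # find a seeded motif clearly dissimilar
            cand = random_pwm(rng, 10, informative=True, motif_id=f"u{i}")
            seed = stable_seed(42, cand.motif_id, canon_pwm.motif_id)
            if similarity_pvalue(cand, canon_pwm, seed=seed).p_value >= 0.3:
                unrelated = cand
                break
        assert unrelated is not None
        pwms = {p.motif_id: p for p in (canon_pwm, decoy, unrelated)}
        exps = [Experiment(f"e{i}", "TFA", f"CT{i}", "") for i in range(4)]
        calls = [
            SpecificCall("decoy", "tf", "TFA", "proximal",
                         frozenset(e.exp_id for e in exps), 0.4),
            SpecificCall(unrelated.motif_id, "tf", "TFA", "proximal",
                         frozenset(e.exp_id for e in exps), 0.4),
        ]
        kept = remove_similar(calls, {"TFA": ["CANON_TFA"]}, pwms, exps,
                              seed=42)
        assert [c.motif_id for c in kept] == [unrelated.motif_id]

    def test_empty_calls(self, rng):
        assert remove_similar([], {}, {}, [], seed=0) == []


@pytest.fixture(scope="module")
def tiny_experiment(rng):
    """10 fixed-width peaks, a canonical motif planted in 4 of them."""
    canon = random_pwm(rng, 10, informative=True, motif_id="canon")
    canon2 = random_pwm(rng, 10, informative=True, motif_id="canon2")
    cof = random_pwm(rng, 8, informative=True, motif_id="cof")
    peaks = []
    for i in range(10):
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=80))
        if i < 4:
            seq = seq[:10] + canon.consensus() + seq[20:]
        if i < 3:
            seq = seq[:40] + cof.consensus() + seq[48:]
        peaks.append(Peak(f"p{i}", "e1", "chr1", 0, 80, sequence=seq))
    exp = Experiment("e1", "TFA", "CT1", "")
    ctx = ScanContext(background=Background.uniform())
    return exp, peaks, canon, canon2, cof, ctx


class TestPartitionAndAbundance:
    def test_partition_planted(self, tiny_experiment):
        exp, peaks, canon, canon2, cof, ctx = tiny_experiment
        part = partition_peaks(
            exp, peaks, {"TFA": ["canon"]}, {"canon": canon}, ctx
        )
        assert part.positive_peak_ids == {"p0", "p1", "p2", "p3"}
        assert len(part.negative_peak_ids) == 6

    def test_multi_canonical_union(self, tiny_experiment, rng):
        exp, peaks, canon, canon2, cof, ctx = tiny_experiment
        # a peak matching only the SECOND canonical motif is positive
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=80))
        seq = seq[:30] + canon2.consensus() + seq[40:]
        extra = Peak("p10", "e1", "chr1", 0, 80, sequence=seq)
        part = partition_peaks(
            exp, peaks + [extra], {"TFA": ["canon", "canon2"]},
            {"canon": canon, "canon2": canon2}, ctx,
        )
        assert "p10" in part.positive_peak_ids

    def test_zero_peaks(self, tiny_experiment):
        exp, _, canon, *_ , ctx = tiny_experiment
        part = partition_peaks(exp, [], {"TFA": ["canon"]}, {"canon": canon},
                               ctx)
        assert part.positive_peak_ids == frozenset()
        assert part.negative_peak_ids == frozenset()

    def test_missing_canonical_errors(self, tiny_experiment):
        exp, peaks, canon, *_ , ctx = tiny_experiment
        with pytest.raises(ValueError, match="TFA"):
            partition_peaks(exp, peaks, {}, {}, ctx)

    def test_abundance_forced_ratio(self, tiny_experiment):
        exp, peaks, canon, canon2, cof, ctx = tiny_experiment
        pwms = [canon, cof]
        presence = experiment_presence(peaks, pwms, ctx)
        part = partition_peaks(exp, peaks, {"TFA": ["canon"]},
                               {"canon": canon}, ctx, presence=presence)
        records = abundance_table(
            {"e1": part}, {"e1": presence}, {"e1": ["canon"]}
        )
        # canonical motif of the experiment's own TF is excluded
        assert {r.motif_id for r in records} == {"cof"}
        prox = next(r for r in records if r.cls == "proximal")
        assert prox.n_peaks == 4 and prox.n_present == 3
        assert prox.abundance == pytest.approx(0.75)

    def test_partition_conserves_peaks(self, tiny_experiment):
        exp, peaks, canon, *_ , ctx = tiny_experiment
        part = partition_peaks(exp, peaks, {"TFA": ["canon"]},
                               {"canon": canon}, ctx)
        assert len(part.positive_peak_ids) + len(part.negative_peak_ids) == 10

    def test_no_negative_peaks_no_distal(self, tiny_experiment):
        exp, peaks, canon, canon2, cof, ctx = tiny_experiment
        presence = experiment_presence(peaks, [cof], ctx)
        part = PeakPartition("e1", frozenset(p.peak_id for p in peaks),
                             frozenset())
        records = abundance_table({"e1": part}, {"e1": presence}, {"e1": []})
        assert all(r.cls == "proximal" for r in records)


class TestThresholdValidation:
    def test_defaults_valid(self):
        ScreenThresholds()

    @pytest.mark.parametrize(
        "kw", [{"prox_ubiq": 0.0}, {"ct_min_exps": 0}, {"pct": 100.0},
               {"sim_alpha": 1.0}]
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            ScreenThresholds(**kw)


class TestWriteReports:
    def _calls(self):
        return [
            SpecificCall("m1", "cell_type", "CT1", "proximal",
                         frozenset({"e1", "e2"}), 0.4),
            SpecificCall("m2", "tf", "TFA", "distal",
                         frozenset({"e3"}), 0.3),
            SpecificCall("m3", "tf", "TFA", "distal",
                         frozenset({"e4"}), 0.25),
        ]

    def test_summary_total(self, tmp_path):
        records = [rec("e1", "m1", "proximal", 40)]
        flags = enrichment_flags(records)
        write_reports(self._calls(), records, flags, tmp_path)
        summary = pd.read_csv(tmp_path / "summary.csv")
        tf_row = summary[summary["key"] == "TFA"].iloc[0]
        assert tf_row["total"] == 2
        assert tf_row["motif_ids"] == "m2, m3"

    def test_zero_calls_headers_only(self, tmp_path):
        write_reports([], [], [], tmp_path)
        for name in ("cell_type_specific.csv", "tf_specific.csv",
                     "proximal.csv", "distal.csv", "summary.csv"):
            df = pd.read_csv(tmp_path / name)
            assert df.empty

    def test_byte_identical_rerun(self, tmp_path):
        records = [rec("e1", "m1", "proximal", 37),
                   rec("e1", "m2", "distal", 12)]
        flags = enrichment_flags(records)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_reports(self._calls(), records, flags, d1)
        write_reports(self._calls(), records, flags, d2)
        for name in ("proximal.csv", "distal.csv", "cell_type_specific.csv",
                     "tf_specific.csv", "summary.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
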