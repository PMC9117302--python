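"""Single-marker scan statistic, permutation thresholds and peak calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rilmap as rm
from rilmap import qtl
from rilmap.genome import Interval
from rilmap.markers import A, B

from conftest import table_from_patterns, MB


class TestPrepareTraitValues:
    def _pheno(self):
        return pd.DataFrame({
            "line": ["L1", "L1", "L2", "L2", "L2"],
            "trait": ["HED"] * 5,
            "environment": ["e1", "e2", "e1", "e1", "e2"],
            "value": [4.0, 6.0, 10.0, 12.0, 20.0],
        })

    def test_replicates_then_environment_means(self):
        v = qtl.prepare_trait_values(self._pheno(), "HED")
        assert v["L1"] == pytest.approx(5.0)        # (4 + 6) / 2
        assert v["L2"] == pytest.approx(15.5)       # (11 + 20) / 2

    def test_environment_subset(self):
        v = qtl.prepare_trait_values(self._pheno(), "HED", ["e1"])
        assert v["L2"] == pytest.approx(11.0)

    def test_min_environment_count(self):
        pheno = self._pheno().iloc[:3]
        v = qtl.prepare_trait_values(pheno, "HED", min_environments=2)
        assert list(v.index) == ["L1"]

    def test_missing_trait(self):
        with pytest.raises(ValueError):
            qtl.prepare_trait_values(self._pheno(), "nope")


class TestSingleMarkerTS:
    def test_hand_computed_variance_ratio(self):
        g = np.array([A, A, A, B, B, B], dtype=np.int8)
        y = np.array([10.0, 11.0, 12.0, 14.0, 15.0, 16.0])
        res = qtl.single_marker_ts(g, y, min_lines=6)
        # RSS_full = 4, RSS_reduced = 28 -> TS = 6 ln 7
        assert res["ts"] == pytest.approx(6 * math.log(7))
        assert res["effect"] == pytest.approx(-4.0)
        assert res["n"] == 6

    def test_equal_class_means_give_zero(self):
        g = np.array([A, A, B, B] * 5, dtype=np.int8)
        y = np.array([1.0, 2.0, 1.0, 2.0] * 5)
        res = qtl.single_marker_ts(g, y)
        assert res["ts"] == pytest.approx(0.0, abs=1e-12)

    def test_collinear_covariate_gives_zero(self):
        g = np.array([A, B] * 12, dtype=np.int8)
        y = np.random.default_rng(0).normal(size=24)
        res = qtl.single_marker_ts(g, y, covariate=g)
        assert res["ts"] == pytest.approx(0.0, abs=1e-8)

    def test_single_class_undefined(self):
        g = np.array([A] * 25, dtype=np.int8)
        res = qtl.single_marker_ts(g, np.arange(25.0))
        assert np.isnan(res["ts"])

    def test_constant_phenotype_raises(self):
        g = np.array([A, B] * 12, dtype=np.int8)
        with pytest.raises(ValueError):
            qtl.single_marker_ts(g, np.ones(24))

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0.1, max_value=50.0),
           st.floats(min_value=-100.0, max_value=100.0),
           st.booleans())
    def test_affine_invariance(self, a, b, flip):
        rng = np.random.default_rng(7)
        g = np.tile([A, B], 15).astype(np.int8)
        y = rng.normal(size=30) + (g == A)
        scale = -a if flip else a
        t1 = qtl.single_marker_ts(g, y)["ts"]
        t2 = qtl.single_marker_ts(g, scale * y + b)["ts"]
        assert t2 == pytest.approx(t1, rel=1e-9, abs=1e-9)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(11)
        calls = rng.choice([0, 1, 2, 3], size=(20, 40),
                           p=[0.1, 0.4, 0.4, 0.1]).astype(np.int8)
        y = rng.normal(size=40)
        ts_vec = qtl.ts_matrix(calls, y)
        for i in range(20):
            assert np.isclose(
                ts_vec[i], qtl.single_marker_ts(calls[i], y)["ts"],
                equal_nan=True,
            )


class TestTsLodConversion:
    def test_printed_anchor(self):
        # a LOD of 5 corresponds to TS just above 23
        ts = 5 * 2 * math.log(10)
        assert int(ts) == 23
        assert qtl.ts_to_lod(23.026) == pytest.approx(5.0, abs=1e-3)

    def test_units(self):
        assert qtl.ts_to_lod(0.0) == 0.0
        assert qtl.ts_to_lod(2 * math.log(10)) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            qtl.ts_to_lod(-1.0)


class TestPermutationThresholds:
    def test_monotone_and_deterministic(self, small_ril):
        _, truth, _ = small_ril
        y = np.random.default_rng(5).normal(size=truth.n_lines)
        t1 = qtl.permutation_thresholds(truth, y, n_perm=200, seed=11)
        t2 = qtl.permutation_thresholds(truth, y, n_perm=200, seed=11)
        assert t1.thresholds == t2.thresholds
        assert t1.ts(0.001) >= t1.ts(0.005) >= t1.ts(0.01) >= t1.ts(0.05)

    def test_too_few_permutations(self, small_ril):
        _, truth, _ = small_ril
        with pytest.raises(ValueError):
            qtl.permutation_thresholds(truth, np.ones(truth.n_lines), n_perm=50)


class TestGenomeScan:
    def test_planted_qtl_found_and_removed_by_covariate(self):
        cfg = rm.SimConfig(layout=rm.toy_layout(2, 100), n_lines=150,
                           generations=6, markers_per_chromosome=50,
                           cm_per_mbp=0.5,
                           qtls=(rm.QtlSpec("y", "chr1", 50 * MB, 1.0),),
                           heritability=0.4, seed=21)
        truth, _ = rm.simulate_ril(cfg)
        values = qtl.prepare_trait_values(rm.simulate_phenotypes(truth, cfg), "y")
        prof = qtl.genome_scan(truth, values, trait="y")
        best = prof.table.loc[prof.table["ts"].idxmax()]
        assert best["chromosome"] == "chr1"
        assert abs(best["position"] - 50 * MB) < 10 * MB
        # conditioning on the peak marker removes the signal
        prof_cov = qtl.genome_scan(truth, values,
                                   covariate_marker=str(best["marker"]))
        chr1 = prof_cov.table[prof_cov.table["chromosome"] == "chr1"]
        assert np.nanmax(chr1["ts"].to_numpy()) < 0.5 * best["ts"]

    def test_lod_column_is_exact_conversion(self, small_ril):
        _, truth, _ = small_ril
        y = np.random.default_rng(2).normal(size=truth.n_lines)
        prof = qtl.genome_scan(truth, y)
        t = prof.table.dropna(subset=["ts"])
        assert np.allclose(t["lod"], t["ts"] / (2 * math.log(10)))


class TestCallPeaks:
    def _profile(self, ts_by_marker, spacing_mb=10):
        n = len(ts_by_marker)
        table = pd.DataFrame({
            "marker": [f"m{i}" for i in range(n)],
            "chromosome": "chr1",
            "position": [(i + 1) * spacing_mb * MB for i in range(n)],
            "n": 100,
            "ts": ts_by_marker,
            "mean_a": 1.0, "mean_b": 0.0,
        })
        table["lod"] = table["ts"] / (2 * math.log(10))
        table["effect"] = 1.0
        return qtl.ScanProfile(table, trait="HED")

    def test_falloff_interval_rule(self):
        prof = self._profile([1, 6, 30, 25, 23, 6, 1])
        peaks = qtl.call_peaks(prof, ts_threshold=23.0)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.peak_marker == "m2"
        # falloff cutoff 24: markers 3-4 stay, marker 5 at 23 drops out
        assert (p.interval.start, p.interval.end) == (30, 40)
        assert p.interval.start <= p.peak_mbp <= p.interval.end

    def test_flat_profile_below_threshold(self):
        prof = self._profile([5, 6, 7, 6, 5])
        assert qtl.call_peaks(prof, ts_threshold=23.0) == []

    def test_two_distant_peaks_survive_exclusion(self):
        ts = [0.0] * 31
        ts[5], ts[25] = 30.0, 28.0  # peaks 200 Mbp apart
        peaks = qtl.call_peaks(self._profile(ts), ts_threshold=23.0)
        assert len(peaks) == 2

    def test_second_peak_masked_within_exclusion(self):
        ts = [0.0] * 16
        ts[5], ts[10] = 30.0, 28.0  # 50 Mbp apart, inside the 75 Mbp mask
        peaks = qtl.call_peaks(self._profile(ts), ts_threshold=23.0)
        assert len(peaks) == 1
        assert peaks[0].ts == 30.0

    def test_intervals_never_overlap(self):
        rng = np.random.default_rng(3)
        ts = rng.uniform(0, 40, size=60)
        peaks = qtl.call_peaks(self._profile(ts.tolist(), spacing_mb=2),
                               ts_threshold=23.0)
        spans = sorted((p.interval.start, p.interval.end) for p in peaks)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


class TestGffExport:
    def _peak(self):
        return qtl.QtlPeak(
            trait="HED", population="TxHd", chromosome="chr4A",
            peak_marker="mk", peak_mbp=318, ts=30.0,
            lod=30.0 / (2 * math.log(10)),
            interval=Interval("chr4A", 274, 318), effect=2.6,
            high_parent="A", threshold_ts=23.0,
        )

    def test_naming_convention(self):
        assert self._peak().name == "HED.TxHd.318"

    def test_roundtrip(self, tmp_path):
        path = tmp_path / "peaks.gff3"
        qtl.export_gff([self._peak()], path)
        back = qtl.read_qtl_gff(path)
        assert len(back) == 1
        assert back[0]["interval"] == Interval("chr4A", 274, 318)
        assert back[0]["ID"] == "HED.TxHd.318"
        assert back[0]["lod"] == pytest.approx(self._peak().lod, abs=1e-4)

    def test_empty_list_writes_valid_header(self, tmp_path):
        path = tmp_path / "empty.gff3"
        qtl.export_gff([], path)
        assert path.read_text() == "##gff-version 3\n"
        assert qtl.read_qtl_gff(path) == []
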