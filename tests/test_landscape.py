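"""Recombination matrices, anomaly detection, heat map, distortion."""

import numpy as np
import pytest

import rilmap as rm
from rilmap import landscape
from rilmap.genome import toy_layout
from rilmap.markers import A, B

from conftest import table_from_patterns, translocation_scenario, MB


class TestPairwiseR:
    def test_identity_and_independence(self):
        x = np.array([A, B] * 10, dtype=np.int8)
        assert landscape.pairwise_r(x, x) == 0.0
        y = x.copy()
        y[:10] = np.where(y[:10] == A, B, A)  # discordant in half the lines
        assert landscape.pairwise_r(x, y) == 0.5

    def test_one_discordant_in_ten(self):
        x = np.array([A] * 10, dtype=np.int8)
        y = x.copy()
        y[0] = B
        assert landscape.pairwise_r(x, y) == pytest.approx(0.1)

    def test_min_informative(self):
        x = np.array([A] * 5, dtype=np.int8)
        assert np.isnan(landscape.pairwise_r(x, x, min_informative=10))
        assert landscape.pairwise_r(x, x, min_informative=5) == 0.0

    def test_het_and_missing_excluded(self):
        table = table_from_patterns({f"L{i}": "AA" for i in range(12)})
        table.calls[0, 0] = 0   # missing at marker 1, line 1
        table.calls[0, 1] = 3   # het at marker 1, line 2
        r = landscape.pairwise_r(table.calls[0], table.calls[1])
        assert r == pytest.approx(0.0)


class TestRecombinationMatrix:
    def _hand_table(self):
        # 3 markers at 3, 9, 25 Mbp on a 30 Mbp chromosome, 20 lines
        rng = np.random.default_rng(3)
        g1 = rng.integers(0, 2, 20)
        g2 = g1.copy(); g2[:2] = 1 - g2[:2]        # r(m1, m2) = 0.1
        g3 = g1.copy(); g3[5:13] = 1 - g3[5:13]    # r(m1, m3) = 0.4
        calls = (np.stack([g1, g2, g3]) + 1).astype(np.int8)
        table = table_from_patterns({f"L{i}": "AAA" for i in range(20)},
                                    positions=[3 * MB, 9 * MB, 25 * MB])
        table.calls[:] = calls
        return table

    def test_hand_averaged_window_values(self):
        table = self._hand_table()
        r12 = landscape.pairwise_r(table.calls[0], table.calls[1])
        r13 = landscape.pairwise_r(table.calls[0], table.calls[2])
        r23 = landscape.pairwise_r(table.calls[1], table.calls[2])
        mat = rm.recombination_matrix(table, toy_layout(1, 30), 16, 10)
        # centers 10, 20, 30; window members: {m1, m2}, {m3}, {m3}
        assert list(mat.coordinates["center"]) == [10.0, 20.0, 30.0]
        assert mat.values[0, 0] == pytest.approx(r12)
        assert mat.values[0, 1] == pytest.approx((r13 + r23) / 2)
        assert mat.values[0, 2] == pytest.approx((r13 + r23) / 2)
        assert np.isnan(mat.values[1, 1])  # single marker: no distinct pairs
        assert np.isnan(mat.values[1, 2])  # same single marker on both sides
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)

    def test_brute_force_oracle(self, small_ril):
        """Window means equal an explicit all-pairs enumeration."""
        _, truth, _ = small_ril
        sub = truth.select_markers(np.arange(5))
        layout = toy_layout(2, 100)
        mat = rm.recombination_matrix(sub, layout, 16, 10, min_informative=10)
        pos = sub.markers["position"].to_numpy() / 1e6
        for i in range(mat.n_windows):
            for j in range(mat.n_windows):
                ci = mat.coordinates.iloc[i]
                cj = mat.coordinates.iloc[j]
                mi = [k for k in range(5)
                      if sub.markers["chromosome"].iat[k] == ci["chromosome"]
                      and abs(pos[k] - ci["center"]) <= 8]
                mj = [k for k in range(5)
                      if sub.markers["chromosome"].iat[k] == cj["chromosome"]
                      and abs(pos[k] - cj["center"]) <= 8]
                vals = [landscape.pairwise_r(sub.calls[a], sub.calls[b])
                        for a in mi for b in mj if a != b]
                vals = [v for v in vals if not np.isnan(v)]
                if mi and mj:
                    if vals:
                        assert mat.values[i, j] == pytest.approx(
                            np.mean(np.minimum(vals, 0.5)))
                    else:
                        assert np.isnan(mat.values[i, j])

    def test_invariance_to_line_order(self, small_ril):
        _, truth, _ = small_ril
        layout = toy_layout(2, 100)
        mat = rm.recombination_matrix(truth, layout)
        perm = np.random.default_rng(0).permutation(truth.n_lines)
        shuffled = rm.MarkerTable(truth.markers.copy(),
                                  [truth.lines[i] for i in perm],
                                  truth.calls[:, perm])
        mat2 = rm.recombination_matrix(shuffled, layout)
        assert np.allclose(mat.values, mat2.values, equal_nan=True)

    def test_coarser_step_subsamples_finer(self, small_ril):
        _, truth, _ = small_ril
        layout = toy_layout(2, 100)
        fine = rm.recombination_matrix(truth, layout, 16, 10)
        coarse = rm.recombination_matrix(truth, layout, 16, 20)
        fine_key = list(zip(fine.coordinates["chromosome"],
                            fine.coordinates["center"]))
        idx = [fine_key.index((c, m)) for c, m in
               zip(coarse.coordinates["chromosome"],
                   coarse.coordinates["center"])]
        assert np.allclose(coarse.values, fine.values[np.ix_(idx, idx)],
                           equal_nan=True)

    def test_independent_chromosomes_near_half(self):
        cfg = rm.SimConfig(layout=toy_layout(2, 100), n_lines=200,
                           generations=6, markers_per_chromosome=50,
                           cm_per_mbp=1.0, seed=9)
        truth, _ = rm.simulate_ril(cfg)
        mat = rm.recombination_matrix(truth, cfg.layout)
        wins = mat.chromosome_windows()
        inter = mat.values[np.ix_(wins["chr1"], wins["chr2"])]
        se = np.sqrt(0.25 / cfg.n_lines)
        # capped at 0.5 from above, so one-sided 4-SE band below 0.5
        frac = np.mean(inter >= 0.5 - 4 * se)
        assert frac >= 0.99

    def test_empty_window_uses_adjacent_markers(self):
        # markers only at the chromosome ends: middle windows still filled
        table = table_from_patterns(
            {f"L{i}": "AABB" for i in range(20)},
            positions=[1 * MB, 2 * MB, 99 * MB, 100 * MB],
        )
        mat = rm.recombination_matrix(table, toy_layout(1, 100), 16, 10)
        assert not np.isnan(mat.values).all()
        mid = mat.coordinates["center"].tolist().index(50.0)
        assert np.isfinite(mat.values[mid, mid])


class TestDetectAnomalies:
    def test_translocation_called_between_chromosomes(self):
        cfg = translocation_scenario(321)
        truth, _ = rm.simulate_ril(cfg)
        mat = rm.recombination_matrix(truth, cfg.layout)
        calls = rm.detect_anomalies(mat)
        inter = [c for c in calls
                 if c.kind == "inter_chromosome_pseudolinkage"]
        assert len(inter) == 1
        assert inter[0].mean_r <= 0.2

    def test_no_calls_on_independent_genome(self):
        cfg = rm.SimConfig(layout=toy_layout(2, 200), n_lines=200,
                           generations=6, markers_per_chromosome=100,
                           cm_per_mbp=4.0, seed=17)
        truth, _ = rm.simulate_ril(cfg)
        mat = rm.recombination_matrix(truth, cfg.layout)
        assert rm.detect_anomalies(mat) == []


class TestHeatmap:
    def test_anchor_colors_and_midpoint_blend(self):
        assert landscape.heatmap_color(0.0) == (1.0, 1.0, 0.0)
        assert landscape.heatmap_color(0.5) == (0.5, 0.0, 0.125)
        mid = landscape.heatmap_color(0.1)  # 50/50 yellow-teal blend
        assert mid == pytest.approx((0.5, 0.75, 0.25))

    def test_render_writes_file(self, small_ril, tmp_path):
        _, truth, _ = small_ril
        mat = rm.recombination_matrix(truth, toy_layout(2, 100))
        out = tmp_path / "heat.png"
        landscape.render_heatmap(mat, out)
        assert out.stat().st_size > 0


class TestDistortionProfile:
    def test_balanced_and_boundary(self):
        table = table_from_patterns(
            {f"L{j}": "".join(r[j] for r in
                              ["AB" * 50, "A" * 90 + "B" * 10, "A" * 100])
             for j in range(100)}
        )
        prof = landscape.distortion_profile(table)
        assert prof["freq_a"].tolist() == [0.5, 0.9, 1.0]
        assert prof["p_binomial"].iloc[0] == pytest.approx(1.0)

    def test_exact_binomial_tail_by_summation(self):
        from math import comb
        table = table_from_patterns(
            {f"L{j}": ("A" if j < 90 else "B") for j in range(100)}
        )
        prof = landscape.distortion_profile(table)
        # two-sided exact test: sum probabilities <= P(90; 100, 0.5)
        pmf = [comb(100, k) * 0.5 ** 100 for k in range(101)]
        expected = sum(p for p in pmf if p <= pmf[90] * (1 + 1e-12))
        assert prof["p_binomial"].iloc[0] == pytest.approx(expected, rel=1e-9)
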