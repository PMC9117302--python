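"""Marker filtering, phasing, double-crossover correction and imputation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rilmap as rm
from rilmap import curation
from rilmap.markers import A, B, H, MISSING, CODE_TO_CHAR

from conftest import table_from_patterns


def _calls_as_strings(table):
    return ["".join(CODE_TO_CHAR[table.calls[i]]) for i in range(table.n_markers)]


class TestFilterMarkers:
    def test_published_threshold_rules(self):
        # per-marker call strings across 10 lines
        lines = {f"L{i}": "" for i in range(10)}
        rows = [
            "AAAABBBBBB",  # clean 50/50 -> retained
            "UUUUUUABAB",  # 6/10 missing -> removed (0.6 > 0.5)
            "AAAAAAAABH",  # MAF (1 + 0.5)/10 = 0.15 -> removed
            "AABBHHAABB",  # het 2/10 = 0.2 > 0.1 -> removed
        ]
        patterns = {line: "".join(r[j] for r in rows)
                    for j, line in enumerate(lines)}
        table = table_from_patterns(patterns)
        out, rep = curation.filter_markers(table)
        assert list(out.markers["marker"]) == ["m1"]
        assert (rep.n_removed_missing, rep.n_removed_maf, rep.n_removed_het) \
            == (1, 1, 1)
        assert rep.n_input == rep.n_retained + rep.n_removed_missing \
            + rep.n_removed_maf + rep.n_removed_het

    def test_retained_at_equality(self):
        # exactly 50% missing / exactly 30% MAF / exactly 10% het: all kept
        rows = ["AAABBUUUUU", "AAAAAAABBB", "AAAABBBBBH"]
        patterns = {f"L{j}": "".join(r[j] for r in rows) for j in range(10)}
        out, _ = curation.filter_markers(table_from_patterns(patterns))
        assert out.n_markers == 3

    def test_identity_thresholds(self):
        table = table_from_patterns({"L1": "AUH", "L2": "BUA", "L3": "UUU"})
        out, _ = curation.filter_markers(table, 1.0, 0.0, 1.0)
        assert out.n_markers == table.n_markers

    def test_bad_inputs(self):
        table = table_from_patterns({"L1": "A"})
        with pytest.raises(ValueError):
            curation.filter_markers(table, max_missing=1.5)
        with pytest.raises(ValueError):
            curation.filter_markers(table.select_markers(np.array([], int)))


class TestPhaseToParents:
    def test_recoding_and_uninformative_drop(self):
        table = table_from_patterns({
            "P1": "ABA",   # parent A
            "P2": "BAA",   # parent B; marker 3 monomorphic in parents
            "L1": "AAB",
            "L2": "BBH",
        })
        out, rep = curation.phase_to_parents(table, "P1", "P2")
        assert out.lines == ["L1", "L2"]
        # marker 1: parents (A,B) -> unchanged; marker 2: swapped -> flipped
        assert _calls_as_strings(out) == ["AB", "BA"]
        assert rep.n_removed_uninformative == 1
        assert rep.n_phase_flipped == 1

    def test_unknown_parent(self):
        table = table_from_patterns({"P1": "A", "L1": "B"})
        with pytest.raises(KeyError):
            curation.phase_to_parents(table, "P1", "nope")


class TestDoubleCrossovers:
    @pytest.mark.parametrize("pattern, expected", [
        ("AABAA", 1),   # singleton disagreement
        ("AAAA", 0),
        ("AABBAA", 0),  # block of two is not a double crossover
        ("AUBAA", 1),   # missing flank skipped: B framed by A...A
        ("AHBHA", 1),   # het flanks skipped the same way
    ])
    def test_single_line_patterns(self, pattern, expected):
        table = table_from_patterns({"L1": pattern})
        per_marker, per_line = curation.count_double_crossovers(table)
        assert per_line["L1"] == expected
        assert per_marker.sum() == expected

    def test_counts_do_not_cross_chromosomes(self):
        table = table_from_patterns(
            {"L1": "AABAA"}, chrom_per_marker=["c1", "c1", "c2", "c2", "c2"]
        )
        _, per_line = curation.count_double_crossovers(table)
        assert per_line["L1"] == 0


class TestCorrectPhaseAndOutliers:
    def test_reverse_phase_marker_flipped(self):
        rng = np.random.default_rng(0)
        n_lines = 60
        base = rng.integers(0, 2, n_lines)  # shared genotype for 3 markers
        calls = np.stack([base, 1 - base, base]) + 1  # middle marker reversed
        table = table_from_patterns({f"L{i}": "AAA" for i in range(n_lines)})
        table.calls[:] = calls.astype(np.int8)
        out, rep = curation.correct_phase_and_outliers(table)
        assert rep.n_phase_flipped == 1
        assert np.array_equal(out.calls[1], out.calls[0])
        assert rep.converged

    def test_clean_table_is_fixed_point(self):
        rng = np.random.default_rng(1)
        base = (rng.integers(0, 2, 80) + 1).astype(np.int8)
        table = table_from_patterns({f"L{i}": "AAAA" for i in range(80)})
        table.calls[:] = np.stack([base] * 4)
        out, rep = curation.correct_phase_and_outliers(table)
        assert rep.n_phase_flipped == 0
        assert rep.n_outliers_removed == 0
        assert np.array_equal(out.calls, table.calls)

    def test_random_marker_removed_as_outlier(self):
        rng = np.random.default_rng(2)
        base = (rng.integers(0, 2, 200) + 1).astype(np.int8)
        noise = (rng.integers(0, 2, 200) + 1).astype(np.int8)
        table = table_from_patterns({f"L{i}": "AAA" for i in range(200)})
        table.calls[:] = np.stack([base, noise, base])
        out, rep = curation.correct_phase_and_outliers(table)
        assert rep.n_outliers_removed == 1
        assert list(out.markers["marker"]) == ["m1", "m3"]


class TestImputeGbsi:
    def test_same_flanks_filled(self):
        table = table_from_patterns({"L1": "AUUA"})
        out, rep = curation.impute_gbsi(table)
        assert _calls_as_strings(out) == list("AAAA")
        assert rep.n_cells_imputed == 2

    def test_differing_flanks_leave_uncertainty_zone(self):
        table = table_from_patterns({"L1": "AUUB"})
        out, _ = curation.impute_gbsi(table)  # default zone = 1
        assert _calls_as_strings(out) == list("AAUB")

    def test_zone_zero_fills_to_midpoint(self):
        table = table_from_patterns({"L1": "AUUB"})
        out, _ = curation.impute_gbsi(table, uncertainty_zone=0)
        assert _calls_as_strings(out) == list("AABB")

    def test_terminal_runs_stay_missing_by_default(self):
        table = table_from_patterns({"L1": "UUA"})
        out, _ = curation.impute_gbsi(table)
        assert _calls_as_strings(out) == list("UUA")
        out2, _ = curation.impute_gbsi(table, fill_terminal=True)
        assert _calls_as_strings(out2) == list("AAA")

    def test_singleton_repair(self):
        table = table_from_patterns({"L1": "AABAA"})
        out, rep = curation.impute_gbsi(table)
        assert _calls_as_strings(out) == list("AAAAA")
        assert rep.n_singletons_repaired == 1

    def test_het_calls_untouched_and_block_runs(self):
        table = table_from_patterns({"L1": "AHUHB"})
        out, _ = curation.impute_gbsi(table)
        assert _calls_as_strings(out) == list("AHUHB")

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.sampled_from("ABHU"), min_size=1, max_size=30),
           st.integers(min_value=0, max_value=3))
    def test_imputation_idempotent(self, chars, zone):
        table = table_from_patterns({"L1": "".join(chars)})
        once, _ = curation.impute_gbsi(table, uncertainty_zone=zone)
        twice, _ = curation.impute_gbsi(once, uncertainty_zone=zone)
        assert np.array_equal(once.calls, twice.calls)


class TestCurationChain:
    def test_chain_reduces_double_crossovers_and_recovers_truth(self):
        cfg = rm.SimConfig(layout=rm.toy_layout(2, 200), n_lines=120,
                           generations=7, markers_per_chromosome=120,
                           cm_per_mbp=0.2, missing_rate=0.3, het_rate=0.0,
                           miscall_rate=0.01, seed=42)
        truth, _ = rm.simulate_ril(cfg)
        observed = rm.degrade(truth, cfg)
        filtered, _ = curation.filter_markers(observed)
        corrected, _ = curation.correct_phase_and_outliers(filtered)
        imputed, _ = curation.impute_gbsi(corrected)
        d0 = curation.count_double_crossovers(filtered)[1].to_numpy()
        d1 = curation.count_double_crossovers(corrected)[1].to_numpy()
        d2 = curation.count_double_crossovers(imputed)[1].to_numpy()
        assert (d1 <= d0).all() and (d2 <= d1).all()

        keep = truth.markers["marker"].isin(imputed.markers["marker"])
        tr = truth.calls[keep.to_numpy()]
        fkeep = filtered.markers["marker"].isin(imputed.markers["marker"])
        obs = filtered.calls[fkeep.to_numpy()]
        newly = (obs == MISSING) & (imputed.calls != MISSING)
        assert newly.sum() > 1000
        accuracy = (imputed.calls[newly] == tr[newly]).mean()
        assert accuracy >= 0.95
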