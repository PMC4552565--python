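import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdaa.inference import (
    DIRECT,
    INVERTED,
    DissimilarityTable,
    StepSignal,
    build_delay_grid,
    build_dissimilarity_table,
    consensus_predict,
    dissimilarity,
    infer_network,
    step_signal,
    ternarize,
    threshold_diagnostics,
)
from cdaa.preprocessing import ChangeSeries
from cdaa.stage_separation import Stage

TIMES = np.array([0.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0])


def change_series(norm_rows: dict, times) -> ChangeSeries:
    times = np.asarray(times, dtype=float)
    norm = pd.DataFrame.from_dict(norm_rows, orient="index")
    norm.columns = pd.RangeIndex(1, len(times))
    return ChangeSeries(raw=norm.copy(), normalized=norm, times=times)


class TestDelayGrid:
    def test_canonical_uneven_grid(self):
        grid = build_delay_grid(TIMES, (0.0, 12.0), (12.0, 24.0))
        assert grid.delta_t == 3.0
        assert grid.m == 4
        assert grid.delays == (0.0, 3.0, 6.0, 9.0)
        assert grid.eval_points == (3.0, 6.0, 9.0, 12.0)

    def test_minimum_window_limits_m(self):
        grid = build_delay_grid([0.0, 1.0, 2.0, 3.0], (0.0, 2.0), (2.0, 3.0))
        assert grid.delta_t == 1.0
        assert grid.m == 1
        assert grid.delays == (0.0,)

    def test_stage_objects_accepted(self):
        grid = build_delay_grid(
            TIMES, Stage("Initiation", 0, 12), Stage("PrimaryResponse", 12, 24)
        )
        assert grid.m == 4

    def test_non_commensurable_times_rejected(self):
        with pytest.raises(ValueError, match="non-commensurable"):
            build_delay_grid([0.0, 1.0, 2.0, 2.0 + 1e-7], (0.0, 2.0), (2.0, 2.0 + 1e-7))


class TestStepSignal:
    def test_half_open_hold(self):
        sig = StepSignal("g", np.array([0.0, 3.0, 6.0]), np.array([0.8, -0.4]))
        assert sig(3.0) == 0.8
        assert sig(3.001) == -0.4
        assert sig(6.0) == -0.4

    @pytest.mark.parametrize("t", [0.0, -1.0, 6.5])
    def test_domain_errors(self, t):
        sig = StepSignal("g", np.array([0.0, 3.0, 6.0]), np.array([0.8, -0.4]))
        with pytest.raises(ValueError, match="domain"):
            sig(t)

    def test_event_thresholding_boundary_maps_to_zero(self):
        vals = np.array([0.8, -0.4, 0.39])
        np.testing.assert_array_equal(ternarize(vals, 0.4), [1, 0, 0])

    def test_zero_threshold_is_the_sign_function(self):
        vals = np.array([0.8, -0.4, 0.0, 0.39])
        np.testing.assert_array_equal(ternarize(vals, 0.0), np.sign(vals))

    def test_step_signal_from_change_series(self):
        ch = change_series({"g": [1.0, -0.5, 0.25]}, [0, 1, 2, 3])
        sig = step_signal(ch, "g", thr=0.4)
        np.testing.assert_array_equal(sig.values, [1, -1, 0])
        with pytest.raises(KeyError):
            step_signal(ch, "missing")


def brute_force_dissimilarity(reg_vals, tgt_vals, times, reg_win, tgt_win):
    """Independent oracle: rational-arithmetic gcd, explicit interval scan."""
    fr = [Fraction(str(b)) - Fraction(str(a)) for a, b in zip(times[:-1], times[1:])]
    g = fr[0]
    for f in fr[1:]:
        g = Fraction(math.gcd(g.numerator * f.denominator, f.numerator * g.denominator),
                     g.denominator * f.denominator)
    dt = float(g)
    m = int(min((reg_win[1] - reg_win[0]) / dt, (tgt_win[1] - tgt_win[0]) / dt))

    def hold(vals, t):
        for k in range(len(times) - 1):
            if times[k] < t <= times[k + 1]:
                return vals[k]
        raise AssertionError("outside domain")

    results = []
    for mm in range(m):
        d = d_hat = 0.0
        for i in range(m):
            ti = reg_win[0] + (i + 1) * dt
            r = hold(reg_vals, ti)
            s = hold(tgt_vals, ti + mm * dt)
            d += abs(r - s)
            d_hat += abs(-r - s)
        d, d_hat = d / m, d_hat / m
        results.append((min(d, d_hat), DIRECT if d <= d_hat else INVERTED))
    return dt, m, results


class TestDissimilarity:
    def test_identical_signals_score_zero_at_zero_delay(self):
        ch = change_series({"a": [1, 0.5, -0.2, -0.2, 0, 0],
                            "b": [1, 0.5, -0.2, -0.2, 0, 0]}, TIMES)
        grid = build_delay_grid(TIMES, (0, 12), (12, 24))
        scores, orients = dissimilarity(
            step_signal(ch, "a"), step_signal(ch, "b"), grid
        )
        assert scores[0] == 0.0
        assert orients[0] == DIRECT

    def test_negated_signal_scores_zero_inverted(self):
        ch = change_series({"a": [1, 0.5, -0.2, -0.2, 0, 0],
                            "b": [-1, -0.5, 0.2, 0.2, 0, 0]}, TIMES)
        grid = build_delay_grid(TIMES, (0, 12), (12, 24))
        scores, orients = dissimilarity(
            step_signal(ch, "a"), step_signal(ch, "b"), grid
        )
        assert scores[0] == 0.0
        assert orients[0] == INVERTED

    def test_shifted_copy_scores_zero_at_its_delay(self):
        times = list(range(9))
        ch = change_series(
            {"reg": [1, 0.5, -0.2, -0.2, 0, 0, 0, 0],
             "tgt": [0, 1, 0.5, -0.2, -0.2, 0, 0, 0]},
            times,
        )
        grid = build_delay_grid(times, (0, 4), (4, 8))
        scores, orients = dissimilarity(
            step_signal(ch, "reg"), step_signal(ch, "tgt"), grid
        )
        assert scores[1] == pytest.approx(0.0, abs=1e-12)
        assert orients[1] == DIRECT
        assert all(s > 0 for i, s in enumerate(scores) if i != 1)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 7)
        times = np.sort(rng.choice(np.arange(13), size=n, replace=False)).astype(float)
        cut1, cut2 = sorted(rng.choice(np.arange(1, n), size=2, replace=False))
        if cut1 == 0 or cut2 == cut1:
            return
        reg_win = (times[0], times[cut1])
        tgt_win = (times[cut1], times[cut2])
        reg_vals = rng.uniform(-1, 1, size=n - 1)
        tgt_vals = rng.uniform(-1, 1, size=n - 1)
        ch = change_series({"r": reg_vals, "t": tgt_vals}, times)
        grid = build_delay_grid(times, reg_win, tgt_win)
        scores, orients = dissimilarity(step_signal(ch, "r"), step_signal(ch, "t"), grid)
        dt, m, expected = brute_force_dissimilarity(
            reg_vals, tgt_vals, times, reg_win, tgt_win
        )
        assert grid.delta_t == pytest.approx(dt, abs=1e-12)
        assert grid.m == m
        for j in range(m):
            assert scores[j] == pytest.approx(expected[j][0], abs=1e-12)
            assert orients[j] == expected[j][1]
        assert (scores >= 0).all() and (scores <= 2).all()


class TestDissimilarityTable:
    grid_times = TIMES

    def build(self, rows, thr=None, strict=False):
        ch = change_series(rows, self.grid_times)
        grid = build_delay_grid(self.grid_times, (0, 12), (12, 24))
        cands = [g for g in rows if g != "tgt"]
        return build_dissimilarity_table(
            "tgt", cands, ch, grid, thr, strict_zero_delay=strict
        )

    def test_coexpressed_candidate_discarded(self):
        table = self.build({"tgt": [1, 0.5, -0.2, -0.2, 0, 0],
                            "copy": [1, 0.5, -0.2, -0.2, 0, 0]})
        assert not table.kept["copy"]
        assert table.surviving.empty

    def test_delayed_candidate_kept_at_positive_delay(self):
        # tgt(t) == cand(t - 3): exact one-step delayed copy on this grid
        table = self.build({"cand": [1, -0.4, -0.4, -0.4, 0, 0],
                            "tgt": [0, 1, -0.4, -0.4, -0.4, 0]})
        assert bool(table.kept["cand"])
        assert table.best.loc["cand", "delay_hours"] == 3.0
        assert table.best.loc["cand", "score"] == pytest.approx(0.0, abs=1e-12)

    def test_all_tied_flat_rows_keep_smallest_positive_delay(self):
        table = self.build({"flat": [0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
                            "tgt": [0.1, 0.1, 0.1, 0.1, 0.1, 0.1]}, thr=0.4)
        assert bool(table.kept["flat"])
        assert table.best.loc["flat", "delay_hours"] == 3.0
        assert table.best.loc["flat", "score"] == 0.0

    def test_strict_policy_discards_zero_delay_ties(self):
        table = self.build({"flat": [0.1] * 6, "tgt": [0.1] * 6}, thr=0.4, strict=True)
        assert not table.kept["flat"]

    def test_target_cannot_be_its_own_candidate(self):
        ch = change_series({"tgt": [1, 0, 0, 0, 0, 0]}, self.grid_times)
        grid = build_delay_grid(self.grid_times, (0, 12), (12, 24))
        with pytest.raises(ValueError, match="own candidate"):
            build_dissimilarity_table("tgt", ["tgt"], ch, grid)

    def test_empty_candidate_list_warns(self):
        ch = change_series({"tgt": [1, 0, 0, 0, 0, 0]}, self.grid_times)
        grid = build_delay_grid(self.grid_times, (0, 12), (12, 24))
        with pytest.warns(UserWarning, match="no candidate regulators"):
            table = build_dissimilarity_table("tgt", [], ch, grid)
        assert table.scores.empty


def toy_table(target, entries, thr):
    """A minimal table: entries = {regulator: (score, delay, orientation)}."""
    index = pd.Index(list(entries), name="regulator")
    best = pd.DataFrame(
        {
            "score": [entries[r][0] for r in index],
            "delay_hours": [entries[r][1] for r in index],
            "orientation": [entries[r][2] for r in index],
        },
        index=index,
    )
    return DissimilarityTable(
        target=target, threshold=thr, grid=None,
        scores=pd.DataFrame(index=index), orientations=pd.DataFrame(index=index),
        kept=pd.Series(True, index=index), best=best,
    )


class TestConsensus:
    # appearance pattern of candidate upstream factors for the iron-response
    # target PYE under the unthresholded, 0.2- and 0.4-thresholded signals
    PATTERN = {
        "ASIL2": (True, True, True),
        "ETF9": (True, False, True),
        "WRKY57": (True, False, True),
        "MYB55": (True, True, False),
        "GNU1": (False, True, False),
        "TG": (False, True, False),
        "LRL3": (False, True, False),
        "WRKY26": (False, True, False),
        "RD26": (False, True, False),
        "COL4": (False, True, True),
        "TGA2": (False, False, True),
        "OBP4": (False, False, True),
    }

    def tables(self):
        out = []
        for j, thr in enumerate([None, 0.2, 0.4]):
            entries = {
                reg: (0.2 if appears[j] else 0.9, 3.0, DIRECT)
                for reg, appears in self.PATTERN.items()
            }
            out.append(toy_table("PYE", entries, thr))
        return out

    def test_two_of_three_rule_selects_the_multi_support_regulators(self):
        edges = consensus_predict("PYE", self.tables(), cutoff=0.4, min_support=2)
        assert {e.regulator for e in edges} == {
            "ASIL2", "ETF9", "WRKY57", "MYB55", "COL4"
        }
        assert all(e.n_supporting_thresholds >= 2 for e in edges)

    def test_single_support_regulators_are_excluded(self):
        edges = consensus_predict("PYE", self.tables(), cutoff=0.4, min_support=2)
        kept = {e.regulator for e in edges}
        for single in ["GNU1", "TG", "LRL3", "WRKY26", "RD26", "TGA2", "OBP4"]:
            assert single not in kept

    def test_sign_and_delay_come_from_the_best_supporting_table(self):
        tables = [
            toy_table("t", {"r": (0.30, 3.0, DIRECT)}, None),
            toy_table("t", {"r": (0.10, 6.0, INVERTED)}, 0.2),
            toy_table("t", {"r": (0.35, 9.0, DIRECT)}, 0.4),
        ]
        (edge,) = consensus_predict("t", tables, cutoff=0.4, min_support=2)
        assert edge.sign == -1
        assert edge.delay_hours == 6.0
        assert edge.min_dissimilarity == 0.10
        assert edge.n_supporting_thresholds == 3


class TestThresholdDiagnostics:
    def make_series(self):
        return change_series(
            {"a": [1.0, 0.3, 0.1, 0.5, 0, 0], "b": [0.25, -1.0, 0.0, 0.9, 0, 0]},
            TIMES,
        )

    def test_zero_threshold_counts_nonzero_changes(self):
        ch = self.make_series()
        diag = threshold_diagnostics(ch, ["a", "b"], [0.0], boundary_time=12.0)
        # a: 3 nonzero early changes, b: 2 -> mean 2.5
        assert diag[0.0] == pytest.approx(2.5)

    def test_unit_threshold_leaves_nothing(self):
        ch = self.make_series()
        diag = threshold_diagnostics(ch, ["a", "b"], [1.0], boundary_time=12.0)
        assert diag[1.0] == 0.0

    def test_monotone_in_threshold(self):
        ch = self.make_series()
        levels = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        diag = threshold_diagnostics(ch, ["a", "b"], levels, boundary_time=12.0)
        assert (np.diff(diag.to_numpy()) <= 1e-12).all()


@given(
    values=st.lists(st.floats(-1, 1, allow_nan=False), min_size=4, max_size=8),
    thr_pair=st.tuples(st.floats(0, 1), st.floats(0, 1)),
)
def test_ternarized_nonzero_count_non_increasing_in_threshold(values, thr_pair):
    lo, hi = sorted(thr_pair)
    vals = np.asarray(values)
    assert np.count_nonzero(ternarize(vals, hi)) <= np.count_nonzero(
        ternarize(vals, lo)
    )


class TestInferNetwork:
    def test_duplicated_target_in_pool_yields_no_self_edge(self, clean_cascade):
        from cdaa.preprocessing import changes, drop_constant_genes, zscore_normalize
        from cdaa.stage_separation import separate_stages

        _, expr, truth = clean_cascade
        x, _ = drop_constant_genes(expr)
        x = x.copy()
        x.loc["tgt_1_copy"] = x.loc["tgt_1"]
        part = separate_stages(changes(zscore_normalize(x)))
        regs = [f"reg_{i}" for i in range(1, 6)] + ["tgt_1_copy"]
        net = infer_network(x, part, ["tgt_1"], regulator_pool=regs)
        assert ("tgt_1_copy", "tgt_1") not in net.edge_set()
        assert ("tgt_1", "tgt_1") not in net.edge_set()

    def test_empty_pool_gives_empty_network(self, clean_cascade):
        from cdaa.preprocessing import changes, drop_constant_genes, zscore_normalize
        from cdaa.stage_separation import separate_stages

        _, expr, _ = clean_cascade
        x, _ = drop_constant_genes(expr)
        part = separate_stages(changes(zscore_normalize(x)))
        with pytest.warns(UserWarning):
            net = infer_network(x, part, ["tgt_1"], regulator_pool=[])
        assert len(net) == 0

    def test_fewer_than_two_thresholds_rejected(self, clean_cascade):
        from cdaa.preprocessing import changes, drop_constant_genes, zscore_normalize
        from cdaa.stage_separation import separate_stages

        _, expr, _ = clean_cascade
        x, _ = drop_constant_genes(expr)
        part = separate_stages(changes(zscore_normalize(x)))
        with pytest.raises(ValueError, match="2 threshold"):
            infer_network(x, part, ["tgt_1"], regulator_pool=["reg_1"],
                          thresholds=(0.4,))
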