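"""Cell tables, contrast ANOVA vs independent oracles, Wilcoxon enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from driftgaze.inference import (
    CellTable,
    MissingCellError,
    cell_means,
    paired_t_test,
    parameter_effects,
    rm_anova,
    wilcoxon_test,
)
from driftgaze.params import CONDITIONS
from driftgaze.session import Session
from tests.conftest import make_trials


class TestCellMeans:
    def test_hand_counted_16_trial_fixture(self):
        rows = []
        for cond_id, (identity, preview) in {
            "FP": ("face", "preview"), "FO": ("face", "outline"),
            "NP": ("noise", "preview"), "NO": ("noise", "outline"),
        }.items():
            # per condition: 4 trials, face chosen k times
            k = {"FP": 3, "FO": 2, "NP": 1, "NO": 0}[cond_id]
            for i in range(4):
                rows.append(("P1", identity, preview, "face" if i < k else "noise", 300.0 + i))
        table = cell_means(Session(make_trials(rows)), "face_choice", "2x2")
        expected = {"FP": 0.75, "FO": 0.5, "NP": 0.25, "NO": 0.0}
        for c in CONDITIONS:
            v = table.values.loc["P1", [(c,)]].iloc[0]
            assert v == expected[c]
            assert 0 <= v <= 1
        assert not table.missing

    def test_missing_outcome_cell_flagged(self):
        rows = [("P1", "face", "preview", "face", 300.0)] * 3
        rows += [("P1", "face", "outline", "noise", 300.0)]
        table = cell_means(Session(make_trials(rows)), "fixation_duration", "2x2x2")
        assert ("P1", ("FP", "noise")) in table.missing

    def test_balanced_synthetic_session_has_no_missing_2x2_cells(self, small_session):
        table = cell_means(small_session, "fixation_duration", "2x2")
        assert not table.missing


def brute_force_rm_anova_2x2x2(cube):
    """Full repeated-measures sums-of-squares decomposition oracle.

    ``cube``: participants x 2 x 2 x 2 array. Returns {effect index: (F, p)}
    with effects keyed by the non-empty subsets of factor axes (1, 2, 3).
    """
    from scipy import stats

    n = cube.shape[0]
    out = {}
    for r in range(1, 4):
        for axes in itertools.combinations((1, 2, 3), r):
            # effect component per participant and cell: apply the centering
            # operator (I - mean) along effect axes, the mean along the rest
            contrib = cube.copy()
            for ax in (1, 2, 3):
                m = contrib.mean(axis=ax, keepdims=True)
                if ax in axes:
                    contrib = contrib - m
                else:
                    contrib = m
            # contrib now holds the effect component per participant/cell
            per_part = contrib.reshape(n, -1)
            cell_effect = per_part.mean(0)
            ss_effect = n * (cell_effect**2).sum()
            ss_inter = (per_part**2).sum() - ss_effect  # effect x participant
            df1 = 1  # all factors two-level
            df2 = n - 1
            F = (ss_effect / df1) / (ss_inter / df2)
            out[axes] = (F, stats.f.sf(F, df1, df2))
    return out


class TestRmAnova:
    def test_f_equals_squared_paired_t(self, rng):
        n = 9
        cube = rng.normal(size=(n, 2, 2))
        values = pd.DataFrame(
            cube.reshape(n, 4),
            index=[f"P{i}" for i in range(n)],
            columns=[(c,) for c in CONDITIONS],
        )
        table = CellTable(values=values, design="2x2", measure="x")
        res = rm_anova(table)
        # inspection effect: mean(FP,FO) - mean(NP,NO) per participant
        scores = cube.reshape(n, 4) @ np.array([1, 1, -1, -1]) / 2
        t = scores.mean() / (scores.std(ddof=1) / np.sqrt(n))
        assert res.loc["inspection", "F"] == pytest.approx(t**2, rel=1e-12)
        assert res.loc["inspection", "df2"] == n - 1

    def test_pure_main_effect_has_zero_interaction(self):
        n = 6
        base = np.arange(n, dtype=float)[:, None, None]
        cube = np.broadcast_to(base, (n, 2, 2)).copy()
        cube[:, 0, :] += 5.0  # factor-1 main effect only, zero noise
        values = pd.DataFrame(
            cube.reshape(n, 4),
            index=[f"P{i}" for i in range(n)],
            columns=[(c,) for c in CONDITIONS],
        )
        res = rm_anova(CellTable(values=values, design="2x2", measure="x"))
        assert res.loc["inspection x preview", "F"] == pytest.approx(0.0, abs=1e-18)

    def test_2x2x2_matches_brute_force_ss_decomposition(self, rng):
        n = 6
        cube = rng.normal(size=(n, 2, 2, 2)) + rng.normal(size=(n, 1, 1, 1))
        cells = list(itertools.product(CONDITIONS, ("face", "noise")))
        values = pd.DataFrame(
            cube.reshape(n, 8), index=[f"P{i}" for i in range(n)], columns=cells
        )
        res = rm_anova(CellTable(values=values, design="2x2x2", measure="x"))
        oracle = brute_force_rm_anova_2x2x2(cube)
        name_of = {(1,): "inspection", (2,): "preview", (3,): "outcome",
                   (1, 2): "inspection x preview", (1, 3): "inspection x outcome",
                   (2, 3): "preview x outcome", (1, 2, 3): "inspection x preview x outcome"}
        assert len(res) == 7
        for axes, (F, p) in oracle.items():
            assert res.loc[name_of[axes], "F"] == pytest.approx(F, rel=1e-9)
            assert res.loc[name_of[axes], "p"] == pytest.approx(p, rel=1e-9)

    def test_2x2_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 8
        cube = rng.normal(size=(n, 2, 2))
        values = pd.DataFrame(
            cube.reshape(n, 4),
            index=[f"P{i}" for i in range(n)],
            columns=[(c,) for c in CONDITIONS],
        )
        res = rm_anova(CellTable(values=values, design="2x2", measure="x"))
        long = pd.DataFrame(
            {
                "participant": np.repeat(np.arange(n), 4),
                "identity": np.tile(["face", "face", "noise", "noise"], n),
                "preview": np.tile(["p", "o", "p", "o"], n),
                "y": cube.reshape(-1),
            }
        )
        pg = pingouin.rm_anova(
            data=long, dv="y", within=["identity", "preview"], subject="participant",
            detailed=True,
        ).set_index("Source")
        assert res.loc["inspection", "F"] == pytest.approx(pg.loc["identity", "F"], rel=1e-6)
        assert res.loc["preview", "F"] == pytest.approx(pg.loc["preview", "F"], rel=1e-6)
        assert res.loc["inspection x preview", "F"] == pytest.approx(
            pg.loc["identity * preview", "F"], rel=1e-6
        )

    def test_missing_cells_raise_with_participants_named(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0, np.nan], [1.0, 2.0, 3.0, 4.0]],
            index=["P1", "P2"],
            columns=[(c,) for c in CONDITIONS],
        )
        table = CellTable(values=values, design="2x2", measure="x",
                          missing=[("P1", ("NO",))])
        with pytest.raises(MissingCellError) as err:
            rm_anova(table)
        assert err.value.participants == ["P1"]


class TestSimpleTests:
    def test_antisymmetric_sample_gives_t_zero_p_one(self):
        res = paired_t_test(np.array([0.4, 0.6, 0.3, 0.7]), popmean=0.5)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0, abs=1e-12)

    def test_paired_t_matches_hand_computation(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([0.0, 1.0, 1.0])
        d = x - y  # [1, 1, 3], mean 5/3, sd 2/sqrt(3)
        t_hand = (5 / 3) / ((2 / np.sqrt(3)) / np.sqrt(3))
        res = paired_t_test(x, y)
        assert res["t"] == pytest.approx(t_hand, rel=1e-12)
        assert res["df"] == 2

    def test_wilcoxon_exact_p_matches_full_sign_enumeration(self):
        values = np.array([0.62, 0.55, 0.48, 0.71, 0.53, 0.44])
        ref = 0.5
        res = wilcoxon_test(values, ref)
        # enumerate all 2^6 sign assignments of the |difference| ranks
        d = values - ref
        ranks = pd.Series(np.abs(d)).rank().to_numpy()
        W_obs = ranks[d > 0].sum()
        total = ranks.sum()
        stats_all = []
        for signs in itertools.product([0, 1], repeat=len(d)):
            w_pos = ranks[np.array(signs, bool)].sum()
            stats_all.append(min(w_pos, total - w_pos))
        W_two = min(W_obs, total - W_obs)
        p_exact = np.mean([s <= W_two for s in stats_all])
        assert res["p"] == pytest.approx(p_exact, abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_test(np.full(5, 0.5), 0.5)
        assert res["p"] == 1.0 and res["n"] == 0


class TestParameterEffects:
    def _truth_table(self, seed, n, null=False):
        from driftgaze.synth import SyntheticConfig, sample_population_params
        from driftgaze.params import DDMParams

        means = None
        if null:
            flat = DDMParams(a=1.0, zr=0.5, v=0.3, t0=0.2, sv=0.3, sz=0.1, st0=0.08)
            means = {c: flat for c in CONDITIONS}
        kwargs = {"population_means": means} if means else {}
        cfg = SyntheticConfig(n_participants=n, seed=seed, **kwargs)
        params = sample_population_params(cfg)
        rows = [
            {"participant_id": pid, "condition": c,
             "v": params[pid][c].v, "t0": params[pid][c].t0, "a": params[pid][c].a}
            for pid in params for c in CONDITIONS
        ]
        return pd.DataFrame(rows)

    def test_report_means_match_input_columns(self):
        table = self._truth_table(0, 8)
        report = parameter_effects(table)
        for c in CONDITIONS:
            expected = table.loc[table["condition"] == c, "v"].mean()
            assert report.condition_stats.loc[("v", c), "mean"] == pytest.approx(expected)

    def test_drift_interaction_detected_more_often_than_t0_interaction(self):
        v_hits = t0_hits = 0
        n_exp = 20
        for seed in range(n_exp):
            report = parameter_effects(self._truth_table(1000 + seed, 24))
            v_hits += report.anovas["v"].loc["inspection x preview", "p"] < 0.05
            t0_hits += report.anovas["t0"].loc["inspection x preview", "p"] < 0.05
        assert v_hits > n_exp / 2  # generating truth carries a v interaction
        assert v_hits > t0_hits

    def test_null_generator_false_positive_rate_near_alpha(self):
        hits = 0
        n_exp = 200
        for seed in range(n_exp):
            report = parameter_effects(self._truth_table(5000 + seed, 12, null=True))
            hits += report.anovas["v"].loc["inspection x preview", "p"] < 0.05
        assert hits / n_exp == pytest.approx(0.05, abs=0.04)
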