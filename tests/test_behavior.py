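import numpy as np
import pandas as pd
import pytest
from scipy import stats

from erfp.behavior import (
    cell_means,
    paired_t,
    rm_anova_2x2,
    summarize_effects,
)
from erfp.exceptions import DegenerateInputError, DesignError


class TestPairedT:
    def test_identical_cells(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.statistic, res.effect_size, res.p) == (0.0, 0.0, 1.0)

    def test_closed_form_diffs_123(self):
        res = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.df == (2,)
        assert res.effect_size == pytest.approx(2.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        a = rng.normal(700, 50, 12)
        b = rng.normal(650, 50, 12)
        r1 = paired_t(a, b)
        r2 = paired_t(2 * a, 2 * b)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-9)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)
        assert r1.effect_size == pytest.approx(r2.effect_size, abs=1e-12)

    def test_matches_scipy(self, rng):
        a = rng.normal(700, 50, 20)
        b = rng.normal(650, 50, 20)
        res = paired_t(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_constant_nonzero_difference(self):
        res = paired_t([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert res.degenerate and np.isnan(res.statistic)

    def test_too_few_participants(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0], [2.0])


def _long_table(cells, participants=6, noise=0.0, seed=0):
    """cells: {(soa, load): mean}"""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(participants):
        offset = rng.normal(0, 20)
        for (soa, load), mu in cells.items():
            rows.append(
                {
                    "participant": p,
                    "soa": soa,
                    "task_load": load,
                    "rt_ms": mu + offset + rng.normal(0, noise),
                }
            )
    return pd.DataFrame(rows)


class TestRmAnova2x2:
    def test_f_equals_t_squared(self, rng):
        cells = {(100, "report"): 850, (1000, "report"): 650,
                 (100, "ignore"): 720, (1000, "ignore"): 625}
        data = _long_table(cells, participants=10, noise=30.0, seed=1)
        res = rm_anova_2x2(data, dv="rt_ms")
        cm = data.groupby(["participant", "soa"])["rt_ms"].mean().unstack()
        t_soa = paired_t(cm[100], cm[1000])
        assert res["soa"].statistic == pytest.approx(t_soa.statistic**2, abs=1e-9)

    def test_hand_computed_sums_of_squares(self):
        # 3 participants x 4 cells, integer-friendly toy data
        data = pd.DataFrame(
            {
                "participant": [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3],
                "soa": [100, 100, 1000, 1000] * 3,
                "task_load": ["report", "ignore"] * 6,
                "rt_ms": [10.0, 6, 7, 5, 12, 7, 8, 7, 14, 9, 8, 6],
            }
        )
        res = rm_anova_2x2(data, dv="rt_ms")
        # oracle: classical sum-of-squares decomposition for the SOA effect
        wide = data.set_index(["participant", "soa", "task_load"])["rt_ms"].unstack([1, 2])
        n, b = 3, 2  # participants, levels of the other factor
        m_sa = wide.T.groupby(level="soa").mean().T  # participant x soa means
        grand = wide.to_numpy().mean()
        m_a = m_sa.mean(axis=0)
        m_s = m_sa.mean(axis=1)
        ss_a = n * b * ((m_a - grand) ** 2).sum()
        resid = m_sa.sub(m_a, axis=1).sub(m_s, axis=0) + grand
        ss_err = b * (resid**2).to_numpy().sum()
        f = ss_a / (ss_err / (n - 1))
        assert res["soa"].statistic == pytest.approx(f, abs=1e-9)
        assert res["soa"].effect_size == pytest.approx(ss_a / (ss_a + ss_err), abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        cells = {(100, "report"): 850, (1000, "report"): 650,
                 (100, "ignore"): 720, (1000, "ignore"): 625}
        data = _long_table(cells, participants=8, noise=40.0, seed=3)
        res = rm_anova_2x2(data, dv="rt_ms")
        ref = pg.rm_anova(
            data=data, dv="rt_ms", within=["soa", "task_load"], subject="participant",
            detailed=True,
        ).set_index("Source")
        for mine, theirs in [
            ("soa", "soa"), ("task_load", "task_load"), ("interaction", "soa * task_load"),
        ]:
            assert res[mine].statistic == pytest.approx(ref.loc[theirs, "F"], rel=1e-6)
            assert res[mine].p == pytest.approx(ref.loc[theirs, "p_unc"], rel=1e-6)

    def test_zero_interaction_contrast(self):
        cells = {(100, "report"): 800, (1000, "report"): 700,
                 (100, "ignore"): 750, (1000, "ignore"): 650}
        data = _long_table(cells, participants=5, noise=0.0, seed=0)
        res = rm_anova_2x2(data, dv="rt_ms")
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_missing_cell_rejected(self):
        data = _long_table({(100, "report"): 800, (1000, "report"): 700}, participants=3)
        with pytest.raises(DesignError):
            rm_anova_2x2(data, dv="rt_ms")


class TestSummarizeEffects:
    def test_hand_built_two_participant_table(self):
        rows = []
        for p, (short, long_) in {1: (900, 650), 2: (800, 600)}.items():
            for soa, rt in ((100, short), (1000, long_)):
                for k in range(2):
                    rows.append(
                        {"participant": p, "soa": soa, "rt_ms": float(rt), "trial": k}
                    )
        out = summarize_effects(pd.DataFrame(rows), experiment=1)
        assert out["mean_rt_short_soa"] == 850.0
        assert out["mean_rt_long_soa"] == 625.0
        assert out["soa_effect_ms"] == 225.0

    def test_symmetric_data_no_effects(self, rng):
        rows = []
        for p in range(6):
            for soa in (100, 1000):
                for load in ("report", "ignore"):
                    for _ in range(10):
                        rows.append(
                            {
                                "participant": p,
                                "soa": soa,
                                "task_load": load,
                                "rt_ms": rng.normal(700, 30),
                            }
                        )
        out = summarize_effects(pd.DataFrame(rows), experiment=2)
        se = 30 / np.sqrt(10) * 2  # rough scale of a null effect
        assert abs(out["dual_task_cost_ms"]) < 3 * se
        assert abs(out["soa_effect_ms"]) < 3 * se

    def test_row_order_invariance(self, rng):
        rows = _long_table(
            {(100, "report"): 850, (1000, "report"): 650,
             (100, "ignore"): 720, (1000, "ignore"): 625},
            participants=5, noise=25.0, seed=2,
        )
        a = summarize_effects(rows, experiment=2)
        b = summarize_effects(rows.sample(frac=1.0, random_state=4), experiment=2)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(DesignError):
            summarize_effects(pd.DataFrame(), experiment=1)

    def test_cell_means_shape(self, rng):
        t = _long_table({(100, "report"): 800, (1000, "report"): 700,
                         (100, "ignore"): 780, (1000, "ignore"): 690}, participants=4)
        cm = cell_means(t, factors=("soa", "task_load"))
        assert cm.shape == (4, 4)
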