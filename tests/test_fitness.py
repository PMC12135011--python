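"""Selection-coefficient inference: QC filters, MLE vs grid oracles,
normalization, invariances."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from lineagefit import (
    GenotypeClass,
    InferenceOptions,
    LineageCountTable,
    SimDesign,
    apply_qc_filters,
    estimate_fitness,
    fit_replicate,
    normalize_to_wildtype,
    simulate_replicate,
)
from lineagefit.fitness import FitnessEstimateSet, QCError


def make_table(counts_dict, classes=None, **kw):
    df = pd.DataFrame(counts_dict).T
    df.columns = [f"T{k}" for k in range(df.shape[1])]
    df.columns = ["P0"] + list(df.columns[1:])
    df.index.name = "barcode"
    if classes is None:
        classes = {bc: (GenotypeClass.WILD_TYPE if bc.startswith("WT")
                        else GenotypeClass.MUTANT) for bc in df.index}
    return LineageCountTable(counts=df.astype(np.int64), classes=classes, **kw)


def joint_poisson_loglik(s, counts, g=1.0):
    """Independent oracle: joint Poisson log-likelihood of all lineages under
    one-step conditional propagation, written directly from the model."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    x = counts / totals
    ll = 0.0
    for k in range(1, counts.shape[1]):
        w = x[:, k - 1] * np.exp(g * np.asarray(s))
        xhat = w / w.sum()
        mu = totals[k] * xhat
        for i in range(counts.shape[0]):
            if x[i, k - 1] == 0:
                continue
            r = counts[i, k]
            ll += (r * np.log(mu[i]) if r > 0 else 0.0) - mu[i]
    return ll


class TestQCFilters:
    def test_parental_count_at_floor_excluded(self):
        t = make_table({"WT_A": [100, 90, 80], "MUT_A": [10, 50, 60],
                        "MUT_B": [100, 90, 80]})
        kept, excl = apply_qc_filters(t)
        assert excl == {"MUT_A": "low_parental_count"}
        assert "MUT_A" not in kept.lineages

    def test_zero_final_count_excluded_as_not_surviving(self):
        t = make_table({"WT_A": [100, 90, 80], "MUT_A": [11, 5, 0],
                        "MUT_B": [100, 90, 80]})
        _, excl = apply_qc_filters(t)
        assert excl == {"MUT_A": "not_surviving"}

    def test_clean_lineages_retained(self):
        t = make_table({"WT_A": [100, 90, 80], "MUT_A": [11, 12, 13]})
        kept, excl = apply_qc_filters(t)
        assert excl == {}
        assert kept.lineages == t.lineages

    def test_class_wipeout_is_error(self):
        t = make_table({"WT_A": [5, 90, 80], "MUT_A": [100, 90, 80]})
        with pytest.raises(QCError, match="wild_type"):
            apply_qc_filters(t)

    def test_filters_apply_to_both_classes(self):
        t = make_table({"WT_A": [9, 90, 80], "WT_B": [100, 90, 80],
                        "MUT_A": [100, 90, 80]})
        _, excl = apply_qc_filters(t)
        assert excl == {"WT_A": "low_parental_count"}


class TestEstimateFitness:
    def test_identical_trajectories_get_identical_estimates(self):
        t = make_table({"WT_A": [50, 60, 70], "MUT_A": [50, 60, 70],
                        "MUT_B": [200, 180, 160]})
        est = estimate_fitness(t)
        s = est.frame["s"]
        assert s["WT_A"] == pytest.approx(s["MUT_A"], abs=1e-6)

    def test_noiseless_recovery_of_known_difference(self):
        d = SimDesign(n_wt=1, n_mut=1, s_wt=0.0, s_mut=0.3, g=1.0,
                      mode="deterministic", read_depth=10_000_000)
        res = simulate_replicate(d)
        est = estimate_fitness(res.table)
        s = est.frame["s"]
        assert s.iloc[1] - s.iloc[0] == pytest.approx(0.3, abs=1e-3)

    def test_single_lineage_conditional_grid_search(self):
        t = make_table({"WT_A": [40, 35, 30], "MUT_A": [30, 35, 42],
                        "MUT_B": [30, 30, 28]})
        est = estimate_fitness(t)
        s_hat = est.frame["s"].to_numpy()
        # fine grid over lineage 1's coefficient with the others fixed at
        # their estimates must peak at the optimizer's answer
        grid = np.arange(-2, 2, 1e-4)
        lls = [joint_poisson_loglik([s_hat[0], g, s_hat[2]], t.counts.to_numpy())
               for g in grid]
        assert abs(grid[int(np.argmax(lls))] - s_hat[1]) <= 2e-4

    def test_joint_grid_equivalence_small_instance(self, rng):
        # 2 lineages, 3 timepoints, total reads <= 100: coordinate MLE must
        # agree with exhaustive search of the joint likelihood.  Only the
        # difference s2 - s1 is identified (the likelihood is invariant to a
        # common shift), so the grid scans that direction.
        for _ in range(5):
            counts = rng.integers(1, 18, size=(2, 3))
            t = make_table({"WT_A": counts[0].tolist(),
                            "MUT_A": counts[1].tolist()})
            est = estimate_fitness(t)
            d_hat = est.frame["s"]["MUT_A"] - est.frame["s"]["WT_A"]
            grid = np.arange(-4, 4, 5e-4)
            lls = [joint_poisson_loglik([0.0, d], counts) for d in grid]
            d_grid = grid[int(np.argmax(lls))]
            assert abs(d_hat - d_grid) < 1e-3

    def test_monotonic_in_final_count(self):
        base = {"WT_A": [100, 100, 100], "MUT_A": [100, 100, 100],
                "MUT_B": [100, 100, 100]}
        prev = -np.inf
        for final in (80, 100, 130, 170):
            d = dict(base, MUT_A=[100, 100, final])
            est = estimate_fitness(make_table(d))
            s = est.frame["s"]["MUT_A"] - est.frame["s"]["WT_A"]
            assert s > prev
            prev = s

    def test_mean_fitness_trajectory_shape(self, small_table):
        est = estimate_fitness(small_table)
        assert list(est.mean_fitness.index) == small_table.timepoints
        # sbar(k) is a frequency-weighted average, so it lies within the
        # range of the per-lineage estimates
        assert est.frame["s"].min() - 1e-9 <= est.mean_fitness.min()
        assert est.mean_fitness.max() <= est.frame["s"].max() + 1e-9

    def test_requires_two_lineages_and_timepoints(self, small_table):
        with pytest.raises(ValueError):
            estimate_fitness(small_table.subset(["WT_A"]))


class TestNormalization:
    @staticmethod
    def from_values(wt, mut):
        frame = pd.DataFrame(
            {
                "class": ["wild_type"] * len(wt) + ["mutant"] * len(mut),
                "s": list(wt) + list(mut),
                "s_norm": np.nan,
                "logL": 0.0,
                "included": True,
                "exclusion_reason": "none",
                "at_bound": False,
            },
            index=[f"L{i}" for i in range(len(wt) + len(mut))],
        )
        return FitnessEstimateSet(
            frame=frame, mean_fitness=pd.Series(dtype=float),
            replicate_id="r", concentration=0.0,
        )

    def test_mean_shift_example(self):
        est = normalize_to_wildtype(self.from_values([0.1, -0.1], [0.2]))
        assert est.frame["s_norm"].iloc[2] == pytest.approx(0.2)

    def test_constant_wildtype(self):
        est = normalize_to_wildtype(self.from_values([0.7, 0.7], [0.9, 0.2]))
        assert est.frame["s_norm"].tolist() == pytest.approx([0, 0, 0.2, -0.5])

    def test_wildtype_mean_exactly_zero(self, small_table):
        est = normalize_to_wildtype(estimate_fitness(small_table))
        wt = est.included_class(GenotypeClass.WILD_TYPE)
        assert abs(wt["s_norm"].mean()) < 1e-12

    def test_no_wildtype_errors(self):
        with pytest.raises(QCError, match="wild-type"):
            normalize_to_wildtype(self.from_values([], [0.2, 0.3]))


class TestPipelineInvariances:
    def test_shift_invariance_of_normalized_estimates(self):
        # adding a constant to every true s changes nothing observable:
        # frequencies depend only on differences
        kw = dict(n_wt=3, n_mut=3, seed=17, census_N=50_000, read_depth=50_000)
        a = fit_replicate(simulate_replicate(
            SimDesign(s_wt=0.0, s_mut=0.4, **kw)).table)
        b = fit_replicate(simulate_replicate(
            SimDesign(s_wt=1.3, s_mut=1.7, **kw)).table)
        assert np.allclose(a.frame["s_norm"], b.frame["s_norm"], atol=1e-9)

    def test_fit_replicate_covers_all_lineages_once(self):
        t = make_table({"WT_A": [100, 90, 80], "WT_B": [90, 95, 85],
                        "MUT_A": [10, 50, 60], "MUT_B": [100, 90, 80]})
        est = fit_replicate(t)
        assert list(est.frame.index) == t.lineages
        assert not est.frame.loc["MUT_A", "included"]
        assert est.frame.loc["MUT_A", "exclusion_reason"] == "low_parental_count"
        assert np.isnan(est.frame.loc["MUT_A", "s_norm"])

    def test_wrightian_conversion(self):
        t = make_table({"WT_A": [100, 100, 100], "MUT_A": [100, 110, 120]})
        est = estimate_fitness(t)
        w = est.wrightian()
        assert np.allclose(w, np.expm1(est.frame["s"]))


@pytest.mark.parametrize("s_true", [-0.5, 0.0, 0.5])
def test_parameter_recovery_rmse(s_true):
    """Over repeated stochastic replicates (census 1e5, depth 1e5) the RMSE of
    the normalized mutant class-mean estimate stays below 0.05."""
    n_runs = 34
    errs = []
    for seed in range(n_runs):
        d = SimDesign(n_wt=10, n_mut=10, s_wt=0.0, s_mut=s_true,
                      census_N=100_000, read_depth=100_000, seed=1000 + seed)
        est = fit_replicate(simulate_replicate(d).table)
        mut = est.included_class(GenotypeClass.MUTANT)
        errs.append(mut["s_norm"].mean() - s_true)
    rmse = float(np.sqrt(np.mean(np.square(errs))))
    assert rmse < 0.05
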