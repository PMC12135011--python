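"""Serial-transfer simulator: dynamics, drift, determinism, dev assay."""

import math

import numpy as np
import pytest

from lineagefit import (
    GenotypeClass,
    SimDesign,
    default_dev_response,
    simulate_dev_assay,
    simulate_experiment,
    simulate_replicate,
)
from lineagefit.simulate import (
    PopulationExtinctError,
    default_start_freq_wt,
    quadratic_dose_response,
)


class TestSimulateReplicate:
    def test_neutral_deterministic_frequencies_constant(self):
        d = SimDesign(n_wt=3, n_mut=3, s_wt=0.0, s_mut=0.0,
                      mode="deterministic", read_depth=600_000)
        freq = simulate_replicate(d).table.frequencies()
        for col in freq.columns[1:]:
            assert np.allclose(freq[col], freq["P0"], atol=1e-9)

    def test_two_lineage_closed_form(self):
        # equal start, s = (0, ln 2), one generation: 0.5*2/(0.5+1) = 2/3
        d = SimDesign(n_wt=1, n_mut=1, start_freq_wt=0.5, s_wt=0.0,
                      s_mut=math.log(2), n_transfers=1,
                      mode="deterministic", read_depth=3_000_000)
        freq = simulate_replicate(d).table.frequencies()
        assert freq["T1"].tolist() == pytest.approx([1 / 3, 2 / 3], abs=1e-6)

    def test_seed_reproducibility(self):
        d = SimDesign(n_wt=4, n_mut=4, s_mut=0.2, seed=11,
                      census_N=10_000, read_depth=10_000)
        a = simulate_replicate(d)
        b = simulate_replicate(d)
        assert a.table.counts.equals(b.table.counts)
        assert a.truth == b.truth

    def test_truth_covers_every_lineage(self):
        res = simulate_replicate(SimDesign(n_wt=3, n_mut=5, seed=0,
                                           census_N=1000, read_depth=1000))
        assert set(res.truth) == set(res.table.lineages)
        assert sum(res.table.class_mask(GenotypeClass.MUTANT)) == 5

    def test_extinction_raises(self):
        d = SimDesign(n_wt=1, n_mut=1, s_wt=-2000.0, s_mut=-2000.0,
                      mode="deterministic")
        with pytest.raises(PopulationExtinctError, match="transfer 1"):
            simulate_replicate(d)

    def test_full_bottleneck_high_depth_approaches_deterministic(self):
        kw = dict(n_wt=2, n_mut=2, s_mut=0.3, read_depth=10_000_000)
        det = simulate_replicate(SimDesign(mode="deterministic", **kw))
        sto = simulate_replicate(
            SimDesign(mode="stochastic", bottleneck_fraction=1.0,
                      census_N=10_000_000, seed=3, **kw)
        )
        f_det = det.table.frequencies().to_numpy()
        f_sto = sto.table.frequencies().to_numpy()
        assert np.abs(f_det - f_sto).max() < 1e-3

    def test_neutral_drift_unbiased(self):
        # with s = 0, drift moves frequencies but not their expectation
        d0 = SimDesign(n_wt=4, n_mut=4, start_freq_wt=0.25, s_mut=0.0,
                       census_N=100_000, read_depth=50_000)
        start = None
        finals = []
        n_runs = 300
        for seed in range(n_runs):
            res = simulate_replicate(
                SimDesign(**{**d0.__dict__, "seed": seed})
            )
            f = res.table.frequencies()
            if start is None:
                start = np.array([0.25 / 4] * 4 + [0.75 / 4] * 4)
            finals.append(f.iloc[:, -1].to_numpy())
        finals = np.array(finals)
        mean = finals.mean(axis=0)
        se = finals.std(axis=0, ddof=1) / np.sqrt(n_runs)
        assert np.all(np.abs(mean - start) < 3 * se + 1e-12)


class TestSimulateExperiment:
    def test_replicate_layout_and_metadata(self):
        d = SimDesign(n_wt=2, n_mut=2, census_N=1000, read_depth=1000)
        results = simulate_experiment(
            concentrations=(0, 1, 2, 3, 4, 5), replicates=3, design=d, seed=1
        )
        assert len(results) == 18
        concs = sorted({r.table.concentration for r in results})
        assert concs == [0, 1, 2, 3, 4, 5]
        ids = [r.table.replicate_id for r in results]
        assert len(set(ids)) == 18

    def test_default_layout_has_extra_3nM_replicates(self):
        d = SimDesign(n_wt=2, n_mut=2, census_N=1000, read_depth=1000)
        results = simulate_experiment(design=d, seed=1)
        per_c = {}
        for r in results:
            per_c[r.table.concentration] = per_c.get(r.table.concentration, 0) + 1
        assert per_c == {0: 3, 1: 3, 2: 3, 3: 5, 4: 3, 5: 3}

    def test_truth_centres_on_dose_response(self):
        d = SimDesign(n_wt=2, n_mut=40, census_N=1000, read_depth=1000)
        results = simulate_experiment(
            concentrations=(0.0,), replicates=3, design=d,
            lineage_sd=0.0, replicate_sd=0.0, seed=2,
        )
        for res in results:
            mut = [s for bc, s in res.truth.items()
                   if res.table.classes[bc] is GenotypeClass.MUTANT]
            assert np.allclose(mut, quadratic_dose_response(0.0))
            wt = [s for bc, s in res.truth.items()
                  if res.table.classes[bc] is GenotypeClass.WILD_TYPE]
            assert np.allclose(wt, 0.0)

    def test_outlier_shift_applied(self):
        d = SimDesign(n_wt=2, n_mut=10, census_N=1000, read_depth=1000)
        results = simulate_experiment(
            concentrations=(3.0,), replicates=3, design=d,
            lineage_sd=0.0, replicate_sd=0.0,
            outlier_shifts={(3.0, 1): -1.0}, seed=3,
        )
        means = []
        for res in results:
            mut = [s for bc, s in res.truth.items()
                   if res.table.classes[bc] is GenotypeClass.MUTANT]
            means.append(np.mean(mut))
        base = quadratic_dose_response(3.0)
        assert means[0] == pytest.approx(base)
        assert means[1] == pytest.approx(base - 1.0)

    def test_start_mix_scheme(self):
        assert default_start_freq_wt(0) == 0.10
        assert default_start_freq_wt(1) == 0.30
        assert all(default_start_freq_wt(c) == 0.50 for c in (2, 3, 4, 5))


class TestDevAssay:
    def test_certain_adulthood(self):
        recs = simulate_dev_assay(lambda g, c: 1.0, n_per_drop=20, n_drops=5,
                                  seed=0)
        assert all(r.n_adult == r.n_total for r in recs)

    def test_half_probability_within_binomial_ci(self):
        recs = simulate_dev_assay(lambda g, c: 0.5, n_per_drop=50,
                                  n_drops=40, seed=1,
                                  concentrations=(0.0,),
                                  genotypes=(GenotypeClass.WILD_TYPE,))
        tot = sum(r.n_total for r in recs)
        adults = sum(r.n_adult for r in recs)
        se = math.sqrt(0.25 / tot)
        assert abs(adults / tot - 0.5) < 4 * se

    def test_seeded_determinism(self):
        a = simulate_dev_assay(default_dev_response, n_per_drop=10, n_drops=3,
                               seed=9)
        b = simulate_dev_assay(default_dev_response, n_per_drop=10, n_drops=3,
                               seed=9)
        assert a == b

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_dev_assay(lambda g, c: 1.5, n_per_drop=5, n_drops=1)

    def test_default_response_endpoints(self):
        # generator truth reproduces the observed wild-type endpoints
        assert default_dev_response(GenotypeClass.WILD_TYPE, 0.0) == pytest.approx(0.631)
        assert default_dev_response(GenotypeClass.WILD_TYPE, 5.0) == pytest.approx(0.034)
        # flat mutant response crosses the wild-type curve at 2.5 nM
        assert default_dev_response(GenotypeClass.MUTANT, 2.5) == pytest.approx(
            default_dev_response(GenotypeClass.WILD_TYPE, 2.5)
        )
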