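"""Sampler correctness: determinism, prior recovery, posterior oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from rcclock.alignment import ProteinAlignment
from rcclock.mcmc import (
    InitializationError,
    InsufficientChainsError,
    McmcConfig,
    PosteriorTrace,
    assess_convergence,
    run_chain,
    run_chains,
    summarize_nodes,
)
from rcclock.priors import (
    Calibration,
    ClockModel,
    RatePrior,
    RootPrior,
    calibration_log_density,
)
from rcclock.simulate import SimulationConfig, simulate_dataset
from rcclock.substitution import PruningEngine, poisson_model
from rcclock.timetree import Node, TimeTree


def cherry_tree():
    a, b, c, d = (Node(x, age=0.0) for x in "ABCD")
    ab, cd, root = Node(age=0.2), Node(age=1.0), Node(age=3.4)
    ab.add_child(a)
    ab.add_child(b)
    cd.add_child(c)
    cd.add_child(d)
    root.add_child(ab)
    root.add_child(cd)
    return TimeTree(root)


class TestDeterminism:
    def test_same_seed_same_trace(self):
        tree, aln, _ = simulate_dataset(SimulationConfig(seed=5, n_tips=6, n_sites=40))
        clock = ClockModel(sigma2=0.1, root_rate=0.25)
        cfg = McmcConfig(iterations=60, burn_in=20, thinning=2, seed=42)
        t1 = run_chain(aln, tree, poisson_model(), clock, RootPrior(3.5, 0.1), (), cfg)
        t2 = run_chain(aln, tree, poisson_model(), clock, RootPrior(3.5, 0.1), (), cfg)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_chain_seeds_offset(self):
        tree, aln, _ = simulate_dataset(SimulationConfig(seed=5, n_tips=6, n_sites=40))
        clock = ClockModel(sigma2=0.1, root_rate=0.25)
        cfg = McmcConfig(iterations=40, burn_in=10, thinning=2, seed=42)
        traces = run_chains(2, aln, tree, poisson_model(), clock,
                            RootPrior(3.5, 0.1), (), cfg)
        assert traces[0].seed != traces[1].seed
        assert not traces[0].data.equals(traces[1].data)

    def test_trace_roundtrip(self, tmp_path):
        tree, aln, _ = simulate_dataset(SimulationConfig(seed=5, n_tips=6, n_sites=40))
        clock = ClockModel(sigma2=0.1, root_rate=0.25)
        cfg = McmcConfig(iterations=40, burn_in=10, thinning=2, seed=1)
        trace = run_chain(aln, tree, poisson_model(), clock,
                          RootPrior(3.5, 0.1), (), cfg)
        p = tmp_path / "trace.tsv"
        trace.save(p)
        back = PosteriorTrace.load(p)
        assert back.node_keys == trace.node_keys
        assert np.allclose(back.data.to_numpy(), trace.data.to_numpy())


class TestPriorOnlySampling:
    def test_calibrated_node_marginal_matches_density(self):
        """Prior-only MCMC reproduces the soft calibration marginal (KS).

        The uncorrelated-gamma clock keeps the rate prior independent
        of node ages, so the calibrated node's exact marginal is the
        calibration density itself.  (Under the autocorrelated clock
        the sigma^2*dt variance couples ages and rates, and the age
        marginal equals the calibration density only after integrating
        rates out.)  The full-window uniform age proposal acts as an
        independence sampler with acceptance roughly equal to the
        calibration width over the root age, so the domain is kept
        small and the chain thinned to near-independence.
        """
        a, b, c, d = (Node(x, age=0.0) for x in "ABCD")
        ab, cd = Node(age=0.2), Node(age=0.35)
        root = Node(age=0.55)
        ab.add_child(a)
        ab.add_child(b)
        cd.add_child(c)
        cd.add_child(d)
        root.add_child(ab)
        root.add_child(cd)
        tree = TimeTree(root)
        cal = Calibration(clade=("A", "B"), min_age=0.124, max_age=0.248)
        cfg = McmcConfig(
            iterations=126_000, burn_in=1000, thinning=25, seed=3,
            use_likelihood=False, sample_alpha=False, sample_rates=False,
        )
        trace = run_chain(
            None, tree, poisson_model(),
            ClockModel(kind="uncorrelated_gamma", gamma_shape=1.0,
                       root_rate=0.25),
            RootPrior(0.6, 0.05), [cal], cfg,
        )
        assert len(trace) == 5000
        node = tree.mrca(["A", "B"])
        draws = trace.data[f"age:n{node.index}"].to_numpy()

        grid = np.linspace(1e-6, 0.55, 4001)
        pdf = np.exp([calibration_log_density(cal, t) for t in grid])
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]

        def cdf_fn(x):
            return np.interp(x, grid, cdf)

        ks = stats.kstest(draws, cdf_fn)
        assert ks.pvalue > 0.01

    def test_hyperparameter_prior_preserved(self):
        """A long prior-only run leaves the sigma^2 hyperprior invariant.

        The multiplier move's Jacobian is part of the acceptance ratio;
        without it the sampled sigma^2 would drift off its log-normal
        prior (median 0.1, sd 1 on the log scale).
        """
        tree = cherry_tree()
        cfg = McmcConfig(iterations=21_000, burn_in=1000, thinning=4, seed=8,
                         use_likelihood=False, sample_alpha=False)
        trace = run_chain(None, tree, poisson_model(),
                          ClockModel(sigma2=0.1, root_rate=0.25),
                          RootPrior(3.4, 0.05), (), cfg)
        logs2 = np.log(trace.data.sigma2.to_numpy())
        n_eff = 200  # conservative ESS guess for the error bars
        assert logs2.mean() == pytest.approx(math.log(0.1), abs=3 / math.sqrt(n_eff))
        assert logs2.std() == pytest.approx(1.0, rel=0.25)


class TestTwoTipPosteriorOracle:
    def test_matches_one_dimensional_quadrature(self):
        """2-tip divergence-age posterior agrees with direct quadrature."""
        config = SimulationConfig(
            seed=12, n_tips=2, root_age=0.5, sigma2=0.05, root_rate=1.0,
            n_sites=100, model=poisson_model(n_categories=1),
        )
        tree, aln, _ = simulate_dataset(config)
        clock = ClockModel(sigma2=0.05, root_rate=1.0)
        root_prior = RootPrior(0.5, 0.2)
        cfg = McmcConfig(
            iterations=25_000, burn_in=1000, thinning=6, seed=7,
            sample_rates=False, sample_alpha=False, sample_hyper=False,
        )
        trace = run_chain(aln, tree, poisson_model(n_categories=1), clock,
                          root_prior, (), cfg)
        draws = trace.data[f"age:n{tree.root.index}"].to_numpy()

        engine = PruningEngine(aln, tree, poisson_model(n_categories=1))
        rate_prior = RatePrior(tree, clock)
        rates = np.array([n.rate for n in tree.nodes])

        def log_post(t):
            ages = np.zeros(3)
            ages[tree.root.index] = t
            blens = np.zeros(3)
            for node in tree.tips():
                blens[node.index] = 1.0 * t
            lp = root_prior.log_density(t)
            lp += rate_prior.log_density(ages, rates, 0.05, None)
            lp += engine.set_state(blens, alpha=1.0)
            return lp

        grid = np.linspace(1e-3, 1.6, 400)
        logs = np.array([log_post(t) for t in grid])
        w = np.exp(logs - logs.max())
        w /= np.trapezoid(w, grid)
        mean_q = np.trapezoid(grid * w, grid)
        sd_q = math.sqrt(np.trapezoid((grid - mean_q) ** 2 * w, grid))

        assert draws.mean() == pytest.approx(mean_q, rel=0.02)
        assert draws.std(ddof=1) == pytest.approx(sd_q, rel=0.02)


class TestConvergence:
    def _toy_trace(self, values, chain_id=0):
        data = pd.DataFrame({"age:n2": values, "rate:n2": np.ones(len(values))})
        return PosteriorTrace(data=data, node_keys={"n2": "k"}, chain_id=chain_id,
                              seed=chain_id, thinning=1)

    def test_identical_traces_pass(self, rng):
        x = rng.normal(3.0, 0.1, size=400)
        report = assess_convergence([self._toy_trace(x, 0), self._toy_trace(x, 1)])
        assert report.passed
        assert report.max_age_mean_discrepancy == 0.0

    def test_disjoint_constant_chains_fail(self):
        a = self._toy_trace(np.full(200, 1.0), 0)
        b = self._toy_trace(np.full(200, 2.0), 1)
        report = assess_convergence([a, b])
        assert not report.passed
        assert math.isinf(report.rhat["age:n2"])

    def test_single_chain_rejected(self):
        with pytest.raises(InsufficientChainsError):
            assess_convergence([self._toy_trace(np.ones(10))])

    def test_prior_only_chains_converge(self):
        """Independent prior-only chains on the cherry fixture pass."""
        tree = cherry_tree()
        cal = Calibration(clade=("A", "B"), min_age=0.124, max_age=0.248)
        cfg = McmcConfig(iterations=21_000, burn_in=1000, thinning=2, seed=17,
                         use_likelihood=False, sample_alpha=False)
        traces = run_chains(4, None, tree, poisson_model(),
                            ClockModel(sigma2=0.1, root_rate=0.25),
                            RootPrior(3.4, 0.05), [cal], cfg)
        report = assess_convergence(traces)
        assert report.passed


class TestSummaries:
    def test_two_point_arithmetic(self, quartet_tree):
        root = quartet_tree.root.index
        cols = {}
        for node in quartet_tree.internal_nodes():
            cols[f"age:n{node.index}"] = [3.0, 3.4] if node.index == root \
                else [node.age, node.age]
        for node in quartet_tree.nodes:
            cols[f"rate:n{node.index}"] = [0.2, 0.2]
        trace = PosteriorTrace(
            data=pd.DataFrame(cols), node_keys={}, chain_id=0, seed=0, thinning=1
        )
        summary = summarize_nodes(trace, quartet_tree)
        rec = summary[summary.node == f"n{root}"].iloc[0]
        assert rec.age_mean == pytest.approx(3.2)
        assert rec.age_sd == pytest.approx(math.sqrt(0.08), abs=1e-9)  # ddof=1

    def test_constant_trace_collapses_interval(self, quartet_tree):
        cols = {
            f"age:n{n.index}": [n.age] * 3 for n in quartet_tree.internal_nodes()
        }
        cols.update({f"rate:n{n.index}": [0.2] * 3 for n in quartet_tree.nodes})
        trace = PosteriorTrace(
            data=pd.DataFrame(cols), node_keys={}, chain_id=0, seed=0, thinning=1
        )
        summary = summarize_nodes(trace, quartet_tree)
        assert (summary.age_sd == 0).all()
        assert (summary.age_lo95 == summary.age_hi95).all()

    def test_empty_trace_rejected(self, quartet_tree):
        trace = PosteriorTrace(data=pd.DataFrame(), node_keys={}, chain_id=0,
                               seed=0, thinning=1)
        with pytest.raises(ValueError, match="empty"):
            summarize_nodes(trace, quartet_tree)

    def test_recorded_states_always_valid(self):
        """Every recorded state satisfies parent>child and rate>0."""
        tree, aln, _ = simulate_dataset(SimulationConfig(seed=6, n_tips=8, n_sites=50))
        clock = ClockModel(sigma2=0.2, root_rate=0.25)
        cfg = McmcConfig(iterations=120, burn_in=20, thinning=1, seed=2)
        trace = run_chain(aln, tree, poisson_model(), clock,
                          RootPrior(3.5, 0.1), (), cfg)
        parent = {n.index: (n.parent.index if n.parent else None)
                  for n in tree.nodes}
        data = trace.data
        for idx, pidx in parent.items():
            assert (data[f"rate:n{idx}"] > 0).all()
            if pidx is None or f"age:n{idx}" not in data:
                continue
            child_age = data[f"age:n{idx}"]
            parent_age = data[f"age:n{pidx}"]
            assert (parent_age > child_age).all()


class TestInitialization:
    def test_contradictory_hard_calibrations_raise(self):
        tree = cherry_tree()
        impossible = [
            Calibration(clade=("A", "B"), min_age=2.0, max_age=3.0, style="hard"),
            Calibration(clade=("A", "B", "C", "D"), max_age=1.0, style="hard"),
        ]
        with pytest.raises(InitializationError):
            run_chain(None, tree, poisson_model(),
                      ClockModel(sigma2=0.1, root_rate=0.25),
                      RootPrior(0.5, 0.05), impossible,
                      McmcConfig(iterations=10, seed=1, use_likelihood=False))
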