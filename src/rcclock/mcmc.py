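"""Metropolis-Hastings sampler for Bayesian node dating.

The target is  prior x likelihood  over node ages (Ga), node rates
(subs/site/Ga), the clock hyperparameter (sigma^2 or gamma shape, plus
the global rate nu0 for the uncorrelated clock) and the site-rate shape
alpha.  The move set is the standard dating repertoire:

1. node-age sliding window, uniform within (max child age, parent age);
2. root-age multiplier;
3. single-node rate multipliers (Jacobian included);
4. sigma^2 / shape / nu0 / alpha multipliers;
5. a rate-time compensating move rescaling one node's age and its rate
   in opposite directions (unit Jacobian), a mixing aid.

Multiplier scales are auto-tuned during burn-in toward 20-45%
acceptance and frozen afterwards.  A single seeded generator drives
each chain; chain seeds derive from the master seed by fixed offsets,
so traces are bit-reproducible from (seed, config).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import ProteinAlignment
from .priors import (
    Calibration,
    ClockModel,
    RatePrior,
    RootPrior,
    TimePrior,
    lognormal_log_density,
)
from .substitution import PruningEngine, SubstitutionModel
from .timetree import TimeTree

NEG_INF = float("-inf")

SIGMA2_HYPER_MEDIAN = 0.1
SHAPE_HYPER_MEDIAN = 1.0
ALPHA_HYPER_MEDIAN = 1.0


class InitializationError(RuntimeError):
    """No admissible starting state under the hard constraints."""


class InsufficientChainsError(ValueError):
    pass


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration (iterations are full sweeps)."""

    iterations: int = 2000
    burn_in: int | None = None      # default: 25% of iterations
    thinning: int = 10
    seed: int = 0
    sample_rates: bool = True
    sample_alpha: bool = True
    sample_hyper: bool = True
    use_likelihood: bool = True     # False: prior-only mode
    tune: bool = True
    engine_dtype: str = "float64"   # pruning cache precision

    @property
    def effective_burn_in(self) -> int:
        return self.iterations // 4 if self.burn_in is None else self.burn_in


@dataclass
class PosteriorTrace:
    """Thinned post-burn-in MCMC samples plus identifying metadata."""

    data: pd.DataFrame
    node_keys: dict[str, str]       # postorder "n<index>" -> tip-set hash key
    chain_id: int
    seed: int
    thinning: int
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False)
        manifest = {
            "chain_id": self.chain_id,
            "seed": self.seed,
            "thinning": self.thinning,
            "node_keys": self.node_keys,
            "config": self.config,
        }
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorTrace":
        path = Path(path)
        data = pd.read_csv(path, sep="\t")
        manifest = json.loads(
            path.with_suffix(path.suffix + ".manifest.json").read_text()
        )
        return cls(
            data=data,
            node_keys=manifest["node_keys"],
            chain_id=manifest["chain_id"],
            seed=manifest["seed"],
            thinning=manifest["thinning"],
            config=manifest.get("config", {}),
        )


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    ess: dict[str, float]
    max_age_mean_discrepancy: float
    passed: bool
    rhat_threshold: float = 1.05
    ess_threshold: float = 100.0
    discrepancy_threshold: float = 0.05


class _Sampler:
    """One chain.  Owns the state arrays and the pruning engine."""

    def __init__(
        self,
        alignment: ProteinAlignment | None,
        tree: TimeTree,
        model: SubstitutionModel,
        clock: ClockModel,
        root_prior: RootPrior,
        calibrations: Sequence[Calibration],
        config: McmcConfig,
        chain_id: int = 0,
    ) -> None:
        self.tree = tree.copy()
        self.clock = clock
        self.config = config
        self.chain_id = chain_id
        self.seed = config.seed + 1000 * chain_id
        self.rng = np.random.default_rng(self.seed)

        nodes = self.tree.nodes
        self.n = len(nodes)
        self.root_index = self.tree.root.index
        self.parent = np.full(self.n, -1, dtype=np.int64)
        self.children: dict[int, tuple[int, int]] = {}
        for node in nodes:
            for child in node.children:
                self.parent[child.index] = node.index
            if node.children:
                self.children[node.index] = (
                    node.children[0].index,
                    node.children[1].index,
                )
        self.is_tip = np.array([node.is_tip for node in nodes])
        self.internal_nonroot = [
            n.index for n in nodes if n.children and n.index != self.root_index
        ]
        self.internal = [n.index for n in nodes if n.children]

        self.time_prior = TimePrior(self.tree, root_prior, calibrations)
        self.rate_prior = RatePrior(self.tree, clock)
        self.acln = clock.kind == "autocorrelated_lognormal"

        # --- state ---
        self.ages = self._initial_ages(root_prior, calibrations)
        self.rates = np.full(self.n, clock.root_rate, dtype=float)
        if self.acln:
            self.hyper = clock.sigma2        # sigma^2
            self.nu0 = clock.root_rate       # unused (root rate is a state var)
        else:
            self.hyper = clock.gamma_shape
            self.nu0 = clock.root_rate
        self.alpha = model.gamma_shape

        self.engine: PruningEngine | None = None
        if config.use_likelihood:
            if alignment is None:
                raise ValueError("likelihood mode needs an alignment")
            dtype = np.float32 if config.engine_dtype == "float32" else np.float64
            self.engine = PruningEngine(alignment, self.tree, model, dtype=dtype)
            self.engine.set_state(self._all_blens(), alpha=self.alpha)
            self.loglik = self.engine.log_likelihood
        else:
            self.loglik = 0.0

        self.log_time = self.time_prior.log_density(self.ages)
        self.log_rate = self.rate_prior.log_density(
            self.ages, self.rates, self.hyper, self.nu0
        )
        self.log_hyper = self._log_hyper()
        if not np.isfinite(self.log_time + self.log_rate + self.log_hyper):
            raise InitializationError("initial state has zero prior density")

        self.scales = {"root": 0.2, "rate": 0.8, "hyper": 0.8, "nu0": 0.5,
                       "alpha": 0.5, "comp": 0.4}
        self._acc = {k: [0, 0] for k in (*self.scales, "age")}

    # ---- initialisation --------------------------------------------

    def _initial_ages(
        self, root_prior: RootPrior, calibrations: Sequence[Calibration]
    ) -> np.ndarray:
        given = np.array(
            [n.age if n.age is not None else np.nan for n in self.tree.nodes]
        )
        if not np.any(np.isnan(given)):
            if np.isfinite(self.time_prior.log_density(given)):
                return given.astype(float)
        for attempt in range(500):
            ages = np.zeros(self.n)
            root_age = root_prior.mean + root_prior.sd * self.rng.standard_normal()
            root_age = max(root_age, root_prior.min_age + root_prior.sd)
            ages[self.root_index] = root_age
            for node in self.tree.preorder():
                i = node.index
                if self.is_tip[i] or i == self.root_index:
                    continue
                frac = self.rng.uniform(0.55, 0.95)
                ages[i] = ages[self.parent[i]] * frac
            if np.isfinite(self.time_prior.log_density(ages)):
                return ages
        conflicts = [c.name or str(c.clade) for _, c in self.time_prior.calibrated]
        raise InitializationError(
            "could not find an admissible starting state; check for "
            f"contradictory calibrations among {conflicts}"
        )

    # ---- branch lengths --------------------------------------------

    def _blen(self, e: int) -> float:
        p = self.parent[e]
        dur = self.ages[p] - self.ages[e]
        if self.acln:
            return 0.5 * (self.rates[p] + self.rates[e]) * dur
        return self.rates[e] * dur

    def _all_blens(self) -> np.ndarray:
        out = np.zeros(self.n)
        for e in range(self.n):
            if e != self.root_index:
                out[e] = self._blen(e)
        return out

    def _edges_for_age(self, i: int) -> list[int]:
        edges = list(self.children.get(i, ()))
        if i != self.root_index:
            edges.append(i)
        return edges

    def _edges_for_rate(self, j: int) -> list[int]:
        if self.acln:
            edges = list(self.children.get(j, ()))
            if j != self.root_index:
                edges.append(j)
            return edges
        return [] if j == self.root_index else [j]

    # ---- posterior pieces ------------------------------------------

    def _log_hyper(self) -> float:
        if self.acln:
            out = lognormal_log_density(self.hyper, math.log(SIGMA2_HYPER_MEDIAN))
        else:
            out = lognormal_log_density(self.hyper, math.log(SHAPE_HYPER_MEDIAN))
            out += lognormal_log_density(
                self.nu0, math.log(self.clock.root_rate)
            )
        out += lognormal_log_density(self.alpha, math.log(ALPHA_HYPER_MEDIAN))
        return out

    @property
    def log_posterior(self) -> float:
        return self.log_time + self.log_rate + self.log_hyper + self.loglik

    # ---- generic Metropolis step -----------------------------------

    def _metropolis(
        self,
        kind: str,
        edges: list[int],
        log_hastings: float,
        new_alpha: float | None = None,
    ) -> bool:
        """Evaluate the already-applied state change; revert on reject.

        The caller mutates ``ages``/``rates``/``hyper`` first and passes
        the affected edge list; this method recomputes priors, updates
        the engine, and returns the accept decision (state restored by
        the caller on reject).
        """
        new_time = self.time_prior.log_density(self.ages)
        if new_time == NEG_INF:
            return False
        new_rate = self.rate_prior.log_density(
            self.ages, self.rates, self.hyper, self.nu0
        )
        if new_rate == NEG_INF:
            return False
        new_hyper = self._log_hyper()

        new_loglik = self.loglik
        used_engine = False
        if self.engine is not None and (edges or new_alpha is not None):
            new_blens = {e: self._blen(e) for e in edges}
            new_loglik = self.engine.propose(new_blens, new_alpha)
            used_engine = True

        delta = (
            (new_time - self.log_time)
            + (new_rate - self.log_rate)
            + (new_hyper - self.log_hyper)
            + (new_loglik - self.loglik)
            + log_hastings
        )
        accept = delta >= 0 or math.log(self.rng.uniform()) < delta
        if accept:
            self.log_time, self.log_rate = new_time, new_rate
            self.log_hyper, self.loglik = new_hyper, new_loglik
            if used_engine:
                self.engine.accept()
        elif used_engine:
            self.engine.reject()
        acc = self._acc[kind]
        acc[0] += int(accept)
        acc[1] += 1
        return accept

    # ---- moves ------------------------------------------------------

    def _move_age_slide(self, i: int) -> None:
        lo = max(self.ages[c] for c in self.children[i])
        hi = self.ages[self.parent[i]]
        if not lo < hi:
            return
        old = self.ages[i]
        self.ages[i] = self.rng.uniform(lo, hi)
        if not self._metropolis("age", self._edges_for_age(i), 0.0):
            self.ages[i] = old

    def _move_root(self) -> None:
        i = self.root_index
        old = self.ages[i]
        m = math.exp(self.scales["root"] * (self.rng.uniform() - 0.5))
        new = old * m
        if new <= max(self.ages[c] for c in self.children[i]):
            self._count("root", False)
            return
        self.ages[i] = new
        if not self._metropolis("root", self._edges_for_age(i), math.log(m)):
            self.ages[i] = old

    def _move_rate(self, j: int) -> None:
        old = self.rates[j]
        m = math.exp(self.scales["rate"] * (self.rng.uniform() - 0.5))
        self.rates[j] = old * m
        if not self._metropolis("rate", self._edges_for_rate(j), math.log(m)):
            self.rates[j] = old

    def _move_hyper(self) -> None:
        old = self.hyper
        m = math.exp(self.scales["hyper"] * (self.rng.uniform() - 0.5))
        self.hyper = old * m
        if not self._metropolis("hyper", [], math.log(m)):
            self.hyper = old

    def _move_nu0(self) -> None:
        old = self.nu0
        m = math.exp(self.scales["nu0"] * (self.rng.uniform() - 0.5))
        self.nu0 = old * m
        if not self._metropolis("nu0", [], math.log(m)):
            self.nu0 = old

    def _move_alpha(self) -> None:
        old = self.alpha
        m = math.exp(self.scales["alpha"] * (self.rng.uniform() - 0.5))
        new = old * m
        saved = self.alpha
        self.alpha = new
        if not self._metropolis("alpha", [], math.log(m), new_alpha=new):
            self.alpha = saved

    def _move_compensating(self) -> None:
        """Rescale one internal node's age and its rate in opposition."""
        if not self.internal_nonroot:
            return
        i = self.internal_nonroot[self.rng.integers(len(self.internal_nonroot))]
        lo = max(self.ages[c] for c in self.children[i])
        hi = self.ages[self.parent[i]]
        m = math.exp(self.scales["comp"] * (self.rng.uniform() - 0.5))
        new_age = self.ages[i] * m
        if not lo < new_age < hi:
            self._count("comp", False)
            return
        old_age, old_rate = self.ages[i], self.rates[i]
        self.ages[i] = new_age
        self.rates[i] = old_rate / m
        # Jacobian of (t, r) -> (m t, r/m) is 1
        if not self._metropolis("comp", self._edges_for_age(i), 0.0):
            self.ages[i], self.rates[i] = old_age, old_rate

    def _count(self, kind: str, accepted: bool) -> None:
        acc = self._acc[kind]
        acc[0] += int(accepted)
        acc[1] += 1

    def _retune(self) -> None:
        for kind in self.scales:
            acc, tot = self._acc[kind]
            if tot < 10:
                continue
            rate = acc / tot
            self.scales[kind] *= math.exp(0.6 * (rate - 0.3))
            self.scales[kind] = min(max(self.scales[kind], 0.01), 5.0)
            self._acc[kind] = [0, 0]

    # ---- main loop --------------------------------------------------

    def sweep(self) -> None:
        for i in self.internal_nonroot:
            self._move_age_slide(i)
        self._move_root()
        if self.config.sample_rates:
            for j in range(self.n):
                if not self.acln and j == self.root_index:
                    continue
                self._move_rate(j)
            self._move_compensating()
        if self.config.sample_hyper:
            self._move_hyper()
            if not self.acln:
                self._move_nu0()
        if self.config.sample_alpha and self.engine is not None:
            self._move_alpha()

    def run(self) -> PosteriorTrace:
        cfg = self.config
        burn = cfg.effective_burn_in
        records: list[np.ndarray] = []
        keys = {f"n{idx}": self.tree.node_key(self.tree.nodes[idx])
                for idx in range(self.n)}
        age_cols = [f"age:n{i}" for i in self.internal]
        rate_cols = [f"rate:n{i}" for i in range(self.n)]
        hyper_name = "sigma2" if self.acln else "shape"
        columns = age_cols + rate_cols + [hyper_name, "alpha", "nu0",
                                          "log_prior", "log_likelihood"]
        for it in range(cfg.iterations):
            self.sweep()
            if cfg.tune and it < burn and (it + 1) % 50 == 0:
                self._retune()
            if it >= burn and (it - burn) % cfg.thinning == 0:
                self._assert_valid()
                row = np.concatenate(
                    [
                        self.ages[self.internal],
                        self.rates,
                        [self.hyper, self.alpha, self.nu0,
                         self.log_time + self.log_rate + self.log_hyper,
                         self.loglik],
                    ]
                )
                records.append(row)
        data = pd.DataFrame(records, columns=columns)
        return PosteriorTrace(
            data=data,
            node_keys=keys,
            chain_id=self.chain_id,
            seed=self.seed,
            thinning=cfg.thinning,
            config={
                "iterations": cfg.iterations,
                "burn_in": burn,
                "thinning": cfg.thinning,
                "seed": cfg.seed,
                "clock": self.clock.kind,
                "use_likelihood": cfg.use_likelihood,
            },
        )

    def _assert_valid(self) -> None:
        durations = (
            self.ages[self.parent[self.parent >= 0]]
            - self.ages[np.flatnonzero(self.parent >= 0)]
        )
        assert np.all(durations > 0), "recorded state violates age ordering"
        assert np.all(self.rates > 0), "recorded state has nonpositive rate"


def run_chain(
    alignment: ProteinAlignment | None,
    tree: TimeTree,
    model: SubstitutionModel,
    clock: ClockModel,
    root_prior: RootPrior,
    calibrations: Sequence[Calibration] = (),
    config: McmcConfig = McmcConfig(),
    chain_id: int = 0,
) -> PosteriorTrace:
    """Run one MCMC chain and return its thinned posterior trace."""
    sampler = _Sampler(
        alignment, tree, model, clock, root_prior, calibrations, config, chain_id
    )
    return sampler.run()


def run_chains(
    n_chains: int,
    alignment: ProteinAlignment | None,
    tree: TimeTree,
    model: SubstitutionModel,
    clock: ClockModel,
    root_prior: RootPrior,
    calibrations: Sequence[Calibration] = (),
    config: McmcConfig = McmcConfig(),
) -> list[PosteriorTrace]:
    """Run several chains with seeds offset from the master seed."""
    return [
        run_chain(alignment, tree, model, clock, root_prior, calibrations,
                  config, chain_id=c)
        for c in range(n_chains)
    ]


# ---------------------------------------------------------------------------
# convergence and summaries
# ---------------------------------------------------------------------------


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R̂ from an (n_chains, n_draws) array; 1.0 for constant input."""
    m, n = chains.shape
    if n < 4:
        return float("nan")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    within = split.var(axis=1, ddof=1).mean()
    between = split.mean(axis=1).var(ddof=1)
    if between == 0 and within == 0:
        return 1.0
    if within == 0:
        return float("inf")
    var_plus = (half - 1) / half * within + between
    return float(np.sqrt(var_plus / within))


def _ess(chains: np.ndarray) -> float:
    import arviz as az

    if np.ptp(chains) == 0:
        return float(chains.size)
    with np.errstate(all="ignore"):
        value = float(az.ess(az.convert_to_dataset(chains))["x"].values.item())
    return value if np.isfinite(value) else 0.0


def assess_convergence(
    traces: Sequence[PosteriorTrace],
    rhat_threshold: float = 1.05,
    ess_threshold: float = 100.0,
    discrepancy_threshold: float = 0.05,
) -> ConvergenceReport:
    """Split-R̂ / ESS per parameter plus cross-chain age-mean discrepancy.

    Pass requires R̂ < 1.05 and ESS > 100 for every node age, and the
    largest cross-chain difference in node-age posterior means below
    0.05 Ga (the precision at which ages are reported).
    """
    if len(traces) < 2:
        raise InsufficientChainsError("convergence assessment needs >= 2 chains")
    n = min(len(t) for t in traces)
    if n == 0:
        raise ValueError("empty traces")
    columns = [c for c in traces[0].data.columns if c.startswith(("age:", "rate:"))]
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    max_disc = 0.0
    passed = True
    for col in columns:
        chains = np.stack([t.data[col].to_numpy()[:n] for t in traces])
        r = _split_rhat(chains)
        rhat[col] = r
        if col.startswith("age:"):
            e = _ess(chains)
            ess[col] = e
            disc = float(np.ptp(chains.mean(axis=1)))
            max_disc = max(max_disc, disc)
            if not (np.isnan(r) or r < rhat_threshold) or e <= ess_threshold:
                passed = False
    if max_disc >= discrepancy_threshold:
        passed = False
    return ConvergenceReport(
        rhat=rhat,
        ess=ess,
        max_age_mean_discrepancy=max_disc,
        passed=passed,
        rhat_threshold=rhat_threshold,
        ess_threshold=ess_threshold,
        discrepancy_threshold=discrepancy_threshold,
    )


def summarize_nodes(
    trace: PosteriorTrace | Sequence[PosteriorTrace], tree: TimeTree
) -> pd.DataFrame:
    """Posterior mean/sd and 95% credible interval per node.

    Accepts one trace or several (pooled).  Ages use the sample standard
    deviation (ddof=1).  Tip rows carry age 0 and their sampled rates.
    Ages are kept at full precision; round to 2 decimals at reporting.
    """
    traces = [trace] if isinstance(trace, PosteriorTrace) else list(trace)
    if not traces or any(len(t) == 0 for t in traces):
        raise ValueError("empty trace")
    data = pd.concat([t.data for t in traces], ignore_index=True)
    keys = traces[0].node_keys
    rows = []
    for node in tree.nodes:
        col_id = f"n{node.index}"
        age_col, rate_col = f"age:{col_id}", f"rate:{col_id}"
        if age_col in data.columns:
            ages = data[age_col].to_numpy()
            age_mean = float(ages.mean())
            age_sd = float(ages.std(ddof=1)) if len(ages) > 1 else 0.0
            lo, hi = (
                (float(np.quantile(ages, 0.025)), float(np.quantile(ages, 0.975)))
                if len(ages) > 1
                else (age_mean, age_mean)
            )
        else:
            age_mean, age_sd, lo, hi = 0.0, 0.0, 0.0, 0.0
        rates = data[rate_col].to_numpy()
        rows.append(
            {
                "node": col_id,
                "key": keys.get(col_id, col_id),
                "label": node.label or (node.name if node.is_tip else ""),
                "is_tip": node.is_tip,
                "age_mean": age_mean,
                "age_sd": age_sd,
                "age_lo95": lo,
                "age_hi95": hi,
                "rate_mean": float(rates.mean()),
                "rate_sd": float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def annotate_tree_with_summary(tree: TimeTree, summary: pd.DataFrame) -> TimeTree:
    """Copy the tree with posterior mean ages and rates written onto nodes."""
    out = tree.copy()
    by_node = summary.set_index("node")
    for node in out.nodes:
        rec = by_node.loc[f"n{node.index}"]
        node.age = 0.0 if node.is_tip else float(rec["age_mean"])
        node.rate = float(rec["rate_mean"])
    out.validate_ages()
    return out
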