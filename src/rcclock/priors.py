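"""Prior densities of the dating model.

Four ingredients:

* a normal **root prior** on the age of the root (mean and sd in Ga),
  truncated to positive ages;
* **fossil calibrations** anchored at the MRCA of a tip set, with hard
  or soft bounds.  Soft bounds place a stated probability mass outside
  each limit (2.5% per two-sided bound, 5% for a single minimum): a
  uniform core carries the remaining mass, the lower tail is a power
  density ``t**theta`` on (0, min) and the upper tail an exponential,
  both matched for continuity at the bound (the Yang-Rannala style
  construction);
* a **node-time prior** that is uniform over the order-constrained
  simplex of uncalibrated internal ages given the root age;
* a **rate-process prior**: either the autocorrelated log-normal clock
  (a child node's log rate is normal around the parent's with variance
  sigma^2 * elapsed time, mean-corrected so E[r_child] = r_parent), or
  an uncorrelated gamma clock with i.i.d. branch rates of mean ``nu0``.

Hyperparameters (sigma^2 or the gamma shape, the site-rate shape alpha,
and the root rate nu0) carry broad log-normal hyperpriors with sd 1 on
the log scale, required for a proper posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, log_ndtr

from .timetree import CladeResolutionError, TimeTree

NEG_INF = float("-inf")
LOG_2PI = math.log(2.0 * math.pi)

#: no node can be older than the planet; closes min-only soft cores
EARTH_AGE_GA = 4.6


@dataclass(frozen=True)
class Calibration:
    """A clade-anchored age constraint (bounds in Ga)."""

    clade: tuple[str, ...]
    min_age: float | None = None
    max_age: float | None = None
    style: str = "soft"                    # 'hard' | 'soft'
    tail_mass_low: float = 0.025
    tail_mass_high: float = 0.025
    upper_limit: float = EARTH_AGE_GA      # support edge for min-only cores
    name: str = ""
    require_monophyly: bool = False

    def __post_init__(self) -> None:
        if self.min_age is None and self.max_age is None:
            raise ValueError("a calibration needs at least one bound")
        if (
            self.min_age is not None
            and self.max_age is not None
            and not self.min_age < self.max_age
        ):
            raise ValueError("min_age must be < max_age")
        for m in (self.tail_mass_low, self.tail_mass_high):
            if not 0.0 <= m < 0.5:
                raise ValueError("tail masses must lie in [0, 0.5)")
        if self.style not in ("hard", "soft"):
            raise ValueError(f"unknown calibration style {self.style!r}")


def calibration_log_density(cal: Calibration, age: float) -> float:
    """Log prior density of a calibrated node age; integrates to 1."""
    if age <= 0:
        return NEG_INF
    lo = cal.min_age
    hi = cal.max_age if cal.max_age is not None else cal.upper_limit
    if cal.style == "hard":
        left = lo if lo is not None else 0.0
        if left <= age <= hi:
            return -math.log(hi - left)
        return NEG_INF

    # soft
    tl = cal.tail_mass_low if lo is not None else 0.0
    tu = cal.tail_mass_high if cal.max_age is not None else 0.0
    left = lo if lo is not None else 0.0
    core = 1.0 - tl - tu
    h = core / (hi - left)
    if left < age <= hi:
        return math.log(h)
    if age <= left:
        # power tail t**theta on (0, min), continuous at min, mass tl
        if tl == 0.0:
            return NEG_INF
        theta = h * left / tl - 1.0
        return math.log(tl * (theta + 1.0)) + theta * math.log(age) \
            - (theta + 1.0) * math.log(left)
    # age > hi
    if tu == 0.0:
        return NEG_INF
    lam = h / tu
    return math.log(h) - lam * (age - hi)


@dataclass(frozen=True)
class RootPrior:
    """Normal prior on the root age, truncated to ``age > min_age``."""

    mean: float
    sd: float
    min_age: float = 0.0

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("root prior mean and sd must be positive")

    def log_density(self, age: float) -> float:
        if age <= self.min_age:
            return NEG_INF
        z = (age - self.mean) / self.sd
        # renormalise over the admissible range (min_age, inf)
        log_norm = log_ndtr((self.mean - self.min_age) / self.sd)
        return -0.5 * (LOG_2PI + z * z) - math.log(self.sd) - log_norm


def root_log_density(prior: RootPrior, age: float) -> float:
    return prior.log_density(age)


@dataclass(frozen=True)
class ClockModel:
    """Rate-process specification for the relaxed clock.

    ``autocorrelated_lognormal``: sigma2 is the log-rate diffusion
    variance per Ga; the branch rate used by the likelihood is the
    arithmetic mean of the endpoint node rates.  ``uncorrelated_gamma``:
    i.i.d. branch rates with the given shape, mean ``root_rate``; the
    child node's rate is the branch rate.
    """

    kind: str = "autocorrelated_lognormal"
    sigma2: float = 0.1
    gamma_shape: float = 1.0
    root_rate: float = 0.2   # subs/site/Ga; also the hyperprior median

    def __post_init__(self) -> None:
        if self.kind not in ("autocorrelated_lognormal", "uncorrelated_gamma"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.kind == "autocorrelated_lognormal" and self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.kind == "uncorrelated_gamma" and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.root_rate <= 0:
            raise ValueError("root_rate must be > 0")

    @property
    def branch_rate_convention(self) -> str:
        return "mean" if self.kind == "autocorrelated_lognormal" else "child"


def lognormal_log_density(x: float, log_median: float, sdlog: float = 1.0) -> float:
    """Log-normal density over x (the broad hyperprior building block)."""
    if x <= 0:
        return NEG_INF
    z = (math.log(x) - log_median) / sdlog
    return -0.5 * (LOG_2PI + z * z) - math.log(sdlog * x)


# ---------------------------------------------------------------------------
# resolved, array-based priors (fast path shared with the functional API)
# ---------------------------------------------------------------------------


class TimePrior:
    """Node-time prior resolved against a fixed topology.

    Resolution maps each calibration to the postorder index of its MRCA
    (raising :class:`CladeResolutionError` if the clade cannot be
    resolved, or is required monophyletic and is not); ``log_density``
    then evaluates on a plain age array, returning ``-inf`` for any
    ordering violation.
    """

    def __init__(
        self,
        tree: TimeTree,
        root_prior: RootPrior,
        calibrations: Iterable[Calibration] = (),
    ) -> None:
        self.root_prior = root_prior
        self.root_index = tree.root.index
        n = len(tree.nodes)
        self.parent = np.full(n, -1, dtype=np.int64)
        for node in tree.nodes:
            for child in node.children:
                self.parent[child.index] = node.index
        self.nonroot = np.array(
            [i for i in range(n) if i != self.root_index], dtype=np.int64
        )
        self.tip_mask = np.array([node.is_tip for node in tree.nodes])
        self.n_internal = int((~self.tip_mask).sum())
        self.calibrated: list[tuple[int, Calibration]] = []
        for cal in calibrations:
            node = tree.mrca(cal.clade, require_monophyly=cal.require_monophyly)
            self.calibrated.append((node.index, cal))

    def log_density(self, ages: np.ndarray) -> float:
        root_age = ages[self.root_index]
        if root_age <= 0:
            return NEG_INF
        durations = ages[self.parent[self.nonroot]] - ages[self.nonroot]
        if np.any(durations <= 0):
            return NEG_INF
        logp = self.root_prior.log_density(float(root_age))
        for idx, cal in self.calibrated:
            logp += calibration_log_density(cal, float(ages[idx]))
            if logp == NEG_INF:
                return NEG_INF
        # uniform over the order-constrained simplex given the root age
        logp += -(self.n_internal - 1) * math.log(root_age)
        return logp


class RatePrior:
    """Rate-process prior resolved against a fixed topology."""

    def __init__(self, tree: TimeTree, clock: ClockModel) -> None:
        self.clock = clock
        self.root_index = tree.root.index
        n = len(tree.nodes)
        self.parent = np.full(n, -1, dtype=np.int64)
        for node in tree.nodes:
            for child in node.children:
                self.parent[child.index] = node.index
        self.nonroot = np.array(
            [i for i in range(n) if i != self.root_index], dtype=np.int64
        )
        self.log_root_rate_median = math.log(clock.root_rate)

    def log_density(
        self,
        ages: np.ndarray,
        rates: np.ndarray,
        sigma2_or_shape: float | None = None,
        nu0: float | None = None,
    ) -> float:
        clock = self.clock
        if np.any(rates <= 0):
            return NEG_INF
        if clock.kind == "autocorrelated_lognormal":
            s2 = clock.sigma2 if sigma2_or_shape is None else sigma2_or_shape
            if s2 <= 0:
                return NEG_INF
            dt = ages[self.parent[self.nonroot]] - ages[self.nonroot]
            if np.any(dt <= 0):
                return NEG_INF
            var = s2 * dt
            logr = np.log(rates[self.nonroot])
            mean = np.log(rates[self.parent[self.nonroot]]) - var / 2.0
            edge_terms = (
                -0.5 * (LOG_2PI + np.log(var) + (logr - mean) ** 2 / var) - logr
            )
            root_term = lognormal_log_density(
                float(rates[self.root_index]), self.log_root_rate_median
            )
            return float(edge_terms.sum()) + root_term
        # uncorrelated gamma: i.i.d. Gamma(shape, shape/nu0) on every node rate
        k = clock.gamma_shape if sigma2_or_shape is None else sigma2_or_shape
        scale_mean = clock.root_rate if nu0 is None else nu0
        if k <= 0 or scale_mean <= 0:
            return NEG_INF
        beta = k / scale_mean
        r = rates
        terms = (k - 1.0) * np.log(r) - beta * r + k * math.log(beta) - gammaln(k)
        return float(terms.sum())


def node_time_log_prior(
    tree: TimeTree,
    root_prior: RootPrior,
    calibrations: Iterable[Calibration] = (),
) -> float:
    """Log node-time prior of the tree's current ages (functional API)."""
    prior = TimePrior(tree, root_prior, calibrations)
    ages = np.array([node.age for node in tree.nodes], dtype=float)
    return prior.log_density(ages)


def rate_log_prior(tree: TimeTree, clock: ClockModel) -> float:
    """Log rate-process prior of the tree's current node rates."""
    prior = RatePrior(tree, clock)
    ages = np.array([node.age for node in tree.nodes], dtype=float)
    rates = np.array(
        [node.rate if node.rate is not None else np.nan for node in tree.nodes]
    )
    if np.any(np.isnan(rates)):
        raise ValueError("every node needs a rate")
    return prior.log_density(ages, rates)


# ---------------------------------------------------------------------------
# packaged calibration profiles
# ---------------------------------------------------------------------------

#: Fossil calibration events for the Type II reaction-center phylogeny,
#: bounds in Ga.  The single flexible point is the MRCA of Cyanobacteria:
#: profile ``calibration_1`` places its minimum at the Great Oxidation
#: Event (2.45 Ga), ``calibration_2`` at 2.70 Ga to allow for crown-group
#: Cyanobacteria producing the pre-GOE "whiffs" of oxygen.
CALIBRATION_EVENTS: dict[str, tuple[float | None, float | None]] = {
    "arabidopsis_populus": (0.082, 0.127),
    "angiosperms": (0.124, 0.248),
    "gymnosperms": (0.306, 0.366),
    "land_plants": (0.475, None),
    "diatoms": (0.190, None),
    "florideae": (0.600, None),
    "red_algae_mrca": (1.2, None),
    "heterocystous_cyanobacteria": (1.6, None),
    "pleurocapsales": (1.7, None),
    "early_multicellular_cyanobacteria": (1.9, None),
    "cyanobacteria_mrca": (2.45, None),
}

PROFILE_OVERRIDES: dict[str, dict[str, tuple[float | None, float | None]]] = {
    "calibration_1": {},
    "calibration_2": {"cyanobacteria_mrca": (2.70, None)},
}


def calibration_profile(
    profile: str,
    clade_map: dict[str, Sequence[str]],
    style: str = "soft",
    drop: Sequence[str] = (),
) -> list[Calibration]:
    """Instantiate a named calibration profile against concrete clades.

    ``clade_map`` maps event names to tip sets of the target tree; events
    without a mapping are skipped (a tree need not contain every clade).
    ``drop`` removes events by name, e.g. to test sensitivity to the
    oldest calibration point.
    """
    if profile not in PROFILE_OVERRIDES:
        raise KeyError(f"unknown profile {profile!r}; "
                       f"choose from {sorted(PROFILE_OVERRIDES)}")
    events = dict(CALIBRATION_EVENTS)
    events.update(PROFILE_OVERRIDES[profile])
    out: list[Calibration] = []
    for name, (lo, hi) in events.items():
        if name in drop or name not in clade_map:
            continue
        single = hi is None
        out.append(
            Calibration(
                clade=tuple(clade_map[name]),
                min_age=lo,
                max_age=hi,
                style=style,
                tail_mass_low=0.05 if single else 0.025,
                tail_mass_high=0.0 if single else 0.025,
                name=name,
            )
        )
    return out


def write_calibration_file(cals: Iterable[Calibration], path: str | Path) -> None:
    """Persist calibrations as a key-value text block per clade."""
    lines = []
    for cal in cals:
        lines.append(f"[{cal.name or 'calibration'}]")
        lines.append("tips = " + ",".join(cal.clade))
        if cal.min_age is not None:
            lines.append(f"min_age = {cal.min_age}")
        if cal.max_age is not None:
            lines.append(f"max_age = {cal.max_age}")
        lines.append(f"style = {cal.style}")
        lines.append(f"tail_mass_low = {cal.tail_mass_low}")
        lines.append(f"tail_mass_high = {cal.tail_mass_high}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_calibration_file(path: str | Path) -> list[Calibration]:
    out: list[Calibration] = []
    block: dict[str, str] = {}
    name = ""

    def flush() -> None:
        if not block:
            return
        out.append(
            Calibration(
                clade=tuple(t for t in block["tips"].split(",") if t),
                min_age=float(block["min_age"]) if "min_age" in block else None,
                max_age=float(block["max_age"]) if "max_age" in block else None,
                style=block.get("style", "soft"),
                tail_mass_low=float(block.get("tail_mass_low", 0.025)),
                tail_mass_high=float(block.get("tail_mass_high", 0.025)),
                name=name,
            )
        )

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            flush()
            block = {}
            name = line.strip("[]")
        else:
            key, _, value = line.partition("=")
            block[key.strip()] = value.strip()
    flush()
    return out
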