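"""Forward simulation: every input the dating pipeline consumes.

The generators emulate the structures the inference addresses: a rooted
chronogram with contemporaneous tips, autocorrelated log-normal node
rates optionally following a fast-early/slow-late exponential trend,
amino-acid alignments evolved under the substitution model, and
identity-versus-time pair tables with a roughly linear decay of less
than 1% identity per 100 Ma.  Every generator is bit-reproducible from
(config, seed); simulation truth is recorded alongside each product.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, ProteinAlignment
from .identity import IdentityPair
from .priors import Calibration
from .substitution import (
    SubstitutionModel,
    gamma_category_rates,
    poisson_model,
)
from .timetree import Node, TimeTree


@dataclass(frozen=True)
class RateTrend:
    """Deterministic rate trend nu(t) = nu_inf + amplitude*exp(-(t_root-t)/tau).

    ``t`` is age in Ga, so the rate starts at ``nu_inf + amplitude`` at
    the root and decays toward ``nu_inf`` at the present, with e-folding
    time ``tau`` (Ga).
    """

    nu_inf: float = 0.12
    amplitude: float = 4.91
    tau: float = 0.5

    def at_age(self, age: float, root_age: float) -> float:
        return self.nu_inf + self.amplitude * np.exp(-(root_age - age) / self.tau)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic dataset (seed is mandatory)."""

    seed: int
    n_tips: int = 20
    root_age: float = 3.5                 # Ga
    clock_kind: str = "autocorrelated_lognormal"
    sigma2: float = 0.1                   # log-rate diffusion variance per Ga
    gamma_shape: float = 1.0              # branch-rate shape (uncorrelated kind)
    root_rate: float = 0.25               # subs/site/Ga
    trend: RateTrend | None = None
    model: SubstitutionModel = field(default_factory=poisson_model)
    n_sites: int = 300

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("need at least two tips")
        if self.root_age <= 0 or self.root_rate <= 0 or self.n_sites < 1:
            raise ValueError("positivity constraint violated")
        if self.sigma2 < 0 or self.gamma_shape <= 0:
            raise ValueError("positivity constraint violated")

    def hash(self) -> str:
        payload = {
            k: v for k, v in self.__dict__.items() if k not in ("model",)
        }
        payload["trend"] = None if self.trend is None else self.trend.__dict__
        payload["model"] = self.model.name
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng([seed, salt])


def truth_table(tree: TimeTree, config: SimulationConfig) -> pd.DataFrame:
    """Per-node ground truth consistent with the emitted tree."""
    rows = []
    for node in tree.nodes:
        expected = (
            None
            if node.parent is None or node.rate is None
            else 0.5 * (node.rate + node.parent.rate) * (node.parent.age - node.age)
        )
        rows.append(
            {
                "node": f"n{node.index}",
                "key": tree.node_key(node),
                "label": node.label or (node.name if node.is_tip else ""),
                "true_age": node.age,
                "true_rate": node.rate,
                "branch_expected_subs": expected,
                "seed": config.seed,
                "config_hash": config.hash(),
            }
        )
    return pd.DataFrame(rows)


def simulate_chronogram(
    config: SimulationConfig, tip_names: Sequence[str] | None = None
) -> tuple[TimeTree, pd.DataFrame]:
    """Random ultrametric tree by successive random coalescence.

    Internal ages are sorted uniforms on (0, root_age) assigned in
    coalescence order; the final join is pinned at ``root_age`` so the
    root age is exactly the configured study condition.
    """
    rng = _rng(config.seed, 1)
    n = config.n_tips
    names = (
        list(tip_names)
        if tip_names is not None
        else [f"t{i + 1:03d}" for i in range(n)]
    )
    if len(names) != n:
        raise ValueError("tip_names length must equal n_tips")
    lineages = [Node(name=name, age=0.0) for name in names]
    inner = np.sort(rng.uniform(0.0, config.root_age, size=max(n - 2, 0)))
    ages = np.concatenate([inner, [config.root_age]])
    for age in ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        joined = Node(age=float(age))
        joined.add_child(lineages[i])
        joined.add_child(lineages[j])
        lineages[j:j + 1] = []
        lineages[i] = joined
    tree = TimeTree(lineages[0])
    tree.validate_ages()
    return tree, truth_table(tree, config)


def simulate_rates(
    tree: TimeTree, config: SimulationConfig
) -> tuple[TimeTree, pd.DataFrame]:
    """Draw node rates in place: autocorrelated walk or i.i.d. gamma.

    Autocorrelated kind: a log-rate random walk down the tree with
    variance sigma^2 * elapsed time around the (optionally trended)
    mean, mean-corrected so E[r_child | r_parent] follows the trend.
    sigma^2 = 0 is allowed here and gives the deterministic trend
    (or a strict clock when no trend is set).
    """
    rng = _rng(config.seed, 2)
    root_age = tree.root.age
    trend = config.trend

    def target(age: float) -> float:
        if trend is None:
            return config.root_rate
        return trend.at_age(age, root_age)

    if config.clock_kind == "autocorrelated_lognormal":
        tree.root.rate = target(root_age)
        for node in tree.preorder():
            for child in node.children:
                dt = node.age - child.age
                var = config.sigma2 * dt
                drift = np.log(target(child.age)) - np.log(target(node.age))
                mean = np.log(node.rate) + drift - var / 2.0
                child.rate = float(
                    np.exp(mean + np.sqrt(var) * rng.standard_normal())
                )
    elif config.clock_kind == "uncorrelated_gamma":
        k = config.gamma_shape
        for node in tree.nodes:
            node.rate = float(
                rng.gamma(shape=k, scale=target(node.age) / k)
            )
    else:
        raise ValueError(f"unknown clock kind {config.clock_kind!r}")
    return tree, truth_table(tree, config)


def simulate_alignment(
    tree: TimeTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
    branch_rate_convention: str = "mean",
) -> ProteinAlignment:
    """Evolve sites down the tree under the model with site-fixed Gamma rates.

    Root states are drawn from pi; each site keeps its Gamma category
    along the whole tree, matching the likelihood's assumption.
    """
    tree.validate_ages(require_rates=True)
    rng = _rng(seed, 3)
    n_cat = model.n_categories
    cat_rates = gamma_category_rates(model.gamma_shape, n_cat)
    site_cat = rng.integers(n_cat, size=n_sites)
    lam, right, left = model.eigensystem()
    pi = model.frequencies

    states: dict[int, np.ndarray] = {
        tree.root.index: rng.choice(20, size=n_sites, p=pi)
    }
    for node in tree.preorder():
        for child in node.children:
            dur = node.age - child.age
            if branch_rate_convention == "mean":
                rate = 0.5 * (node.rate + child.rate)
            else:
                rate = child.rate
            parent_states = states[node.index]
            child_states = np.empty(n_sites, dtype=np.int64)
            for k in range(n_cat):
                blen = rate * dur * cat_rates[k]
                P = np.clip((right * np.exp(lam * blen)[None, :]) @ left, 0.0, None)
                P /= P.sum(axis=1, keepdims=True)
                sel = site_cat == k
                if not np.any(sel):
                    continue
                rows = P[parent_states[sel]]
                u = rng.random(rows.shape[0])
                child_states[sel] = (u[:, None] > rows.cumsum(axis=1)).sum(axis=1)
            states[child.index] = child_states
    ids, rows = [], []
    for tip in tree.tips():
        ids.append(tip.name)
        rows.append("".join(AMINO_ACIDS[s] for s in states[tip.index]))
    return ProteinAlignment(tuple(ids), tuple(rows))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[TimeTree, ProteinAlignment, pd.DataFrame]:
    """Chronogram + rates + alignment in one call (the pipeline's input)."""
    tree, _ = simulate_chronogram(config)
    tree, truth = simulate_rates(tree, config)
    aln = simulate_alignment(
        tree,
        config.model,
        config.n_sites,
        config.seed,
        branch_rate_convention=(
            "mean" if config.clock_kind == "autocorrelated_lognormal" else "child"
        ),
    )
    return tree, aln, truth


def generate_identity_pairs(
    n_pairs: int = 23,
    slope: float = -0.8,
    intercept: float = 100.0,
    noise_sd: float = 0.3,
    time_range: tuple[float, float] = (0.05, 2.0),
    seed: int = 0,
) -> tuple[list[IdentityPair], pd.DataFrame]:
    """Identity-vs-time pairs with a linear trend (% per Ga) plus noise.

    Defaults emulate the observed Proterozoic decay of reaction-center
    protein identity: about 0.8% per 100 Ma over the last 2 Ga.
    """
    if n_pairs < 2:
        raise ValueError("need at least two pairs")
    rng = _rng(seed, 4)
    times = rng.uniform(*time_range, size=n_pairs)
    idents = np.clip(
        intercept + slope * times + noise_sd * rng.standard_normal(n_pairs),
        0.0,
        100.0,
    )
    pairs = [
        IdentityPair(f"p{i:02d}a", f"p{i:02d}b", float(idents[i]), float(times[i]))
        for i in range(n_pairs)
    ]
    truth = pd.DataFrame(
        {
            "slope": slope,
            "intercept": intercept,
            "noise_sd": noise_sd,
            "seed": seed,
        },
        index=[0],
    )
    return pairs, truth


def calibrations_at_true_ages(
    tree: TimeTree,
    n: int = 3,
    rel_width: float = 0.15,
    tail_mass: float = 0.025,
) -> list[Calibration]:
    """Soft calibrations bracketing the true ages of ``n`` internal nodes.

    Nodes are picked at age quantiles of the internal-node distribution
    (excluding the root), so calibrations spread over the depth of the
    tree the way fossil constraints do.
    """
    candidates = [
        node for node in tree.internal_nodes() if node is not tree.root
    ]
    if not candidates:
        raise ValueError("tree has no internal non-root nodes")
    candidates.sort(key=lambda nd: nd.age)
    qs = np.linspace(0.15, 0.85, n)
    picked: list[Node] = []
    for q in qs:
        node = candidates[int(round(q * (len(candidates) - 1)))]
        if node not in picked:
            picked.append(node)
    tipsets = tree.tip_sets()
    out = []
    for node in picked:
        out.append(
            Calibration(
                clade=tuple(sorted(tipsets[node.index])),
                min_age=node.age * (1.0 - rel_width),
                max_age=node.age * (1.0 + rel_width),
                style="soft",
                tail_mass_low=tail_mass,
                tail_mass_high=tail_mass,
                name=f"true_age_{tree.node_key(node)}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# the reaction-center-shaped fixture
# ---------------------------------------------------------------------------


def _random_subtree(
    names: Sequence[str], crown_age: float, rng: np.random.Generator
) -> Node:
    """Random coalescent subtree over ``names`` with crown at ``crown_age``."""
    lineages = [Node(name=n, age=0.0) for n in names]
    if len(lineages) == 1:
        return lineages[0]
    inner = np.sort(rng.uniform(0.0, crown_age, size=len(lineages) - 2))
    for age in np.concatenate([inner, [crown_age]]):
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        joined = Node(age=float(age))
        joined.add_child(lineages[i])
        joined.add_child(lineages[j])
        del lineages[j]
        lineages[i] = joined
    return lineages[0]


def _join(age: float, left: Node, right: Node, label: str | None = None) -> Node:
    node = Node(age=age, label=label)
    node.add_child(left)
    node.add_child(right)
    return node


def reaction_center_fixture(
    seed: int = 0,
) -> tuple[TimeTree, dict[str, tuple[str, ...]]]:
    """A 74-taxon labeled chronogram shaped like the Type II RC protein tree.

    The oxygenic branch carries the five D1 groups (G0-G2 atypical,
    G3 microaerobic, G4 dominant, the latter containing cyanobacterial
    and photosynthetic-eukaryote sequences) plus D2; the anoxygenic
    branch carries L and M.  Key nodes are labeled II (root), D0
    (D1/D2 duplication), K (L/M duplication) and standard_d1 (ancestral
    standard D1, MRCA of G3+G4).  True ages form a self-consistent
    chronology (root 3.5, D0 3.2, standard D1 2.6, K 2.87 Ga).

    Returns the tree and a clade map from calibration event names to
    tip sets, usable directly with
    :func:`rcclock.priors.calibration_profile`.
    """
    rng = _rng(seed, 5)

    # eukaryote D1 (within G4): fixed chronology matching the fossil events
    arabpop = _join(0.105, Node(name="g4_arabidopsis", age=0.0),
                    Node(name="g4_populus", age=0.0))
    angios = _join(0.19, Node(name="g4_amborella", age=0.0), arabpop)
    gymnos = _join(0.33, Node(name="g4_cycas", age=0.0), angios)
    plants = _join(0.50, Node(name="g4_marchantia", age=0.0), gymnos)
    diatoms = _join(0.25, Node(name="g4_phaeodactylum", age=0.0),
                    Node(name="g4_thalassiosira", age=0.0))
    greens = _join(0.70, diatoms, plants)
    florid = _join(0.80, Node(name="g4_porphyra", age=0.0), greens)
    euk = _join(1.30, Node(name="g4_cyanidium", age=0.0), florid)

    hetero = _join(1.65, Node(name="g4_nostoc", age=0.0),
                   Node(name="g4_anabaena", age=0.0))
    clade_b = _join(1.85, hetero, euk)
    pleuro = _join(1.75, Node(name="g4_pleurocapsa", age=0.0),
                   Node(name="g4_chroococcidiopsis", age=0.0))
    clade_a = _join(2.05, pleuro, clade_b)
    pseudo = _join(1.95, Node(name="g4_pseudanabaena1", age=0.0),
                   Node(name="g4_pseudanabaena2", age=0.0))
    rest = _join(2.30, pseudo, clade_a)
    g4 = _join(2.45, Node(name="g4_gloeobacter", age=0.0), rest, label="G4")

    g3 = _random_subtree([f"g3_{i}" for i in range(1, 7)], 1.9, rng)
    g3.label = "G3"
    standard = _join(2.60, g3, g4, label="standard_d1")
    g2 = _random_subtree([f"g2_{i}" for i in range(1, 5)], 1.8, rng)
    g2.label = "G2"
    n_g2 = _join(2.80, g2, standard)
    g1 = _random_subtree([f"g1_{i}" for i in range(1, 5)], 1.6, rng)
    g1.label = "G1"
    n_g1 = _join(2.90, g1, n_g2)
    g0 = _random_subtree([f"g0_{i}" for i in range(1, 5)], 1.5, rng)
    g0.label = "G0"
    d1 = _join(3.00, g0, n_g1, label="D1")

    d2_names = ["d2_gloeobacter"] + [f"d2_{i}" for i in range(1, 12)]
    d2_rest = _random_subtree(d2_names[1:], 2.3, rng)
    d2 = _join(2.45, Node(name="d2_gloeobacter", age=0.0), d2_rest, label="D2")
    d0 = _join(3.20, d1, d2, label="D0")

    l_clade = _random_subtree([f"l_{i}" for i in range(1, 15)], 1.9, rng)
    l_clade.label = "L"
    m_clade = _random_subtree([f"m_{i}" for i in range(1, 15)], 1.85, rng)
    m_clade.label = "M"
    k_node = _join(2.87, l_clade, m_clade, label="K")

    root = _join(3.50, d0, k_node, label="II")
    tree = TimeTree(root)
    tree.validate_ages()

    def tips_under(node: Node) -> tuple[str, ...]:
        return tuple(sorted(tree.tip_sets()[node.index]))

    clade_map = {
        "arabidopsis_populus": ("g4_arabidopsis", "g4_populus"),
        "angiosperms": tips_under(angios),
        "gymnosperms": tips_under(gymnos),
        "land_plants": tips_under(plants),
        "diatoms": tips_under(diatoms),
        "florideae": tips_under(florid),
        "red_algae_mrca": tips_under(euk),
        "heterocystous_cyanobacteria": tips_under(hetero),
        "pleurocapsales": tips_under(pleuro),
        "early_multicellular_cyanobacteria": tips_under(pseudo),
        "cyanobacteria_mrca": tips_under(g4),
    }
    return tree, clade_map
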