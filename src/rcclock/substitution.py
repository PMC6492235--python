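"""Amino-acid substitution models and the pruning likelihood.

Models are time-reversible 20-state CTMCs built from a symmetric
exchangeability matrix S and equilibrium frequencies pi,

    q_ij = S_ij * pi_j   (i != j),   diagonal = -row sum,

normalised so that one unit of branch length is one expected substitution
per site.  The Poisson model has all exchangeabilities equal and
pi = 1/20; the empirical LG matrix ships as a PAML-layout data file and
user matrices in the same format are accepted.

Among-site rate variation uses the discrete-Gamma approximation with
equal-probability categories (category rate = category mean), four
categories by default.

The likelihood of an alignment given a chronogram with rates is computed
by Felsenstein pruning over compressed site patterns, with per-node
rescaling so alignments of at least 1,000 sites by 100 tips stay in
range.  ``PruningEngine`` additionally supports partial recomputation
after single-edge changes, which is what makes the MCMC sampler
affordable: a changed edge only dirties conditional likelihoods on the
path to the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .alignment import AMINO_ACIDS, ProteinAlignment
from .timetree import TimeTree

N_STATES = 20
_STATE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MISSING_CODE = N_STATES  # '-' and 'X' sum over all states


class ModelError(ValueError):
    pass


class TaxonMappingError(KeyError):
    """Tip names of the tree do not match the alignment ids."""


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible amino-acid model with discrete-Gamma rate heterogeneity."""

    exchangeabilities: np.ndarray   # symmetric 20x20, zero diagonal
    frequencies: np.ndarray        # length 20, sums to 1
    gamma_shape: float = 1.0
    n_categories: int = 4
    name: str = "custom"

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (N_STATES, N_STATES) or not np.allclose(S, S.T):
            raise ModelError("exchangeabilities must be a symmetric 20x20 matrix")
        if np.any(S < 0):
            raise ModelError("exchangeabilities must be nonnegative")
        if pi.shape != (N_STATES,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
            raise ModelError("frequencies must be 20 nonnegative values summing to 1")
        if self.gamma_shape <= 0 or self.n_categories < 1:
            raise ModelError("gamma_shape must be > 0 and n_categories >= 1")
        object.__setattr__(self, "exchangeabilities", S)
        object.__setattr__(self, "frequencies", pi / pi.sum())

    @property
    def rate_matrix(self) -> np.ndarray:
        """Q with unit expected substitution rate at equilibrium."""
        S, pi = self.exchangeabilities, self.frequencies
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices(N_STATES)] = -Q.sum(axis=1)
        mu = -float(pi @ np.diag(Q))
        return Q / mu

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetric eigendecomposition of Q (reversibility exploited)."""
        pi = self.frequencies
        sq = np.sqrt(pi)
        B = (sq[:, None] * self.rate_matrix) / sq[None, :]
        lam, U = np.linalg.eigh((B + B.T) / 2.0)
        left = U.T * sq[None, :]          # U^T D^{1/2}
        right = U / sq[:, None]           # D^{-1/2} U
        return lam, right, left

    def with_frequencies(self, frequencies: np.ndarray) -> "SubstitutionModel":
        return replace(self, frequencies=np.asarray(frequencies, float))


def poisson_model(gamma_shape: float = 1.0, n_categories: int = 4) -> SubstitutionModel:
    S = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
    pi = np.full(N_STATES, 1.0 / N_STATES)
    return SubstitutionModel(S, pi, gamma_shape, n_categories, name="poisson")


def read_paml_model(
    path: str | Path, gamma_shape: float = 1.0, n_categories: int = 4, name: str = "custom"
) -> SubstitutionModel:
    """Read a PAML-layout model file: 190 lower-triangle values + 20 frequencies."""
    values = [float(tok) for tok in Path(path).read_text().split()]
    if len(values) != 190 + N_STATES:
        raise ModelError(
            f"expected 190 exchangeabilities + 20 frequencies, got {len(values)} values"
        )
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    pi = np.array(values[190:])
    return SubstitutionModel(S, pi, gamma_shape, n_categories, name=name)


def lg_model(gamma_shape: float = 1.0, n_categories: int = 4) -> SubstitutionModel:
    """The LG empirical matrix (Le & Gascuel 2008), PAML state order."""
    with resources.as_file(resources.files("rcclock.data") / "lg.paml") as p:
        return read_paml_model(p, gamma_shape, n_categories, name="lg")


def gamma_category_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean-one discrete-Gamma rates: means of equal-probability bins.

    Bin boundaries are quantiles of Gamma(alpha, alpha); the rate of a
    bin is its conditional mean, computed in closed form through the
    Gamma(alpha+1) CDF, then renormalised so the average is exactly 1.
    """
    from scipy.stats import gamma as gamma_dist

    if alpha <= 0 or n_categories < 1:
        raise ModelError("alpha must be > 0 and n_categories >= 1")
    if n_categories == 1:
        return np.ones(1)
    probs = np.arange(1, n_categories) / n_categories
    cuts = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    upper_cdf = gamma_dist.cdf(edges, a=alpha + 1.0, scale=1.0 / alpha)
    rates = n_categories * np.diff(upper_cdf)
    return rates / rates.mean()


def transition_matrix(model: SubstitutionModel, branch_length: float) -> np.ndarray:
    """P(t) = exp(Q t); rows sum to 1, P(0) = I."""
    if branch_length < 0:
        raise ModelError("branch length must be >= 0")
    lam, right, left = model.eigensystem()
    P = (right * np.exp(lam * branch_length)[None, :]) @ left
    return np.clip(P, 0.0, None)


@dataclass
class LikelihoodResult:
    log_likelihood: float
    per_site: np.ndarray | None = field(default=None, repr=False)


def expected_branch_lengths(tree: TimeTree, convention: str = "mean") -> np.ndarray:
    """Expected substitutions/site per edge, indexed by child node.

    ``mean``: branch rate is the arithmetic mean of the endpoint node
    rates (the Kishino-Thorne convention used with the autocorrelated
    clock).  ``child``: the child node's rate is the branch rate (used
    with the uncorrelated clock, where rates are per-branch).
    """
    blens = np.zeros(len(tree.nodes))
    for node in tree.nodes:
        if node.parent is None:
            continue
        dur = node.parent.age - node.age
        if convention == "mean":
            rate = 0.5 * (node.parent.rate + node.rate)
        elif convention == "child":
            rate = node.rate
        else:
            raise ValueError(f"unknown branch-rate convention {convention!r}")
        blens[node.index] = rate * dur
    return blens


def _encode_patterns(
    aln: ProteinAlignment, tip_order: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compress alignment columns into unique site patterns with weights."""
    codes = np.empty((len(tip_order), aln.n_sites), dtype=np.int64)
    for row_i, name in enumerate(tip_order):
        try:
            row = aln.row(name)
        except KeyError:
            raise TaxonMappingError(
                f"tree tip {name!r} has no matching alignment row"
            ) from None
        codes[row_i] = [_STATE_INDEX.get(ch, MISSING_CODE) for ch in row]
    patterns, inverse, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts.astype(float), inverse



# --- optional numba acceleration of the pruning kernels ------------------
try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _k_partial(a, b, out, scale, floor):
        n_cat, n_pat, n_state = a.shape
        for p in range(n_pat):
            m = floor
            for k in range(n_cat):
                for s in range(n_state):
                    v = a[k, p, s] * b[k, p, s]
                    out[k, p, s] = v
                    if v > m:
                        m = v
            scale[p] = np.log(m)
            inv = 1.0 / m
            for k in range(n_cat):
                for s in range(n_state):
                    out[k, p, s] *= inv

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _partial_numpy(a, b, out, scale, floor):
    np.multiply(a, b, out=out)
    m = np.maximum(out.max(axis=(0, 2)), floor)
    out /= m[None, :, None]
    np.log(m, out=scale)


class PruningEngine:
    """Felsenstein pruning with cached conditionals and overlay proposals.

    Layout is (categories, patterns, 20) so per-category work is one
    BLAS call.  Two caches are kept per node: the scaled conditional
    likelihood ``partial`` (internal nodes) and the edge contribution
    ``contrib`` — P_edge applied to the child's conditionals (every
    non-root node).  ``set_state`` recomputes everything.  ``propose``
    recomputes only what a changed edge (or a new alpha) dirties, but
    writes the results into a transient overlay: ``accept`` commits the
    overlay into the caches, ``reject`` simply drops it, so rejected
    proposals never copy cache arrays.
    """

    def __init__(
        self,
        alignment: ProteinAlignment,
        tree: TimeTree,
        model: SubstitutionModel,
        dtype: type = np.float64,
    ) -> None:
        self.tree = tree
        self.model = model
        self.dtype = np.dtype(dtype)
        self.scale_floor = 1e-300 if self.dtype == np.float64 else 1e-30
        self.n_cat = model.n_categories
        self.nodes = tree.nodes
        self.n_nodes = len(self.nodes)
        self.root_index = tree.root.index
        tip_nodes = tree.tips()
        if set(t.name for t in tip_nodes) != set(alignment.ids):
            extra = set(alignment.ids) - set(t.name for t in tip_nodes)
            missing = set(t.name for t in tip_nodes) - set(alignment.ids)
            raise TaxonMappingError(
                f"tree/alignment mismatch (tree-only: {sorted(missing)}, "
                f"alignment-only: {sorted(extra)})"
            )
        tip_order = [t.name for t in tip_nodes]
        patterns, self.counts, self.site_to_pattern = _encode_patterns(
            aln=alignment, tip_order=tip_order
        )
        self.n_patterns = patterns.shape[1]
        self.n_sites = alignment.n_sites
        # one-hot tip conditionals with an extra all-ones column for missing
        self.tip_onehot: dict[int, np.ndarray] = {}
        for i, t in enumerate(tip_nodes):
            H = np.zeros((self.n_patterns, N_STATES + 1), dtype=dtype)
            H[np.arange(self.n_patterns), patterns[i]] = 1.0
            self.tip_onehot[t.index] = H

        self.lam, self.right, self.left = model.eigensystem()
        self.pi = model.frequencies
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.children: dict[int, tuple[int, int]] = {}
        for node in self.nodes:
            for child in node.children:
                self.parent[child.index] = node.index
            if node.children:
                self.children[node.index] = (
                    node.children[0].index,
                    node.children[1].index,
                )
        self.internal = [n.index for n in self.nodes if n.children]  # postorder

        shape = (self.n_nodes, self.n_cat, self.n_patterns, N_STATES)
        self.P = np.zeros((self.n_nodes, self.n_cat, N_STATES, N_STATES),
                          dtype=dtype)
        self.partial = np.zeros(shape, dtype=dtype)   # internal rows only
        self.contrib = np.zeros(shape, dtype=dtype)   # non-root rows only
        self.own_scale = np.zeros((self.n_nodes, self.n_patterns), dtype=dtype)
        self.cum_scale = np.zeros((self.n_nodes, self.n_patterns), dtype=dtype)
        self.pi_typed = self.pi.astype(dtype)
        self.blens = np.zeros(self.n_nodes)
        self.alpha = model.gamma_shape
        self.cat_rates = gamma_category_rates(self.alpha, self.n_cat)
        self._loglik: float = np.nan
        self._pend: dict | None = None

    # ---- state ------------------------------------------------------

    def set_state(self, blens: np.ndarray, alpha: float | None = None) -> float:
        if np.any(np.asarray(blens) < 0):
            raise ModelError("branch lengths must be >= 0")
        self.blens = np.asarray(blens, dtype=float).copy()
        if alpha is not None:
            self.alpha = float(alpha)
            self.cat_rates = gamma_category_rates(self.alpha, self.n_cat)
        nonroot = [i for i in range(self.n_nodes) if i != self.root_index]
        self.P[nonroot] = self._compute_P(nonroot, self.blens[nonroot],
                                          self.cat_rates)
        for v in self.internal:
            for c in self.children[v]:
                self._edge_contrib_into(c, self.P[c], self._read_partial(c),
                                        self.contrib[c])
            _partial_impl(
                self.contrib[self.children[v][0]],
                self.contrib[self.children[v][1]],
                self.partial[v],
                self.own_scale[v],
                self.scale_floor,
            )
            cum = self.own_scale[v].copy()
            for c in self.children[v]:
                if c in self.children:
                    cum += self.cum_scale[c]
            self.cum_scale[v] = cum
        self._loglik = self._root_loglik(self.partial[self.root_index],
                                         self.cum_scale[self.root_index])
        return self._loglik

    @property
    def log_likelihood(self) -> float:
        return self._loglik

    # ---- computation helpers ----------------------------------------

    def _compute_P(
        self, edge_nodes: list[int], blens: np.ndarray, cat_rates: np.ndarray
    ) -> np.ndarray:
        t = np.asarray(blens)[:, None] * cat_rates[None, :]           # (e, cat)
        expo = np.exp(self.lam[None, None, :] * t[:, :, None])        # (e, cat, 20)
        P = (self.right[None, None] * expo[:, :, None, :]) @ self.left
        return np.clip(P, 0.0, None).astype(self.dtype)

    def _edge_contrib_into(
        self, e: int, P: np.ndarray, child_partial: np.ndarray | None,
        out: np.ndarray,
    ) -> None:
        """out[k] = conditionals of child e pushed through P[k]."""
        H = self.tip_onehot.get(e)
        if H is not None:
            ones = np.ones((self.n_cat, N_STATES, 1), dtype=self.dtype)
            PeT = np.ascontiguousarray(
                np.concatenate([P, ones], axis=2).transpose(0, 2, 1)
            )
            for k in range(self.n_cat):
                np.dot(H, PeT[k], out=out[k])
        else:
            PT = np.ascontiguousarray(P.transpose(0, 2, 1))
            for k in range(self.n_cat):
                np.dot(child_partial[k], PT[k], out=out[k])

    def _root_loglik(self, root_partial: np.ndarray, root_cum: np.ndarray) -> float:
        site = (root_partial @ self.pi_typed).mean(axis=0, dtype=np.float64)
        return float(self.counts @ (np.log(site) + root_cum))

    def _read_partial(self, e: int) -> np.ndarray | None:
        return None if e in self.tip_onehot else self.partial[e]

    def _dirty_path(self, edge_nodes: list[int]) -> list[int]:
        dirty: set[int] = set()
        for e in edge_nodes:
            v = self.parent[e]
            while v != -1 and v not in dirty:
                dirty.add(v)
                v = self.parent[v]
        return sorted(dirty)  # postorder indices: children before parents

    # ---- proposal protocol ------------------------------------------

    def propose(
        self, new_blens: dict[int, float], new_alpha: float | None = None
    ) -> float:
        """Evaluate an edge/alpha change, returning the new log-likelihood.

        Results live in an overlay until :meth:`accept` commits them;
        :meth:`reject` discards them at no cost.
        """
        if self._pend is not None:
            raise RuntimeError("previous proposal not resolved")
        if any(b < 0 for b in new_blens.values()):
            raise ModelError("branch lengths must be >= 0")

        if new_alpha is not None:
            edges = [i for i in range(self.n_nodes) if i != self.root_index]
            cat_rates = gamma_category_rates(float(new_alpha), self.n_cat)
            blens = self.blens.copy()
            for e, b in new_blens.items():
                blens[e] = b
        else:
            edges = [e for e, b in new_blens.items() if b != self.blens[e]]
            cat_rates = self.cat_rates
            blens = None

        dirty = self._dirty_path(edges)
        contrib_dirty = set(edges) | {v for v in dirty if v != self.root_index}
        pend_P: dict[int, np.ndarray] = {}
        pend_contrib: dict[int, np.ndarray] = {}
        pend_partial: dict[int, np.ndarray] = {}
        pend_own: dict[int, np.ndarray] = {}
        pend_cum: dict[int, np.ndarray] = {}

        if edges:
            use_blens = (
                blens[edges] if blens is not None
                else np.array([new_blens[e] for e in edges])
            )
            P_new = self._compute_P(edges, use_blens, cat_rates)
            for i, e in enumerate(edges):
                pend_P[e] = P_new[i]

        kp_shape = (self.n_cat, self.n_patterns, N_STATES)
        for v in dirty:
            c1, c2 = self.children[v]
            for c in (c1, c2):
                if c in contrib_dirty:
                    out = np.empty(kp_shape, dtype=self.dtype)
                    child_partial = (
                        None if c in self.tip_onehot
                        else pend_partial.get(c, self.partial[c])
                    )
                    self._edge_contrib_into(
                        c, pend_P.get(c, self.P[c]), child_partial, out
                    )
                    pend_contrib[c] = out
            part = np.empty(kp_shape, dtype=self.dtype)
            own = np.empty(self.n_patterns, dtype=self.dtype)
            _partial_impl(
                pend_contrib.get(c1, self.contrib[c1]),
                pend_contrib.get(c2, self.contrib[c2]),
                part, own, self.scale_floor,
            )
            pend_partial[v] = part
            pend_own[v] = own
            cum = own.copy()
            for c in (c1, c2):
                if c in self.children:
                    cum += pend_cum.get(c, self.cum_scale[c])
            pend_cum[v] = cum

        root = self.root_index
        new_loglik = self._root_loglik(
            pend_partial.get(root, self.partial[root]),
            pend_cum.get(root, self.cum_scale[root]),
        )
        self._pend = {
            "P": pend_P,
            "contrib": pend_contrib,
            "partial": pend_partial,
            "own": pend_own,
            "cum": pend_cum,
            "blens": dict(new_blens),
            "alpha": new_alpha,
            "cat_rates": cat_rates,
            "loglik": new_loglik,
        }
        return new_loglik

    def accept(self) -> None:
        p = self._pend
        if p is None:
            raise RuntimeError("nothing to accept")
        for e, arr in p["P"].items():
            self.P[e] = arr
        for e, arr in p["contrib"].items():
            self.contrib[e] = arr
        for v, arr in p["partial"].items():
            self.partial[v] = arr
        for v, arr in p["own"].items():
            self.own_scale[v] = arr
        for v, arr in p["cum"].items():
            self.cum_scale[v] = arr
        for e, b in p["blens"].items():
            self.blens[e] = b
        if p["alpha"] is not None:
            self.alpha = float(p["alpha"])
            self.cat_rates = p["cat_rates"]
        self._loglik = p["loglik"]
        self._pend = None

    def reject(self) -> None:
        if self._pend is None:
            raise RuntimeError("nothing to reject")
        self._pend = None

    def per_site_log_likelihood(self) -> np.ndarray:
        site = (self.partial[self.root_index] @ self.pi_typed).mean(
            axis=0, dtype=np.float64
        )
        logs = np.log(site) + self.cum_scale[self.root_index]
        return logs[self.site_to_pattern]


_partial_impl = _k_partial if _HAVE_NUMBA else _partial_numpy


def log_likelihood(
    alignment: ProteinAlignment,
    tree: TimeTree,
    model: SubstitutionModel,
    branch_rate_convention: str = "mean",
    per_site: bool = False,
) -> LikelihoodResult:
    """Pruning log-likelihood of an alignment given a dated, rated tree."""
    tree.validate_ages(require_rates=True)
    engine = PruningEngine(alignment, tree, model)
    total = engine.set_state(
        expected_branch_lengths(tree, branch_rate_convention), alpha=model.gamma_shape
    )
    sites = engine.per_site_log_likelihood() if per_site else None
    return LikelihoodResult(log_likelihood=total, per_site=sites)
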