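"""Pairwise percent identity and the identity-versus-time regression.

Reaction-center core proteins lose sequence identity roughly linearly over
the Proterozoic — less than 1% per 100 Ma.  Extrapolating that trend back
in time shows that a constant rate cannot reach the low identities shared
by deep paralogs (D1 vs D2 ~29%, D1/D2 vs L/M ~17%) within the age of the
Earth, which is the motivation for the relaxed-clock analysis.

Identity between two aligned rows is computed column-wise; when the two
sequences have different ungapped lengths the longer one is taken as 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import GAP, ProteinAlignment


class UndefinedIdentityError(ValueError):
    """Both rows are all-gap: identity has no denominator."""


class SingularFitError(ValueError):
    """All divergence times coincide: the regression slope is undefined."""


class NoCrossingError(ValueError):
    """A non-negative slope never reaches the target identity."""


@dataclass(frozen=True)
class IdentityPair:
    label_a: str
    label_b: str
    identity: float          # percent, [0, 100]
    divergence_time: float   # Ga

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.divergence_time < 0:
            raise ValueError("divergence time must be >= 0")


@dataclass(frozen=True)
class LinearFit:
    slope: float        # % identity per Ga (negative for decay)
    intercept: float    # % identity at time 0
    r_squared: float
    n: int

    @property
    def slope_per_100ma(self) -> float:
        """Slope re-expressed in % per 100 Ma (1 Ga = 10 x 100 Ma)."""
        return self.slope / 10.0


def percent_identity(
    a: str, b: str, mask: Sequence[int] | None = None
) -> float:
    """Column-wise percent identity between two rows of one alignment.

    Matching non-gap residues are counted and divided by the larger of
    the two ungapped lengths, implementing the longest-as-100% rule.
    ``mask`` optionally restricts the computation to a subset of columns.
    """
    if len(a) != len(b):
        raise ValueError("rows must come from the same alignment")
    a = a.upper()
    b = b.upper()
    if mask is not None:
        a = "".join(a[i] for i in mask)
        b = "".join(b[i] for i in mask)
    len_a = sum(1 for c in a if c != GAP)
    len_b = sum(1 for c in b if c != GAP)
    denom = max(len_a, len_b)
    if denom == 0:
        raise UndefinedIdentityError("both rows are all-gap")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    return 100.0 * matches / denom


def pairs_from_alignment(
    aln: ProteinAlignment,
    table: pd.DataFrame,
    mask: Sequence[int] | None = None,
) -> list[IdentityPair]:
    """Build identity pairs from a divergence-time table.

    ``table`` needs columns ``label_a``, ``label_b``, ``divergence_time_ga``;
    an optional ``identity`` column overrides computation from the alignment.
    """
    out = []
    for rec in table.itertuples(index=False):
        if hasattr(rec, "identity") and not pd.isna(rec.identity):
            ident = float(rec.identity)
        else:
            ident = percent_identity(aln.row(rec.label_a), aln.row(rec.label_b), mask)
        out.append(
            IdentityPair(rec.label_a, rec.label_b, ident, float(rec.divergence_time_ga))
        )
    return out


def fit_identity_regression(pairs: Iterable[IdentityPair]) -> LinearFit:
    """Ordinary least squares of percent identity on divergence time."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise SingularFitError("need at least two pairs")
    t = np.array([p.divergence_time for p in pairs])
    y = np.array([p.identity for p in pairs])
    if np.ptp(t) == 0:
        raise SingularFitError("all divergence times are equal")
    res = stats.linregress(t, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(pairs),
    )


def extrapolate_time_to_identity(fit: LinearFit, target_identity: float) -> float:
    """Time (Ga) at which the fitted line reaches ``target_identity``.

    Used to show that the Proterozoic rate, extrapolated as constant,
    would need tens of Ga to fall to deep-paralog identity levels.
    """
    if fit.slope >= 0:
        raise NoCrossingError("non-negative slope never decays to the target")
    return (target_identity - fit.intercept) / fit.slope


def write_pair_table(pairs: Iterable[IdentityPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "label_a": p.label_a,
                "label_b": p.label_b,
                "identity": p.identity,
                "divergence_time_ga": p.divergence_time,
            }
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> list[IdentityPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        IdentityPair(r.label_a, r.label_b, float(r.identity), float(r.divergence_time_ga))
        for r in df.itertuples(index=False)
    ]
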