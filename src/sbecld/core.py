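"""Core data model for linear and branched glucans and their chain-length
distributions (CLDs).

The central objects are

:class:`ChainPopulation`
    a multiset of linear-chain degrees of polymerization (DP) with integer
    counts — the substrate and product of every branching or debranching
    operation in this package.  A population conserves total glucose
    (``sum(dp * count)``) under branching/debranching.

:class:`BranchedGlucan`
    an explicit branched molecule: linear segments joined by α-(1→6) links.
    Only the multiset of segment lengths matters for CLD analysis (the
    measured quantity is always the *debranched* product), but the full
    structure is kept so that conservation can be checked structurally.

:class:`NumberCLD` / :class:`WeightLogCLD` / :class:`DifferenceCLD`
    the measurement-side representations: the number distribution
    ``N_de(X)`` (FACE-style), the SEC weight distribution ``w(log X)``
    evaluated on a (possibly non-integer) DP grid, and a signed molar-%
    difference distribution.

Conventions
-----------
* DP values are integers >= 1 (anhydroglucose units).
* Branch attachment positions are 1-based, counted from the reducing end of
  the parent segment.  They are recorded for structural checking but never
  enter CLD analyses.
* Population and CLD files are 2-column delimited text (tab by default)
  with headers ``dp<TAB>count`` and ``dp<TAB>value``, sorted by dp.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError, StructuralError

__all__ = [
    "LinearChain",
    "ChainPopulation",
    "BranchedGlucan",
    "NumberCLD",
    "WeightLogCLD",
    "DifferenceCLD",
    "debranch",
    "to_number_cld",
    "read_population",
    "write_population",
    "read_cld",
    "write_cld",
]


@dataclass(frozen=True)
class LinearChain:
    """A linear α-(1→4) glucan chain of ``dp`` anhydroglucose units."""

    dp: int

    def __post_init__(self) -> None:
        if self.dp < 1:
            raise ParameterError(f"chain dp must be >= 1, got {self.dp}")


class ChainPopulation:
    """Multiset of linear chains, keyed by degree of polymerization.

    Parameters
    ----------
    counts
        Mapping ``dp -> count``.  Keys must be >= 1 and counts >= 0; zero
        counts are dropped.
    """

    def __init__(self, counts: Mapping[int, int] | None = None) -> None:
        self._counts: Counter[int] = Counter()
        if counts:
            for dp, c in counts.items():
                dp = int(dp)
                c = int(c)
                if dp < 1:
                    raise ParameterError(f"dp must be >= 1, got {dp}")
                if c < 0:
                    raise ParameterError(f"count must be >= 0, got {c}")
                if c:
                    self._counts[dp] += c

    # -- basic protocol ----------------------------------------------------
    @property
    def counts(self) -> dict[int, int]:
        """Counts as a plain dict sorted by dp."""
        return dict(sorted(self._counts.items()))

    def __getitem__(self, dp: int) -> int:
        return self._counts.get(dp, 0)

    def __len__(self) -> int:
        return len(self._counts)

    def __bool__(self) -> bool:
        return self.total_chains > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChainPopulation):
            return NotImplemented
        return self._counts == other._counts

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ChainPopulation(n_chains={self.total_chains}, "
            f"glucose={self.total_glucose}, "
            f"dp_range={self.dp_range()})"
        )

    # -- invariant quantities ---------------------------------------------
    @property
    def total_chains(self) -> int:
        """Number of chains, Σ count."""
        return sum(self._counts.values())

    @property
    def total_glucose(self) -> int:
        """Total anhydroglucose units, Σ dp·count (conserved by branching)."""
        return sum(dp * c for dp, c in self._counts.items())

    def dp_range(self) -> tuple[int, int] | None:
        if not self._counts:
            return None
        return min(self._counts), max(self._counts)

    def mean_dp(self) -> float:
        if not self:
            raise DegenerateInputError("mean dp of an empty population")
        return self.total_glucose / self.total_chains

    # -- construction / conversion ----------------------------------------
    @classmethod
    def from_chains(cls, dps: Iterable[int]) -> "ChainPopulation":
        return cls(Counter(int(d) for d in dps))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """``(dp, count)`` arrays sorted by dp."""
        if not self._counts:
            return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        dp = np.array(sorted(self._counts), dtype=np.int64)
        n = np.array([self._counts[d] for d in dp], dtype=np.int64)
        return dp, n

    def copy(self) -> "ChainPopulation":
        return ChainPopulation(self._counts)

    def add(self, dp: int, count: int = 1) -> None:
        if dp < 1:
            raise ParameterError(f"dp must be >= 1, got {dp}")
        self._counts[dp] += count
        if self._counts[dp] < 0:
            raise ParameterError(f"count at dp {dp} went negative")
        if self._counts[dp] == 0:
            del self._counts[dp]


@dataclass
class BranchedGlucan:
    """A branched glucan (or forest of them) as segments plus α-(1→6) links.

    ``segments[i]`` is the dp of linear segment ``i``.  Each link
    ``(child, parent, position)`` attaches the reducing end of segment
    ``child`` to ``position`` (1-based from the reducing end) of segment
    ``parent``.  The link graph must be a forest: debranching then yields
    exactly the multiset of segment lengths.
    """

    segments: list[int]
    links: list[tuple[int, int, int]] = field(default_factory=list)

    def n_molecules(self) -> int:
        self.validate()
        return len(self.segments) - len(self.links)

    def validate(self) -> None:
        n = len(self.segments)
        for i, s in enumerate(self.segments):
            if s < 1:
                raise StructuralError(f"segment {i} has dp {s} < 1")
        parent_of: dict[int, int] = {}
        for child, parent, pos in self.links:
            if not (0 <= child < n) or not (0 <= parent < n):
                raise StructuralError(f"dangling link index ({child}, {parent})")
            if child == parent:
                raise StructuralError(f"segment {child} linked to itself")
            if child in parent_of:
                raise StructuralError(f"segment {child} has two parents")
            if not (1 <= pos <= self.segments[parent]):
                raise StructuralError(
                    f"attachment position {pos} outside parent segment "
                    f"{parent} (dp {self.segments[parent]})"
                )
            parent_of[child] = parent
        # forest check: following parents from any node must terminate
        for start in parent_of:
            seen = {start}
            node = start
            while node in parent_of:
                node = parent_of[node]
                if node in seen:
                    raise StructuralError("cycle in branch link graph")
                seen.add(node)


def debranch(glucan: BranchedGlucan) -> ChainPopulation:
    """Hydrolyse all α-(1→6) links, returning the constituent linear chains.

    The in-silico analogue of exhaustive isoamylase treatment: the result is
    exactly the multiset of segment lengths.  Total glucose equals the sum
    of segment lengths and the number of chains equals the number of
    segments.

    Raises
    ------
    StructuralError
        If the link graph has a cycle, a dangling index, or an attachment
        position outside its parent segment.
    """
    glucan.validate()
    return ChainPopulation.from_chains(glucan.segments)


# ---------------------------------------------------------------------------
# CLD representations
# ---------------------------------------------------------------------------

_NUMBER_NORMS = ("none", "area", "chains100")


class NumberCLD:
    """Number chain-length distribution ``N_de(X)`` on an integer DP grid.

    ``normalization`` is one of ``'none'`` (raw counts), ``'area'``
    (sums to 1) or ``'chains100'`` (molar %, sums to 100 — the convention
    used for difference distributions).
    """

    def __init__(
        self, values: Mapping[int, float], normalization: str = "none"
    ) -> None:
        if normalization not in _NUMBER_NORMS:
            raise ParameterError(f"unknown normalization {normalization!r}")
        vals = {}
        for dp, v in values.items():
            dp = int(dp)
            v = float(v)
            if dp < 1:
                raise ParameterError(f"dp must be >= 1, got {dp}")
            if v < 0:
                raise ParameterError(f"negative value at dp {dp}")
            vals[dp] = v
        self.values: dict[int, float] = dict(sorted(vals.items()))
        self.normalization = normalization
        total = sum(self.values.values())
        if normalization == "chains100" and abs(total - 100.0) > 1e-9:
            raise ParameterError(
                f"chains100 CLD must sum to 100, got {total!r}"
            )
        if normalization == "area" and abs(total - 1.0) > 1e-9:
            raise ParameterError(f"area CLD must sum to 1, got {total!r}")

    def __getitem__(self, dp: int) -> float:
        return self.values.get(dp, 0.0)

    def __len__(self) -> int:
        return len(self.values)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        dp = np.array(list(self.values), dtype=np.int64)
        v = np.array(list(self.values.values()), dtype=float)
        return dp, v

    def total(self) -> float:
        return sum(self.values.values())

    def renormalized(self, normalization: str) -> "NumberCLD":
        """Return a copy under a different normalization convention."""
        if normalization == "none":
            return NumberCLD(self.values, "none")
        total = self.total()
        if total <= 0:
            raise DegenerateInputError("cannot normalize an all-zero CLD")
        scale = {"area": 1.0, "chains100": 100.0}[normalization] / total
        vals = {dp: v * scale for dp, v in self.values.items()}
        # enforce the sum invariant exactly against float round-off
        err = {"area": 1.0, "chains100": 100.0}[normalization] - sum(vals.values())
        if vals and err != 0.0:
            bulk = max(vals, key=vals.get)  # absorb round-off where it is relatively smallest
            vals[bulk] += err
        return NumberCLD(vals, normalization)

    def support_min(self) -> int:
        if not self.values:
            raise DegenerateInputError("empty CLD has no support")
        return min(self.values)


class WeightLogCLD:
    """SEC-style weight distribution ``w(log X)`` on a DP grid.

    ``x`` may be non-integer (an SEC elution-derived grid); ``w`` holds the
    weight distribution evaluated at ``log10(x)``.  ``normalization`` is
    ``'none'`` or ``'max1'`` (curve scaled to unit maximum, the convention
    used to overlay time courses).
    """

    def __init__(
        self,
        x: np.ndarray | Iterable[float],
        w: np.ndarray | Iterable[float],
        normalization: str = "none",
    ) -> None:
        self.x = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
        self.w = np.asarray(list(w) if not isinstance(w, np.ndarray) else w, dtype=float)
        if self.x.shape != self.w.shape:
            raise ParameterError("x and w must have equal length")
        if self.x.size and np.any(np.diff(self.x) <= 0):
            raise ParameterError("x grid must be strictly increasing")
        if np.any(self.w < -1e-12):
            raise ParameterError("weight distribution must be nonnegative")
        if normalization not in ("none", "max1"):
            raise ParameterError(f"unknown normalization {normalization!r}")
        self.normalization = normalization
        if normalization == "max1" and self.w.size and abs(self.w.max() - 1.0) > 1e-9:
            raise ParameterError("max1 distribution must have unit maximum")

    def __len__(self) -> int:
        return self.x.size

    def renormalized(self, normalization: str) -> "WeightLogCLD":
        if normalization == "none":
            return WeightLogCLD(self.x, self.w, "none")
        m = self.w.max() if self.w.size else 0.0
        if m <= 0:
            raise DegenerateInputError("cannot max-normalize an all-zero curve")
        return WeightLogCLD(self.x, self.w / m, "max1")

    def area(self) -> float:
        """Integral of ``w`` over log10(X) (trapezoid on the stored grid)."""
        if self.x.size < 2:
            return float(self.w.sum())
        return float(np.trapezoid(self.w, np.log10(self.x)))


class DifferenceCLD:
    """Signed molar-% difference distribution ΔN_de(X).

    Built by :func:`sbecld.analysis.difference_cld` from two chains100
    CLDs; its values sum to zero by construction.
    """

    def __init__(self, values: Mapping[int, float]) -> None:
        self.values: dict[int, float] = {
            int(dp): float(v) for dp, v in sorted(values.items())
        }

    def __getitem__(self, dp: int) -> float:
        return self.values.get(dp, 0.0)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        dp = np.array(list(self.values), dtype=np.int64)
        v = np.array(list(self.values.values()), dtype=float)
        return dp, v

    def total(self) -> float:
        return sum(self.values.values())


def to_number_cld(pop: ChainPopulation, normalization: str = "none") -> NumberCLD:
    """Convert a chain population to a number CLD.

    ``chains100`` normalizes total chains to 100 (the molar-% convention of
    difference distributions); ``area`` to 1; ``none`` keeps raw counts.

    Raises
    ------
    DegenerateInputError
        For an empty population with normalization other than ``'none'``.
    """
    if normalization not in _NUMBER_NORMS:
        raise ParameterError(f"unknown normalization {normalization!r}")
    raw = NumberCLD({dp: float(c) for dp, c in pop.counts.items()}, "none")
    if normalization == "none":
        return raw
    if not pop:
        raise DegenerateInputError(
            f"cannot {normalization}-normalize an empty population"
        )
    return raw.renormalized(normalization)


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------


def write_population(pop: ChainPopulation, path: str | Path, sep: str = "\t") -> None:
    dp, n = pop.as_arrays()
    pd.DataFrame({"dp": dp, "count": n}).to_csv(path, sep=sep, index=False)


def read_population(path: str | Path, sep: str = "\t") -> ChainPopulation:
    df = pd.read_csv(path, sep=sep)
    if list(df.columns[:2]) != ["dp", "count"]:
        raise ParameterError(
            f"population file must have columns dp,count; got {list(df.columns)}"
        )
    return ChainPopulation(dict(zip(df["dp"].astype(int), df["count"].astype(int))))


def write_cld(cld: NumberCLD | DifferenceCLD, path: str | Path, sep: str = "\t") -> None:
    dp, v = cld.as_arrays()
    pd.DataFrame({"dp": dp, "value": v}).to_csv(path, sep=sep, index=False)


def read_cld(path: str | Path, sep: str = "\t", normalization: str = "none") -> NumberCLD:
    df = pd.read_csv(path, sep=sep)
    if list(df.columns[:2]) != ["dp", "value"]:
        raise ParameterError(
            f"CLD file must have columns dp,value; got {list(df.columns)}"
        )
    return NumberCLD(dict(zip(df["dp"].astype(int), df["value"])), normalization)
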