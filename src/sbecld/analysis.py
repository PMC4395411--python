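"""Derived CLD statistics: number↔weight transforms, difference
distributions, enzyme-activity arithmetic, minima and peak detection.

The two measurement channels give complementary views of a debranched
population.  FACE counts labelled reducing ends, so it reports the number
distribution ``N_de(X)``; an SEC refractive-index detector reports the
weight distribution on a logarithmic size axis, ``w(log X)``.  For a
distribution over DP ``X`` the two are related by

    w(log X) ∝ X² · N_de(X)

(one factor of X for mass-weighting, one for the d(log X) measure).

Difference distributions ΔN_de(X) compare a branching product against its
substrate with both normalized to 100 total chains (molar %), so Δ sums to
zero and positive values mark chain lengths enriched by the enzyme.

Specific activity follows the unit-U definition: nmol of new branches per
minute per mg enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import DifferenceCLD, NumberCLD, WeightLogCLD
from .errors import DataError, DegenerateInputError, ParameterError

__all__ = [
    "ActivityRecord",
    "number_to_weight_log",
    "weight_log_to_number",
    "difference_cld",
    "specific_activity",
    "activity_percent",
    "min_detected_dp",
    "detect_peaks",
    "mean_dp",
]


@dataclass(frozen=True)
class ActivityRecord:
    """One specific-activity determination.

    ``u = new_branches / (time × enzyme_mass)`` in nmol·min⁻¹·mg⁻¹.
    """

    u: float
    new_branches: float
    time: float
    enzyme_mass: float


def number_to_weight_log(n: NumberCLD, normalization: str = "none") -> WeightLogCLD:
    """Transform a number CLD to the SEC weight distribution w(log X).

    ``w(X) = X² · N_de(X)`` on the same DP grid; pass
    ``normalization='max1'`` for the unit-maximum convention used to
    overlay SEC time courses.
    """
    if not len(n):
        raise DegenerateInputError("cannot transform an empty CLD")
    dp, v = n.as_arrays()
    w = WeightLogCLD(dp.astype(float), (dp.astype(float) ** 2) * v, "none")
    return w.renormalized(normalization) if normalization != "none" else w


def weight_log_to_number(w: WeightLogCLD, normalization: str = "none") -> NumberCLD:
    """Invert the weight transform: ``N_de(X) ∝ w(log X) / X²``.

    Only meaningful on an integer DP grid (exact round trip with
    :func:`number_to_weight_log`); SEC grids should be interpolated to
    integer DP first.
    """
    if not len(w):
        raise DegenerateInputError("cannot invert an empty distribution")
    dp = np.rint(w.x).astype(int)
    if np.any(np.abs(w.x - dp) > 1e-9):
        raise ParameterError("weight distribution is not on an integer DP grid")
    vals = {int(d): float(val) / float(d) ** 2 for d, val in zip(dp, w.w)}
    out = NumberCLD(vals, "none")
    return out.renormalized(normalization) if normalization != "none" else out


def difference_cld(product: NumberCLD, substrate: NumberCLD) -> DifferenceCLD:
    """Molar-% difference distribution, product minus substrate.

    Both inputs are normalized to 100 total chains, then subtracted dp-wise
    over the union of their supports; the result sums to zero (up to float
    round-off absorbed in the normalization).
    """
    if not len(product) or not len(substrate):
        raise DegenerateInputError("difference CLD needs two non-empty CLDs")
    p = product.renormalized("chains100")
    s = substrate.renormalized("chains100")
    support = sorted(set(p.values) | set(s.values))
    return DifferenceCLD({dp: p[dp] - s[dp] for dp in support})


def specific_activity(
    n0_chains_nmol: float,
    n1_chains_nmol: float,
    time_min: float,
    enzyme_mg: float,
) -> ActivityRecord:
    """Specific activity from total chain counts before and after reaction.

    ``u = (n1 − n0) / (time × mass)`` — the unit-U definition (nmol of new
    branches per minute per mg enzyme); each new branch corresponds to one
    new chain in the debranched product.
    """
    if time_min <= 0 or enzyme_mg <= 0:
        raise ParameterError("time and enzyme mass must be positive")
    if n1_chains_nmol < n0_chains_nmol:
        raise DataError(
            f"chain count decreased ({n0_chains_nmol} -> {n1_chains_nmol}); "
            "branching cannot remove chains"
        )
    delta = n1_chains_nmol - n0_chains_nmol
    return ActivityRecord(
        u=delta / (time_min * enzyme_mg),
        new_branches=delta,
        time=time_min,
        enzyme_mass=enzyme_mg,
    )


def activity_percent(mutant_u: float, wt_u: float) -> float:
    """Mutant activity as a percentage of wild type, ``100 · mutant / WT``."""
    if wt_u == 0:
        raise ParameterError("wild-type activity is zero; percentage undefined")
    return 100.0 * mutant_u / wt_u


def min_detected_dp(n: NumberCLD, threshold_fraction: float = 0.0) -> int:
    """Smallest DP whose value exceeds ``threshold_fraction × max value``.

    With the default threshold 0 this is the detection minimum — e.g. DP 6
    for wild-type SBEIIa products, DP ≤ 5 for the relaxed R456K mutant.
    """
    if not len(n):
        raise DegenerateInputError("empty CLD")
    _, v = n.as_arrays()
    vmax = v.max()
    if vmax <= 0:
        raise DegenerateInputError("all-zero CLD")
    for dp, val in n.values.items():
        if val > threshold_fraction * vmax:
            return dp
    raise DegenerateInputError("no value exceeds the detection threshold")


def detect_peaks(w: WeightLogCLD, min_prominence: float = 0.05) -> list[int]:
    """DP locations of local maxima of a weight distribution.

    Prominence is measured on the max-normalized curve (SEC overlays are
    conventionally scaled to unit maximum), on the log10(X) grid the curve
    is stored on.  Returns rounded DP values sorted ascending; an empty
    list for monotone curves.
    """
    if not len(w):
        raise DegenerateInputError("empty weight distribution")
    y = w.w
    m = y.max()
    if m <= 0:
        return []
    idx, _ = find_peaks(y / m, prominence=min_prominence)
    return sorted(int(round(w.x[i])) for i in idx)


def mean_dp(n: NumberCLD) -> float:
    """Number-average DP, Σ X·N(X) / Σ N(X) (normalization-invariant)."""
    if not len(n):
        raise DegenerateInputError("empty CLD")
    dp, v = n.as_arrays()
    tot = v.sum()
    if tot <= 0:
        raise DegenerateInputError("all-zero CLD")
    return float((dp * v).sum() / tot)
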