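"""Synthetic substrates and emulated measurement channels.

Every downstream stage of the package is testable without laboratory data:
this module generates the two substrate types used in the in-vitro
branching experiments and emulates the two CLD measurement channels.

Substrates
----------
* linear "debranched potato amylose" — long linear α-(1→4) glucans with a
  number-average DP near 500, modelled as a discretized log-normal with a
  configurable coefficient of variation (broad, unimodal, as SEC traces of
  debranched amylose are);
* an amylopectin-like branched substrate — chain lengths sampled from the
  steady-state biosynthesis model, standing in for a commercial maize
  amylopectin whose true CLD is only available as a figure.  Explicitly
  synthetic, not a digitization.

Measurements
------------
* FACE — exact counting of labelled chains up to a truncation DP
  (~160 for the real instrument) plus multinomial sampling noise; reports
  the number distribution normalized to 100 chains.
* SEC — the weight transform w(log X) = X²·N(X) convolved with a Gaussian
  band-broadening kernel on the log10(X) axis (area-preserving), plus
  optional additive detector noise.

Both measurements are pure: they never modify the population, and are
bit-reproducible given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .biosynthesis import EnzymeSetParams, Propensity, DEFAULT_PROPENSITY, steady_state_cld
from .core import ChainPopulation, NumberCLD, WeightLogCLD, to_number_cld
from .analysis import number_to_weight_log
from .errors import DegenerateInputError, ParameterError

__all__ = [
    "SubstrateSpec",
    "InstrumentSpec",
    "make_linear_substrate",
    "make_amylopectin_substrate",
    "face_measure",
    "sec_measure",
]


@dataclass(frozen=True)
class SubstrateSpec:
    """Recipe for a synthetic substrate population.

    ``dispersion`` is the coefficient of variation of the chain-length
    distribution (default 0.5, a broad unimodal amylose-like spread).
    """

    kind: str = "linear_amylose"
    n_chains: int = 10_000
    mean_dp: float = 500.0
    dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("linear_amylose", "amylopectin_like"):
            raise ParameterError(f"unknown substrate kind {self.kind!r}")
        if self.n_chains < 0:
            raise ParameterError("n_chains must be >= 0")
        if self.mean_dp < 1:
            raise ParameterError("mean_dp must be >= 1")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")


@dataclass(frozen=True)
class InstrumentSpec:
    """Measurement-channel parameters.

    ``face_max_dp`` — FACE truncation DP (the technique resolves up to
    roughly DP 160); ``face_sampling_n`` — number of labelled chains
    counted (``None`` for exact counting); ``sec_band_sigma`` — SEC band
    broadening as a Gaussian sd on the log10(X) axis; ``noise_scale`` —
    additive detector noise as a fraction of the curve maximum.
    """

    face_max_dp: int = 160
    face_sampling_n: int | None = 100_000
    sec_band_sigma: float = 0.05
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.face_max_dp < 1:
            raise ParameterError("face_max_dp must be >= 1")
        if self.face_sampling_n is not None and self.face_sampling_n < 1:
            raise ParameterError("face_sampling_n must be >= 1 or None")
        if self.sec_band_sigma < 0:
            raise ParameterError("sec_band_sigma must be >= 0")
        if self.noise_scale < 0:
            raise ParameterError("noise_scale must be >= 0")


def make_linear_substrate(spec: SubstrateSpec) -> ChainPopulation:
    """Sample a linear-amylose-like population of long chains.

    Chain lengths follow a log-normal with mean ``mean_dp`` and coefficient
    of variation ``dispersion``, rounded to integers and truncated at
    DP >= 1.  Deterministic given the spec (including its seed);
    ``n_chains = 0`` yields an empty population.
    """
    if spec.kind != "linear_amylose":
        raise ParameterError("make_linear_substrate requires kind='linear_amylose'")
    if spec.n_chains == 0:
        return ChainPopulation()
    rng = np.random.default_rng(spec.seed)
    if spec.dispersion == 0:
        dps = np.full(spec.n_chains, int(round(spec.mean_dp)))
    else:
        sigma2 = np.log1p(spec.dispersion**2)
        mu = np.log(spec.mean_dp) - sigma2 / 2.0
        dps = np.rint(rng.lognormal(mu, np.sqrt(sigma2), spec.n_chains)).astype(int)
    dps = np.maximum(dps, 1)
    return ChainPopulation.from_chains(dps)


def make_amylopectin_substrate(
    enzyme_sets: EnzymeSetParams | Sequence[EnzymeSetParams],
    n_chains: int,
    seed: int = 0,
    *,
    propensity: Propensity = DEFAULT_PROPENSITY,
    x_max: int = 120,
) -> ChainPopulation:
    """Sample an amylopectin-like population from the biosynthesis model.

    The model CLD (mixture over the given enzyme sets, weighted by their
    ``weight`` fields) is sampled multinomially, so the empirical CLD
    converges to the model CLD as ``n_chains`` grows.  Deterministic given
    the seed.
    """
    if n_chains < 0:
        raise ParameterError("n_chains must be >= 0")
    if n_chains == 0:
        return ChainPopulation()
    sets = [enzyme_sets] if isinstance(enzyme_sets, EnzymeSetParams) else list(enzyme_sets)
    if not sets:
        raise ParameterError("at least one enzyme set is required")
    from .biosynthesis import combine_sets  # local to avoid cycle at import

    solutions = [
        steady_state_cld(p, x_max=x_max, propensity=propensity) for p in sets
    ]
    mixture = combine_sets(solutions, [p.weight for p in sets])
    dp, v = mixture.as_arrays()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_chains, v / v.sum())
    return ChainPopulation(
        {int(d): int(c) for d, c in zip(dp, counts) if c > 0}
    )


def face_measure(pop: ChainPopulation, instrument: InstrumentSpec) -> NumberCLD:
    """Emulate FACE: exact number CLD up to the truncation DP, with
    multinomial sampling noise, normalized to 100 chains over the observed
    support.

    Raises
    ------
    DegenerateInputError
        If the population is empty or every chain is above the truncation.
    """
    if not pop:
        raise DegenerateInputError("cannot measure an empty population")
    dp, n = pop.as_arrays()
    keep = dp <= instrument.face_max_dp
    dp, n = dp[keep], n[keep]
    if dp.size == 0 or n.sum() == 0:
        raise DegenerateInputError(
            f"no chains at or below the FACE truncation DP {instrument.face_max_dp}"
        )
    if instrument.face_sampling_n is None:
        observed = n.astype(float)
    else:
        rng = np.random.default_rng(instrument.seed)
        p = n / n.sum()
        observed = rng.multinomial(instrument.face_sampling_n, p).astype(float)
    raw = NumberCLD(
        {int(d): float(c) for d, c in zip(dp, observed) if c > 0}, "none"
    )
    return raw.renormalized("chains100")


def sec_measure(
    pop: ChainPopulation,
    instrument: InstrumentSpec,
    *,
    grid_points_per_sigma: int = 8,
    pad_sigmas: float = 6.0,
) -> WeightLogCLD:
    """Emulate SEC: weight transform plus Gaussian band broadening on the
    log10(X) axis and optional additive detector noise.

    With ``sec_band_sigma == 0`` and no noise this returns exactly
    ``number_to_weight_log`` of the population.  The broadened curve is
    evaluated on a uniform log10(X) grid fine enough that its trapezoid
    area matches the unbroadened area to better than 1e-6 (the Gaussian
    kernel integrates to one on the log axis).
    """
    if not pop:
        raise DegenerateInputError("cannot measure an empty population")
    sigma = instrument.sec_band_sigma
    exact = number_to_weight_log(to_number_cld(pop, "none"))
    if sigma == 0:
        w = exact.w.copy()
        if instrument.noise_scale > 0:
            rng = np.random.default_rng(instrument.seed)
            w = w + rng.normal(0.0, instrument.noise_scale * w.max(), w.size)
            w = np.maximum(w, 0.0)
        return WeightLogCLD(exact.x, w)

    logx = np.log10(exact.x)
    lo = logx.min() - pad_sigmas * sigma
    hi = logx.max() + pad_sigmas * sigma
    n_grid = max(64, int(np.ceil((hi - lo) / (sigma / grid_points_per_sigma))) + 1)
    u = np.linspace(lo, hi, n_grid)
    # point-mass convolution: each dp contributes mass X^2 * count
    w = np.zeros_like(u)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for m, c in zip(exact.w, logx):
        w += m * norm * np.exp(-0.5 * ((u - c) / sigma) ** 2)
    if instrument.noise_scale > 0:
        rng = np.random.default_rng(instrument.seed)
        w = w + rng.normal(0.0, instrument.noise_scale * w.max(), w.size)
        w = np.maximum(w, 0.0)
    return WeightLogCLD(10.0**u, w)
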