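# Methods

## The branching reaction and its constraints

A starch-branching enzyme (SBE) cleaves an internal α-(1→4) bond of a donor
chain and transfers the released fragment to an acceptor through a new
α-(1→6) bond. The package models the enzyme's specificity with three
integers:

| parameter | meaning | WT default |
|---|---|---|
| `x_min` | minimum DP of the transferred fragment | 6 |
| `x_0` | minimum DP of the residual fragment | 6 |
| `min_donor_dp` | donor-eligibility floor (binding-subsite count) | `x_min + x_0` = 12 |

A donor of length *X* therefore has `max(0, X − x_min − x_0 + 1)` eligible
cut positions, and is ineligible below `min_donor_dp`. The R456K mutant is
modelled with relaxed fragment minima (2, 2) under the unchanged donor floor
of 12: the subsite count is retained, only the cut position varies more.
Everything downstream sees only the *debranched* view — a multiset of chain
lengths — because branch positions never survive debranching; the simulator
can nevertheless maintain the explicit branched structure (segments plus
1-based attachment positions counted from the reducing end) so that tests
can verify that debranching the structure reproduces the population ledger,
and that the debranched CLD is invariant to inter- versus intra-chain
transfer.

### Cut-position kernels

The cut kernel weights the transferred length over its eligible range.
Two kernels ship with the package:

- `uniform_kernel` — every eligible cut equally likely (the default and the
  R456K emulation, matching its broad DP 2–5 product range);
- `geometric_kernel(decay=0.45)` — geometric preference for the shortest
  eligible transfer, used for the wild type so that the modal transferred
  length is DP 6 with DP 7 second. The decay value is an emulation knob
  chosen to produce that preference order, not a measured constant.

The kernel is data (an argument), not hard-coded truth; a user-supplied
mixture kernel can emulate multi-site behaviour. The uniform-kernel R456K
preset reproduces the appearance of DP 2–5 products but places the largest
enrichment at DP 2 rather than DP 6; reproducing a residual DP-6 preference
would need a structured kernel for which there is no parameterization, so
this is left as a documented limitation.

### In-vitro time stepping

No reaction rate depends on time between samples, so time advances in
sampled intervals with Poisson event counts rather than a full event-time
simulation: the expected number of cleavages over an interval is
`specific_activity × enzyme_mass × Δt × population_scale × events_per_nmol`,
with the Poisson draw per interval (or the rounded expectation in the
deterministic variant used for exact-arithmetic checks). Each event selects
a donor with probability proportional to its eligible-site count (an enzyme
encountering internal bonds at random; per-chain selection is available as
`donor_selection="chain"` for sensitivity checks), applies the kernel,
removes the donor and adds both fragments. Glucose is conserved exactly and
`chains(t) − chains(0)` equals the cumulative event count exactly. When
eligible donors run out the trace is flagged `saturated`.

The nmol↔event scale is explicit: one simulated event is one new branch;
`events_per_nmol` (default 1) maps physical nmol to simulated counts so a
small simulated population can stand in for a physical reaction
(`population_scale` carries the fraction simulated).

## Measurement emulation

**FACE** counts fluorophore-labelled reducing ends, so it measures the
number distribution N_de(X) accurately but only up to a truncation
(default DP 160). It is emulated as exact counting over the truncated
support plus multinomial sampling noise (`face_sampling_n` labelled chains;
`None` for exact counting), normalized to 100 chains. No labelling-
efficiency bias is modelled.

**SEC** with a refractive-index detector measures the weight distribution
on a logarithmic size axis, w(log X) = X²·N_de(X) (one factor of X for
mass-weighting, one for the d(log X) measure; the transform exponent is
fixed at 2). Band broadening is a Gaussian kernel on the log10 X axis
(default σ = 0.05) applied as an exact point-mass convolution on a uniform
log grid (σ/8 spacing, ±6σ padding), which preserves area to better than
1e-6; detector noise is additive Gaussian (default off). Only forward
broadening is modelled — no deconvolution.

**Universal calibration** maps SEC elution volume to molar mass through the
hydrodynamic-volume proxy K·M^(1+α) with the Mark–Houwink pair for
DMSO/LiBr at 80 °C (K = 2.424e-4 dL/g, α = 0.68). The calibration curve is
a least-squares polynomial (default degree 3) in Ve, required to be
strictly decreasing over the fitted range; DP = M / 162.2 (anhydroglucose
residue mass; neglecting chain-end water costs <0.2 % above DP 60, ~5 % at
DP 2). One Mark–Houwink pair is applied to standards and samples — both are
α-glucans in the same eluent — so K cancels exactly in the round trip
(asserted numerically in the tests). Pullulan elution volumes are
instrument-specific, so calibration is exercised on synthetic standards
generated from a known column law.

## The steady-state enzyme-set model

In the growing granule, chains elongate (starch synthase) and branch (SBE)
concurrently. The model keeps exactly these two reactions on the chain
population:

- elongation: every chain X → X+1 at rate 1 (the time unit);
- branching: a chain with X ≥ S is cleaved into residual R (uniform on
  [x_0, X − x_min]) and transferred X − R, both of which count as chains.

Each branching event adds net one chain, so the population grows
exponentially and the measured CLD is the self-similar shape n(X): the
leading eigenvector of the linear generator, with growth rate g its
eigenvalue. By construction g equals the population-averaged branching
propensity at the converged shape; the solver reports the gap in this
identity as a self-consistency diagnostic (≤1e-8 in the tests).

### Branching propensity: a genuinely open discretization

How the per-chain cleavage rate scales with chain length is not fixed by
the reaction scheme, so the solver and the stochastic oracle both support
three conventions:

| convention | rate for a chain of length X ≥ S | reading |
|---|---|---|
| `random_bond` (default) | β·(X−S+1)/X | the enzyme engages a chain at rate β and attacks a random glucose position; the cut succeeds only if both fragments satisfy the minima |
| `per_chain` | β | one encounter per chain regardless of length |
| `per_site` | β·(X−S+1) | every eligible bond is an independent target |

`random_bond` is the default because it is the direct mechanistic reading
of "cleaves an internal α-(1→4) linkage" with the constraints acting as a
filter, and because it is the convention whose Variation-A scan reproduces
the documented behaviour of the long-chain tail: the DP>13 content relative
to the reference reaches its maximum, 110 %, at the most asymmetric
constraint split (the per-chain convention gives 124 % there). All three
conventions satisfy the structural invariants (solver–oracle agreement,
constraint compliance, β monotonicity), and the convention is an explicit
argument everywhere.

**Known limitation — the location of the CLD maximum.** Experimentally
characterized amylopectin CLDs, and enzyme-set analyses of them, place the
global maximum at the subsite sum S (DP 13 for the reference set, stable as
the split between the minima varies). The two-reaction model here places
its maximum 1–3 DP below S (DP 10 at the reference parameters, DP 10–12
across the Variation-A scan) under every propensity convention: with β of
order 1, donors barely overshoot S before being cleaved, so fragment births
concentrate just above the two minima and the exponential growth factor
tilts the shape toward them. Reproducing a maximum pinned exactly at S at
β = 1.4 appears to require model structure beyond these two reactions
(e.g. debranching-enzyme trimming of short branches, or a different
normalization of β against synthase activity), which is out of scope here.
The acceptance suite states the at-S expectation and the discrepancy is
reported, not absorbed: the scan's full mode table is emitted alongside the
headline value.

### Solver and oracle

The solver builds the dense generator on DP 1..x_max (default 120;
elongation out of the boundary is absorbing) and runs power iteration on
the shifted matrix A + cI with c making it nonnegative, normalizing each
step, until the L1 change per iteration is below the tolerance (default
1e-10); it errors if more than 1e-6 of the mass sits at the truncation
boundary. The oracle is the exact embedded jump chain of the same two
reactions, implemented by uniformization: a uniform chain draw plus a
thinning acceptance reproduces the length-dependent propensities exactly,
so only O(1) work per event is needed (numba-compiled). Both routes agree
to total-variation distance <0.005 at 2×10⁵ chains across the test grid
β ∈ {0.7, 1.4, 2.8} × (x_min, x_0) ∈ {(6,6), (6,7), (2,11)} — well inside
the 0.05 acceptance band.

β fitting minimizes the sum of squared molar-% differences over DP 1–30
(the range FACE resolves reliably for amylopectin) with a bounded scalar
search (tolerance 1e-8); probes whose CLD would spill past x_max are
penalized rather than crashing the search. Fitting the model to its own
noiseless output recovers β = 1.4 to <1e-9; under multinomial sampling
noise at 1e5 chains it recovers β within 0.1. Mixtures of enzyme sets are
supported through `combine_sets` (weighted molar-% sum, renormalized);
all scan anchors use a single set.

## Synthetic substrates

- **Linear amylose-like**: discretized log-normal chain lengths, mean DP
  500, coefficient of variation 0.5 (broad and unimodal, as debranched
  amylose distributions are), truncated at DP ≥ 1. The mean and CV are the
  only anchored facts; the log-normal shape is a documented, swappable
  choice.
- **Amylopectin-like**: multinomial samples from the steady-state model CLD
  at the reference parameters (β = 1.4, x_min = 6, x_0 = 7). Explicitly a
  synthetic stand-in — the commercial amylopectin it emulates is
  characterized only graphically — so tests against it validate the
  package's internal consistency (constraint minima, difference-pattern
  signs, normalization identities), not agreement with any real substrate.
  In particular its mode sits at DP 10 (see the limitation above) where a
  real amylopectin's is nearer 12–13, which slightly shifts where the
  WT difference distribution crosses zero: enrichment is asserted to be
  contiguous from DP 6 and confined to DP ≤ 11, not to fill DP 6–11
  exactly.

All generators and measurements are bit-reproducible given their spec and
seed, and measurements never mutate the population.

## Numerical and interface choices

- Populations are integer multisets; conservation checks are exact integer
  identities, not tolerances.
- chains100/area normalizations force their sum invariant exactly by
  absorbing float round-off into the largest bin.
- Peak detection runs on the max-normalized curve (SEC overlay convention)
  with relative prominence 0.05 by default, via standard peak finding on
  the stored log-grid.
- Degenerate inputs (empty populations, all-zero CLDs, everything above the
  FACE truncation) raise typed errors rather than returning NaNs.
- File formats are two-column delimited text (`dp/count`, `dp/value`,
  `molar_mass/elution_volume_mL`) with headers, sorted by dp.
- Pipeline runs write a manifest (resolved config, package version, output
  checksums); identical (config, seed) runs are byte-identical. Enzyme
  presets are a YAML data file, not constants in code; the Y352F/E513D
  activities are nominal 1 %-of-WT placeholders flagged `unanchored` (their
  true residual activities are below the assay's resolution).

## Problem sizes

The test suite and the reproduction script use: 10³–10⁴ chains for
in-vitro simulations (≥10⁴ cleavage events for constraint-minimum checks),
2×10⁵ chains for solver–oracle comparisons, 10⁵ labelled chains for FACE
sampling, and x_max = 120–240 for the eigen-solver. These sizes put
sampling error well below every asserted tolerance while keeping the full
suite under a minute of compute.
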