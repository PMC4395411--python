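# sbecld

Chain-length-distribution (CLD) analysis and simulation for starch-branching
enzymes (SBEs), built around maize SBEIIa and its single-residue mutants.

Starch-branching enzyme cleaves an internal α-(1→4) linkage of a donor glucan
and re-attaches the released fragment through an α-(1→6) bond, creating a new
branch. Two chain-length constraints govern the reaction: the transferred
segment must be at least *X*<sub>min</sub> glucose units and the residual
segment at least *X*<sub>0</sub>, so the shortest cleavable donor has
DP *S* = *X*<sub>min</sub> + *X*<sub>0</sub> (the enzyme's essential
binding-subsite count). For wild-type maize SBEIIa both minima are 6: the
shortest product chain is DP 6 and the shortest croppable donor is DP 12.
Mutants can change the activity (R363K, Y352F, E513D, S349F) or relax the
fragment minima while keeping the subsite count (R456K: minima 2 under an
unchanged donor floor of 12).

The package provides, as a plain Python library plus a thin CLI:

- **`sbecld.core`** — glucan data model: chain populations (multisets of DP),
  explicit branched molecules, debranching, CLD containers and delimited-text
  IO. Glucose is conserved exactly through every branching/debranching step.
- **`sbecld.branching`** — a stochastic event simulator of in-vitro SBE
  action under (*X*<sub>min</sub>, *X*<sub>0</sub>) constraints, with
  configurable cut-position kernels and physical activity bookkeeping in
  nmol·min⁻¹·mg⁻¹ (unit U).
- **`sbecld.synthetic`** — synthetic substrates (linear amylose-like chains,
  amylopectin-like populations drawn from the biosynthesis model) and the two
  emulated measurement channels: FACE (number CLD, truncated near DP 160) and
  SEC (weight distribution *w*(log *X*) with Gaussian band broadening).
- **`sbecld.analysis`** — the derived statistics: *w*(log *X*) = *X*²·
  *N*<sub>de</sub>(*X*) transforms, molar-% difference distributions
  Δ*N*<sub>de</sub>(*X*), specific-activity arithmetic, detection minima and
  peak finding.
- **`sbecld.calibration`** — SEC universal calibration from pullulan
  standards via the Mark–Houwink equation (*K* = 2.424×10⁻⁴ dL/g, α = 0.68
  for DMSO/LiBr at 80 °C), converting elution volume to molar mass and DP.
- **`sbecld.biosynthesis`** — a steady-state enzyme-set model of the
  amylopectin CLD: chains elongate at rate 1 and branch with propensity set
  by β (the branching:synthase activity ratio) under the chain-length
  constraints; the CLD is the leading eigenvector of the growth dynamics.
  Includes an exact Gillespie oracle, β fitting, and the
  *X*<sub>min</sub>-variation scans.
- **`sbecld.pipeline` / `sbecld.cli`** — config-driven, manifest-logged
  end-to-end runs (`sbecld run-experiment`, `sbecld predict-cld`, …).

## Worked example

Predicting the amylopectin CLD for the reference enzyme set
(β = 1.4, *X*<sub>min</sub> = 6, *X*<sub>0</sub> = 7) and scanning the
constraint split (`python examples/04_predict_amylopectin_cld.py`):

```
reference CLD: mode DP 10, growth rate g = 0.0880, DP>13 tail 23.9 molar %
stochastic oracle agrees: total-variation distance 0.0044 at 2e5 chains
beta refit from the model's own CLD: 1.4000 (SSE 1.2e-16)
Variation A (beta 1.4) and B (beta 0.7), X_min + X_0 = 13:
  x_min x_0 | mode_A tail>13_A ratio_A% | mode_B tail>13_B
      2  11 |    12    26.29    110.0 |    13    39.45
      ...
      6   7 |    10    23.89    100.0 |    11    37.96
      ...
     11   2 |    12    26.29    110.0 |    13    39.45
```

The growth rate *g* is the eigenvalue of the self-similar growth dynamics
(chains added per unit time per chain); the master-equation solution and an
independent exact stochastic simulation agree to a total-variation distance
of 0.004. Halving β (Variation B) raises the long-chain (DP > 13) content at
every scan point — weaker branching leaves longer chains — and the
long-chain content relative to the reference peaks at 110 % where the split
between the two minima is most asymmetric.

The activity assay round trip (`python examples/05_activity_assay.py`)
simulates one hour of branching at 34.3 nmol·min⁻¹·mg⁻¹ and recovers the
activity from the chain-count increase via the unit-U definition:

```
simulated 103115 cleavage events = 2062 nmol of new branches in 60 min
recovered specific activity: 34.37 nmol/min/mg (input was 34.30)
mutant activities as % of wild type (34.3 nmol/min/mg):
  R363K: 55.4%
  R456K: 27.7%
```

The other examples cover in-vitro branching time courses
(`01_invitro_branching.py`), FACE difference patterns for WT vs R456K
(`02_face_difference_patterns.py`) and SEC universal calibration
(`03_sec_calibration.py`).

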