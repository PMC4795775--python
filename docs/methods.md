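# Methods

## The labeling model

The model tracks, for every carbon of every amino-acid precursor, which
*source* it came from: a light hexose unit, a heavy hexose unit, or air CO₂.
Cells consume hexose molecules that are wholly light (probability *u*, the
light-sugar usage fraction) or wholly heavy (1 − *u*, up to tracer purity,
which is handled later by the measurement operator). Because the tracers are
uniformly labeled, all carbons inherited from one hexose molecule are
perfectly correlated — only the partition of a fragment's carbons into
independent source units matters, plus the branch structure of the network.

Precursors and their carbon counts: triose phosphates (3PG/PEP/pyruvate,
3 C, one hexose half each), acetyl-CoA (2 C, from one triose unit),
oxaloacetate (4 C), α-ketoglutarate (5 C), erythrose-4-phosphate (4 C) and a
one-carbon CO₂ pool. Four branch fractions, each in [0, 1], are the free
biochemical parameters:

| parameter | meaning | reference value |
|---|---|---|
| `ap` | anaplerotic (pyruvate + CO₂) vs TCA-turnover origin of OAA | 0.9 |
| `rev` | reverse (reductive, OAA + CO₂) vs forward (OAA + AcCoA) origin of AKG | 0.5 |
| `ppp` | oxidative (one unit) vs non-oxidative (2+2 units) origin of E4P | 0.5 |
| `co2` | air (unlabeled) vs recaptured (decarboxylation-donor) CO₂ | 0.1 |

The reference values are the ones used for all theory illustrations and
synthetic defaults; fits treat all four (plus *u*, per state) as free.

Atom mappings follow canonical biochemistry. Forward TCA:
AKG(C1…C5) = (OAA C4, OAA C3, OAA C2, AcCoA C2, AcCoA C1), with OAA C1
released at isocitrate dehydrogenase. Turnover: AKG loses C1 and its
remaining four carbons become OAA via succinate/fumarate, whose rotational
symmetry averages every pattern with its reversal; the same scrambling is
applied on the reverse (reductive) arc OAA → succinate → AKG, since that
path also traverses fumarate. Recaptured CO₂ carries the label of a
decarboxylation donor, modeled as a fresh triose-unit draw (heavy with
probability 1 − *u*); this avoids a circular dependence of the CO₂ pool on
the TCA intermediates and is accurate to the extent that pyruvate-level
decarboxylations dominate. Air CO₂ is a third label that weighs like a
light carbon; it is tracked separately so that fragments exposed to
anaplerotic CO₂ can be excluded from shift analyses.

The mutual dependence OAA ← AKG ← OAA is resolved as the stationary point
of the linear isotopomer balance over all 3⁴ = 81 OAA and 3⁵ = 243 AKG
positional patterns, with successive turns treated as independent (the
standard stationary-isotopomer assumption). Because the one-turn kernel is
column-stochastic, the balance is an affine system solved directly
(`numpy.linalg.solve`); `ap` is floored at 1e-9, which reproduces the
`ap → 0` limit (turnover memory of the anaplerotic entry composition)
without the slow mixing an iterative scheme faces near `rev = 1`. An
explicit truncated-history iteration is retained as an independent oracle
in the tests, and a Monte-Carlo simulator of the same generative rules
(`isopop.montecarlo`) validates the solver at random parameter points.

Amino-acid maps (config-overridable): Ala/Ser = one triose; Gly = triose
C1–C2; Val = 2 pyruvate − CO₂; Leu = AcCoA + 2 pyruvate − 2 CO₂;
Ile = OAA + pyruvate − CO₂; Thr/Asp/Asn/Met-backbone = OAA;
Glu/Gln/Pro = AKG; Arg = AKG + CO₂; Lys = pyruvate + OAA − CO₂
(diaminopimelate stoichiometry — a simplification: budding yeast actually
uses the α-aminoadipate route; the map is kept at the
pyruvate + OAA default for continuity with the simplified network and can
be overridden); Phe/Tyr = 2 PEP + E4P − CO₂. The methionine methyl carbon
(C1 metabolism) is not modeled and no default-panel fragment contains it.

## Measurement operator

GC-MS observes the derivatized ion, not the bare carbon skeleton. For each
fragment, a linear operator maps the number of heavy *source* carbons to
the observed MID: a binomial purity factor on the heavy carbons (each stays
¹³C with probability 0.99, the purity of commercial [U-¹³C]glucose), a
binomial natural-abundance factor on the light carbons (¹³C 0.0107), and
the exact multinomial isotope pattern of all non-source atoms (H, N, O, S,
Si and derivatization carbons, IUPAC abundances; ²⁹Si 0.04685 and ³⁰Si
0.03092 dominate because every TBDMS group contributes one silicon).
Columns are truncated to the fragment's channel window and renormalized.

The default window is **source carbons + 2** mass channels beyond M+0. The
+2 tail covers the ²⁹Si/³⁰Si/³⁴S isotopes, which carry essentially all
non-source isotope mass; further channels hold < 10⁻³ abundance and no
information, and padding vectors with jointly-near-zero channels was found
to dominate (and spuriously inflate) concatenated-channel correlation
statistics.

The default panel holds 29 fragments — [M−57] (all carbons) and [M−159]
(loses C1) for Ala, Gly, Val, Leu, Ile, Pro, Ser, Thr, Phe, Asp, Glu, Tyr,
Lys, plus [M−85] for Val and Asp and [M−57] for Arg — chosen for ease of
modeling, reproducibility and lack of interfering species, with elemental
formulas derived from the amino-acid composition and TBDMS count. Two
flags are computed from the carbon maps: *single-unit* fragments (all
retained carbons from one triose/AcCoA unit: the Ala, Gly, Ser fragments),
which are identical under one- and two-state models and therefore carry no
deconvolution signal; and the 8-fragment *shift subset* (Val m57/m85/m159,
Leu m57/m159, Phe m57/m159, Tyr m57) — multi-unit fragments never
inheriting a CO₂-pool carbon — used for intermediate-mass analysis. The
panel, tracer and maps are overridable from a YAML config.

## Fitting and model selection

The one-state model has 5 free parameters (*u*, AP, REV, PPP, CO2); the
two-state model has 11 (a weight plus 5 per state, weight bounded to
[0.01, 0.99], states reported in descending *u* to remove the label-swap
degeneracy). Fitting minimizes the residual sum of squares between the
measured and predicted concatenated channel vectors with bounded
trust-region least squares (`scipy.optimize.least_squares`, trf), from a
seeded Sobol multistart (default 20 starts; tolerance 1e-9). Goodness of
fit is reported as *f* = √Σr² after omitting the single most positive and
single most negative residual of the concatenated vector (an alternative
reading of the omission rule — dropping the extreme mass channel per
fragment — is available behind `f_from_residuals`/`FitOptions`); each
start's solution is scored by this reported *f* and the best start wins.
The optimizer itself uses the smooth un-omitted objective. The two-state
fit always includes the duplicated one-state solution as an unoptimized
candidate, so *f*₂ ≤ *f*₁ holds by construction, as required for a nested
comparison.

Model choice: two states are called iff log₁₀(*f*₁/*f*₂) strictly exceeds
the threshold (default 0.2; *f*₂ floored at 1e-12). The boundary value 0.2
itself is conservatively called one-state. Information criteria (AIC/BIC)
are deliberately not offered: with ~100 informative channels and strong
inter-channel correlation they do not discriminate here. Replicates are
fit independently and summarized per row; raising the threshold can only
reduce the number of two-state calls (monotonicity, verified in tests).

## Pooling and kinetics

Computational pooling is the channel-wise convex combination
pA·A + (1 − pA)·B of two measurements — exactly what a physical pool would
measure, since MIDs are linear in population composition. Pool annotations
carry min(pA, 1 − pA) and |u_A − u_B|, the two axes that govern inference
error; ground-truth usages of the pooled sources are taken from their
one-state fits.

Dilution correction: material present at the previous time point is still
present, diluted by w = 2^(−Δdoublings); the new synthesis of the interval
is (D_t − w·D_{t−1})/(1 − w), computed per channel and fragment, with
negative channels (noise-driven) clipped to zero before renormalization
and the clipped mass reported as a diagnostic. Sequential (consecutive
pairs) is the default because uptake behavior can drift between intervals;
cumulative correction against t₀ is available. The correction is the exact
algebraic inverse of mixture construction on noise-free inputs.

Intermediate-mass species are quantified per fragment by nonnegative
least-squares attribution of the observed MID to the isotopic-species
templates — the columns of that fragment's measurement operator, which
already encode purity and natural abundance. The intermediate fraction is
1 − (weight of the pure-light column) − (weight of the pure-heavy column),
averaged over the shift subset. Template attribution (rather than a raw
mass cutoff) is required because impurity smears the pure species across
neighboring channels.

## Synthetic data

The generator emulates the reference experiment designs: `mix_then_grow`
(one-state cultures over the usage series 1, 0.9, 0.75, 0.5, 0.25, 0.1, 0 —
the 1:0, 9:1, 3:1, 1:1, 1:3, 1:9, 0:1 mixing ratios), `grow_then_mix`
(pure-light and pure-heavy cultures pooled over the same ratio series:
5 two-state designs plus 2 pure controls, 21 samples at 3 replicates),
`two_state_general`, `shift_timecourse` (old/new mixtures weighted
2^(−doublings) at stamps 0.9, 2, 4.5, 9) and `coutilization_shift` (a
light-pregrown pool plus per-interval co-utilizing synthesis with the
light share drifting 0.40 → 0.84 over four doublings). Noise is additive
truncated-Gaussian per channel, sd 0.005 absolute abundance — the scale of
replicate standard errors in careful GC-MS amino-acid panels — followed by
renormalization; `calibrate_noise` estimates the pooled sd from real
replicates, and a Dirichlet alternative sits behind a flag.

What the generator does *not* emulate: fragment-specific noise
heteroscedasticity, chromatographic interference, drift between batches,
vacuolar amino-acid stores and recycling (so synthetic shift data contain
no genuine intermediate-mass species), and cross-feeding. Passing tests on
synthetic data therefore demonstrate correctness of the inference
machinery under the stated noise model, not robustness to every artifact
of real chromatograms; inference errors on real data are expected to be
several-fold larger (percent-scale rather than the sub-percent recoveries
seen on synthetic inputs), while remaining within the method's operating
envelope (usage differences ≳ 25 points between subpopulations).

## Numerical choices and problem sizes

* Stationary balance: direct solve, `ap` floored at 1e-9; truncated-history
  iteration (tolerance 1e-10, cap 10⁴) kept as oracle and fallback.
* MID tables renormalized on read when the channel sum is within 5% of 1,
  rejected otherwise, per fragment group.
* Heavy statistical checks use 100 simulations per operating
  characteristic (false-positive rate on one-state 50:50 data; detection
  rate on 50/50 mixtures separated by 40 usage points) with 4 optimizer
  starts per fit — start-count sensitivity was flat well beyond this for
  these designs. The Monte-Carlo solver validation uses 10⁶ draws at 20
  random parameter points, with `ap` drawn from [0.1, 1] to bound the
  turnover-history truncation depth.
* "Agreement within 3 standard errors" for the Monte-Carlo check is
  asserted statistically: across all ~5000 compared pattern frequencies at
  most 1% may exceed 3 SE (the two-sided normal expectation is ~0.3%) and
  none may exceed 6 SE; a strict max-|z| < 3 over thousands of draws would
  reject a *correct* sampler with high probability.

## Known limitations

* The network is deliberately minimal: no compartmentation, no exchange
  fluxes beyond the four branch fractions, no nitrogen/hydrogen isotopes,
  no net flux magnitudes. It measures *uptake choice*, not flux.
* At most two discrete states; continuous usage distributions or ≥3 states
  are out of scope.
* The two-state model is weakly identified when the usage difference falls
  below ~25 points or the minor population below a few percent — the
  f-ratio then sits near the threshold and parameter estimates inherit
  large spread.
* Single-unit fragments contribute nothing to state deconvolution; panels
  dominated by them weaken the method.
* The default fragment panel reconstructs a standard TBDMS series from
  stated selection criteria; laboratories should drop in their own panel
  (channel windows, interference exclusions) via the config file.
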