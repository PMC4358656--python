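# Methods

## The per-cell model

Each agent is a deterministic 12-species ODE system; all stochasticity is
extrinsic (parameter draws fixed at birth). Time is in hours, signaling and
apoptosis species in molecules/cell, mass and general machinery (GM) in
dimensionless model units (1 mass unit ≈ 300 μm³, the mean resting volume;
the conversion constant is configurable).

**NF-κB module.** Active IKK is an external forcing,
`IKK(t) = scale·(basal + amp·e^{−k_decay·t})` after stimulation onset and
`scale·basal` before; `scale` is the per-cell total-IKK multiplier. Each
dimer (RelA:p50, cRel:p50) shuttles between an inactive cytoplasmic pool and
a nuclear active form: import is proportional to IKK, export grows with the
IκB pool (sequestration), so IκB degradation by IKK releases NF-κB and
NF-κB-induced IκB synthesis (a cooperative Hill term in total nuclear NF-κB)
closes the negative feedback. RelA total is a conserved per-cell quantity;
cRel protein is synthesized (translation rate `tr_crel`, with NF-κB-induced
amplification) and degraded slowly (28-h lifetime), which makes the cRel
pool a slowly mixing, heritable component of cell state — as observed for
protein levels in sibling cells.

**Apoptosis module.** A constant post-stimulation death signal activates a
caspase pool, inhibited by Bcl-XL through the factor
`1 + (Bcl_XL/K_inh)^4`; caspase cleaves PARP, and cPARP relaxes toward the
quasi-steady level `S ∝ ka_casp/(F·dg_parp)` with a 25-h time constant. The
cell dies when cPARP rises through 25,000 molecules/cell. The sharp
inhibition exponent makes protection switch-like: cells with induced Bcl-XL
saturate far below threshold; cells without it cross at ~15–25 h. During
equilibration the death signal is off, so cPARP stays at zero.

**Cell cycle / growth module.** GM production is
`mass · gm_myc_max · hill(Myc, K_gm, 2)` (biosynthesis scales with cell
size and is Myc-gated) and GM decays with a 20-h lifetime; mass grows as
`k_mass·GM`. The mitosis readout relaxes (2/h) toward
`hill(CycD, 80, 4) · hill(mass, mass_div, 8)` and division fires on an
upward crossing of 0.2 after at least 1 h below it (debounce against solver
chatter). Because division requires mass ≈ `mass_div` (≈ 5× the mean
resting mass), division is effectively a sizer, growers roughly quintuple
before the first division, and daughters born at half the division size
cycle in ~12 h.

**Coupling.** Nuclear NF-κB drives the CycD, Myc and Bcl-XL promoters with
cooperative Hill kinetics. The Bcl-XL drive weights cRel:p50 twice RelA:p50
(cRel accounts for roughly two thirds of Bcl-XL expression); the Myc/CycD
drive is RelA-dominant (`w_crel_g = 0.1`). This division of labor is the
model's central claim: removing cRel leaves the growth trajectory within
~15% of wild type over a cycle (RelA compensates, aided by reduced IκB
feedback) while stripping growing cells of apoptosis protection — growth is
cRel-independent, survival of growers is not.

## Extrinsic noise and inheritance

Noise-eligible parameters are sampled once per founder: conserved totals
(RelA total, IKK scale, division size) from lognormals moment-matched to
the target arithmetic mean and CV; synthesis-type rates from normals
truncated at zero by resampling (clipping would put an atom at zero and
silently kill synthesis). At division each daughter's value is the average
of the mother's and an independent fresh draw, so the population variance
relaxes to its stationary value (σ²/3 of the fresh-draw variance) and kin
correlations decay geometrically. Mass and GM are partitioned with a single
draw `r_a ~ N(1, CV_partition)` truncated to (0, 2): daughter A receives the
fraction `r_a/2`, daughter B the remainder — conservation is exact, and both
quantities use the same split. Nuclear dimers are redistributed evenly
between nucleus and cytoplasm (nuclear amount halved, total conserved) to
mimic nuclear-envelope breakdown; all other concentrations are copied.

The three protein groups exposed to the noise-scan machinery are the
negative regulators of NF-κB activation (IκB), the positive regulators (IKK
scale, RelA total, cRel translation), and all other (cell-cycle/apoptosis)
proteins. Group scans multiply rate means by 1.1 or fixed totals by 1.5, or
double CVs, one manipulation at a time.

## Numerics

The surrogate system is smooth and only mildly stiff (fastest rates a few
per hour), so each agent is integrated with a compiled fixed-step classical
RK4 at `dt = 0.005 h` (stability margin > 20× for the fastest rate; the
step is snapped to divide the 0.2-h output grid). Against an independent
RK4 at `dt = 1e-3 h` the trajectories agree to better than 1e-4 relative.
Threshold crossings are detected by sign change over a step and located by
20 bisections of the step fraction (≈ 5e-9 h), far inside the 1e-3 h timing
tolerance. If death and division are located within 1e-3 h of each other,
death wins (a completed apoptotic program trumps mitosis); otherwise the
earlier event does. Species values are clamped at zero inside the
right-hand side, so small negative solver excursions cannot feed back;
trajectories are asserted nonnegative to 1e-9 of each species' scale.

Equilibration integrates each founder under basal IKK with death signaling
off for at least 24 h, until the maximum species change over a 1-h window
falls below 1e-4 of the species scale (96-h cap with a warning counter in
the run manifest); a mitosis-readout crossing during equilibration raises a
configuration error, since the parameter draw is then not quiescent.

Randomness derives from one root seed through `SeedSequence` spawn keys:
each agent's stream is keyed by its lineage path, the partition draw by a
dedicated sibling key, so results are independent of the order in which
agents are solved and identical across reruns.

## Calibration

The Hill constants, IKK decay, growth-law constants and noise CVs are free
knobs; they were fitted (`scripts/calibrate.py`) so the wild-type run
reproduces the observed feature set: division fractions of ~38% / ~85% /
~9% in generations 0 / 1 / 6, sister same-fate concordance ~90%, sister and
cousin interdivision-time R² of ~0.74 and ~0.44, ~5× gen-0 grower fold
growth, and a gen-1+ median cycle well under 20 h. Three structural
features emerged as necessary during the fit and are retained as defaults:

* fate fractions are set by a race, not a threshold: the death clock of
  unprotected cells (~15–25 h) competes with growth to division size
  (~30–40 h in generation 0), and the Bcl-XL protection switch decides who
  is exposed;
* the generational decline of division is driven by the decaying IKK input
  (fitted `k_decay = 0.009/h`) filtered through per-lineage IKK/cRel
  abundance differences;
* kin correlations require a slowly mixing heritable state. GM (20-h
  lifetime) carries most of the timing heritability: its per-generation
  correlation decay `e^{−12/20} ≈ 0.55` matches the observed cousin/sister
  R² ratio. Per-daughter fresh noise (division size, GM rate, partition
  asymmetry) sets the sister ceiling.

## Analytics definitions

* Growers: trailing means (5 samples) of start and end volume; grower iff
  gain ≥ 350 μm³ or end ≥ 800 μm³; both thresholds rescale together for
  ±25% sensitivity reruns. A cell that grew and shrank back fails both.
* Growth fit: least squares over `V = v0` then `v0·e^{k(τ−t_gro)}`, with
  `t_gro` searched on the sampling grid (coarsened to 64 candidates for
  long tracks, then refined), `k` optimized in 1-D per candidate and `v0`
  closed-form. `Tgro` of simulated cells always comes from this fit, never
  from the simulator's internals, so simulated and tracked data are
  analyzed identically.
* Fate windows: generation 0 counts events at 12–36 h after stimulation,
  generations 1+ at 0–24 h after birth; cells censored before the window
  end leave the denominator; error bars follow the 1/n convention.
* Kin statistics: sisters share a parent, cousins a grandparent but not a
  parent. R² is the squared symmetrized Pearson correlation (each unordered
  pair entered in both orders); same-fate concordance uses pairs with both
  fates observed.
* Race bound: `P_lb = f_resp · mean_j F̂_gro(Tdie_j)` with `F̂_gro` the
  empirical CDF of growth-onset times and `f_resp` the generation-0
  dividing fraction (using the growing fraction instead is an option). The
  decision-model expectation is 0 by definition. The estimator is verified
  against a Monte-Carlo race simulation in the test suite.
* Expected divisions per progenitor: `E = Σ_g Π_{i≤g} f_i` over the
  observed division-fraction chain.

## The synthetic-lineage generator

`bcelldyn.fixtures` produces lineage trees with known ground truth and no
ODEs: per-generation division probabilities, lognormal fate timings (times
to divide/die are long-tailed), a mother-level shared latent factor with
weight `w` so the sister log-time correlation equals `w` by construction,
and piecewise growth-curve volumes with multiplicative noise. It emulates
the *statistical shape* of tracked data — generation structure, censoring,
kin timing correlation, grower trajectories — and deliberately not the
mechanism: no molecular state, no race between programs, fate independent
of timing. Passing the parameter-recovery suite on fixture data therefore
validates the analytics, not the biology; the mechanistic claims are tested
on the ODE engine itself.

## Problem sizes and runtime

The shipped default run is the full study condition (250 founders, 144 h,
~2,800 cells) and completes in well under a minute; unit tests use 6–12
founders, the parameter-recovery suite 800–2,000 synthetic founders, and
the perturbation comparisons 100 founders each.

## Limitations

* The three submodules are reduced surrogates with the published interface
  species, thresholds and couplings, not transcriptions of the full
  published reaction lists; module internals are replaceable behind
  `IntegratedModel` without touching the agent engine.
* No intrinsic (reaction-count) noise, no paracrine coupling, no spatial
  effects, no receptor-proximal TLR9 biochemistry.
* Mechanical early death seen in microscopy is not generated (real
  pipelines filter it; the simulator simply has no such process).
* The low-dose preset's IKK-decay multiplier (2.0) and the death-signal
  composition of the rapamycin preset are modeling choices recorded in the
  preset definitions, not measured quantities.
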