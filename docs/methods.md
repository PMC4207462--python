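# Methods

`teleflux` couples stochastic single-gene expression dynamics to a
deterministic mass-action model of signal transduction and uses the coupled
system to run in-silico single-cell experiments on TRAIL-induced apoptosis.
This note describes the models, the numerical choices, and the limits of what
the synthetic experiments can show.

## The stochastic protein-turnover model

Each protein is produced by one gene described by the two-state (telegraph)
model.  Four reactions are stochastic and simulated exactly with the
Gillespie algorithm:

    G_off -> G_on        rate k_on        (promoter activation)
    G_on  -> G_off       rate k_off       (promoter inactivation)
    G_on  -> G_on + m    rate k_m         (transcription while ON)
    m     -> 0           rate gamma_m * m (mRNA decay)

Translation and protein degradation are deterministic:

    dp/dt = k_p * m - gamma_p * p

so between stochastic events the protein follows the exact exponential
relaxation `p(t) = k_p m / gamma_p + (p0 - k_p m / gamma_p) exp(-gamma_p t)`;
no ODE solver is involved at this layer.  All times are hours, all levels
molecules per cell; half-lives convert to rates as `gamma = ln 2 / t_half`.

### Stationary moments

Because the drift of `(g, m, p)` is linear, first and second moments close
exactly.  With `lambda = k_on + k_off` and ON-fraction `f = k_on / lambda`:

    <m>      = f k_m / gamma_m
    Cov(g,m) = f (1-f) k_m / (lambda + gamma_m)
    Var(m)   = <m> [1 + k_m (1-f) / (lambda + gamma_m)]
    <p>      = k_p <m> / gamma_p
    Cov(g,p) = k_p Cov(g,m) / (lambda + gamma_p)
    Cov(m,p) = [k_p Var(m) + k_m Cov(g,p)] / (gamma_m + gamma_p)
    Var(p)   = k_p Cov(m,p) / gamma_p

These expressions were derived from the moment equations of the master
equation coupled to the linear protein ODE and validated against brute-force
Gillespie estimates before being relied on (the test suite keeps that
cross-check).  For the standard long-lived parameterization below they give a
protein coefficient of variation of 0.25.

### Autocorrelation and mixing time

By the regression theorem for linear-drift processes, the covariance vector
`C(tau) = Cov(p(0), [g,m,p](tau))` obeys `dC/dtau = A C` where `A` is the
drift matrix of the means.  The implementation evaluates `expm(A tau)`
directly, which remains exact when two relaxation rates coincide; the
three-exponential closed form is kept as an independent cross-check in the
tests.  The *mixing time* is defined as the smallest lag at which the
normalized, mean-removed protein ACF reaches 1/2; it is found by doubling
bracketing plus bisection to 1e-3 h.  For a typical long-lived protein
(half-life 27 h, mRNA 9 h) the mixing time is ~41 h and varies only weakly
across two decades of promoter switching times — this insensitivity is what
licenses using one standard turnover parameterization for most proteins.

### Parameterization from observables

Rates are rarely measured directly; the package constrains them from six
observables: mean protein and mRNA levels, protein and mRNA half-lives, and
mean promoter ON/OFF durations (`k_off = 1/T_on`, `k_on = 1/T_off`, synthesis
rates solved from the stationary-mean identities).  The *standard* model used
for long-lived proteins is: protein half-life 27 h, mRNA half-life 9 h, mean
mRNA 17, `T_on = 0.1 h`, `T_off = 2.6 h` (typical values from multi-gene
studies in mammalian cells); mean protein levels are protein-specific.

### Stationary sampling

Population snapshots are drawn by burn-in simulation from a deterministic
start (means, majority promoter state) for 5 mixing times (configurable).
At that horizon the residual autocorrelation with the start state is below
3%.  Genes locked OFF (`k_on = 0`) short-circuit to the exact degenerate
stationary state.

## The hybrid cell model

A cell is a species vector evolving under mass-action ODEs (reactions +
first-order degradation + per-gene synthesis `k_p m_i(t)`) coupled to one
telegraph gene model per native protein.  Two structural facts make the
scheme exact rather than approximate:

1. gene-layer propensities depend only on promoter and mRNA state, never on
   protein levels, so the full event schedule can be pre-sampled
   ("presample" mode, the default) or consumed event by event ("interleave");
   both orderings use the same per-gene random streams and produce the same
   trajectory;
2. between mRNA-count changes the synthesis term is constant, so the ODE
   system is integrated segment by segment with LSODA (analytic Jacobian,
   rtol 1e-6, atol 1e-3 molecules by default) and restarted at each change.
   Promoter flips do not alter the right-hand side and do not force restarts.

Two exact fast paths are used when their preconditions hold: a *quiescent*
phase (every reaction is permanently inert because a required reactant is a
zero-level species that cannot be produced — e.g. any resting cell before
ligand addition) is advanced through the gene layer alone; a
*synthesis-blocked* phase (the cycloheximide idealization, all `k_p = 0`)
decouples the ODE system from the gene layer and is integrated in one sweep.
These paths are what make population-scale experiments affordable; they are
bit-compatible with the general path where both apply.

Numerical hygiene: species are recorded on a configurable output grid
(default 0.05 h; the experiment drivers use 0.1 h) plus all integration
breakpoints; negative excursions are clipped to zero, with a logged warning
when they exceed the absolute tolerance; solver failures raise with the time
attached.  Division duplicates the mother state exactly (equal-repartition
assumption — levels are per-cell copy numbers whose concentrations are
preserved when volume halves); daughters receive independent random streams.

## The TRAIL-apoptosis application

The deterministic layer is a transcription of the published extrinsic
apoptosis reaction model (EARM): 58 species, 70 irreversible mass-action
reactions (receptor/DISC assembly, initiator and effector caspases, XIAP,
the Bid-Bax-Bcl2 mitochondrial switch, Smac/cytochrome-c release, the
apoptosome, PARP cleavage), with rate constants in the vendored
`data/earm.yaml` (per-second units, converted on load; membrane-localized
bimolecular rates pre-divided by the mitochondrial volume fraction 0.07).
All 17 native proteins carry turnover models; their mean levels are the base
model's initial conditions.  The effector-to-initiator feedback (cleavage of
pro-caspase 6 by caspase 3) is removed by default by zeroing the whole
pC6+C3 reaction group — zeroing only the catalytic step would leave pC6 as
an unintended caspase-3 sink of 1e4 binding sites, which is not the intent
of removing the loop.

Degradation of non-native forms (complexes, cleaved and translocated
species) uses a single configurable active-form half-life, default 15 h
(model behavior is insensitive between 5 and 27 h; only ~2 h changes
outcomes appreciably).  One structural exception: complexes containing the
short-lived inhibitors Flip or Mcl1 inherit those proteins' fast degradation
rates.  This reflects their ubiquitin-driven turnover, which degrades the
complex with the client bound, and it is load-bearing: it is what turns
Mcl1 binding of truncated Bid from a reversible buffer into a genuine sink,
the mechanism by which ongoing Mcl1 expression rescues cells from TRAIL.

Presets for the two short-lived proteins:

| preset                    | Flip/Mcl1 half-lives (protein/mRNA) | promoter T_on/T_off |
|---------------------------|-------------------------------------|---------------------|
| `non_fitted`              | 0.5 h / 2 h                         | 0.1 / 2.6 h (standard) |
| `fitted`                  | 0.4 h / 1 h                         | 16 / 24 h (slow)    |
| `mcl1_only_low_switching` | 0.4 h / 1 h                         | Mcl1 16/24, Flip standard |

Slow switching with short half-lives produces large, rare fluctuations and a
bimodal stationary distribution (modes at zero and at the ON-state level);
standard switching with the same half-lives gives a unimodal distribution
with its mode at zero.

Doses map linearly to ligand molecules through the base model's anchor
(50 ng/mL = 3000 molecules/cell, configurable).  MOMP is detected when half
of the (current) mitochondrial Smac pool has been released, linearly
interpolated between grid points; death when half of total PARP is cleaved.
Both fractions are configurable.

## Experiment protocols

* **Sister cells** — mothers are stationary samples; each divides at a
  uniform time within the 20 h pre-treatment window (the window is stated by
  the protocol; the uniform law is our choice — an asynchronous culture over
  a window shorter than the cycle is near-uniform).  Both daughters run
  through treatment (ligand addition, optional synthesis blockade) for 8 h.
  The fate-inheritance curve is the Pearson correlation of sister MOMP times
  in sliding bins (width 2 h, step 1 h, minimum 50 pairs) of the
  pair-averaged division-to-MOMP duration, computed on the symmetrized pair
  set so the arbitrary sister order drops out.  Edge bins of this estimator
  carry a small selection artifact (conditioning on the pair average), which
  is why tests assert on central bins.
* **Agreement score** — the published model-data quantification is not
  reproducible from the available text; the package uses a documented
  surrogate behind a stable interface: mean squared difference of MOMP-time
  histogram frequencies (relative to all cells) plus a weighted squared
  surviving-fraction difference.  It is symmetric, zero iff the summaries
  agree, and swappable should the original formula become available.
* **Grid scan** — re-runs the sister experiment at reduced population size
  per grid point over Flip/Mcl1 promoter switching times and records each
  objective's agreement; per-point failures are recorded and do not abort
  the scan.
* **Repeated TRAIL** — a naive population is treated; death (cleaved-PARP
  criterion) removes cells continuously; the ligand is washed out at the end
  of the assay window (a medium change, our protocol choice); survivors
  divide with a gaussian cell cycle (27 +/- 3 h; the first division time of
  each cell is uniform within its current cycle) and the population is
  uniformly subsampled to a cap after each checkpoint.  At each requested
  interval the survivors and a fresh naive control are washed, re-dosed and
  assayed; the resistance gain is the ratio of survival fractions.  Cells do
  not divide during an assay window.
* **Determinants** — over-representation ratios (survivor mean / population
  mean) of each native protein's level and promoter state at treatment time,
  with two-sided permutation tests (10^4 permutations by default).  Flags
  are reported both per feature at the 5% level and Benjamini-Hochberg
  adjusted across features; the null calibration property (fate assigned
  independently of state gives ~5% flags) applies to the per-feature flags,
  which is what a single-protein significance statement corresponds to.
* **Recovery** — survivor/naive level ratios per day against the
  turnover-only expectation `mean + (l0 - mean) exp(-gamma_p t)`; deviation
  indicates selection or residual signaling.

## What the synthetic experiments do and do not show

The generator reproduces the *modeled* sources of cell-to-cell variability:
transcriptional bursting, mRNA and protein turnover, and their interaction
with signaling.  It deliberately omits noise in the signaling reactions
themselves, correlated expression across genes (e.g. shared transcription
factors), cell-cycle-dependent transcription, partitioning noise at
division, and any TRAIL-induced gene regulation (survival pathways).
Agreement of the in-silico protocols with the package's expectations
therefore validates the machinery, not the biology; the biological claims
inherit the assumptions above.

A transcription caveat: the EARM rate table is vendored from the published
base model rather than re-derived, and its deterministic dose-to-MOMP delays
were verified against that model's published behavior.  With this
transcription the fitted preset yields clear fractional killing under TRAIL
alone, but the surviving fraction at 8 h sits in the 5-25% range (depending
on the active-form half-life) rather than ~40%: a cell holding its Mcl1
promoter ON throughout still commits to MOMP at ~5.6 h in the deterministic
limit, i.e. the Bid-to-Bax arm is a factor ~2 stronger relative to the Mcl1
sink than in the original parameterization.  The same imbalance slows the
relaxation of reversible resistance: the day-1 resistance gain is large and
dose-dependent as expected, but residual signaling (persistent DISC and
initiator caspase) keeps selecting for high-Mcl1 cells for days, so the gain
has not fully returned to 1 by a five-day interval.  Both discrepancies are
documented rather than tuned away, since the vendored constants are a
published set, not free parameters; the corresponding quantitative tests are
left failing with this analysis.

## Problem sizes

The shipped experiment defaults follow the study conditions (10^4 pairs or
cells, 8 h observation, 24 h assay windows).  The test suite and the
reproduction script run the same protocols at reduced population sizes
(10^3 cells for fate-variability runs, ~10^2 for multi-day propagation),
chosen so Monte-Carlo error stays well inside the asserted tolerances.
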