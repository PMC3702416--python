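# Methods

## Scope and design

`phenofit` estimates parameters of ODE "strain models" against qualitative
viability phenotypes and analyzes the resulting archives.  The package is
model-agnostic: the protocol, sampler, optimizer and analyses only see the
`StrainModel` contract (wild-type vector, strain table, one deterministic
integration step, a scalar division signal with a declared threshold, a
mass partition, a mass accessor, optional named cycle events).  Parameter
identity is by name throughout; parameters held fixed by convention (see
below) are declared as a name set and excluded from sampling, mutation and
perturbation.

## The viability protocol

A strain simulation integrates the model over a horizon of **2000 min**
with fixed-step forward Euler, **dt = 0.05 min** (the stepping routine is
pluggable; the bundled model also ships a compiled whole-trajectory kernel
that the protocol uses when present, and the two paths are cross-checked in
the tests).  Division is detected as a downward crossing of the model's
division signal through its threshold, with linear interpolation for the
crossing time and size; the model's own mass partition is applied at the
crossing.  Classification:

* mass exceeding **25 units** at any time: the cell has arrested while
  growth continues — **inviable** (the simulation stops there; this
  short-circuits any division history);
* a non-finite state during integration is recorded as a numerical-failure
  flag and classified inviable, never raised;
* at least **3 divisions** and a last division size within **5%**
  (non-strict, relative to the *earlier* size, both comparisons required)
  of each of the two previous division sizes: **viable**;
* a last size that disagrees with the previous division but agrees with the
  one before it: period-doubled division sizes, **indeterminate**;
* anything else (too few divisions without blow-up): **indeterminate**.

Indeterminate calls match neither observed phenotype, so their indicator is
always 0.  The minimum-3-divisions rule is the conservative reading of a
convergence test that needs a last and two previous sizes; slow dividers are
deliberately not called viable.

Wild-type bootstrap: the wild type is simulated once per parameter vector
from the vector's own initial-condition entries ("input ICs").  If viable,
the full state just after its last division (the "newborn" state) seeds all
mutant simulations; if not, configured default ICs are used so mutants can
still be scored.  One consequence, preserved by design: the input-IC
entries of the vector influence the objective only through the wild-type
simulation, so they rank among the least critical parameters.

## Latin-hypercube sampling

The search region is the per-parameter interval
[max(0, c·(1−p)), c·(1+p)] around a center vector c.  Each non-degenerate
dimension is split into n equal subintervals; each sample occupies exactly
one subinterval per dimension (independent permutations per dimension) at a
uniform position inside the cell.  Uniform-in-cell was chosen over midpoint
placement to keep marginals continuous; stratification is asserted exactly
in the tests.  Frozen names keep the center value; a zero-width range is
sampled as the constant 0 and logged.

## Differential evolution

Classic difference mutation v = x_j + F·(x_j′ − x_j″) with the two
co-parents drawn uniformly without replacement from the other lineages,
componentwise crossover u_i = v_i if rand ≤ C else x_i, and greedy
(offspring replaces parent iff strictly better) or non-greedy (iff at least
equal) selection.  Defaults F = 0.1, C = 0.5.  Numerical choices:

* negative mutant components are clamped to 0 (rates and amounts are
  nonnegative); clamping also matches the semantics of zeroed parameters in
  model reduction.  Reflection was rejected for simplicity;
* there is no forced crossover index: an offspring may equal its parent;
* offspring are not confined to the initial sampling cube — only
  nonnegativity is enforced;
* randomness is one seeded root generator with sub-streams derived per
  (generation, lineage), so runs replay bit-exactly and evaluation order
  cannot change results;
* a run may be told to stop after a generation in which some member attains
  a stated full-panel objective (used with the attainable maximum): later
  generations cannot improve on an attained maximum, so reported bests and
  medians are unaffected while run time drops substantially;
* every parent and offspring is archived with the outcome bits of the
  *full* strain table even when selection uses a subset, so analyses can
  re-score any slice afterwards.  After G generations the archive holds
  N·(G+1) parent rows and N·G offspring rows.

Restarts: `resample_restart` takes the best member at a chosen generation
(ties to the lowest lineage index, deterministically) and Latin-hypercube
resamples a fractional cube around it.  A converged population (all members
identical) is an exact DE fixed point, so restarting is the designed escape
hatch; the tests demonstrate the fixed point and the escape.

## Competition statistics

From an m×n binary acceptance matrix (rows: evaluated vectors of whatever
provenance the caller selects — trial offspring by default; columns:
phenotypes): acceptance ratios Āₗ (column means), pairwise correlations
R_{k,l} = C_{k,l}/√(C_{k,k}C_{l,l}) with the 1/(m−1) sample covariance, and
competitiveness R̂ₖ = Σ_{l≠k} R_{k,l}.  Zero-variance columns (phenotypes
captured by all vectors or none) carry no correlation information: their R
entries are defined 0, they are excluded from R̂ sums, and their own R̂ is
NaN and flagged.  The k *least competitive* phenotypes (largest R̂, ties by
strain id) can be dropped from the selection objective; archives keep full
bits, so final populations are re-scored on the complete panel.

## Sensitivity analysis and model reduction

Around each elite base vector, every varying parameter is perturbed one at
a time over nine levels (×0.8, 1.2, 0.6, 1.4, 0.4, 1.6, 0.2, 1.8, and set
to zero).  A *loss* is a perturbation flipping a phenotype from captured
(by that base) to not captured; the captured baseline is per base vector,
and phenotypes a base never captured are excluded from its ledger.  Gains
of previously missed phenotypes are logged separately and never offset
losses.  Per-phenotype totals rank *fragile* phenotypes, per-parameter
totals rank *critical* parameters (percent-of-losses reported to 2
decimals), and the exact conservation identity Σ fragility = Σ criticality
= total losses is asserted in the tests.  Non-sensible combinations are
declarative exclusions — (base or wildcard, parameter, level) triples —
removed from the grid with a counter, since they are model semantics, not
framework logic.  `reduce_model` zeroes a dispensable name set;
`synthetic_lethality_screen` zeroes one reaction rate at a time, skips
rates that break wild-type viability, and reports experimentally viable
single mutants whose call flips to inviable.

## The bundled toy model

A three-variable caricature of a growing-and-dividing cell:

```
dX/dt = ks_x·M + ka_x·X²/(J_x² + X²) − (kd_x + kd_xy·Y)·X
dY/dt = ks_y·X − kd_y·Y
dM/dt = mu·M
```

X is an autocatalytic activator synthesized in proportion to mass, Y a slow
inhibitor tracking X, M exponentially growing mass.  Division fires when X
falls through `theta_div`; the daughter keeps `f_daughter` of the mass; a
"start" event (X rising through `theta_start`) precedes division every
cycle, giving the order-of-events audit a two-event schedule.  The growth
rate (doubling time 100 min) and daughter fraction (0.4) are fixed by
convention; the other 9 kinetic constants and 3 initial conditions are
searchable (D = 14).  At the ground truth the wild type divides every
~132 min at size ≈ 4.0 (14 divisions per horizon).  Behaviour classes, all
reachable by parameter changes and exercised by the panel and tests:
stable cycles; growth arrest with mass blow-up (e.g. deleting X synthesis
or autocatalysis, or growth rate ×5); and genuine period-doubled division
sizes in a declared band of the inhibitor-efficacy parameter
(kd_xy ×1.40–1.45 of ground truth).

The 34-strain panel covers both wild-type growth conditions, deletions,
hypomorphs, overexpression and point mutants of every pathway arm, one
initial-condition mutant (dispensable by construction), and paired "edge"
strains placed just inside the viability windows of five parameters.  Edge
pairs pull their parameter in opposite directions — the designed
competitive pairs — and make joint satisfaction genuinely hard: a ±50%
degraded start typically captures 8–25 of 34, Latin-hypercube seeding keeps
roughly 10–35 of 100 samples, and differential evolution recovers the full
panel within tens to a few hundred generations.  Observed labels are always
computed from the ground truth through the protocol itself (never written
by hand), so the panel is self-consistent, a perfect score is attainable,
and any protocol change surfaces as a panel diff.

## Study-scale defaults and problem sizes

The recovery experiments use 100 LH samples, population N = 19, F = 0.1,
C = 0.5, non-greedy selection, up to 300 generations, ±50% multiplicative
degradation of the ground truth, and seeds derived by fixed offsets from
one integer.  The scheduling identities are computed at full study scale
(15 elite vectors × 9 levels × 149 varying of 152 named parameters;
119-strain tables).  The experiment suites run the toy panel (34 strains,
2000-min horizon, dt = 0.05) in a few minutes on one CPU.

## What the toy experiments do and do not show

They validate the framework end to end — protocol classification, exact
stratification, optimizer invariants and bit-exact replay, archive
statistics against brute-force oracles, competition-guided subset selection
and the sensitivity ledger's conservation — on a model whose ground truth
is known.  They do not show biological realism: the toy model's three
variables compress an entire regulatory network, its viability windows and
rankings have no yeast counterpart, its panel lacks measurement error and
condition-dependent phenotypes (labels are protocol-consistent by
construction), and recovery of a perfect score is expected because the
ground truth lies in the searched space.  Conclusions about any real model
require plugging that model into the same contract.

## Known limitations

* Fixed-step Euler is the reference integrator (chosen for parity with the
  protocol's definition); stiff user models would need a custom step hook.
* The objective treats all strains equally; no weighting or partial credit.
* Correlation-based competitiveness is a linear summary of binary columns;
  significance testing and partial correlations are out of scope.
* Single-parameter perturbation cannot see compensating multi-parameter
  directions; dispensability is relative to the panel and the grid levels.
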