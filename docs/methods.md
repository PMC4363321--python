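# Methods

## Model

A product system is a set of single-output unit processes.  The technology
matrix **A** (product flows × processes) holds production entries (positive)
and consumption entries (negative); the intervention matrix **B**
(elementary flows × processes) holds emissions per unit activity.  For a
demand vector **f** encoding the functional unit (here one tonne of live
fish), the scaling vector solves **A·s = f**, the inventory is
**g = B·s**, and the carbon footprint is **h = q·g** with **q** the vector
of GWP₁₀₀ characterization factors.  Systems are small and dense; the solve
is a direct dense factorization with an explicit error when the condition
estimate exceeds 1e12.  Only single-output processes are supported — data
are expected pre-allocated — and units are carried as labels, checked for
consistency at link time, never converted.

## Uncertainty model

Every uncertain parameter carries one of five families: point, lognormal
(geometric mean, geometric SD), normal, triangular, uniform.  The *central
value* of a spec is always its arithmetic mean, because that is what the
matrices are populated with; a lognormal attached to a consumption entry is
mirrored (negative geometric mean).  Fitting uses maximum likelihood per
family and Anderson–Darling selection against the fitted CDF, ties broken
in favour of lognormal (the generic background-database assumption).
Triangular and uniform supports are the sample extremes widened by 1% of
the range (the triangular mode comes from a 101-point likelihood grid);
without the widening the AD statistic diverges at the extremes.  At
n = 500 the selection recovers lognormal, normal, uniform and *asymmetric*
triangular generators in well over 80% of replications; a symmetric
triangular is genuinely close to a normal and is identified only about half
the time — a property of the families, not of the selector.

Additional dispersion — inherent uncertainty, spread removed by horizontal
averaging, and unrepresentativeness — is accepted as user-supplied ln-space
variances added to the fitted ln-variance (squared-cv equivalents for
normal bases).  The published numeric factor tables for these components
are not reprinted here; accepting them as variances keeps the engine
faithful to the additive protocol without inventing numbers.  After
widening, the geometric mean is rescaled so the arithmetic mean — and hence
the matrix entry — is unchanged.

Sampling is sign-preserving: draws from normal/triangular/uniform specs
whose sign differs from the central value's are rejected and redrawn (a
sign flip inside **A** corrupts the linear system), with a 1000-attempt
limit that flags pathological specs.  Whether the original modelling
chain truncated or allowed sign changes is not documented anywhere we
know of; rejection is this package's choice.

GWP uncertainty is taken at the GWP level: CO₂ is exactly 1 in every draw
(its uncertainty is definitionally zero once GWPs are read as dependent
AGWP ratios), other gases draw from normal(gwp, σ) truncated at zero, with
σ back-calculated from the published 90% range as (P95 − P05)/(2·1.645) —
1.645 verbatim, matching the printed convention rather than the exact
z₀.₉₅.  The bundled defaults are the AR5 GWP₁₀₀ values: CH₄ 28 (90% range
±40%), N₂O 265 (±30%).

## Dependent sampling and the RNG contract

Each distribution-annotated matrix cell registers its `parameter_id` in a
shared-parameter registry; the same id appearing in several alternatives
means *one* draw per run written to all its cells (dependent mode).  The
draw for parameter p in run k comes from a dedicated PCG64 substream seeded
by (master_seed, blake2b(p), k), plus the alternative index in independent
mode.  Consequences: dependent sharing is exact (not merely correlated),
results are independent of evaluation order, and changing `n_runs` never
changes earlier draws.  One GWP vector per run is shared across
alternatives in dependent mode.  Runs with a singular sampled technology
matrix are discarded and logged rather than resampled (resampling would
bias the surviving distribution); more than 5% discards aborts.

Per-run differences Δₖ = h_{A,k} − h_{B,k} ("relative results") are only
defined for dependent-mode result sets; independent results are refused
with an explicit error since their runs are not paired.

## Statistical ladder

For two alternatives: Shapiro–Wilk on the differences (α = 0.05) gates
between the paired t-test and the one-sample Wilcoxon signed-rank test.
The Wilcoxon drops zero differences (Pratt's method behind a flag), uses
midranks for ties, and computes the exact null distribution of W⁺ for
n ≤ 25 via the generating-polynomial dynamic program over doubled midranks
— identical by construction to enumerating all 2ⁿ sign assignments, which
is what the test suite checks it against at n ≤ 12.  Beyond n = 25 the
normal approximation applies the standard tie and continuity corrections.
Two-sided p-values are 2·min(P(W ≤ w), P(W ≥ w)) capped at 1; one-sided
testing is available since comparative hypotheses are usually directional,
and a nonzero null margin is supported via `mu0`.  The minimum is five
nonzero differences (the smallest n at which the exact two-sided test can
reach 0.0625).

For three or more alternatives: the Friedman test with MC runs as blocks
(midranks, tie-corrected chi-square), or a balanced two-way ANOVA with the
run as a block.  Post-hoc grouping uses all pairwise Wilcoxon tests with
Holm correction (staying within the paired tests above) or Tukey HSD on
the blocked mean square.  Alternatives are ordered by median footprint and
partitioned greedily: a new cluster starts whenever the next alternative is
distinguished from any member of the current one, so cluster members are
pairwise non-distinguished and ranks are contiguous from 1; ranks map to
green/yellow/red labels (red reused beyond three clusters).  The partition
is order-invariant because the ordering is by median (id as tie-break).

The median confidence interval is the conservative distribution-free
order-statistic interval: ranks from the binomial(n, ½) quantiles at
(1 − level)/2, coverage ≥ level for any continuous distribution (at
n = 1000 and 95%: order statistics 469 and 532).  A bootstrap alternative
was considered and rejected as unnecessary at MC sample sizes.

## Synthetic case

The generator emulates the structure of a two-farm-type aquaculture
comparison: a background supply chain (electricity, commercial feed
milling, farm-made feed, transport, with CO₂/N₂O emission intensities)
whose parameter ids are identical across alternatives, a foreground
farming process per alternative consuming those backgrounds in different
quantities (commercial feed share 0.69 vs 0.94 of a 1.8 t/t feed input),
and unshared direct pond CH₄/N₂O emissions with per-alternative parameter
ids.  Background emission intensities are lognormal with geometric SDs of
1.2–1.5; pond emissions (60 kg CH₄, 2 kg N₂O per tonne fish, gsd 1.2 for
both farm types) fold the farm-to-farm spread of a surveyed group into the
exchange dispersion, mirroring horizontal averaging.  Magnitudes were
chosen once to land central footprints in the plausible 3.5–4.5 t
CO₂-eq/tonne range for this production system.

All technosphere amounts are point values: survey quantities enter as
group averages, and the variability is carried by the emission
intensities.  Two consequences matter for interpretation: the expected
per-run difference equals the constructed central-value difference
exactly (the footprint is linear in the B and GWP draws), and with zero
effect the difference distribution is symmetric (the pond terms are
exchangeable between alternatives), so the signed-rank test is calibrated
on this case by construction.  Uncertain **A** entries are fully supported
by the engine and exercised in tests, but real foreground input-amount
uncertainty, correlations between distinct parameters (beyond sharing),
and multi-output allocation are *not* represented — passing tests on this
case say nothing about those features of real data.

`true_effect` injects the target central difference (default 824 kg
CO₂-eq, descending linearly across alternatives when there are more than
two) as extra point-valued background electricity demand on the
higher-footprint alternatives, after first equalizing the baselines, so
the constructed difference is exact rather than approximate.

## Problem sizes and defaults

Monte Carlo default 1000 runs, α = 0.05, two-sided; the full two-farm
comparison at 1000 runs solves in well under a second.  The test suite's
replication studies use 10–100 seeded replications at 40–1000 runs each,
sizes at which the checked properties (variance reduction under dependent
sampling, paired-power dominance over the two-sample Mann–Whitney,
type-I calibration near 5%, ≥ 90% CI coverage of the constructed effect)
have comfortable margins.  The paired-power comparison runs at 40 runs and
a 300 kg effect because at 1000 runs both tests have power ≈ 1 and the
comparison is vacuous.

## Known limitations

Single-output processes only; no allocation, no consequential modelling,
no parameter-to-parameter correlation other than exact sharing; GWP is the
only impact category and GWP₁₀₀ the only horizon; Monte Carlo is the only
propagation method (no Latin hypercube or Taylor series).  The per-(run,
parameter) substream scheme costs a generator construction per draw —
negligible at these system sizes, the price of exact, order-independent
sharing.
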