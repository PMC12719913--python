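# Methods

## Model

The package simulates chemostat-style consumer–resource–predator communities

    dN_i/dt = N_i ( Σ_j μ_ij R_j − m_i − Σ_h g_hi P_h − mq_i N_i^(x_i−1) )
    dP_h/dt = P_h ( Σ_i f_hi N_i − mp_h )
    dR_j/dt = a (s_j − R_j) − Σ_i V_ij N_i R_j

with substitutable resources, linear functional responses, and negative
density dependence as a per-capita loss `mq·N^(x−1)`. The mortality exponent
`x` may be any value above 1; every analysis and default uses quadratic
mortality (`x = 2`), where the term has the familiar logistic-like form
`mq·N` per capita. `m` and `mq` are fields of each species, but all built-in
generators and the analytic formulas assume community-uniform values;
species-specific mortality only rescales results without changing their
structure, so no separate treatment is provided. Predators have no
density-dependent mortality of their own (their loss is the linear `mp`),
matching the model structure throughout.

Assumptions worth making explicit: resources are substitutable and uptake is
linear (no saturation), supply is constant in time, space is implicit, and
demography is deterministic. Spatial structure, stochasticity and
time-varying supply are deliberately out of scope — they are alternative
diversity-maintenance mechanisms, not part of this framework.

Top-down guilds idealise resources as non-constraining; this is implemented
as `ResourceEnvironment(fixed=True)`, which pins `R ≡ s` and zeroes the
resource derivative. It is the model's own definition of that guild, not a
numerical shortcut.

## Parameters and units

All rates (μ·R, m, mq·N, g·P, f·N, mp, a) are per unit time; concentrations
and densities are in arbitrary but consistent units. Defaults used by the
generators: m = 0.1, mp = 0.1, a = 1, mq = 0.01, yield Y = μ/V = 0.3,
predator assimilation f = (2/3)·g. Trait trade-offs: growth rates μ evenly
spaced and decreasing over [0.5, 2.0]; vulnerability g = c·μ^β with β = 2
and c = 1.6, chosen so the mid-guild μ/g ratio (~0.5) sits in the same
regime as the two-prey diamond example (μ/g of 0.32 and 0.70). β > 1 is
required: it makes μ decreasing and μ/g increasing along the ranking, the
gleaner–defender ordering that stabilises diamond-web coexistence.

## Equilibration

`find_equilibrium` integrates populations in **log-density space** with
LSODA (rtol 1e−8; log-density absolute tolerance 1e−8, resources 1e−10).
Log space matters: assembly transients of predator–prey webs pass through
extremely deep troughs (densities below 1e−25 that later recover), which a
linear-space integrator truncates at its absolute tolerance and which naive
extinction pinning would misread as extinctions. A population goes extinct
only when its log-density underflows; zero is absorbing.

Convergence is declared when the max-norm residual — per-capita rates of all
populations above the extinction threshold, plus the resource rate scaled by
`a·s` — falls below 1e−8, after which a Newton polish on the extant
sub-community drives the state to a machine-precision root (this also zeroes
sub-threshold stragglers and closes the resource mass balance exactly).

Two slow endgames are resolved directly rather than waited out:

* **Slow sorting.** When the residual is small (< 1e−4) but near-neutral
  species are still slowly growing or declining, the candidate equilibrium
  (first with all above-threshold species, then with the declining ones
  excluded) is solved by Newton and accepted only if it is locally stable
  (finite-difference Jacobian of the extant subsystem) and no excluded
  population has positive invasion growth there — i.e. it is verifiably the
  trajectory's ω-limit.
* **Ringing vs. cycling.** If the horizon is exhausted, a trailing window
  (20% of the horizon, 400 samples) is inspected. Variation (CV > 1e−3)
  without secular trend in the robustly extant densities marks oscillation;
  shrinking amplitude, or a stable polished root at the window mean, marks a
  damped spiral and is reported as converged. Otherwise the window-averaged
  densities are reported as a cycle-averaged equilibrium, with the caveat
  that the analytic control formulas are exact only at static equilibria.
  The no-trend test ignores near-threshold species (below 100× the
  extinction threshold) so that a slow exclusion inside a limit cycle does
  not block cycle averaging.

The horizon ladder starts at `t_max` (default 1e4 time units) with one
guaranteed doubling; further doublings (up to 32·t_max) happen only while a
small-residual endgame is demonstrably in progress. The extinction threshold
defaults to 1e−6 — far below typical equilibrium densities (1e−2…1e1 at the
default parameters) — and survivor sets are robust to tenfold changes at the
supply points exercised in the tests. Assembly experiments start all species
at 1e−3, predators at 1e−3, resources at supply; sequential-invasion studies
instead seed the resident at its equilibrium and the invader at ~1e−6.

`simulate` (trajectory export) integrates in linear space and pins declining
populations below the extinction threshold to zero between sampling chunks,
which is the natural contract for a trajectory product; equilibrium results
never depend on it.

## Coexistence analysis

Single-resident equilibria are computed algebraically wherever the structure
allows: a lone consumer reduces to a scalar root in N (resources eliminate
as `R_j = a·s_j/(a + V_j N)`), and a resident with one predator sits at the
predator's subsistence density `N = mp/f`, with `P` from the prey's
zero-growth condition and `s = R̂(1 + V·mp/(a·f))` from supply balance.
Other structures fall back to ODE equilibration. Supply-point
classification follows mutual invasibility: no feasible species → `none`;
mutual invasion → `coexistence`; one-way invasion → competitive exclusion;
both feasible but neither invades → `priority_effect`. For three species,
pairwise logic is supplemented by a full assembly simulation whenever at
least two pairs are mutually invasible, because pairwise coexistence does
not guarantee a triple point; a 2D map labels cells from the algebraic
short-circuits and reports classification failures as `unknown` cells
rather than aborting.

The diamond-web thresholds are derived from the single-resident equilibrium
and the invader's zero-growth condition:

    s21 = [(g1−g2)m − mq·mp·g2/f1] / (g1μ2 − g2μ1) · (1 + V1·mp/(a·f1))
    s12 = [(g1−g2)m + mq·mp·g1/f2] / (g1μ2 − g2μ1) · (1 + V2·mp/(a·f2))

valid under μ1 > μ2, g1 ≥ g2, g1μ2 − g2μ1 > 0 (better grower less
defended). They agree with numeric invasion bisection to ~1e−10 relative,
and mq = 0 recovers the classic resource-competition special case. With
g1 = g2 and mq = 0 both numerators vanish and the thresholds degenerate to
zero (no trade-off, no interior window).

## Control formulas

The guild formulas run their sums over the *realized* surviving set: the
implementation predicts, drops species with non-positive predicted density,
and re-predicts until the set is stable (at most n iterations). A negative
prediction marks infeasibility of the assumed coexisting set — it is never
clipped; only the pointwise `N = G/mq` evaluation clips at zero, since it
is a per-species statement. The guild decompositions require uniform mq and
quadratic mortality, and both refuse mq = 0 with a pointer to the classic
equal-growth-rate limit rather than returning infinities. Self-consistent
solvers (`bottom_up_equilibrium`, `top_down_equilibrium`) obtain R̂ or P̂
from scratch — a scalar bracket on the resource balance, or linear
elimination of P — so predictions can be made without running the ODE.

## PDR pipeline and what the generator does (not) emulate

Synthetic communities place n species on an even μ grid with a
deterministic power-law trade-off; predator diets are contiguous windows of
width `ceil(n_prey/n_predators) + overlap` over trait-ranked prey, evenly
started and truncated at the last prey (no wrap-around: the two trade-off
extremes should not share a predator). One predator covering everything is
the diamond limit; one predator per prey is fully specialist predation.
This emulates the *structure* the theory needs — a smooth gleaner–defender
continuum and tunable apparent-competition strength — but not features of
real communities such as trait noise, non-nested diets, omnivory, or
varying yields; conclusions from passing tests are about the mechanism, not
about any particular natural system.

Richness sweeps equilibrate each supply point independently from the common
assembly init and record survivor counts (consumers only; predators are
tracked separately); non-convergent points become NaN, never fabricated
values. Shape classification regresses richness on standardized log₁₀
supply and its square (OLS, α = 0.05): a significant quadratic with an
interior fitted extremum gives Concave−/Concave+, otherwise a significant
linear term gives Linear±, otherwise NS. Two refinements guard the
taxonomy: the observed extreme must itself be interior and beat both
endpoints (a monotone convex rise is a trend, not an anti-hump), and a
constant curve returns NS with a degeneracy flag. Log-supply is the
productivity axis throughout; empirical PDR work often uses standing
biomass as the productivity proxy, a deliberate divergence documented here.

Problem sizes: the test suite and the acceptance script run communities of
30 species over 20 log-spaced supply points on [0.02, 20] — wide enough to
expose both PDR limbs at these trait defaults — and scan predator counts
{1, 2, 5, 10, 30}. The full-scale experiment (100 species, 40 points on
[0.01, 100]) is available through `default_supply_grid` and the CLI. The
location of the unimodal→increasing transition depends on parameterization;
the package asserts its existence and monotonicity, not its exact predator
count.

## Known limitations

* No bifurcation continuation or formal limit-cycle machinery; oscillation
  handling is the windowed heuristic described above.
* Local stability is used only to discriminate ringing from cycling, not
  reported as an analysis product.
* Guild control formulas cover a single shared limiting factor; mixed
  resource-and-predator limitation has no closed form here, and the caller
  chooses which decomposition applies.
* Three-species classification relies on a single assembly init; true
  priority effects among triples would need multiple inits.
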