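# Methods

## The models

`phytovz` implements four nested community models of a phytoplankton
population, its lytic virus and its zooplankton grazer, written in nitrogen
molar currency (μmolN·L⁻¹).  Elemental quotas — Qp per cell, Qv per virion,
Qz per grazer — convert between molar concentrations and the count
concentrations (ind·L⁻¹) that field measurements report; every rate that
moves nitrogen between compartments of different quota carries the
appropriate quota ratio.

The state is `[S, I, V, R, Z]`: susceptible host, infected host, free
virus, resistant host, grazer.  The variants are

* **SVZ** — no infected class: adsorption converts host nitrogen into
  `β` virions instantaneously.  This is the Lotka–Volterra-like baseline;
  with two linear predators of one prey it obeys competitive exclusion.
* **SIVZ** — infections last a latent period `τ` in an explicit `I` class,
  which the grazer also consumes (intraguild predation); lysis of `I`
  releases `β·Qv/Qp` of the cell's nitrogen as virions, the remainder
  leaving as dissolved/particulate lysate split by the shunt fraction `γ`
  (diagnostic fluxes `J_DON`, `J_PON`; no explicit microbial loop).
* **SVRZ / SIVRZ** — add a resistant type `R` coupled to `S` by a mutation
  fraction `r`, with extracellular resistance (reduced adsorption `φR`),
  intracellular resistance (reduced infection probability `εVR`) and a
  growth cost `1 − ζ`.

Shared terms: logistic bottom-up control `−(S+R)/(τK·K)·X` approximating
nutrient limitation with carrying capacity `K`; non-preferential grazing
with clearance `gZ`, gross growth efficiency `εZ` and linear mortality
`dZ`; optional quadratic closure mortalities `dV2·V²` (nonspecific viral
losses) and `dZ2·Z²` (unresolved higher predation).

One transcription choice: in the SVRZ virus balance the adsorption loss
onto resistant cells is `−(φR/Qp)·R·V`, the form consistent with its SIVRZ
counterpart and with mass action.

## Trait layer

Sizes determine parameters allometrically:

* cell quotas from carbon-content allometries (diatoms, other eukaryotes)
  or a fixed cyanobacterial carbon density of 470 fgC·μm⁻³, converted to
  nitrogen by the Redfield ratio 16/106;
* virion quotas from a capsid polynomial in the virion radius (nm) that
  counts nitrogen atoms; dividing by Avogadro's number gives μmolN.  The
  atom-count reading (not a mass) is fixed by requiring published
  count↔molar concentration pairs for marine virions to round-trip;
* grazer quotas from a size-structured carbon allometry over the sphere
  volume of the grazer radius;
* encounter kernels from Smoluchowski diffusive capture with a Stokes–
  Einstein virion diffusivity, multiplied by a host-swimming factor for
  non-diatom eukaryotes (cyanobacteria and diatoms rely on diffusion only);
* maximum growth rates `μmax = a_t·Vol^b` with the cyanobacterial slope
  positive (+0.08) and the diatom/picoeukaryote slope negative (−0.08);
* half-saturation constants `Nc = Hc·μmax·Qmin/Umax`;
* environments modulate growth by `N/(N+Nc)` and growth plus all
  mortalities (`dS`, `dV`, `dZ`, both quadratic terms — but not adsorption,
  latent period or burst size) by an Eppley temperature factor, and replace
  `K` by the resource–consumer equivalence `w(Ndeep−N)(N+Nc)/(μT·N)`.

### Parameter provenance

Grazing parameters (`gZ` = 9.8 (μmolN/L)⁻¹d⁻¹, `εZ` = 0.3, `dZ` =
0.067 d⁻¹, reference `dZ2` = 1.4), the reference cyanophage life history
(β = 15, τ = 0.37 d) and the capsid/carbon allometries are literature
values.  Constants not printed in available sources are package defaults
chosen once, at realistic magnitudes, and exposed in
`src/phytovz/data/*.yaml` (marked PLACEHOLDER):

* organism sizes and virion radii were chosen so that the derived
  encounter kernels match independently reported encounter/resistance
  ratios for each host class (e.g. ~2.2×10⁻⁹ L·d⁻¹ for the
  *Prochlorococcus*-class host with a 35 nm virion);
* the default viral decay `dV` = 0.06 d⁻¹ is bracketed (0.054–0.063) by
  the adsorption rate at which the instantaneous-burst model exchanges its
  surviving predator, a boundary the reference regime maps pin between
  1.0×10⁻¹⁰ and 1.167×10⁻¹⁰ L·d⁻¹;
* the default carrying capacity `K` = 1.0 μmolN·L⁻¹ (with `τK` = 1 d) is
  fixed by three qualitative anchors of the reference dynamics: system
  collapse at (φS = 10⁻⁸ L·d⁻¹, τ = 0.37 d), grazer exclusion at
  (10⁻⁹, 0.37), and an oscillatory coexistence band passing through
  (≈1.6×10⁻¹⁰, τ = 0.2);
* `dS` = 0.1 d⁻¹, `r` = 10⁻⁷, `γ` = 0.5, resistance cost 0.2 and the
  uptake allometry surrogates are plain placeholders.

A derived-constant audit block is stored in the organism config; tests
regenerate it bit-for-bit from the trait layer, so the YAML can never
drift from the code.

## Numerics

**Integration.** Classical fixed-step RK4 with a 30-minute step, 20 model
years by default (25 for the instantaneous-burst exclusion runs, which
approach exclusion slowly).  Compartments are clipped at zero after each
full step; clip events are counted on the trajectory.  The inner loop is
JIT-compiled (numba).  Known limitation: at the most extreme adsorption
rates the host crash in the instantaneous-burst model legitimately
under-runs double precision within one oscillation, so the virus (and
sometimes the whole system) registers as excluded where a milder
parameterisation would retain it.

**Existence and oscillation.** A compartment is present when its count
concentration exceeds 1 ind·L⁻¹ at any sample of the final year (a `mean`
mode is available).  Oscillation is flagged when the amplitude spectrum
(2|FFT|/n, DC removed) of the raw final-year virus count series exceeds
1 ind·L⁻¹.

**Equilibria.** The steady-state catalogue (5 classes for SIVZ, 11 for
SIVRZ including δ-states at trace abundance) is evaluated
semi-analytically: host-only, host–grazer and host–virus states in closed
form; interior states by damped Newton on a reduced two-unknown (S, Z)
system in which the virus balance fixes V and the infection balance fixes
I; the resistant-type catalogue by multistart root-finding on the full
five-dimensional system with class-biased deterministic seeds (S-dominant,
R-dominant via a mirrored problem, and mixed-host seeds).  Every returned
state must pass a right-hand-side residual check (≤10⁻⁹ for feasible
states); stability is the spectral abscissa of the analytic Jacobian,
cross-checked against central finite differences in the tests.  The
δ-threshold for "trace abundance" is 10 ind·L⁻¹ (configurable).

**Invasion analysis.** Mutual invasibility (Chesson) treats the virus as
the coupled (I, V) subsystem.  The grazer's invasion growth rate is the
trapezoid time-average of its per-capita growth (with Z → 0) over one
detected cycle of S in the host–virus resident — peaks found with
`scipy.signal.find_peaks` at 5 % prominence of the series range, falling
back to the final year for steady residents.  The virus's invasion rate on
the host–grazer resident is the dominant Floquet exponent of the
periodically forced linear (I, V) system (log spectral radius of the
monodromy matrix over one cycle), which reduces exactly to the frozen
Jacobian eigenvalue for a steady resident (the usual case: that resident
is a stable node).  Ten replicates randomise resident initial conditions
log-uniformly over ±1 decade (seeded); a replicate whose host–virus
resident collapses fails, and a parameter point is "not assessable" only
when all replicates collapse.

**MCT decomposition.** Each predator's growth rate is expressed as a
function of the fluctuating resources: the grazer's is linear in S + I, the
virus's is the frozen-environment dominant eigenvalue of its (I, V)
subsystem, a nonlinear (concave) function of S.  The fluctuation-free term
freezes resources at cycle means; nonlinearity-in-X terms let one resource
fluctuate at a time; an interaction term closes the budget exactly.
Relative components are invader minus resident.  For the linear grazer the
nonlinearity terms vanish identically (Jensen equality), so its negative
fluctuation-free relative growth inside the coexistence band is compensated
entirely by the virus's negative response to S fluctuations — the relative
nonlinearity in S.

**Fitting.** The grid search scores the algebraic interior equilibrium of
the infected-class model (never simulations) in each environment, for every
combination of adsorption rate, intracellular resistance, resistance cost,
and the three mortality parameters, using a vectorised damped-Newton solve
across all combinations at once.  Combinations are discarded unless the
equilibrium is feasible, locally stable and passes the ecological screen
(infected-cell percentage within the environment's closed interval, 0–50 %
virus-induced mortality, virus:phytoplankton count ratio above one); the
survivors are ranked by the weighted mean over environments of the total
absolute relative error to the target counts.  Resistance summary
statistics use product–moment correlation on log10-transformed factors,
since they span orders of magnitude.

## Synthetic data

The scenario layer generates everything the test-bench needs: planted
target sets taken from a known stable coexistence equilibrium (optionally
with seeded log-normal noise; constraint bounds widened to admit the
truth), and analytic toy trajectories (constant, sinusoid, and a neutral
Lotka–Volterra cycle integrated independently at high accuracy) for the
Fourier, peak-detection and quadrature fixtures.  These fixtures emulate
idealised, noise-free population dynamics; they contain none of the
measurement error, transients or spatial structure of real field series,
so passing tests demonstrate correctness of the machinery, not field
realism.

## Problem sizes used in the shipped analyses

The acceptance script builds the regime map at 40×40 log-spaced cells over
φS ∈ [10⁻¹², 10⁻⁸] L·d⁻¹ and τ ∈ [0.1, 30] d with full 20-year runs, and
runs the 10-replicate invasion analysis on every simulated-coexistence
cell (a few minutes on one core).  The in-suite regime checks use a 16×12
grid; grid resolutions are arguments everywhere.

## Known limitations

* Constants without a printed source (environment factors, several default
  rates) are placeholders; the equilibrium fit therefore reproduces the
  *structure* of the published best-fit resistance pattern (anticorrelated
  extracellular/intracellular resistance, low best-fit viral decay,
  grazer quadratic mortality above its reference value) but not its exact
  numbers.
* Invasion growth rates are nearly replicate-invariant here because
  residents converge to their attractors well within 20 years; analyses
  whose replicate spread matters should shorten the resident runs or
  enlarge the initial-condition spread.
* No bifurcation tracking: oscillation onset is detected empirically, not
  located analytically.
* The mutation fraction only couples S and R linearly; no evolution of
  resistance strength.
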