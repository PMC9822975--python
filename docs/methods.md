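# Methods

`channelphys` analyzes two-electrode voltage-clamp (TEVC) recordings of
proton-gated DEG/ENaC-family channels expressed in *Xenopus laevis* oocytes,
plus the count/time statistics of cnidocyte-discharge and prey-capture
assays. This note documents the models, the defaults and why they were
chosen, the numerical details, and what the synthetic-data generator does
and does not emulate.

## Ion activities (solutions)

Bench recipes are expanded to fully dissociated ions (1.8 mM CaCl₂ → 1.8 mM
Ca²⁺ + 3.6 mM Cl⁻). Ionic strength is I = ½ Σ cᵢzᵢ² with concentrations
converted from mM to molar. Single-ion activity coefficients use the Davies
equation, log₁₀ fᵢ = −0.509 z² (√I/(1+√I) − 0.2 I); for a single ion the
two-ion valence product z₁z₂ reduces to z², the standard single-ion
convention. The 0.509 constant is fixed; its temperature dependence is not
modeled, nor are extended Debye–Hückel/Pitzer corrections or
liquid-junction potentials — the Davies form is adequate to I ≈ 0.5 M and
all shipped recipes sit near 0.15 M.

Buffers and chelators (HEPES, MES, EGTA, PVP) are neutral components and do
not enter I by default; their ionization state is rarely stated on bench
recipes, and a user who knows the ionized fraction can list that fraction
as an explicit ionic species instead. Proton activity is always 10^(−pH)
molar and is never Davies-corrected, because pH already reports an
activity. NMDG⁺ is treated as fully protonated (+1) at pH 7.4. Recipes
that omit the counter-ions of pH titrants commonly carry a small charge
imbalance; compositions warn above 1 mM net charge rather than fail.

The shipped `data/solutions.yaml` holds the standard bath (140 NaCl /
1.8 CaCl₂ / 1.0 MgCl₂ / HEPES, pH 7.4; I = 0.1484 M), its MES-buffered
acidic variants, the Na⁺ and Ca²⁺ bi-ionic selectivity solutions
(I = 0.143 M and 0.1565 M), and OR-2 storage medium. The K⁺ bi-ionic
recipe is the Na⁺ recipe with KCl substituted mole-for-mole — a
conventional choice, flagged as such in the file.

## Response amplitudes (recordings)

Current is µA with inward current negative. For each ligand-application
window: baseline is the **median** over the 2 s preceding the window
(median, not mean, for robustness to noise spikes); the peak is the sample
with the largest absolute deviation from baseline (sign-aware without a
hard-coded polarity); the sustained level is the mean over the final 25% of
the window, by which time solution exchange and desensitization have
settled under all default kinetics. A response is classified *biphasic*
(fast transient relaxing onto a plateau) when transient/sustained amplitude
ratio ≥ 1.5 **and** the peak falls in the first 20% of the window; both
thresholds are configurable, and the late-peak guard keeps slowly
developing monophasic currents from being misread as transients. Whether
dose–response points use peak or sustained amplitude is the caller's
choice; sustained is the right default here because desensitizing acidic
steps otherwise double-count the transient.

The 20 Hz acquisition filter is a property of the recording (and of the
simulator), not of the analyzer: measured data arrive already filtered, so
the analysis never re-filters.

## Reversal potentials and permeability ratios (selectivity)

Ramp currents (−70 → +60 mV in 6 s) are corrected for background
conductances by subtracting the pH 7.4 control ramp from the same cell;
the control is linearly interpolated onto the test grid (≥ 50 mV overlap
required). The first 2% of each ramp is discarded to clear the capacitive
onset. Erev is located on a 5-sample moving-average copy (suppressing
noise-induced spurious crossings) but always interpolated linearly between
the two **raw** bracketing samples; when several crossings survive
smoothing, the one nearest the zero of a least-squares line through the
whole curve is used. On any noiseless monotone curve this is exact to
within half the grid spacing.

Permeability ratios follow the GHK voltage relations,

    P_Na/P_K  = (a_K,o / a_Na,o) · exp(ΔErev·F/RT),      ΔErev = E_Na − E_K
    P_Ca/P_Na = a_Na,o (1 + exp(E_Ca·F/RT)) / (4 a_Ca,o exp(ΔErev·F/RT))

with F = 96485.332 C/mol, R = 8.314462 J/(mol·K), default T = 293.15 K
(room temperature; RT/F ≈ 25.26 mV). External concentrations enter as
Davies activities by default, with a documented toggle to nominal
concentrations: for the monovalent ratio with symmetric 140 mM solutions
the coefficients cancel, but for the divalent ratio the two conventions
differ by more than a factor of two, and published divalent ratios often do
not state which was used. The 1 mM Ca²⁺ in the Na⁺ bi-ionic solution is
treated as negligible on the Na side. Whole-curve GHK fits and multi-ion
Eisenman analysis are out of scope.

## Hill fits (dose_response)

Activation: R = R_max·cⁿ/(cⁿ + EC50ⁿ); inhibition (partial block):
R = R_top·[f_res + (1−f_res)/(1 + (c/IC50)ⁿ)], with f_res ∈ [0,1] the
residual unblocked fraction (pinnable to 0 for full block) and R_top a free
top amplitude that absorbs the normalization error arising when the lowest
tested blocker concentration already blocks slightly. Proton data are
fitted in [H⁺] space and reported additionally as pH50 = −log₁₀ EC50.

Each replicate (oocyte) is normalized to its own maximal absolute response
and fitted independently (Levenberg–Marquardt via lmfit); parameters are
then summarized as mean ± S.D./S.E.M. across replicates, so reported
spreads include biological variance. The half-maximal constant is optimized
as log₁₀(c₅₀), initialized by log-interpolating the stimulus bracketing the
half-maximal response; the Hill coefficient is bounded to (0.1, 10] and
initialized at 1. Data whose rank correlation with concentration runs
against the requested direction are flagged non-converged and excluded from
the summary with a warning — the Hill family is monotone, so such fits are
meaningless rather than merely poor. Kinetic desensitization modeling and
global multi-condition fits are out of scope.

## Assay statistics (behavior_stats)

Discharged-capsule counts per imaged area are compared with the classical
parametric toolkit at α = 0.05: equal-variance unpaired Student's t
(Welch behind a flag), one-way ANOVA from the textbook sums of squares, and
Bonferroni (pairwise t × number of pairs, capped at 1) or Tukey–Kramer
(studentized-range on the ANOVA's within-group mean square) pairwise
comparisons. The statistics are authored here rather than delegated so they
can be validated against an independent reference implementation; the tests
require agreement with scipy to 10⁻⁶ and the F = t² identity for two
groups. Zero-variance degenerate groups report p = 1 with a warning rather
than failing. The discharge pipeline is *protected*: pairwise comparisons
run only when the omnibus ANOVA rejects, which is also how its type-I error
is calibrated (≈ α under the null simulator). Counts can optionally be
normalized to a common reference area (density × 10⁴ µm²) before testing;
Poisson GLMs and survival analysis of capture times are deliberately out of
scope, matching the ANOVA-on-counts practice of the assays it serves.

## Synthetic data (synthetic_data)

The generator produces every input format the analysis reads, with known
ground truth.

**Step currents.** Proton activity at the membrane relaxes exponentially
to the bath value (solution-exchange τ = 0.5 s, pump-driven bench
exchange); open probability is Hill([H⁺]) (default pH50 5.8, n = 1) times
a desensitization gate d(t) that relaxes (τ_d = 1 s) to a steady state
d∞(pH): 1 at pH ≥ 5.5 (onset), declining linearly to 0.3 at pH 4.0. This
single-exponential-to-a-floor form is an explicit stand-in — it reproduces
the phenomenology the classifier must detect (monophasic responses at
moderate acidity, biphasic below the onset, sustained component shrinking
with acidity) without claiming measured kinetics. Current is
g_max·P_open·(V_h − E_rev) with g_max = 50 µS and E_rev = +40 mV at
V_h = −70 mV, giving µA-scale inward currents typical of strongly
expressing oocytes. An optional CaCC contamination transient (amplitude
scaled by how far the channel opens) is added at application onset and is
suppressed exactly by the EGTA toggle, mirroring chelator-injected control
cells. Gaussian noise (S.D. 0.02 µA) is added and the trace is causally
low-pass filtered (4th-order Butterworth, 20 Hz) to match 1 kHz/20 Hz
bench acquisition.

**Ramp currents.** Per-ion GHK constant-field fluxes (valence-2 term for
Ca²⁺) summed over the voltage command, plus linear leak (1 µS to −20 mV)
and filtered noise; internal milieu defaults to oocyte-typical placeholders
(Na⁺ 10, K⁺ 110, Ca²⁺ 10⁻⁴ mM — configurable, as true values are cell-
dependent). The GHK family is chosen because the permeability-ratio
equations above are its exact consequences: the noiseless simulated Erev
equals the GHK voltage-equation closed form, so the full pipeline
(subtract → Erev → ratio) recovers specified ratios exactly, and with
bench-like noise to within a few percent. The acquisition filter is linear,
so leak subtraction still cancels exactly and its group delay shifts both
bi-ionic Erevs equally, leaving ΔErev unbiased.

**Tables.** Dose–response tables place replicate amplitudes on a Hill
curve with lognormal per-oocyte expression scaling (σ = 0.3) and 5%
multiplicative noise by default. Discharge counts are
Poisson(mean × area/10⁴ µm²) with lognormally varying imaged areas;
capture times are the sorted order statistics of three lognormal draws per
animal (right-skewed, ordered first ≤ second ≤ third).

What the simulators do **not** emulate: Markov single-channel gating,
temperature-dependent kinetics, realistic CaCC Ca²⁺ dynamics, series-
resistance and space-clamp artifacts, drift/rundown, and overdispersion of
counts beyond Poisson. Passing tests therefore demonstrate that the
analysis recovers the parameters of data satisfying its own model
assumptions at realistic noise — not that those assumptions hold for any
particular bench dataset.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded per call;
identical seeds give bit-identical outputs, and the ramp test/control pair
derives independent streams from one seed. The validation suite uses
problem sizes chosen to make the statistical checks sharp at desk scale:
1000 random monotone curves for the Erev estimator, 50 seeded noisy ramp
round trips, 100 simulated 9-replicate dose–response experiments, 100
random datasets for reference-implementation equivalence, and 2000 null
simulations for type-I calibration of the discharge pipeline.
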