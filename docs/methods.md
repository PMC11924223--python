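# Methods

## The model

`evbkit` analyzes a chemical reaction in the empirical valence bond (EVB)
picture. A reaction step is described by two (or three) *diabatic* states —
fixed bonding arrangements such as "ATP + neutral Tyr + Asp⁻" (reactant),
"ADP + metaphosphate + TyrOH" (intermediate) and "ADP + phosphotyrosine +
AspH" (product) — each carrying its own potential surface. The adiabatic
ground surface is the lowest eigenvalue of a small Hamiltonian whose
diagonal holds the diabat energies plus per-state *gas-phase shifts*
α<sub>i</sub> and whose off-diagonal holds the *couplings* H<sub>ij</sub>:

    E_g(x) = lowest eigenvalue of  [ ε_i(x) + α_i   on the diagonal,
                                     H_ij           off the diagonal ]

α sets the relative energetics of the states (hence the reaction free
energy); H mixes the states at their crossing (hence lowers the barrier).
These two constants per reaction leg are the *only* fitted quantities in an
EVB parametrization; everything else is the diabatic surfaces.

In the package the configurational coordinate x is one-dimensional and
dimensionless, and diabats are harmonic, ε(x) = ½f(x−x₀)² + c, with an
optional quartic term. Two equal-f parabolas displaced by d give the
standard Marcus phenomenology with reorganization energy λ = ½f·d²: a
crossing (uncoupled barrier) at (λ+ΔG⁰)²/4λ above the reactant minimum, and
coupling that cuts ≈H off the top. This is the minimal structure that
supports every estimator downstream; it deliberately replaces the all-atom
enzyme/solvent surfaces of a production EVB study, which are outside this
package's scope.

Sign conventions. The reaction coordinate is the **energy gap**
Δε(x) = (ε_i+α_i) − (ε_j+α_j) for the driven pair — the standard EVB choice,
because it is well defined for any system that has diabat energies. Positive
gap means the second state lies below the first; the reactant basin sits at
negative gap. Energies are kcal/mol throughout, with
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and k_B/h = 2.0837×10¹⁰ s⁻¹ K⁻¹ pinned in
`constants.py`.

Three-state (dissociative) reactions are treated as two sequential
two-state legs, each diagonalized as a 2×2 problem; a full 3×3
diagonalization is available in `evb.adiabatic_ground(..., active="all")`
but is not the default, since the dissociative path never invokes direct
reactant–product coupling (H₁₃ = 0).

## Surrogate sampling

The synthetic-data stage replaces molecular dynamics with overdamped
(position) Langevin dynamics on each window's *mapping potential*
ε_m = Σ λ_i (ε_i + α_i):

    x ← x − βD ε_m′(x) dt + √(2D dt) η,  η ~ N(0,1)

whose stationary density is the Boltzmann distribution of ε_m. Only the
configurational distribution matters to the FEP and umbrella-sampling
estimators, so inertial dynamics would add a parameter without adding
information. For purely harmonic topologies the drift is linear and the
whole window is generated as a first-order linear recurrence
(`scipy.signal.lfilter`), which makes a full 101-window replicate cost a
few tens of milliseconds; quartic states fall back to an explicit step
loop.

Defaults (all overridable in `SamplerParams`): T = 300 K, D = 1,
dt = 2.5×10⁻⁴, 2 000 steps per window with the first 10 % discarded as
equilibration, divergence guard at |x| > 50. With the stiffest preset
diabat (f = 200) this puts βDf·dt ≈ 0.084, giving a stationary-variance
discretization bias of ~2 % — visible as a ≲0.1 kcal/mol end-to-end FEP
bias on the benchmarks, well inside the replicate noise. The per-window
length is a desk-scale choice; production EVB runs use a few thousand MD
steps per window at far higher cost per step.

Seeding is splittable: every window draws from
`SeedSequence([master_seed, replicate, leg, window])`, so adding replicates
or windows never perturbs existing streams, and each replicate emulates an
independent trajectory started from freshly randomized velocities.
Optional per-replicate jitter (`jitter_sd`, default 0) adds a normal offset
to each non-reference diabat constant, emulating the conformational
heterogeneity that makes enzyme replicate ensembles broader than solution
ones; the enzyme presets set it to 0.5 kcal/mol, which reproduces
replicate-to-replicate barrier spreads of ~0.4–0.6 kcal/mol, the same
order as the SEMs reported for ensemble EVB studies of this kind. What the
generator does **not** emulate: conformational substates with slow
exchange, anharmonic solvent response, multi-dimensional reaction
coordinates, or any structural realism — a passing test shows the
*analysis chain* is correct, not that a real kinase behaves this way.

## FEP accumulation

Windows follow a λ schedule from the initial to the final state: 101
uniform windows (0.01 increments) for a dissociative leg; for the
associative (concerted) mechanism 30 extra windows are merged in, spaced
linearly in the open interval (0.3, 1.0), for 131 total. The interval
reading — equally spaced interior points of (0.3, 1) merged into the base
grid — is one of several possible placements of the "extra windows beyond
λ = 0.3" and is fixed here; duplicates after the merge raise an error
rather than being silently dropped.

Adjacent windows are bridged by the forward Zwanzig estimator

    ΔG(m→m+1) = −(1/β) ln ⟨ exp(−β(ε_{m+1} − ε_m)) ⟩_m

evaluated with a max-shifted log-sum-exp. Increments whose effective sample
size falls below 10 log a warning but do not abort. A bidirectional average
is available behind a flag; the default is forward-only, matching a
sequentially driven protocol. Because ε depends on α only through the
per-state shifts, a post-hoc change of α moves the end-to-end total
*exactly* linearly (telescoping identity) — this is what makes calibration
cheap and exact in the ΔG⁰ direction.

## Umbrella-sampling profiles

The free-energy profile along the gap is reconstructed by reweighting every
frame onto the adiabatic surface, anchored by the FEP window free energies.
With occupancy weighting (windows weighted by their frame count in each
bin) the estimator collapses to a single per-bin average:

    ΔG(X) = −(1/β) ln [ (1/N(X)) Σ_{frames in X} exp(−β(ΔG_m + E_g − ε_m)) ]

computed entirely in log space with per-bin max shifts (reweighting
exponents of several hundred β-units occur routinely and are safe).
Occupancy weighting is the simplest standard choice; the original
post-processing programs do not publish their exact window weights, and
the difference is second-order for well-overlapped windows.

Numerical choices: 200 uniform bins over the observed gap range, ≥ 25
frames to report a bin (masked otherwise, never interpolated); feature
detection (minima/barrier) on a 3-bin moving average, with reported values
taken from the **unsmoothed** bins — smoothing is for locating extrema
only, because a 3-bin average measurably flattens the cusp-shaped maximum
of an uncoupled (H = 0) crossing. Profiles with fewer than ~15 valid bins
skip the smoothing entirely. Barrier ties are broken toward the bin
nearest gap = 0. A profile whose populated bins do not contiguously cover
the crossing raises an undersampling error naming the gap range. Uncoupled
cusp benchmarks in the test suite pass finer bins (400–800) where the
default width would add a resolution artifact comparable to the quantity
under test. Fully degenerate profiles (identical diabats → gap ≡ 0)
collapse to a flat single-bin profile with all-zero features, which makes
the null-perturbation control well defined.

Leg profiles are joined by rigidly shifting the second leg so its reactant
(intermediate) minimum continues at the first leg's product free energy —
the same construction used to present two-step profiles with a shared
baseline. The composite barrier is the global maximum relative to the
leg-1 reactant minimum.

## Calibration (reference-reaction parametrization)

The reference ("water") reaction anchors the EVB model to experiment:

* activation free energy 27.9 kcal/mol — from the ATP⁴⁻ methanolysis rate
  3.4×10⁻¹⁰ s⁻¹ M⁻¹ via Eyring (30.3 kcal/mol at 1 M, 298.15 K) minus the
  RT ln 55 = 2.4 kcal/mol standard-state correction to contact
  concentration;
* the metaphosphate intermediate parametrized 0.5 kcal/mol below the
  profile maximum (the transient intermediate is experimentally
  inaccessible; placing it just below the maximum is the standard technical
  approximation for a species at the stationary point);
* total reaction free energy 0.6 kcal/mol, from the cycle −9 kcal/mol (ATP
  hydrolysis) + 9.6 kcal/mol (≈7-unit pKa gap between the donor and
  acceptor side chains, ln 10·RT·ΔpKa);
* the second dissociative leg constrained so the composite second maximum
  matches the first (own-frame barrier 27.9 − 27.4 = 0.5 kcal/mol, leg
  ΔG⁰ = 0.6 − 27.4 = −26.8 kcal/mol). Exact equality of the two maxima is
  used; the source protocol states only "similar heights".

Fitting is **post hoc**: stored trajectories keep per-frame diabat
components and the α vector in force at sampling time, so new (α, H)
re-shift the energies, re-accumulate FEP and re-profile without
resampling. The sampling distribution remains that of the provisional
parameters — the standard approximation of EVB post-processing; it makes
the fit deterministic, and the preset provisional values sit close to the
calibrated fix point so the residual approximation error is small. The
solver is a damped two-variable Broyden iteration on
(ΔG‡ − target, ΔG⁰/offset − target), started from α implied by the target
ΔG⁰ (near-exact by linearity) and H = 0, with a finite-difference initial
Jacobian, step cap of 8 kcal/mol, H clipped at 0, and a 0.05 kcal/mol
convergence tolerance; non-convergence returns best-effort parameters with
`converged=False` instead of raising. The fitted quantities are the
**ensemble means** of the replicate profile features (the reference
protocol parametrizes on the whole trajectory ensemble, and single-profile
features carry ~0.5 kcal/mol of bin-level noise that the ensemble mean
suppresses).

Transferability: parameters fitted on the water presets are installed
unchanged on the enzyme presets by `transfer_parameters` — enforced by the
pipeline and checked by a checksum of the parameter block. In the
surrogate, scenario-to-scenario catalytic differences therefore live
entirely in the diabat offsets/displacements (standing in for the enzyme
environment's effect on the diabats), never in per-scenario α or H.

## Scenario presets

`water_dissociative` (two legs, calibration targets attached, n = 10) and
`water_associative` (one leg, targets 27.9/0.6, n = 10) are the reference
scenarios. The five `enzyme_*` presets are *named parameter presets, not
structural models*: harmonic diabats with f = 200, displacement 1.0
(dissociative family, λ = 100) or 1.1402 (associative family, λ = 130),
and offsets c₂ solved on the adiabatic surface so that, under the
water-fitted parameter block, the barriers land near the qualitative
emulation targets (Site I ≈ 9, dissociative-initial ≈ 15.7, associative ≈
17.3, two-Mg ≈ 20.5, Site II ≈ 26.9 kcal/mol), reproducing the catalytic
ordering Site I < dissociative-initial < associative < two-Mg < Site II ≈
water. The printed enzyme barriers of the original all-atom study are
ordering targets only; nothing at desk scale can (or should) reproduce
their absolute values, which encode all-atom energetics. Enzyme presets
run n = 30 replicates with offset jitter 0.5; the replicate counts are a
desk-scale stand-in for the >100-trajectory protocol of production
studies.

## Ensemble statistics and rates

Per replicate, the activation free energy is read off the (composite)
profile. The ensemble summary implements the reported procedure exactly:
sort the barriers, keep the lowest max(1, ⌊fraction·n⌋) (fraction 0.10 by
default; floor with a minimum of one handles n not divisible by 10; ties
at the boundary include the earlier replicate), report their mean, SEM and
SD (ddof = 1, over the selected subset) plus the single lowest barrier.
This selection is a *procedure*, not an unbiased estimator — selecting the
low tail deliberately biases toward barriers the fastest-reacting
conformations see. Rates follow from Eyring,
k = κ(k_BT/h)exp(−ΔG‡/RT), with κ = 1 and T = 300 K on the simulation
side; experiment-side conversions default to 298.15 K, the temperature
consistent with the published rate↔barrier arithmetic (300 K would give
30.6 rather than 30.3 kcal/mol for the methanolysis anchor).
Pseudo-second-order experimental constants (s⁻¹ M⁻¹) are treated as
effective first-order at the 1 M standard state before conversion.
Replicates that fail are excluded with a logged count; a run aborts if
more than 10 % fail.

## Known limitations

* The 1-D harmonic surrogate cannot probe mechanistic discrimination in a
  real system; it validates the estimators and the protocol.
* Forward-only Zwanzig carries the usual finite-sampling bias (positive in
  each increment, ~0.01 kcal/mol over 100 windows at default lengths), and
  the Euler–Maruyama discretization adds a ~2 % effective-temperature bias;
  both are far below replicate noise at the preset scale.
* Profile feature values inherit per-bin noise (~0.3–0.5 kcal/mol in basin
  bins at default sampling); ensemble means, not single profiles, are the
  quantitative outputs.
* The calibration fit targets the empirical estimator, so fitted H absorbs
  small estimator biases; parameters are transferable *within* the package
  between scenarios sharing the estimator settings, which mirrors how EVB
  parametrizations are transferable between simulations sharing a
  protocol.
* The final proton transfer from the aspartate to the phosphotyrosine is
  not modeled anywhere in the chain (thermodynamically downhill
  bookkeeping only), and no attempt is made to model magnesium ions,
  solvent or protein structure explicitly.
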