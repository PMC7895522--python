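# Methods

This note records the models behind each analysis stage, the parameter
choices and their rationale, the design decisions taken where the
underlying protocol is genuinely open, and what the synthetic generators
do and do not emulate.

## Units and geometry conventions

Internal units are fixed: lengths in nm, times in ns, pressures in bar,
energies in k_BT at the configured temperature (default 310 K,
k_BT = 4.28×10⁻²¹ J). Readers convert on ingest (LAMMPS dumps default to
Å, MDAnalysis reports Å and ps), so a single conversion boundary exists.
Coordinates are stored wrapped into the primary orthorhombic box; every
distance uses the minimum-image convention, and any cutoff at or above
half the smallest relevant box edge raises an error rather than silently
producing ambiguous neighbor assignments.

A molecule's position is the unweighted mean of its bead coordinates after
minimum-image unwrapping of the molecule around its first bead. The choice
of a molecular reference point for TG–TG and TG–PL distances is not
uniquely determined by the protocol these analyses implement; the mean
position is the default because it is symmetric and stable under bead-count
changes, and the frame API keeps the bead-level coordinates available for
callers who prefer minimum inter-bead distances.

## Lens detection and nucleation kinetics

A TG aggregate is a single-linkage cluster: two TG molecules belong to the
same lens candidate iff they are connected by a chain of pairwise distances
≤ 3.5 nm. Clustering runs on a periodic KD-tree plus sparse connected
components; its contract is *exactness*, gated in the tests by a dense
all-pairs union-find oracle, not approximation speed.

A formation event requires a cluster of ≥ 25 TG at every sampled frame of
a 5 ns window, with cluster identity across frames resolved by maximal
membership overlap. This is the strictest reading of "stable": a single
frame below threshold inside the window resets the candidate. Frame
spacing must not exceed the persistence window, otherwise the criterion is
untestable and the configuration is rejected.

The nucleation rate over replicas is k = 1/⟨t_form⟩ with the error
σ_k = σ_t/⟨t⟩² by first-order propagation (σ_t = sample SD). Replicas with
no event inside the scheduled run (1.5 µs) are censored; a fully censored
condition reports k = 0 with error 1/T_total. When censoring is mixed,
censored replicas are imputed at the horizon, making the rate an explicit
lower bound (flagged in the estimate). The alternative replica averaging —
mean of inverse times — is available behind a switch; the default inverts
the mean time. The estimator 1/⟨t⟩ is biased at small n
(E[1/⟨t⟩] = nλ/(n−1), i.e. 1.5 λ at n = 3 for exponential waiting times);
the package documents and tests this sampling law rather than "correcting"
it, because the three-replica protocol it mirrors uses the plain inverse.

Relative nucleation energies use k = τ₀⁻¹ exp(−E/k_BT), so
E/k_BT = −ln(k τ₀), reported as E(composition)/E(reference). The attempt
time τ₀ is not determined by rate measurements alone; the default is 1 ns
and `tau0_sensitivity` reports the ratio across a τ₀ grid so the
dependence is visible instead of hidden.

## Diluted-TG equilibrium

Per frame, TG molecules partition into three disjoint classes:

* **lens** — within 5.0 nm of another TG *and* farther than 2.8 nm from
  every PL;
* **diluted** — non-lens TG at least 2.5 nm (the lens margin) from every
  lens TG;
* **boundary** — the remaining rim TG, excluded from numerator and
  denominator because they exchange continuously with the lens.

The reported concentration is always 100·N_TG,diluted/N_PL,lens-free —
a TG/PL ratio, never mol% of total lipid. With molecule-mean positions the
PL lens-margin test is implied by the 2.8 nm lens criterion (a PL within
2.5 nm of a lens TG would have disqualified that TG), so the margin is
binding only for the TG classes; it is still applied to PLs verbatim so
that bead-level or user-modified cutoffs behave correctly. The denominator
counts PL species only by default; a flag includes DAG and sterols.

Equilibrium statistics average the per-frame percentage over a trailing
1.5 µs window (configurable, including explicit (t₀, t₁) windows for
pre/post-injection comparisons), then take mean and sample SD across
replicas. A stationarity warning fires when the two half-window means
differ by more than 2 SD. Dissolution detection requires permanence: the
dissolution time is the first frame after the *last* frame containing a
≥ 25-TG aggregate, so transient dips below threshold do not count.

Lens extents are per-axis max − min of the lens TG coordinates after
unwrapping the lens around its own center, so a lens straddling a periodic
boundary measures correctly.

## Pressure-profile mechanics

Conventions: P_T = (P_xx+P_yy)/2, P_N = P_zz, π(z) = P_T − P_N, midplane
at z = 0. Tables are re-centered on load using the midpoint of the two
deepest π(z) minima (the bilayer symmetry point); featureless profiles
fall back to the grid midpoint. Stress·volume tables convert via
P = −S/V_slab.

π_CH integrates max(π(z), 0) between the glycerol minima with Simpson's
rule on a 0.001 nm (0.01 Å) grid, after cubic-spline interpolation of the
tabulated profile; minima are auto-detected as the deepest local minimum
on each side of the midplane, with manual override. 1 bar·nm = 0.1 mN/m.
On smooth analytic fixtures this reproduces closed forms to better than
10⁻⁶ relative; the only error sources are the spline (exact at table
nodes) and the O(h⁴) Simpson remainder.

The leaflet first moment is κ_b c₀ = −∫₀^{L_z/2} z π(z) dz, mirrored with
matching sign for the lower leaflet so mirror-symmetric profiles give
equal leaflet values; the asymmetry is reported. c₀ follows from κ_b
expressed in mN/m·nm² (1 k_BT at 310 K = 4.28 mN/m·nm²), and the
curvature stress is κ_b c₀² in k_BT/nm². The monolayer modulus is taken as
half the bilayer modulus fitted from fluctuations — a declared convention,
overridable, since monolayer-resolved fluctuation fits are outside this
package's scope.

Height fields bin reference beads (role "glycerol" by default) per leaflet
on a lateral grid; empty cells are filled from the nearest occupied cell
and counted, with an error above 20% empty. The Fourier bending modulus
uses ⟨|h_q|²⟩ = k_BT/(A κ q⁴) under the convention h_q = FFT(h)/N². The
estimate is the fixed-slope (−4) least-squares fit over modes in the first
four nonzero q-shells capped at 1 nm⁻¹ (equivalently the geometric mean of
per-mode κ_q = k_BT/(A q⁴ S_q)); the free-slope log–log fit is returned
purely as a diagnostic of spectral shape. Flat fields are flagged as
having no measurable undulation instead of returning a number.

The real-space estimator block-averages each frame into b×b patches and
compares the variance of patch means against the exact discrete-mode
Helfrich prediction Σ_q S(q)|D_b(q_x)D_b(q_y)|², where D_b is the
Dirichlet-kernel window of a b-cell average. Because the prediction scales
as 1/κ, each patch size yields an estimate and the geometric mean is
reported. Computing the normalization analytically at runtime replaces a
stored calibration constant: it is exact for the generator's ensemble and
removes a hidden dependency on the calibration grid. Patch variance must
decrease with patch size for a q⁻⁴ spectrum (the retained long-wavelength
modes dominate); a violation warns and rejects the fit. This estimator is
a validated stand-in for real-space deformation analyses in the
literature, not a reconstruction of any specific published scheme.

## Enrichment maps

Density maps are time-averaged molecule counts per lateral cell divided by
cell area, optionally recentered per frame on the lens centroid (computed
with circular means so boundary-straddling lenses work). Enrichment is
[ρ_X/(ρ_X+ρ_background)]/x_bulk with a configurable background species
set; cells expected to hold fewer than 5 molecules over the averaging
window are masked. When x_bulk is computed from the same frames, the
density-weighted mean enrichment over unmasked cells is exactly 1 — used
as a normalization identity test.

## Study orchestration and correlations

`run_study` executes the three stages per composition, derives relative
nucleation energies against a declared reference, and fits ordinary least
squares with Pearson r for the cross-composition pairs (E_nucl ratio vs
excess TG; diluted TG vs π_CH; diluted TG vs κ_b c₀²). Correlations report
r and n but no p-values — with a handful of compositions the fit itself is
the message. Per-composition failures are recorded and the study
continues; reports embed the config and a config hash and are
deterministic under a fixed seed. A constant-y input returns slope 0 and
r = 0 (no linear association) rather than an error; constant-x is an
error, since the fit is genuinely undefined.

The synthetic study constructor builds compositions whose diluted plateau
is affine in π_CH (with multiplicative noise) and whose nucleation rate
grows exponentially with the resulting excess TG, with the base rate
chosen so even the slowest composition forms well inside the 1.5 µs
horizon — this keeps every relative energy defined, which the
monotonicity check needs. A `deterministic` nucleation switch replaces
sampled waiting times with their mean for noise-free monotonicity
demonstrations.

## Synthetic generators: what they emulate, and what they do not

The generators reproduce the *statistical structure* each analysis
assumes, with known ground truth:

* lattice bilayers (0.64 nm²/lipid, 1–4 beads per lipid at fixed internal
  geometry) with jitter — enough realism for distance, clustering,
  leaflet and binning logic, none for energetics;
* implanted biconvex lenses with recorded membership, the monolayers
  displaced outward with a 2 nm clearance so the lens interior classifies
  as lens and only a thin rim is boundary;
* lens-coexistence trajectories in which a fixed exchangeable TG pool
  fluctuates binomially between lens and bilayer — composition is
  conserved across frames and the per-frame diluted count has the
  fluctuation statistics of lens↔bilayer exchange;
* exponential nucleation waiting times (the constant-rate null model
  implied by k ∝ exp(−E/k_BT)) with censoring, plus static-geometry
  trajectories whose lens appears at the drawn time;
* Gaussian height fields drawn mode-by-mode from the Helfrich spectrum,
  with an optional 3-SE-per-shell self check;
* analytic pressure profiles (Gaussian lobes or piecewise-linear
  trapezoids) carrying closed-form tension, π_CH and first moments —
  for the clipped positive part of multi-lobe profiles the zero crossings
  are polished with root finding and the erf closed forms summed over the
  positive intervals;
* relaxation series c(t) = c_∞(1 − e^{−t/τ}) with optional injection
  steps and Gaussian noise.

Passing tests on these fixtures demonstrates that the *analysis
operations* are correct and internally consistent. They do not show that
a particular force field reproduces experimental nucleation rates or
chemical potentials: there is no thermodynamics in the generators, no
correlated dynamics between frames (each frame is independently jittered),
no protein machinery, and the pressure profiles are imposed rather than
derived from configurations.

## Problem sizes and numerical defaults

The shipped test and reproduction workloads use: 100 random configurations
up to 500 TG for the clustering oracle; 20 trajectories for event
recovery; 10⁵ Monte-Carlo triplets for the estimator law; lens-coexistence
systems of 1836/5508/9180 TG in 6050–12250 PL with 6 replicas × 6 frames
for size independence; 512 frames on 64² grids, 5 seeds, for each
κ ∈ {5, 10, 20, 40} k_BT; and 8-composition synthetic studies. These sizes
put every statistical acceptance check several standard errors away from
its threshold while keeping the whole suite in the minutes range on one
CPU.

## Known limitations

* The diluted-TG classification with molecule-mean positions makes the PL
  lens-margin test logically redundant (see above); with bead-minimum
  distances that redundancy disappears, and results should state which
  reference point was used.
* Leaflet assignment for height fields uses the global reference-bead
  mean, which assumes the bilayer does not wrap through the z boundary.
* The real-space bending estimator shares the discrete-mode machinery with
  the generator convention; on real trajectories its normalization is
  exact only to the extent the midplane field is bending-dominated and
  tensionless.
* Relative nucleation energies are τ₀-dependent by construction; only
  tendencies across compositions at fixed τ₀ are meaningful.
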