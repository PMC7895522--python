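# blistertools

Analysis toolkit for triglyceride (TG) blister formation in coarse-grained
bilayer simulations — the earliest, lens-shaped stage of lipid droplet
biogenesis in the ER membrane.

Cells store neutral lipids in droplets that nucleate between the two
leaflets of a phospholipid (PL) bilayer once the TG concentration exceeds
its solubility limit, behaving like a first-order phase separation: a
condensed oil lens coexists with "diluted" TG dissolved in the bilayer.
How fast lenses nucleate and how much TG the bilayer retains both depend on
the surrounding lipids through the lateral stresses they build into the
membrane. `blistertools` implements the full analysis chain connecting
these quantities, for people who run (or want to reason about) CG membrane
simulations of nascent lipid droplets:

- **Lens detection and nucleation kinetics** — a lens is a single-linkage
  cluster of ≥ 25 TG molecules within a 3.5 nm minimum-image cutoff,
  stable for ≥ 5 ns. Over replicas the nucleation rate is
  k = 1/⟨t_form⟩ (censored runs at the 1.5 µs horizon), and relative
  nucleation energies follow k ∝ exp(−E_nucl/k_BT), reported as
  E_nucl/E_nucl(reference).
- **Diluted-TG equilibrium (chemical-potential proxy)** — per frame, TG
  partitions into *lens* (within 5 nm of another TG and farther than
  2.8 nm from every PL), *diluted* (in the lens-free region, ≥ 2.5 nm from
  the lens) and an excluded *boundary* rim; the equilibrium concentration
  is 100·N_TG,diluted/N_PL,free averaged over a trailing 1.5 µs window,
  with error bars from replicate SD. Excess TG = nominal % − equilibrium %.
- **Membrane mechanics from lateral pressure profiles** — with
  π(z) = P_T − P_N, the chain pressure π_CH is the Simpson integral (0.01 Å
  bins) of the positive region between the glycerol minima; the monolayer
  first moment −∫₀^{L_z/2} z π(z) dz = κ_b c₀ yields the spontaneous
  curvature c₀ and the curvature stress κ_b c₀²; bending moduli come from
  the Helfrich undulation spectrum ⟨|h_q|²⟩ = k_BT/(A κ q⁴) (Fourier route)
  and from patch-averaged height variances (real-space route).
- **Lateral enrichment maps** — per-species density maps around a lens and
  the enrichment [ρ_X/(ρ_X+ρ_bg)] / x_bulk.
- **Study orchestration** — multi-composition runs with the
  cross-composition correlations (E_nucl vs excess TG; diluted TG vs π_CH
  or κ_b c₀²).
- **Synthetic data generators** — bead bilayers with implanted lenses of
  known membership, exponential nucleation times with censoring, Helfrich
  height fields with known κ, analytic pressure profiles with closed-form
  integrals, and relaxation series with known plateaus, so every stage is
  verifiable without running molecular dynamics.

## Worked example

```python
import blistertools as bt
from blistertools.synth import (
    gen_lens_system, gen_stress_profile, gen_helfrich_fields,
    gen_nucleation_replicas,
)

# 1) nucleation kinetics from three replicas
sample = gen_nucleation_replicas(rate_us=2.0, n_replicas=3, seed=1,
                                 with_trajectories=True)
tracks = [bt.detect_lens_formation(t) for t in sample.trajectories]
est = bt.nucleation_rate(tracks, total_time_us=1.5)
print(f"formation times (us): {[round(t, 3) for t in est.times_us]}")
print(f"rate = {est.rate_us:.2f} +- {est.rate_err_us:.2f} us^-1")

# 2) equilibrium diluted TG next to an implanted 1836-TG lens
traj, truth = gen_lens_system(n_pl=6050, n_tg_lens=1836,
                              diluted_fraction=1.1, n_frames=6, seed=1)
series = bt.diluted_series(traj)
mean, sd = bt.plateau_stats([series], window=500.0)
print(f"diluted TG plateau = {mean:.2f}% (true fraction 1.10%)")
print(f"excess TG at a 6% setup = {bt.excess_tg(6.0, mean):.2f}%")

# 3) stress metrics from an analytic lateral pressure profile
profile, refs = gen_stress_profile(chain_amp=300.0)
m = bt.stress_metrics(profile, kappa_b_kT=10.0)
print(f"pi_CH = {m.pi_ch_mN_m:.2f} mN/m   kb*c0 = {m.kb_c0_mN_m_nm:.2f} mN/m nm")
print(f"c0 = {m.c0_per_nm:.3f} nm^-1   kappa_b*c0^2 = {m.curvature_stress_kT_nm2:.3f} kT/nm^2")

# 4) bending modulus from simulated height fluctuations
fields = gen_helfrich_fields(kappa_kT=20.0, box_l=40.0, grid=64,
                             n_frames=512, seed=1)
spec = bt.kappa_fourier(fields, (40.0, 40.0))
print(f"bilayer kappa = {spec.kappa_kT:.1f} kT (monolayer {spec.kappa_b_kT:.1f} kT), "
      f"spectrum slope {spec.slope:.2f}")
```

Output:

```
formation times (us): [0.54, 0.155, 1.5]
rate = 1.37 +- 1.29 us^-1
diluted TG plateau = 1.02% (true fraction 1.10%)
excess TG at a 6% setup = 4.98%
pi_CH = 49.24 mN/m   kb*c0 = 31.51 mN/m nm
c0 = 0.736 nm^-1   kappa_b*c0^2 = 5.421 kT/nm^2
bilayer kappa = 19.8 kT (monolayer 9.9 kT), spectrum slope -4.21
```

Reading it: one of the three replicas never formed a lens inside the
1.5 µs horizon, so its time enters at the horizon and the rate is a lower
bound with a wide error bar — exactly how censored replicas are handled
throughout. The diluted-TG plateau recovers the fraction the generator
implanted to within the binomial exchange noise; the spectrum slope near −4
confirms the fitted fluctuation spectrum is in the bending-dominated
regime.

A `blistertools` console command exposes the same stages
(`nucleation`, `dilute`, `mechanics`, `maps`, `synth`, `study`); see
`blistertools --help` and the commented study config in
`examples/study.yaml`.

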