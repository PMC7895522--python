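# Example multi-composition study at synthetic (desk) scale.
#
# Each composition bundles the three stages the report joins together:
#   nucleation   - replica lens-formation times drawn at `rate_us` (per us),
#                  censored at the 1.5 us horizon
#   equilibrium  - diluted-TG relaxation replicas with the given plateau (%)
#   profile      - analytic lateral pressure profile whose chain pressure
#                  pi_CH (mN/m) is set by `chain_amp`
# Labels follow the "+X mol% SPECIES" convention (relative to a DOPC
# bilayer); TG percentages are TG/PL ratios.
#
# Run with:  blistertools study --config examples/study.yaml

seed: 1
reference: "100% DOPC"

compositions:
  - label: "100% DOPC"            # 3200 DOPC-scale reference bilayer
    nominal_percent: 6.0          # TG/PL ratio of the nucleation setup
    kappa_b_kT: 10.0              # monolayer bending modulus
    nucleation: {rate_us: 1.5, n_replicas: 3}
    equilibrium: {plateau_percent: 1.1, tau_ns: 300.0, noise_sd: 0.1, n_replicas: 2}
    profile: {chain_amp: 20.0}

  - label: "+ 30 mol% DOPE"       # cone-shaped PE raises chain pressure,
    nominal_percent: 6.0          # lowers the diluted-TG plateau
    kappa_b_kT: 11.0
    nucleation: {rate_us: 2.5, n_replicas: 3}
    equilibrium: {plateau_percent: 0.8, tau_ns: 300.0, noise_sd: 0.1, n_replicas: 2}
    profile: {chain_amp: 28.0}

  - label: "+ 20 mol% DAG"        # DAG strongly depletes TG from the bilayer
    nominal_percent: 6.0
    kappa_b_kT: 10.5
    nucleation: {rate_us: 4.0, n_replicas: 3}
    equilibrium: {plateau_percent: 0.5, tau_ns: 250.0, noise_sd: 0.1, n_replicas: 2}
    profile: {chain_amp: 35.0}

  - label: "+ 60 mol% DPPC"       # saturated chains lower chain pressure,
    nominal_percent: 6.0          # retaining more TG in the bilayer
    kappa_b_kT: 12.0
    nucleation: {rate_us: 1.0, n_replicas: 3}
    equilibrium: {plateau_percent: 1.4, tau_ns: 350.0, noise_sd: 0.1, n_replicas: 2}
    profile: {chain_amp: 16.0}

  - label: "+ 60 mol% DLPC"       # short chains: most TG stays dissolved
    nominal_percent: 6.0
    kappa_b_kT: 8.0
    nucleation: {rate_us: 0.8, n_replicas: 3}
    equilibrium: {plateau_percent: 1.8, tau_ns: 350.0, noise_sd: 0.1, n_replicas: 2}
    profile: {chain_amp: 12.0}

  - label: "+ 10 mol% CHOL"
    nominal_percent: 6.0
    kappa_b_kT: 13.0
    nucleation: {rate_us: 2.0, n_replicas: 3}
    equilibrium: {plateau_percent: 0.9, tau_ns: 300.0, noise_sd: 0.1, n_replicas: 2}
    profile: {chain_amp: 24.0}
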