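"""Multi-composition study orchestration and correlation analyses.

A *study* bundles, per lipid composition, the nucleation kinetics (rate and
relative nucleation energy), the equilibrium diluted-TG plateau (chemical
potential proxy), the excess TG of the nucleation setup, and the
LPP-derived stress metrics (pi_CH, kappa_b c0^2), then quantifies the
cross-composition relationships: nucleation energy vs excess TG, and
diluted TG vs chain pressure or curvature stress. Correlations are ordinary
least squares with Pearson r (no p-values are attached; with a handful of
compositions r and n carry the message).

At desk scale the study runs on synthetic inputs with known ground truth;
the same report layout applies to real trajectory/profile inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .equilibrium import excess_tg, plateau_stats
from .errors import ContractError
from .kinetics import nucleation_rate, relative_nucleation_energy
from .mechanics import first_moment_curvature, chain_pressure, curvature_stress
from .synth import (
    gen_nucleation_replicas,
    gen_relaxation_series,
    gen_stress_profile,
)

__all__ = ["CorrelationFit", "StudyResult", "correlate", "run_study", "synthetic_study_config"]


@dataclass
class CorrelationFit:
    slope: float
    intercept: float
    pearson_r: float
    slope_stderr: float
    n: int


def correlate(x, y) -> CorrelationFit:
    """Ordinary least squares y = slope*x + intercept with Pearson r.

    Requires >= 3 finite paired points and nonzero variance in x. A constant
    y returns slope 0 and r 0 (no linear association, not undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ContractError("correlate needs >= 3 paired points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ContractError("correlate requires finite values")
    if np.ptp(x) == 0:
        raise ContractError("zero variance in x: fit undefined")
    if np.ptp(y) == 0:
        return CorrelationFit(0.0, float(y[0]), 0.0, 0.0, len(x))
    res = stats.linregress(x, y)
    return CorrelationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        slope_stderr=float(res.stderr),
        n=len(x),
    )


@dataclass
class StudyResult:
    """Per-composition metric rows plus cross-composition correlation fits."""

    rows: pd.DataFrame
    correlations: dict[str, CorrelationFit]
    config: dict
    errors: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "rows": json.loads(self.rows.to_json(orient="records", double_precision=12)),
            "correlations": {k: asdict(v) for k, v in self.correlations.items()},
            "errors": self.errors,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()
            ).hexdigest()[:16],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def synthetic_study_config(
    n_compositions: int = 6,
    seed: int = 0,
    pi_ch_range: tuple[float, float] = (10.0, 40.0),
    diluted_slope: float = -0.04,
    diluted_intercept: float = 2.2,
    noise_frac: float = 0.05,
    nominal_percent: float = 6.0,
    kappa_b_kT: float = 10.0,
) -> dict:
    """Desk-scale study with a constructed affine diluted-TG vs pi_CH law.

    Compositions span ``pi_ch_range`` in chain pressure; the true diluted
    plateau of composition i is ``intercept + slope * pi_CH_i`` (plus
    relative noise), and nucleation rates increase with the resulting excess
    TG so that the relative nucleation energy decreases with it. The
    construction parameters are recorded in the config for ground-truth
    comparison.
    """
    rng = np.random.default_rng(seed)
    pis = np.linspace(*pi_ch_range, n_compositions)
    comps = []
    for i, pi_target in enumerate(pis):
        plateau = diluted_intercept + diluted_slope * pi_target
        plateau *= 1.0 + rng.normal(0, noise_frac)
        plateau = max(plateau, 0.05)
        excess = nominal_percent - plateau
        # constructed kinetics: rate grows exponentially with excess TG, with
        # the slowest composition still forming well inside the 1.5 us horizon
        rate = 1.2 * np.exp(0.55 * (excess - 4.0))
        comps.append(
            {
                "label": f"synthetic-{chr(65 + i)}",
                "nominal_percent": nominal_percent,
                "kappa_b_kT": kappa_b_kT,
                "nucleation": {"rate_us": float(rate), "n_replicas": 3},
                "equilibrium": {
                    "plateau_percent": float(plateau),
                    "tau_ns": 300.0,
                    "noise_sd": 0.1,
                    "n_replicas": 2,
                },
                "profile": {
                    "form": "gaussian-lobes",
                    # chain amplitude tuned so the analytic pi_CH tracks the target
                    "chain_amp": float(pi_target),
                },
            }
        )
    return {
        "seed": seed,
        "reference": comps[0]["label"],
        "construction": {
            "diluted_slope": diluted_slope,
            "diluted_intercept": diluted_intercept,
            "noise_frac": noise_frac,
        },
        "compositions": comps,
    }


def _profile_for(comp: dict, scale_to_pi: bool = True):
    """Generate the composition's analytic pressure profile, scaling the
    chain amplitude so its pi_CH (mN/m) matches the configured value."""
    p = dict(comp.get("profile", {}))
    target = p.pop("chain_amp", 300.0)
    base, refs = gen_stress_profile(**p, chain_amp=300.0)
    if scale_to_pi:
        scale = target / refs["pi_ch_mN_m"]
        base.p_t = base.p_t * scale
        refs = {
            k: (v * scale if isinstance(v, float) else v) for k, v in refs.items()
        }
    return base, refs


def run_study(config: dict) -> StudyResult:
    """Execute the nucleation, equilibrium and mechanics stages per
    composition and the cross-composition correlations.

    Per-composition failures are recorded in ``errors`` and the study
    continues. The report is deterministic under a fixed config seed.
    """
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    rows = []
    errors: dict[str, str] = {}
    estimates = {}
    for comp in config["compositions"]:
        label = comp["label"]
        try:
            row = {"label": label, "nominal_percent": comp.get("nominal_percent", 6.0)}
            # nucleation stage
            nuc = comp.get("nucleation")
            if nuc:
                n_rep = nuc.get("n_replicas", 3)
                if nuc.get("deterministic"):
                    # noise-free study variant: every replica forms at the
                    # mean waiting time (censored past the horizon)
                    t = np.inf if nuc["rate_us"] == 0 else 1.0 / nuc["rate_us"]
                    pairs = [(min(t, 1.5), t > 1.5)] * n_rep
                else:
                    sample = gen_nucleation_replicas(
                        rate_us=nuc["rate_us"],
                        n_replicas=n_rep,
                        seed=int(rng.integers(2**31)),
                    )
                    pairs = list(zip(sample.times_us, sample.censored))
                est = nucleation_rate(pairs, label=label)
                estimates[label] = est
                row["rate_us"] = est.rate_us
                row["rate_err_us"] = est.rate_err_us
            # equilibrium stage
            eq = comp.get("equilibrium")
            if eq:
                reps = [
                    gen_relaxation_series(
                        plateau_percent=eq["plateau_percent"],
                        tau_ns=eq.get("tau_ns", 300.0),
                        noise_sd=eq.get("noise_sd", 0.1),
                        seed=int(rng.integers(2**31)),
                    )[0]
                    for _ in range(eq.get("n_replicas", 2))
                ]
                mean, sd = plateau_stats(reps)
                row["diluted_percent"] = mean
                row["diluted_sd"] = sd
                row["excess_percent"] = excess_tg(row["nominal_percent"], mean)
            # mechanics stage
            if comp.get("profile"):
                profile, _refs = _profile_for(comp)
                kappa_b = comp.get("kappa_b_kT", 10.0)
                pi_ch, pi_sd = chain_pressure(profile)
                fm = first_moment_curvature(profile, kappa_b)
                stress, stress_sd = curvature_stress(kappa_b, fm.c0, 0.0, fm.c0_sd)
                row["pi_ch_mN_m"] = pi_ch
                row["kb_c0_mN_m_nm"] = fm.kb_c0
                row["kappa_b_kT"] = kappa_b
                row["curvature_stress_kT_nm2"] = stress
            rows.append(row)
        except Exception as exc:  # study continues past per-composition failures
            errors[label] = f"{type(exc).__name__}: {exc}"
    table = pd.DataFrame(rows)
    # relative nucleation energies against the reference composition
    ref_label = config.get("reference")
    if ref_label in estimates:
        ref = estimates[ref_label]
        ratios = {}
        for label, est in estimates.items():
            try:
                ratios[label] = relative_nucleation_energy(est, ref)
            except ContractError:
                ratios[label] = (np.nan, np.nan)
        table["enucl_ratio"] = [
            ratios.get(lb, (np.nan, np.nan))[0] for lb in table["label"]
        ]
        table["enucl_ratio_err"] = [
            ratios.get(lb, (np.nan, np.nan))[1] for lb in table["label"]
        ]
    correlations = {}
    pairs = [
        ("enucl_vs_excess", "excess_percent", "enucl_ratio"),
        ("diluted_vs_pi_ch", "pi_ch_mN_m", "diluted_percent"),
        ("diluted_vs_curvature_stress", "curvature_stress_kT_nm2", "diluted_percent"),
    ]
    for name, xcol, ycol in pairs:
        if xcol in table.columns and ycol in table.columns:
            sub = table[[xcol, ycol]].dropna()
            if len(sub) >= 3 and np.ptp(sub[xcol].to_numpy()) > 0:
                correlations[name] = correlate(
                    sub[xcol].to_numpy(), sub[ycol].to_numpy()
                )
    return StudyResult(rows=table, correlations=correlations, config=config, errors=errors)
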