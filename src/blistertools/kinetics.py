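"""Blister (lens) nucleation detection and kinetics.

A triglyceride lens is detected as a single-linkage cluster of TG molecules:
two TG belong to the same aggregate iff they are connected by a chain of
pairwise minimum-image distances at or below the cutoff (default 3.5 nm).
A formation event requires an aggregate of at least ``min_size`` TG
(default 25) that persists — tracked across frames by maximal membership
overlap — through every sampled frame of a ``persistence`` window
(default 5 ns).

The nucleation rate over replicas is the inverse of the mean formation
time; replicas without an event within the scheduled run (default 1.5 us)
are censored. With at least one event, censored replicas are imputed at the
run length, giving a lower bound on the rate; with no events at all the
rate is 0 with error 1/total_time. The rate error follows first-order
propagation: sigma_rate = sigma_t / <t>^2 with sigma_t the sample SD of
the formation times.

Relative nucleation energies use rate = tau0^-1 exp(-E/kT), i.e.
E/kT = -ln(rate * tau0), reported as the ratio E(composition)/E(reference).
The attempt time tau0 is not physically determined here (default 1 ns);
ratios are tau0-dependent, so a sensitivity helper is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import BeadFrame, Trajectory, check_cutoff, periodic_kdtree
from .errors import ConfigurationError, ContractError

__all__ = [
    "LensTrack",
    "NucleationEstimate",
    "cluster_tg",
    "detect_lens_formation",
    "nucleation_rate",
    "relative_nucleation_energy",
    "tau0_sensitivity",
]


def _tg_positions(frame: BeadFrame) -> tuple[np.ndarray, np.ndarray]:
    tg = frame.molecules_of_category("tg")
    if len(tg) == 0:
        return tg, np.empty((0, 3))
    return tg, frame.molecule_positions(tg)


def cluster_tg(frame: BeadFrame, cutoff: float = 3.5) -> list[set[int]]:
    """Partition TG molecules into single-linkage components at ``cutoff``.

    Returns a list of sets of molecule ids (singletons included), sorted by
    decreasing size. Distances are between molecule mean positions under the
    minimum-image convention; exactness against a brute-force all-pairs
    oracle is part of the test contract.
    """
    check_cutoff(cutoff, frame.box, axes=(0, 1))
    tg, pos = _tg_positions(frame)
    n = len(tg)
    if n == 0:
        return []
    tree = periodic_kdtree(pos, frame.box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        graph = coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    comps: list[set[int]] = [set() for _ in range(n_comp)]
    for mol, lab in zip(tg.tolist(), labels):
        comps[lab].add(int(mol))
    comps.sort(key=len, reverse=True)
    return comps


@dataclass
class LensTrack:
    """Per-frame TG cluster partitions with the detected formation event."""

    times: np.ndarray  # ns
    partitions: list[list[set[int]]]
    formation_time_ns: float | None  # None when censored
    censored: bool
    lens_members: set[int] | None  # members at the confirmed onset frame
    candidates: list[tuple[float, int, float]]  # (onset ns, size, persisted ns)
    cutoff: float = 3.5
    min_size: int = 25
    persistence_ns: float = 5.0
    total_time_us: float | None = None

    @property
    def formation_time_us(self) -> float | None:
        if self.formation_time_ns is None:
            return None
        return self.formation_time_ns / 1000.0

    def largest_sizes(self) -> np.ndarray:
        return np.array(
            [max((len(c) for c in part), default=0) for part in self.partitions]
        )


def _best_overlap(cluster: set[int], partition: list[set[int]]) -> set[int] | None:
    """Successor cluster by maximal membership overlap (ties by size)."""
    best, best_ov = None, 0
    for cand in partition:
        ov = len(cluster & cand)
        if ov > best_ov or (ov == best_ov and ov > 0 and best is not None
                            and len(cand) > len(best)):
            best, best_ov = cand, ov
    return best if best_ov > 0 else None


def detect_lens_formation(
    traj: Trajectory,
    min_size: int = 25,
    persistence_ns: float = 5.0,
    cutoff: float = 3.5,
) -> LensTrack:
    """Scan a trajectory for the earliest persistent TG aggregate.

    The formation time is the earliest sampled time t such that one tracked
    aggregate of size >= ``min_size`` exists at *every* sampled frame in
    [t, t + persistence]. Tracking across frames follows maximal membership
    overlap. If the window would extend past the last frame the event cannot
    be confirmed and the track is censored.
    """
    times = traj.times
    if len(times) > 1:
        max_gap = float(np.max(np.diff(times)))
        if max_gap > persistence_ns:
            raise ConfigurationError(
                f"frame spacing {max_gap} ns exceeds persistence {persistence_ns} ns; "
                "the stability criterion is untestable"
            )
    partitions = [cluster_tg(f, cutoff=cutoff) for f in traj.frames]
    big = [[c for c in part if len(c) >= min_size] for part in partitions]
    n = len(times)
    formation_ns: float | None = None
    lens_members: set[int] | None = None
    candidates: list[tuple[float, int, float]] = []
    # (frame, members) pairs already visited as continuations of an earlier
    # onset; a fresh onset there would follow the identical successor chain
    # and fail at the same frame, so it can be skipped.
    tracked: set[tuple[int, frozenset]] = set()
    for i in range(n):
        for cluster in big[i]:
            if (i, frozenset(cluster)) in tracked:
                continue
            cur = cluster
            j = i
            ok = True
            while times[j] < times[i] + persistence_ns:
                if j + 1 >= n:
                    ok = False  # window extends past the trajectory
                    break
                nxt = _best_overlap(cur, big[j + 1])
                if nxt is None:
                    ok = False
                    break
                tracked.add((j + 1, frozenset(nxt)))
                cur = nxt
                j += 1
            persisted = float(times[j] - times[i])
            candidates.append((float(times[i]), len(cluster), persisted))
            if ok and formation_ns is None:
                formation_ns = float(times[i])
                lens_members = set(cluster)
        if formation_ns is not None:
            break
    return LensTrack(
        times=times,
        partitions=partitions,
        formation_time_ns=formation_ns,
        censored=formation_ns is None,
        lens_members=lens_members,
        candidates=candidates,
        cutoff=cutoff,
        min_size=min_size,
        persistence_ns=persistence_ns,
        total_time_us=traj.total_time_us,
    )


@dataclass
class NucleationEstimate:
    """Replica formation times with the derived rate and its error."""

    times_us: list[float]  # event times; censored replicas at total_time
    censored: list[bool]
    rate_us: float  # us^-1
    rate_err_us: float
    total_time_us: float
    mixed_censoring: bool = False
    method: str = "inverse-mean-time"
    enucl_over_kT: float | None = None
    enucl_err: float | None = None
    label: str | None = None
    extras: dict = field(default_factory=dict)


def nucleation_rate(
    tracks: "list[LensTrack] | list[tuple[float, bool]]",
    total_time_us: float = 1.5,
    method: str = "inverse-mean-time",
    label: str | None = None,
) -> NucleationEstimate:
    """Rate of lens formation over replicas.

    ``tracks`` may be LensTrack objects or (time_us, censored) pairs.
    ``method`` selects the replica averaging: 'inverse-mean-time' (the
    default reading: invert the mean formation time) or 'mean-inverse-time'
    (average the per-replica inverse times).
    """
    if not tracks:
        raise ContractError("nucleation_rate needs at least one replica")
    pairs: list[tuple[float, bool]] = []
    for t in tracks:
        if isinstance(t, LensTrack):
            if t.censored:
                pairs.append((t.total_time_us or total_time_us, True))
            else:
                pairs.append((t.formation_time_us, False))
        else:
            pairs.append((float(t[0]), bool(t[1])))
    censored = [c for _, c in pairs]
    if all(censored):
        return NucleationEstimate(
            times_us=[total_time_us] * len(pairs),
            censored=censored,
            rate_us=0.0,
            rate_err_us=1.0 / total_time_us,
            total_time_us=total_time_us,
            method=method,
            label=label,
        )
    # censored replicas imputed at the scheduled run length (lower-bound rate)
    times = np.array([total_time_us if c else t for t, c in pairs])
    sd = float(np.std(times, ddof=1)) if len(times) > 1 else 0.0
    if method == "inverse-mean-time":
        mean_t = float(np.mean(times))
        rate = 1.0 / mean_t
        err = sd / mean_t**2
    elif method == "mean-inverse-time":
        inv = 1.0 / times
        rate = float(np.mean(inv))
        err = float(np.std(inv, ddof=1)) if len(times) > 1 else 0.0
    else:
        raise ContractError(f"unknown rate method {method!r}")
    return NucleationEstimate(
        times_us=times.tolist(),
        censored=censored,
        rate_us=rate,
        rate_err_us=err,
        total_time_us=total_time_us,
        mixed_censoring=any(censored),
        method=method,
        label=label,
    )


def _energy_over_kT(rate_us: float, rate_err_us: float, tau0_ns: float) -> tuple[float, float]:
    if rate_us <= 0:
        raise ContractError(
            "rate <= 0: nucleation energy undefined for fully censored conditions"
        )
    x = rate_us * tau0_ns / 1000.0  # dimensionless rate * attempt time
    energy = -math.log(x)
    err = rate_err_us / rate_us  # |dE/drate| * sigma = sigma/rate
    return energy, err


def relative_nucleation_energy(
    est: NucleationEstimate,
    ref: NucleationEstimate,
    tau0_ns: float = 1.0,
) -> tuple[float, float]:
    """E_nucl(composition)/E_nucl(reference) with propagated relative error.

    Uses rate = tau0^-1 exp(-E/kT): E/kT = -ln(rate * tau0). Both rates must
    be positive; compositions whose replicas are all censored have no defined
    energy. Because the attempt time tau0 is not pinned down by the rate
    measurements alone, the ratio depends on tau0 (see
    :func:`tau0_sensitivity`).
    """
    e1, de1 = _energy_over_kT(est.rate_us, est.rate_err_us, tau0_ns)
    e2, de2 = _energy_over_kT(ref.rate_us, ref.rate_err_us, tau0_ns)
    if e2 == 0:
        raise ContractError("reference energy is 0 at this tau0; ratio undefined")
    ratio = e1 / e2
    rel_err = abs(ratio) * math.sqrt((de1 / e1) ** 2 + (de2 / e2) ** 2) if e1 != 0 else (
        de1 / abs(e2)
    )
    est.enucl_over_kT, est.enucl_err = e1, de1
    return ratio, rel_err


def tau0_sensitivity(
    est: NucleationEstimate,
    ref: NucleationEstimate,
    tau0_grid_ns: tuple[float, ...] = (0.1, 1.0, 10.0),
) -> dict[float, float]:
    """E-ratio across a grid of attempt times, for reporting alongside
    the default tau0 result."""
    return {
        t0: relative_nucleation_energy(est, ref, tau0_ns=t0)[0]
        for t0 in tau0_grid_ns
    }
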