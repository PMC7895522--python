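"""Equilibrium diluted-TG quantification: the chemical-potential proxy.

A planar bilayer coexisting with a pre-formed TG lens equilibrates at a
characteristic concentration of TG dissolved in the bilayer. Per frame, TG
molecules are partitioned into three disjoint classes:

* **lens** — TG within ``tg_tg`` (5 nm) of another TG *and* farther than
  ``tg_pl`` (2.8 nm) from every phospholipid;
* **diluted** — non-lens TG inside the *lens-free* region, i.e. at least
  ``margin`` (2.5 nm) from every lens TG;
* **boundary** — the remaining TG at the lens rim, excluded from both the
  numerator and denominator because molecules there exchange continuously
  with the lens.

The diluted concentration is 100 * N_TG,diluted / N_PL,lens-free (percent
relative to phospholipids, never mol% of total lipid). The equilibrium value
is the mean over a trailing window (default 1.5 us), with the error bar
taken as the SD across independent replicas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BeadFrame, Trajectory, check_cutoff, periodic_kdtree, unwrap_group
from .errors import ConfigurationError, ContractError
from .kinetics import cluster_tg

__all__ = [
    "TGClassification",
    "DilutedTGSeries",
    "LensExtent",
    "classify_tg",
    "diluted_series",
    "plateau_stats",
    "detect_dissolution",
    "lens_extent",
    "excess_tg",
]


@dataclass
class TGClassification:
    """Disjoint TG classes plus the lens-free PL set for one frame."""

    lens: set[int]
    diluted: set[int]
    boundary: set[int]
    lens_free_pl: set[int]

    @property
    def percent(self) -> float:
        """100 * diluted TG / lens-free PL (0 when no PL qualifies)."""
        if not self.lens_free_pl:
            return 0.0
        return 100.0 * len(self.diluted) / len(self.lens_free_pl)


def classify_tg(
    frame: BeadFrame,
    tg_tg: float = 5.0,
    tg_pl: float = 2.8,
    margin: float = 2.5,
    denominator: str = "pl",
) -> TGClassification:
    """Partition TG into lens / diluted / boundary against the PL matrix.

    ``denominator`` chooses the lens-free count: 'pl' (phospholipid species
    only, the default convention) or 'all-lipids' (DAG and sterols included).
    Distances are between molecule mean positions, minimum image.
    """
    for cut in (tg_tg, tg_pl, margin):
        check_cutoff(cut, frame.box)
    pl = frame.molecules_of_category("pl")
    if len(pl) == 0:
        raise ContractError("classify_tg requires at least one PL molecule")
    tg = frame.molecules_of_category("tg")
    if len(tg) == 0:
        return TGClassification(set(), set(), set(), set(pl.tolist()))
    tg_pos = frame.molecule_positions(tg)
    pl_pos = frame.molecule_positions(pl)
    tg_tree = periodic_kdtree(tg_pos, frame.box)
    pl_tree = periodic_kdtree(pl_pos, frame.box)

    # TG with another TG within tg_tg
    pairs = tg_tree.query_pairs(tg_tg, output_type="ndarray")
    near_tg = np.zeros(len(tg), dtype=bool)
    if len(pairs):
        near_tg[pairs.ravel()] = True
    # TG within tg_pl of any PL
    d_pl, _ = pl_tree.query(np.mod(tg_pos, frame.box), k=1)
    near_pl = d_pl <= tg_pl

    lens_mask = near_tg & ~near_pl
    lens = {int(m) for m in tg[lens_mask]}

    if lens:
        lens_tree = periodic_kdtree(tg_pos[lens_mask], frame.box)
        # lens-free lipids: >= margin from every lens TG
        d_lens_pl, _ = lens_tree.query(np.mod(pl_pos, frame.box), k=1)
        free_pl_mask = d_lens_pl >= margin
        d_lens_tg, _ = lens_tree.query(np.mod(tg_pos, frame.box), k=1)
        free_tg_mask = ~lens_mask & (d_lens_tg >= margin)
    else:
        free_pl_mask = np.ones(len(pl), dtype=bool)
        free_tg_mask = np.ones(len(tg), dtype=bool)

    diluted = {int(m) for m in tg[free_tg_mask]}
    boundary = {int(m) for m in tg} - lens - diluted
    if denominator == "pl":
        free_denom = {int(m) for m in pl[free_pl_mask]}
    elif denominator == "all-lipids":
        others = np.concatenate(
            [
                frame.molecules_of_category(cat)
                for cat in ("dag", "sterol")
            ]
        ) if len(frame.molecules_of_category("dag")) or len(
            frame.molecules_of_category("sterol")
        ) else np.empty(0, dtype=np.int64)
        free_denom = {int(m) for m in pl[free_pl_mask]}
        if len(others):
            o_pos = frame.molecule_positions(others)
            if lens:
                d_o, _ = lens_tree.query(np.mod(o_pos, frame.box), k=1)
                free_denom |= {int(m) for m in others[d_o >= margin]}
            else:
                free_denom |= {int(m) for m in others}
    else:
        raise ContractError(f"unknown denominator {denominator!r}")
    return TGClassification(lens, diluted, boundary, free_denom)


@dataclass
class DilutedTGSeries:
    """Per-frame diluted-TG classification results for one replica."""

    table: pd.DataFrame  # columns: time_ns, n_lens, n_diluted, n_boundary, n_free_pl, percent
    params: dict

    @property
    def times(self) -> np.ndarray:
        return self.table["time_ns"].to_numpy()

    @property
    def percent(self) -> np.ndarray:
        return self.table["percent"].to_numpy()


def diluted_series(
    traj: Trajectory,
    tg_tg: float = 5.0,
    tg_pl: float = 2.8,
    margin: float = 2.5,
    denominator: str = "pl",
) -> DilutedTGSeries:
    """Apply :func:`classify_tg` frame by frame; no smoothing."""
    rows = []
    for i, frame in enumerate(traj.frames):
        try:
            cls = classify_tg(frame, tg_tg=tg_tg, tg_pl=tg_pl, margin=margin,
                              denominator=denominator)
        except Exception as exc:
            raise type(exc)(f"frame {i} (t={frame.time} ns): {exc}") from exc
        rows.append(
            {
                "time_ns": frame.time,
                "n_lens": len(cls.lens),
                "n_diluted": len(cls.diluted),
                "n_boundary": len(cls.boundary),
                "n_free_pl": len(cls.lens_free_pl),
                "percent": cls.percent,
            }
        )
    return DilutedTGSeries(
        table=pd.DataFrame(rows),
        params={"tg_tg": tg_tg, "tg_pl": tg_pl, "margin": margin,
                "denominator": denominator},
    )


def _window_mean(times: np.ndarray, values: np.ndarray,
                 window: "float | tuple[float, float]") -> float:
    """Mean of values over a trailing window (ns) or an explicit (t0, t1)."""
    if np.ndim(window) == 0:
        t1 = times[-1]
        t0 = t1 - float(window)
        if t0 < times[0] - 1e-9:
            raise ConfigurationError(
                f"window {window} ns longer than the {times[-1] - times[0]} ns series"
            )
    else:
        t0, t1 = window
        if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
            raise ConfigurationError("window outside the series time span")
    mask = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
    if not mask.any():
        raise ConfigurationError("window contains no frames")
    vals = values[mask]
    # stationarity check: first vs second half-window means
    half = len(vals) // 2
    if half >= 2:
        m1, m2 = vals[:half].mean(), vals[half:].mean()
        sd = vals.std(ddof=1)
        if sd > 0 and abs(m1 - m2) > 2 * sd:
            warnings.warn(
                "plateau window looks non-stationary: half-window means differ "
                f"by more than 2 SD ({m1:.3g} vs {m2:.3g})",
                stacklevel=3,
            )
    return float(vals.mean())


def plateau_stats(
    series: "list[DilutedTGSeries] | list[pd.DataFrame]",
    window: "float | tuple[float, float]" = 1500.0,
) -> tuple[float, float]:
    """Equilibrium concentration: per-replica window mean, then mean and
    sample SD across replicas (SD = 0 for a single replica).

    ``window`` is the trailing window length in ns (default the last 1.5 us)
    or an explicit ``(t0, t1)`` interval — the latter supports pre/post
    comparisons around a TG-injection event.
    """
    if not series:
        raise ContractError("plateau_stats needs at least one replica")
    means = []
    for s in series:
        tab = s.table if isinstance(s, DilutedTGSeries) else s
        means.append(_window_mean(tab["time_ns"].to_numpy(),
                                  tab["percent"].to_numpy(), window))
    mean = float(np.mean(means))
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return mean, sd


def detect_dissolution(
    traj: Trajectory,
    min_size: int = 25,
    cutoff: float = 3.5,
) -> float | None:
    """Time (ns) after which no aggregate of ``min_size`` TG ever reappears.

    Dissolution requires permanence: transient dips below the size threshold
    followed by re-formation do not qualify; the reported time is the first
    frame after the *last* frame containing a qualifying aggregate. Returns
    None when a lens persists through the final frame.
    """
    sizes = []
    for frame in traj.frames:
        comps = cluster_tg(frame, cutoff=cutoff)
        sizes.append(max((len(c) for c in comps), default=0))
    sizes = np.array(sizes)
    if sizes[0] < min_size:
        raise ContractError(
            f"no lens in the first frame (largest aggregate {sizes[0]} < {min_size})"
        )
    if sizes[-1] >= min_size:
        return None
    last_alive = int(np.max(np.nonzero(sizes >= min_size)[0]))
    return float(traj.times[last_alive + 1])


@dataclass
class LensExtent:
    """Per-axis lens extents (nm), per frame and time-averaged."""

    per_frame: np.ndarray  # (n_frames, 3)
    mean: np.ndarray  # (3,)


def lens_extent(
    frames: "Trajectory | list[BeadFrame]",
    lens_sets: "list[set[int]] | set[int]",
) -> LensExtent:
    """Lens dimensions as max - min of the lens TG coordinates per axis,
    after unwrapping the lens around its own center, averaged over frames."""
    frame_list = list(frames.frames) if isinstance(frames, Trajectory) else list(frames)
    if isinstance(lens_sets, set):
        lens_sets = [lens_sets] * len(frame_list)
    extents = []
    for frame, lens in zip(frame_list, lens_sets):
        if not lens:
            raise ContractError("lens_extent requires a non-empty lens")
        beads = frame.beads_of_molecules(lens)
        coords = unwrap_group(frame.coords[beads], frame.box)
        extents.append(coords.max(axis=0) - coords.min(axis=0))
    per_frame = np.array(extents)
    return LensExtent(per_frame=per_frame, mean=per_frame.mean(axis=0))


def excess_tg(nominal_percent: float, equilibrium_percent: float) -> float:
    """Excess TG: the nominal TG/PL percentage of a nucleation setup minus
    the equilibrium diluted concentration (both in percent)."""
    if nominal_percent < 0 or equilibrium_percent < 0:
        raise ContractError("percentages must be >= 0")
    return nominal_percent - equilibrium_percent
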