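"""Synthetic fixtures with known ground truth for every analysis stage.

These generators emulate the *statistical structure* the analyses assume —
two-leaflet bead lattices, implanted lenses of known membership, exponential
nucleation waiting times with censoring, Helfrich q^-4 height spectra,
analytic lateral-pressure profiles, and relaxation series with a known
plateau — so the whole pipeline is verifiable without molecular dynamics.

Bead-level realism is deliberately minimal (1-5 beads per lipid at fixed
internal geometry): sufficient to exercise distance, clustering and leaflet
logic, not energetics. Every generator is deterministic under a fixed seed
and attaches its :class:`SyntheticSpec` to the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf

from .core import BeadFrame, Trajectory, periodic_kdtree
from .equilibrium import DilutedTGSeries, classify_tg
from .errors import ContractError
from .mechanics import PressureProfile

__all__ = [
    "SyntheticSpec",
    "gen_bilayer_frame",
    "implant_lens",
    "gen_lens_system",
    "gen_classification_frame",
    "gen_nucleation_replicas",
    "gen_helfrich_fields",
    "gen_stress_profile",
    "gen_relaxation_series",
    "gen_uniform_mixture_frames",
]


@dataclass
class SyntheticSpec:
    """Provenance record attached to every generated fixture."""

    generator: str
    params: dict
    seed: int | None

    def as_dict(self) -> dict:
        return {"generator": self.generator, "seed": self.seed, **self.params}


# bead templates: (role, |z offset| nm from the leaflet anchor plane)
_PL_BEADS = (("head", 2.2), ("glycerol", 1.6), ("tail", 0.9), ("tail", 0.3))
_DAG_BEADS = (("glycerol", 1.5), ("tail", 0.9), ("tail", 0.3))
_CHOL_BEADS = (("head", 1.4), ("tail", 0.6))
_TG_BEADS = (("glycerol", 0.15), ("tail", 0.05), ("tail", -0.05), ("tail", -0.15))

_PL_SET = {"DOPC", "DOPE", "DPPC", "DLPC", "DLPE", "POPC"}
_TG_SET = {"TG", "TOOP", "TOPP"}


def _template(species: str):
    if species in _PL_SET:
        return _PL_BEADS
    if species in _TG_SET:
        return _TG_BEADS
    if species == "DAG":
        return _DAG_BEADS
    if species == "CHOL":
        return _CHOL_BEADS
    return (("other", 0.5),)


def gen_bilayer_frame(
    composition: dict[str, int],
    box_z: float = 14.0,
    area_per_lipid: float = 0.64,
    jitter: float = 0.08,
    tg_mode: str = "uniform-diluted",
    seed: int | None = 0,
    time: float = 0.0,
) -> tuple[BeadFrame, dict]:
    """Two-leaflet lattice bilayer with the requested composition.

    Membrane lipids (PL, DAG, CHOL) sit on a jittered square lattice sized
    from ``area_per_lipid`` (0.64 nm^2, a fluid-bilayer value), split evenly
    between leaflets with species shuffled across sites. TG molecules are
    placed near the midplane: uniformly at random in the lateral plane
    (``tg_mode='uniform-diluted'``) or not at all (``'none'``).

    Returns the frame plus ground truth: leaflet assignment per membrane
    molecule and the TG molecule ids.
    """
    rng = np.random.default_rng(seed)
    mem_species: list[str] = []
    tg_species: list[str] = []
    for sp, n in sorted(composition.items()):
        if n < 0:
            raise ContractError("negative molecule count")
        (tg_species if sp in _TG_SET else mem_species).extend([sp] * n)
    if tg_mode == "none":
        tg_species = []
    n_mem = len(mem_species)
    if n_mem == 0:
        raise ContractError("composition needs membrane lipids")
    n_upper = n_mem // 2 + (n_mem % 2)
    n_side = math.ceil(math.sqrt(n_upper))
    a = math.sqrt(area_per_lipid)
    lx = ly = n_side * a
    if jitter > a / 2:
        raise ContractError("jitter exceeds half the lattice spacing (packing bound)")
    box = np.array([lx, ly, box_z])
    z_mid = box_z / 2.0
    order = rng.permutation(n_mem)
    shuffled = [mem_species[i] for i in order]

    coords, b2m, roles = [], [], []
    m2s: dict[int, str] = {}
    leaflet: dict[int, int] = {}
    mol = 0
    for leaf, count, sign in ((0, n_upper, +1), (1, n_mem - n_upper, -1)):
        offset = leaf * n_upper
        for k in range(count):
            sp = shuffled[offset + k]
            gx, gy = divmod(k, n_side)
            x = (gx + 0.5) * a + rng.normal(0, jitter)
            y = (gy + 0.5) * a + rng.normal(0, jitter)
            for role, dz in _template(sp):
                coords.append((x, y, z_mid + sign * (dz + rng.normal(0, jitter))))
                b2m.append(mol)
                roles.append(role)
            m2s[mol] = sp
            leaflet[mol] = leaf
            mol += 1
    tg_ids = []
    for sp in tg_species:
        x, y = rng.uniform(0, lx), rng.uniform(0, ly)
        zc = z_mid + rng.normal(0, 0.2)
        for role, dz in _template(sp):
            coords.append((x + rng.normal(0, jitter), y + rng.normal(0, jitter), zc + dz))
            b2m.append(mol)
            roles.append(role)
        m2s[mol] = sp
        tg_ids.append(mol)
        mol += 1
    frame = BeadFrame(
        time=time,
        box=box,
        coords=np.array(coords),
        bead_to_molecule=np.array(b2m),
        molecule_to_species=m2s,
        bead_role=roles,
    )
    truth = {
        "leaflet": leaflet,
        "tg_ids": tg_ids,
        "spec": SyntheticSpec(
            "gen_bilayer_frame",
            {"composition": dict(composition), "box_z": box_z, "tg_mode": tg_mode},
            seed,
        ),
    }
    return frame, truth


def implant_lens(
    frame: BeadFrame,
    n_tg: int,
    radius: float,
    thickness: float,
    tg_species: str = "TG",
    center_xy: tuple[float, float] | None = None,
    pl_clearance: float = 2.0,
    seed: int | None = 0,
) -> tuple[BeadFrame, set[int]]:
    """Implant a biconvex TG lens between the leaflets.

    TG molecules are sampled uniformly inside the lens volume
    |z - z_mid| < (thickness/2) (1 - (rho/radius)^2). Membrane beads over a
    slightly wider footprint are displaced outward by the local lens
    half-thickness plus ``pl_clearance``, keeping the monolayers clear of
    the oil phase as they are in a real blister.
    Returns the new frame and the true lens membership (new molecule ids).
    """
    if n_tg == 0:
        return frame, set()
    box = frame.box
    if 2 * radius >= min(box[0], box[1]) or thickness + 2 * pl_clearance >= box[2]:
        raise ContractError("lens does not fit in the box")
    rng = np.random.default_rng(seed)
    cx, cy = center_xy if center_xy is not None else (box[0] / 2, box[1] / 2)
    z_mid = float(np.mean(frame.coords[:, 2]))
    half = thickness / 2.0

    pts = np.empty((n_tg, 3))
    got = 0
    while got < n_tg:
        n_draw = 2 * (n_tg - got) + 16
        rho = radius * np.sqrt(rng.uniform(0, 1, n_draw))
        phi = rng.uniform(0, 2 * np.pi, n_draw)
        z = rng.uniform(-half, half, n_draw)
        keep = np.abs(z) < half * (1 - (rho / radius) ** 2)
        sel = np.nonzero(keep)[0][: n_tg - got]
        pts[got : got + len(sel), 0] = cx + rho[sel] * np.cos(phi[sel])
        pts[got : got + len(sel), 1] = cy + rho[sel] * np.sin(phi[sel])
        pts[got : got + len(sel), 2] = z_mid + z[sel]
        got += len(sel)

    # displace membrane beads outward over a widened footprint
    coords = frame.coords.copy()
    dx = coords[:, 0] - cx
    dy = coords[:, 1] - cy
    rho_b = np.hypot(dx - box[0] * np.round(dx / box[0]), dy - box[1] * np.round(dy / box[1]))
    r_foot = radius + pl_clearance
    inside = rho_b < r_foot
    bump = np.zeros(len(coords))
    bump[inside] = (half + pl_clearance) * (1 - (rho_b[inside] / r_foot) ** 2)
    coords[:, 2] += np.where(coords[:, 2] >= z_mid, bump, -bump)

    mol0 = int(frame.bead_to_molecule.max()) + 1
    new_coords = [coords]
    new_b2m = [frame.bead_to_molecule]
    new_roles = [np.asarray(frame.bead_role)]
    m2s = dict(frame.molecule_to_species)
    members = set()
    add_c, add_m, add_r = [], [], []
    for i in range(n_tg):
        mol = mol0 + i
        for role, dz in _template(tg_species):
            add_c.append(pts[i] + (0, 0, dz))
            add_m.append(mol)
            add_r.append(role)
        m2s[mol] = tg_species
        members.add(mol)
    new_coords.append(np.array(add_c))
    new_b2m.append(np.array(add_m))
    new_roles.append(np.array(add_r))
    out = BeadFrame(
        time=frame.time,
        box=box,
        coords=np.concatenate(new_coords),
        bead_to_molecule=np.concatenate(new_b2m),
        molecule_to_species=m2s,
        bead_role=np.concatenate(new_roles),
        species_categories=frame.species_categories,
    )
    return out, members


def gen_lens_system(
    n_pl: int = 6050,
    n_tg_lens: int = 1836,
    diluted_fraction: float = 1.1,
    radius: float = 12.5,
    thickness: float = 8.0,
    pl_species: str = "DOPC",
    n_frames: int = 6,
    frame_dt_ns: float = 100.0,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Bilayer + implanted lens + diluted TG at a known true fraction.

    The lens-free PL count is measured once by classifying the lens-only
    frame; each subsequent frame then draws its diluted-TG count from a
    binomial law at ``diluted_fraction`` percent of that free-PL count
    (emulating lens<->bilayer exchange fluctuations) and scatters those TG
    next to randomly chosen far-from-lens PLs, so they classify as diluted
    by construction. Ground truth: lens membership and the target fraction.
    """
    rng = np.random.default_rng(seed)
    box_z = thickness + 14.0
    base, _ = gen_bilayer_frame(
        {pl_species: n_pl}, box_z=box_z, tg_mode="none", seed=int(rng.integers(2**31))
    )
    lensed, members = implant_lens(
        base, n_tg_lens, radius=radius, thickness=thickness,
        seed=int(rng.integers(2**31)),
    )
    cls0 = classify_tg(lensed)
    free_pl0 = sorted(cls0.lens_free_pl)
    n_free0 = len(free_pl0)
    if n_free0 == 0:
        raise ContractError("no lens-free PL; box too small for this lens")
    # PLs safely inside the lens-free region (margin + 1.5 nm from the lens)
    lens_pos = lensed.molecule_positions(np.array(sorted(members)))
    tree = periodic_kdtree(lens_pos, lensed.box)
    pl_pos = lensed.molecule_positions(np.array(free_pl0))
    d, _ = tree.query(pl_pos, k=1)
    safe_pl = np.array(free_pl0)[d >= 2.5 + 1.5]
    # fixed exchangeable TG pool (conserves composition across frames): per
    # frame a binomial number of pool members sit diluted in the bilayer,
    # the rest park inside the lens
    p_target = n_free0 * diluted_fraction / 100.0
    pool = int(p_target + 5 * math.sqrt(p_target)) + 5
    z_mid = float(np.mean(lensed.coords[:, 2]))
    lens_center = np.array([lensed.box[0] / 2, lensed.box[1] / 2, z_mid])
    frames = []
    for k in range(n_frames):
        f = lensed.translated(rng.normal(0, 0.05, 3))  # thermal jitter stand-in
        f.time = k * frame_dt_ns
        n_dil = min(int(rng.binomial(n_free0, diluted_fraction / 100.0)), pool,
                    len(safe_pl))
        hosts = rng.choice(safe_pl, size=n_dil, replace=False)
        host_pos = f.molecule_positions(hosts)
        add_c, add_m, add_r = [], [], []
        m2s = dict(f.molecule_to_species)
        mol0 = int(f.bead_to_molecule.max()) + 1
        positions = list(host_pos + rng.normal(0, 0.1, (n_dil, 3)))
        # parked pool members: tight cluster at the lens core (classifies as lens)
        for _ in range(pool - n_dil):
            positions.append(lens_center + rng.normal(0, 0.8, 3) * (1, 1, 0.3))
        for i, p in enumerate(positions):
            mol = mol0 + i
            for role, dz in _template("TG"):
                add_c.append(p + (0, 0, dz))
                add_m.append(mol)
                add_r.append(role)
            m2s[mol] = "TG"
        if add_c:
            f = BeadFrame(
                time=f.time,
                box=f.box,
                coords=np.concatenate([f.coords, np.array(add_c)]),
                bead_to_molecule=np.concatenate([f.bead_to_molecule, np.array(add_m)]),
                molecule_to_species=m2s,
                bead_role=np.concatenate([np.asarray(f.bead_role), np.array(add_r)]),
            )
        frames.append(f)
    traj = Trajectory(frames=frames, metadata={"generator": "gen_lens_system"})
    truth = {
        "lens_members": members,
        "diluted_fraction": diluted_fraction,
        "n_free_pl0": n_free0,
        "spec": SyntheticSpec(
            "gen_lens_system",
            {
                "n_pl": n_pl,
                "n_tg_lens": n_tg_lens,
                "diluted_fraction": diluted_fraction,
                "radius": radius,
                "thickness": thickness,
                "n_frames": n_frames,
            },
            seed,
        ),
    }
    return traj, truth


def gen_classification_frame(
    n_lens: int = 100,
    n_diluted: int = 10,
    n_pl: int = 1000,
    seed: int = 0,
) -> tuple[BeadFrame, dict]:
    """Hand-constructible frame for the diluted-TG protocol.

    A compact TG ball far from all PLs (every member > 2.8 nm from any PL,
    within 5 nm of another TG), ``n_diluted`` isolated TG scattered among
    the PLs (> 2.5 nm from the ball, each adjacent to a PL), and a PL
    lattice entirely outside the lens margin — so classify_tg must return
    exactly (n_lens, n_diluted, 0) and percent 100 * n_diluted / n_pl.
    Single-bead molecules keep the geometry exact.
    """
    rng = np.random.default_rng(seed)
    spacing = 1.4
    n_side = math.ceil(math.sqrt(n_pl * 1.6))
    pl_region = n_side * spacing
    lens_c = np.array([8.0, 8.0, 5.0])
    lens_clearance = 9.0  # > ball radius (3) + tg_pl (2.8) + margin (2.5)
    box = np.array([max(pl_region, 40.0), max(pl_region, 40.0), 14.0])

    # compact lens ball, radius 3, chain-connected at 5 nm trivially
    ball = []
    while len(ball) < n_lens:
        p = rng.uniform(-3, 3, 3) * np.array([1, 1, 0.4])
        if np.linalg.norm(p) <= 3.0:
            ball.append(lens_c + p)
    ball = np.array(ball)

    # PL lattice avoiding the clearance disc around the lens
    pls = []
    k = 0
    while len(pls) < n_pl:
        gx, gy = divmod(k, n_side)
        k += 1
        if k > n_side * n_side:
            raise ContractError("PL lattice exhausted; increase box")
        p = np.array([(gx + 0.5) * spacing, (gy + 0.5) * spacing, 5.0])
        if np.linalg.norm((p - lens_c)[:2]) >= lens_clearance:
            pls.append(p)
    pls = np.array(pls)

    # diluted TG: adjacent to distinct PLs, pairwise > 5 nm, far from lens
    dil = []
    chosen: list[np.ndarray] = []
    for idx in rng.permutation(len(pls)):
        p = pls[idx] + np.array([0.3, 0.0, 0.0])
        if np.linalg.norm((p - lens_c)[:2]) < lens_clearance + 1.0:
            continue
        if all(np.linalg.norm(p - q) > 6.0 for q in chosen):
            chosen.append(p)
            dil.append(p)
        if len(dil) == n_diluted:
            break
    if len(dil) < n_diluted:
        raise ContractError("could not place diluted TG; increase box")
    dil = np.array(dil)

    coords = np.concatenate([ball, dil, pls])
    n_tg = n_lens + n_diluted
    b2m = np.arange(len(coords))
    m2s = {i: ("TG" if i < n_tg else "DOPC") for i in range(len(coords))}
    frame = BeadFrame(
        time=0.0,
        box=box,
        coords=coords,
        bead_to_molecule=b2m,
        molecule_to_species=m2s,
    )
    truth = {
        "lens": set(range(n_lens)),
        "diluted": set(range(n_lens, n_tg)),
        "percent": 100.0 * n_diluted / n_pl,
        "spec": SyntheticSpec(
            "gen_classification_frame",
            {"n_lens": n_lens, "n_diluted": n_diluted, "n_pl": n_pl},
            seed,
        ),
    }
    return frame, truth


@dataclass
class NucleationSample:
    """Drawn nucleation waiting times, optionally with trajectories."""

    times_us: list[float]
    censored: list[bool]
    trajectories: list[Trajectory] = field(default_factory=list)
    true_formation_ns: list[float | None] = field(default_factory=list)
    true_members: list[set[int] | None] = field(default_factory=list)
    spec: SyntheticSpec | None = None


def gen_nucleation_replicas(
    rate_us: float,
    n_replicas: int,
    t_max_us: float = 1.5,
    seed: int = 0,
    with_trajectories: bool = False,
    frame_dt_ns: float = 5.0,
    n_tg: int = 45,
    lens_size: int = 30,
    n_pl: int = 200,
) -> NucleationSample:
    """Exponential nucleation waiting times with censoring at ``t_max_us``.

    With ``with_trajectories``, each replica also gets a bead trajectory:
    TG singletons on a sparse lattice (> 5 nm apart, never clustering at the
    3.5 nm cutoff) until the drawn event time, after which ``lens_size`` of
    them sit in a compact blob at the box center. The true formation time is
    the first sampled frame at or after the drawn time.
    """
    if rate_us < 0:
        raise ContractError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    if rate_us == 0:
        times = np.full(n_replicas, np.inf)
    else:
        times = rng.exponential(1.0 / rate_us, n_replicas)
    censored = times > t_max_us
    sample = NucleationSample(
        times_us=[t_max_us if c else float(t) for t, c in zip(times, censored)],
        censored=censored.tolist(),
        spec=SyntheticSpec(
            "gen_nucleation_replicas",
            {"rate_us": rate_us, "n_replicas": n_replicas, "t_max_us": t_max_us},
            seed,
        ),
    )
    if not with_trajectories:
        return sample
    t_max_ns = t_max_us * 1000.0
    for r in range(n_replicas):
        event_ns = None if censored[r] else times[r] * 1000.0
        traj, true_t, members = _nucleation_trajectory(
            event_ns, t_max_ns, frame_dt_ns, n_tg, lens_size, n_pl,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        sample.trajectories.append(traj)
        sample.true_formation_ns.append(true_t)
        sample.true_members.append(members)
    return sample


def _nucleation_trajectory(event_ns, t_max_ns, dt_ns, n_tg, lens_size, n_pl, rng):
    spacing = 6.0  # sparse TG lattice spacing, safely above the 3.5 nm cutoff
    core = 18.0  # central exclusion zone reserved for the blob
    n_side = math.ceil(math.sqrt(n_tg * 2.2))
    lx = max(n_side * spacing, core + 2 * spacing + 8)
    box = np.array([lx, lx, 10.0])
    center = box / 2
    sparse = []
    k = 0
    while len(sparse) < n_tg and k < n_side**2:
        gx, gy = divmod(k, n_side)
        k += 1
        p = np.array([(gx + 0.5) * spacing, (gy + 0.5) * spacing, 5.0])
        if np.max(np.abs((p - center)[:2])) > core / 2:
            sparse.append(p)
    if len(sparse) < n_tg:
        raise ContractError("sparse TG lattice exhausted")
    sparse = np.array(sparse)
    # compact blob grid (1.5 nm spacing) inside the core zone
    side = math.ceil(math.sqrt(lens_size))
    blob = np.array(
        [
            center + np.array([(i - side / 2 + 0.5) * 1.5, (j - side / 2 + 0.5) * 1.5, 0.0])
            for i in range(side)
            for j in range(side)
        ][:lens_size]
    )
    pl_side = math.ceil(math.sqrt(n_pl))
    pl = np.array(
        [
            [(i + 0.5) * lx / pl_side, (j + 0.5) * lx / pl_side, 2.0]
            for i in range(pl_side)
            for j in range(pl_side)
        ][:n_pl]
    )
    if event_ns is None:
        true_t = None
        t_end = t_max_ns
    else:
        true_t = math.ceil((event_ns - 1e-9) / dt_ns) * dt_ns
        # the run continues until the formation is confirmed, so pad past the
        # event by a generous stability window
        t_end = true_t + 30.0
    times = np.arange(0.0, t_end + dt_ns / 2, dt_ns)
    m2s = {i: "TG" for i in range(n_tg)}
    m2s.update({n_tg + i: "DOPC" for i in range(n_pl)})
    members = set(range(lens_size)) if true_t is not None else None
    frames = []
    for t in times:
        tg = sparse.copy()
        if true_t is not None and t >= true_t:
            tg[:lens_size] = blob
        coords = np.concatenate([tg, pl]) + rng.normal(0, 0.05, (n_tg + n_pl, 3))
        frames.append(
            BeadFrame(
                time=float(t),
                box=box,
                coords=coords,
                bead_to_molecule=np.arange(n_tg + n_pl),
                molecule_to_species=m2s,
            )
        )
    return (
        Trajectory(frames=frames, total_time_us=t_max_ns / 1000.0),
        true_t,
        members,
    )


def gen_helfrich_fields(
    kappa_kT: float,
    box_l: float,
    grid: int = 64,
    n_frames: int = 512,
    seed: int = 0,
    kT: float = 1.0,
    self_check: bool = False,
) -> np.ndarray:
    """Independent height-field frames obeying the tensionless Helfrich
    spectrum <|h_q|^2> = kT/(A kappa q^4) (Fourier convention
    h(r) = sum_q h_q e^{iqr}).

    Returns an (n_frames, grid, grid) array in nm. ``self_check`` verifies
    the empirical shell spectrum against the target within 3 standard
    errors per shell.
    """
    if kappa_kT <= 0:
        raise ContractError("kappa must be > 0")
    rng = np.random.default_rng(seed)
    n = grid
    area = box_l * box_l
    qx = 2 * np.pi * np.fft.fftfreq(n, d=box_l / n)
    qxg, qyg = np.meshgrid(qx, qx, indexing="ij")
    qmag = np.hypot(qxg, qyg)
    s = np.zeros_like(qmag)
    nz = qmag > 0
    s[nz] = kT / (area * kappa_kT * qmag[nz] ** 4)
    amp = np.sqrt(s)
    g = rng.standard_normal((n_frames, n, n, 2)) / math.sqrt(2.0)
    h_q = amp[None] * (g[..., 0] + 1j * g[..., 1])
    fields = math.sqrt(2.0) * (n * n) * np.real(np.fft.ifft2(h_q, axes=(1, 2)))
    if self_check:
        h_hat = np.fft.fft2(fields, axes=(1, 2)) / (n * n)
        meas = np.mean(np.abs(h_hat) ** 2, axis=0)
        dq = 2 * np.pi / box_l
        shell = np.round(qmag / dq).astype(int)
        for sh in range(1, 5):
            m = shell == sh
            target = s[m].mean()
            got = meas[m].mean()
            se = target / math.sqrt(np.count_nonzero(m) * n_frames)
            if abs(got - target) > 3 * se * math.sqrt(2):
                raise AssertionError(
                    f"shell {sh}: spectrum {got:g} vs target {target:g} beyond 3 SE"
                )
    return fields


def _gauss_integral(a_amp, mu, sigma, lo, hi):
    """Integral of A exp(-(z-mu)^2 / 2 sigma^2) over [lo, hi]."""
    s2 = sigma * math.sqrt(2.0)
    return a_amp * sigma * math.sqrt(math.pi / 2.0) * (
        erf((hi - mu) / s2) - erf((lo - mu) / s2)
    )


def _gauss_first_moment(a_amp, mu, sigma, lo, hi):
    """Integral of z A exp(-(z-mu)^2 / 2 sigma^2) over [lo, hi]."""
    g = lambda z: math.exp(-((z - mu) ** 2) / (2 * sigma**2))
    return a_amp * (sigma**2 * (g(lo) - g(hi))) + mu * _gauss_integral(
        a_amp, mu, sigma, lo, hi
    )


def gen_stress_profile(
    form: str = "gaussian-lobes",
    chain_amp: float = 300.0,
    chain_pos: float = 0.8,
    chain_sigma: float = 0.35,
    head_pos: float = 2.0,
    head_sigma: float = 0.3,
    z_max: float = 4.0,
    dz: float = 0.001,
    asymmetry: float = 0.0,
    zero_tension: bool = True,
) -> tuple[PressureProfile, dict]:
    """Analytic lateral-pressure profile with attached reference integrals.

    ``gaussian-lobes``: positive chain lobes at +-``chain_pos`` and negative
    headgroup lobes at +-``head_pos`` whose amplitude is set for zero net
    tension. ``asymmetry`` scales the upper-leaflet lobes by (1+asymmetry).
    ``piecewise``: continuous piecewise-linear lobes with exact polynomial
    integrals.

    The attached dict carries tension, pi_CH between the head minima, and
    the per-leaflet first moments -int z pi dz, computed independently of
    the Simpson pipeline (closed forms; adaptive quadrature for the clipped
    positive part where no elementary form exists).
    """
    z = np.arange(-z_max, z_max + dz / 2, dz)
    up = 1.0 + asymmetry
    if form == "gaussian-lobes":
        head_amp = (
            -chain_amp * chain_sigma / head_sigma if zero_tension else -0.5 * chain_amp
        )
        lobes = [
            (chain_amp * up, chain_pos, chain_sigma),
            (chain_amp, -chain_pos, chain_sigma),
            (head_amp * up, head_pos, head_sigma),
            (head_amp, -head_pos, head_sigma),
        ]

        def pi_of(x):
            return sum(
                a * np.exp(-((x - mu) ** 2) / (2 * sg**2)) for a, mu, sg in lobes
            )

        pi = pi_of(z)
        tension_ref = sum(
            _gauss_integral(a, mu, sg, -np.inf, np.inf) for a, mu, sg in lobes
        )
        moment_up = -sum(_gauss_first_moment(a, mu, sg, 0.0, z_max) for a, mu, sg in lobes)
        moment_lo = sum(_gauss_first_moment(a, mu, sg, -z_max, 0.0) for a, mu, sg in lobes)
        # positive-part integral between the head minima: locate the zero
        # crossings of pi(z) (bracketed on the fine grid, polished with
        # brentq) and sum the erf closed forms over the positive intervals
        def scalar_pi(x):
            return float(pi_of(np.array([x]))[0])

        window = (z >= -head_pos) & (z <= head_pos)
        zw, pw = z[window], pi[window]
        edges = [zw[0]]
        sign_change = np.nonzero(np.sign(pw[:-1]) * np.sign(pw[1:]) < 0)[0]
        for i in sign_change:
            edges.append(brentq(scalar_pi, zw[i], zw[i + 1], xtol=1e-14))
        edges.append(zw[-1])
        pi_ch_ref = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            if scalar_pi(0.5 * (lo + hi)) > 0:
                pi_ch_ref += sum(
                    _gauss_integral(a, mu, sg, lo, hi) for a, mu, sg in lobes
                )
        minima = (-head_pos, head_pos)
    elif form == "piecewise":
        # trapezoid chain lobes on [0.3, 1.3] (plateau [0.5, 1.1]), mirrored;
        # negative head trapezoids sized for zero tension
        def trap(x, lo, p0, p1, hi, amp):
            x = np.asarray(x, dtype=float)
            y = np.zeros_like(x)
            ramp_up = (x >= lo) & (x < p0)
            y[ramp_up] = amp * (x[ramp_up] - lo) / (p0 - lo)
            y[(x >= p0) & (x <= p1)] = amp
            ramp_dn = (x > p1) & (x <= hi)
            y[ramp_dn] = amp * (hi - x[ramp_dn]) / (hi - p1)
            return y

        c_area = chain_amp * ((1.1 - 0.5) + 0.5 * (0.2 + 0.2))  # per lobe
        h_amp = -c_area / ((2.6 - 2.0) + 0.5 * (0.2 + 0.2)) if zero_tension else -chain_amp
        def pi_of(x):
            x = np.asarray(x, dtype=float)
            return (
                up * trap(x, 0.3, 0.5, 1.1, 1.3, chain_amp)
                + trap(-x, 0.3, 0.5, 1.1, 1.3, chain_amp)
                + up * trap(x, 1.8, 2.0, 2.6, 2.8, h_amp)
                + trap(-x, 1.8, 2.0, 2.6, 2.8, h_amp)
            )

        pi = pi_of(z)

        def trap_m0(lo, p0, p1, hi, amp):
            return amp * ((p1 - p0) + 0.5 * ((p0 - lo) + (hi - p1)))

        def trap_m1(lo, p0, p1, hi, amp):
            # int z * trap(z) dz over the support (closed polynomial form)
            ramp_up = amp / (p0 - lo) * (p0**3 / 3 - lo * p0**2 / 2 - (lo**3 / 3 - lo**3 / 2))
            plateau = amp * (p1**2 - p0**2) / 2
            ramp_dn = amp / (hi - p1) * (hi * (hi**2 - p1**2) / 2 - (hi**3 - p1**3) / 3)
            return ramp_up + plateau + ramp_dn

        tension_ref = (1 + up) * (
            trap_m0(0.3, 0.5, 1.1, 1.3, chain_amp) + trap_m0(1.8, 2.0, 2.6, 2.8, h_amp)
        )
        m1 = trap_m1(0.3, 0.5, 1.1, 1.3, chain_amp) + trap_m1(1.8, 2.0, 2.6, 2.8, h_amp)
        moment_up = -up * m1
        moment_lo = -m1
        # positive region between the head minima is the chain lobes alone
        pi_ch_ref = (1 + up) * trap_m0(0.3, 0.5, 1.1, 1.3, chain_amp)
        minima = (-2.3, 2.3)
    else:
        raise ContractError(f"unknown profile form {form!r}")
    profile = PressureProfile(
        z=z,
        p_n=np.zeros_like(z),
        p_t=pi,
        l_z=2 * z_max,
        minima=minima,
        metadata={"generator": "gen_stress_profile", "form": form},
    )
    refs = {
        "tension_mN_m": tension_ref * 0.1,
        "pi_ch_mN_m": pi_ch_ref * 0.1,
        "moment_upper_mN_m_nm": moment_up * 0.1,
        "moment_lower_mN_m_nm": moment_lo * 0.1,
        "asymmetric": asymmetry != 0.0,
    }
    return profile, refs


def gen_relaxation_series(
    plateau_percent: float = 1.1,
    tau_ns: float = 300.0,
    noise_sd: float = 0.1,
    duration_ns: float = 4500.0,
    dt_ns: float = 10.0,
    n_pl_free: int = 3025,
    injection: dict | None = None,
    seed: int = 0,
) -> tuple[DilutedTGSeries, SyntheticSpec]:
    """Diluted-TG relaxation series with a known plateau.

    percent(t) = plateau (1 - e^{-t/tau}) + Gaussian noise; with
    ``injection={'time_ns': t0, 'step_percent': s}`` the series jumps by s
    at t0 and decays back to the plateau with the same time constant
    (excess TG returning to the lens). Counts are the rounded molecule
    numbers implied by ``n_pl_free``; the percent column stays exact.
    """
    if plateau_percent < 0 or tau_ns <= 0 or noise_sd < 0:
        raise ContractError("relaxation series needs plateau >= 0, tau > 0, noise >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_ns + dt_ns / 2, dt_ns)
    clean = plateau_percent * (1.0 - np.exp(-t / tau_ns))
    if injection is not None:
        t0 = float(injection["time_ns"])
        step = float(injection["step_percent"])
        after = t >= t0
        clean[after] += step * np.exp(-(t[after] - t0) / tau_ns)
    percent = clean + (rng.normal(0, noise_sd, len(t)) if noise_sd > 0 else 0.0)
    percent = np.clip(percent, 0.0, None)
    counts = np.round(percent / 100.0 * n_pl_free).astype(int)
    table = pd.DataFrame(
        {
            "time_ns": t,
            "n_lens": 0,
            "n_diluted": counts,
            "n_boundary": 0,
            "n_free_pl": n_pl_free,
            "percent": percent,
        }
    )
    spec = SyntheticSpec(
        "gen_relaxation_series",
        {
            "plateau_percent": plateau_percent,
            "tau_ns": tau_ns,
            "noise_sd": noise_sd,
            "duration_ns": duration_ns,
            "injection": injection,
        },
        seed,
    )
    return DilutedTGSeries(table=table, params=spec.as_dict()), spec


def gen_uniform_mixture_frames(
    n_x: int = 200,
    n_other: int = 800,
    species_x: str = "DOPE",
    species_other: str = "DOPC",
    box_l: float = 40.0,
    n_frames: int = 50,
    seed: int = 0,
) -> list[BeadFrame]:
    """Laterally uniform two-species frames (single-bead molecules) for
    density/enrichment map fixtures; bulk fraction of X is
    n_x / (n_x + n_other) by construction."""
    rng = np.random.default_rng(seed)
    n = n_x + n_other
    m2s = {i: (species_x if i < n_x else species_other) for i in range(n)}
    frames = []
    for k in range(n_frames):
        coords = np.column_stack(
            [
                rng.uniform(0, box_l, n),
                rng.uniform(0, box_l, n),
                np.full(n, 5.0),
            ]
        )
        frames.append(
            BeadFrame(
                time=float(k),
                box=np.array([box_l, box_l, 10.0]),
                coords=coords,
                bead_to_molecule=np.arange(n),
                molecule_to_species=m2s,
            )
        )
    return frames
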