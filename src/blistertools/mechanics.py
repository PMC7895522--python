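"""Lateral-pressure and fluctuation mechanics of planar bilayers.

Stress conventions (fixed package-wide): the lateral pressure profile is
pi(z) = P_T(z) - P_N(z) with P_T = (P_xx + P_yy)/2 and P_N = P_zz, z along
the bilayer normal with the midplane at z = 0. Pressures in bar, z in nm;
1 bar*nm = 0.1 mN/m.

Derived scalars:

* **pi_CH** (hydrophobic chain pressure) — Simpson integral of the positive
  part of pi(z) between the two glycerol minima, on a 0.001 nm (0.01 A)
  grid, in mN/m.
* **first moment / spontaneous curvature** — per leaflet,
  kappa_b * c0 = -int_0^{Lz/2} z pi(z) dz (mirrored with matching sign for
  the lower leaflet so that identical leaflets give equal values); c0
  follows after expressing the monolayer bending modulus kappa_b in
  mN/m*nm^2 (1 kT at 310 K = 4.28 mN/m*nm^2).
* **curvature stress** — kappa_b * c0^2 in kT/nm^2.

Bending moduli come from membrane height fluctuations. The Fourier route
fits the Helfrich spectrum <|h_q|^2> = kT/(A kappa q^4) of the bilayer
midplane height field (fixed slope -4 least squares in log-log space over
the low-q shells; free-slope fit reported as a diagnostic). The monolayer
modulus is taken as half the bilayer value. The real-space route compares
the variance of patch-averaged heights against the discrete-mode Helfrich
prediction for block averaging.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson
from scipy.interpolate import CubicSpline

from .core import (
    BAR_NM_TO_MN_PER_M,
    BeadFrame,
    kT_mN_per_m_nm2,
)
from .errors import (
    ConfigurationError,
    ContractError,
    DetectionError,
    FitError,
    ParseError,
)

__all__ = [
    "PressureProfile",
    "StressMetrics",
    "HeightFields",
    "FluctuationSpectrum",
    "load_stress_table",
    "combine_replicas",
    "tension",
    "glycerol_minima",
    "chain_pressure",
    "first_moment_curvature",
    "curvature_stress",
    "stress_metrics",
    "extract_height_field",
    "kappa_fourier",
    "kappa_realspace",
]

FINE_GRID_NM = 0.001  # 0.01 Angstrom integration bins


@dataclass
class PressureProfile:
    """z-resolved normal/tangential pressure, optionally with replicas.

    ``z`` is strictly increasing with the bilayer midplane at 0. When
    per-replica curves are present, ``p_n``/``p_t`` hold the replica means.
    """

    z: np.ndarray  # nm
    p_n: np.ndarray  # bar
    p_t: np.ndarray  # bar
    l_z: float | None = None  # box height, nm
    replicas: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    minima: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.p_n = np.asarray(self.p_n, dtype=float)
        self.p_t = np.asarray(self.p_t, dtype=float)
        if np.any(np.diff(self.z) <= 0):
            raise ParseError("z grid must be strictly increasing")
        if self.z.shape != self.p_n.shape or self.z.shape != self.p_t.shape:
            raise ContractError("z, p_n, p_t must share one shape")
        if self.l_z is None:
            self.l_z = 2.0 * float(np.max(np.abs(self.z)))

    @property
    def pi(self) -> np.ndarray:
        """Lateral pressure pi(z) = P_T - P_N, in bar."""
        return self.p_t - self.p_n

    def replica_profiles(self) -> "list[PressureProfile]":
        if not self.replicas:
            return [self]
        return [
            PressureProfile(z=self.z, p_n=pn, p_t=pt, l_z=self.l_z, minima=self.minima)
            for pn, pt in self.replicas
        ]


def _recenter(z: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Shift z so the midpoint of the two deepest local minima of pi (the
    bilayer symmetry point) sits at 0; falls back to the grid midpoint for
    featureless profiles."""
    mins = _local_minima(z, pi)
    if len(mins) >= 2:
        vals = pi[mins]
        order = np.argsort(vals)
        z1, z2 = sorted(z[mins[order[:2]]])
        center = 0.5 * (z1 + z2)
    else:
        center = 0.5 * (z[0] + z[-1])
    return z - center


def _local_minima(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    interior = np.nonzero((y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:]))[0] + 1
    return interior


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def load_stress_table(
    path: str | os.PathLike,
    convention: str = "pressure",
    recenter: bool = True,
) -> PressureProfile:
    """Read a whitespace-delimited per-slab stress/pressure table.

    The header (first non-empty line, '#' optional) names the columns:
    ``z`` plus either ``Pxx Pyy Pzz`` (convention='pressure', bar) or
    ``Sxx Syy Szz`` (convention='stress-volume', bar*nm^3, converted via
    P = -S / V_slab with the slab volume read from a ``# slab_volume <nm^3>``
    comment). z may be in nm (default) or Angstrom (``# z_unit angstrom``).
    """
    header: list[str] | None = None
    rows: list[list[float]] = []
    slab_volume: float | None = None
    z_scale = 1.0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0].lower() in ("slab_volume", "v_slab"):
                    slab_volume = float(parts[-1])
                elif parts and parts[0].lower() == "z_unit":
                    z_scale = 0.1 if parts[1].lower().startswith("ang") else 1.0
                elif header is None and parts and not _is_number(parts[0]):
                    header = [p.lower() for p in parts]
                continue
            parts = line.split()
            if header is None:
                if not _is_number(parts[0]):
                    header = [p.lower() for p in parts]
                    continue
                raise ParseError("table must start with a column header", lineno)
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"bad numeric row {line!r}", lineno) from exc
    if header is None or not rows:
        raise ParseError("empty stress table")
    data = np.array(rows)
    cols = {name: data[:, i] for i, name in enumerate(header)}
    if "z" not in cols:
        raise ParseError(f"no z column in header {header}")
    z = cols["z"] * z_scale
    if np.any(np.diff(z) <= 0):
        raise ParseError("non-monotone z grid")
    if convention == "pressure":
        try:
            pxx, pyy, pzz = cols["pxx"], cols["pyy"], cols["pzz"]
        except KeyError as exc:
            raise ParseError(f"pressure convention needs Pxx/Pyy/Pzz, header {header}") from exc
    elif convention == "stress-volume":
        if slab_volume is None:
            raise ConfigurationError(
                "stress-volume convention requires a '# slab_volume <nm^3>' comment"
            )
        try:
            sxx, syy, szz = cols["sxx"], cols["syy"], cols["szz"]
        except KeyError as exc:
            raise ParseError(f"stress-volume convention needs Sxx/Syy/Szz, header {header}") from exc
        pxx, pyy, pzz = -sxx / slab_volume, -syy / slab_volume, -szz / slab_volume
    else:
        raise ContractError(f"unknown convention {convention!r}")
    p_t = 0.5 * (pxx + pyy)
    p_n = pzz
    if recenter:
        z = _recenter(z, p_t - p_n)
    return PressureProfile(
        z=z, p_n=p_n, p_t=p_t, metadata={"path": str(path), "convention": convention}
    )


def combine_replicas(profiles: list[PressureProfile]) -> PressureProfile:
    """Merge replica profiles (identical grids) into one with mean curves."""
    if not profiles:
        raise ContractError("no profiles to combine")
    z = profiles[0].z
    for p in profiles[1:]:
        if p.z.shape != z.shape or not np.allclose(p.z, z):
            raise ContractError("replica z grids differ")
    reps = [(p.p_n, p.p_t) for p in profiles]
    return PressureProfile(
        z=z,
        p_n=np.mean([r[0] for r in reps], axis=0),
        p_t=np.mean([r[1] for r in reps], axis=0),
        l_z=profiles[0].l_z,
        replicas=reps,
    )


def tension(profile: PressureProfile, warn_tol_mN_m: float = 0.1) -> float:
    """Integral of pi(z) over the box, in mN/m; warns when a nominally
    tension-free bilayer exceeds ``warn_tol_mN_m`` in magnitude."""
    t = simpson(profile.pi, x=profile.z) * BAR_NM_TO_MN_PER_M
    if abs(t) > warn_tol_mN_m:
        warnings.warn(
            f"profile carries net tension {t:.3g} mN/m (tolerance {warn_tol_mN_m})",
            stacklevel=2,
        )
    return float(t)


def glycerol_minima(profile: PressureProfile) -> tuple[float, float]:
    """Auto-detect the glycerol-region minima: the deepest local minimum of
    pi(z) on each side of the midplane."""
    z, pi = profile.z, profile.pi
    mins = _local_minima(z, pi)
    left = [i for i in mins if z[i] < 0]
    right = [i for i in mins if z[i] > 0]
    if not left or not right:
        raise DetectionError(
            "no local pi(z) minima on both sides of the midplane; pass minima manually"
        )
    z1 = float(z[min(left, key=lambda i: pi[i])])
    z2 = float(z[min(right, key=lambda i: pi[i])])
    return z1, z2


def _fine_pi(profile: PressureProfile, z0: float, z1: float) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline interpolation of pi(z) onto the 0.01 A integration grid."""
    if z0 < profile.z[0] - 1e-9 or z1 > profile.z[-1] + 1e-9:
        raise ConfigurationError(
            f"[{z0}, {z1}] nm outside the profile grid "
            f"[{profile.z[0]}, {profile.z[-1]}]"
        )
    n = max(int(round((z1 - z0) / FINE_GRID_NM)), 4)
    zz = np.linspace(z0, z1, n + 1)
    spline = CubicSpline(profile.z, profile.pi)
    return zz, spline(zz)


def chain_pressure(
    profile: PressureProfile,
    minima: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """pi_CH: Simpson integral of max(pi(z), 0) between the glycerol minima.

    Returns (value, SD) in mN/m; the SD comes from per-replica curves when
    present, otherwise 0. Minima are auto-detected unless given.
    """
    if minima is None:
        minima = profile.minima or glycerol_minima(profile)
    z1, z2 = minima
    if not (z1 < 0 < z2):
        raise ContractError(f"minima must straddle the midplane, got {minima}")
    values = []
    for rep in profile.replica_profiles():
        zz, pi = _fine_pi(rep, z1, z2)
        values.append(simpson(np.clip(pi, 0.0, None), x=zz) * BAR_NM_TO_MN_PER_M)
    val = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return val, sd


@dataclass
class FirstMoment:
    """First-moment results per leaflet (mN/m * nm) and derived c0 (nm^-1)."""

    kb_c0_upper: float
    kb_c0_lower: float
    kb_c0: float  # leaflet average
    kb_c0_sd: float  # across replicas
    asymmetry: float  # upper - lower
    c0: float
    c0_sd: float
    kappa_b_kT: float


def first_moment_curvature(
    profile: PressureProfile,
    kappa_b_kT: float,
    temperature: float = 310.0,
) -> FirstMoment:
    """Monolayer spontaneous curvature from the LPP first moment.

    Per leaflet, kappa_b*c0 = -int_0^{Lz/2} z pi(z) dz (upper) and the
    z-mirrored integral for the lower leaflet, signed so identical leaflets
    agree. c0 converts via kappa_b in mN/m*nm^2.
    """
    if kappa_b_kT <= 0:
        raise ContractError("kappa_b must be > 0")
    half = profile.l_z / 2.0
    if profile.z[-1] < half - 1e-6 or profile.z[0] > -half + 1e-6:
        raise ConfigurationError(
            f"profile grid [{profile.z[0]}, {profile.z[-1]}] does not span a full "
            f"leaflet (+-{half} nm)"
        )
    uppers, lowers = [], []
    for rep in profile.replica_profiles():
        zz_u, pi_u = _fine_pi(rep, 0.0, half)
        uppers.append(-simpson(zz_u * pi_u, x=zz_u) * BAR_NM_TO_MN_PER_M)
        zz_l, pi_l = _fine_pi(rep, -half, 0.0)
        lowers.append(simpson(zz_l * pi_l, x=zz_l) * BAR_NM_TO_MN_PER_M)
    mu, ml = float(np.mean(uppers)), float(np.mean(lowers))
    means = 0.5 * (np.array(uppers) + np.array(lowers))
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    kb = kappa_b_kT * kT_mN_per_m_nm2(temperature)  # mN/m * nm^2
    kb_c0 = 0.5 * (mu + ml)
    return FirstMoment(
        kb_c0_upper=mu,
        kb_c0_lower=ml,
        kb_c0=kb_c0,
        kb_c0_sd=sd,
        asymmetry=mu - ml,
        c0=kb_c0 / kb,
        c0_sd=sd / kb,
        kappa_b_kT=kappa_b_kT,
    )


def curvature_stress(
    kappa_b_kT: float,
    c0: float,
    kappa_b_sd: float = 0.0,
    c0_sd: float = 0.0,
) -> tuple[float, float]:
    """Monolayer curvature stress kappa_b * c0^2 in kT/nm^2, with
    first-order error propagation from the two inputs."""
    if kappa_b_kT <= 0:
        raise ContractError("kappa_b must be > 0")
    value = kappa_b_kT * c0**2
    var = (c0**2 * kappa_b_sd) ** 2 + (2 * kappa_b_kT * c0 * c0_sd) ** 2
    return float(value), float(math.sqrt(var))


@dataclass
class StressMetrics:
    """Bundle of LPP-derived stress descriptors for one composition."""

    pi_ch_mN_m: float
    pi_ch_sd: float
    kb_c0_mN_m_nm: float
    kb_c0_sd: float
    c0_per_nm: float
    kappa_b_kT: float
    curvature_stress_kT_nm2: float
    curvature_stress_sd: float
    tension_mN_m: float
    minima: tuple[float, float]


def stress_metrics(
    profile: PressureProfile,
    kappa_b_kT: float,
    kappa_b_sd: float = 0.0,
    temperature: float = 310.0,
    minima: tuple[float, float] | None = None,
) -> StressMetrics:
    """One-call pipeline: tension check, pi_CH, first moment, c0, stress."""
    minima = minima or profile.minima or glycerol_minima(profile)
    pi_ch, pi_sd = chain_pressure(profile, minima=minima)
    fm = first_moment_curvature(profile, kappa_b_kT, temperature=temperature)
    stress, stress_sd = curvature_stress(kappa_b_kT, fm.c0, kappa_b_sd, fm.c0_sd)
    return StressMetrics(
        pi_ch_mN_m=pi_ch,
        pi_ch_sd=pi_sd,
        kb_c0_mN_m_nm=fm.kb_c0,
        kb_c0_sd=fm.kb_c0_sd,
        c0_per_nm=fm.c0,
        kappa_b_kT=kappa_b_kT,
        curvature_stress_kT_nm2=stress,
        curvature_stress_sd=stress_sd,
        tension_mN_m=tension(profile),
        minima=minima,
    )


# ---------------------------------------------------------------------------
# height fields and bending moduli


@dataclass
class HeightFields:
    """Per-leaflet and midplane height fields on a lateral grid (nm)."""

    upper: np.ndarray
    lower: np.ndarray
    mid: np.ndarray
    box_xy: tuple[float, float]
    n_empty: int


def _fill_nearest(field: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Nearest-neighbor fill of empty lateral cells (periodic)."""
    if not mask.any():
        return field
    from scipy.spatial import cKDTree

    nx, ny = field.shape
    filled = np.array(np.nonzero(~mask)).T.astype(float)
    empty = np.array(np.nonzero(mask)).T.astype(float)
    tree = cKDTree(filled, boxsize=(nx, ny))
    _, idx = tree.query(empty, k=1)
    out = field.copy()
    src = filled[idx].astype(int)
    out[empty[:, 0].astype(int), empty[:, 1].astype(int)] = field[src[:, 0], src[:, 1]]
    return out


def extract_height_field(
    frame: BeadFrame,
    grid: tuple[int, int] = (32, 32),
    role: str = "glycerol",
    max_empty_fraction: float = 0.2,
) -> HeightFields:
    """Leaflet height fields from reference-bead z positions.

    Reference beads (default role 'glycerol') are split into leaflets by
    their z relative to the global reference-bead mean, binned into an
    Nx x Ny lateral grid, and averaged per cell. Empty cells are filled from
    the nearest occupied cell; more than ``max_empty_fraction`` empty cells
    raises a resolution error (grid too fine for the bead density).
    """
    nx, ny = grid
    sel = np.nonzero(frame.bead_role == role)[0]
    if len(sel) == 0:
        raise ContractError(f"no beads with role {role!r}")
    xy = frame.coords[sel, :2]
    z = frame.coords[sel, 2]
    zmid = z.mean()
    lx, ly = float(frame.box[0]), float(frame.box[1])
    ix = np.minimum((xy[:, 0] / lx * nx).astype(int), nx - 1)
    iy = np.minimum((xy[:, 1] / ly * ny).astype(int), ny - 1)
    fields = []
    n_empty_total = 0
    for leaflet_mask in (z >= zmid, z < zmid):
        count = np.zeros((nx, ny))
        total = np.zeros((nx, ny))
        np.add.at(count, (ix[leaflet_mask], iy[leaflet_mask]), 1.0)
        np.add.at(total, (ix[leaflet_mask], iy[leaflet_mask]), z[leaflet_mask])
        empty = count == 0
        n_empty_total += int(empty.sum())
        if empty.mean() > max_empty_fraction:
            raise ConfigurationError(
                f"{empty.mean():.0%} empty cells on a {nx}x{ny} grid; grid too fine"
            )
        with np.errstate(invalid="ignore"):
            mean = np.where(empty, 0.0, total / np.maximum(count, 1))
        fields.append(_fill_nearest(mean, empty))
    upper, lower = fields
    return HeightFields(
        upper=upper,
        lower=lower,
        mid=0.5 * (upper + lower),
        box_xy=(lx, ly),
        n_empty=n_empty_total,
    )


@dataclass
class FluctuationSpectrum:
    """Shell-averaged undulation spectrum with the fitted bending modulus."""

    q_shells: np.ndarray  # nm^-1
    spectrum: np.ndarray  # <|h_q|^2>, nm^2
    kappa_kT: float  # bilayer modulus
    kappa_b_kT: float  # monolayer modulus (= kappa/2)
    slope: float  # free-slope diagnostic (Helfrich expects -4)
    q_range: tuple[float, float]
    n_frames: int
    no_undulation: bool = False


def _mode_grid(shape: tuple[int, int], box_xy: tuple[float, float]):
    nx, ny = shape
    lx, ly = box_xy
    qx = 2 * np.pi * np.fft.fftfreq(nx, d=lx / nx)
    qy = 2 * np.pi * np.fft.fftfreq(ny, d=ly / ny)
    return np.meshgrid(qx, qy, indexing="ij")


def kappa_fourier(
    fields: "np.ndarray | list[np.ndarray]",
    box_xy: tuple[float, float],
    q_max: float = 1.0,
    n_shells: int = 4,
    kT: float = 1.0,
) -> FluctuationSpectrum:
    """Bending modulus from the Helfrich undulation spectrum.

    ``fields`` is a sequence of midplane height fields (nm) on a common
    grid. Fourier amplitudes use the convention h(r) = sum_q h_q e^{iqr}
    (h_q = FFT/N^2), under which the tensionless Helfrich expectation is
    <|h_q|^2> = kT/(A kappa q^4). kappa is the fixed-slope least-squares
    estimate over modes in the first ``n_shells`` nonzero q-shells capped at
    ``q_max``; the free-slope log-log fit is returned as a diagnostic.
    With kT = 1 (default) kappa is reported in kT units.
    """
    arr = np.asarray(fields, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    n_frames, nx, ny = arr.shape
    lx, ly = box_xy
    area = lx * ly
    h_q = np.fft.fft2(arr, axes=(1, 2)) / (nx * ny)
    s_q = np.mean(np.abs(h_q) ** 2, axis=0)
    qxg, qyg = _mode_grid((nx, ny), box_xy)
    qmag = np.hypot(qxg, qyg)
    dq = 2 * np.pi / max(lx, ly)
    shell = np.round(qmag / dq).astype(int)
    sel = (shell >= 1) & (shell <= n_shells) & (qmag <= q_max + 1e-12)
    if np.count_nonzero(np.unique(shell[sel])) < 3:
        raise FitError(
            f"fewer than 3 q-shells with q <= {q_max}; enlarge the box or q_max"
        )
    s_sel = s_q[sel]
    q_sel = qmag[sel]
    if np.all(s_sel <= 0) or np.mean(s_sel) < 1e-300:
        return FluctuationSpectrum(
            q_shells=np.unique(q_sel),
            spectrum=np.zeros_like(np.unique(q_sel)),
            kappa_kT=np.inf,
            kappa_b_kT=np.inf,
            slope=np.nan,
            q_range=(float(q_sel.min()), float(q_sel.max())),
            n_frames=n_frames,
            no_undulation=True,
        )
    # fixed-slope (-4) least squares == per-mode kappa geometric mean
    kappa_modes = kT / (area * q_sel**4 * s_sel)
    kappa = float(np.exp(np.mean(np.log(kappa_modes))))
    # shell averages + free-slope diagnostic
    shells = np.unique(shell[sel])
    q_shells = np.array([qmag[sel][shell[sel] == s].mean() for s in shells])
    s_shells = np.array([s_q[sel][shell[sel] == s].mean() for s in shells])
    slope = float(np.polyfit(np.log(q_shells), np.log(s_shells), 1)[0])
    return FluctuationSpectrum(
        q_shells=q_shells,
        spectrum=s_shells,
        kappa_kT=kappa,
        kappa_b_kT=kappa / 2.0,
        slope=slope,
        q_range=(float(q_sel.min()), float(q_sel.max())),
        n_frames=n_frames,
    )


def _block_variance_prediction(
    shape: tuple[int, int], box_xy: tuple[float, float], b: int
) -> float:
    """Expected variance of b x b block-averaged heights for a unit-kappa
    (kT = 1) Helfrich field on the discrete mode grid: the sum over modes of
    S(q) |D_b(qx) D_b(qy)|^2 with Dirichlet-kernel block windows."""
    nx, ny = shape
    lx, ly = box_xy
    qxg, qyg = _mode_grid(shape, box_xy)
    qmag = np.hypot(qxg, qyg)
    dx, dy = lx / nx, ly / ny

    def dirichlet(q, d):
        x = q * d / 2.0
        num = np.sin(b * x)
        den = b * np.sin(x)
        out = np.ones_like(q)
        nz = np.abs(den) > 1e-300
        out[nz] = num[nz] / den[nz]
        return out

    w = (dirichlet(qxg, dx) * dirichlet(qyg, dy)) ** 2
    s = np.zeros_like(qmag)
    nz = qmag > 0
    s[nz] = 1.0 / (lx * ly * qmag[nz] ** 4)
    return float(np.sum(s * w))


def kappa_realspace(
    fields: "np.ndarray | list[np.ndarray]",
    box_xy: tuple[float, float],
    patch_sizes: list[int] | None = None,
    kT: float = 1.0,
) -> float:
    """Bending modulus from real-space patch-averaged height variances.

    For each patch size b, heights are averaged over non-overlapping b x b
    blocks (per-frame mean removed) and the empirical variance is compared
    with the discrete-mode Helfrich prediction, which scales as 1/kappa;
    kappa is the geometric mean of the per-size ratios. Variance must
    decrease with patch size (long wavelengths dominate a q^-4 spectrum);
    a monotonicity violation triggers a warning and fit rejection.
    """
    arr = np.asarray(fields, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    _, nx, ny = arr.shape
    if nx != ny:
        raise ContractError("real-space estimator expects a square grid")
    if patch_sizes is None:
        patch_sizes = [b for b in (2, 4, 8, 16) if nx % b == 0 and b <= nx // 4]
    if not patch_sizes:
        raise ContractError("no valid patch sizes for this grid")
    centered = arr - arr.mean(axis=(1, 2), keepdims=True)
    variances = []
    for b in patch_sizes:
        blocks = centered.reshape(arr.shape[0], nx // b, b, ny // b, b).mean(axis=(2, 4))
        variances.append(float(np.mean(blocks**2)))
    variances = np.array(variances)
    if np.all(variances < 1e-300):
        raise FitError("flat fields: no measurable undulation to fit")
    if len(variances) > 1 and np.any(np.diff(variances) > 0):
        warnings.warn(
            "patch variance does not decrease with patch size; fit rejected",
            stacklevel=2,
        )
        raise FitError("variance vs patch size violates Helfrich monotonicity")
    preds = np.array(
        [_block_variance_prediction((nx, ny), box_xy, b) for b in patch_sizes]
    )
    kappas = kT * preds / variances
    return float(np.exp(np.mean(np.log(kappas))))
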