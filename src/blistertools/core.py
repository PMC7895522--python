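"""Domain types and shared geometry for bilayer/blister analysis.

Internal unit conventions, fixed package-wide: lengths in nm, times in ns,
pressures in bar, energies in kT (at the configured temperature). Readers
convert on ingest; nothing downstream ever sees Angstroms.

A :class:`BeadFrame` is a single time point of a coarse-grained bilayer
simulation: bead coordinates in an orthorhombic periodic box plus the
bead -> molecule -> species bookkeeping needed to ask molecular questions
(which molecules are triglyceride, where is a molecule's mean position).
Coordinates are stored wrapped into the primary box and all distances use
the minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import AmbiguityError, ContractError, StructuralError

__all__ = [
    "PL_SPECIES",
    "TG_SPECIES",
    "SPECIES_CATEGORY",
    "ROLES",
    "BOLTZMANN_J_PER_K",
    "BAR_NM_TO_MN_PER_M",
    "kT_joule",
    "kT_mN_per_m_nm2",
    "BeadFrame",
    "Trajectory",
    "CompositionSpec",
    "AnalysisConfig",
    "composition_summary",
    "minimum_image",
    "periodic_kdtree",
    "check_cutoff",
    "unwrap_group",
]

# ---------------------------------------------------------------------------
# species vocabulary and constants

#: Bilayer-forming phospholipids (concentration denominators).
PL_SPECIES = frozenset({"DOPC", "DOPE", "DPPC", "DLPC", "DLPE", "POPC"})

#: Neutral-lipid (triglyceride) species, the de-mixing phase.
TG_SPECIES = frozenset({"TG", "TOOP", "TOPP"})

#: Default species -> category map; extensible per-frame via ``species_categories``.
SPECIES_CATEGORY: dict[str, str] = {
    **{s: "pl" for s in PL_SPECIES},
    **{s: "tg" for s in TG_SPECIES},
    "DAG": "dag",
    "CHOL": "sterol",
}

ROLES = ("head", "glycerol", "tail", "other")

BOLTZMANN_J_PER_K = 1.380649e-23
#: 1 bar * nm = 0.1 mN/m (pressure integrated across a slab).
BAR_NM_TO_MN_PER_M = 0.1


def kT_joule(temperature: float = 310.0) -> float:
    """Thermal energy in joules; 4.28e-21 J at 310 K."""
    return BOLTZMANN_J_PER_K * temperature


def kT_mN_per_m_nm2(temperature: float = 310.0) -> float:
    """Thermal energy expressed in mN/m * nm^2 (= 1e-21 J)."""
    return kT_joule(temperature) / 1e-21


# ---------------------------------------------------------------------------
# geometry helpers


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map displacement vector(s) into the minimum-image cell [-L/2, L/2)."""
    disp = np.asarray(disp, dtype=float)
    box = np.asarray(box, dtype=float)
    return disp - box * np.round(disp / box)


def check_cutoff(cutoff: float, box: np.ndarray, axes: Sequence[int] = (0, 1, 2)) -> None:
    """Reject cutoffs at or beyond half the smallest relevant box edge."""
    box = np.asarray(box, dtype=float)
    half = min(box[a] for a in axes) / 2.0
    if cutoff >= half:
        raise AmbiguityError(
            f"cutoff {cutoff} nm >= half the smallest box edge ({half} nm); "
            "minimum-image distances are ambiguous"
        )


def periodic_kdtree(points: np.ndarray, box: np.ndarray) -> cKDTree:
    """KD-tree with periodic wrap-around in an orthorhombic box."""
    box = np.asarray(box, dtype=float)
    pts = np.mod(np.asarray(points, dtype=float), box)
    # guard against points landing exactly on the upper boundary after mod
    pts = np.where(pts >= box, 0.0, pts)
    return cKDTree(pts, boxsize=box)


def unwrap_group(coords: np.ndarray, box: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Unwrap a set of coordinates to the periodic images nearest ``reference``
    (default: the first coordinate). Used to give a molecule or a lens a
    well-defined extent even when it straddles a box boundary."""
    coords = np.asarray(coords, dtype=float)
    if reference is None:
        reference = coords[0]
    return reference + minimum_image(coords - reference, box)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class BeadFrame:
    """One frame of bead coordinates with molecular bookkeeping.

    Parameters
    ----------
    time : float
        Frame time in ns.
    box : array (3,)
        Orthorhombic box edges (Lx, Ly, Lz) in nm; periodic in all axes.
    coords : array (N, 3)
        Bead positions in nm; wrapped into [0, L) on construction.
    bead_to_molecule : array (N,)
        Molecule id per bead.
    molecule_to_species : mapping
        Molecule id -> species label.
    bead_role : sequence of str
        Per-bead role, one of {'head', 'glycerol', 'tail', 'other'}.
    species_categories : mapping, optional
        Extra or overriding species -> category entries ('pl', 'tg', 'dag',
        'sterol', ...). The built-in vocabulary stays closed unless extended
        here (typically from topology metadata).
    """

    time: float
    box: np.ndarray
    coords: np.ndarray
    bead_to_molecule: np.ndarray
    molecule_to_species: Mapping[int, str]
    bead_role: np.ndarray | Sequence[str] | None = None
    species_categories: Mapping[str, str] | None = None

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.bead_to_molecule = np.asarray(self.bead_to_molecule, dtype=np.int64)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ContractError(f"box must be 3 positive edges, got {self.box!r}")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ContractError("coords must be an (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ContractError("coordinates must be finite")
        n = len(self.coords)
        if self.bead_to_molecule.shape != (n,):
            raise ContractError("bead_to_molecule must map every bead to one molecule")
        if self.bead_role is None:
            self.bead_role = np.full(n, "other", dtype="U8")
        else:
            self.bead_role = np.asarray(self.bead_role, dtype="U8")
            if self.bead_role.shape != (n,):
                raise ContractError("bead_role must have one entry per bead")
        self.molecule_to_species = dict(self.molecule_to_species)
        cats = dict(SPECIES_CATEGORY)
        if self.species_categories:
            cats.update(self.species_categories)
        self._categories = cats
        mols = np.unique(self.bead_to_molecule)
        missing = [m for m in mols.tolist() if m not in self.molecule_to_species]
        if missing:
            raise ContractError(f"molecules without species label: {missing[:5]}")
        unknown = sorted(
            {s for s in self.molecule_to_species.values() if s not in cats}
        )
        if unknown:
            raise ContractError(
                f"species {unknown} outside the declared vocabulary; extend via "
                "species_categories"
            )
        # store wrapped
        self.coords = np.mod(self.coords, self.box)
        self.coords = np.where(self.coords >= self.box, 0.0, self.coords)
        self._mol_pos_cache: dict | None = None

    # -- molecular views ----------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def molecule_ids(self) -> np.ndarray:
        return np.unique(self.bead_to_molecule)

    def category(self, species: str) -> str:
        return self._categories.get(species, "other")

    def molecules_of_category(self, category: str) -> np.ndarray:
        """Molecule ids whose species maps to ``category`` ('pl', 'tg', ...)."""
        return np.array(
            sorted(
                m
                for m, s in self.molecule_to_species.items()
                if self._categories.get(s) == category
            ),
            dtype=np.int64,
        )

    def molecules_of_species(self, species: str | Iterable[str]) -> np.ndarray:
        wanted = {species} if isinstance(species, str) else set(species)
        return np.array(
            sorted(m for m, s in self.molecule_to_species.items() if s in wanted),
            dtype=np.int64,
        )

    def molecule_positions(self, molecule_ids: np.ndarray | None = None) -> np.ndarray:
        """Unweighted mean bead position per molecule, after minimum-image
        unwrapping of each molecule around its first bead; wrapped back into
        the box. This is the default molecular reference point for all
        distance-based operations."""
        if self._mol_pos_cache is None:
            order = np.argsort(self.bead_to_molecule, kind="stable")
            mols_sorted = self.bead_to_molecule[order]
            uniq, starts, counts = np.unique(
                mols_sorted, return_index=True, return_counts=True
            )
            coords_sorted = self.coords[order]
            # minimum-image unwrap of each molecule around its first bead
            refs = np.repeat(coords_sorted[starts], counts, axis=0)
            disp = minimum_image(coords_sorted - refs, self.box)
            sums = np.add.reduceat(disp, starts, axis=0)
            pos = coords_sorted[starts] + sums / counts[:, None]
            pos = np.mod(pos, self.box)
            pos = np.where(pos >= self.box, 0.0, pos)
            self._mol_pos_cache = {int(m): i for i, m in enumerate(uniq)}, pos
        index, pos = self._mol_pos_cache
        if molecule_ids is None:
            return pos
        rows = np.array([index[int(m)] for m in np.atleast_1d(molecule_ids)])
        return pos[rows]

    def beads_of_molecules(self, molecule_ids: Iterable[int]) -> np.ndarray:
        wanted = np.isin(self.bead_to_molecule, np.asarray(list(molecule_ids)))
        return np.nonzero(wanted)[0]

    def species_counts(self) -> dict[str, int]:
        return {
            s: int(
                sum(1 for sp in self.molecule_to_species.values() if sp == s)
            )
            for s in sorted(set(self.molecule_to_species.values()))
        }

    def translated(self, shift: np.ndarray) -> "BeadFrame":
        """Rigidly translate all beads (with periodic wrap)."""
        return replace(self, coords=np.mod(self.coords + np.asarray(shift), self.box))


@dataclass
class CompositionSpec:
    """Molecule counts per species with the TG/PL ratio bookkeeping.

    The neutral-lipid concentration convention of the whole package:
    ``tg_pl_ratio`` is 100 * N_TG / N_PL (percent of TG relative to
    phospholipid count, never mol% of total lipid).
    """

    species_counts: Mapping[str, int]
    tg_species: str | None = None
    species_categories: Mapping[str, str] | None = None

    def __post_init__(self):
        self.species_counts = {k: int(v) for k, v in self.species_counts.items()}
        if any(v < 0 for v in self.species_counts.values()):
            raise ContractError("species counts must be >= 0")
        cats = dict(SPECIES_CATEGORY)
        if self.species_categories:
            cats.update(self.species_categories)
        self._categories = cats
        if self.n_pl == 0:
            raise ContractError("composition must contain at least one PL species")
        if self.tg_species is None:
            tg_present = [
                s for s, n in self.species_counts.items()
                if cats.get(s) == "tg" and n > 0
            ]
            self.tg_species = tg_present[0] if tg_present else "TG"

    def _count(self, category: str) -> int:
        return sum(
            n for s, n in self.species_counts.items()
            if self._categories.get(s) == category
        )

    @property
    def n_pl(self) -> int:
        return self._count("pl")

    @property
    def n_tg(self) -> int:
        return self._count("tg")

    @property
    def tg_pl_ratio(self) -> float:
        """Percent: 100 * N_TG / N_PL."""
        return 100.0 * self.n_tg / self.n_pl

    def label(self) -> str:
        parts = [f"{n} {s}" for s, n in sorted(self.species_counts.items()) if n > 0]
        return " + ".join(parts)


@dataclass
class Trajectory:
    """Time-ordered frames with constant composition.

    ``total_time_us`` defaults to the span of the frame times but may be set
    explicitly (e.g. the scheduled run length for censoring bookkeeping).
    """

    frames: Sequence[BeadFrame]
    replica_id: str | int | None = None
    total_time_us: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = list(self.frames)
        if not self.frames:
            raise ContractError("trajectory needs at least one frame")
        times = np.array([f.time for f in self.frames])
        if np.any(np.diff(times) <= 0):
            raise StructuralError("frame times must be strictly increasing")
        counts0 = self.frames[0].species_counts()
        for i, f in enumerate(self.frames[1:], start=1):
            if f.species_counts() != counts0:
                raise StructuralError(
                    f"composition changes at frame {i}: {f.species_counts()} != {counts0}"
                )
        if self.total_time_us is None:
            self.total_time_us = (times[-1] - times[0]) / 1000.0

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def composition(self) -> CompositionSpec:
        return composition_summary(self)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def composition_summary(traj: "Trajectory | BeadFrame") -> CompositionSpec:
    """Count molecules per species and derive the TG/PL percentage.

    Examples: 3200 DOPC + 192 TG gives a 6.0% TG/PL ratio; 1280 DOPC +
    1920 DPPC + 128 TG gives 4.0%.
    """
    frame = traj.frames[0] if isinstance(traj, Trajectory) else traj
    return CompositionSpec(
        species_counts=frame.species_counts(),
        species_categories=getattr(frame, "species_categories", None),
    )


@dataclass
class AnalysisConfig:
    """Shared parameters for all analysis stages.

    Defaults are the production analysis settings: lens criterion 25 TG
    within 3.5 nm stable for 5 ns; diluted-TG selection 5.0 / 2.8 / 2.5 nm;
    plateau window = trailing 1.5 us; censoring horizon 1.5 us; T = 310 K.
    """

    temperature: float = 310.0  # K
    seed: int | None = None
    # lens kinetics
    cluster_cutoff: float = 3.5  # nm
    min_size: int = 25
    persistence_ns: float = 5.0
    total_time_us: float = 1.5
    tau0_ns: float = 1.0  # attempt-time normalization for rate -> energy
    # diluted-TG protocol
    tg_tg_cutoff: float = 5.0  # nm
    tg_pl_cutoff: float = 2.8  # nm
    lens_margin: float = 2.5  # nm
    plateau_window_ns: float = 1500.0
    # reference-point convention: 'mean' molecule position or 'min-bead' distance
    distance_mode: str = "mean"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ContractError("temperature must be > 0")
        for name in ("cluster_cutoff", "persistence_ns", "tg_tg_cutoff",
                     "tg_pl_cutoff", "lens_margin", "plateau_window_ns", "tau0_ns"):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be > 0")

    @property
    def kT_J(self) -> float:
        return kT_joule(self.temperature)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
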