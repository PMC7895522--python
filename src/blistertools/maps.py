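"""2D lateral density and enrichment/depletion maps.

Number-density maps are time-averaged molecule counts per lateral cell
divided by the cell area (nm^-2). With lens-centered alignment each frame is
translated so the lens centroid sits at the box center before binning, so
maps accumulate in the lens frame of reference.

Enrichment of species X against a background set follows
enrichment(cell) = [rho_X / (rho_X + rho_background)] / x_bulk, where x_bulk
is the bulk fraction of X within the same species set. Cells whose total
density falls below a floor (too few molecules to estimate a fraction) are
masked. By construction the density-weighted mean enrichment over unmasked
cells is 1 when bulk fraction and maps come from the same frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BeadFrame, Trajectory
from .errors import ContractError

__all__ = ["EnrichmentMap", "lateral_density", "enrichment", "lens_centroid"]


def lens_centroid(frame: BeadFrame, lens: set[int]) -> np.ndarray:
    """Periodic (circular-mean) centroid of the lens molecules' xy position."""
    if not lens:
        raise ContractError("empty lens")
    pos = frame.molecule_positions(np.array(sorted(lens)))
    box = frame.box
    ang = 2 * np.pi * pos / box
    mean = np.arctan2(np.sin(ang).mean(axis=0), np.cos(ang).mean(axis=0))
    return np.mod(mean / (2 * np.pi) * box, box)


@dataclass
class EnrichmentMap:
    """Enrichment values on a lateral grid with the low-density mask."""

    values: np.ndarray  # (nx, ny), dimensionless, >= 0
    mask: np.ndarray  # True where the cell is excluded (low density)
    bulk_fraction: float
    cell_nm: tuple[float, float]


def lateral_density(
    traj: "Trajectory | list[BeadFrame]",
    species: str | list[str],
    grid: tuple[int, int] = (32, 32),
    alignment: str = "none",
    lens_sets: "list[set[int]] | None" = None,
) -> np.ndarray:
    """Time-averaged lateral number-density map (nm^-2) for a species.

    ``alignment='lens-centered'`` recenters every frame on the centroid of
    the corresponding entry of ``lens_sets`` (per-frame lens memberships,
    e.g. from classify_tg) before binning; without a lens the frame is used
    box-centered as-is.
    """
    frames = list(traj.frames) if isinstance(traj, Trajectory) else list(traj)
    if not frames:
        raise ContractError("no frames")
    nx, ny = grid
    lx, ly = float(frames[0].box[0]), float(frames[0].box[1])
    acc = np.zeros((nx, ny))
    wanted = [species] if isinstance(species, str) else list(species)
    for k, frame in enumerate(frames):
        mols = frame.molecules_of_species(wanted)
        if len(mols) == 0:
            raise ContractError(f"species {wanted} absent from frame {k}")
        pos = frame.molecule_positions(mols)[:, :2]
        if alignment == "lens-centered" and lens_sets is not None and lens_sets[k]:
            center = lens_centroid(frame, lens_sets[k])[:2]
            shift = np.array([lx / 2, ly / 2]) - center
            pos = np.mod(pos + shift, (lx, ly))
        ix = np.minimum((pos[:, 0] / lx * nx).astype(int), nx - 1)
        iy = np.minimum((pos[:, 1] / ly * ny).astype(int), ny - 1)
        np.add.at(acc, (ix, iy), 1.0)
    cell_area = (lx / nx) * (ly / ny)
    return acc / (len(frames) * cell_area)


def enrichment(
    map_x: np.ndarray,
    map_background: np.ndarray,
    bulk_fraction: float,
    density_floor: float | None = None,
    n_frames: int = 1,
    cell_nm: tuple[float, float] = (1.0, 1.0),
) -> EnrichmentMap:
    """Enrichment of species X against X + background, normalized by bulk.

    ``map_background`` is the summed density map of the *other* species in
    the declared set (so total = map_x + map_background). ``density_floor``
    masks cells expected to hold fewer molecules than the floor over the
    averaging window (default: 5 molecules per cell across ``n_frames``).
    """
    if map_x.shape != map_background.shape:
        raise ContractError("maps must share one grid")
    if not (0.0 < bulk_fraction < 1.0):
        raise ContractError("bulk fraction must be in (0, 1)")
    total = map_x + map_background
    cell_area = cell_nm[0] * cell_nm[1]
    if density_floor is None:
        density_floor = 5.0 / (n_frames * cell_area)
    mask = total < density_floor
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, map_x / np.where(total > 0, total, 1.0), 0.0)
    values = np.where(mask, np.nan, frac / bulk_fraction)
    return EnrichmentMap(
        values=values, mask=mask, bulk_fraction=bulk_fraction, cell_nm=cell_nm
    )


def density_weighted_mean(emap: EnrichmentMap, total_density: np.ndarray) -> float:
    """Mean enrichment weighted by total density over unmasked cells; equals
    1 exactly when the bulk fraction is computed from the same frames."""
    ok = ~emap.mask
    w = total_density[ok]
    return float(np.sum(emap.values[ok] * w) / np.sum(w))
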