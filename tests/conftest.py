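"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's KD-tree/cell-list code
paths: clustering uses an O(N^2) pairwise union-find, classification uses
dense all-pairs distance matrices. They are the ground truth the optimized
implementations are gated against.
"""

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# brute-force oracles


def min_image_dist(a, b, box):
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1))


def pairwise_min_image(points, box):
    """Dense (N, N) minimum-image distance matrix."""
    points = np.asarray(points, dtype=float)
    d = points[:, None, :] - points[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1))


def cross_min_image(a, b, box):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1))


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def brute_force_clusters(points, box, cutoff):
    """All-pairs single-linkage connected components (list of index sets)."""
    n = len(points)
    if n == 0:
        return []
    dist = pairwise_min_image(points, box)
    uf = _UnionFind(n)
    close = np.triu(dist <= cutoff, k=1)
    for i, j in np.argwhere(close):
        uf.union(int(i), int(j))
    comps = {}
    for i in range(n):
        comps.setdefault(uf.find(i), set()).add(i)
    return sorted(comps.values(), key=len, reverse=True)


def brute_force_classify(tg_pos, pl_pos, box, tg_tg=5.0, tg_pl=2.8, margin=2.5):
    """Dense-matrix lens/diluted/boundary partition (index sets over TG)."""
    n_tg = len(tg_pos)
    if n_tg == 0:
        return set(), set(), set(), set(range(len(pl_pos)))
    dtt = pairwise_min_image(tg_pos, box)
    np.fill_diagonal(dtt, np.inf)
    dtp = cross_min_image(tg_pos, pl_pos, box)
    near_tg = (dtt <= tg_tg).any(axis=1)
    near_pl = (dtp <= tg_pl).any(axis=1)
    lens = set(np.nonzero(near_tg & ~near_pl)[0].tolist())
    if lens:
        lens_idx = sorted(lens)
        d_tg_lens = dtt[:, lens_idx].min(axis=1)
        d_pl_lens = dtp.T[:, lens_idx].min(axis=1)
        free_pl = set(np.nonzero(d_pl_lens >= margin)[0].tolist())
        diluted = {
            i for i in range(n_tg)
            if i not in lens and d_tg_lens[i] >= margin
        }
    else:
        free_pl = set(range(len(pl_pos)))
        diluted = set(range(n_tg))
    boundary = set(range(n_tg)) - lens - diluted
    return lens, diluted, boundary, free_pl


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def lens_system():
    """Small implanted-lens trajectory with known diluted fraction."""
    from blistertools.synth import gen_lens_system

    traj, truth = gen_lens_system(
        n_pl=1800, n_tg_lens=400, diluted_fraction=1.5, radius=7.0,
        thickness=7.0, n_frames=4, seed=11,
    )
    return traj, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_single_bead_frame(rng, n_tg, n_pl, box):
    """Uniform random single-bead TG/PL frame (no structure)."""
    from blistertools.core import BeadFrame

    n = n_tg + n_pl
    coords = rng.uniform(0, 1, (n, 3)) * box
    species = {i: ("TG" if i < n_tg else "DOPC") for i in range(n)}
    return BeadFrame(
        time=0.0,
        box=np.asarray(box, dtype=float),
        coords=coords,
        bead_to_molecule=np.arange(n),
        molecule_to_species=species,
    )
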