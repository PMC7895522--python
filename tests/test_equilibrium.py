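"""Diluted-TG protocol: classification, plateaus, dissolution, extents."""

import numpy as np
import pytest

from blistertools.core import BeadFrame, Trajectory
from blistertools.equilibrium import (
    classify_tg,
    detect_dissolution,
    diluted_series,
    excess_tg,
    lens_extent,
    plateau_stats,
)
from blistertools.errors import ConfigurationError, ContractError
from blistertools.synth import (
    gen_classification_frame,
    gen_relaxation_series,
)

from conftest import brute_force_classify


def simple_frame(tg_pos, pl_pos, box=(60.0, 60.0, 20.0), time=0.0):
    tg_pos = np.asarray(tg_pos, dtype=float).reshape(-1, 3)
    pl_pos = np.asarray(pl_pos, dtype=float).reshape(-1, 3)
    coords = np.vstack([tg_pos, pl_pos]) if len(tg_pos) else pl_pos
    n_tg = len(tg_pos)
    species = {i: ("TG" if i < n_tg else "DOPC") for i in range(len(coords))}
    return BeadFrame(
        time=time,
        box=np.asarray(box),
        coords=coords,
        bead_to_molecule=np.arange(len(coords)),
        molecule_to_species=species,
    )


class TestClassifyTG:
    def test_single_tg_near_pl_is_diluted(self):
        frame = simple_frame([[10, 10, 10]], [[11, 10, 10]])
        cls = classify_tg(frame)
        assert cls.lens == set() and cls.boundary == set()
        assert cls.diluted == {0}
        assert cls.percent == pytest.approx(100.0)

    def test_zero_tg_gives_empty_sets(self):
        frame = simple_frame(np.empty((0, 3)), [[5, 5, 5], [8, 8, 8]])
        cls = classify_tg(frame)
        assert cls.lens == cls.diluted == cls.boundary == set()
        assert cls.percent == 0.0

    def test_no_pl_rejected(self):
        frame = BeadFrame(
            time=0.0,
            box=np.array([60.0, 60.0, 20.0]),
            coords=np.array([[1.0, 1.0, 1.0]]),
            bead_to_molecule=np.array([0]),
            molecule_to_species={0: "TG"},
        )
        with pytest.raises(ContractError):
            classify_tg(frame)

    def test_constructed_frame_classified_exactly(self):
        frame, truth = gen_classification_frame(100, 10, 1000, seed=3)
        cls = classify_tg(frame)
        assert cls.lens == truth["lens"]
        assert cls.diluted == truth["diluted"]
        assert cls.boundary == set()
        assert cls.percent == truth["percent"] == 1.0

    def test_matches_brute_force_oracle(self, rng):
        # unstructured random frame: the partition must match dense all-pairs
        box = np.array([40.0, 40.0, 16.0])
        tg = rng.uniform(0, 1, (60, 3)) * box
        pl = rng.uniform(0, 1, (400, 3)) * box
        frame = simple_frame(tg, pl, box=tuple(box))
        cls = classify_tg(frame)
        lens, diluted, boundary, free_pl = brute_force_classify(tg % box, pl % box, box)
        assert cls.lens == lens
        assert cls.diluted == diluted
        assert cls.boundary == boundary
        assert {m - 60 for m in cls.lens_free_pl} == free_pl

    def test_partition_is_complete_and_disjoint(self, lens_system):
        traj, _ = lens_system
        for frame in traj.frames:
            cls = classify_tg(frame)
            tg = set(frame.molecules_of_category("tg").tolist())
            assert cls.lens | cls.diluted | cls.boundary == tg
            assert len(cls.lens) + len(cls.diluted) + len(cls.boundary) == len(tg)

    def test_margin_choice_changes_percent_little(self, lens_system):
        # selection-threshold convergence: margin 2.0 -> 3.0 nm
        traj, _ = lens_system
        frame = traj.frames[0]
        percents = [
            classify_tg(frame, margin=m).percent for m in (2.0, 2.5, 3.0)
        ]
        ref = percents[1]
        assert all(abs(p - ref) / ref < 0.05 for p in percents)

    def test_all_lipids_denominator_counts_more(self):
        tg = [[10.0, 10.0, 10.0]]
        pl = [[12.0, 10.0, 10.0]]
        coords = np.array(tg + pl + [[20.0, 20.0, 10.0]])
        species = {0: "TG", 1: "DOPC", 2: "CHOL"}
        frame = BeadFrame(
            time=0.0, box=np.array([60.0, 60.0, 20.0]), coords=coords,
            bead_to_molecule=np.arange(3), molecule_to_species=species,
        )
        assert len(classify_tg(frame).lens_free_pl) == 1
        assert len(classify_tg(frame, denominator="all-lipids").lens_free_pl) == 2


class TestDilutedSeries:
    def test_constant_frames_constant_series(self):
        frame, _ = gen_classification_frame(50, 5, 500, seed=1)
        frames = []
        for k in range(4):
            frames.append(
                BeadFrame(
                    time=float(k), box=frame.box, coords=frame.coords,
                    bead_to_molecule=frame.bead_to_molecule,
                    molecule_to_species=frame.molecule_to_species,
                )
            )
        series = diluted_series(Trajectory(frames=frames))
        assert np.ptp(series.percent) == 0.0

    def test_monotone_release_gives_increasing_percent(self):
        # k TG leave the blob per frame and appear among the PLs
        frames = []
        base, truth = gen_classification_frame(60, 0, 800, seed=2)
        pl_ids = sorted(set(base.molecule_to_species) - truth["lens"])
        pl_pos = base.molecule_positions(np.array(pl_ids))
        # hosts far from the lens for the released TG
        far = pl_pos[np.linalg.norm(pl_pos[:, :2] - [8.0, 8.0], axis=1) > 14.0]
        for k in range(5):
            coords = base.coords.copy()
            for j in range(5 * k):
                coords[j] = far[j] + (0.3, 0.0, 0.0)
            frames.append(
                BeadFrame(
                    time=float(k), box=base.box, coords=coords,
                    bead_to_molecule=base.bead_to_molecule,
                    molecule_to_species=base.molecule_to_species,
                )
            )
        series = diluted_series(Trajectory(frames=frames))
        assert np.all(np.diff(series.percent) > 0)

    def test_relaxation_series_approaches_plateau(self):
        series, _ = gen_relaxation_series(
            plateau_percent=1.1, tau_ns=300.0, noise_sd=0.0, seed=0
        )
        assert series.percent[-1] == pytest.approx(1.1, abs=1e-6)
        assert np.all(np.diff(series.percent) >= 0)


class TestPlateauStats:
    def test_two_constant_replicas(self):
        reps = [
            gen_relaxation_series(p, tau_ns=1e-6, noise_sd=0.0, seed=0)[0]
            for p in (1.0, 1.2)
        ]
        mean, sd = plateau_stats(reps)
        assert mean == pytest.approx(1.1)
        assert sd == pytest.approx(np.std([1.0, 1.2], ddof=1))

    def test_single_replica_zero_sd(self):
        rep, _ = gen_relaxation_series(2.0, tau_ns=1e-6, noise_sd=0.0, seed=0)
        mean, sd = plateau_stats([rep])
        assert mean == pytest.approx(2.0)
        assert sd == 0.0

    def test_noisy_relaxation_recovers_plateau(self):
        reps = [
            gen_relaxation_series(1.1, tau_ns=300.0, noise_sd=0.1, seed=s)[0]
            for s in (0, 1)
        ]
        mean, sd = plateau_stats(reps)
        assert mean == pytest.approx(1.1, abs=0.1)

    def test_window_longer_than_series_rejected(self):
        rep, _ = gen_relaxation_series(1.0, duration_ns=1000.0, seed=0)
        with pytest.raises(ConfigurationError):
            plateau_stats([rep], window=5000.0)

    def test_injection_returns_to_plateau(self):
        reps = [
            gen_relaxation_series(
                1.1, tau_ns=300.0, noise_sd=0.08, duration_ns=6000.0,
                injection={"time_ns": 3000.0, "step_percent": 1.0}, seed=s,
            )[0]
            for s in (0, 1)
        ]
        pre = plateau_stats(reps, window=(1500.0, 3000.0))
        post = plateau_stats(reps, window=(4500.0, 6000.0))
        sd = max(pre[1], post[1], 0.02)
        assert abs(pre[0] - post[0]) < 3 * sd + 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            plateau_stats([])


def shrink_traj(sizes, min_size=25):
    """Trajectory whose largest aggregate follows the given size schedule."""
    frames = []
    total = max(sizes) + 10
    for k, n in enumerate(sizes):
        # n TG in a blob, the rest scattered far apart
        blob = np.array([[30 + 0.9 * (i % 10), 30 + 0.9 * (i // 10), 10.0] for i in range(n)])
        solo = np.array(
            [[2 + 7 * (j % 8), 2 + 7 * (j // 8), 3.0] for j in range(total - n)]
        )
        coords = np.vstack([blob, solo])
        frames.append(
            BeadFrame(
                time=float(k), box=np.array([60.0, 60.0, 20.0]), coords=coords,
                bead_to_molecule=np.arange(total),
                molecule_to_species={i: "TG" for i in range(total)},
            )
        )
    return Trajectory(frames=frames)


class TestDissolution:
    def test_monotone_shrinkage(self):
        traj = shrink_traj([50, 40, 30, 24, 10, 5, 2, 1])
        assert detect_dissolution(traj) == pytest.approx(3.0)

    def test_stable_lens_returns_none(self):
        traj = shrink_traj([100] * 6)
        assert detect_dissolution(traj) is None

    def test_reformation_pushes_dissolution_later(self):
        traj = shrink_traj([50, 20, 20, 40, 30, 10, 5, 2])
        assert detect_dissolution(traj) == pytest.approx(5.0)

    def test_no_initial_lens_rejected(self):
        traj = shrink_traj([10, 5])
        with pytest.raises(ContractError):
            detect_dissolution(traj)


class TestLensExtent:
    def test_box_aligned_extent(self):
        pts = np.array(
            [
                [10.0, 12.0, 4.0],
                [35.0, 37.0, 9.0],
                [20.0, 20.0, 6.0],
            ]
        )
        frame = simple_frame(pts, [[50, 50, 15]], box=(60.0, 60.0, 20.0))
        ext = lens_extent([frame], {0, 1, 2})
        np.testing.assert_allclose(ext.mean, [25.0, 25.0, 5.0])

    def test_extent_across_periodic_boundary(self):
        pts = np.array([[58.0, 10.0, 10.0], [2.0, 10.0, 10.0]])
        frame = simple_frame(pts, [[30, 30, 15]], box=(60.0, 60.0, 20.0))
        ext = lens_extent([frame], {0, 1})
        assert ext.mean[0] == pytest.approx(4.0)

    def test_single_molecule_extent_zero(self):
        frame = simple_frame([[10, 10, 10]], [[30, 30, 15]])
        ext = lens_extent([frame], {0})
        np.testing.assert_allclose(ext.mean, [0.0, 0.0, 0.0])

    def test_empty_lens_rejected(self):
        frame = simple_frame([[10, 10, 10]], [[30, 30, 15]])
        with pytest.raises(ContractError):
            lens_extent([frame], set())


class TestExcessTG:
    @pytest.mark.parametrize(
        "nominal, eq, expected", [(6.0, 1.1, 4.9), (6.0, 6.0, 0.0), (6.0, 0.5, 5.5)]
    )
    def test_arithmetic(self, nominal, eq, expected):
        assert excess_tg(nominal, eq) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ContractError):
            excess_tg(-1.0, 0.5)
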