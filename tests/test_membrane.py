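import numpy as np
import pandas as pd
import pytest

from dendrysis import (
    MembraneFrame,
    MembraneSpec,
    ProtonationSpec,
    conditional_pka_profile,
    generate_membrane_system,
    generate_protonation_series,
    insertion_coordinate,
    local_deformation,
    profile_by_insertion,
    radial_thickness_profile,
)


def flat_membrane(half=19.0, n=64, box=(40.0, 40.0), z_shift=0.0):
    rng = np.random.default_rng(0)
    xy = rng.uniform(0, box[0], size=(n, 2))
    upper = np.column_stack([xy, np.full(n, half + z_shift)])
    lower = np.column_stack([xy, np.full(n, -half + z_shift)])
    return MembraneFrame(upper=upper, lower=lower, box=box)


class TestInsertionCoordinate:
    def test_point_on_phosphate_plane(self):
        mem = flat_membrane()
        assert insertion_coordinate([5.0, 5.0, 19.0], mem, "insertion") == \
            pytest.approx(0.0)

    def test_point_at_membrane_center(self):
        mem = flat_membrane()
        center = [5.0, 5.0, mem.center_z]
        assert insertion_coordinate(center, mem, "center") == pytest.approx(0.0)
        assert insertion_coordinate(center, mem, "insertion") == \
            pytest.approx(19.0)

    def test_water_side_negative(self):
        mem = flat_membrane()
        assert insertion_coordinate([0.0, 0.0, 25.0], mem, "insertion") == \
            pytest.approx(-6.0)

    def test_lower_leaflet_sign(self):
        mem = flat_membrane()
        assert insertion_coordinate([0.0, 0.0, -14.0], mem, "insertion") == \
            pytest.approx(5.0)

    def test_global_z_translation_invariant(self):
        a = flat_membrane()
        b = flat_membrane(z_shift=7.5)
        for mode in ("center", "insertion"):
            assert insertion_coordinate([1.0, 1.0, 12.0], a, mode) == \
                pytest.approx(
                    insertion_coordinate([1.0, 1.0, 19.5], b, mode))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            insertion_coordinate([0, 0, 0], flat_membrane(), "sideways")


class TestProfileByInsertion:
    def test_constant_values(self, rng):
        ins = rng.uniform(-5, 5, 3000)
        prof = profile_by_insertion(np.full(3000, 2.5), ins, bin_width=2.0,
                                    min_count=100)
        retained = prof.retained
        np.testing.assert_allclose(prof.mean[retained], 2.5)
        np.testing.assert_allclose(prof.sem[retained], 0.0)

    @pytest.mark.parametrize("min_count", [400, 1500, 2500])
    def test_discard_rule_exact_threshold(self, min_count):
        """A slice one point short of the threshold is discarded; at the
        threshold it is retained."""
        short = np.concatenate([np.zeros(min_count - 1), np.ones(min_count)])
        ins = np.concatenate([np.full(min_count - 1, 0.5),
                              np.full(min_count, 1.5)])
        prof = profile_by_insertion(short, ins, bin_width=1.0,
                                    min_count=min_count)
        assert prof.count[0] == min_count - 1 and not prof.retained[0]
        assert np.isnan(prof.mean[0])
        assert prof.retained[1] and prof.mean[1] == 1.0
        assert (prof.count[prof.retained] >= min_count).all()

    def test_linear_signal_recovered(self, rng):
        ins = rng.uniform(0, 10, 20_000)
        vals = 3.0 * ins - 2.0 + rng.normal(scale=0.5, size=20_000)
        prof = profile_by_insertion(vals, ins, bin_width=1.0, min_count=400)
        centers = prof.bin_centers[prof.retained]
        means = prof.mean[prof.retained]
        sems = prof.sem[prof.retained]
        np.testing.assert_array_less(np.abs(means - (3.0 * centers - 2.0)),
                                     3 * sems + 0.05)

    def test_replicate_based_sem(self, rng):
        ins = np.tile(np.full(500, 0.5), 4)
        vals = np.concatenate([np.full(500, v) for v in (1.0, 2.0, 3.0, 4.0)])
        reps = np.repeat(np.arange(4), 500)
        prof = profile_by_insertion(vals, ins, bin_width=1.0, min_count=100,
                                    replicate_ids=reps)
        assert prof.mean[0] == pytest.approx(2.5)
        expected_sem = np.std([1, 2, 3, 4], ddof=1) / 2
        assert prof.sem[0] == pytest.approx(expected_sem)

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            profile_by_insertion(np.ones(10), np.ones(10), bin_width=0.0)


class TestConditionalPka:
    def build(self, toy_branch, coupling, n_frames=4000, n_rep=4, seed=0):
        rng = np.random.default_rng(seed)
        pka_map = {s.site_id: 10.4 for s in toy_branch.sites}
        series, ins = [], []
        for rep in range(n_rep):
            for ph in (4.5, 5.5, 6.5, 7.5):
                z = rng.uniform(-6, 10, n_frames)
                spec = ProtonationSpec(pka=pka_map, pH=ph, n_frames=n_frames,
                                       insertion_coupling=coupling,
                                       seed=int(rng.integers(2**31)))
                series.append(generate_protonation_series(
                    spec, insertions=z if coupling else None,
                    topology=toy_branch, replicate=rep))
                ins.append(z)
        return series, ins

    def test_desolvation_profile_recovered(self, toy_branch):
        """pKa(z) tracks the generating sigmoid and drops below the bulk
        value at deep insertion."""
        coupling = (6.0, 2.0, 1.0)
        series, ins = self.build(toy_branch, coupling)
        prof = conditional_pka_profile(series, ins, bin_width=2.0,
                                       min_count=2500)
        ok = prof[prof.defined & prof.retained]
        assert len(ok) >= 5
        z = ok.bin_center.to_numpy()
        expected = 10.4 - 6.0 / (1.0 + np.exp(-(z - 2.0)))
        # well-characterized slices: generating pKa inside the sampled pH
        # window where the fit is an interpolation, not an extrapolation
        well = (expected > 4.5) & (expected < 7.5)
        assert well.sum() >= 2
        np.testing.assert_array_less(
            np.abs(ok.pka.to_numpy()[well] - expected[well]), 0.1)
        deep = ok.pka.to_numpy()[z > 6.0]
        assert (deep < 10.4 - 3.0).all()

    def test_flat_profile_without_coupling(self, toy_branch):
        series, ins = self.build(toy_branch, None, n_frames=6000, seed=3)
        prof = conditional_pka_profile(series, ins, bin_width=4.0,
                                       min_count=2500)
        ok = prof[prof.defined & prof.retained]
        assert len(ok) >= 2
        # bulk pKa 10.4 estimated from pH <= 7.5 data only: a long
        # extrapolation, so each slice is accurate only to its jackknife SE
        pka = ok.pka.to_numpy()
        err = ok.pka_err.to_numpy()
        np.testing.assert_array_less(np.abs(pka - 10.4), 4 * err + 0.1)

    def test_min_count_discard(self, toy_branch):
        series, ins = self.build(toy_branch, None, n_frames=50, seed=4)
        prof = conditional_pka_profile(series, ins, bin_width=2.0,
                                       min_count=2500)
        assert not prof.retained.any()
        assert prof.pka.isna().all()

    def test_requires_two_ph(self, toy_branch):
        pka_map = {s.site_id: 10.4 for s in toy_branch.sites}
        spec = ProtonationSpec(pka=pka_map, pH=7.5, n_frames=100, seed=5)
        s = generate_protonation_series(spec, topology=toy_branch)
        with pytest.raises(ValueError, match="2 pH"):
            conditional_pka_profile([s], [np.zeros(100)])


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def dimpled_system(depth=6.0, width=20.0, noise=0.3, n_frames=15,
                   n_lipids=4096, box=200.0, seed=21):
    mspec = MembraneSpec(n_lipids_per_leaflet=n_lipids, box=(box, box),
                         dimple=(depth, width) if depth else None,
                         noise_sd=noise, seed=seed)
    track = np.tile([box / 2, box / 2, 25.0], (n_frames, 1))
    frames, _ = generate_membrane_system(mspec, track)
    return frames, track, mspec


class TestLocalDeformation:
    def test_flat_membrane_near_zero(self):
        frames, track, _ = dimpled_system(depth=0.0, noise=0.4, seed=22)
        dev, sem = local_deformation(frames, track)
        assert dev == pytest.approx(0.0, abs=3 * sem + 0.05)

    def test_recovers_central_depth(self):
        """A wide 6 A dimple pulls contact lipids ~6 A toward the membrane
        center; the estimate matches the analytic expectation computed from
        the noiseless twin geometry."""
        frames, track, mspec = dimpled_system()
        dev, sem = local_deformation(frames, track)
        # oracle: same lipid positions, displacement known in closed form
        quiet, _, _ = dimpled_system(noise=0.0)
        expected = []
        for f in quiet:
            d = f.upper[:, :2] - track[0, :2]
            d -= 200.0 * np.round(d / 200.0)
            r = np.sqrt((d**2).sum(axis=1))
            disp = -6.0 * np.exp(-r**2 / (2 * 20.0**2))
            expected.append(disp[r <= 6.0].mean() - disp[r > 15.0].mean())
        assert dev == pytest.approx(np.mean(expected), abs=3 * sem + 0.05)
        assert -6.5 < dev < -4.5  # central depth, minus bulk contamination

    def test_bulk_cutoff_insensitive_without_dimple(self):
        frames, track, _ = dimpled_system(depth=0.0, noise=0.3, seed=23)
        d15, s15 = local_deformation(frames, track, bulk_cutoff=15.0)
        d30, s30 = local_deformation(frames, track, bulk_cutoff=30.0)
        assert d15 == pytest.approx(d30, abs=3 * (s15 + s30) + 0.05)

    def test_no_bulk_lipids_rejected(self):
        frames, track, _ = dimpled_system(n_lipids=64, box=20.0, seed=24)
        with pytest.raises(ValueError, match="bulk"):
            local_deformation(frames, track, bulk_cutoff=50.0)


class TestRadialProfile:
    def test_flat_membrane_profile_near_zero(self):
        frames, track, _ = dimpled_system(depth=0.0, noise=0.3, seed=25)
        prof = radial_thickness_profile(frames, track)
        ok = ~np.isnan(prof.deviation)
        np.testing.assert_array_less(np.abs(prof.deviation[ok]),
                                     3 * prof.sem[ok] + 0.1)

    def test_gaussian_dimple_recovered(self):
        frames, track, _ = dimpled_system(width=10.0)
        prof = radial_thickness_profile(frames, track)
        quiet, _, _ = dimpled_system(width=10.0, noise=0.0)
        # oracle: per-slice analytic displacement minus bulk, own binning
        expected = np.full(len(prof.r_centers), np.nan)
        acc = [[] for _ in prof.r_centers]
        for f in quiet:
            d = f.upper[:, :2] - track[0, :2]
            d -= 200.0 * np.round(d / 200.0)
            r = np.sqrt((d**2).sum(axis=1))
            disp = -6.0 * np.exp(-r**2 / (2 * 10.0**2))
            bulk = disp[r > 15.0].mean()
            for k, c in enumerate(prof.r_centers):
                sel = (r >= c - 0.5) & (r < c + 0.5)
                if sel.any():
                    acc[k].append(disp[sel].mean() - bulk)
        for k, chunk in enumerate(acc):
            if chunk:
                expected[k] = np.mean(chunk)
        ok = ~np.isnan(prof.deviation) & ~np.isnan(expected)
        assert ok.sum() > 30
        np.testing.assert_array_less(
            np.abs(prof.deviation[ok] - expected[ok]),
            3 * prof.sem[ok] + 0.05)
        # the well bottom reaches the generated depth (less bulk offset)
        assert prof.deviation[ok][0] == pytest.approx(expected[ok][0], abs=0.5)
        assert expected[ok][0] < -5.0

    def test_well_with_protruding_ring(self):
        """A central well compensated by a raised ring: negative core,
        positive ring, near-zero integral."""
        rng = np.random.default_rng(26)
        n = 4096
        xy = rng.uniform(0, 200, size=(n, 2))
        d = xy - 100.0
        r = np.sqrt((d**2).sum(axis=1))
        ring = 4.0 * np.exp(-((r - 12.0) ** 2) / 8.0)
        well = -6.0 * np.exp(-r**2 / 50.0)
        frames = []
        for _ in range(5):
            z_up = 19.0 + well + ring + rng.normal(scale=0.1, size=n)
            frames.append(MembraneFrame(
                upper=np.column_stack([xy, z_up]),
                lower=np.column_stack([xy, np.full(n, -19.0)]),
                box=(200.0, 200.0)))
        track = np.tile([100.0, 100.0, 25.0], (5, 1))
        prof = radial_thickness_profile(frames, track, bulk_cutoff=25.0,
                                        r_max=25.0)
        ok = ~np.isnan(prof.deviation)
        inner = prof.deviation[ok & (prof.r_centers < 4)]
        ringband = prof.deviation[ok & (prof.r_centers > 10)
                                  & (prof.r_centers < 14)]
        assert (inner < -2.0).all()
        assert (ringband > 1.0).all()

    def test_lateral_wrap_invariance(self):
        frames, track, _ = dimpled_system(width=10.0, n_frames=3)
        shifted = track + [200.0, 0.0, 0.0]
        a = radial_thickness_profile(frames, track)
        b = radial_thickness_profile(frames, shifted)
        np.testing.assert_allclose(a.deviation, b.deviation, equal_nan=True)

    def test_bad_slicing_rejected(self):
        frames, track, _ = dimpled_system(n_frames=1)
        with pytest.raises(ValueError, match="positive"):
            radial_thickness_profile(frames, track, step=0.0)
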