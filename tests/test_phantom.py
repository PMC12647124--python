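import numpy as np
import pytest
from scipy import ndimage

from mucomap import phantom as ph
from mucomap.stats import simple_linreg

from conftest import digital_disc_count


def flood_fill_component_count(mask):
    """Oracle: count 26-connected components by explicit flood fill."""
    visited = np.zeros(mask.shape, dtype=bool)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    count = 0
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        count += 1
        stack = [start]
        visited[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                q = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(q, mask.shape)):
                    if mask[q] and not visited[q]:
                        visited[q] = True
                        stack.append(q)
    return count


class TestTreeSpec:
    def test_duplicate_ids_rejected(self):
        b = ph.Branch(1, None, (0, 0, 0), (1, 0, 0), 10, 2, 1, "LL")
        with pytest.raises(ValueError, match="unique"):
            ph.TreeSpec((b, b))

    def test_two_roots_rejected(self):
        b1 = ph.Branch(1, None, (0, 0, 0), (1, 0, 0), 10, 2, 1, "LL")
        b2 = ph.Branch(2, None, (0, 5, 5), (1, 0, 0), 10, 2, 1, "LL")
        with pytest.raises(ValueError, match="root"):
            ph.TreeSpec((b1, b2))

    def test_generation_chain_enforced(self):
        b1 = ph.Branch(1, None, (0, 0, 0), (1, 0, 0), 10, 2, 1, "LL")
        b2 = ph.Branch(2, 1, (5, 0, 0), (0, 1, 0), 10, 2, 3, "LL")
        with pytest.raises(ValueError, match="generation"):
            ph.TreeSpec((b1, b2))

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            ph.TreeSpec(
                (ph.Branch(1, None, (0, 0, 0), (1, 0, 0), 10, 0.0, 1, "LL"),)
            )


class TestBuildTreeVolume:
    def test_empty_spec_gives_empty_volume(self):
        built = ph.build_tree_volume(ph.TreeSpec(()), (16, 16, 16), 1.0)
        assert not built.lumen.any()
        assert not built.labels.any()

    def test_single_branch_slice_counts_match_disc_oracle(self):
        branch = ph.Branch(1, None, (5, 32, 32), (1, 0, 0), 50, 10, 1, "LL")
        built = ph.build_tree_volume(ph.TreeSpec((branch,)), (64, 64, 64), 1.0)
        expected = digital_disc_count(10)
        for z in range(6, 54):
            assert int(built.lumen[z].sum()) == expected

    def test_two_branch_tree_labels_and_connectivity(self):
        s2 = 1 / np.sqrt(2)
        spec = ph.TreeSpec(
            (
                ph.Branch(1, None, (4, 32, 32), (1, 0, 0), 50, 8, 1, "LL"),
                ph.Branch(2, 1, (30, 32, 32), (s2, s2, 0), 25, 5, 2, "LL"),
            )
        )
        built = ph.build_tree_volume(spec, (64, 64, 64), 1.0)
        assert set(np.unique(built.labels)) == {0, 1, 2}
        assert flood_fill_component_count(built.lumen) == 1

    def test_branch_outside_volume_names_branch(self):
        branch = ph.Branch(7, None, (5, 8, 8), (1, 0, 0), 100, 4, 1, "LL")
        with pytest.raises(ValueError, match="branch 7"):
            ph.build_tree_volume(ph.TreeSpec((branch,)), (32, 32, 32), 1.0)

    def test_voxel_size_scales_geometry(self):
        # radius 20 um at 2 um voxels = 10-voxel digital disc
        branch = ph.Branch(1, None, (5, 32, 32), (1, 0, 0), 80, 20, 1, "LL")
        built = ph.build_tree_volume(ph.TreeSpec((branch,)), (64, 64, 64), 2.0)
        assert int(built.lumen[20].sum()) == digital_disc_count(10)

    def test_disconnected_branches_warn(self):
        spec = ph.TreeSpec(
            (
                ph.Branch(1, None, (4, 16, 16), (1, 0, 0), 10, 3, 1, "LL"),
                ph.Branch(2, 1, (40, 48, 48), (1, 0, 0), 10, 3, 2, "LL"),
            )
        )
        with pytest.warns(UserWarning, match="components"):
            ph.build_tree_volume(spec, (64, 64, 64), 1.0)

    @pytest.mark.parametrize("radius", [8, 10, 14])
    def test_digitised_disc_area_within_5pct_of_circle(self, radius):
        assert digital_disc_count(radius) == pytest.approx(
            np.pi * radius**2, rel=0.05
        )


class TestCarveMucus:
    def test_plug_full_occlusion(self, cylinder_phantom):
        dep = ph.Deposit(1, (0.1, 0.2), "plug", fill_fraction=1.0)
        mucus, truth = ph.carve_mucus(cylinder_phantom, [dep])
        t = truth.table
        covered = t[(t.station >= 10) & (t.station < 20)]
        uncovered = t[(t.station >= 25) & (t.station < 95)]
        assert (covered.true_area_ratio == 1.0).all()
        assert (covered.true_contact_ratio == 1.0).all()
        assert (uncovered.true_area_ratio == 0.0).all()
        assert (uncovered.true_contact_ratio == 0.0).all()

    def test_crescent_contact_half(self, cylinder_phantom):
        dep = ph.Deposit(
            1, (0.0, 1.0), "crescent", angular_coverage=180.0, thickness=3
        )
        mucus, truth = ph.carve_mucus(cylinder_phantom, [dep])
        t = truth.table
        interior = t[(t.station > 5) & (t.station < 95)]
        assert interior.true_contact_ratio.mean() == pytest.approx(0.5, abs=0.06)

    def test_crescent_contact_matches_polar_angle_oracle(self, cylinder_phantom):
        # brute-force: classify the perimeter voxels of one interior slice by
        # polar angle about the axis (oracle independent of the carver)
        dep = ph.Deposit(
            1, (0.0, 1.0), "crescent", angular_coverage=180.0, thickness=3
        )
        mucus, truth = ph.carve_mucus(cylinder_phantom, [dep])
        z = 50
        lum = cylinder_phantom.lumen
        per = np.zeros_like(lum[z])
        ys, xs = np.nonzero(lum[z])
        for y, x in zip(ys, xs):
            neighbours = [(y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)]
            if any(not lum[z, ny, nx] for ny, nx in neighbours):
                per[y, x] = True
        pm = int(np.sum(per & mucus[z]))
        pa = int(np.sum(per))
        row = truth.table.query("branch_id == 1 and station == @z - 10").iloc[0]
        assert row.true_contact_ratio == pytest.approx(pm / pa)

    def test_empty_deposits_all_zero(self, cylinder_phantom):
        mucus, truth = ph.carve_mucus(cylinder_phantom, [])
        assert not mucus.any()
        assert (truth.table.true_area_ratio == 0).all()
        assert (truth.table.true_contact_ratio == 0).all()

    def test_unknown_branch_raises(self, cylinder_phantom):
        dep = ph.Deposit(99, (0.1, 0.2), "plug", fill_fraction=1.0)
        with pytest.raises(ValueError, match="99"):
            ph.carve_mucus(cylinder_phantom, [dep])

    def test_mucus_subset_of_lumen(self, cylinder_phantom):
        dep = ph.Deposit(1, (0.0, 1.0), "annulus", thickness=4)
        mucus, _ = ph.carve_mucus(cylinder_phantom, [dep])
        assert not np.any(mucus & ~cylinder_phantom.lumen)

    def test_ratios_in_unit_interval_and_consistent(self, cylinder_phantom):
        dep = ph.deposit_for_ratios(1, 0.4, 0.6)
        _, truth = ph.carve_mucus(cylinder_phantom, [dep])
        t = truth.table
        assert ((t.true_area_ratio >= 0) & (t.true_area_ratio <= 1)).all()
        assert ((t.true_contact_ratio >= 0) & (t.true_contact_ratio <= 1)).all()
        zero_area = t[t.true_area_ratio == 0]
        assert (zero_area.true_contact_ratio == 0).all()

    @pytest.mark.parametrize("area,contact", [(0.1, 0.5), (0.5, 0.5), (0.75, 0.25)])
    def test_programmed_ratios_hit(self, cylinder_phantom, area, contact):
        dep = ph.deposit_for_ratios(1, area, contact, (0.1, 0.9))
        _, truth = ph.carve_mucus(cylinder_phantom, [dep])
        t = truth.table
        mid = t[(t.station > 15) & (t.station < 85)]
        assert mid.true_area_ratio.mean() == pytest.approx(area, abs=0.05)
        assert mid.true_contact_ratio.mean() == pytest.approx(contact, abs=0.06)

    def test_invariants_on_deposit_spec(self):
        with pytest.raises(ValueError):
            ph.Deposit(1, (0.1, 0.2), "plug", fill_fraction=0.5)
        with pytest.raises(ValueError):
            ph.Deposit(1, (0.1, 0.2), "annulus", angular_coverage=90, thickness=2)
        with pytest.raises(ValueError):
            ph.Deposit(1, (0.5, 0.1), "plug", fill_fraction=1.0)


class TestRenderIntensity:
    def test_noiseless_three_levels(self, cylinder_phantom):
        dep = ph.Deposit(1, (0.3, 0.5), "plug", fill_fraction=1.0)
        mucus, _ = ph.carve_mucus(cylinder_phantom, [dep])
        vol = ph.render_intensity(cylinder_phantom.lumen, mucus, 0.0)
        assert set(np.unique(vol)) == {0.10, 0.60, 0.85}

    def test_determinism(self, cylinder_phantom):
        mucus = np.zeros_like(cylinder_phantom.lumen)
        a = ph.render_intensity(cylinder_phantom.lumen, mucus, 0.05, seed=42)
        b = ph.render_intensity(cylinder_phantom.lumen, mucus, 0.05, seed=42)
        assert np.array_equal(a, b)
        c = ph.render_intensity(cylinder_phantom.lumen, mucus, 0.05, seed=43)
        assert not np.array_equal(a, c)

    def test_class_means_near_nominal(self, cylinder_phantom):
        dep = ph.Deposit(1, (0.2, 0.6), "plug", fill_fraction=1.0)
        mucus, _ = ph.carve_mucus(cylinder_phantom, [dep])
        vol = ph.render_intensity(cylinder_phantom.lumen, mucus, 0.05, seed=0)
        air = cylinder_phantom.lumen & ~mucus
        tissue = ~cylinder_phantom.lumen
        for mask, level in ((air, 0.10), (mucus, 0.60), (tissue, 0.85)):
            assert mask.sum() >= 10_000
            assert float(vol[mask].mean()) == pytest.approx(level, abs=0.01)

    def test_mucus_outside_lumen_rejected(self):
        lumen = np.zeros((8, 8, 8), dtype=bool)
        mucus = np.zeros((8, 8, 8), dtype=bool)
        mucus[0, 0, 0] = True
        with pytest.raises(ValueError, match="subset"):
            ph.render_intensity(lumen, mucus, 0.0)


class TestCohortTable:
    def test_noiseless_line_recovered_exactly(self):
        df = ph.generate_cohort_ratio_table(20, 2.5, 4.0, 0.0, (1, 20), seed=1)
        res = simple_linreg(df.mean_area_ratio_pct, df.mean_contact_ratio_pct)
        assert res.slope == pytest.approx(2.5)
        assert res.intercept == pytest.approx(4.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_defaults_match_reference_parameters(self):
        df = ph.generate_cohort_ratio_table(500, seed=0)
        x = df.mean_area_ratio_pct
        assert x.min() >= 0.7 and x.max() <= 15.5
        res = simple_linreg(x, df.mean_contact_ratio_pct)
        assert res.slope == pytest.approx(3.204, abs=0.25)
        assert res.intercept == pytest.approx(7.243, abs=2.5)

    def test_degenerate_n_raises(self):
        with pytest.raises(ValueError):
            ph.generate_cohort_ratio_table(1)

    def test_negative_noise_raises(self):
        with pytest.raises(ValueError):
            ph.generate_cohort_ratio_table(5, noise_sd=-1.0)

    def test_determinism(self):
        a = ph.generate_cohort_ratio_table(10, seed=9)
        b = ph.generate_cohort_ratio_table(10, seed=9)
        assert a.equals(b)


@pytest.fixture(scope="module")
def catalog():
    from mucomap.scoring import default_catalog

    return default_catalog()


class TestScoreTable:
    def test_all_zero_probs(self, catalog):
        probs = {("wt", "adult"): (1.0, 0.0, 0.0)}
        df = ph.generate_score_table(catalog, probs, 3, seed=0)
        assert (df.score == 0).all()
        assert len(df) == 3 * len(catalog)

    def test_all_two_probs_mean(self, catalog):
        probs = {("tg", "juvenile"): (0.0, 0.0, 1.0)}
        df = ph.generate_score_table(catalog, probs, 2, seed=0)
        assert df.groupby("animal_id")["score"].mean().eq(2.0).all()

    def test_determinism(self, catalog):
        probs = {("tg", "adult"): (0.3, 0.4, 0.3)}
        a = ph.generate_score_table(catalog, probs, 2, seed=5)
        b = ph.generate_score_table(catalog, probs, 2, seed=5)
        assert a.equals(b)

    def test_bad_probs_raise(self, catalog):
        with pytest.raises(ValueError, match="sum"):
            ph.generate_score_table(catalog, {("wt", "adult"): (0.5, 0.4, 0.2)}, 1)
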