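import numpy as np
import pytest
from scipy import ndimage

from mucomap import phantom as ph
from mucomap.cross_section import (
    geodesic_cross_sections,
    main_branch_seed_slice,
    perimeter_mask,
    skeleton_cross_sections,
    skeletonize,
    slice_cross_sections,
)

from conftest import digital_disc_count


@pytest.fixture(scope="module")
def cylinder_with_annulus(cylinder_phantom):
    dep = ph.Deposit(1, (0.15, 0.85), "annulus", thickness=3)
    mucus, truth = ph.carve_mucus(cylinder_phantom, [dep])
    return cylinder_phantom, mucus, truth


class TestSliceMethod:
    def test_one_record_per_slice_constant_count(self, cylinder_phantom):
        mucus = np.zeros(cylinder_phantom.shape, dtype=bool)
        records = slice_cross_sections(cylinder_phantom.labels, mucus)
        assert len(records) == 100
        expected = digital_disc_count(12, size=128)
        assert all(r.lumen_count == expected for r in records)
        assert all(r.planar for r in records)

    def test_tilted_cylinder_smears_by_sqrt2(self, tilted_phantom):
        mucus = np.zeros(tilted_phantom.shape, dtype=bool)
        records = slice_cross_sections(tilted_phantom.labels, mucus)
        counts = [r.lumen_count for r in records if 30 < r.station < 85]
        median = float(np.median(counts))
        # elliptical smear: area ~ pi R^2 * sqrt(2)
        assert median == pytest.approx(np.pi * 144 * np.sqrt(2), rel=0.08)

    def test_empty_label_map(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        assert slice_cross_sections(labels, np.zeros((8, 8, 8), bool)) == []

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            slice_cross_sections(
                np.zeros((4, 4, 4), np.int32), np.zeros((4, 4, 5), bool)
            )

    def test_mucus_counts_match_truth(self, cylinder_with_annulus):
        built, mucus, truth = cylinder_with_annulus
        records = slice_cross_sections(built.labels, mucus)
        by_station = {r.station: r for r in records}
        for row in truth.table.itertuples(index=False):
            rec = by_station[row.station + 10]  # branch starts at z = 10
            assert rec.mucus_count / rec.lumen_count == pytest.approx(
                row.true_area_ratio
            )


class TestSkeletonize:
    def test_straight_cylinder_axis_recovery(self, cylinder_phantom):
        skel = skeletonize(cylinder_phantom.lumen)
        assert len(skel.paths) == 1
        # every skeleton node within 1 voxel (radially) of the true axis
        for node in skel.nodes:
            assert abs(node[1] - 64) <= 1 and abs(node[2] - 64) <= 1

    def test_skeleton_inside_mask(self, two_branch_phantom):
        built, _, _ = two_branch_phantom
        skel = skeletonize(built.lumen)
        for node in skel.nodes:
            assert built.lumen[tuple(node)]

    def test_solid_ball_degenerate(self):
        mask = np.zeros((32, 32, 32), dtype=bool)
        zz, yy, xx = np.meshgrid(*[np.arange(32)] * 3, indexing="ij")
        mask[(zz - 16) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 < 100] = True
        skel = skeletonize(mask)
        assert len(skel) > 0
        for node in skel.nodes:
            assert mask[tuple(node)]

    def test_two_disjoint_tubes_two_components(self):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[5:35, 8:12, 8:12] = True
        mask[5:35, 28:32, 28:32] = True
        skel = skeletonize(mask)
        lab, n = ndimage.label(mask, np.ones((3, 3, 3)))
        comps = {lab[tuple(node)] for node in skel.nodes}
        assert n == 2 and comps == {1, 2}

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            skeletonize(np.zeros((4, 4, 4), dtype=bool))

    def test_tangents_are_unit(self, cylinder_phantom):
        skel = skeletonize(cylinder_phantom.lumen)
        finite = np.all(np.isfinite(skel.tangent), axis=1)
        norms = np.linalg.norm(skel.tangent[finite], axis=1)
        assert np.allclose(norms, 1.0)


class TestSkeletonMethod:
    def test_matches_slice_method_on_aligned_cylinder(self, cylinder_with_annulus):
        built, mucus, _ = cylinder_with_annulus
        slice_recs = {r.station: r for r in slice_cross_sections(built.labels, mucus)}
        skel = skeletonize(built.lumen)
        records = skeleton_cross_sections(built.lumen, skel, mucus)
        assert records
        for rec in records:
            z = rec.node[0]
            if 20 < z < 100 and z in slice_recs:
                assert rec.lumen_count == slice_recs[z].lumen_count
                assert rec.mucus_count == slice_recs[z].mucus_count

    def test_tilted_cylinder_no_smear(self, tilted_phantom):
        mucus = np.zeros(tilted_phantom.shape, dtype=bool)
        skel = skeletonize(tilted_phantom.lumen)
        records = skeleton_cross_sections(tilted_phantom.lumen, skel, mucus)
        interior = [
            r.lumen_count
            for r in records
            if 10 < r.station < len(skel.paths[r.branch_id]) - 10
        ]
        assert interior
        assert float(np.median(interior)) == pytest.approx(np.pi * 144, rel=0.08)

    def test_no_record_at_junctions(self, two_branch_phantom):
        built, mucus, _ = two_branch_phantom
        skel = skeletonize(built.lumen)
        junction_nodes = {
            tuple(skel.nodes[i]) for i in np.nonzero(skel.degree >= 3)[0]
        }
        assert junction_nodes  # the phantom does bifurcate
        records = skeleton_cross_sections(built.lumen, skel, mucus)
        assert all(r.node not in junction_nodes for r in records)


class TestGeodesicMethod:
    def test_bins_coincide_with_slices_on_aligned_cylinder(self, cylinder_with_annulus):
        built, mucus, _ = cylinder_with_annulus
        slice_recs = {r.station: r for r in slice_cross_sections(built.labels, mucus)}
        seed = main_branch_seed_slice(built.labels)
        records, excluded = geodesic_cross_sections(
            built.lumen, seed, mucus, bin_width=1.0, labels=built.labels
        )
        assert not excluded.any()
        for rec in records:
            z = rec.station + 10  # seed slice at z = 10
            if z in slice_recs:
                assert rec.lumen_count == slice_recs[z].lumen_count
                assert rec.mucus_count == slice_recs[z].mucus_count
            assert not rec.planar

    def test_detached_blob_excluded(self, cylinder_phantom):
        mask = cylinder_phantom.lumen.copy()
        mask[120:125, 5:10, 5:10] = True  # detached blob
        mucus = np.zeros(mask.shape, dtype=bool)
        seed = np.zeros(mask.shape, dtype=bool)
        seed[10] = mask[10]
        records, excluded = geodesic_cross_sections(mask, seed, mucus)
        assert excluded.sum() == 125
        blob_voxels = np.argwhere(excluded)
        assert (blob_voxels[:, 0] >= 120).all()

    def test_seed_covering_whole_mask_single_bin(self, cylinder_phantom):
        mucus = np.zeros(cylinder_phantom.shape, dtype=bool)
        records, _ = geodesic_cross_sections(
            cylinder_phantom.lumen, cylinder_phantom.lumen, mucus
        )
        assert len(records) == 1
        assert records[0].lumen_count == int(cylinder_phantom.lumen.sum())

    def test_disjoint_seed_raises(self, cylinder_phantom):
        seed = np.zeros(cylinder_phantom.shape, dtype=bool)
        seed[0, 0, 0] = True
        with pytest.raises(ValueError, match="disjoint"):
            geodesic_cross_sections(
                cylinder_phantom.lumen, seed, np.zeros_like(seed)
            )

    def test_bins_partition_reachable_mask(self, two_branch_phantom):
        built, mucus, _ = two_branch_phantom
        seed = main_branch_seed_slice(built.labels)
        records, excluded = geodesic_cross_sections(
            built.lumen, seed, mucus, labels=built.labels
        )
        total = sum(r.lumen_count for r in records)
        assert total + int(excluded.sum()) == int(built.lumen.sum())


class TestInvariants:
    def test_record_subset_invariants(self, cylinder_with_annulus):
        built, mucus, _ = cylinder_with_annulus
        skel = skeletonize(built.lumen)
        all_records = (
            slice_cross_sections(built.labels, mucus)
            + skeleton_cross_sections(built.lumen, skel, mucus)
            + geodesic_cross_sections(
                built.lumen, main_branch_seed_slice(built.labels), mucus
            )[0]
        )
        for r in all_records:
            assert 0 <= r.mucus_count <= r.lumen_count
            assert 0 <= r.perimeter_count <= r.lumen_count
            assert r.mucus_perimeter_count <= min(r.perimeter_count, r.mucus_count)

    def test_three_methods_agree_on_aligned_cylinder(self, cylinder_with_annulus):
        built, mucus, _ = cylinder_with_annulus
        slice_by_z = {
            r.station: r.mucus_count / r.lumen_count
            for r in slice_cross_sections(built.labels, mucus)
        }
        skel = skeletonize(built.lumen)
        skel_by_z = {
            r.node[0]: r.mucus_count / r.lumen_count
            for r in skeleton_cross_sections(built.lumen, skel, mucus)
        }
        geo_by_z = {
            r.station + 10: r.mucus_count / r.lumen_count
            for r in geodesic_cross_sections(
                built.lumen, main_branch_seed_slice(built.labels), mucus
            )[0]
        }
        common = sorted(
            set(slice_by_z) & set(skel_by_z) & set(geo_by_z) & set(range(25, 96))
        )
        assert len(common) > 40
        for z in common:
            assert abs(slice_by_z[z] - skel_by_z[z]) <= 0.03
            assert abs(slice_by_z[z] - geo_by_z[z]) <= 0.03
            assert abs(skel_by_z[z] - geo_by_z[z]) <= 0.03

    def test_perimeter_mask_is_6_boundary(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        per = perimeter_mask(mask)
        inner = np.zeros_like(mask)
        inner[3:5, 3:5, 3:5] = True
        assert np.array_equal(per, mask & ~inner)
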