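"""Unit tests of 3D feature extraction and population statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import rotate

import lfcyto as lf


VOX = (0.1, 0.1, 0.1)


def _sphere_volume(d, grid=None, voxel=VOX, center=(0, 0, 0), density=1.0):
    obj = lf.PhantomObject("b", center,
                           [lf.Component("b", lf.Sphere(d), 0, density)])
    if grid is None:
        n = int(d / min(voxel)) + 11
        grid = (n, n, n)
    return lf.voxelize(obj, voxel, grid)[0]


# ---------------------------------------------------------------- segmentation

def test_two_separated_spheres_give_two_labels():
    obj = lf.PhantomObject(
        "pair", (0, 0, 0),
        [lf.Component("p", lf.Puncta(((-1.5, 0, 0), (1.5, 0, 0)), 1.0), 0, 1.0)])
    vol = lf.voxelize(obj, VOX, (31, 31, 61))[0]
    labels, recs = lf.segment_objects(vol, method="otsu", voxel=VOX)
    assert len(recs) == 2
    for r in recs:
        # thresholding at the edge midpoint biases the volume by at most
        # one surface-voxel shell
        assert r.volume == pytest.approx(np.pi / 6.0, rel=0.15)


def test_min_size_filter_removes_specks(rng):
    vol = _sphere_volume(1.0)
    speck = (2, 2, 2)
    vol[speck] = vol.max()
    labels, recs = lf.segment_objects(vol, method="fraction_of_max",
                                      voxel=VOX, params={"min_size": 5})
    assert len(recs) == 1
    assert labels[speck] == 0


def test_empty_volume_gives_no_records():
    labels, recs = lf.segment_objects(np.zeros((8, 8, 8)), voxel=VOX)
    assert recs == []
    assert labels.max() == 0


# ---------------------------------------------------------------- FWHM

def test_fwhm_of_gaussian_blob_closed_form():
    # FWHM = 2 sqrt(2 ln 2) sigma = 2.3548 sigma
    sigma = 0.2     # µm
    zz, yy, xx = (np.mgrid[0:41, 0:41, 0:41] - 20) * 0.05
    blob = np.exp(-(zz ** 2 + yy ** 2 + xx ** 2) / (2 * sigma ** 2))
    for ax in ("x", "y", "z"):
        w = lf.measure_fwhm(blob, (20, 20, 20), ax, voxel=(0.05, 0.05, 0.05))
        assert w == pytest.approx(2.3548 * sigma * 1e3, rel=0.02)
    # intensity scaling leaves the width untouched
    w1 = lf.measure_fwhm(blob * 1234.5, (20, 20, 20), "x", voxel=(0.05,) * 3)
    assert w1 == pytest.approx(2.3548 * sigma * 1e3, rel=0.02)


def test_fwhm_unbounded_flag():
    flat = np.ones((5, 5, 5))
    assert np.isnan(lf.measure_fwhm(flat, (2, 2, 2), "x", voxel=VOX))


# ---------------------------------------------------------------- diameter

def test_equivalent_diameter_examples():
    assert lf.equivalent_diameter(4.18879) == pytest.approx(2.0, abs=1e-4)
    assert lf.equivalent_diameter(np.pi / 6.0) == pytest.approx(1.0)
    with pytest.raises(lf.DomainError):
        lf.equivalent_diameter(0.0)


@settings(max_examples=50, deadline=None)
@given(st.floats(min_value=1e-6, max_value=1e6),
       st.floats(min_value=1.0001, max_value=10.0))
def test_equivalent_diameter_monotone(v, factor):
    assert lf.equivalent_diameter(v * factor) > lf.equivalent_diameter(v)


# ---------------------------------------------------------------- ellipsoid

def test_ellipsoid_fit_recovers_sphere():
    vol = _sphere_volume(4.0)
    radii, degenerate = lf.fit_ellipsoid(vol, voxel=VOX)
    assert not degenerate
    assert np.allclose(radii, 2.0, rtol=0.03)


def test_ellipsoid_fit_recovers_axis_aligned_ellipsoid():
    zz, yy, xx = (np.mgrid[0:81, 0:61, 0:41] - np.array([40, 30, 20])[:, None, None, None]) * 0.1
    inside = (xx / 1.0) ** 2 + (yy / 2.0) ** 2 + (zz / 3.0) ** 2 <= 1.0
    radii, _ = lf.fit_ellipsoid(inside.astype(float), voxel=VOX)
    assert radii[0] == pytest.approx(3.0, rel=0.03)
    assert radii[1] == pytest.approx(2.0, rel=0.03)
    assert radii[2] == pytest.approx(1.0, rel=0.03)
    assert radii[0] >= radii[1] >= radii[2]


def test_ellipsoid_fit_rotation_invariance():
    zz, yy, xx = (np.mgrid[0:81, 0:81, 0:81] - 40) * 0.1
    inside = ((xx / 1.0) ** 2 + (yy / 2.5) ** 2 + (zz / 1.5) ** 2 <= 1.0).astype(float)
    rot = rotate(inside, 35.0, axes=(1, 2), reshape=False, order=1)
    r0, _ = lf.fit_ellipsoid(inside, voxel=VOX)
    r1, _ = lf.fit_ellipsoid(rot, voxel=VOX)
    assert np.allclose(r0, r1, rtol=0.03)


def test_ellipsoid_fit_needs_enough_voxels():
    small = np.zeros((5, 5, 5))
    small[2, 2, 2] = 1.0
    with pytest.raises(lf.DomainError):
        lf.fit_ellipsoid(small, voxel=VOX)


# ---------------------------------------------------------------- N:C ratio

def test_nc_ratio_printed_worked_example():
    cell = lf.CellFeatureRecord(0, volume=np.pi / 6 * 7.99 ** 3)
    nuc = lf.CellFeatureRecord(1, volume=np.pi / 6 * 6.57 ** 3)
    r = lf.nc_ratio(cell, nuc)
    assert r == pytest.approx((6.57 / 7.99) ** 3, rel=1e-12)
    assert not cell.nc_flagged


def test_nc_ratio_identity_and_flagging():
    a = lf.CellFeatureRecord(0, volume=10.0)
    b = lf.CellFeatureRecord(1, volume=10.0)
    assert lf.nc_ratio(a, b) == 1.0
    big_nuc = lf.CellFeatureRecord(2, volume=12.0)
    r = lf.nc_ratio(a, big_nuc)
    assert r > 1.0 and a.nc_flagged


def test_nc_ratio_population_recovery(rng):
    # cohort of generated cells: the mean measured ratio recovers the
    # generator value within the sampling error
    ratios = []
    for i in range(60):
        d_cell = rng.normal(7.99, 0.4)
        d_nuc = d_cell * (6.57 / 7.99) * rng.normal(1.0, 0.02)
        obj = lf.make_cell_phantom("membrane_nucleus", d_cell=d_cell,
                                   d_nuc=d_nuc)
        ratios.append(obj.truth["nc_ratio"])
    expected = (6.57 / 7.99) ** 3
    se = np.std(ratios) / np.sqrt(len(ratios))
    assert abs(np.mean(ratios) - expected) < 4 * se + 0.01


# ---------------------------------------------------------------- micronuclei

def test_micronuclei_metrics_single_component_is_intact():
    rec = lf.CellFeatureRecord(0, volume=12.0, centroid=(1, 2, 3), intensity=5.0)
    count, vol, dist = lf.micronuclei_metrics([rec])
    assert (count, vol, dist) == (1, 12.0, 0.0)


def test_micronuclei_two_equal_components():
    a = lf.CellFeatureRecord(0, volume=2.0, centroid=(0, 0, 0), intensity=1.0)
    b = lf.CellFeatureRecord(1, volume=2.0, centroid=(0, 0, 4.0), intensity=1.0)
    count, vol, dist = lf.micronuclei_metrics([a, b])
    assert count == 2
    assert dist == pytest.approx(2.0)


def test_micronuclei_distance_matches_generator():
    # small, well-separated fragments: segmentation must recover the
    # generator's dispersion within voxel tolerance
    v_total = 4 * np.pi / 6 * 0.9 ** 3       # four 0.9 µm fragments
    obj = None
    for seed in range(20):
        cand = lf.make_cell_phantom("apoptotic", k_micronuclei=4,
                                    dispersion=2.0, seed=seed, d_cell=12.0,
                                    v_nuclei_total=v_total, n_mito=0)
        offs = np.asarray(cand.components[0].geometry.offsets)
        dmin = min(np.linalg.norm(offs[i] - offs[j])
                   for i in range(4) for j in range(i + 1, 4))
        if dmin > 0.9 + 0.3:                  # fragments clearly separated
            obj = cand
            break
    assert obj is not None
    vols = lf.voxelize(obj, VOX, (121, 121, 121))
    labels, recs = lf.segment_objects(vols[0], method="otsu", voxel=VOX)
    assert len(recs) == 4
    count, vol, dist = lf.micronuclei_metrics(recs)
    assert count == 4
    assert dist == pytest.approx(2.0, abs=0.2)    # voxel-scale tolerance
    assert vol == pytest.approx(obj.truth["micronuclei_mean_volume"], rel=0.15)


# ---------------------------------------------------------------- enclosure

def test_mito_enclosure_trivial_bounds(rng):
    cube = np.array([[z, y, x] for z in (0, 4) for y in (0, 4) for x in (0, 4)],
                    dtype=float)
    outside = rng.uniform(10, 20, size=(50, 3))
    assert lf.mito_enclosure_fraction(outside, cube) == 0.0
    inside = rng.uniform(0.5, 3.5, size=(50, 3))
    frac = lf.mito_enclosure_fraction(inside, cube)
    assert frac == pytest.approx(50.0 / (8 + 50), rel=1e-9)


def test_mito_enclosure_half_enclosed_voxel_oracle(rng):
    # hull of a dense cube of corner points is the cube [0,4]^3: membership
    # is analytic, so a brute-force box test is the oracle
    corners = np.array([[z, y, x] for z in (0, 4) for y in (0, 4) for x in (0, 4)],
                       dtype=float)
    mito = rng.uniform(-1, 5, size=(400, 3))
    inside = np.all((mito >= 0) & (mito <= 4), axis=1)
    expected = inside.sum() / (len(corners) + len(mito))
    got = lf.mito_enclosure_fraction(mito, corners)
    assert got == pytest.approx(expected, rel=0.02)


def test_mito_enclosure_empty_micronuclei():
    with pytest.warns(UserWarning):
        assert lf.mito_enclosure_fraction(np.ones((3, 3)), np.empty((0, 3))) == 0.0


# ---------------------------------------------------------------- populations

def _bead_records(rng, counts=(20, 20, 20, 20), diam=(0.42, 1.05, 2.05, 4.02)):
    recs = []
    for cls, (n, d) in enumerate(zip(counts, diam)):
        for _ in range(n):
            dd = d * rng.normal(1.0, 0.06)
            vol = np.pi / 6 * dd ** 3
            # measured intensity tracks the measured volume (same object)
            recs.append(lf.CellFeatureRecord(
                len(recs), volume=vol,
                diameter=lf.equivalent_diameter(vol),
                intensity=2e5 * vol * rng.lognormal(0.0, 0.08)))
    return recs


def test_population_count_four_classes_stable_over_seeds():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        summary = lf.population_count(_bead_records(rng))
        assert summary.n_clusters == 4
        assert summary.total == 80
        d = summary.cluster_means["mean_diameter"].to_numpy()
        assert np.all(np.diff(d) > 0)


def test_population_count_single_class():
    rng = np.random.default_rng(0)
    recs = _bead_records(rng, counts=(40,), diam=(2.0,))
    assert lf.population_count(recs).n_clusters == 1


def test_gaussian_fit_diameter_parameter_recovery(rng):
    d = rng.normal(7.99, 0.5, size=400)
    mean, sigma = lf.gaussian_fit_diameter(d)
    assert mean == pytest.approx(7.99, abs=0.1)
    assert sigma == pytest.approx(0.5, abs=0.12)
    # zero-variance cohort: exact mean
    m0, s0 = lf.gaussian_fit_diameter(np.full(20, 3.3))
    assert (m0, s0) == (3.3, 0.0)


def test_gaussian_fit_bin_width_invariance(rng):
    d = rng.normal(6.57, 0.4, size=500)
    m_fd, _ = lf.gaussian_fit_diameter(d, bins="fd")
    m_20, _ = lf.gaussian_fit_diameter(d, bins=20)
    m_40, _ = lf.gaussian_fit_diameter(d, bins=40)
    assert m_20 == pytest.approx(m_fd, rel=0.02)
    assert m_40 == pytest.approx(m_fd, rel=0.02)


def test_positive_fraction_recovery(rng):
    # 80% positives at 10x reporter intensity, Otsu gate on log-intensity
    n = 200
    pos = rng.lognormal(np.log(1e4), 0.25, size=int(0.8 * n))
    neg = rng.lognormal(np.log(1e3), 0.25, size=n - int(0.8 * n))
    vals = np.concatenate([pos, neg])
    frac = lf.positive_fraction(vals)
    se = 100 * np.sqrt(0.8 * 0.2 / n)
    assert frac == pytest.approx(80.0, abs=3 * se)
    assert lf.positive_fraction(neg, threshold=1e5) == 0.0


def test_positive_fraction_threshold_monotone(rng):
    vals = rng.lognormal(8.0, 1.0, size=300)
    fracs = [lf.positive_fraction(vals, threshold=t)
             for t in np.quantile(vals, [0.1, 0.3, 0.5, 0.7, 0.9])]
    assert np.all(np.diff(fracs) <= 0)


def test_records_table_roundtrip():
    rng = np.random.default_rng(1)
    recs = _bead_records(rng, counts=(3,), diam=(1.0,))
    table = lf.records_to_frame(recs)
    assert len(table) == 3
    assert {"volume", "diameter", "intensity", "radius_a"} <= set(table.columns)
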