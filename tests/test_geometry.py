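"""Tissue-map construction and rasterization."""

import numpy as np
import pytest
from scipy import ndimage

from pfafield import (GeometrySpec, ScarSpec, TissueLabel, TissueMap,
                      build_model, rasterize)


@pytest.fixture(scope="module")
def scar():
    return ScarSpec()


@pytest.mark.parametrize("model,point,expected", [
    ("A", (5.0, 3.0), TissueLabel.MYOCARDIUM),
    ("A", (5.0, 8.0), TissueLabel.FAT),
    ("A", (5.0, 10.0), TissueLabel.CONNECTIVE),
    ("A", (5.0, -5.0), TissueLabel.BLOOD),
    ("A", (0.5, 0.2), TissueLabel.ELECTRODE),   # inserted tip
    ("A", (0.5, -10.0), TissueLabel.INSULATED_SHAFT),
    ("B", (5.0, 8.0), TissueLabel.CONNECTIVE),
    ("B", (5.0, 3.0), TissueLabel.MYOCARDIUM),
    ("C", (2.0, 3.0), TissueLabel.FIBROSIS),
    ("C", (2.0, 0.7), TissueLabel.MYOCARDIUM),  # subendocardial rim
    ("D", (0.1, 3.6), TissueLabel.FAT),         # dominant slab
    ("E", (0.1, 3.0), TissueLabel.MYOCARDIUM),  # channel on the axis
    ("E", (3.0, 3.0), TissueLabel.FIBROSIS),
    ("F", (2.0, 0.7), TissueLabel.FIBROSIS),    # blocked subendocardium
])
def test_model_labels(model, point, expected, scar):
    tmap = build_model(model, scar=scar if model in "CDEF" else None, seed=1)
    assert tmap.label_at(*point) == expected


def test_unknown_model_and_missing_scar():
    with pytest.raises(ValueError, match="unknown model_id"):
        build_model("G")
    with pytest.raises(ValueError, match="requires a ScarSpec"):
        build_model("C")


def test_spec_invariants():
    with pytest.raises(ValueError):
        GeometrySpec(insertion_depth=4.0)  # > electrode length
    with pytest.raises(ValueError):
        GeometrySpec(wall_thickness=-1.0)
    with pytest.raises(ValueError):
        ScarSpec(main_fat_slab_top=5.0, main_fat_slab_bottom=4.0)


def test_seeded_model_reproducible(scar):
    m1 = build_model("D", scar=scar, seed=1)
    m2 = build_model("D", scar=scar, seed=1)
    assert m1.to_config() == m2.to_config()
    g1 = rasterize(m1, 0.2)
    g2 = rasterize(m2, 0.2)
    assert np.array_equal(g1.labels, g2.labels)
    m3 = build_model("D", scar=scar, seed=2)
    assert not np.array_equal(g1.labels, rasterize(m3, 0.2).labels)


def test_blobs_lie_inside_scar(scar):
    tmap = build_model("D", scar=scar, seed=1)
    from shapely.geometry import box
    scar_poly = box(0.0, scar.scar_top_depth, scar.scar_radius,
                    scar.scar_bottom_depth)
    blobs = [g for g in tmap.fat_inclusions() if g.kind == "blob"]
    assert len(blobs) == scar.fat_blob_count
    for b in blobs:
        assert scar_poly.covers(b.polygon)


def test_raster_partition_and_fat_area():
    tmap = build_model("A")
    grid = rasterize(tmap, 0.1)
    assert (grid.labels >= 0).all()  # every cell labeled
    s = tmap.spec
    domain_area = s.domain_radius * (s.z_bottom - s.z_top)
    fat_band_area = s.domain_radius * s.epicardial_fat_thickness
    frac = grid.area_fraction(TissueLabel.FAT)
    assert frac == pytest.approx(fat_band_area / domain_area, rel=0.01)


def test_raster_refinement_consistency():
    tmap = build_model("A")
    a1 = rasterize(tmap, 0.1).tissue_areas()
    a2 = rasterize(tmap, 0.05).tissue_areas()
    for name in ("MYOCARDIUM", "FAT", "BLOOD", "CONNECTIVE"):
        assert a1[name] == pytest.approx(a2[name], rel=0.02)
    assert sum(a1.values()) == pytest.approx(sum(a2.values()), rel=0.01)


def test_raster_warns_when_too_coarse():
    tmap = build_model("A")
    with pytest.warns(UserWarning, match="smallest feature"):
        rasterize(tmap, 0.5)


def test_channel_model_has_connected_myocardial_path(scar):
    """Model E: viable myocardium runs from the surface under the
    electrode down to the deep myocardium below the scar."""
    tmap = build_model("E", scar=scar, seed=1)
    grid = rasterize(tmap, 0.1)
    myo = grid.labels == int(TissueLabel.MYOCARDIUM)
    lab, _ = ndimage.label(myo)
    zc = grid.z_centers
    rc = grid.r_centers
    i0 = int(np.argmin(np.abs(rc - 0.1)))
    j_top = int(np.argmin(np.abs(zc - (tmap.spec.tip_z + 0.1))))
    j_deep = int(np.argmin(np.abs(zc - 6.5)))  # below the scar
    assert lab[i0, j_top] != 0
    assert lab[i0, j_top] == lab[i0, j_deep]


def test_config_roundtrip(scar):
    m = build_model("D", scar=scar, seed=7)
    m2 = TissueMap.from_config(m.to_config())
    assert m2.to_config() == m.to_config()
    assert np.array_equal(rasterize(m, 0.2).labels, rasterize(m2, 0.2).labels)
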