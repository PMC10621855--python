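"""Axisymmetric tissue geometry for focal PFA simulations.

The computational domain is the (r, z) half-plane obtained by cutting the
3D scene along the catheter axis: ``r`` is the distance from the axis and
``z`` is depth, with ``z = 0`` at the undisturbed endocardial surface and
``z > 0`` pointing into the ventricular wall.  Blood fills ``z < 0``; a
blunt-tip ablation electrode sits on the axis, inserted a fraction of a
millimetre into the tissue, with an insulated shaft running up through the
blood pool.

Six wall models are supported:

* ``A`` - homogeneous myocardium with a 2-mm epicardial fat layer,
* ``B`` - as A with the fat layer replaced by connective tissue,
* ``C`` - a fibrotic (scar) region embedded in the wall, no fat inside,
* ``D`` - as C with fat deposited in the scar: one dominant slab plus a
  seeded set of small elliptical blobs (a parametric stand-in for a
  histology-derived deposit),
* ``E`` - as C with a channel of viable myocardium under the electrode,
* ``F`` - as C with the subendocardial myocardium under the electrode
  replaced by fibrosis (a "blocked" wall).

All user-facing lengths are in millimetres.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import shapely
import yaml
from shapely.affinity import rotate, scale, translate
from shapely.geometry import LineString, Point, Polygon, box

__all__ = [
    "TissueLabel",
    "GeometrySpec",
    "ScarSpec",
    "Region",
    "TissueMap",
    "LabelGrid",
    "build_model",
    "rasterize",
    "MODEL_IDS",
]

MODEL_IDS = ("A", "B", "C", "D", "E", "F")


class TissueLabel(enum.IntEnum):
    """Material labels; every point of the domain carries exactly one."""

    MYOCARDIUM = 0
    FIBROSIS = 1
    FAT = 2
    BLOOD = 3
    CONNECTIVE = 4
    ELECTRODE = 5
    INSULATED_SHAFT = 6


@dataclass(frozen=True)
class GeometrySpec:
    """Macroscopic geometry (mm).

    Defaults describe a 7-Fr (2.33 mm) catheter with a 3.5-mm blunt tip
    inserted 0.5 mm into a 7-mm ventricular wall covered by 2 mm of
    epicardial fat, surrounded by a blood pool above and connective
    tissue below.  ``fillet_radius`` rounds the electrode tip corner to
    regularize the edge-field singularity of a flat-ended cylinder.
    """

    wall_thickness: float = 7.0
    epicardial_fat_thickness: float = 2.0
    electrode_diameter: float = 7.0 / 3.0  # 7 Fr, 1 Fr = 1/3 mm
    electrode_length: float = 3.5
    insertion_depth: float = 0.5
    domain_radius: float = 40.0
    domain_height_blood: float = 20.0
    domain_depth_connective: float = 20.0
    fillet_radius: float = 0.1

    def __post_init__(self) -> None:
        vals = asdict(self)
        for name, v in vals.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.insertion_depth >= self.electrode_length:
            raise ValueError("insertion_depth must be < electrode_length")
        if (self.wall_thickness + self.epicardial_fat_thickness
                >= self.wall_thickness + self.epicardial_fat_thickness
                + self.domain_depth_connective):
            raise ValueError("domain too shallow")
        if self.fillet_radius >= self.electrode_radius:
            raise ValueError("fillet_radius must be < electrode radius")

    @property
    def electrode_radius(self) -> float:
        return self.electrode_diameter / 2.0

    @property
    def z_bottom(self) -> float:
        """Lower domain boundary (mm below the endocardial surface)."""
        return (self.wall_thickness + self.epicardial_fat_thickness
                + self.domain_depth_connective)

    @property
    def z_top(self) -> float:
        """Upper domain boundary (negative, in the blood pool)."""
        return -self.domain_height_blood

    @property
    def tip_z(self) -> float:
        """Depth of the electrode tip face (= insertion depth)."""
        return self.insertion_depth

    @property
    def electrode_top_z(self) -> float:
        return self.insertion_depth - self.electrode_length


@dataclass(frozen=True)
class ScarSpec:
    """Parametric scar with optional fat deposits (mm).

    The scar is a fibrotic disc of radius ``scar_width / 2`` spanning
    depths ``scar_top_depth`` to ``scar_top_depth + scar_depth_extent``.
    For the fat-deposition model the dominant deposit is a rounded-rim
    slab between ``main_fat_slab_top`` and ``main_fat_slab_bottom``,
    wide enough to span the lesion footprint, plus ``fat_blob_count``
    seeded elliptical blobs representing patchy fat.
    """

    scar_width: float = 20.0
    scar_depth_extent: float = 5.0
    scar_top_depth: float = 1.0
    fat_blob_count: int = 6
    fat_blob_size_range: tuple[float, float] = (0.3, 1.0)
    main_fat_slab_top: float = 2.6
    main_fat_slab_bottom: float = 4.59
    main_fat_slab_width: float = 14.0
    channel_width: float = 2.0
    subendocardial_fibrosis_thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.main_fat_slab_top >= self.main_fat_slab_bottom:
            raise ValueError("slab top must be above slab bottom")
        if not (self.scar_top_depth <= self.main_fat_slab_top
                and self.main_fat_slab_bottom <= self.scar_bottom_depth):
            raise ValueError("fat slab must lie inside the scar")
        lo, hi = self.fat_blob_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid fat_blob_size_range")

    @property
    def scar_radius(self) -> float:
        return self.scar_width / 2.0

    @property
    def scar_bottom_depth(self) -> float:
        return self.scar_top_depth + self.scar_depth_extent


@dataclass(frozen=True)
class Region:
    """One labeled closed region of the half-plane.

    ``kind`` distinguishes geometric roles (``"layer"`` for stratified
    bands, ``"blob"``/``"slab"`` for discrete fat inclusions, ...); the
    solver only consumes ``label``, but lesion diagnostics use ``kind``
    to find fat inclusions.
    """

    label: TissueLabel
    polygon: Polygon
    kind: str = "layer"
    name: str = ""


def _electrode_polygon(spec: GeometrySpec) -> Polygon:
    re_, zt, zb, f = (spec.electrode_radius, spec.electrode_top_z,
                      spec.tip_z, spec.fillet_radius)
    theta = np.linspace(0.0, np.pi / 2.0, 17)
    arc_r = (re_ - f) + f * np.cos(theta)
    arc_z = (zb - f) + f * np.sin(theta)
    coords = [(0.0, zt), (re_, zt), (re_, zb - f)]
    coords += list(zip(arc_r[1:], arc_z[1:]))
    coords += [(0.0, zb)]
    return Polygon(coords)


def _ellipse(cr: float, cz: float, a: float, b: float, angle_deg: float) -> Polygon:
    e = Point(0.0, 0.0).buffer(1.0, quad_segs=16)
    e = scale(e, a, b)
    e = rotate(e, angle_deg)
    return translate(e, cr, cz)


def _fat_slab(scar: ScarSpec) -> Polygon:
    half = (scar.main_fat_slab_bottom - scar.main_fat_slab_top) / 2.0
    zc = (scar.main_fat_slab_bottom + scar.main_fat_slab_top) / 2.0
    r_end = scar.main_fat_slab_width / 2.0 - half
    if r_end <= 0:
        raise ValueError("main_fat_slab_width too small for its thickness")
    spine = LineString([(-half, zc), (r_end, zc)])  # extend past axis: clipped later
    slab = spine.buffer(half, quad_segs=24)
    return slab


def _seeded_blobs(scar: ScarSpec, slab: Polygon | None,
                  spec: GeometrySpec, seed: int) -> list[Polygon]:
    """Rejection-sample elliptical fat blobs inside the scar.

    Blobs avoid the dominant slab, the electrode, each other and the
    scar boundary (0.15 mm clearance).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = scar.fat_blob_size_range
    scar_poly = box(0.0, scar.scar_top_depth, scar.scar_radius,
                    scar.scar_bottom_depth)
    keepout = scar_poly.boundary.buffer(0.15)
    if slab is not None:
        keepout = keepout.union(slab.buffer(0.2))
    blobs: list[Polygon] = []
    tries = 0
    while len(blobs) < scar.fat_blob_count:
        tries += 1
        if tries > 400:
            raise RuntimeError(
                "could not place fat blobs inside the scar; loosen ScarSpec")
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        cr = rng.uniform(0.3, scar.scar_radius - 0.3)
        cz = rng.uniform(scar.scar_top_depth + 0.3, scar.scar_bottom_depth - 0.3)
        ang = rng.uniform(0.0, 180.0)
        e = _ellipse(cr, cz, a, b, ang)
        e = e.intersection(box(0.0, -1e3, 1e3, 1e3))  # clip to r >= 0
        if e.is_empty or not scar_poly.covers(e):
            continue
        if e.intersects(keepout):
            continue
        if any(e.buffer(0.1).intersects(other) for other in blobs):
            continue
        blobs.append(e)
    return blobs


@dataclass
class TissueMap:
    """Labeled tissue regions for one wall model.

    ``regions`` is an ordered list painted first-match-wins, so later
    (background) regions may geometrically overlap earlier inclusions.
    """

    spec: GeometrySpec
    model_id: str
    regions: list[Region]
    seed: int = 0
    scar: ScarSpec | None = None

    # -- queries ---------------------------------------------------------
    def labels_at(self, r: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Vectorized label lookup at points (mm); first matching region wins."""
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        out = np.full(r.shape, -1, dtype=np.int32)
        todo = np.ones(r.shape, dtype=bool)
        for reg in self.regions:
            if not todo.any():
                break
            hit = shapely.intersects_xy(reg.polygon, r[todo], z[todo])
            idx = np.flatnonzero(todo)
            sel = idx[hit]
            out.flat[sel] = int(reg.label)
            todo.flat[sel] = False
        return out

    def label_at(self, r: float, z: float) -> TissueLabel:
        v = int(self.labels_at(np.array([r]), np.array([z]))[0])
        if v < 0:
            raise ValueError(f"point ({r}, {z}) mm outside the domain")
        return TissueLabel(v)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(r_min, r_max, z_min, z_max) in mm."""
        s = self.spec
        return (0.0, s.domain_radius, s.z_top, s.z_bottom)

    def fat_inclusions(self) -> list[Region]:
        """Discrete intramyocardial fat deposits (blobs and slab)."""
        return [g for g in self.regions
                if g.label == TissueLabel.FAT and g.kind in ("blob", "slab")]

    def interface_z_lines(self) -> list[float]:
        """Horizontal material interfaces the mesh should conform to."""
        s = self.spec
        lines = [float(s.z_top), float(s.electrode_top_z), 0.0,
                 float(s.tip_z), float(s.wall_thickness),
                 float(s.wall_thickness + s.epicardial_fat_thickness),
                 float(s.z_bottom)]
        if self.scar is not None and self.model_id in "CDEF":
            lines += [self.scar.scar_top_depth, self.scar.scar_bottom_depth]
            if self.model_id == "D":
                lines += [self.scar.main_fat_slab_top,
                          self.scar.main_fat_slab_bottom]
        return sorted(set(lines))

    def interface_r_lines(self) -> list[float]:
        s = self.spec
        lines = [0.0, float(s.electrode_radius), float(s.domain_radius)]
        if self.scar is not None and self.model_id in "CDEF":
            lines.append(self.scar.scar_radius)
            if self.model_id == "E":
                lines.append(self.scar.channel_width / 2.0)
        return sorted(set(lines))

    # -- serialization ---------------------------------------------------
    def to_config(self) -> str:
        """Dump the generating parameters as a YAML document (mm)."""
        d = {
            "model_id": self.model_id,
            "seed": int(self.seed),
            "geometry": asdict(self.spec),
            "scar": asdict(self.scar) if self.scar is not None else None,
        }
        if d["scar"] is not None:
            d["scar"]["fat_blob_size_range"] = list(
                d["scar"]["fat_blob_size_range"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_config(cls, text: str) -> "TissueMap":
        d = yaml.safe_load(text)
        spec = GeometrySpec(**d["geometry"])
        scar = None
        if d.get("scar"):
            sc = dict(d["scar"])
            sc["fat_blob_size_range"] = tuple(sc["fat_blob_size_range"])
            scar = ScarSpec(**sc)
        return build_model(d["model_id"], spec, scar, seed=int(d.get("seed", 0)))


def build_model(model_id: str, spec: GeometrySpec | None = None,
                scar: ScarSpec | None = None, seed: int = 0) -> TissueMap:
    """Assemble the labeled tissue map for one of the wall models A-F."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    spec = spec or GeometrySpec()
    if model_id in "CDEF" and scar is None:
        raise ValueError(f"model {model_id} requires a ScarSpec")

    s = spec
    big = s.domain_radius + 1.0
    regions: list[Region] = [
        Region(TissueLabel.ELECTRODE, _electrode_polygon(s), "device", "electrode"),
        Region(TissueLabel.INSULATED_SHAFT,
               box(0.0, s.z_top, s.electrode_radius, s.electrode_top_z),
               "device", "shaft"),
    ]

    if model_id == "E":
        regions.append(Region(
            TissueLabel.MYOCARDIUM,
            box(0.0, scar.scar_top_depth, scar.channel_width / 2.0,
                scar.scar_bottom_depth),
            "channel", "myocardial_channel"))

    if model_id == "D":
        slab = _fat_slab(scar).intersection(box(0.0, -1e3, big, 1e3))
        for i, blob in enumerate(_seeded_blobs(scar, slab, s, seed)):
            regions.append(Region(TissueLabel.FAT, blob, "blob", f"fat_blob_{i}"))
        regions.append(Region(TissueLabel.FAT, slab, "slab", "fat_slab"))

    if model_id == "F":
        regions.append(Region(
            TissueLabel.FIBROSIS,
            box(0.0, 0.0, scar.scar_radius,
                scar.subendocardial_fibrosis_thickness),
            "scar", "subendocardial_fibrosis"))

    if model_id in "CDEF":
        regions.append(Region(
            TissueLabel.FIBROSIS,
            box(0.0, scar.scar_top_depth, scar.scar_radius,
                scar.scar_bottom_depth),
            "scar", "scar"))

    # background layers (painted last)
    regions.append(Region(TissueLabel.BLOOD,
                          box(0.0, s.z_top, big, 0.0), "layer", "blood"))
    regions.append(Region(TissueLabel.MYOCARDIUM,
                          box(0.0, 0.0, big, s.wall_thickness),
                          "layer", "myocardium"))
    band_label = TissueLabel.CONNECTIVE if model_id == "B" else TissueLabel.FAT
    regions.append(Region(band_label,
                          box(0.0, s.wall_thickness, big,
                              s.wall_thickness + s.epicardial_fat_thickness),
                          "layer", "epicardial_band"))
    regions.append(Region(TissueLabel.CONNECTIVE,
                          box(0.0, s.wall_thickness + s.epicardial_fat_thickness,
                              big, s.z_bottom),
                          "layer", "connective"))
    return TissueMap(spec=s, model_id=model_id, regions=regions,
                     seed=seed, scar=scar if model_id in "CDEF" else None)


@dataclass
class LabelGrid:
    """Cell-centered label raster of the (r, z) half-plane (mm)."""

    r_edges: np.ndarray
    z_edges: np.ndarray
    labels: np.ndarray  # shape (nr_cells, nz_cells), int

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def area_fraction(self, label: TissueLabel) -> float:
        """Fraction of half-plane area carrying ``label`` (planar, not revolved)."""
        return float(np.mean(self.labels == int(label)))

    def tissue_areas(self) -> dict[str, float]:
        """Planar area (mm^2) per label."""
        dr = np.diff(self.r_edges)[:, None]
        dz = np.diff(self.z_edges)[None, :]
        cell = dr * dz
        out = {}
        for lab in TissueLabel:
            out[lab.name] = float(cell[self.labels == int(lab)].sum())
        return out


def rasterize(tissue_map: TissueMap, h: float) -> LabelGrid:
    """Rasterize a tissue map to a cell-centered label grid at resolution ``h`` mm."""
    if h <= 0:
        raise ValueError("h must be > 0")
    smallest = min(tissue_map.spec.fillet_radius,
                   tissue_map.scar.fat_blob_size_range[0]
                   if tissue_map.scar is not None else np.inf)
    if h > smallest:
        warnings.warn(
            f"raster resolution h={h} mm exceeds the smallest feature "
            f"({smallest} mm); small regions may be missed", stacklevel=2)
    r0, r1, z0, z1 = tissue_map.bounds
    r_edges = np.arange(r0, r1 + 0.5 * h, h)
    z_edges = np.arange(z0, z1 + 0.5 * h, h)
    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    R, Z = np.meshgrid(rc, zc, indexing="ij")
    labels = tissue_map.labels_at(R.ravel(), Z.ravel()).reshape(R.shape)
    return LabelGrid(r_edges=r_edges, z_edges=z_edges, labels=labels)
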