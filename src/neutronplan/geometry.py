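"""Phantom and treatment-room geometry.

Three irradiation setups are supported:

* the solid water phantom: a Perspex box (63.5 x 63.5 x 52 cm^3, 2 cm walls)
  filled with water, an entrance window (12 x 34 cm^2) sealed by two 1.5 mm
  aluminum plates, and an array of 40 water-equivalent scoring chambers on
  the beam axis (radius 0.38 cm, height 1.21 cm, depths 0.5 ... 39.5 cm);
* the same phantom voxelised (box enlarged to 64 x 64 x 52 cm^3 so the
  0.2 x 0.2 x 0.5 cm^3 voxels divide it exactly);
* an anthropomorphic voxel phantom (file-loaded, or the built-in synthetic
  head/neck stand-in) with organ IDs projected onto tissue materials.

Coordinates are continuous cm.  The beam travels along +x and enters the
phantom face at x = 0; voxel indices are 0-based with half-open intervals
[i*d, (i+1)*d).  The optional treatment-room shell is six concrete slabs
(83 cm, 50 cm for the beam-entry wall) with a 20 x 30 cm^2 beam window.

Geometry is resolved first-fit: the packed box list is ordered innermost
first, so every point maps to exactly one material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .materials import Material, MaterialTable, load_materials

__all__ = [
    "SolidBoxPhantom",
    "RoomShell",
    "VoxelPhantom",
    "ChamberArray",
    "Geometry",
    "chamber_depths",
    "chamber_volume",
    "voxelise_box",
    "load_voxel_phantom",
    "save_voxel_phantom",
    "crop_upper",
    "synthetic_head_phantom",
    "build_solid_water_geometry",
    "build_voxel_water_geometry",
    "build_head_geometry",
    "SOURCE_X",
]

SOURCE_X = -59.9  # cm; source plane just inside the room at the beam window


@dataclass
class ChamberArray:
    """Tube-shaped water scoring chambers along the beam axis (axis vertical)."""

    first_depth: float = 0.5   # cm
    pitch: float = 1.0         # cm
    count: int = 40
    radius: float = 0.38       # cm
    height: float = 1.21       # cm

    @property
    def half_height(self) -> float:
        return self.height / 2.0

    @property
    def volume(self) -> float:
        return chamber_volume(self.radius, self.height)

    @property
    def depths(self) -> np.ndarray:
        return chamber_depths(self.first_depth, self.pitch, self.count)


@dataclass
class SolidBoxPhantom:
    """Perspex-walled water box with entrance window and chamber array."""

    outer: tuple[float, float, float] = (63.5, 63.5, 52.0)  # x (depth), y, z cm
    wall: float = 2.0
    window: tuple[float, float] = (12.0, 34.0)   # y x z aperture
    al_plate: float = 0.15                       # one plate; two are stacked
    n_al_plates: int = 2
    chambers: ChamberArray = field(default_factory=ChamberArray)

    def __post_init__(self) -> None:
        water_depth = self.outer[0] - 2 * self.wall
        last = self.chambers.first_depth + (self.chambers.count - 1) * self.chambers.pitch
        if last + self.chambers.radius >= water_depth:
            raise ValueError("chamber array does not fit inside the water volume")

    @property
    def water_interior(self) -> tuple[float, float, float]:
        return tuple(d - 2 * self.wall for d in self.outer)


@dataclass
class RoomShell:
    """Schematic concrete treatment room around the phantom."""

    wall: float = 83.0            # cm
    exit_wall: float = 50.0       # beam-entry side
    window: tuple[float, float] = (20.0, 30.0)  # y x z
    half_height: float = 145.0    # beam axis to floor/ceiling
    half_width: float = 150.0     # beam axis to side walls
    length: float = 300.0         # interior length along the beam

    def __post_init__(self) -> None:
        if self.window[0] / 2 > self.half_width or self.window[1] / 2 > self.half_height:
            raise ValueError("beam window does not fit inside the exit wall")


def chamber_depths(first: float, pitch: float, count: int) -> np.ndarray:
    """Arithmetic chamber-depth sequence: first, first+pitch, ..."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    return first + pitch * np.arange(count)


def chamber_volume(radius: float, height: float) -> float:
    """Cylinder volume pi r^2 h (cm^3)."""
    if radius < 0 or height < 0:
        raise ValueError("radius and height must be >= 0")
    return float(np.pi * radius**2 * height)


# ----------------------------------------------------------------------------
# voxel phantoms
# ----------------------------------------------------------------------------

@dataclass
class VoxelPhantom:
    """Integer-labelled voxel grid.

    ``ids`` holds organ IDs (or directly material IDs when ``organ_map`` is
    None).  Axis convention: x = columns (patient right -> left), y = rows
    (front -> back), z = slices (feet -> head).
    """

    ids: np.ndarray                       # (nx, ny, nz) unsigned integers
    voxel_size: tuple[float, float, float]  # cm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    organ_map: dict[int, int] | None = None   # organ ID -> material ID
    name: str = "phantom"

    def __post_init__(self) -> None:
        self.ids = np.ascontiguousarray(self.ids)
        if self.ids.ndim != 3:
            raise ValueError("phantom grid must be 3-D")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ids.shape

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.ids.shape, self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(self.ids.size)

    @property
    def voxel_volume(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    def material_ids(self) -> np.ndarray:
        """Project organ IDs onto material IDs."""
        if self.organ_map is None:
            return self.ids
        present = np.unique(self.ids)
        missing = [int(i) for i in present if int(i) not in self.organ_map]
        if missing:
            raise KeyError(f"organ ID(s) not in organ map: {missing}")
        lut = np.zeros(int(present.max()) + 1, dtype=np.int64)
        for org, mat in self.organ_map.items():
            if org <= present.max():
                lut[org] = mat
        return lut[self.ids]


def voxelise_box(extent: tuple[float, float, float],
                 voxel: tuple[float, float, float],
                 material_id: int = 1) -> VoxelPhantom:
    """Uniform-material voxelisation of a box; voxels must divide it exactly."""
    shape = []
    for e, v in zip(extent, voxel):
        n = e / v
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"voxel size {v} does not divide extent {e} exactly "
                f"({n} voxels); enlarge the box")
        shape.append(int(round(n)))
    ids = np.full(tuple(shape), material_id, dtype=np.uint16)
    return VoxelPhantom(ids, tuple(voxel), organ_map=None, name="voxelised_box")


def crop_upper(phantom: VoxelPhantom, n_slices: int) -> VoxelPhantom:
    """Keep the top ``n_slices`` along z (head end); origin is adjusted."""
    nz = phantom.shape[2]
    if n_slices <= 0:
        raise ValueError("n_slices must be > 0")
    if n_slices > nz:
        raise ValueError(f"cannot keep {n_slices} of {nz} slices")
    ox, oy, oz = phantom.origin
    oz += (nz - n_slices) * phantom.voxel_size[2]
    return VoxelPhantom(phantom.ids[:, :, nz - n_slices:].copy(), phantom.voxel_size,
                        (ox, oy, oz), phantom.organ_map, phantom.name + "_upper")


# --- phantom files: text header + raw little-endian uint16 grid, x fastest --

_MAGIC = "NPVOX 1"


def save_voxel_phantom(phantom: VoxelPhantom, grid_path: str | Path,
                       organ_map_path: str | Path | None = None) -> None:
    nx, ny, nz = phantom.shape
    vx, vy, vz = phantom.voxel_size
    header = (f"{_MAGIC}\n"
              f"shape {nx} {ny} {nz}\n"
              f"voxel_mm {vx*10:.6g} {vy*10:.6g} {vz*10:.6g}\n"
              f"origin_cm {phantom.origin[0]:.6g} {phantom.origin[1]:.6g} "
              f"{phantom.origin[2]:.6g}\n"
              f"dtype uint16\nEND\n")
    # payload x fastest: flat index i + nx*(j + ny*k)
    payload = phantom.ids.astype("<u2").transpose(2, 1, 0).tobytes()
    with open(grid_path, "wb") as f:
        f.write(header.encode())
        f.write(payload)
    if organ_map_path is not None and phantom.organ_map is not None:
        lines = [f"{org} {mat} organ_{org}" for org, mat in sorted(phantom.organ_map.items())]
        Path(organ_map_path).write_text("\n".join(lines) + "\n")


def load_voxel_phantom(grid_path: str | Path,
                       organ_map_path: str | Path | None = None) -> VoxelPhantom:
    grid_path = Path(grid_path)
    raw = grid_path.read_bytes()
    end = raw.find(b"END\n")
    if not raw.startswith(_MAGIC.encode()) or end < 0:
        raise ValueError(f"not a phantom file: {grid_path}")
    header = raw[:end].decode().splitlines()
    fields = {}
    for line in header[1:]:
        key, *vals = line.split()
        fields[key] = vals
    nx, ny, nz = (int(v) for v in fields["shape"])
    voxel = tuple(float(v) / 10.0 for v in fields["voxel_mm"])
    origin = tuple(float(v) for v in fields["origin_cm"])
    payload = raw[end + 4:]
    expected = nx * ny * nz * 2
    if len(payload) != expected:
        raise ValueError(
            f"phantom payload length {len(payload)} does not match header "
            f"shape {nx}x{ny}x{nz} ({expected} bytes)")
    ids = np.frombuffer(payload, dtype="<u2").reshape(nz, ny, nx).transpose(2, 1, 0)
    organ_map = None
    if organ_map_path is not None:
        organ_map = {}
        for line in Path(organ_map_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            org, mat, *_name = line.split()
            organ_map[int(org)] = int(mat)
    phantom = VoxelPhantom(ids.copy(), voxel, origin, organ_map, grid_path.stem)
    if organ_map is not None:
        phantom.material_ids()  # raises on unmapped IDs
    return phantom


# ----------------------------------------------------------------------------
# synthetic head/neck phantom (stand-in for an unavailable reference phantom)
# ----------------------------------------------------------------------------

# organ IDs used by the generator; most project 1:1 onto material IDs, the
# six salivary glands and the eyes get their own organ IDs.
_GLAND_ORGANS = {
    "parotid_r": 110, "parotid_l": 111,
    "submandibular_r": 112, "submandibular_l": 113,
    "sublingual_r": 114, "sublingual_l": 115,
}
_EYE_ORGAN = 120          # vitreous humour -> water
_TRACHEA_ORGAN = 105      # lumen -> air


def synthetic_head_phantom(
    seed: int = 0,
    shape: tuple[int, int, int] = (299, 137, 337),
    voxel_size: tuple[float, float, float] = (0.1775, 0.1775, 0.484),
) -> tuple[VoxelPhantom, dict[str, np.ndarray]]:
    """Layered ellipsoidal head/neck/upper-torso phantom with ROI masks.

    Synthetic anatomy standing in for a CT-segmented reference phantom: a
    layered head (skin/adipose/muscle/skull/CSF/brain), a neck with spine,
    trachea, oesophagus, thyroid and the six salivary glands, and an upper
    torso (lungs, heart, liver, spleen, breast).  Skin is enforced as the
    one-voxel body surface, so the outermost tissue voxel along any ray is
    skin.  Deterministic for a given seed (the seed only jitters small-organ
    positions).  Returns the phantom (organ-ID grid + organ map) and a dict
    of boolean ROI masks for the glands and the body.
    """
    nx, ny, nz = shape
    if nx < 40 or ny < 40 or nz < 60:
        raise ValueError(f"shape {shape} too small for the layered head model")
    rng = np.random.default_rng(seed)
    vx, vy, vz = voxel_size
    X, Y, Z = nx * vx, ny * vy, nz * vz
    # voxel-centre coordinate grids (broadcast, cm)
    xs = (np.arange(nx) + 0.5)[:, None, None] * vx
    ys = (np.arange(ny) + 0.5)[None, :, None] * vy
    zs = (np.arange(nz) + 0.5)[None, None, :] * vz

    ids = np.zeros(shape, dtype=np.uint16)

    # reference anatomy is defined in a body frame: lateral (x) and
    # antero-posterior (y) offsets and all sizes scale with s; vertical
    # positions hang from the head centre, so the model is scale-invariant
    s = min(X / 53.07, Y / 24.32, Z / 163.1, 1.0)
    cx0, cy0 = 0.5 * X, 0.5 * Y
    hz = 0.90 * Z  # head centre height

    def ell(off, semi):
        """Ellipsoid at body-frame offset (cm); paints >= 1 voxel."""
        cxx, cyy, czz = cx0 + off[0], cy0 + off[1], hz + off[2]
        m = (((xs - cxx) / semi[0]) ** 2 + ((ys - cyy) / semi[1]) ** 2
             + ((zs - czz) / semi[2]) ** 2) <= 1.0
        if not m.any():  # guarantee at least the centre voxel
            i = min(max(int(cxx / vx), 0), nx - 1)
            j = min(max(int(cyy / vy), 0), ny - 1)
            k = min(max(int(czz / vz), 0), nz - 1)
            m[i, j, k] = True
        return m

    def cyl(offx, offy, rx, ry, zlo, zhi):
        """Vertical cylinder at body-frame offsets; z range relative to hz."""
        cxx, cyy = cx0 + offx, cy0 + offy
        return ((((xs - cxx) / rx) ** 2 + ((ys - cyy) / ry) ** 2) <= 1.0) \
            & (zs >= hz + zlo) & (zs <= hz + zhi)

    # --- body envelope: head + jaw + neck + upper torso ---
    head_semi = np.array([7.8, 9.6, 10.8]) * s
    head = ell((0, 0, 0), head_semi)
    jaw = ell((0, -2.5 * s, -9.5 * s), (4.5 * s, 6.5 * s, 4.0 * s))
    neck = cyl(0, 0, 5.0 * s, 5.6 * s, -26.5 * s, -8.5 * s)
    torso = cyl(0, 0, 16.5 * s, 10.5 * s, -57.0 * s, -22.0 * s)
    body = head | jaw | neck | torso

    t_skin = max(0.25, 1.05 * max(vx, vy))
    t_fat = max(0.5, 1.05 * max(vx, vy))
    # fill body with skin, then adipose and muscle from eroded shapes
    ids[body] = 19
    inner1 = (ell((0, 0, 0), head_semi - t_skin)
              | ell((0, -2.5 * s, -9.5 * s),
                    (4.5 * s - t_skin, 6.5 * s - t_skin, 4.0 * s - t_skin))
              | cyl(0, 0, 5.0 * s - t_skin, 5.6 * s - t_skin,
                    -26.5 * s, -8.5 * s)
              | cyl(0, 0, 16.5 * s - t_skin, 10.5 * s - t_skin,
                    -56.6 * s, -22.4 * s))
    ids[inner1] = 28
    tsf = t_skin + t_fat
    inner2 = (ell((0, 0, 0), head_semi - tsf)
              | ell((0, -2.5 * s, -9.5 * s),
                    (4.5 * s - tsf, 6.5 * s - tsf, 4.0 * s - tsf))
              | cyl(0, 0, 5.0 * s - tsf, 5.6 * s - tsf, -26.5 * s, -8.5 * s)
              | cyl(0, 0, 16.5 * s - tsf, 10.5 * s - tsf,
                    -56.2 * s, -22.8 * s))
    ids[inner2] = 21

    # --- skull with diploe, CSF, brain ---
    sk = head_semi - tsf - 0.4 * s
    ids[ell((0, 0, 0), sk)] = 23                        # outer table, cortical
    ids[ell((0, 0, 0), sk - max(0.45 * s, vx))] = 26    # diploe, yellow marrow
    ids[ell((0, 0, 0), sk - max(0.9 * s, 2 * vx))] = 23  # inner table
    br = sk - 1.6 * s
    ids[ell((0, 0, 0), br + 0.3 * s)] = 35              # CSF
    ids[ell((0, 0, 0), br)] = 11                        # brain

    # --- upper-torso organs (below the head-and-neck treatment region) ---
    for sx in (-1.0, 1.0):
        ids[ell((sx * 6.9 * s, 0, -40.0 * s), (5.2 * s, 6.2 * s, 7.8 * s))] = 13
        ids[ell((sx * 4.2 * s, -8.2 * s, -42.0 * s),
                (3.4 * s, 1.9 * s, 3.2 * s))] = 27       # breasts
    ids[ell((2.1 * s, -2.0 * s, -44.0 * s), (4.2 * s, 4.4 * s, 4.2 * s))] = 22
    ids[ell((-6.4 * s, 1.2 * s, -52.0 * s), (6.0 * s, 6.4 * s, 3.4 * s))] = 29
    ids[ell((8.5 * s, 2.4 * s, -52.0 * s), (2.6 * s, 3.2 * s, 2.6 * s))] = 31
    ids[ell((0, -4.6 * s, -34.0 * s), (1.6 * s, 1.3 * s, 2.4 * s))] = 36  # thymus

    # --- vertebral column with spinal canal ---
    ids[cyl(0, 3.1 * s, 1.9 * s, 1.9 * s, -55.0 * s, -9.0 * s)] = 23
    ids[cyl(0, 3.1 * s, 1.3 * s, 1.3 * s, -55.0 * s, -9.0 * s)] = 24
    ids[cyl(0, 3.1 * s, max(0.6 * s, vx), max(0.6 * s, vy),
            -55.0 * s, -9.0 * s)] = 25
    ids[cyl(0, 4.3 * s, max(0.55 * s, vx), max(0.55 * s, vy),
            -55.0 * s, -8.5 * s)] = 35                   # CSF in the canal
    ids[cyl(0, 4.3 * s, max(0.35 * s, 0.8 * vx), max(0.35 * s, 0.8 * vy),
            -55.0 * s, -8.5 * s)] = 18                   # spinal cord

    # --- airway, oesophagus, thyroid ---
    ids[cyl(0, -2.6 * s, 1.25 * s, 1.25 * s, -48.0 * s, -10.5 * s)] = 14
    trachea = cyl(0, -2.6 * s, max(0.85 * s, vx), max(0.85 * s, vy),
                  -48.0 * s, -10.5 * s)
    ids[trachea] = 5
    ids[cyl(0, -0.4 * s, max(0.5 * s, vx), max(0.5 * s, vy),
            -55.0 * s, -16.0 * s)] = 33                  # oesophagus
    ids[ell((0, -3.0 * s, -12.5 * s), (2.2 * s, 1.3 * s, 1.4 * s))
        & ~trachea] = 16                                 # thyroid lobes

    # --- mouth and face ---
    ids[ell((0, -3.5 * s, -9.5 * s), (2.6 * s, 2.2 * s, 1.5 * s))] = 37  # tongue
    ids[ell((0, -5.2 * s, -9.3 * s), (2.3 * s, 1.1 * s, 0.9 * s))] = 17  # mucosa
    for sx in (-1.0, 1.0):
        ids[ell((sx * 1.6 * s, -5.6 * s, -9.0 * s),
                (max(0.8 * s, vx), max(0.5 * s, vy), max(0.5 * s, vz)))] = 34
        ids[ell((sx * 4.0 * s, -6.7 * s, 2.7 * s),
                (1.25 * s, 1.25 * s, 1.25 * s))] = 10    # sclera
        ids[ell((sx * 4.0 * s, -6.7 * s, 2.7 * s),
                (0.95 * s, 0.95 * s, 0.95 * s))] = 1     # vitreous humour
        ids[ell((sx * 4.0 * s, -7.6 * s, 2.7 * s),
                (max(0.4 * s, vx), max(0.3 * s, vy), max(0.4 * s, vz)))] = 15
    ids[ell((0, 0.5 * s, -1.0 * s), (max(0.6 * s, vx), max(0.5 * s, vy),
                                     max(0.4 * s, vz)))] = 38  # pituitary
    # carotid vessels and neck lymph nodes (positions jittered by the seed)
    for sx in (-1.0, 1.0):
        jx = 0.4 * s * (rng.random() - 0.5)
        ids[cyl(sx * 2.2 * s + jx, -1.2 * s,
                max(0.4 * s, vx), max(0.4 * s, vy), -24.0 * s, -10.0 * s)] = 12
        jz = 1.5 * s * (rng.random() - 0.5)
        ids[ell((sx * 3.4 * s, 0.3 * s, -13.0 * s + jz),
                (max(0.6 * s, vx), max(0.6 * s, vy), max(0.8 * s, vz)))] = 36

    # --- salivary glands (ROI organs) ---
    gland_geo = {
        "parotid_r": ((-5.8 * s, 0.5 * s, -6.0 * s), (1.2 * s, 1.7 * s, 1.9 * s)),
        "parotid_l": ((5.8 * s, 0.5 * s, -6.0 * s), (1.2 * s, 1.7 * s, 1.9 * s)),
        "submandibular_r": ((-3.3 * s, -3.3 * s, -9.8 * s),
                            (1.1 * s, 1.3 * s, 1.1 * s)),
        "submandibular_l": ((3.3 * s, -3.3 * s, -9.8 * s),
                            (1.1 * s, 1.3 * s, 1.1 * s)),
        "sublingual_r": ((-1.1 * s, -3.9 * s, -9.4 * s),
                         (0.65 * s, 0.75 * s, 0.65 * s)),
        "sublingual_l": ((1.1 * s, -3.9 * s, -9.4 * s),
                         (0.65 * s, 0.75 * s, 0.65 * s)),
    }
    rois: dict[str, np.ndarray] = {}
    for gname, (off, semi) in gland_geo.items():
        mask = ell(off, semi) & body
        if not mask.any():
            raise ValueError(f"shape {shape} too small: gland {gname} is empty")
        ids[mask] = _GLAND_ORGANS[gname]
        rois[gname] = mask
    # glands must be disjoint: later paints win, so drop overlaps
    for gname in rois:
        rois[gname] = (ids == _GLAND_ORGANS[gname])

    # structures are defined inside the body, but coarse voxelisation can
    # leave stray painted voxels beyond the envelope
    ids[~body] = 0

    # --- enforce skin as the one-voxel body surface ---
    interior = body.copy()
    for ax in range(3):
        interior &= np.roll(body, 1, axis=ax) & np.roll(body, -1, axis=ax)
    edge = np.zeros_like(body)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    edge[:, :, 0] = edge[:, :, -1] = True
    surface = body & (~interior | edge)
    ids[surface] = 19
    ids[trachea & ~surface] = _TRACHEA_ORGAN

    organ_map = {
        0: 0, 1: 1, 5: 5, 10: 10, 11: 11, 12: 12, 13: 13, 14: 14, 15: 15,
        16: 16, 17: 17, 18: 18, 19: 19, 21: 21, 22: 22, 23: 23, 24: 24,
        25: 25, 26: 26, 27: 27, 28: 28, 29: 29, 31: 31, 33: 33, 34: 34,
        35: 35, 36: 36, 37: 37, 38: 38,
        _TRACHEA_ORGAN: 5, _EYE_ORGAN: 1,
    }
    organ_map.update({org: 20 for org in _GLAND_ORGANS.values()})
    phantom = VoxelPhantom(ids, voxel_size, (0.0, 0.0, 0.0), organ_map,
                           "synthetic_head")
    rois["body"] = body
    return phantom, rois


# ----------------------------------------------------------------------------
# packed transport geometry
# ----------------------------------------------------------------------------

@dataclass
class Geometry:
    """Packed first-fit box geometry (+ optional voxel grid) for the kernel."""

    materials: list[Material]        # kernel order; slot 0 is vacuum
    boxes_lo: np.ndarray             # (nb, 3)
    boxes_hi: np.ndarray
    box_mat: np.ndarray              # (nb,) kernel index, -2 = voxel grid
    grid_mat: np.ndarray             # flat int16 (dummy size 1 when unused)
    gn: np.ndarray                   # (3,) int64
    gorigin: np.ndarray              # (3,) float64
    gvoxel: np.ndarray               # (3,) float64
    score_mode: int                  # 0 = chamber array, 1 = grid region map
    chambers: ChamberArray | None
    region_map: np.ndarray           # flat int32 (grid mode)
    n_regions: int
    region_mass_g: np.ndarray        # (n_regions,)
    region_volume_cm3: np.ndarray
    source_x: float
    description: str = ""
    grid_shape: tuple[int, int, int] | None = None

    def material_at(self, point) -> Material:
        """First-fit material lookup (python mirror of the kernel rule)."""
        x, y, z = point
        for b in range(self.boxes_lo.shape[0]):
            if all(self.boxes_lo[b, a] <= p < self.boxes_hi[b, a]
                   for a, p in enumerate((x, y, z))):
                mi = self.box_mat[b]
                if mi == -2:
                    idx = [min(max(int((p - self.gorigin[a]) / self.gvoxel[a]), 0),
                               self.gn[a] - 1) for a, p in enumerate((x, y, z))]
                    flat = (idx[0] * self.gn[1] + idx[1]) * self.gn[2] + idx[2]
                    return self.materials[self.grid_mat[flat]]
                return self.materials[mi]
        raise ValueError(f"point {point} is outside the world")


def _kernel_materials(mat_table: MaterialTable, used_ids: list[int]) -> tuple[list[Material], dict[int, int]]:
    """Materials in kernel order (vacuum first) and id -> index map."""
    mats = [mat_table[0] if 0 in mat_table else Material.vacuum()]
    index = {0: 0}
    for mid in used_ids:
        if mid == 0 or mid in index:
            continue
        index[mid] = len(mats)
        mats.append(mat_table[mid])
    return mats, index


_DUMMY_GRID = dict(
    grid_mat=np.zeros(1, dtype=np.int16),
    gn=np.array([1, 1, 1], dtype=np.int64),
    gorigin=np.zeros(3), gvoxel=np.ones(3),
)

_WORLD_LO = (-160.0, -240.0, -235.0)
_WORLD_HI = (330.0, 240.0, 235.0)


def _room_boxes(room: RoomShell, index: dict[int, int]):
    """Concrete slabs + air beam-window channel, innermost-first order."""
    con = index[4]
    air = index[5]
    hw, hh, L = room.half_width, room.half_height, room.length
    w, t = room.wall, room.exit_wall
    wy, wz = room.window[0] / 2, room.window[1] / 2
    x0 = -60.0            # interior front (beam-entry) wall face
    x1 = x0 + L           # interior back wall face
    boxes = [
        # beam window channel through the entry wall
        ((x0 - t, -wy, -wz), (x0, wy, wz), air),
        ((x0 - t, -hw - w, -hh - w), (x0, hw + w, hh + w), con),      # entry wall
        ((x1, -hw - w, -hh - w), (x1 + w, hw + w, hh + w), con),      # back wall
        ((x0 - t, hw, -hh - w), (x1 + w, hw + w, hh + w), con),       # left wall
        ((x0 - t, -hw - w, -hh - w), (x1 + w, -hw, hh + w), con),     # right wall
        ((x0 - t, -hw, hh), (x1 + w, hw, hh + w), con),               # ceiling
        ((x0 - t, -hw, -hh - w), (x1 + w, hw, -hh), con),             # floor
    ]
    return boxes


def _finish_geometry(boxes, mats, score_kwargs, source_x, desc, **grid_kwargs):
    nb = len(boxes)
    lo = np.zeros((nb, 3))
    hi = np.zeros((nb, 3))
    bm = np.zeros(nb, dtype=np.int32)
    for i, (blo, bhi, m) in enumerate(boxes):
        lo[i] = blo
        hi[i] = bhi
        bm[i] = m
    kwargs = dict(_DUMMY_GRID)
    kwargs.update(grid_kwargs)
    return Geometry(materials=mats, boxes_lo=lo, boxes_hi=hi, box_mat=bm,
                    source_x=source_x, description=desc, **kwargs, **score_kwargs)


def build_solid_water_geometry(
    mat_table: MaterialTable | None = None,
    room: RoomShell | None = None,
    phantom: SolidBoxPhantom | None = None,
) -> Geometry:
    """Solid-box water phantom with chamber scoring, optional room shell."""
    mat_table = mat_table or load_materials()
    phantom = phantom or SolidBoxPhantom()
    mats, index = _kernel_materials(mat_table, [1, 2, 3, 4, 5])
    ox, oy, oz = phantom.outer
    wi = phantom.water_interior
    wy, wz = phantom.window[0] / 2, phantom.window[1] / 2
    al = phantom.al_plate * phantom.n_al_plates
    boxes = [
        # window aperture: air gap in the wall, sealed by the Al plates
        ((-phantom.wall, -wy, -wz), (-al, wy, wz), index[5]),
        ((-al, -wy, -wz), (0.0, wy, wz), index[3]),
        ((0.0, -wi[1] / 2, -wi[2] / 2), (wi[0], wi[1] / 2, wi[2] / 2), index[1]),
        ((-phantom.wall, -oy / 2, -oz / 2), (ox - phantom.wall, oy / 2, oz / 2),
         index[2]),
    ]
    if room is not None:
        boxes.extend(_room_boxes(room, index))
    boxes.append((_WORLD_LO, _WORLD_HI, index[5]))  # world air
    ch = phantom.chambers
    n = ch.count
    mass = ch.volume * mat_table[1].density
    score = dict(score_mode=0, chambers=ch,
                 region_map=np.zeros(1, dtype=np.int32), n_regions=n,
                 region_mass_g=np.full(n, mass),
                 region_volume_cm3=np.full(n, ch.volume))
    desc = "solid water box" + (" + room" if room else "")
    return _finish_geometry(boxes, mats, score, SOURCE_X, desc)


VOXEL_WATER_EXTENT = (64.0, 64.0, 52.0)
VOXEL_WATER_VOXEL = (0.2, 0.2, 0.5)
_VOX_ORIGIN = (-2.6, -32.0, -26.0)


def build_voxel_water_geometry(
    mat_table: MaterialTable | None = None,
    room: RoomShell | None = None,
    phantom: SolidBoxPhantom | None = None,
) -> Geometry:
    """Voxelised water phantom (64 x 64 x 52 cm^3, 0.2 x 0.2 x 0.5 cm^3 voxels).

    Voxel materials are the solid-box materials sampled at voxel centres, so
    walls and window are rendered at voxel resolution.  Scoring regions are
    the 40 eight-voxel blocks (4 lateral x 2 vertical) centred on the beam
    axis at the chamber depths, with a collection volume of 0.16 cm^3 each.
    """
    mat_table = mat_table or load_materials()
    phantom = phantom or SolidBoxPhantom()
    mats, index = _kernel_materials(mat_table, [1, 2, 3, 4, 5])
    nxv = [int(round(e / v)) for e, v in zip(VOXEL_WATER_EXTENT, VOXEL_WATER_VOXEL)]
    nx, ny, nz = nxv
    vx, vy, vz = VOXEL_WATER_VOXEL
    gox, goy, goz = _VOX_ORIGIN
    cx = gox + (np.arange(nx) + 0.5)[:, None, None] * vx
    cy = goy + (np.arange(ny) + 0.5)[None, :, None] * vy
    cz = goz + (np.arange(nz) + 0.5)[None, None, :] * vz
    wi = phantom.water_interior
    wy, wz = phantom.window[0] / 2, phantom.window[1] / 2
    al = phantom.al_plate * phantom.n_al_plates
    grid = np.full((nx, ny, nz), index[5], dtype=np.int16)
    in_perspex = ((cx >= -phantom.wall) & (cx < phantom.outer[0] - phantom.wall)
                  & (np.abs(cy) < phantom.outer[1] / 2)
                  & (np.abs(cz) < phantom.outer[2] / 2))
    grid[in_perspex] = index[2]
    in_water = ((cx >= 0) & (cx < wi[0])
                & (np.abs(cy) < wi[1] / 2) & (np.abs(cz) < wi[2] / 2))
    grid[in_water] = index[1]
    in_ap = (np.abs(cy) < wy) & (np.abs(cz) < wz)
    grid[(cx >= -phantom.wall) & (cx < -al) & in_ap] = index[5]
    grid[(cx >= -al) & (cx < 0) & in_ap] = index[3]

    # 8-voxel depth-dose collection blocks at the chamber depths
    ch = phantom.chambers
    region_map = np.full((nx, ny, nz), -1, dtype=np.int32)
    iy0 = ny // 2 - 2
    iz0 = nz // 2 - 1
    for j, d in enumerate(ch.depths):
        ix = int((d - gox) / vx)
        region_map[ix, iy0:iy0 + 4, iz0:iz0 + 2] = j
    n = ch.count
    block_vol = 8 * vx * vy * vz
    score = dict(score_mode=1, chambers=ch,
                 region_map=np.ascontiguousarray(region_map.ravel()),
                 n_regions=n,
                 region_mass_g=np.full(n, block_vol * mat_table[1].density),
                 region_volume_cm3=np.full(n, block_vol))
    lo = (gox, goy, goz)
    hi = (gox + nx * vx, goy + ny * vy, goz + nz * vz)
    boxes = [(lo, hi, -2)]
    if room is not None:
        boxes.extend(_room_boxes(room, index))
    boxes.append((_WORLD_LO, _WORLD_HI, index[5]))
    desc = "voxelised water box" + (" + room" if room else "")
    return _finish_geometry(
        boxes, mats, score, SOURCE_X, desc,
        grid_mat=np.ascontiguousarray(grid.ravel()),
        gn=np.array([nx, ny, nz], dtype=np.int64),
        gorigin=np.array([gox, goy, goz]),
        gvoxel=np.array(VOXEL_WATER_VOXEL),
        grid_shape=(nx, ny, nz),
    )


def build_head_geometry(
    phantom: VoxelPhantom,
    mat_table: MaterialTable | None = None,
    margin: float = 10.0,
) -> Geometry:
    """Voxel-phantom geometry with per-voxel dose scoring.

    The phantom's x = 0 face (patient right side) is the beam entry face;
    the grid is centred on the beam axis in y and z.  Every voxel is its own
    scoring region (region index = flat voxel index).
    """
    mat_table = mat_table or load_materials()
    mat_grid = phantom.material_ids()
    used = sorted(int(u) for u in np.unique(mat_grid))
    mats, index = _kernel_materials(mat_table, used)
    lut = np.zeros(max(used) + 1, dtype=np.int16)
    for mid in used:
        lut[mid] = index[mid]
    grid = lut[mat_grid]
    nx, ny, nz = phantom.shape
    vx, vy, vz = phantom.voxel_size
    gox, goy, goz = 0.0, -ny * vy / 2.0, -nz * vz / 2.0
    nvox = phantom.n_voxels
    dens = np.zeros(len(mats))
    for mid, ki in index.items():
        dens[ki] = mat_table[mid].density
    voxvol = phantom.voxel_volume
    mass = dens[grid.ravel()] * voxvol
    if 5 not in index:  # air needed for the world
        index[5] = len(mats)
        mats.append(mat_table[5])
    boxes = [
        ((gox, goy, goz), (gox + nx * vx, goy + ny * vy, goz + nz * vz), -2),
        ((gox - margin, goy - margin, goz - margin),
         (gox + nx * vx + margin, goy + ny * vy + margin, goz + nz * vz + margin),
         index[5]),
    ]
    score = dict(score_mode=1, chambers=None,
                 region_map=np.arange(nvox, dtype=np.int32),
                 n_regions=nvox,
                 region_mass_g=mass,
                 region_volume_cm3=np.full(nvox, voxvol))
    return _finish_geometry(
        boxes, mats, score, gox - margin / 2, f"voxel phantom {phantom.name}",
        grid_mat=np.ascontiguousarray(grid.ravel()),
        gn=np.array([nx, ny, nz], dtype=np.int64),
        gorigin=np.array([gox, goy, goz]),
        gvoxel=np.array([vx, vy, vz]),
        grid_shape=(nx, ny, nz),
    )
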