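"""Voxel-lattice data model and 3D bone histomorphometry.

The simulation domain is a regular isotropic voxel lattice.  Each voxel is
either marrow, unmineralized osteoid, or mineralized bone, and carries a
mineral-density scalar expressed as a fraction of a configurable maximum
(default 1200 mg HA/cm^3, roughly the density of fully mineralized human
trabecular tissue).  All morphometric indices used by the virtual trial
(BV/TV, Tb.Th, MS/BS, ES/BS, Oc.N/BS, tissue mineral content) are computed
directly on this lattice in 3D.

Coordinates are 0-based (z, y, x) array indices; the x index varies fastest
in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

# Tissue labels
MARROW = 0
OSTEOID = 1
BONE = 2

#: Default maximum mineral density [mg HA/cm^3]
DEFAULT_MAX_MINERAL_DENSITY = 1200.0


@dataclass
class VoxelGrid:
    """3D lattice of tissue state.

    Parameters
    ----------
    tissue : ndarray of uint8, shape (nz, ny, nx)
        Per-voxel label: ``MARROW``, ``OSTEOID`` or ``BONE``.
    voxel_size : float
        Isotropic voxel edge length [mm].
    mineral : ndarray of float64, same shape
        Mineral density as a fraction of ``max_mineral_density``; 0 in marrow.
    max_mineral_density : float
        Density of fully mineralized tissue [mg HA/cm^3].
    """

    tissue: np.ndarray
    voxel_size: float
    mineral: np.ndarray = None  # type: ignore[assignment]
    max_mineral_density: float = DEFAULT_MAX_MINERAL_DENSITY

    def __post_init__(self) -> None:
        self.tissue = np.ascontiguousarray(self.tissue, dtype=np.uint8)
        if self.tissue.ndim != 3 or self.tissue.size == 0:
            raise ValueError("degenerate domain: tissue must be a non-empty 3D array")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if self.mineral is None:
            self.mineral = np.where(self.tissue != MARROW, 1.0, 0.0)
        self.mineral = np.ascontiguousarray(self.mineral, dtype=np.float64)
        if self.mineral.shape != self.tissue.shape:
            raise ValueError("mineral and tissue shapes differ")
        self.validate()

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tissue.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel [mm^3]."""
        return self.voxel_size**3

    @property
    def bone_mask(self) -> np.ndarray:
        """Boolean mask of mineralized/osteoid tissue (the 'bone' phase)."""
        return self.tissue != MARROW

    @property
    def marrow_mask(self) -> np.ndarray:
        return self.tissue == MARROW

    @property
    def mineral_density(self) -> np.ndarray:
        """Per-voxel mineral density [mg HA/cm^3]."""
        return self.mineral * self.max_mineral_density

    def validate(self) -> None:
        """Check the tissue/mineral invariants, raising ``ValueError`` on breach."""
        marrow = self.tissue == MARROW
        if np.any(self.mineral[marrow] != 0.0):
            raise ValueError("mineral density must be zero in marrow")
        if np.any(self.mineral < 0.0) or np.any(self.mineral > 1.0 + 1e-12):
            raise ValueError("mineral fraction outside [0, 1]")

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(
            tissue=self.tissue.copy(),
            voxel_size=self.voxel_size,
            mineral=self.mineral.copy(),
            max_mineral_density=self.max_mineral_density,
        )

    def tissue_mineral_content(self, resorbed_frac: np.ndarray | None = None) -> float:
        """Tissue mineral content [mg HA]: sum of mineral density times voxel volume.

        ``resorbed_frac`` optionally discounts partially resorbed voxels.
        """
        m = self.mineral
        if resorbed_frac is not None:
            m = m * (1.0 - resorbed_frac)
        # mg HA/cm^3 * mm^3 -> mg HA requires the 1e-3 cm^3/mm^3 factor
        return float(m.sum() * self.max_mineral_density * self.voxel_volume * 1e-3)


@dataclass
class SurfaceSet:
    """Bone surface voxels with face-count-weighted areas.

    ``voxels`` are lattice coordinates (N, 3) of BONE/OSTEOID voxels with at
    least one face-adjacent marrow voxel; ``exposed_faces`` counts the marrow
    faces of each, so ``area_per_voxel = exposed_faces * voxel_size**2``.
    """

    voxels: np.ndarray
    exposed_faces: np.ndarray
    voxel_size: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def area_per_voxel(self) -> np.ndarray:
        """Surface area attributed to each surface voxel [mm^2]."""
        return self.exposed_faces * self.voxel_size**2

    @property
    def total_area(self) -> float:
        """Total bone surface area BS [mm^2]."""
        return float(self.exposed_faces.sum() * self.voxel_size**2)


@dataclass
class MorphometrySample:
    """Static and dynamic morphometry at one sampling time."""

    time: float  # days
    bv_tv: float
    tb_th: float  # mm
    ms_bs: float
    es_bs: float
    ocn_bs: float  # osteoclasts per mm^2 bone surface
    tmc_change: float  # percent change from baseline


# ----------------------------------------------------------------------
# Static morphometry
# ----------------------------------------------------------------------

def compute_bv_tv(grid: VoxelGrid) -> float:
    """Bone volume fraction: (BONE + OSTEOID voxels) / total voxels."""
    if grid.tissue.size == 0:
        raise ValueError("degenerate domain")
    return float(np.count_nonzero(grid.tissue != MARROW)) / grid.tissue.size


def extract_surface(grid: VoxelGrid) -> SurfaceSet:
    """Bone surface by 6-connectivity face adjacency to marrow.

    Voxels on the domain boundary do not count outside-the-domain faces as
    exposed; the domain is treated as embedded in bone-like padding, matching
    the biopsy-core convention that cut faces are not remodeling surface.
    """
    bone = grid.bone_mask
    exposed = np.zeros(grid.shape, dtype=np.int8)
    for axis in range(3):
        for shift in (1, -1):
            neighbor_is_marrow = np.zeros_like(bone)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
            else:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            neighbor_is_marrow[tuple(dst)] = ~bone[tuple(src)]
            exposed += (bone & neighbor_is_marrow).astype(np.int8)
    coords = np.argwhere(exposed > 0)
    # deterministic lexicographic order from argwhere (C order)
    return SurfaceSet(
        voxels=coords,
        exposed_faces=exposed[tuple(coords.T)].astype(np.int64)
        if len(coords)
        else np.zeros(0, dtype=np.int64),
        voxel_size=grid.voxel_size,
    )


def surface_mask(grid: VoxelGrid) -> np.ndarray:
    """Boolean mask of surface voxels (bone with >=1 face-adjacent marrow)."""
    bone = grid.bone_mask
    eroded = ndimage.binary_erosion(bone, structure=ndimage.generate_binary_structure(3, 1))
    return bone & ~eroded


@njit(cache=True)
def _paint_thickness(coords, radii, thick, nz, ny, nx):  # pragma: no cover - numba
    for i in range(len(coords)):
        z0, y0, x0 = coords[i, 0], coords[i, 1], coords[i, 2]
        r = radii[i]
        d = 2.0 * r
        ir = int(np.floor(r))
        r2 = r * r
        for dz in range(-ir, ir + 1):
            z = z0 + dz
            if z < 0 or z >= nz:
                continue
            for dy in range(-ir, ir + 1):
                y = y0 + dy
                if y < 0 or y >= ny:
                    continue
                for dx in range(-ir, ir + 1):
                    x = x0 + dx
                    if x < 0 or x >= nx:
                        continue
                    if dz * dz + dy * dy + dx * dx <= r2:
                        if thick[z, y, x] < d:
                            thick[z, y, x] = d
    return thick


def compute_tb_th(grid: VoxelGrid) -> float:
    """Mean trabecular thickness [mm] by largest-inscribed-sphere fitting.

    For every bone voxel the local thickness is the diameter of the largest
    sphere that contains the voxel and fits inside the bone phase
    (distance-transform sphere-fitting); Tb.Th is the mean over bone voxels.
    The distance map is padded with bone at the domain boundary so cut faces
    do not bias the thickness downward.
    """
    bone = grid.bone_mask
    if not bone.any():
        raise ValueError("no bone voxels")
    padded = np.pad(bone, 1, mode="edge")
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]
    # distance to nearest marrow voxel *center* overestimates the inscribed
    # radius by half a voxel
    radii = edt[bone] - 0.5
    coords = np.argwhere(bone)
    thick = np.zeros(grid.shape, dtype=np.float64)
    _paint_thickness(coords, radii, thick, *grid.shape)
    return float(thick[bone].mean() * grid.voxel_size)


# ----------------------------------------------------------------------
# Dynamic morphometry
# ----------------------------------------------------------------------

#: Event kinds for the remodeling event log
EV_FORM = "FORM"
EV_ERODE = "ERODE"
EV_MINERALIZE = "MINERALIZE"
EV_APOPTOSIS = "APOPTOSIS"
EV_ACTIVATE = "ACTIVATE"

#: Default trailing window for dynamic indices [days] (one month, 365/12)
DEFAULT_WINDOW = 30.4


@dataclass
class EventLog:
    """Time-stamped formation/resorption event log.

    Stored as parallel lists for cheap appends during simulation; exported
    via :meth:`to_frame`.
    """

    times: list = field(default_factory=list)
    voxels: list = field(default_factory=list)
    kinds: list = field(default_factory=list)

    def add(self, time: float, voxel: tuple[int, int, int], kind: str) -> None:
        self.times.append(time)
        self.voxels.append(voxel)
        self.kinds.append(kind)

    def extend(self, time: float, voxels: np.ndarray, kind: str) -> None:
        for v in voxels:
            self.add(time, (int(v[0]), int(v[1]), int(v[2])), kind)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self):
        import pandas as pd

        vox = np.asarray(self.voxels, dtype=np.int64).reshape(len(self.times), 3)
        return pd.DataFrame(
            {
                "time_days": self.times,
                "z": vox[:, 0],
                "y": vox[:, 1],
                "x": vox[:, 2],
                "event": self.kinds,
            }
        )


def dynamic_morphometry(
    grid: VoxelGrid,
    events: EventLog,
    window: float,
    *,
    time: float = 0.0,
    n_osteoclasts: int = 0,
    tmc_change: float = 0.0,
) -> MorphometrySample:
    """Monthly static + dynamic morphometry sample.

    MS/BS: fraction of current surface voxels with >=1 formation event in the
    trailing window.  ES/BS: fraction with >=1 erosion event in the window.
    Oc.N/BS: osteoclast count divided by total surface area [1/mm^2] — the 3D
    analogue of the clinical osteoclast-number index.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    surf = extract_surface(grid)
    n_surf = surf.n_voxels
    ms_bs = es_bs = 0.0
    if n_surf and len(events):
        t = np.asarray(events.times)
        recent = (t > time - window) & (t <= time)
        if recent.any():
            vox = np.asarray(events.voxels, dtype=np.int64)[recent]
            kinds = np.asarray(events.kinds, dtype=object)[recent]
            surf_lin = set(
                np.ravel_multi_index(tuple(surf.voxels.T), grid.shape).tolist()
            )
            lin = np.ravel_multi_index(tuple(vox.T), grid.shape)
            formed = {int(v) for v, k in zip(lin, kinds) if k == EV_FORM}
            eroded = {int(v) for v, k in zip(lin, kinds) if k == EV_ERODE}
            ms_bs = len(formed & surf_lin) / n_surf
            es_bs = len(eroded & surf_lin) / n_surf
    area = surf.total_area
    ocn_bs = n_osteoclasts / area if area > 0 else 0.0
    return MorphometrySample(
        time=time,
        bv_tv=compute_bv_tv(grid),
        tb_th=compute_tb_th(grid) if grid.bone_mask.any() else 0.0,
        ms_bs=ms_bs,
        es_bs=es_bs,
        ocn_bs=ocn_bs,
        tmc_change=tmc_change,
    )
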