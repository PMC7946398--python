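"""Digital cardiac rod and epoxy-resin phantoms with ground-truth masks.

The cardiac rod is a 9-cm soft-tissue cylinder holding a centered "heart"
cylinder of slightly higher attenuation (for CNR estimation), nine
cylindrical CaHA inserts spanning three densities (100/250/400 mg/cm^3) and
three diameters (1.2/3.0/5.0 mm) at 7.0 mm height, and a thin tilted air gap
whose line-spread function drives MTF estimation.  The epoxy rod is a
homogeneous cylinder used only for noise-power-spectrum estimation.

All attenuation is monoenergetic at a single effective energy; images are
expressed in Hounsfield units through the standard affine map
HU = 1000 (mu - mu_water) / mu_water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

# Label conventions.  Inserts get IDs 1..9 so that per-insert tables can be
# indexed directly; structural tissues use IDs above the insert range.
LABEL_AIR = 0
LABEL_SOFT_TISSUE = 10
LABEL_HEART = 11
LABEL_AIR_GAP = 12

#: attenuation of water (1/mm) at the 60 keV effective energy of a 120 kVp beam
MU_WATER_60KEV = 0.0206


@dataclass(frozen=True)
class MaterialModel:
    """Monoenergetic attenuation model anchoring the HU conversion.

    ``caha_hu_per_density`` is the calibration slope mapping CaHA density
    (mg/cm^3) to HU; the default 1.6 HU/(mg/cm^3) places the 100 mg/cm^3
    inserts partially below the 130-HU scoring threshold and the 400 mg/cm^3
    inserts far above it, which is the regime the scoring study probes.
    """

    mu_water: float = MU_WATER_60KEV
    mu_air: float = 0.0
    mu_soft_tissue: float = MU_WATER_60KEV * 1.035
    caha_hu_per_density: float = 1.6

    def __post_init__(self) -> None:
        if not (self.mu_water > self.mu_air >= 0.0):
            raise ValueError("require mu_water > mu_air >= 0")
        if self.caha_hu_per_density <= 0:
            raise ValueError("caha_hu_per_density must be positive")

    def hu_from_mu(self, mu):
        return hu_from_mu(mu, self)

    def mu_from_hu(self, hu):
        return self.mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0)

    def mu_caha(self, density_mg_cm3: float) -> float:
        """Attenuation of a CaHA insert of the given density."""
        return float(self.mu_from_hu(self.caha_hu_per_density * density_mg_cm3))


def hu_from_mu(mu, materials: MaterialModel):
    """Map linear attenuation (1/mm) to Hounsfield units."""
    if materials.mu_water == 0:
        raise ValueError("mu_water must be nonzero for the HU mapping")
    return 1000.0 * (np.asarray(mu, dtype=float) - materials.mu_water) / materials.mu_water


@dataclass(frozen=True)
class InsertSpec:
    """One cylindrical CaHA insert (axis along z)."""

    density: float  # mg/cm^3
    diameter: float  # mm
    height: float  # mm
    center: tuple[float, float, float]  # (x, y, z) mm in the phantom frame

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class GapSpec:
    """Thin planar air gap, seen in-slice as a tilted line segment."""

    center: tuple[float, float] = (0.0, -21.0)  # mm
    angle_deg: float = 3.0  # tilt relative to the x axis
    length: float = 20.0  # mm along the line
    width: float | None = None  # mm across; None -> one voxel


@dataclass(frozen=True)
class GridSpec:
    """Reconstruction / phantom voxel grid, centered on the rotation axis."""

    nx: int = 128
    ny: int = 128
    nz: int = 6
    dx: float = 0.75  # mm
    dy: float = 0.75
    dz: float = 1.5

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nz, self.ny, self.nx)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    def axis_coords(self):
        """Voxel-center coordinates (x, y, z) in mm, origin at grid center."""
        x = (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.dx
        y = (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.dy
        z = (np.arange(self.nz) - (self.nz - 1) / 2.0) * self.dz
        return x, y, z


#: voxel grid of the original acquisition (0.32 mm in-plane, 1.5 mm slices)
FULL_GRID = GridSpec(nx=384, ny=384, nz=6, dx=0.32, dy=0.32, dz=1.5)


@dataclass
class PhantomVolume:
    """Voxelized attenuation map plus label masks.

    Arrays are stored slice-major, shape ``(nz, ny, nx)``.
    """

    mu: np.ndarray
    labels: np.ndarray
    grid: GridSpec
    materials: MaterialModel
    inserts: list[InsertSpec] = field(default_factory=list)
    gap: GapSpec | None = None
    rod_radius: float = 45.0  # mm

    def __post_init__(self) -> None:
        if self.mu.shape != self.labels.shape:
            raise ValueError("mu and label fields must share a shape")
        if np.any(self.mu < 0):
            raise ValueError("attenuation must be nonnegative")

    @property
    def voxel_volume(self) -> float:
        g = self.grid
        return g.dx * g.dy * g.dz

    def insert_mask(self, insert_id: int) -> np.ndarray:
        return self.labels == insert_id

    def rod_mask(self) -> np.ndarray:
        x, y, _ = self.grid.axis_coords()
        xx, yy = np.meshgrid(x, y)
        in_rod = xx**2 + yy**2 <= self.rod_radius**2
        return np.broadcast_to(in_rod, self.mu.shape).copy()

    def interior_mask(self, margin_voxels: int = 4) -> np.ndarray:
        """Rod interior excluding a margin from the rod edge (for NPS ROIs)."""
        x, y, _ = self.grid.axis_coords()
        xx, yy = np.meshgrid(x, y)
        margin = margin_voxels * max(self.grid.dx, self.grid.dy)
        inner = xx**2 + yy**2 <= (self.rod_radius - margin) ** 2
        return np.broadcast_to(inner, self.mu.shape).copy()

    def background_mask(self, erode_mm: float = 2.0) -> np.ndarray:
        """Homogeneous soft-tissue region away from heart, inserts and gap.

        Used for noise measurements; keeps a clearance of ``erode_mm`` from
        every non-background structure.
        """
        from scipy import ndimage

        bg = self.labels == LABEL_SOFT_TISSUE
        other = (self.labels != LABEL_SOFT_TISSUE)
        it = max(1, int(round(erode_mm / min(self.grid.dx, self.grid.dy))))
        grown = np.empty_like(other)
        for k in range(other.shape[0]):
            grown[k] = ndimage.binary_dilation(other[k], iterations=it)
        return bg & ~grown

    def hu(self) -> np.ndarray:
        return hu_from_mu(self.mu, self.materials)


def nominal_insert_volume(diameter: float, height: float) -> float:
    """Analytic cylinder volume pi (d/2)^2 h, rounded to 0.1 mm^3."""
    if diameter <= 0 or height <= 0:
        raise ValueError("diameter and height must be positive")
    return round(math.pi * (diameter / 2.0) ** 2 * height, 1)


def study_inserts(
    densities=(400.0, 250.0, 100.0),
    diameters=(5.0, 3.0, 1.2),
    height: float = 7.0,
    ring_radius: float = 30.0,
) -> list[InsertSpec]:
    """The nine-insert study configuration on a ring inside the rod.

    Inserts are ordered densest/largest first so that insert ID 1 is the
    highest-score lesion, mirroring how score tables are usually presented.
    """
    specs = []
    k = 0
    for density in densities:
        for diameter in diameters:
            angle = math.radians(90.0 + 40.0 * k)
            center = (ring_radius * math.cos(angle), ring_radius * math.sin(angle), 0.0)
            specs.append(InsertSpec(density, diameter, height, center))
            k += 1
    return specs


def _supersample_offsets(grid: GridSpec, n: int = 3):
    """Subvoxel offsets of an n x n x n supersampling stencil (mm)."""
    off = (np.arange(n) - (n - 1) / 2.0) / n
    ox, oy, oz = np.meshgrid(off * grid.dx, off * grid.dy, off * grid.dz, indexing="ij")
    return np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)


def _cylinder_fraction(grid: GridSpec, cx, cy, cz, radius, half_height, supersample=3):
    """Per-voxel volume fraction inside a z-aligned cylinder (supersampled)."""
    x, y, z = grid.axis_coords()
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    frac = np.zeros(grid.shape, dtype=np.float64)
    for ox, oy, oz in _supersample_offsets(grid, supersample):
        inside = ((xx + ox - cx) ** 2 + (yy + oy - cy) ** 2 <= radius**2) & (
            np.abs(zz + oz - cz) <= half_height
        )
        frac += inside
    return frac / supersample**3


def _gap_fraction(grid: GridSpec, gap: GapSpec, supersample=3):
    """Per-voxel fraction inside the tilted planar air gap."""
    width = gap.width if gap.width is not None else grid.dx
    x, y, z = grid.axis_coords()
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    c, s = math.cos(math.radians(gap.angle_deg)), math.sin(math.radians(gap.angle_deg))
    frac = np.zeros(grid.shape, dtype=np.float64)
    for ox, oy, _ in _supersample_offsets(grid, supersample):
        u = (xx + ox - gap.center[0]) * c + (yy + oy - gap.center[1]) * s
        v = -(xx + ox - gap.center[0]) * s + (yy + oy - gap.center[1]) * c
        inside = (np.abs(u) <= gap.length / 2.0) & (np.abs(v) <= width / 2.0)
        frac += inside
    return frac / supersample**3


def build_cardiac_rod(
    inserts: list[InsertSpec],
    grid: GridSpec = GridSpec(),
    materials: MaterialModel = MaterialModel(),
    rod_radius: float = 45.0,
    heart_radius: float = 15.0,
    heart_hu_offset: float = 30.0,
    gap: GapSpec | None = GapSpec(),
    supersample: int = 3,
) -> PhantomVolume:
    """Rasterize the cardiac rod phantom with 3x3x3 boundary supersampling.

    Partial-volume voxels at cylinder boundaries receive the volume-weighted
    mixture of the two attenuations; labels follow the majority material.
    """
    # validate insert placement
    for i, a in enumerate(inserts):
        r_out = math.hypot(a.center[0], a.center[1]) + a.radius
        if r_out > rod_radius:
            raise ValueError(f"insert {i + 1} extends outside the rod")
        for b in inserts[i + 1 :]:
            d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d < a.radius + b.radius:
                raise ValueError("overlapping inserts")

    x, y, _ = grid.axis_coords()
    if rod_radius > max(abs(x[0]), x[-1]) + grid.dx / 2 or rod_radius > max(abs(y[0]), y[-1]) + grid.dy / 2:
        raise ValueError("grid does not cover the rod")

    labels = np.full(grid.shape, LABEL_AIR, dtype=np.int16)

    half_z = (grid.nz * grid.dz) / 2.0 + grid.dz  # rod spans the whole grid in z
    rod_frac = _cylinder_fraction(grid, 0.0, 0.0, 0.0, rod_radius, half_z, supersample)
    labels[rod_frac >= 0.5] = LABEL_SOFT_TISSUE

    mu_heart = float(materials.mu_from_hu(hu_from_mu(materials.mu_soft_tissue, materials) + heart_hu_offset))
    heart_frac = _cylinder_fraction(grid, 0.0, 0.0, 0.0, heart_radius, half_z, supersample)
    labels[heart_frac >= 0.5] = LABEL_HEART

    # Attenuation: blend each structure against its surrounding material.
    # Inserts and heart sit fully inside soft tissue, the gap replaces the
    # local mixture by air, so the blends never double-count.
    mu = np.full(grid.shape, materials.mu_air, dtype=np.float64)
    mu += rod_frac * (materials.mu_soft_tissue - materials.mu_air)
    mu += heart_frac * (mu_heart - materials.mu_soft_tissue)
    if gap is not None:
        gap_frac = _gap_fraction(grid, gap, supersample)
        mu += gap_frac * (materials.mu_air - mu)
        labels[gap_frac >= 0.5] = LABEL_AIR_GAP
    for k, ins in enumerate(inserts, start=1):
        mu_ins = materials.mu_caha(ins.density)
        if mu_ins <= materials.mu_soft_tissue:
            raise ValueError("insert attenuation must exceed soft tissue")
        frac = _cylinder_fraction(
            grid, ins.center[0], ins.center[1], ins.center[2], ins.radius, ins.height / 2.0, supersample
        )
        mu += frac * (mu_ins - materials.mu_soft_tissue)
        labels[frac >= 0.5] = k
        # sub-voxel inserts may majority-cover no voxel on coarse grids; the
        # ground-truth mask still needs the insert to exist, so label the
        # voxels traversed by the insert axis
        x, y, z = grid.axis_coords()
        ix = int(np.argmin(np.abs(x - ins.center[0])))
        iy = int(np.argmin(np.abs(y - ins.center[1])))
        in_z = np.abs(z - ins.center[2]) <= ins.height / 2.0
        labels[in_z, iy, ix] = k

    return PhantomVolume(
        mu=mu, labels=labels, grid=grid, materials=materials, inserts=list(inserts), gap=gap, rod_radius=rod_radius
    )


def build_epoxy_rod(
    grid: GridSpec = GridSpec(),
    materials: MaterialModel = MaterialModel(),
    rod_radius: float = 45.0,
    epoxy_hu: float = 30.0,
    supersample: int = 3,
) -> PhantomVolume:
    """Homogeneous cylinder used for noise-texture (NPS) estimation."""
    mu_epoxy = float(materials.mu_from_hu(epoxy_hu))
    half_z = (grid.nz * grid.dz) / 2.0 + grid.dz
    frac = _cylinder_fraction(grid, 0.0, 0.0, 0.0, rod_radius, half_z, supersample)
    mu = materials.mu_air + frac * (mu_epoxy - materials.mu_air)
    labels = np.where(frac >= 0.5, LABEL_SOFT_TISSUE, LABEL_AIR).astype(np.int16)
    return PhantomVolume(
        mu=mu, labels=labels, grid=grid, materials=materials, inserts=[], gap=None, rod_radius=rod_radius
    )


def measured_insert_volume(phantom: PhantomVolume, insert_id: int, supersample: int = 3) -> float:
    """Voxelized volume of one insert (mm^3), partial boundary voxels included.

    Integrates the supersampled coverage fractions of the insert cylinder on
    the phantom grid, so boundary voxels contribute their covered part
    rather than all-or-nothing; this converges to pi r^2 h as the grid is
    refined.
    """
    ins = phantom.inserts[insert_id - 1]
    frac = _cylinder_fraction(
        phantom.grid, ins.center[0], ins.center[1], ins.center[2],
        ins.radius, ins.height / 2.0, supersample,
    )
    return float(frac.sum()) * phantom.voxel_volume
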