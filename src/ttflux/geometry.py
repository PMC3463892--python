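"""Synthetic t-tubule + half-sarcomere microdomain geometry.

The model compartment is one repeating unit of a rabbit ventricular
myocyte: a rectangular half-sarcomere box whose upper face is the outer
sarcolemma, pierced by a single t-tubule running into the cell depth.
The real compartment was segmented from confocal stacks; here it is
emulated from published morphometrics:

* box 2.34 x 2.58 um in the sarcolemmal plane, 5.76 um deep,
* t-tubule ~4.6 um long, diameter 0.39-0.62 um (elliptical cross
  section), constrictions every ~1.87 um reducing the cross-sectional
  area to ~57.7% of nominal,
* cytosolic volume 0.0282 pL; membrane area 15.9 um^2 split into
  7.8 um^2 (t-tubule) and 8.1 um^2 (outer sarcolemma).

A flat-capped box cannot reproduce the printed volume/outer-area pair
(flat cap: 6.04 um^2 < 8.1 um^2, volume 0.0348 pL > 0.0282 pL), so the
outer sarcolemma is carved as a smooth sinusoidal relief whose mean
depth removes the excess volume and whose slope supplies the excess
area.  Relief amplitude/wavelength and the tubule mean diameter are
calibrated against the three printed morphometrics.

Coordinates: the tubule runs along z, z = 0 is the outer face plane,
voxel-center convention.  All lengths in um, areas um^2, volumes pL
(1 um^3 = 1e-3 pL).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

UM3_TO_PL = 1e-3

# voxel occupancy labels
CYTOSOL = 0
EXTERIOR = 1  # above the outer-sarcolemma relief
LUMEN = 2     # t-tubule lumen

# boundary-face labels
FACE_OUTER = 1
FACE_TTUBULE = 2
FACE_REFLECTIVE = 3


class GeometryError(ValueError):
    """Raised when a geometry spec cannot be realized on the grid."""


@dataclass(frozen=True)
class TTubuleSpec:
    """Idealized single t-tubule: elliptical cross section, sinusoidal
    constrictions at the mean published period (population variance is a
    between-tubule statistic and is not sampled)."""

    length: float = 4.6                 # um, lumen depth below the mouth
    mean_diameter: float = 0.4918       # um, geometric mean of printed range
    diameter_range: tuple[float, float] = (0.39, 0.62)
    eccentricity: float = 1.59          # major/minor axis ratio >= 1
    constriction_period: float = 1.87   # um
    constriction_area_fraction: float = 0.577  # area at maximal constriction
    axis: int = 2                       # tubule axis (z); only 2 supported
    mouth_center: tuple[float, float] = (1.17, 1.29)  # um, on outer face

    def __post_init__(self):
        if not (0 < self.constriction_area_fraction <= 1):
            raise GeometryError("constriction_area_fraction must be in (0,1]")
        if self.eccentricity < 1:
            raise GeometryError("eccentricity is major/minor and must be >= 1")
        if self.axis != 2:
            raise GeometryError("only a z-axis tubule is supported")
        lo, hi = self.diameter_range
        if not (0 < lo <= hi):
            raise GeometryError("invalid diameter_range")

    @property
    def semi_axes(self) -> tuple[float, float]:
        """(a, b) ellipse semi-axes; 2a = d*sqrt(e), 2b = d/sqrt(e)."""
        r = self.mean_diameter / 2.0
        s = np.sqrt(self.eccentricity)
        return r * s, r / s

    def area_scale(self, z: np.ndarray | float) -> np.ndarray | float:
        """Cross-section area modulation: 1 at the mouth, dipping to the
        constriction fraction every period."""
        f = self.constriction_area_fraction
        return 1.0 - (1.0 - f) * 0.5 * (1.0 - np.cos(2 * np.pi * np.asarray(z) / self.constriction_period))


#: steepness of the relief walls (dimensionless shape constant); the
#: clipped profile saturates at the full amplitude over most of the face,
#: which decouples volume removal (amplitude) from membrane-area excess
#: (wavelength) -- an unclipped sinusoid cannot satisfy the printed
#: volume/outer-area pair within a physically shallow amplitude.
RELIEF_SHARPNESS = 4.0


@dataclass(frozen=True)
class BoxSpec:
    """Half-sarcomere box with a plateau-clipped sinusoidal relief carved
    into the outer sarcolemma.

    The relief depth below the z=0 plane is
        r(x, y) = A * min(1, (g/2) * (1 - cos(k(x-x0)) * cos(k(y-y0)))),
    with sharpness g = RELIEF_SHARPNESS, anchored (r = 0) at
    ``relief_anchor`` so the line-scan column there starts at the true
    outer face.  Amplitude A (the maximum depth) removes volume; the
    wavelength sets wall slope and hence outer membrane area.
    """

    dimensions: tuple[float, float, float] = (2.34, 2.58, 5.76)
    outer_relief_amplitude: float = 1.10   # um (A); 0 -> flat cap
    outer_relief_wavelength: float = 3.2   # um (2*pi/k)
    relief_anchor: tuple[float, float] | None = None  # default: set by builder

    def __post_init__(self):
        if min(self.dimensions) <= 0:
            raise GeometryError("box dimensions must be positive")
        if self.outer_relief_amplitude < 0:
            raise GeometryError("relief amplitude must be >= 0")
        # the relief must stay a shallow feature of the compartment
        if self.outer_relief_amplitude >= 0.2 * self.dimensions[2]:
            raise GeometryError("relief amplitude must stay below 20% of depth")

    def relief(self, x: np.ndarray, y: np.ndarray,
               anchor: tuple[float, float]) -> np.ndarray:
        a = self.outer_relief_amplitude
        if a == 0:
            return np.zeros(np.broadcast(x, y).shape)
        k = 2 * np.pi / self.outer_relief_wavelength
        x0, y0 = anchor
        base = 0.5 * RELIEF_SHARPNESS * (
            1.0 - np.cos(k * (x - x0)) * np.cos(k * (y - y0)))
        return a * np.minimum(1.0, base)


@dataclass(frozen=True)
class Morphometrics:
    volume: float        # pL
    area_total: float    # um^2
    area_ttubule: float  # um^2
    area_outer: float    # um^2


@dataclass
class LabeledGrid:
    """Voxelized microdomain with occupancy and boundary-face labels.

    Boundary faces are stored flat: ``face_voxel`` indexes the cytosolic
    voxel owning the face (flat index into the cytosol arrays used by the
    solver), ``face_label`` is one of the FACE_* constants and
    ``face_patch`` holds the LCC-cluster id (-1 = none).
    """

    voxel_size: float
    labels: np.ndarray                  # (nx, ny, nz) uint8 occupancy
    ttubule: TTubuleSpec
    box: BoxSpec
    seed: int
    relief_anchor: tuple[float, float]
    # boundary faces (filled by build_geometry)
    face_voxel: np.ndarray = field(default=None, repr=False)   # (nf,) int
    face_ijk: np.ndarray = field(default=None, repr=False)     # (nf, 3) int
    face_normal: np.ndarray = field(default=None, repr=False)  # (nf, 3) int8
    face_label: np.ndarray = field(default=None, repr=False)   # (nf,) uint8
    face_patch: np.ndarray = field(default=None, repr=False)   # (nf,) int
    cyt_index: np.ndarray = field(default=None, repr=False)    # (nx,ny,nz) -> flat or -1
    cyt_ijk: np.ndarray = field(default=None, repr=False)      # (ncyt, 3)
    area_correction: dict = field(default_factory=dict)        # label -> factor
    cluster_centers: np.ndarray = field(default=None, repr=False)  # (k, 3) um
    z_mouth: float = 0.0   # relief depth at the tubule mouth center, um
    z_tip: float = 0.0     # carved lumen tip depth, um

    @property
    def n_cytosol(self) -> int:
        return self.cyt_ijk.shape[0]

    @property
    def voxel_volume(self) -> float:
        """um^3 per voxel."""
        return self.voxel_size ** 3

    @property
    def cytosol_volume_pl(self) -> float:
        return self.n_cytosol * self.voxel_volume * UM3_TO_PL

    @property
    def face_area(self) -> float:
        """Raw (staircase) area of one voxel face, um^2."""
        return self.voxel_size ** 2

    def membrane_faces(self) -> np.ndarray:
        """Indices of faces on the sarcolemma (outer or t-tubule)."""
        return np.flatnonzero((self.face_label == FACE_OUTER)
                              | (self.face_label == FACE_TTUBULE))

    def face_centers(self) -> np.ndarray:
        """(nf, 3) face-center coordinates in um."""
        h = self.voxel_size
        centers = (self.face_ijk + 0.5) * h
        return centers + 0.5 * h * self.face_normal

    def voxel_centers(self, ijk: np.ndarray) -> np.ndarray:
        return (np.asarray(ijk) + 0.5) * self.voxel_size


@dataclass
class ProbeSet:
    """Measurement locations mirroring the line-scan experiment.

    The scan line runs in the transverse cell direction (along the
    tubule axis, i.e. into the cell), offset 200 nm laterally from the
    t-tubule mouth edge; cytosolic sample spots sit at 1.5 and 5.3 um
    along it.  The sub-sarcolemmal mask is the ~40-50 nm cytosol shell
    against the membrane where transporters sense Ca.
    """

    shell_depth: float                 # nm
    subsarc_mask: np.ndarray           # (ncyt,) bool
    shell_fraction: np.ndarray         # (ncyt,) fraction of voxel volume
                                       # within shell_depth of the membrane
    mouth_point: int                   # flat cytosol index
    distal_point: int                  # flat cytosol index
    linescan_voxels: np.ndarray        # (nl,) flat cytosol indices, ordered in z
    linescan_positions: np.ndarray     # (nl,) um along the line
    cytosol_spots: tuple[int, int]     # flat indices at 1.5 / 5.3 um


# --------------------------------------------------------------------------
# builders


def _analytic_outer_area(ttubule: TTubuleSpec | None, box: BoxSpec,
                         anchor: tuple[float, float], n: int = 400) -> float:
    """Quadrature area of the relief surface z=r(x,y), minus the mouth hole."""
    lx, ly, _ = box.dimensions
    x = (np.arange(n) + 0.5) * lx / n
    y = (np.arange(n) + 0.5) * ly / n
    X, Y = np.meshgrid(x, y, indexing="ij")
    if box.outer_relief_amplitude == 0:
        integrand = np.ones_like(X)
        R = np.zeros_like(X)
    else:
        a = box.outer_relief_amplitude
        g = 0.5 * RELIEF_SHARPNESS
        k = 2 * np.pi / box.outer_relief_wavelength
        x0, y0 = anchor
        R = box.relief(X, Y, anchor)
        # slopes vanish on the clipped plateaus
        active = g * (1.0 - np.cos(k * (X - x0)) * np.cos(k * (Y - y0))) < 1.0
        rx = a * g * k * np.sin(k * (X - x0)) * np.cos(k * (Y - y0)) * active
        ry = a * g * k * np.cos(k * (X - x0)) * np.sin(k * (Y - y0)) * active
        integrand = np.sqrt(1.0 + rx ** 2 + ry ** 2)
    if ttubule is not None:
        # mouth hole: (x,y) inside the tubule cross-section where the
        # lumen pierces the surface (evaluated at the local relief depth)
        cx, cy = ttubule.mouth_center
        ae, be = ttubule.semi_axes
        s = np.sqrt(ttubule.area_scale(R))
        hole = ((X - cx) / (ae * s)) ** 2 + ((Y - cy) / (be * s)) ** 2 <= 1.0
        integrand = np.where(hole, 0.0, integrand)
    return float(integrand.mean() * lx * ly)


def _analytic_outer_area_no_tubule(box: BoxSpec,
                                   anchor: tuple[float, float]) -> float:
    return _analytic_outer_area(None, box, anchor)


def _analytic_ttubule_area(ttubule: TTubuleSpec, box: BoxSpec,
                           anchor: tuple[float, float], z_tip: float,
                           nz: int = 600, nth: int = 128) -> float:
    """Quadrature lateral area of the modulated elliptical tube plus the
    flat tip, clipped to the part below the outer relief surface."""
    cx, cy = ttubule.mouth_center
    ae, be = ttubule.semi_axes
    z = np.linspace(0, z_tip, nz + 1)
    zc = 0.5 * (z[:-1] + z[1:])
    dz = z[1] - z[0]
    th = (np.arange(nth) + 0.5) * 2 * np.pi / nth
    dth = 2 * np.pi / nth
    s = np.sqrt(ttubule.area_scale(zc))
    ds = np.gradient(s, zc)
    S, TH = np.meshgrid(s, th, indexing="ij")
    DS = np.meshgrid(ds, th, indexing="ij")[0]
    ZC = np.meshgrid(zc, th, indexing="ij")[0]
    # p(z,th) = (cx + a s cos, cy + b s sin, z)
    px = cx + ae * S * np.cos(TH)
    py = cy + be * S * np.sin(TH)
    # |p_z x p_th| with p_z = (a s' cos, b s' sin, 1), p_th = (-a s sin, b s cos, 0)
    cxv = -be * S * np.cos(TH)
    cyv = -ae * S * np.sin(TH)
    czv = (ae * DS * np.cos(TH)) * (be * S * np.cos(TH)) \
        - (be * DS * np.sin(TH)) * (-ae * S * np.sin(TH))
    elem = np.sqrt(cxv ** 2 + cyv ** 2 + czv ** 2)
    relief = box.relief(px, py, anchor) if box.outer_relief_amplitude else np.zeros_like(px)
    elem = np.where(ZC >= relief, elem, 0.0)
    lateral = float(elem.sum() * dz * dth)
    tip = np.pi * ae * be * float(ttubule.area_scale(z_tip))
    return lateral + tip


def default_relief_anchor(ttubule: TTubuleSpec) -> tuple[float, float]:
    """Anchor the relief zero at the line-scan column: 200 nm laterally
    from the tubule mouth edge along +x."""
    cx, cy = ttubule.mouth_center
    ae, _ = ttubule.semi_axes
    return (cx + ae + 0.2, cy)


def build_geometry(ttubule: TTubuleSpec | None, box: BoxSpec,
                   voxel_size: float, seed: int = 0) -> LabeledGrid:
    """Voxelize the microdomain and label occupancy and boundary faces.

    Deterministic for fixed inputs (the seed is carried for cluster
    placement downstream).  ``ttubule=None`` builds the box alone (used
    by degenerate-geometry oracles).  Raises ``GeometryError`` when the
    voxel size cannot resolve the narrowest tubule cross-section
    (< 3 voxels) or the tubule does not fit in the box.
    """
    if voxel_size > 0.1 + 1e-12:
        raise GeometryError("voxel_size must be <= 100 nm")
    lx, ly, lz = box.dimensions
    if ttubule is not None:
        ae, be = ttubule.semi_axes
        cx, cy = ttubule.mouth_center
        anchor = box.relief_anchor or default_relief_anchor(ttubule)

        min_scale = np.sqrt(ttubule.constriction_area_fraction)
        min_diameter = 2 * be * min_scale
        if min_diameter < 3 * voxel_size:
            raise GeometryError(
                f"voxel size {voxel_size} um too coarse: narrowest tubule "
                f"diameter {min_diameter:.3f} um spans < 3 voxels")
        if not (ae < cx < lx - ae and be < cy < ly - be):
            raise GeometryError("tubule intersects box sides")

        z_mouth = float(box.relief(np.array(cx), np.array(cy), anchor)) \
            if box.outer_relief_amplitude else 0.0
        # where the relief buries the mouth, the carve depth is capped at
        # the bottom margin (the nominal length then exceeds the box)
        z_tip = min(z_mouth + ttubule.length, lz - 2 * voxel_size)
        if z_tip - z_mouth < 0.5 * ttubule.length:
            raise GeometryError("tubule does not fit below the relief")
    else:
        anchor = box.relief_anchor or (lx / 2, ly / 2)
        z_mouth = z_tip = 0.0

    h = voxel_size
    # round half up (with an epsilon against float representation of the
    # quotient) so a .5 grid count never truncates the box
    nx, ny, nz = (int(np.floor(d / h + 0.5 + 1e-9)) for d in box.dimensions)

    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h
    X, Y = np.meshgrid(x, y, indexing="ij")

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    relief = box.relief(X, Y, anchor) if box.outer_relief_amplitude else np.zeros((nx, ny))
    labels[relief[:, :, None] > z[None, None, :]] = EXTERIOR

    if ttubule is not None:
        s = np.sqrt(ttubule.area_scale(z))  # (nz,)
        ell = ((X[:, :, None] - cx) / (ae * s[None, None, :])) ** 2 \
            + ((Y[:, :, None] - cy) / (be * s[None, None, :])) ** 2
        in_tube = (ell <= 1.0) & (z[None, None, :] <= z_tip)
        labels[in_tube & (labels == CYTOSOL)] = LUMEN

    grid = LabeledGrid(voxel_size=h, labels=labels, ttubule=ttubule, box=box,
                       seed=seed, relief_anchor=anchor)
    grid.z_mouth = z_mouth
    grid.z_tip = z_tip
    _index_cytosol(grid)
    _label_faces(grid)
    _check_connected(grid)
    _compute_area_corrections(grid)
    return grid


def _index_cytosol(grid: LabeledGrid) -> None:
    cyt = grid.labels == CYTOSOL
    idx = -np.ones(grid.labels.shape, dtype=np.int64)
    ijk = np.argwhere(cyt)
    idx[cyt] = np.arange(ijk.shape[0])
    grid.cyt_index = idx
    grid.cyt_ijk = ijk


def _label_faces(grid: LabeledGrid) -> None:
    labels = grid.labels
    nx, ny, nz = labels.shape
    fv, fijk, fn, fl = [], [], [], []

    def add(mask_ijk, normal, face_lab):
        if mask_ijk.shape[0] == 0:
            return
        fv.append(grid.cyt_index[tuple(mask_ijk.T)])
        fijk.append(mask_ijk)
        fn.append(np.tile(np.asarray(normal, dtype=np.int8), (mask_ijk.shape[0], 1)))
        fl.append(np.full(mask_ijk.shape[0], face_lab, dtype=np.uint8))

    cyt = labels == CYTOSOL
    for axis in range(3):
        for d in (-1, 1):
            nb = np.roll(labels, -d, axis=axis)
            # neighbor occupancy seen from each voxel; mark out-of-range
            edge = np.zeros_like(labels, dtype=bool)
            sl = [slice(None)] * 3
            sl[axis] = -1 if d == 1 else 0
            edge[tuple(sl)] = True
            normal = [0, 0, 0]
            normal[axis] = d
            # domain-boundary faces
            bmask = cyt & edge
            if axis == 2 and d == -1:
                face_lab = FACE_OUTER       # z=0 plane is the flat outer cap
            else:
                face_lab = FACE_REFLECTIVE  # box sides and bottom
            add(np.argwhere(bmask), normal, face_lab)
            # interior faces against exterior/lumen
            imask = cyt & ~edge
            nb_ext = imask & (nb == EXTERIOR)
            add(np.argwhere(nb_ext), normal, FACE_OUTER)
            nb_lum = imask & (nb == LUMEN)
            add(np.argwhere(nb_lum), normal, FACE_TTUBULE)

    grid.face_voxel = np.concatenate(fv)
    grid.face_ijk = np.concatenate(fijk)
    grid.face_normal = np.concatenate(fn)
    grid.face_label = np.concatenate(fl)
    grid.face_patch = np.full(grid.face_voxel.shape[0], -1, dtype=np.int64)


def _check_connected(grid: LabeledGrid) -> None:
    from scipy.ndimage import label as cc_label
    cyt = grid.labels == CYTOSOL
    _, ncomp = cc_label(cyt)
    if ncomp != 1:
        raise GeometryError(f"cytosol is not a single connected component ({ncomp})")


def _compute_area_corrections(grid: LabeledGrid) -> None:
    """Per-label staircase-correction factors: ratio of the analytic
    (smooth) surface area to the raw voxel-face area at this resolution.
    Flux distribution is normalized against raw areas, so the residual
    bias never corrupts whole-cell fluxes."""
    a_raw_tt = float(np.sum(grid.face_label == FACE_TTUBULE)) * grid.face_area
    a_raw_out = float(np.sum(grid.face_label == FACE_OUTER)) * grid.face_area
    if grid.ttubule is not None:
        a_tt = _analytic_ttubule_area(grid.ttubule, grid.box,
                                      grid.relief_anchor, grid.z_tip)
        a_out = _analytic_outer_area(grid.ttubule, grid.box, grid.relief_anchor)
    else:
        a_tt = 0.0
        a_out = _analytic_outer_area_no_tubule(grid.box, grid.relief_anchor)
    grid.area_correction = {
        FACE_TTUBULE: a_tt / a_raw_tt if a_raw_tt else 1.0,
        FACE_OUTER: a_out / a_raw_out if a_raw_out else 1.0,
    }


def measure_morphometrics(grid: LabeledGrid) -> Morphometrics:
    """Volume from cytosol voxel counts; areas from labeled faces with
    the per-label staircase correction."""
    if grid.face_label is None:
        raise GeometryError("grid has no labeled boundary faces")
    vol = grid.cytosol_volume_pl
    a_tt = float(np.sum(grid.face_label == FACE_TTUBULE)) * grid.face_area \
        * grid.area_correction.get(FACE_TTUBULE, 1.0)
    a_out = float(np.sum(grid.face_label == FACE_OUTER)) * grid.face_area \
        * grid.area_correction.get(FACE_OUTER, 1.0)
    return Morphometrics(volume=vol, area_total=a_tt + a_out,
                         area_ttubule=a_tt, area_outer=a_out)


# --------------------------------------------------------------------------
# calibration


#: printed morphometric targets of the compartment
PRINTED_MORPHOMETRICS = Morphometrics(volume=0.0282, area_total=15.9,
                                      area_ttubule=7.8, area_outer=8.1)


def calibrate_geometry(targets: Morphometrics = PRINTED_MORPHOMETRICS,
                       voxel_size: float = 0.04,
                       ttubule: TTubuleSpec | None = None,
                       box: BoxSpec | None = None,
                       tol: float = 0.03, max_sweeps: int = 6,
                       ) -> tuple[TTubuleSpec, BoxSpec]:
    """Tune (mean_diameter, relief amplitude, relief wavelength) so the
    measured morphometrics hit the targets within ``tol`` (3% default).

    Deterministic coordinate descent, one 1D solve per sweep step in the
    order diameter -> amplitude -> wavelength: each morphometric is
    dominated by one knob (tubule area, volume, outer area) with only
    weak cross-coupling, so a few sweeps converge.  Raises
    ``GeometryError`` with the best residuals if tolerance is not met.
    """
    no_tubule = targets.area_ttubule == 0
    tt0 = None if no_tubule else (ttubule or TTubuleSpec())
    bx0 = box or BoxSpec()
    params = {
        "d": 0.0 if no_tubule else tt0.mean_diameter,
        "a": bx0.outer_relief_amplitude,
        "w": bx0.outer_relief_wavelength,
    }
    hmin = 3 * voxel_size
    d_lo = 0.0 if no_tubule else hmin / np.sqrt(tt0.constriction_area_fraction) \
        * np.sqrt(tt0.eccentricity) + 1e-6
    bounds = {"d": (max(0.2, d_lo), 0.95),
              "a": (0.0, 0.199 * bx0.dimensions[2] - 1e-6),
              "w": (0.8, 6.0)}

    def specs(p):
        tt = None if no_tubule else replace(tt0, mean_diameter=p["d"])
        bx = replace(bx0, outer_relief_amplitude=p["a"],
                     outer_relief_wavelength=p["w"])
        return tt, bx

    def measure(p):
        tt, bx = specs(p)
        return measure_morphometrics(build_geometry(tt, bx, voxel_size))

    def errs(m):
        e_tt = 0.0 if no_tubule else (abs(m.area_ttubule - targets.area_ttubule)
                                      / targets.area_ttubule)
        return (e_tt,
                abs(m.volume - targets.volume) / targets.volume,
                abs(m.area_outer - targets.area_outer) / targets.area_outer)

    plan = [("a", lambda m: m.volume, targets.volume),
            ("w", lambda m: m.area_outer, targets.area_outer)]
    if not no_tubule:
        plan.insert(0, ("d", lambda m: m.area_ttubule, targets.area_ttubule))
    for sweep in range(max_sweeps):
        for key, metric, target in plan:
            def f(v):
                q = dict(params)
                q[key] = float(v)
                try:
                    return metric(measure(q)) - target
                except GeometryError:
                    return np.nan  # infeasible point (e.g. tubule no longer fits)
            params[key] = _solve_1d(f, params[key], *bounds[key],
                                    rtol=0.3 * tol, target_scale=target)
        m = measure(params)
        if max(errs(m)) < tol:
            log.info("geometry calibrated in %d sweep(s): %s", sweep + 1, m)
            return specs(params)
    m = measure(params)
    e = errs(m)
    raise GeometryError(
        "geometry calibration failed: residuals "
        f"area_tt={e[0]:.3f} volume={e[1]:.3f} area_outer={e[2]:.3f}")


def _solve_1d(f, p_start, lo, hi, rtol, target_scale,
              iters=10, n_scan=9) -> float:
    """Deterministic 1D solve of f(p) = 0: secant from the start point,
    falling back to a coarse bracket scan + bisection when the secant
    leaves the bounds.  Returns the best parameter found."""
    p0 = float(np.clip(p_start, lo, hi))
    f0 = f(p0)
    if np.isfinite(f0) and abs(f0) < rtol * abs(target_scale):
        return p0
    p1 = float(np.clip(p0 * 1.08 + 0.02 * (hi - lo), lo, hi))
    f1 = f(p1)
    cand = [(p, abs(v)) for p, v in ((p0, f0), (p1, f1)) if np.isfinite(v)]
    best = min(cand, key=lambda t: t[1]) if cand else (p0, np.inf)
    for _ in range(iters):
        if not (np.isfinite(f0) and np.isfinite(f1)) or f1 == f0:
            break
        p2 = p1 - f1 * (p1 - p0) / (f1 - f0)
        if not (lo <= p2 <= hi):
            break
        f2 = f(p2)
        if np.isfinite(f2) and abs(f2) < best[1]:
            best = (p2, abs(f2))
        if np.isfinite(f2) and abs(f2) < rtol * abs(target_scale):
            return p2
        p0, f0, p1, f1 = p1, f1, p2, f2
    # bracket scan fallback
    ps = np.linspace(lo, hi, n_scan)
    fs = np.array([f(p) for p in ps])
    ok = np.isfinite(fs)
    ps, fs = ps[ok], fs[ok]
    if ps.size == 0:
        return best[0]
    j = int(np.argmin(np.abs(fs)))
    if abs(fs[j]) < best[1]:
        best = (float(ps[j]), abs(fs[j]))
    sc = np.nonzero(np.diff(np.sign(fs)) != 0)[0]
    if sc.size:
        i = int(sc[0])
        a, b, fa, fb = ps[i], ps[i + 1], fs[i], fs[i + 1]
        for _ in range(iters):
            p = 0.5 * (a + b)
            fp = f(p)
            if abs(fp) < best[1]:
                best = (float(p), abs(fp))
            if abs(fp) < rtol * abs(target_scale):
                return float(p)
            if np.sign(fp) == np.sign(fa):
                a, fa = p, fp
            else:
                b, fb = p, fp
    return best[0]


# --------------------------------------------------------------------------
# LCC clusters and probes


def place_lcc_clusters(grid: LabeledGrid, n: int = 3, diameter: float = 0.2,
                       pinned_depth: float = 2.0,
                       spacing: float | None = None,
                       seed: int | None = None) -> LabeledGrid:
    """Mark ``n`` disjoint ~200 nm patches of t-tubule membrane faces as
    LCC clusters.  One center is pinned at ``pinned_depth`` below the
    outer surface; the rest sit at ``spacing`` above/below it, or at
    seeded-random depths with non-overlap enforced.  ``n = 0`` leaves the
    grid unchanged (continuous-LCC mode)."""
    if n == 0:
        return grid
    if n < 1:
        raise GeometryError("n must be >= 0")
    tt = grid.ttubule
    if spacing is not None and spacing > tt.length:
        raise GeometryError("requested spacing exceeds tubule length")

    faces_tt = np.flatnonzero(grid.face_label == FACE_TTUBULE)
    centers_f = grid.face_centers()[faces_tt]
    cx, cy = tt.mouth_center
    z_mouth = grid.z_mouth
    z_lo = z_mouth + max(0.3, diameter)            # keep clear of the mouth rim
    z_hi = grid.z_tip - diameter / 2 - grid.voxel_size
    rng = np.random.default_rng(grid.seed if seed is None else seed)

    depths = [z_mouth + pinned_depth]
    if spacing is not None:
        for k in range(1, n):
            side = 1 if k % 2 else -1
            depths.append(depths[0] + side * spacing * ((k + 1) // 2))
    else:
        min_sep = diameter * 1.5
        tries = 0
        while len(depths) < n:
            cand = float(rng.uniform(z_lo, z_hi))
            if all(abs(cand - d) >= min_sep for d in depths):
                depths.append(cand)
            tries += 1
            if tries > 10000:
                raise GeometryError("could not place non-overlapping clusters")
    depths = [float(np.clip(d, z_lo, z_hi)) for d in depths]
    if len(set(np.round(depths, 6))) < n or any(
            abs(a - b) < diameter for i, a in enumerate(depths)
            for b in depths[i + 1:]):
        raise GeometryError("cluster layout overlaps; adjust spacing/seed")

    thetas = rng.uniform(0, 2 * np.pi, size=n)
    ae, be = tt.semi_axes
    patch = np.full(grid.face_voxel.shape[0], -1, dtype=np.int64)
    ccenters = []
    for k, (zk, th) in enumerate(zip(depths, thetas)):
        s = float(np.sqrt(tt.area_scale(zk)))
        center = np.array([cx + ae * s * np.cos(th), cy + be * s * np.sin(th), zk])
        d2 = np.sum((centers_f - center) ** 2, axis=1)
        sel = faces_tt[d2 <= (diameter / 2) ** 2]
        if sel.size == 0:
            sel = faces_tt[[int(np.argmin(d2))]]
        if np.any(patch[sel] >= 0):
            raise GeometryError("cluster patches overlap on the membrane")
        patch[sel] = k
        ccenters.append(center)
    grid.face_patch = patch
    grid.cluster_centers = np.asarray(ccenters)
    if np.any(grid.face_label[patch >= 0] != FACE_TTUBULE):
        raise GeometryError("cluster patch touched non-tubule membrane")
    return grid


def make_probes(grid: LabeledGrid, shell_depth: float = 50.0) -> ProbeSet:
    """Build the sub-sarcolemmal mask, line-scan column and probe points.

    ``shell_depth`` in nm (40-50).  Points that fall outside the cytosol
    are snapped to the nearest cytosolic voxel (logged)."""
    if not (40.0 <= shell_depth <= 50.0):
        raise GeometryError("shell_depth must be within [40, 50] nm")
    h = grid.voxel_size
    n_layers = max(1, int(round(shell_depth * 1e-3 / h)))

    mem = grid.membrane_faces()
    sub = np.zeros(grid.n_cytosol, dtype=bool)
    sub[grid.face_voxel[mem]] = True
    if n_layers > 1:
        # grow the shell through cytosol adjacency
        from scipy.ndimage import binary_dilation
        vol = np.zeros(grid.labels.shape, dtype=bool)
        vol[tuple(grid.cyt_ijk[sub].T)] = True
        cyt = grid.labels == CYTOSOL
        for _ in range(n_layers - 1):
            vol = binary_dilation(vol) & cyt
        sub = vol[tuple(grid.cyt_ijk.T)]

    # per-voxel fraction of volume within shell_depth of the membrane,
    # by adjacency layer: layer k spans [k h, (k+1) h) from the wall.
    # Keeping the excluded TnC volume tied to the physical shell depth
    # (rather than to whole voxel layers) makes it resolution-consistent.
    depth_um = shell_depth * 1e-3
    frac = np.zeros(grid.n_cytosol)
    layer_mask = np.zeros(grid.n_cytosol, dtype=bool)
    layer_mask[grid.face_voxel[mem]] = True
    from scipy.ndimage import binary_dilation
    cyt = grid.labels == CYTOSOL
    vol = np.zeros(grid.labels.shape, dtype=bool)
    vol[tuple(grid.cyt_ijk[layer_mask].T)] = True
    covered = np.zeros(grid.n_cytosol, dtype=bool)
    k = 0
    while depth_um > k * h and layer_mask.any():
        f = float(np.clip((depth_um - k * h) / h, 0.0, 1.0))
        frac[layer_mask & ~covered] = f
        covered |= layer_mask
        vol = binary_dilation(vol) & cyt
        layer_mask = vol[tuple(grid.cyt_ijk.T)] & ~covered
        k += 1

    # mouth probe: sub-sarc voxel on the tubule wall just below the rim.
    # Corner voxels where the tubule meets the outer-surface relief own
    # several membrane faces and overweight the local source; prefer a
    # wall voxel with a single membrane face.
    tt_faces = np.flatnonzero(grid.face_label == FACE_TTUBULE)
    zc = grid.face_centers()[tt_faces, 2]
    nface = np.bincount(grid.face_voxel[grid.membrane_faces()],
                        minlength=grid.n_cytosol)
    single = nface[grid.face_voxel[tt_faces]] == 1
    cand = tt_faces[single] if single.any() else tt_faces
    zcand = grid.face_centers()[cand, 2]
    mouth_face = cand[int(np.argmin(zcand))]
    mouth_point = int(grid.face_voxel[mouth_face])

    # distal probe: against the deepest LCC cluster patch (or deepest
    # tubule face when no clusters are placed)
    cl_faces = np.flatnonzero(grid.face_patch >= 0)
    if cl_faces.size:
        deepest_patch = grid.face_patch[cl_faces[np.argmax(
            grid.face_centers()[cl_faces, 2])]]
        pf = cl_faces[grid.face_patch[cl_faces] == deepest_patch]
        distal_face = pf[int(np.argmax(grid.face_centers()[pf, 2]))]
    else:
        distal_face = tt_faces[int(np.argmax(zc))]
    distal_point = int(grid.face_voxel[distal_face])

    # line-scan column at the relief anchor (r = 0 there, so the column
    # is cytosolic from the outer face down, bar the tubule if crossed)
    ax, ay = grid.relief_anchor
    ix = int(np.clip(ax / h - 0.5, 0, grid.labels.shape[0] - 1))
    iy = int(np.clip(ay / h - 0.5, 0, grid.labels.shape[1] - 1))
    col = grid.cyt_index[ix, iy, :]
    zsel = np.flatnonzero(col >= 0)
    if zsel.size != grid.labels.shape[2]:
        log.info("line-scan column clipped to %d/%d cytosolic voxels",
                 zsel.size, grid.labels.shape[2])
    line_vox = col[zsel]
    line_pos = (zsel + 0.5) * h

    def snap(target_um):
        j = int(np.argmin(np.abs(line_pos - target_um)))
        if abs(line_pos[j] - target_um) > h:
            log.info("probe spot at %.2f um snapped to %.2f um",
                     target_um, line_pos[j])
        return int(line_vox[j])

    spots = (snap(1.5), snap(5.3))
    return ProbeSet(shell_depth=shell_depth, subsarc_mask=sub,
                    shell_fraction=frac,
                    mouth_point=mouth_point, distal_point=distal_point,
                    linescan_voxels=line_vox, linescan_positions=line_pos,
                    cytosol_spots=spots)
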