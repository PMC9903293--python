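"""FEM meshes of the unit disk / cylinder and the 3-sphere thorax phantom.

The domain is dimensionless with radius 1. The phantom places a small
high-conductivity "heart" inclusion between two larger low-conductivity
"lung" inclusions, the layout used for simulated-breathing studies where
the lung radius sweeps while the heart stays fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay

# Lung centers: the nominal lateral position (+-0.45, -0.05) scaled so that the
# largest lung in the sweep (r = 0.6) still fits inside the unit disk.
_LUNG_NOMINAL = np.array([0.45, -0.05])
_LUNG_CENTER = _LUNG_NOMINAL * (0.4 / np.hypot(*_LUNG_NOMINAL))

DEFAULT_HEART_CENTER = (0.0, 0.1)
DEFAULT_LEFT_LUNG_CENTER = (-float(_LUNG_CENTER[0]), float(_LUNG_CENTER[1]))
DEFAULT_RIGHT_LUNG_CENTER = (float(_LUNG_CENTER[0]), float(_LUNG_CENTER[1]))

_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class Mesh:
    """Simplicial FEM mesh with 16 ordered boundary electrode groups.

    nodes : (n_nodes, dim) coordinates, domain radius 1
    elements : (n_elements, dim+1) node-index simplices, positively oriented
    electrode_nodes : ordered node-index groups, counter-clockwise from angle 0
    """

    nodes: np.ndarray
    elements: np.ndarray
    electrode_nodes: tuple[np.ndarray, ...]
    dimension: int
    height: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_nodes)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        """Signed area (2D) / volume (3D) per element; positive by construction."""
        pts = self.nodes[self.elements]
        edges = pts[:, 1:, :] - pts[:, :1, :]
        if self.dimension == 2:
            return 0.5 * np.linalg.det(edges)
        return np.linalg.det(edges) / 6.0

    def electrode_centers(self) -> np.ndarray:
        return np.array([self.nodes[g].mean(axis=0) for g in self.electrode_nodes])


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and conductivities of the heart + two-lungs phantom.

    Conductivities are in arbitrary units: heart 2, lungs 0.5 against a
    background fixed at 1. All lengths are fractions of the domain radius.
    """

    heart_radius: float = 0.3
    heart_conductivity: float = 2.0
    lung_radius: float = 0.4
    lung_conductivity: float = 0.5
    background_conductivity: float = 1.0
    heart_center: tuple[float, float] = DEFAULT_HEART_CENTER
    left_lung_center: tuple[float, float] = DEFAULT_LEFT_LUNG_CENTER
    right_lung_center: tuple[float, float] = DEFAULT_RIGHT_LUNG_CENTER

    def __post_init__(self):
        if self.heart_radius < 0 or self.lung_radius < 0:
            raise ValueError("inclusion radii must be non-negative")
        for c in (self.heart_conductivity, self.lung_conductivity,
                  self.background_conductivity):
            if c <= 0:
                raise ValueError("conductivities must be positive")
        for center, radius, name in (
            (self.heart_center, self.heart_radius, "heart"),
            (self.left_lung_center, self.lung_radius, "left lung"),
            (self.right_lung_center, self.lung_radius, "right lung"),
        ):
            if np.hypot(*center) + radius > 1.0 + 1e-6:
                raise ValueError(
                    f"{name} inclusion (center {center}, radius {radius}) "
                    "extends outside the unit-radius domain"
                )

    def inclusions(self):
        """(center, radius, conductivity) triples; heart last so it wins overlaps."""
        return (
            (np.asarray(self.left_lung_center), self.lung_radius, self.lung_conductivity),
            (np.asarray(self.right_lung_center), self.lung_radius, self.lung_conductivity),
            (np.asarray(self.heart_center), self.heart_radius, self.heart_conductivity),
        )


def _disk_points(target_element_size: float, n_electrodes: int):
    """Concentric-ring point cloud; the outer ring hosts the electrode nodes.

    The outer ring count is a multiple of n_electrodes so that nodes sit
    exactly at the electrode angles 2*pi*k/n_electrodes.
    """
    h = float(target_element_size)
    n_rings = max(2, round(1.0 / h))
    per_arc = max(1, round(2 * np.pi / (n_electrodes * h)))
    n_outer = n_electrodes * per_arc

    pts = [np.zeros((1, 2))]
    for k in range(1, n_rings + 1):
        r = k / n_rings
        if k == n_rings:
            n_k = n_outer
        else:
            # every ring count is a multiple of n_electrodes so the mesh is
            # invariant under rotation by one electrode spacing; this makes
            # the homogeneous-disk frame exactly periodic across stim blocks
            n_k = n_electrodes * max(1, round(2 * np.pi * r / (n_electrodes * h)))
        theta = 2 * np.pi * np.arange(n_k) / n_k
        # stagger alternate interior rings by half an electrode spacing
        # (also a symmetry of the 16-fold group) to avoid co-radial slivers
        if k < n_rings:
            theta = theta + (np.pi / n_electrodes) * (k % 2)
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    points = np.vstack(pts)
    outer_start = points.shape[0] - n_outer
    electrode_idx = outer_start + per_arc * np.arange(n_electrodes)
    return points, electrode_idx, outer_start


def _orient_positive(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    pts = nodes[elements]
    edges = pts[:, 1:, :] - pts[:, :1, :]
    det = np.linalg.det(edges)
    flip = det < 0
    elements = elements.copy()
    elements[flip, -2], elements[flip, -1] = (
        elements[flip, -1].copy(), elements[flip, -2].copy())
    return elements


def _build_disk_mesh(target_element_size: float, n_electrodes: int,
                     jitter: float = 0.0, seed: int = 0) -> Mesh:
    points, electrode_idx, outer_start = _disk_points(
        target_element_size, n_electrodes)
    if jitter > 0:
        # displace interior nodes to emulate an unstructured mesh; boundary
        # (and hence electrode) nodes stay exactly on the circle
        rng = np.random.default_rng(seed)
        interior = np.arange(1, outer_start)
        shift = rng.uniform(-1, 1, (interior.size, 2)) * jitter * target_element_size
        moved = points[interior] + shift
        r = np.linalg.norm(moved, axis=1)
        ok = r < 1.0 - 0.3 * target_element_size
        points[interior[ok]] = moved[ok]
    tri = Delaunay(points)
    elements = _orient_positive(points, tri.simplices.astype(np.int64))
    groups = tuple(np.array([i], dtype=np.int64) for i in electrode_idx)
    return Mesh(nodes=points, elements=elements, electrode_nodes=groups,
                dimension=2)


def _build_cylinder_mesh(target_element_size: float, n_electrodes: int,
                         height: float, electrode_half_width_deg: float,
                         jitter: float = 0.0, seed: int = 0) -> Mesh:
    """Extrude the disk mesh into layers of prisms, each split into 3 tets."""
    disk = _build_disk_mesh(target_element_size, n_electrodes,
                            jitter=jitter, seed=seed)
    n2d = disk.n_nodes
    # even layer count so a node layer sits exactly at mid-height for the
    # electrode plane
    n_layers = 2 * max(1, round(height / (2 * target_element_size)))
    zs = np.linspace(0.0, height, n_layers + 1)

    nodes = np.vstack([
        np.column_stack([disk.nodes, np.full(n2d, z)]) for z in zs
    ])

    tets = []
    for layer in range(n_layers):
        lo, hi = layer * n2d, (layer + 1) * n2d
        for tri_el in disk.elements:
            a, b, c = (int(v) for v in tri_el)
            # conforming prism split keyed on global index order
            v = sorted([a, b, c])
            i, j, k = v
            bot = {a: lo + a, b: lo + b, c: lo + c}
            top = {a: hi + a, b: hi + b, c: hi + c}
            tets.append([bot[i], bot[j], bot[k], top[i]])
            tets.append([top[i], top[j], top[k], bot[j]])
            tets.append([bot[j], bot[k], top[i], top[k]])
    elements = _orient_positive(nodes, np.asarray(tets, dtype=np.int64))

    # electrode groups: lateral-boundary nodes at the mid-height layer within
    # the configured angular half-width of each electrode angle
    mid_layer = n_layers // 2
    lo = mid_layer * n2d
    r2d = np.hypot(disk.nodes[:, 0], disk.nodes[:, 1])
    boundary2d = np.where(np.abs(r2d - 1.0) < _BOUNDARY_TOL)[0]
    angles = np.mod(np.arctan2(disk.nodes[boundary2d, 1],
                               disk.nodes[boundary2d, 0]), 2 * np.pi)
    half_width = np.deg2rad(electrode_half_width_deg)
    groups = []
    for k in range(n_electrodes):
        center = 2 * np.pi * k / n_electrodes
        d = np.abs(np.angle(np.exp(1j * (angles - center))))
        sel = boundary2d[d <= half_width + 1e-12]
        if sel.size == 0:
            sel = boundary2d[[int(np.argmin(d))]]
        groups.append(np.sort(lo + sel).astype(np.int64))
    return Mesh(nodes=nodes, elements=elements, electrode_nodes=tuple(groups),
                dimension=3, height=height)


def build_mesh(dimension: int = 2, n_electrodes: int = 16,
               target_element_size: float = 0.08, height: float = 1.0,
               electrode_half_width_deg: float = 4.0,
               jitter: float = 0.0, seed: int = 0) -> Mesh:
    """Mesh the unit disk (2D) or unit-radius cylinder (3D).

    16 equispaced electrode groups sit on the lateral boundary, counter-
    clockwise from angle 0; in 3D they are placed at the mid-height plane.
    The 2D disk is the fast path; the 3D cylinder mirrors the cylindrical
    tank geometry of bench phantoms.

    ``jitter`` displaces interior nodes by a uniform random fraction of the
    element size (seeded), emulating the irregular unstructured meshes that
    general-purpose mesh generators produce; ``jitter=0`` keeps the exactly
    16-fold-symmetric structured mesh.
    """
    if dimension not in (2, 3):
        raise ValueError(f"dimension must be 2 or 3, got {dimension}")
    if target_element_size <= 0:
        raise ValueError("target_element_size must be positive")
    per_arc = 2 * np.pi / (n_electrodes * target_element_size)
    if per_arc < 0.5:
        raise ValueError(
            "element size too coarse to host "
            f"{n_electrodes} distinct electrode groups")
    if dimension == 2:
        return _build_disk_mesh(target_element_size, n_electrodes,
                                jitter=jitter, seed=seed)
    return _build_cylinder_mesh(target_element_size, n_electrodes, height,
                                electrode_half_width_deg,
                                jitter=jitter, seed=seed)


def assign_phantom(mesh: Mesh, spec: PhantomSpec) -> np.ndarray:
    """Per-element conductivity field for the phantom.

    Membership is decided by the element centroid; the heart is assigned
    after the lungs so it wins any overlap. In 3D the inclusions are spheres
    centered on the electrode plane.
    """
    centroids = mesh.element_centroids()
    sigma = np.full(mesh.n_elements, spec.background_conductivity)
    z0 = (mesh.height or 0.0) / 2.0
    lung_gap = np.linalg.norm(
        np.asarray(spec.left_lung_center) - np.asarray(spec.right_lung_center))
    if 0 < lung_gap < 2 * spec.lung_radius:
        warnings.warn("lung inclusions overlap each other", stacklevel=2)
    for center, radius, value in spec.inclusions():
        if radius <= 0:
            continue
        if mesh.dimension == 2:
            d2 = ((centroids[:, 0] - center[0]) ** 2
                  + (centroids[:, 1] - center[1]) ** 2)
        else:
            d2 = ((centroids[:, 0] - center[0]) ** 2
                  + (centroids[:, 1] - center[1]) ** 2
                  + (centroids[:, 2] - z0) ** 2)
        sigma[d2 <= radius ** 2] = value
    return sigma


def breathing_sequence(base_spec: PhantomSpec, n_frames: int,
                       lung_radius_start: float = 0.3,
                       lung_radius_end: float = 0.6) -> list[PhantomSpec]:
    """Phantom states of a simulated breath: lungs expand, heart stays fixed.

    The lung radius is linearly interpolated from start to end over
    ``n_frames`` states; all other fields copy ``base_spec``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_frames == 1:
        radii = np.array([lung_radius_start])
    else:
        radii = np.linspace(lung_radius_start, lung_radius_end, n_frames)
    return [replace(base_spec, lung_radius=float(r)) for r in radii]
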