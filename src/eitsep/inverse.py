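"""Linearized difference imaging: Jacobian, one-step solver, rasterization.

The conductivity change between a measurement frame and a reference frame
is recovered with a single regularized Gauss-Newton step at the reference
conductivity (the standard difference-EIT solver family), then sampled onto
a square pixel grid with a circular support mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy.sparse.linalg import splu
from matplotlib.tri import Triangulation, TrapezoidMapTriFinder
from scipy.spatial import cKDTree

from eitsep.mesh import Mesh
from eitsep.forward import (
    Frame, Protocol, adjacent_protocol, assemble_system,
    _element_gradients, _ground_node,
)


@dataclass(frozen=True)
class Jacobian:
    """Sensitivity matrix dv/dsigma at the reference conductivity.

    ``matrix`` has one row per protocol measurement and one column per mesh
    element; ``reference_frame`` holds the simulated voltages at
    ``sigma_ref``.
    """

    matrix: np.ndarray
    mesh: Mesh
    protocol: Protocol
    sigma_ref: np.ndarray
    reference_frame: Frame


@dataclass(frozen=True)
class ReconImage:
    """g x g conductivity-change image on [-1, 1]^2 with a circular mask.

    ``values`` is NaN outside the mask; ``mask`` is True on supported pixels.
    """

    values: np.ndarray
    mask: np.ndarray
    grid_size: int

    def pixel_coords(self):
        """(x, y) 1-D pixel-center coordinate arrays."""
        g = self.grid_size
        step = 2.0 / g
        c = -1.0 + step * (np.arange(g) + 0.5)
        return c, c

    @property
    def pixel_area(self) -> float:
        return (2.0 / self.grid_size) ** 2


@dataclass(frozen=True)
class Profile:
    """Horizontal center cut of a reconstructed image."""

    x: np.ndarray
    values: np.ndarray


def compute_jacobian(mesh: Mesh, sigma_ref: np.ndarray | None = None,
                     protocol: Protocol | None = None) -> Jacobian:
    """Adjoint-method sensitivities of every measurement to every element.

    For measurement (stim s, pair m), dv/dsigma_e = -vol_e * grad(u_s).grad(u_m)
    where u_s, u_m are the potentials driven through the stimulation and
    measurement pairs with unit current. Adjacent drive means the 16 drive
    fields cover both roles, so one factorization serves all 208 rows.
    """
    protocol = protocol or adjacent_protocol(mesh.n_electrodes)
    if sigma_ref is None:
        sigma_ref = np.ones(mesh.n_elements)
    sigma_ref = np.asarray(sigma_ref, dtype=float)

    A = assemble_system(mesh, sigma_ref)
    ground = _ground_node(mesh)
    A = A.tolil(copy=True)
    A[ground, :] = 0.0
    A[:, ground] = 0.0
    A[ground, ground] = 1.0
    lu = splu(A.tocsc())

    n_el = mesh.n_electrodes
    rhs = np.zeros((mesh.n_nodes, n_el))
    for d in range(n_el):
        src, snk = mesh.electrode_nodes[d], mesh.electrode_nodes[(d + 1) % n_el]
        rhs[src, d] += 1.0 / len(src)
        rhs[snk, d] -= 1.0 / len(snk)
    rhs[ground, :] = 0.0
    u = lu.solve(rhs)                              # (n_nodes, 16)

    grads, vols = _element_gradients(mesh)
    # per-element gradient of each drive field: (n_elements, dim, n_drives)
    u_loc = u[mesh.elements, :]                    # (n_el_m, dim+1, 16)
    grad_u = np.einsum("eid,eik->edk", grads, u_loc)

    J = np.empty((protocol.flat_length, mesh.n_elements))
    pots = np.empty((n_el, n_el))
    for e in range(n_el):
        pots[:, e] = u[mesh.electrode_nodes[e], :].mean(axis=0)
    ref_values = np.empty(protocol.flat_length)
    for s, block in enumerate(protocol.meas_pairs):
        gs = grad_u[:, :, s]
        for m, (a, b) in enumerate(block):
            gm = grad_u[:, :, a]                   # meas pair (a, a+1) = drive a
            row = -vols * np.einsum("ed,ed->e", gs, gm)
            J[protocol.flat_index(s, m)] = row
            ref_values[protocol.flat_index(s, m)] = pots[s, a] - pots[s, b]
    ref_frame = Frame(values=ref_values, protocol=protocol, label="reference")
    return Jacobian(matrix=J, mesh=mesh, protocol=protocol,
                    sigma_ref=sigma_ref, reference_frame=ref_frame)


def reconstruct(jacobian: Jacobian, frame: Frame,
                reference_frame: Frame | None = None,
                hyperparameter: float = 0.05,
                prior: str = "noser") -> np.ndarray:
    """One-step regularized Gauss-Newton difference reconstruction.

    Solves (J'J + lam^2 R) dsigma = J'(v - v_ref) with R the NOSER diagonal
    diag(J'J)^0.5 or the identity (Tikhonov).
    """
    v_ref = (reference_frame or jacobian.reference_frame).values
    dv = frame.values - v_ref
    return reconstruction_operator(jacobian, hyperparameter, prior) @ dv


_OPERATOR_CACHE: dict = {}


def reconstruction_operator(jacobian: Jacobian, hyperparameter: float = 0.05,
                            prior: str = "noser") -> np.ndarray:
    """The linear map (J'J + lam^2 R)^-1 J' applied by :func:`reconstruct`.

    Cached per (Jacobian, hyperparameter, prior) so repeated reconstructions
    on one mesh factorize the normal equations only once.
    """
    if hyperparameter <= 0:
        raise ValueError("hyperparameter must be positive")
    key = (id(jacobian), float(hyperparameter), prior)
    hit = _OPERATOR_CACHE.get(key)
    if hit is not None and hit[0] is jacobian:
        return hit[1]
    J = jacobian.matrix
    JtJ = J.T @ J
    diag = np.diag(JtJ)
    if prior == "noser":
        R = np.diag(np.sqrt(diag))
        lam_scale = np.sqrt(diag).mean()
    elif prior == "tikhonov":
        R = np.eye(J.shape[1])
        lam_scale = diag.mean()
    else:
        raise ValueError(f"unknown prior {prior!r}")
    lhs = JtJ + hyperparameter ** 2 * lam_scale * R
    try:
        c, low = sla.cho_factor(lhs)
        op = sla.cho_solve((c, low), J.T)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "normal equations not positive definite (ill-conditioned); "
            "increase the hyperparameter") from err
    _OPERATOR_CACHE[key] = (jacobian, op)
    if len(_OPERATOR_CACHE) > 8:
        _OPERATOR_CACHE.pop(next(iter(_OPERATOR_CACHE)))
    return op


def _slice_elements(mesh: Mesh, slab_half_width: float = 0.15):
    """2D triangulation view of the mesh for rasterization.

    In 2D it is the mesh itself. In 3D only the electrode-plane slab
    |z - h/2| < slab_half_width contributes; pixel lookup then falls back to
    the nearest in-slab element centroid.
    """
    if mesh.dimension == 2:
        return mesh.nodes, mesh.elements, np.arange(mesh.n_elements)
    z0 = (mesh.height or 1.0) / 2.0
    cz = mesh.element_centroids()[:, 2]
    keep = np.where(np.abs(cz - z0) < slab_half_width)[0]
    return None, None, keep


def rasterize(mesh: Mesh, delta_sigma: np.ndarray, grid_size: int = 32,
              slab_half_width: float = 0.15) -> ReconImage:
    """Sample the element-wise conductivity change onto a square pixel grid.

    Each in-disk pixel takes the value of the element containing its center
    (2D) or of the nearest electrode-plane-slab element (3D); pixels outside
    the unit disk are masked out (NaN).
    """
    if grid_size < 8:
        raise ValueError("grid_size must be at least 8")
    delta_sigma = np.asarray(delta_sigma, dtype=float)
    if delta_sigma.shape != (mesh.n_elements,):
        raise ValueError("delta_sigma must have one value per element")
    g = grid_size
    step = 2.0 / g
    c = -1.0 + step * (np.arange(g) + 0.5)
    X, Y = np.meshgrid(c, c)                      # row i = y index
    mask = X ** 2 + Y ** 2 <= 1.0
    values = np.full((g, g), np.nan)

    if mesh.dimension == 2:
        tri = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.elements)
        finder = TrapezoidMapTriFinder(tri)
        el = finder(X[mask], Y[mask])
        vals = np.where(el >= 0, delta_sigma[np.clip(el, 0, None)], np.nan)
        if np.any(el < 0):
            # pixel centers in the sliver between hull chords: nearest centroid
            tree = cKDTree(mesh.element_centroids())
            pts = np.column_stack([X[mask][el < 0], Y[mask][el < 0]])
            _, nearest = tree.query(pts)
            vals[el < 0] = delta_sigma[nearest]
        values[mask] = vals
    else:
        _, _, keep = _slice_elements(mesh, slab_half_width)
        cent = mesh.element_centroids()[keep][:, :2]
        tree = cKDTree(cent)
        pts = np.column_stack([X[mask], Y[mask]])
        _, nearest = tree.query(pts)
        values[mask] = delta_sigma[keep][nearest]
    return ReconImage(values=values, mask=mask, grid_size=g)


def center_cut(image: ReconImage) -> Profile:
    """The in-mask image row nearest y = 0, left to right."""
    xs, ys = image.pixel_coords()
    row = int(np.argmin(np.abs(ys)))
    sel = image.mask[row]
    return Profile(x=xs[sel], values=image.values[row, sel])
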