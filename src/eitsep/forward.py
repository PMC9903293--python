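"""Adjacent-drive protocol and linear-FEM forward solution.

Current of unit amplitude is injected through consecutive electrode pairs;
for each injection the differential voltages of the 13 adjacent electrode
pairs not carrying current are recorded, giving the 16 x 13 = 208 values of
one frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from eitsep.mesh import Mesh


@dataclass(frozen=True)
class Protocol:
    """Adjacent stimulation/measurement pattern.

    ``stim_pairs[k] = (k, k+1 mod n)``; ``meas_pairs[k]`` lists, in increasing
    order starting just after the stim pair, every adjacent pair sharing no
    electrode with it. ``flat index = 13*stim + meas`` for the 16-electrode
    case.
    """

    n_electrodes: int
    stim_pairs: tuple[tuple[int, int], ...]
    meas_pairs: tuple[tuple[tuple[int, int], ...], ...]

    @property
    def n_meas_per_stim(self) -> int:
        return len(self.meas_pairs[0])

    @property
    def flat_length(self) -> int:
        return sum(len(m) for m in self.meas_pairs)

    def flat_index(self, stim: int, meas: int) -> int:
        return stim * self.n_meas_per_stim + meas


@dataclass(frozen=True)
class Frame:
    """One complete acquisition: ordered differential voltages + protocol."""

    values: np.ndarray
    protocol: Protocol
    label: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size != self.protocol.flat_length:
            raise ValueError(
                f"frame must hold exactly {self.protocol.flat_length} values, "
                f"got {v.size}")
        if not np.all(np.isfinite(v)):
            raise ValueError("frame contains non-finite values")


def adjacent_protocol(n_electrodes: int = 16) -> Protocol:
    """Build the adjacent (neighboring) drive protocol.

    For 16 electrodes this yields 16 stimulation pairs with 13 measurements
    each: 208 values per frame.
    """
    n = n_electrodes
    if n < 8 or n % 2:
        raise ValueError("n_electrodes must be even and >= 8")
    stim_pairs = tuple((k, (k + 1) % n) for k in range(n))
    meas_pairs = []
    for k in range(n):
        banned = {k, (k + 1) % n}
        block = []
        for step in range(n):
            m = (k + 2 + step) % n
            pair = (m, (m + 1) % n)
            if banned & set(pair):
                continue
            block.append(pair)
        meas_pairs.append(tuple(block))
    return Protocol(n_electrodes=n, stim_pairs=stim_pairs,
                    meas_pairs=tuple(meas_pairs))


def _element_gradients(mesh: Mesh):
    """Per-element shape-function gradients and volumes for P1 elements.

    Returns (grads, vols): grads has shape (n_el, dim+1, dim) with
    grads[e, i] = grad of the barycentric basis of local node i.
    """
    pts = mesh.nodes[mesh.elements]          # (n_el, dim+1, dim)
    edges = pts[:, 1:, :] - pts[:, :1, :]
    dim = mesh.dimension
    det = np.linalg.det(edges)
    vols = det / (2.0 if dim == 2 else 6.0)
    inv = np.linalg.inv(edges)               # (n_el, dim, dim)
    g_rest = np.swapaxes(inv, 1, 2)          # grad of nodes 1..dim
    g0 = -g_rest.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g_rest], axis=1)
    return grads, vols


def assemble_system(mesh: Mesh, sigma: np.ndarray) -> sp.csr_matrix:
    """Sparse FEM conductance matrix for the Laplace operator div(sigma grad u).

    Symmetric positive-semidefinite with a one-dimensional constant null
    space on a connected mesh.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (mesh.n_elements,):
        raise ValueError("sigma must have one value per element")
    if np.any(sigma <= 0):
        raise ValueError("conductivity must be positive everywhere")
    grads, vols = _element_gradients(mesh)
    if np.any(vols <= 0):
        raise ValueError("mesh contains degenerate or inverted elements")
    # local stiffness K_e[i,j] = sigma_e * vol_e * grad_i . grad_j
    local = np.einsum("eid,ejd->eij", grads, grads)
    local *= (sigma * vols)[:, None, None]
    nloc = mesh.dimension + 1
    rows = np.repeat(mesh.elements, nloc, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, nloc)).ravel()
    A = sp.coo_matrix((local.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return A.tocsr()


def _ground_node(mesh: Mesh) -> int:
    """A boundary node belonging to no electrode group (potential reference)."""
    r = np.linalg.norm(mesh.nodes[:, :2], axis=1)
    boundary = set(np.where(np.abs(r - 1.0) < 1e-9)[0])
    for group in mesh.electrode_nodes:
        boundary -= set(int(i) for i in group)
    if not boundary:
        raise RuntimeError("no non-electrode boundary node available to ground")
    return min(boundary)


def _electrode_potentials(mesh: Mesh, A: sp.csr_matrix,
                          current: float = 1.0) -> np.ndarray:
    """Electrode-averaged potentials for every adjacent-pair drive.

    Returns (n_electrodes, n_electrodes): row d holds the 16 electrode
    potentials when unit current enters electrode d and leaves d+1.
    """
    n_el = mesh.n_electrodes
    ground = _ground_node(mesh)
    A = A.tolil(copy=True)
    A[ground, :] = 0.0
    A[:, ground] = 0.0
    A[ground, ground] = 1.0
    lu = splu(A.tocsc())

    rhs = np.zeros((mesh.n_nodes, n_el))
    for d in range(n_el):
        src, snk = mesh.electrode_nodes[d], mesh.electrode_nodes[(d + 1) % n_el]
        rhs[src, d] += current / len(src)
        rhs[snk, d] -= current / len(snk)
    rhs[ground, :] = 0.0
    u = lu.solve(rhs)                        # (n_nodes, n_drives)
    pots = np.empty((n_el, n_el))
    for e in range(n_el):
        pots[:, e] = u[mesh.electrode_nodes[e], :].mean(axis=0)
    return pots


def solve_forward(mesh: Mesh, sigma: np.ndarray,
                  protocol: Protocol | None = None,
                  current: float = 1.0, label: str | None = None) -> Frame:
    """Simulate one frame of adjacent-drive differential voltages.

    The gap (point-electrode) model injects the drive current at the
    electrode node group and reads voltages as node-potential differences;
    one non-electrode boundary node is grounded, which differential
    measurements make immaterial.
    """
    protocol = protocol or adjacent_protocol(mesh.n_electrodes)
    if protocol.n_electrodes != mesh.n_electrodes:
        raise ValueError("protocol / mesh electrode-count mismatch")
    A = assemble_system(mesh, sigma)
    pots = _electrode_potentials(mesh, A, current=current)
    values = np.empty(protocol.flat_length)
    for s, block in enumerate(protocol.meas_pairs):
        for m, (a, b) in enumerate(block):
            values[protocol.flat_index(s, m)] = pots[s, a] - pots[s, b]
    return Frame(values=values, protocol=protocol, label=label)


def simulate_sequence(mesh: Mesh, specs, protocol: Protocol | None = None,
                      noise_std: float = 0.0,
                      rng: np.random.Generator | None = None):
    """Frames for a breathing sequence plus the homogeneous reference frame.

    Returns ``(frames, reference)``. Optional additive Gaussian noise with
    standard deviation ``noise_std`` (absolute voltage units) is applied to
    the sequence frames only.
    """
    from eitsep.mesh import assign_phantom

    protocol = protocol or adjacent_protocol(mesh.n_electrodes)
    if specs:
        bg = specs[0].background_conductivity
    else:
        bg = 1.0
    reference = solve_forward(
        mesh, np.full(mesh.n_elements, bg), protocol, label="reference")
    frames = []
    for i, spec in enumerate(specs):
        sigma = assign_phantom(mesh, spec)
        frame = solve_forward(mesh, sigma, protocol, label=f"frame{i}")
        if noise_std > 0:
            if rng is None:
                rng = np.random.default_rng()
            frame = Frame(values=frame.values + rng.normal(0, noise_std, frame.values.size),
                          protocol=protocol, label=frame.label)
        frames.append(frame)
    return frames, reference
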