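"""Plain-text I/O for frames, meshes, images and profiles, plus MAT loading.

Frame CSV dialect: UTF-8, '.' decimal, header row ``stim_index,meas_index,
voltage``; rows may appear in any order and are restored to the canonical
protocol flat order on read.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from eitsep.mesh import Mesh
from eitsep.forward import Frame, Protocol, adjacent_protocol
from eitsep.inverse import ReconImage, Profile


def write_frame(frame: Frame, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["stim_index", "meas_index", "voltage"])
        prot = frame.protocol
        for s in range(prot.n_electrodes):
            for m in range(prot.n_meas_per_stim):
                w.writerow([s, m, repr(float(frame.values[prot.flat_index(s, m)]))])


def read_frame(path, protocol: Protocol | None = None) -> Frame:
    protocol = protocol or adjacent_protocol(16)
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != [
                "stim_index", "meas_index", "voltage"]:
            raise ValueError(f"{path}: missing frame CSV header")
        values = np.full(protocol.flat_length, np.nan)
        n_rows = 0
        for row in reader:
            if not row:
                continue
            try:
                s, m, v = int(row[0]), int(row[1]), float(row[2])
            except (ValueError, IndexError) as err:
                raise ValueError(f"{path}: non-numeric or short row {row!r}") from err
            if not (0 <= s < protocol.n_electrodes
                    and 0 <= m < protocol.n_meas_per_stim):
                raise ValueError(f"{path}: stim/meas index out of range in {row!r}")
            values[protocol.flat_index(s, m)] = v
            n_rows += 1
    if n_rows != protocol.flat_length or np.isnan(values).any():
        raise ValueError(
            f"{path}: expected exactly {protocol.flat_length} measurements "
            f"covering every (stim, meas) pair, got {n_rows} rows")
    return Frame(values=values, protocol=protocol, label=path.stem)


def save_mesh(mesh: Mesh, path) -> None:
    """Single-file text archive: NODES / ELEMENTS / ELECTRODE sections.

    Node lines hold coordinates, element lines node indices, electrode lines
    the ordered node group of one electrode.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# eitsep mesh dimension={mesh.dimension} "
                 f"height={mesh.height if mesh.height is not None else ''}\n")
        fh.write(f"NODES {mesh.n_nodes}\n")
        for p in mesh.nodes:
            fh.write(" ".join(repr(float(c)) for c in p) + "\n")
        fh.write(f"ELEMENTS {mesh.n_elements}\n")
        for el in mesh.elements:
            fh.write(" ".join(str(int(i)) for i in el) + "\n")
        fh.write(f"ELECTRODES {mesh.n_electrodes}\n")
        for g in mesh.electrode_nodes:
            fh.write(" ".join(str(int(i)) for i in g) + "\n")


def load_mesh(path) -> Mesh:
    path = Path(path)
    lines = path.read_text().splitlines()
    header = lines[0]
    dim = int(header.split("dimension=")[1].split()[0])
    hfield = header.split("height=")[1].strip()
    height = float(hfield) if hfield else None
    i = 1
    assert lines[i].startswith("NODES")
    n = int(lines[i].split()[1]); i += 1
    nodes = np.array([[float(c) for c in lines[i + k].split()] for k in range(n)])
    i += n
    assert lines[i].startswith("ELEMENTS")
    m = int(lines[i].split()[1]); i += 1
    elements = np.array([[int(c) for c in lines[i + k].split()] for k in range(m)],
                        dtype=np.int64)
    i += m
    assert lines[i].startswith("ELECTRODES")
    ne = int(lines[i].split()[1]); i += 1
    groups = tuple(np.array([int(c) for c in lines[i + k].split()], dtype=np.int64)
                   for k in range(ne))
    return Mesh(nodes=nodes, elements=elements, electrode_nodes=groups,
                dimension=dim, height=height)


def write_image(image: ReconImage, path) -> None:
    """CSV grid (row-major, NaN for masked pixels)."""
    np.savetxt(path, image.values, delimiter=",")


def read_image(path) -> ReconImage:
    values = np.loadtxt(path, delimiter=",")
    g = values.shape[0]
    if values.shape != (g, g):
        raise ValueError("image CSV must be square")
    step = 2.0 / g
    c = -1.0 + step * (np.arange(g) + 0.5)
    X, Y = np.meshgrid(c, c)
    mask = X ** 2 + Y ** 2 <= 1.0
    return ReconImage(values=np.where(mask, values, np.nan), mask=mask, grid_size=g)


def write_image_png(image: ReconImage, path, title: str | None = None) -> None:
    """Diverging-colormap rendering with masked corners transparent."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    v = np.ma.masked_invalid(image.values)
    lim = float(np.abs(v).max()) or 1.0
    ax.imshow(v, origin="lower", extent=(-1, 1, -1, 1), cmap="RdBu_r",
              vmin=-lim, vmax=lim)
    ax.set_xticks([]); ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=100, bbox_inches="tight", transparent=True)
    plt.close(fig)


def write_profile(profile: Profile, path) -> None:
    np.savetxt(path, np.column_stack([profile.x, profile.values]),
               delimiter=",", header="x,value", comments="")


def load_eidors_sample(path, protocol: Protocol | None = None) -> list[Frame]:
    """Load a MAT-container acquisition (frames x measurements) as Frames.

    Best-effort interface for 16-electrode adjacent-drive sample datasets:
    the first 2-D numeric array with a 208-compatible axis is used; frames
    are returned in acquisition order.
    """
    from scipy.io import loadmat

    protocol = protocol or adjacent_protocol(16)
    try:
        mat = loadmat(path)
    except Exception as err:
        raise ValueError(f"unreadable MAT container {path}") from err
    want = protocol.flat_length
    for key, arr in mat.items():
        if key.startswith("__") or not isinstance(arr, np.ndarray):
            continue
        arr = np.asarray(arr)
        if arr.ndim != 2 or not np.issubdtype(arr.dtype, np.number):
            continue
        if arr.shape[1] == want:
            data = arr.real.astype(float)
        elif arr.shape[0] == want:
            data = arr.real.astype(float).T
        else:
            continue
        return [Frame(values=row, protocol=protocol, label=f"frame{i}")
                for i, row in enumerate(data)]
    shapes = {k: v.shape for k, v in mat.items()
              if isinstance(v, np.ndarray) and not k.startswith("__")}
    raise ValueError(
        f"no frames-by-{want}-measurements array found in {path} "
        f"(arrays present: {shapes})")
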