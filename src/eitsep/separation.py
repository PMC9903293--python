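"""Pre-reconstruction separation of cardiac and ventilatory voltage content.

A single raw 208-voltage frame is decomposed either

* as a 13 x 16 measurement matrix (rows = the 13 measurement positions,
  columns = the 16 current-injection pairs) via PCA on the column-centered
  covariance, or
* as a serial 208-sample signal via empirical mode decomposition (EMD,
  classic cubic-spline sifting),

and recomposed with per-component weights. The ventilation (lung) signal
concentrates in one dominant component — PC4 for the PCA path and IMF1 for
the EMD path under the default policies — so zeroing it yields a
cardiac-selective frame, and boosting it slightly (gain 1.01) yields a
ventilation-selective frame.

Component indices in the public API are 1-based ("PC4", "IMF1").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from eitsep.forward import Frame, Protocol, adjacent_protocol

#: lung-dominant principal component (1-based) under the default phantom
LUNG_PC = 4
#: lung-dominant intrinsic mode function (1-based)
LUNG_IMF = 1


# --------------------------------------------------------------------------
# frame <-> measurement matrix

def frame_to_matrix(frame: Frame | np.ndarray,
                    protocol: Protocol | None = None) -> np.ndarray:
    """Reshape a 208-value frame to the 13 x 16 measurement matrix.

    Entry (m, s) is measurement m of stimulation block s, so columns follow
    the current-injection index.
    """
    if isinstance(frame, Frame):
        values, protocol = frame.values, frame.protocol
    else:
        values = np.asarray(frame, dtype=float)
        protocol = protocol or adjacent_protocol(16)
    if values.size != protocol.flat_length:
        raise ValueError(
            f"expected {protocol.flat_length} values, got {values.size}")
    n_meas, n_stim = protocol.n_meas_per_stim, protocol.n_electrodes
    return values.reshape(n_stim, n_meas).T.copy()


def matrix_to_frame(matrix: np.ndarray, protocol: Protocol | None = None,
                    label: str | None = None) -> Frame:
    """Inverse of :func:`frame_to_matrix`."""
    protocol = protocol or adjacent_protocol(16)
    matrix = np.asarray(matrix, dtype=float)
    expected = (protocol.n_meas_per_stim, protocol.n_electrodes)
    if matrix.shape != expected:
        raise ValueError(f"expected matrix of shape {expected}, got {matrix.shape}")
    return Frame(values=matrix.T.reshape(-1), protocol=protocol, label=label)


# --------------------------------------------------------------------------
# PCA path

@dataclass(frozen=True)
class PCADecomposition:
    """Eigen-decomposition of the column-centered measurement matrix.

    ``eigenvectors`` columns are the 16 principal directions in injection
    space (descending eigenvalue); ``scores`` is the 13 x 16 projection of
    the centered data. Completeness: ``recompose(ones) == input`` exactly up
    to round-off.
    """

    column_means: np.ndarray           # (16,)
    eigenvectors: np.ndarray           # (16, 16), columns = components
    eigenvalues: np.ndarray            # (16,), descending, >= 0
    scores: np.ndarray                 # (13, 16)

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def explained_share(self) -> np.ndarray:
        """Cumulative eigenvalue share, in [0, 1]."""
        total = self.eigenvalues.sum()
        return np.cumsum(self.eigenvalues) / total

    def significant_components(self, rel_tol: float = 1e-10) -> int:
        return int(np.sum(self.eigenvalues > rel_tol * self.eigenvalues.max()))


def pca_decompose(matrix: np.ndarray) -> PCADecomposition:
    """PCA of the 13 x 16 measurement matrix.

    Columns (injections) are the variables, rows (measurement positions) the
    observations: each column is mean-centered over its 13 rows and the
    16 x 16 covariance (normalization 1/(13-1)) is eigen-decomposed. A
    column-centered 13-row matrix has rank at most 12, so at most 12
    eigenvalues are significant. Eigenvector signs are fixed by making each
    component's largest-magnitude loading positive.
    """
    X = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("measurement matrix contains non-finite values")
    n_obs = X.shape[0]
    means = X.mean(axis=0)
    Xc = X - means
    cov = Xc.T @ Xc / (n_obs - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign convention
    flip = evecs[np.abs(evecs).argmax(axis=0), np.arange(evecs.shape[1])] < 0
    evecs[:, flip] *= -1.0
    scores = Xc @ evecs
    return PCADecomposition(column_means=means, eigenvectors=evecs,
                            eigenvalues=evals, scores=scores)


def pca_recompose(decomp: PCADecomposition,
                  weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted recomposition: means + sum_i w_i * score_i (x) eigvec_i."""
    n = decomp.n_components
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError(f"weights must have length {n}")
    return decomp.column_means + (decomp.scores * weights) @ decomp.eigenvectors.T


def _pca_weighted_frame(frame: Frame, component: int, weight: float) -> Frame:
    decomp = pca_decompose(frame_to_matrix(frame))
    if not 1 <= component <= decomp.n_components:
        raise ValueError(
            f"component must be in 1..{decomp.n_components} (got {component})")
    w = np.ones(decomp.n_components)
    w[component - 1] = weight
    out = pca_recompose(decomp, w)
    return matrix_to_frame(out, frame.protocol, label=frame.label)


def separate_heart_pca(frame: Frame, component: int = LUNG_PC) -> Frame:
    """Cardiac-selective frame: remove the lung-dominant principal component.

    Recomposes with weight 0 on PC ``component`` (1-based, default PC4) and
    1 on all others.
    """
    return _pca_weighted_frame(frame, component, 0.0)


def separate_lung_pca(frame: Frame, gain: float = 1.01,
                      component: int = LUNG_PC) -> Frame:
    """Ventilation-selective frame: boost the lung-dominant PC by ``gain``."""
    if gain < 0:
        raise ValueError("gain must be non-negative")
    return _pca_weighted_frame(frame, component, gain)


# --------------------------------------------------------------------------
# EMD path

@dataclass(frozen=True)
class EMDDecomposition:
    """Intrinsic mode functions + residue of a serial frame.

    IMF1 is the fastest-oscillating mode. Completeness: the IMFs plus the
    residue sum back to the input signal.
    """

    imfs: tuple[np.ndarray, ...]
    residue: np.ndarray
    sift_counts: tuple[int, ...] = ()

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray):
    """Indices of strict local maxima and minima (plateaus collapse to one)."""
    dx = np.diff(x)
    # collapse exact plateaus by propagating the previous slope sign
    sign = np.sign(dx)
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    sc = sign[1:] - sign[:-1]
    maxima = np.where(sc < 0)[0] + 1
    minima = np.where(sc > 0)[0] + 1
    return maxima, minima


def _mirrored_envelope(x: np.ndarray, extrema: np.ndarray, t: np.ndarray,
                       n_mirror: int = 2) -> np.ndarray:
    """Cubic-spline envelope through ``extrema`` with mirror end extension.

    The first/last ``n_mirror`` extrema are reflected about the signal's end
    points so the spline is supported beyond both ends.
    """
    idx = extrema.astype(float)
    vals = x[extrema]
    n = x.size
    k = min(n_mirror, idx.size)
    left_t = 2 * 0.0 - idx[:k][::-1] - 0.0    # reflect about t=0
    left_v = vals[:k][::-1]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    right_v = vals[-k:][::-1]
    tt = np.concatenate([left_t, idx, right_t])
    vv = np.concatenate([left_v, vals, right_v])
    tt, keep = np.unique(tt, return_index=True)
    vv = vv[keep]
    if tt.size < 2:
        return np.full(n, vv[0] if vv.size else 0.0)
    if tt.size < 4:
        spline = CubicSpline(tt, vv, bc_type="natural")
    else:
        spline = CubicSpline(tt, vv)
    return spline(t)


def zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))


def emd_decompose(signal: np.ndarray, sd_threshold: float = 0.2,
                  max_sifts: int = 10, max_imfs: int = 32,
                  n_mirror: int = 2) -> EMDDecomposition:
    """Empirical mode decomposition by classic sifting.

    Upper/lower envelopes are cubic splines through the local maxima/minima
    with ``n_mirror`` extrema mirrored past each end; a candidate is sifted
    until the Cauchy criterion SD = sum((h_prev-h)^2)/sum(h_prev^2) drops
    below ``sd_threshold`` or ``max_sifts`` iterations are reached. IMFs are
    extracted until the residue is monotone or has fewer than 3 extrema.
    A monotone input yields no IMFs and residue == input.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("signal must be 1-D with at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    t = np.arange(x.size, dtype=float)
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    residue = x.copy()
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residue)
        if maxima.size + minima.size < 3 or maxima.size < 2 or minima.size < 2:
            break
        h = residue.copy()
        n_sift = 0
        while n_sift < max_sifts:
            mx, mn = _local_extrema(h)
            if mx.size < 2 or mn.size < 2:
                break
            upper = _mirrored_envelope(h, mx, t, n_mirror)
            lower = _mirrored_envelope(h, mn, t, n_mirror)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            n_sift += 1
            denom = np.sum(h ** 2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        counts.append(n_sift)
        residue = residue - h
    return EMDDecomposition(imfs=tuple(imfs), residue=residue,
                            sift_counts=tuple(counts))


def emd_recompose(decomp: EMDDecomposition, weights: np.ndarray | None = None,
                  residue_weight: float = 1.0) -> np.ndarray:
    """Weighted sum of IMFs plus the (weighted) residue."""
    n = decomp.n_imfs
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError(f"weights must have length {n}")
    out = residue_weight * decomp.residue
    for w, imf in zip(weights, decomp.imfs):
        out = out + w * imf
    return out


def _emd_weighted_frame(frame: Frame, component: int, weight: float,
                        **emd_kwargs) -> Frame:
    decomp = emd_decompose(frame.values, **emd_kwargs)
    w = np.ones(decomp.n_imfs)
    if decomp.n_imfs >= component:
        w[component - 1] = weight
    values = emd_recompose(decomp, w, residue_weight=1.0)
    return Frame(values=values, protocol=frame.protocol, label=frame.label)


def separate_heart_emd(frame: Frame, component: int = LUNG_IMF,
                       **emd_kwargs) -> Frame:
    """Cardiac-selective frame: drop the lung-dominant IMF (default IMF1).

    All other IMFs and the residue are kept at weight 1, so
    ``output + IMF1 == input`` exactly.
    """
    return _emd_weighted_frame(frame, component, 0.0, **emd_kwargs)


def separate_lung_emd(frame: Frame, gain: float = 1.01,
                      component: int = LUNG_IMF, **emd_kwargs) -> Frame:
    """Ventilation-selective frame: scale the lung-dominant IMF by ``gain``."""
    if gain < 0:
        raise ValueError("gain must be non-negative")
    return _emd_weighted_frame(frame, component, gain, **emd_kwargs)
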