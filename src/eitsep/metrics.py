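"""GREIT figures of merit for reconstructed difference images.

An image is scored against a known circular target (positive sign for the
heart, negative for a lung) through its quarter-amplitude pixel set: the
in-mask pixels whose signed amplitude reaches one quarter of the image
maximum in the expected sign.

All lengths are in domain-radius units, so the reported figures are
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from eitsep.inverse import ReconImage


@dataclass(frozen=True)
class TargetSpec:
    """The simulated target disk an image is compared against."""

    center: tuple[float, float]
    radius: float
    sign: int = +1

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("target radius must be positive")
        if np.hypot(*self.center) >= 1.0:
            raise ValueError("target center must lie inside the unit disk")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass(frozen=True)
class FOMReport:
    """Figures of merit for one image/target pair.

    PE — distance from target center to the quarter-set centroid;
    SD — fraction of quarter-set amplitude outside the equal-area circle;
    RNG — opposite-sign amplitude outside that circle over same-sign
    amplitude inside it; AR, RES reported alongside.
    """

    PE: float
    SD: float
    RNG: float
    AR: float
    RES: float

    def as_dict(self) -> dict:
        return asdict(self)


def quarter_amplitude_set(image: ReconImage, sign: int = +1) -> np.ndarray:
    """Boolean mask of pixels with sign*value >= 1/4 of the signed maximum."""
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    vals = np.where(image.mask, image.values, np.nan)
    signed = sign * vals
    peak = np.nanmax(signed)
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("image has no pixel of the expected sign")
    with np.errstate(invalid="ignore"):
        return image.mask & (signed >= 0.25 * peak)


def figures_of_merit(image: ReconImage, target: TargetSpec,
                     weighted_centroid: bool = True) -> FOMReport:
    """Score an image against a target disk.

    The quarter-amplitude set defines the reconstructed blob; its
    (amplitude-weighted) centroid and the circle C of equal area centered
    there define PE, SD and RNG as documented on :class:`FOMReport`.
    """
    q = quarter_amplitude_set(image, target.sign)
    if not q.any():
        raise ValueError("degenerate (empty) quarter-amplitude set")
    xs, ys = image.pixel_coords()
    X, Y = np.meshgrid(xs, ys)
    vals = np.where(image.mask, image.values, 0.0)
    signed = target.sign * vals

    amp_q = signed[q]
    w = amp_q if weighted_centroid else np.ones_like(amp_q)
    cx = float(np.sum(w * X[q]) / np.sum(w))
    cy = float(np.sum(w * Y[q]) / np.sum(w))
    pe = float(np.hypot(cx - target.center[0], cy - target.center[1]))

    # circle C of area equal to the quarter set, centered at its centroid
    area_q = q.sum() * image.pixel_area
    rc = np.sqrt(area_q / np.pi)
    in_c = image.mask & ((X - cx) ** 2 + (Y - cy) ** 2 <= rc ** 2)

    sd = float(np.sum(signed[q & ~in_c]) / np.sum(amp_q))

    same_in_c = np.sum(np.clip(signed[in_c], 0.0, None))
    opp_outside = np.sum(np.clip(-signed[image.mask & ~in_c], 0.0, None))
    rng = float(opp_outside / same_in_c) if same_in_c > 0 else np.inf

    ar = float(np.sum(amp_q))
    res = float(np.sqrt(q.sum() / image.mask.sum()))
    return FOMReport(PE=pe, SD=sd, RNG=rng, AR=ar, RES=res)
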