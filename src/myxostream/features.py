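"""Per-pixel feature fields: speed, nematic alignment, density.

Three rasters are derived from consecutive persistence images and feed the
stream mask:

* **speed** — dense optical flow between consecutive frames (iterative
  Lucas-Kanade: local brightness-constancy least squares with Gaussian
  neighborhood weighting), reported as per-pixel displacement magnitude in
  px/frame;
* **alignment** — nematic orientation estimated per small window from the
  second moment of the DC-suppressed windowed power spectrum (stripes
  concentrate spectral power along their normal, so the reported cell
  orientation is perpendicular to the dominant spectral axis), then a
  scalar nematic order parameter S = |<exp(2i*theta)>| over a neighborhood
  of orientation vectors, upsampled to pixel resolution;
* **density** — Gaussian-smoothed intensity (sigma 10 px by default) that
  blurs individual cells into a local density estimate.

Axis convention: x is the column axis, y the row axis (y increases
downward); angles are measured from +x toward +y and reported modulo pi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import optical_flow_ilk
from skimage.transform import resize

logger = logging.getLogger(__name__)

__all__ = [
    "SpeedField",
    "OrientationField",
    "AlignmentField",
    "DensityField",
    "optical_flow_speed",
    "local_orientation",
    "order_parameter",
    "density_field",
]


@dataclass
class SpeedField:
    """Dense optical-flow result: components and magnitude, px/frame."""

    vx: np.ndarray
    vy: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


@dataclass
class OrientationField:
    """Nematic orientation on a grid of window centers.

    ``theta`` is in [0, pi); ``weight`` is the spectral anisotropy of each
    window in [0, 1] (0 for an isotropic spectrum — the angle is then
    meaningless but still defined). ``centers_y``/``centers_x`` give the
    pixel coordinates of the grid nodes.
    """

    theta: np.ndarray
    weight: np.ndarray
    centers_y: np.ndarray
    centers_x: np.ndarray
    window_px: int
    grid_spacing_px: int


@dataclass
class AlignmentField:
    """Nematic scalar order parameter S in [0, 1] at pixel resolution."""

    S: np.ndarray
    S_grid: np.ndarray
    neighborhood_radius: int = 2


@dataclass
class DensityField:
    """Gaussian-smoothed intensity raster."""

    rho: np.ndarray
    sigma_px: float = 10.0


def optical_flow_speed(
    frame_a: np.ndarray, frame_b: np.ndarray, radius: int = 7
) -> SpeedField:
    """Dense optical flow from ``frame_a`` to ``frame_b``.

    Positive ``vx`` means content moving toward larger column index,
    positive ``vy`` toward larger row index. Constant frames carry no
    gradient information; the flow is then zero and a warning is logged.
    """
    frame_a = np.asarray(frame_a, dtype=np.float64)
    frame_b = np.asarray(frame_b, dtype=np.float64)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have equal shapes")
    if np.ptp(frame_a) == 0 and np.ptp(frame_b) == 0:
        logger.warning("constant frames: optical flow undefined, returning zero field")
        z = np.zeros_like(frame_a)
        return SpeedField(vx=z, vy=z.copy())
    if np.array_equal(frame_a, frame_b):
        z = np.zeros_like(frame_a)
        return SpeedField(vx=z, vy=z.copy())
    vy, vx = optical_flow_ilk(frame_a, frame_b, radius=radius)
    return SpeedField(vx=vx, vy=vy)


def _window_starts(size: int, window_px: int, spacing: int) -> np.ndarray:
    return np.arange(0, size - window_px + 1, spacing)


def local_orientation(
    frame: np.ndarray, window_px: int = 15, overlap: float = 0.70
) -> OrientationField:
    """Windowed-FFT nematic orientation field.

    The frame is tiled with ``window_px`` windows whose spacing is
    ``round((1-overlap)*window_px)`` (5 px for the 15-px / 70% default).
    Each window is Hann-tapered and Fourier transformed; the second-moment
    (inertia) tensor of the DC-suppressed power spectrum gives the dominant
    spectral axis, and the cell orientation is reported perpendicular to
    it, modulo pi. The anisotropy weight (lambda1-lambda2)/(lambda1+lambda2)
    of the tensor is returned alongside: near 0 for isotropic windows.
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    if h < window_px or w < window_px:
        raise ValueError(f"frame smaller than window ({window_px} px)")
    spacing = max(1, int(np.floor((1.0 - overlap) * window_px + 0.5)))
    ys = _window_starts(h, window_px, spacing)
    xs = _window_starts(w, window_px, spacing)

    hann = np.hanning(window_px)
    taper = np.outer(hann, hann)
    # spectral coordinates, DC at the center after fftshift
    k = np.fft.fftshift(np.fft.fftfreq(window_px))
    ky, kx = np.meshgrid(k, k, indexing="ij")
    dc = (np.abs(kx) < 1e-12) & (np.abs(ky) < 1e-12)

    theta = np.zeros((len(ys), len(xs)))
    weight = np.zeros_like(theta)
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            win = frame[y0 : y0 + window_px, x0 : x0 + window_px]
            win = (win - win.mean()) * taper
            power = np.abs(np.fft.fftshift(np.fft.fft2(win))) ** 2
            power[dc] = 0.0
            total = power.sum()
            if total <= 0:
                theta[i, j] = 0.0
                weight[i, j] = 0.0
                continue
            mxx = np.sum(power * kx * kx) / total
            myy = np.sum(power * ky * ky) / total
            mxy = np.sum(power * kx * ky) / total
            # principal axis of the spectral inertia tensor = stripe normal
            spec_angle = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)
            lam = np.sqrt(((mxx - myy) / 2.0) ** 2 + mxy**2)
            mean_lam = (mxx + myy) / 2.0
            weight[i, j] = lam / mean_lam if mean_lam > 0 else 0.0
            theta[i, j] = (spec_angle + np.pi / 2.0) % np.pi
    centers = window_px // 2
    return OrientationField(
        theta=theta,
        weight=weight,
        centers_y=ys + centers,
        centers_x=xs + centers,
        window_px=window_px,
        grid_spacing_px=spacing,
    )


def order_parameter(
    orient: OrientationField | np.ndarray,
    neighborhood: int = 2,
    out_shape: tuple[int, int] | None = None,
) -> AlignmentField:
    """Nematic scalar order parameter over square angle neighborhoods.

    For each grid node, S = sqrt(<cos 2theta>^2 + <sin 2theta>^2) averaged
    over the (2*neighborhood+1)^2 surrounding orientation vectors; edge
    nodes use truncated neighborhoods. All windows contribute with equal
    weight. S is 1 for identical angles, and decays as 1/sqrt(n) toward 0
    for uniform-random angles. If ``out_shape`` is given (or an
    :class:`OrientationField` is passed) the grid is bilinearly upsampled
    to pixel resolution.
    """
    if isinstance(orient, OrientationField):
        theta = orient.theta
        if out_shape is None and orient.centers_y.size and orient.centers_x.size:
            out_shape = (
                int(orient.centers_y[-1] + orient.window_px // 2 + 1),
                int(orient.centers_x[-1] + orient.window_px // 2 + 1),
            )
    else:
        theta = np.asarray(orient, dtype=np.float64)
    size = 2 * neighborhood + 1
    c = np.cos(2.0 * theta)
    s = np.sin(2.0 * theta)
    kernel = np.ones((size, size))
    # truncated-neighborhood mean: divide by the in-bounds vector count
    counts = ndimage.convolve(np.ones_like(c), kernel, mode="constant", cval=0.0)
    cm = ndimage.convolve(c, kernel, mode="constant", cval=0.0) / counts
    sm = ndimage.convolve(s, kernel, mode="constant", cval=0.0) / counts
    S_grid = np.clip(np.hypot(cm, sm), 0.0, 1.0)
    if out_shape is None:
        S = S_grid
    else:
        S = np.clip(resize(S_grid, out_shape, order=1, mode="edge", anti_aliasing=False), 0.0, 1.0)
    return AlignmentField(S=S, S_grid=S_grid, neighborhood_radius=neighborhood)


def density_field(frame: np.ndarray, sigma_px: float = 10.0) -> DensityField:
    """Gaussian-smoothed intensity with reflective boundary handling."""
    frame = np.asarray(frame, dtype=np.float64)
    rho = ndimage.gaussian_filter(frame, sigma=sigma_px, mode="reflect")
    return DensityField(rho=rho, sigma_px=sigma_px)
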