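"""Scalp-time images: 2D electrode projection, linear interpolation onto a
standardised 32 x 32 scalp grid, and anisotropic Gaussian smoothing.

Electrode positions are flattened with an azimuthal-equidistant projection
(2D radius proportional to the polar angle from the vertex, azimuth
preserved) and scaled to land inside the grid: 32 x 32 pixels of
4.25 x 5.38 mm, x spanning -68..+68 mm (left to right) and y -98..+72 mm
(posterior to anterior).  Channel values are interpolated piecewise-linearly
(Delaunay barycentric) at pixel centres; pixels outside the convex hull of
the projected channels are masked rather than extrapolated.  Stacking the
interpolated planes over time gives the X x Y x time observation unit of the
mass-univariate analysis, smoothed with a separable Gaussian kernel
(default 9 mm x 9 mm x 20 ms FWHM) using mask-weighted (renormalised)
convolution so borders are not attenuated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

from touchersp.timefreq import BandPowerEpochs

NX, NY = 32, 32
PIXEL_MM = (4.25, 5.38)
X_EXTENT_MM = (-68.0, 68.0)
Y_MIN_MM = -98.0  # top edge = -98 + 32*5.38 = 74.16 (approx. the +72 of a
# 170-mm nominal extent; the pixel size is taken as exact)

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


class ScalpError(ValueError):
    """Labelled error from the scalp-imaging stage."""


@dataclass
class ScalpGrid:
    """Grid geometry plus the precomputed channel->pixel interpolation."""

    ch_names: list[str]
    ch_xy_mm: np.ndarray  # n_ch x 2 projected coordinates
    x_mm: np.ndarray  # NX pixel-centre x coordinates
    y_mm: np.ndarray  # NY pixel-centre y coordinates
    weights: np.ndarray  # (NX*NY) x n_ch barycentric weights, rows of zeros outside hull
    mask: np.ndarray  # NX x NY bool, True inside the convex hull

    @property
    def nx(self) -> int:
        return len(self.x_mm)

    @property
    def ny(self) -> int:
        return len(self.y_mm)

    def geometry_dict(self) -> dict:
        return {
            "nx": self.nx,
            "ny": self.ny,
            "pixel_mm": list(PIXEL_MM),
            "x_mm": [float(self.x_mm[0]), float(self.x_mm[-1])],
            "y_mm": [float(self.y_mm[0]), float(self.y_mm[-1])],
            "projection": "azimuthal_equidistant",
            "n_in_mask": int(self.mask.sum()),
        }


@dataclass
class ScalpTimeImages:
    """A stack of scalp-time images: ``data`` images x NX x NY x T (dB),
    NaN outside the scalp mask; ``labels`` one row per image."""

    data: np.ndarray
    t_ms: np.ndarray
    grid: ScalpGrid
    labels: pd.DataFrame
    subject: str = ""
    band: str = ""
    provenance: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Projection and interpolation
# ---------------------------------------------------------------------------


def _project_positions(montage: pd.DataFrame, projection: str, margin: float) -> np.ndarray:
    pos = montage[["x_m", "y_m", "z_m"]].to_numpy(dtype=float)
    r = np.linalg.norm(pos, axis=1)
    if np.any(r <= 0):
        raise ScalpError("montage contains a zero-radius electrode position")
    theta = np.arccos(np.clip(pos[:, 2] / r, -1.0, 1.0))  # polar angle from vertex
    rho_xy = np.hypot(pos[:, 0], pos[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(rho_xy > 0, pos[:, 0] / rho_xy, 0.0)
        uy = np.where(rho_xy > 0, pos[:, 1] / rho_xy, 0.0)
    if projection == "azimuthal_equidistant":
        rad = theta
    elif projection == "stereographic":
        rad = 2.0 * np.tan(theta / 2.0)
    else:
        raise ScalpError(f"unknown projection {projection!r}")
    u = rad * ux
    v = rad * uy
    # uniform scale: land every channel inside the (asymmetric) grid extents
    y_hi = Y_MIN_MM + NY * PIXEL_MM[1]
    limits = []
    for arr, lo, hi in ((u, X_EXTENT_MM[0], X_EXTENT_MM[1]), (v, Y_MIN_MM, y_hi)):
        amax, amin = arr.max(), arr.min()
        if amax > 0:
            limits.append(margin * hi / amax)
        if amin < 0:
            limits.append(margin * lo / amin)
    if not limits:
        raise ScalpError("degenerate montage: all electrodes project to the vertex")
    s = min(limits)
    return np.column_stack([u * s, v * s])


def project_electrodes(
    montage: pd.DataFrame,
    *,
    projection: str = "azimuthal_equidistant",
    margin: float = 0.92,
) -> ScalpGrid:
    """Flatten the 3D montage onto the standardised 32 x 32 scalp grid.

    The vertex maps to (0, 0); azimuth (hence left/right and
    anterior/posterior ordering) is preserved.  Raises on degenerate
    (coplanar through the vertex / < 3 usable) montages.
    """
    xy = _project_positions(montage, projection, margin)
    x_mm = X_EXTENT_MM[0] + PIXEL_MM[0] * (np.arange(NX) + 0.5)
    y_mm = Y_MIN_MM + PIXEL_MM[1] * (np.arange(NY) + 0.5)

    n_ch = len(xy)
    if n_ch < 3:
        raise ScalpError("interpolation needs >= 3 channels")
    try:
        tri = Delaunay(xy)
    except QhullError as exc:
        raise ScalpError(f"degenerate montage (collinear projections): {exc}") from exc

    gx, gy = np.meshgrid(x_mm, y_mm, indexing="ij")
    pix = np.column_stack([gx.ravel(), gy.ravel()])
    simplex = tri.find_simplex(pix)
    inside = simplex >= 0
    weights = np.zeros((NX * NY, n_ch))
    if inside.any():
        T = tri.transform[simplex[inside], :2]  # (m, 2, 2)
        r = pix[inside] - tri.transform[simplex[inside], 2]
        b = np.einsum("mij,mj->mi", T, r)
        bary = np.column_stack([b, 1.0 - b.sum(axis=1)])
        verts = tri.simplices[simplex[inside]]
        rows = np.repeat(np.flatnonzero(inside), 3)
        weights[rows, verts.ravel()] = bary.ravel()
    mask = inside.reshape(NX, NY)
    return ScalpGrid(list(montage["label"]), xy, x_mm, y_mm, weights, mask)


def interpolate_to_grid(values: np.ndarray, grid: ScalpGrid) -> np.ndarray:
    """Linearly interpolate per-channel values onto the grid.

    ``values``: (..., n_ch) -> (..., NX, NY); out-of-hull pixels are NaN.
    Exact at channel positions and reproduces constants in-mask.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != grid.weights.shape[1]:
        raise ScalpError(
            f"got {values.shape[-1]} channel values for a {grid.weights.shape[1]}-channel grid"
        )
    planes = values @ grid.weights.T  # (..., NX*NY)
    planes = planes.reshape(values.shape[:-1] + (grid.nx, grid.ny))
    planes[..., ~grid.mask] = np.nan
    return planes


def stack_images(
    band: BandPowerEpochs,
    grid: ScalpGrid,
    *,
    time_decim: int = 1,
) -> ScalpTimeImages:
    """Build one scalp-time image per trial from a band map.

    ``time_decim`` keeps every n-th time sample (plain decimation; the band
    power is already heavily oversampled relative to the wavelet bandwidth).
    """
    data = np.asarray(band.data, dtype=float)[..., ::time_decim]  # trials x ch x T
    t_ms = band.t_ms[::time_decim]
    vals = np.moveaxis(data, 1, -1)  # trials x T x ch
    planes = interpolate_to_grid(vals, grid)  # trials x T x NX x NY
    planes = np.moveaxis(planes, 1, -1).astype(np.float32)  # trials x NX x NY x T
    return ScalpTimeImages(
        data=planes,
        t_ms=t_ms,
        grid=grid,
        labels=band.trials.reset_index(drop=True),
        subject=band.subject,
        band=band.band,
        provenance=[{"step": "stack_images", "time_decim": time_decim,
                     "grid": grid.geometry_dict()}],
    )


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def smooth_gaussian(
    img: ScalpTimeImages,
    fwhm: tuple[float, float, float] = (9.0, 9.0, 20.0),
) -> ScalpTimeImages:
    """Separable Gaussian smoothing, FWHM in (mm, mm, ms).

    sigma = FWHM / sqrt(8 ln 2) per axis, converted to voxel units from the
    pixel size and the image time step.  Outside-mask voxels are excluded by
    renormalised (mask-weighted) convolution, which preserves constants
    in-mask exactly.
    """
    if any(f <= 0 for f in fwhm):
        raise ScalpError("FWHM components must be > 0")
    if len(img.t_ms) > 1:
        dt = float(img.t_ms[1] - img.t_ms[0])
    else:
        dt = 1.0
    sig = (
        fwhm[0] * FWHM_TO_SIGMA / PIXEL_MM[0],
        fwhm[1] * FWHM_TO_SIGMA / PIXEL_MM[1],
        fwhm[2] * FWHM_TO_SIGMA / dt,
    )
    mask = img.grid.mask
    dtype = img.data.dtype if img.data.dtype in (np.float32, np.float64) else np.float64
    m3 = np.broadcast_to(mask[..., None], mask.shape + (img.data.shape[-1],)).astype(dtype)
    den = ndimage.gaussian_filter(m3, sigma=sig, mode="constant")
    arr = np.nan_to_num(img.data, nan=0.0).astype(dtype, copy=False)
    if arr.ndim == 3:
        num = ndimage.gaussian_filter(arr * m3, sigma=sig, mode="constant")
    else:
        num = ndimage.gaussian_filter(arr * m3[None], sigma=(0,) + tuple(sig), mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[..., ~mask, :] = np.nan
    return ScalpTimeImages(
        data=out.astype(dtype),
        t_ms=img.t_ms,
        grid=img.grid,
        labels=img.labels,
        subject=img.subject,
        band=img.band,
        provenance=img.provenance + [{"step": "smooth_gaussian", "fwhm": list(fwhm),
                                      "sigma_voxels": [float(s) for s in sig]}],
    )
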