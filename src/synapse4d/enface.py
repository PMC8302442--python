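"""En-face synapse reconstruction and depletion quantitation.

The synapse is viewed face-on by fitting a plane to the contact surface,
resampling each channel onto a grid in that plane (trilinear interpolation)
and taking a maximum-intensity projection through a 3 um slab centred on
the plane.  The depleted area statistic is

    % depleted = 100 * (1 - A_above / A_filled)

where ``A_above`` is the synapse area above the background threshold and
``A_filled`` the same area with internal gaps filled - equivalently
100 * hole / footprint on binary images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_isodata, threshold_otsu
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)

__all__ = ["Plane", "EnFaceMap", "DepletionResult", "fit_synapse_plane",
           "enface_projection", "line_profile", "depletion_fraction"]


@dataclass(frozen=True)
class Plane:
    origin_um: np.ndarray      # (z, y, x)
    normal: np.ndarray         # unit (z, y, x), oriented CTL -> target


@dataclass
class EnFaceMap:
    """Per-channel 2D intensity maps in the synapse plane."""

    maps: dict[str, np.ndarray]
    plane: Plane
    pixel_size_um: float
    slab_thickness_um: float
    basis_um: np.ndarray       # (2, 3) in-plane unit vectors (z, y, x)

    def channel(self, name: str) -> np.ndarray:
        return self.maps[name]


@dataclass(frozen=True)
class DepletionResult:
    channel: str
    synapse_footprint_area_um2: float
    above_threshold_area_um2: float
    percent_depleted: float
    threshold_used: float


def fit_synapse_plane(surface_coords_um: np.ndarray,
                      ctl_centroid_um=None,
                      target_centroid_um=None) -> Plane:
    """Least-squares plane through synapse-surface voxel centres.

    The normal is oriented from CTL towards target when centroids are
    supplied.  Raises on degenerate (collinear or too small) surfaces.
    """
    pts = np.asarray(surface_coords_um, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 surface voxels to fit a plane")
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-9:
        raise ValueError("degenerate (collinear) synapse surface")
    normal = vt[2]
    if ctl_centroid_um is not None and target_centroid_um is not None:
        direction = (np.asarray(target_centroid_um, dtype=float)
                     - np.asarray(ctl_centroid_um, dtype=float))
        if np.dot(normal, direction) < 0:
            normal = -normal
    return Plane(origin_um=centroid, normal=normal / np.linalg.norm(normal))


def _plane_basis(normal: np.ndarray) -> np.ndarray:
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, normal)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, seed)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return np.stack([u, v])


def enface_projection(stack: np.ndarray, plane: Plane, voxel_size_zyx,
                      channel_names, *, slab_thickness_um: float = 3.0,
                      half_extent_um: float = 5.0,
                      pixel_size_um: float | None = None) -> EnFaceMap:
    """Oblique-slab maximum projection of each channel onto the plane.

    ``stack`` is (C, Z, Y, X).  Each channel is resampled trilinearly onto
    an in-plane grid at offsets spanning the slab, then max-projected along
    the normal.  Sampling points outside the volume contribute nothing; a
    warning is emitted when the slab is partially outside.
    """
    if slab_thickness_um <= 0:
        raise ValueError("slab thickness must be positive")
    v = np.asarray(voxel_size_zyx, dtype=float)
    if pixel_size_um is None:
        pixel_size_um = float(v[1:].min())
    basis = _plane_basis(plane.normal)
    r = np.arange(-half_extent_um, half_extent_um + pixel_size_um / 2,
                  pixel_size_um)
    n_off = max(int(np.ceil(slab_thickness_um / v.min())) + 1, 3)
    offsets = np.linspace(-slab_thickness_um / 2, slab_thickness_um / 2,
                          n_off)
    uu, vv = np.meshgrid(r, r, indexing="ij")
    base = (plane.origin_um[None, None, :]
            + uu[..., None] * basis[0][None, None, :]
            + vv[..., None] * basis[1][None, None, :])
    shape_um = (np.asarray(stack.shape[1:]) - 1) * v
    outside = False
    maps = {name: np.zeros(uu.shape, dtype=np.float32)
            for name in channel_names}
    for off in offsets:
        pts = base + off * plane.normal[None, None, :]
        if (pts < -1e-6).any() or (pts > shape_um + 1e-6).any():
            outside = True
        idx = (pts / v).reshape(-1, 3).T
        for ci, name in enumerate(channel_names):
            sampled = ndimage.map_coordinates(
                stack[ci].astype(np.float32), idx, order=1, mode="constant",
                cval=0.0).reshape(uu.shape)
            np.maximum(maps[name], sampled, out=maps[name])
    if outside:
        warnings.warn("en-face slab partially outside the volume; "
                      "projection computed over available voxels",
                      stacklevel=2)
    return EnFaceMap(maps=maps, plane=plane, pixel_size_um=pixel_size_um,
                     slab_thickness_um=slab_thickness_um, basis_um=basis)


def line_profile(image: np.ndarray, p0, p1, width_px: int = 1,
                 pixel_size_um: float = 1.0):
    """Mean intensity across ``width_px`` along the p0->p1 segment.

    Endpoints are (row, col) pixel coordinates inside the image; samples
    are taken at pixel pitch.  Returns (distances_um, profile).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    for p in (p0, p1):
        if (p < 0).any() or (p >= np.asarray(image.shape)).any():
            raise ValueError("profile endpoints must lie inside the map")
    length = np.linalg.norm(p1 - p0)
    n = max(int(np.round(length)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)
    line = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    direction = (p1 - p0) / max(length, 1e-12)
    perp = np.array([-direction[1], direction[0]])
    half = (width_px - 1) / 2
    offs = np.linspace(-half, half, max(width_px, 1))
    samples = (line[None, :, :] + offs[:, None, None] * perp[None, None, :])
    vals = ndimage.map_coordinates(image.astype(np.float32),
                                   samples.reshape(-1, 2).T, order=1,
                                   mode="nearest").reshape(len(offs), n)
    return t * length * pixel_size_um, vals.mean(axis=0)


def depletion_fraction(enface: EnFaceMap, channel: str, *,
                       threshold_method: str = "midlevel",
                       threshold_value: float | None = None,
                       ) -> DepletionResult:
    """Percent of the synapse footprint depleted of ``channel`` signal.

    The footprint is the largest above-threshold connected component with
    internal gaps filled (debris outside it is ignored); the statistic is
    ``100 * (1 - above/footprint)``.  Raises when nothing is above
    threshold.

    Threshold methods: ``"midlevel"`` (default) places the cut halfway
    between the background level (image median) and the signal plateau
    (99th percentile), so the binary edge sits at the 50% intensity
    crossing of a PSF-blurred boundary - the unbiased edge position;
    ``"otsu"`` and ``"isodata"`` weight class histograms and tend to expand
    smooth-edged bright regions; ``"fixed"`` uses ``threshold_value``.
    """
    img = np.asarray(enface.channel(channel), dtype=float)
    if threshold_method in ("midlevel", "isodata", "otsu"):
        if np.ptp(img) <= 0:
            raise ValueError("uniform en-face map: no detectable synapse")
        if threshold_method == "midlevel":
            thr = 0.5 * (float(np.median(img))
                         + float(np.percentile(img, 99)))
        elif threshold_method == "isodata":
            thr = float(threshold_isodata(img))
        else:
            thr = float(threshold_otsu(img))
    elif threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("fixed threshold requires threshold_value")
        thr = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = img > thr
    if not binary.any():
        raise ValueError("empty footprint: no detectable synapse signal")
    # "gaps filled in": bridge sub-pixel breaks in a thin rim before the
    # topological fill, then take the largest connected footprint.  The
    # above-threshold numerator stays the raw binary, so the closing is a
    # no-op on clean fixtures.
    closed = ndimage.binary_closing(binary, structure=np.ones((3, 3)),
                                    iterations=2)
    lab = cc_label(closed)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    component = lab == largest
    footprint = ndimage.binary_fill_holes(component)
    px_area = enface.pixel_size_um ** 2
    above = float((binary & footprint).sum()) * px_area
    filled = float(footprint.sum()) * px_area
    return DepletionResult(
        channel=channel,
        synapse_footprint_area_um2=filled,
        above_threshold_area_um2=above,
        percent_depleted=100.0 * (1.0 - above / filled),
        threshold_used=thr,
    )
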