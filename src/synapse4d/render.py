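"""Rasterise ground-truth choreography into noisy multi-channel volumes.

The optical model is deliberately plain: cells are ellipsoids (the CTL with
a trailing uropod protrusion until its retraction time), the target is a
membrane shell, centrosome and granules are Gaussian spots, and the Ca2+
channel is whole-CTL intensity switched by the latent flux state.  Body
channels are blurred with a Gaussian PSF; photon conversion applies Poisson
shot noise plus Gaussian read noise.  No spherical aberration, bleaching or
target-death rendering.

Scene layout: the target sits just right of the synapse plane (+x towards
the target), the CTL just left of it; the centrosome position along x is
``x_synapse - d(t)`` where ``d`` is the latent distance profile, so every
measured distance has an exact latent counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .movie import Movie
from .params import ImagingParams
from .simulate import GroundTruth

__all__ = ["render_movie", "render_conjugate_stack", "ConjugateTruth",
           "CTL_RADIUS_UM", "TARGET_RADIUS_UM"]

CTL_RADIUS_UM = 3.2
TARGET_RADIUS_UM = 3.3
TARGET_SHELL_UM = 0.45
PRECONTACT_GAP_UM = 1.6
#: how far the CTL sphere presses past the synapse plane while in contact;
#: sets the contact-disc (synapse footprint) radius
CONTACT_INDENT_UM = 0.8
CA_BASELINE_REL = 0.35
SPOT_SIGMA_CEN = (0.7, 0.35, 0.35)     # (z, y, x) um
SPOT_SIGMA_GRA = (0.6, 0.30, 0.30)
#: non-delivered granules keep at least this margin from the synapse plane
GRANULE_REAR_MIN_UM = 1.25
GRANULE_REAR_MAX_UM = 2.2
DELIVERED_DISTANCE_UM = 0.25


@dataclass(frozen=True)
class ConjugateTruth:
    """Latent parameters of one rendered fixed conjugate."""

    depletion_fraction: float
    plane_origin_um: tuple[float, float, float]   # (z, y, x)
    plane_normal: tuple[float, float, float]      # unit, CTL -> target
    footprint_radius_um: float


def _grids_um(params: ImagingParams):
    vz, vy, vx = params.voxel_size_zyx
    nz, ny, nx = params.volume_shape
    zz = (np.arange(nz, dtype=np.float32) * vz)[:, None, None]
    yy = (np.arange(ny, dtype=np.float32) * vy)[None, :, None]
    xx = (np.arange(nx, dtype=np.float32) * vx)[None, None, :]
    return zz, yy, xx


def _ellipsoid(zz, yy, xx, center_zyx, radii_zyx):
    cz, cy, cx = center_zyx
    rz, ry, rx = radii_zyx
    return (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
            + ((xx - cx) / rx) ** 2) <= 1.0


def _add_spot(vol, params, center_zyx, sigma_zyx, amplitude):
    """Analytic Gaussian spot added on a local crop (fast path)."""
    v = params.voxel_size_zyx
    idx = [c / vi for c, vi in zip(center_zyx, v)]
    lo, hi, axes = [], [], []
    for ax in range(3):
        half = max(2, int(np.ceil(4 * sigma_zyx[ax] / v[ax])))
        l = max(int(np.floor(idx[ax])) - half, 0)
        h = min(int(np.ceil(idx[ax])) + half + 1, vol.shape[ax])
        if l >= h:
            return
        lo.append(l)
        hi.append(h)
        axes.append(np.arange(l, h, dtype=np.float32) * v[ax])
    gz = np.exp(-0.5 * ((axes[0] - center_zyx[0]) / sigma_zyx[0]) ** 2)
    gy = np.exp(-0.5 * ((axes[1] - center_zyx[1]) / sigma_zyx[1]) ** 2)
    gx = np.exp(-0.5 * ((axes[2] - center_zyx[2]) / sigma_zyx[2]) ** 2)
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
        amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :])


def _apply_noise(photons, rng, read_noise, signal_mask):
    """Shot noise plus read noise.

    Voxels carrying rendered signal get exact Poisson draws; pure-background
    voxels (constant low rate, the bulk of the volume) use the Gaussian
    N(lam, lam + read^2) approximation, indistinguishable to every
    downstream detector once read noise is added.
    """
    flat = np.clip(photons, 0, None).ravel()
    out = flat + (np.sqrt(flat + read_noise ** 2)
                  * rng.standard_normal(flat.size, dtype=np.float32))
    sig = np.flatnonzero(signal_mask.ravel())
    if sig.size:
        out[sig] = rng.poisson(flat[sig].astype(np.float64))
        if read_noise > 0:
            out[sig] += read_noise * rng.standard_normal(
                sig.size, dtype=np.float32)
    return np.clip(out, 0, None).reshape(photons.shape)


def _granule_offsets(rng, n_granules, cluster_radius_um):
    """Rearward-biased cluster offsets (z, y, x) around the centrosome.

    The x offset is negative (away from the synapse) so that non-delivered
    granules keep a clear margin from the contact; the lateral spread
    follows the condition's cluster radius (tighter clustering with
    stronger signal).
    """
    off_x = -rng.uniform(GRANULE_REAR_MIN_UM, GRANULE_REAR_MAX_UM, n_granules)
    ang = rng.uniform(0, 2 * np.pi, n_granules)
    rad = rng.uniform(0.0, cluster_radius_um, n_granules)
    return np.stack([rad * np.sin(ang), rad * np.cos(ang), off_x], axis=1)


def _slot_centers(params, n):
    """Lateral (y) slot centres for up to a few conjugate pairs."""
    _, ey, _ = params.extent_um_zyx
    pitch = 2 * TARGET_RADIUS_UM + 2 * CTL_RADIUS_UM + 3.0
    n_max = max(1, int(ey // pitch))
    if n > n_max:
        raise ValueError(
            f"{n} cell pairs do not fit the field of view "
            f"(capacity {n_max}); cells would leave the field")
    if n == 1:
        return [ey / 2]
    span = ey - pitch
    return [pitch / 2 + span * i / (n - 1) for i in range(n)]


def render_movie(truths: list[GroundTruth], params: ImagingParams,
                 rng_seed: int, *, noise: bool = True) -> Movie:
    """Render ground-truth CTLs into a (T, C, Z, Y, X) movie.

    Only the channels listed in ``params.channel_names`` are rasterised, so
    callers can drop e.g. the granule channel when it is not analysed.

    Raises
    ------
    ValueError
        If the conjugate pairs cannot be placed without leaving the field.
    """
    rng = np.random.default_rng(rng_seed)
    zz, yy, xx = _grids_um(params)
    ez, ey, ex = params.extent_um_zyx
    x_s = 0.52 * ex                      # synapse plane
    cz = ez / 2
    if x_s + 2 * TARGET_RADIUS_UM > ex - 0.5:
        raise ValueError("target cell would leave the field in x")
    if min(cz, ez - cz) < CTL_RADIUS_UM - 0.4:
        raise ValueError("cells would leave the field in z")
    slots = _slot_centers(params, len(truths))

    want = set(params.channel_names)
    t_axis = np.arange(params.n_frames) * params.frame_interval
    data = np.zeros((params.n_frames, len(params.channel_names),
                     *params.volume_shape), dtype=np.float32)

    # per-truth static randomisation
    per_cell = []
    for truth in truths:
        offsets = _granule_offsets(rng, truth.n_granules,
                                   truth.granule_cluster_radius_um)
        jit = rng.normal(0.0, 0.05, size=(params.n_frames, 3))
        per_cell.append((offsets, jit))

    sigma_vox = tuple(s / v for s, v in zip(
        (params.psf_sigma_xyz[2], params.psf_sigma_xyz[1],
         params.psf_sigma_xyz[0]), params.voxel_size_zyx))

    for truth, cy, (gran_off, jit) in zip(truths, slots, per_cell):
        ep = truth.principal_episode if truth.episodes else None
        # contact-disc radius from the spherical-cap indentation
        cap_r = np.sqrt(CTL_RADIUS_UM ** 2
                        - (CTL_RADIUS_UM - CONTACT_INDENT_UM) ** 2)
        pose_cache = {}          # (gap, uropod) -> (body, shell)
        for f, t in enumerate(t_axis):
            # CTL gap to the synapse plane at this time (negative = pressed
            # into the contact, truncated at the plane)
            if ep is None:
                gap = PRECONTACT_GAP_UM
                in_contact = False
                d_eval = truth.d0_um if np.isfinite(truth.d0_um) else 5.0
            else:
                in_contact = ep.start_s <= t < ep.end_s
                if in_contact:
                    gap = -CONTACT_INDENT_UM
                    d_eval = float(truth.centrosome_distance(t - ep.start_s))
                elif t < ep.start_s:
                    gap = min(PRECONTACT_GAP_UM,
                              0.02 + 0.25 * max(ep.start_s - t, 0.0))
                    d_eval = truth.d0_um
                else:
                    gap = min(PRECONTACT_GAP_UM,
                              0.02 + 0.25 * (t - ep.end_s))
                    d_eval = float(truth.centrosome_distance(ep.dwell_s))
            ctl_cx = x_s - CTL_RADIUS_UM - gap
            ctl_center = (cz, cy, ctl_cx)
            tgt_cx = x_s + TARGET_RADIUS_UM + min(gap, 0.0)
            tgt_center = (cz, cy, tgt_cx)

            retract = truth.uropod_retraction_s
            has_uropod = retract is None or t < retract
            pose = (round(gap, 3), has_uropod)
            if pose in pose_cache:    # static poses recur every contact frame
                body, shell = pose_cache[pose]
            else:
                body = _ellipsoid(
                    zz, yy, xx, ctl_center,
                    (CTL_RADIUS_UM, CTL_RADIUS_UM, CTL_RADIUS_UM))
                if in_contact:        # flattened against the synapse plane
                    body &= xx <= x_s
                if has_uropod:
                    body |= _ellipsoid(
                        zz, yy, xx,
                        (cz, cy, ctl_cx - 1.05 * CTL_RADIUS_UM),
                        (1.1, 1.1, 2.0))
                shell = None
                if "target" in want:
                    r = np.sqrt((zz - tgt_center[0]) ** 2
                                + (yy - tgt_center[1]) ** 2
                                + (xx - tgt_center[2]) ** 2)
                    shell = np.abs(r - TARGET_RADIUS_UM) <= TARGET_SHELL_UM
                    if in_contact:
                        # target membrane apposed across the contact disc;
                        # the cap sits on the target side of the plane so the
                        # measured surface is not dragged into the CTL
                        shell &= xx >= x_s
                        rho = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2)
                        shell |= ((xx >= x_s) & (xx <= x_s + TARGET_SHELL_UM)
                                  & (rho <= cap_r + 0.3))
                if len(pose_cache) < 8:
                    pose_cache[pose] = (body, shell)

            if "actin" in want:
                data[f, params.channel_index("actin")] += body
            if "target" in want:
                data[f, params.channel_index("target")] += shell
            if "calcium" in want:
                lvl = CA_BASELINE_REL + (1 - CA_BASELINE_REL) * float(
                    truth.flux_state(t))
                data[f, params.channel_index("calcium")] += lvl * body

            # centrosome position: x = x_s - d(t), following the CTL body
            # before/after contact
            # keep the rendered spot clear of both cell poles so its PSF
            # centroid stays inside the segmented mask
            d_render = float(np.clip(d_eval + jit[f, 2] * 0.8, 0.3,
                                     2 * CTL_RADIUS_UM - 0.65))
            front_x = x_s if in_contact else ctl_cx + CTL_RADIUS_UM
            cen = np.array([cz + jit[f, 0], cy + jit[f, 1],
                            front_x - d_render])
            if "centrosome" in want:
                _add_spot(data[f, params.channel_index("centrosome")],
                          params, cen, SPOT_SIGMA_CEN, 3.0)
            if "granule" in want:
                ch = params.channel_index("granule")
                docked_now = (in_contact and truth.docking_time_s is not None
                              and (t - ep.start_s) >= truth.docking_time_s)
                for gi, off in enumerate(gran_off):
                    if truth.delivered and gi == 0 and docked_now:
                        pos = np.array([cz + off[0] * 0.4,
                                        cy + 0.8 + off[1] * 0.4,
                                        x_s - DELIVERED_DISTANCE_UM])
                    else:
                        pos = cen + off
                    # keep granules inside the CTL sphere
                    rel = pos - np.array(ctl_center)
                    nrm = np.linalg.norm(rel)
                    rmax = CTL_RADIUS_UM - 0.35
                    if nrm > rmax:
                        pos = np.array(ctl_center) + rel * (rmax / nrm)
                    _add_spot(data[f, ch], params, pos, SPOT_SIGMA_GRA, 1.8)

    # optics and camera
    blur_channels = [c for c in ("actin", "target", "calcium") if c in want]
    for name in blur_channels:
        ci = params.channel_index(name)
        for f in range(params.n_frames):
            data[f, ci] = ndimage.gaussian_filter(data[f, ci], sigma_vox)
    photons = params.background_level + params.photon_scale * data
    if noise:
        photons = _apply_noise(photons, rng, params.read_noise,
                               data > 1e-5)
    return Movie(data=photons, params=params)


def render_conjugate_stack(true_depletion_fraction: float,
                           params: ImagingParams, rng_seed: int, *,
                           noise: bool = True,
                           footprint_radius_um: float = 2.2,
                           ctl_radius_um: float = 3.0,
                           target_radius_um: float = 3.0,
                           ) -> tuple[np.ndarray, ConjugateTruth]:
    """Render one fixed CTL-target conjugate as a (C, Z, Y, X) stack.

    The synapse footprint carries cortical actin and charge-probe signal
    with a central below-threshold disc occupying ``true_depletion_fraction``
    of the footprint area.  The synapse plane is tilted away from the axes
    (10-30 degrees from x) to exercise oblique slicing.
    """
    if not 0.0 <= true_depletion_fraction <= 1.0:
        raise ValueError("depletion fraction must lie in [0, 1]")
    if params.n_frames != 1:
        raise ValueError("fixed conjugate stacks are single time point")
    rng = np.random.default_rng(rng_seed)
    zz, yy, xx = _grids_um(params)
    ez, ey, ex = params.extent_um_zyx
    center = np.array([ez / 2, ey / 2, ex / 2])

    theta = np.deg2rad(rng.uniform(10.0, 30.0))
    phi = rng.uniform(0.0, 2 * np.pi)
    # unit normal, mostly +x with a random oblique tilt (z, y, x)
    normal = np.array([np.sin(theta) * np.sin(phi),
                       np.sin(theta) * np.cos(phi),
                       np.cos(theta)])

    dist_axial = ((zz - center[0]) * normal[0] + (yy - center[1]) * normal[1]
                  + (xx - center[2]) * normal[2])
    rho2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2 - dist_axial ** 2)
    rho = np.sqrt(np.clip(rho2, 0, None))

    # depleted disc: below-threshold area fraction of the footprint.  A
    # cortical rim of at least 0.3 um always remains (a synapse with zero
    # residual signal could not be located by any footprint rule), so
    # fractions near 1 compress to the rim-limited maximum.
    hole_radius = min(np.sqrt(true_depletion_fraction) * footprint_radius_um,
                      footprint_radius_um - 0.3)
    in_disc = (np.abs(dist_axial) <= 0.5) & (rho <= footprint_radius_um)
    annulus = in_disc & (rho >= hole_radius)
    if true_depletion_fraction == 0.0:
        annulus = in_disc

    ctl_center = center - ctl_radius_um * 0.92 * normal
    tgt_center = center + target_radius_um * 0.92 * normal
    # keep cell-body fill out of the synapse disc (through the full en-face
    # slab depth) so the depleted hole is genuinely dark in the projection
    near_disc = (np.abs(dist_axial) <= 1.9) & (rho <= footprint_radius_um)
    ctl_body = (_ellipsoid(zz, yy, xx, ctl_center, (ctl_radius_um,) * 3)
                & (dist_axial <= 0.1) & ~near_disc)
    tgt_body = _ellipsoid(zz, yy, xx, tgt_center,
                          (target_radius_um,) * 3) & (dist_axial >= 0.1)

    chans = {}
    chans["actin"] = 0.22 * ctl_body + 1.0 * annulus
    chans["charge"] = 0.18 * ctl_body + 0.9 * annulus
    chans["target"] = 1.0 * tgt_body
    data = np.zeros((len(params.channel_names), *params.volume_shape),
                    dtype=np.float32)
    sigma_vox = tuple(s / v for s, v in zip(
        (params.psf_sigma_xyz[2], params.psf_sigma_xyz[1],
         params.psf_sigma_xyz[0]), params.voxel_size_zyx))
    for name, vol in chans.items():
        if name in params.channel_names:
            ci = params.channel_index(name)
            data[ci] = ndimage.gaussian_filter(vol.astype(np.float32),
                                               sigma_vox)
    photons = params.background_level + params.photon_scale * data
    if noise:
        photons = _apply_noise(photons, rng, params.read_noise,
                               data > 1e-5)
    truth = ConjugateTruth(
        depletion_fraction=float(true_depletion_fraction),
        plane_origin_um=tuple(center.tolist()),
        plane_normal=tuple(normal.tolist()),
        footprint_radius_um=footprint_radius_um,
    )
    return photons, truth
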