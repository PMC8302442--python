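"""Physical imaging calibration shared by the generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition geometry and noise model for one movie or fixed stack.

    Parameters
    ----------
    voxel_size_xyz : (x, y, z) voxel edge lengths in micrometres.
    frame_interval : seconds between consecutive z-stacks.
    n_frames : number of time points (1 allowed for fixed stacks).
    volume_shape : (Z, Y, X) voxel counts.
    psf_sigma_xyz : Gaussian PSF sigma per axis in micrometres.
    photon_scale : expected photon count at unit fluorophore density.
    background_level : mean background photons per voxel.
    read_noise : Gaussian read-noise sigma in photons.
    channel_names : ordered channel labels; must be unique.
    """

    voxel_size_xyz: tuple[float, float, float] = (0.4, 0.4, 0.8)
    frame_interval: float = 10.0
    n_frames: int = 120
    volume_shape: tuple[int, int, int] = (12, 96, 96)
    psf_sigma_xyz: tuple[float, float, float] = (0.3, 0.3, 0.6)
    photon_scale: float = 200.0
    background_level: float = 10.0
    read_noise: float = 2.0
    channel_names: tuple[str, ...] = (
        "actin", "target", "centrosome", "granule", "calcium",
    )

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size_xyz):
            raise ValueError("voxel sizes must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if any(s < 1 for s in self.volume_shape):
            raise ValueError("volume_shape entries must be >= 1")
        if any(v <= 0 for v in self.psf_sigma_xyz):
            raise ValueError("psf sigmas must be positive")
        if self.photon_scale <= 0 or self.background_level < 0:
            raise ValueError("photon_scale must be > 0, background >= 0")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    # -- convenience -------------------------------------------------------
    @property
    def voxel_size_zyx(self) -> tuple[float, float, float]:
        x, y, z = self.voxel_size_xyz
        return (z, y, x)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def extent_um_zyx(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.volume_shape, self.voxel_size_zyx))

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def with_(self, **kw) -> "ImagingParams":
        return replace(self, **kw)


#: z-step used for live movies (matches the 0.8 um plane spacing of the
#: spinning-disk acquisitions the generator emulates)
LIVE_DEFAULTS = ImagingParams()

#: fine z-step (0.2 um) single-time-point stack for fixed conjugates
FIXED_DEFAULTS = ImagingParams(
    voxel_size_xyz=(0.2, 0.2, 0.2),
    frame_interval=1.0,
    n_frames=1,
    volume_shape=(56, 108, 108),
    psf_sigma_xyz=(0.15, 0.15, 0.35),
    channel_names=("actin", "charge", "target"),
)
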