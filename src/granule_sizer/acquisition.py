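"""Optical acquisition model for a high-content screening microscope.

Defaults describe a 40x air objective (NA 0.6) confocal plate reader
imaging a green emitter (0.52 um), sampled at 0.325 um/px on a 16-bit
camera. All geometry downstream (resolution limit, sub-resolution object
filtering, PSF width) derives from this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AcquisitionModel:
    """Parameters of the imaging system and noise model.

    Attributes
    ----------
    pixel_size : float
        Object-space pixel size, um per pixel.
    magnification : float
        Objective magnification (informational).
    numerical_aperture : float
        Objective NA; sets the diffraction limit.
    emission_wavelength : float
        Emission wavelength in um.
    psf_sigma : float
        Gaussian PSF standard deviation in um. The default
        0.21 * lambda / NA approximates the Airy core of a widefield PSF.
    bit_depth : int
        Camera bit depth (8..16); output images are quantized to this.
    read_noise_sd : float
        Additive Gaussian read noise, intensity counts.
    background_level : float
        Constant background offset, intensity counts.
    photon_scale : float
        Counts recorded per unit fluorophore density per pixel.
    field_shape : tuple
        Field size in pixels, (rows, cols).
    """

    pixel_size: float = 0.325
    magnification: float = 40.0
    numerical_aperture: float = 0.6
    emission_wavelength: float = 0.52
    psf_sigma: float = 0.21 * 0.52 / 0.6
    bit_depth: int = 16
    read_noise_sd: float = 2.0
    background_level: float = 100.0
    photon_scale: float = 200.0
    field_shape: tuple = (512, 512)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if not 8 <= self.bit_depth <= 16:
            raise ValueError("bit_depth must be in [8, 16]")
        if self.resolution_limit <= self.pixel_size:
            raise ValueError(
                "sampling coarser than the resolution limit: "
                f"{self.resolution_limit:.3f} um <= {self.pixel_size:.3f} um/px"
            )

    @property
    def resolution_limit(self) -> float:
        """Rayleigh resolution limit 0.61 * lambda / NA, in um."""
        return 0.61 * self.emission_wavelength / self.numerical_aperture

    @property
    def max_gray(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def field_extent(self) -> tuple:
        """Physical field size (height, width) in um."""
        return (
            self.field_shape[0] * self.pixel_size,
            self.field_shape[1] * self.pixel_size,
        )
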