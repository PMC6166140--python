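"""Optical configuration and the diffraction-limited size cutoff.

Segmented objects smaller than the lateral resolution limit of the
microscope cannot be genuine exocytic sites and are discarded. The limit
is the Rayleigh criterion d = 0.61 * lambda / NA; the corresponding
minimum credible object area is that of a disc of diameter d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["OpticalConfig", "rayleigh_resolution", "subresolution_cutoff"]


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition optics of a confocal plate reader.

    Parameters
    ----------
    magnification : objective magnification (40x air lens by default).
    numerical_aperture : objective NA, in (0, 1.5].
    emission_wavelength_um : emission wavelength in micrometres,
        in [0.4, 0.8] (0.52 um ~ green emission of a typical
        secondary-antibody fluorophore).
    pixel_size_um : projected pixel size in the sample plane, um/px.
    """

    magnification: float = 40.0
    numerical_aperture: float = 0.6
    emission_wavelength_um: float = 0.52
    pixel_size_um: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.numerical_aperture <= 1.5:
            raise ValueError(
                f"numerical aperture must be in (0, 1.5], got {self.numerical_aperture}"
            )
        if not 0.4 <= self.emission_wavelength_um <= 0.8:
            raise ValueError(
                "emission wavelength must be in [0.4, 0.8] um, got "
                f"{self.emission_wavelength_um}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size_um}")


def rayleigh_resolution(optical: OpticalConfig) -> float:
    """Lateral Rayleigh resolution d = 0.61 * lambda / NA, in micrometres."""
    return 0.61 * optical.emission_wavelength_um / optical.numerical_aperture


def subresolution_cutoff(optical: OpticalConfig) -> float:
    """Minimum credible object area in um^2: a disc of diameter d.

    With the default NA 0.6 and lambda 0.52 um this is ~0.2195 um^2.
    Objects strictly below the cutoff are removed; objects exactly at it
    are kept.
    """
    d = rayleigh_resolution(optical)
    return math.pi * (d / 2.0) ** 2
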