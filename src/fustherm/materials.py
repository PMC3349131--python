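"""Thermal material constants for tissue and blood.

The two-domain bioheat model treats the tissue as a homogeneous conductor with
an *effective* conductivity ``k_eff`` that absorbs the mixing effect of vessels
too small to resolve individually, while blood inside discretely modelled
vessels keeps its own constants. Defaults are generic muscle/blood values.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MaterialProperties:
    """Tissue and blood thermal constants (SI units, temperatures in deg C).

    Attributes
    ----------
    rho_t : float
        Tissue mass density, kg/m^3.
    c_pt : float
        Tissue specific heat, J kg^-1 K^-1.
    k_eff : float
        Effective tissue conductivity, W m^-1 K^-1 (inflated to account for
        thermally insignificant microvasculature).
    rho_b, c_pb, k_b : float
        Blood density, specific heat and conductivity.
    t_core : float
        Core/arterial temperature in deg C; boundary and inlet reference.
    """

    rho_t: float = 1000.0
    c_pt: float = 4000.0
    k_eff: float = 1.8
    rho_b: float = 1060.0
    c_pb: float = 3840.0
    k_b: float = 0.6
    t_core: float = 37.0

    def __post_init__(self) -> None:
        for name in ("rho_t", "c_pt", "k_eff", "rho_b", "c_pb", "k_b"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def rc_t(self) -> float:
        """Volumetric heat capacity of tissue, J m^-3 K^-1."""
        return self.rho_t * self.c_pt

    @property
    def rc_b(self) -> float:
        """Volumetric heat capacity of blood, J m^-3 K^-1."""
        return self.rho_b * self.c_pb

    @property
    def alpha_t(self) -> float:
        """Tissue thermal diffusivity k_eff/(rho_t*c_pt), m^2/s."""
        return self.k_eff / self.rc_t

    @property
    def alpha_b(self) -> float:
        """Blood thermal diffusivity, m^2/s."""
        return self.k_b / self.rc_b
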