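"""Separable Gaussian focal power deposition.

The deposited power density of the focused-ultrasound field is modelled
directly (no wave propagation) as a separable Gaussian,

    P(u) = P0 * prod_u exp(-ln2 * u^2 / R_u^2),

where u are coordinates relative to the focus in the beam frame and the R_u
follow from the focal half-power width and height. "Half-power width/height"
is read as the FULL width at half maximum, so R_u = FWHM/2: the Gaussian falls
to P0/2 exactly at u = R_u. This reading is exposed explicitly through the
``fwhm_*`` constructor arguments, since the alternative (half-width at half
maximum, R_u = FWHM) would rescale every absolute temperature by a fixed
geometric factor.

Power is deposited in tissue and lumen alike; both domain equations carry the
same source term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import Grid

__all__ = ["SourceSpec", "power_field", "single_vessel_source", "treatment_source"]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class SourceSpec:
    """Gaussian focal spot.

    Attributes
    ----------
    p0 : float
        Peak power density at the focus, W/m^3.
    r_trans : float
        Transverse half-power radius R_x = R_y (m) = FWHM width / 2.
    r_axial : float
        Axial half-power radius R_z (m) = FWHM height / 2.
    focus : tuple of float
        Focus position in domain coordinates (m). In axisymmetric mode only
        the z component is used and the focus must be on the axis.
    beam_axis : tuple of float
        Unit vector along the beam; the default (0, 0, -1) propagates
        downward through the block. Because R_x = R_y the field depends only
        on the axial/transverse split, so the sign is irrelevant to P.
    """

    p0: float
    r_trans: float
    r_axial: float
    focus: tuple[float, float, float]
    beam_axis: tuple[float, float, float] = (0.0, 0.0, -1.0)

    def __post_init__(self) -> None:
        if self.p0 < 0:
            raise ValueError("p0 must be >= 0")
        if self.r_trans <= 0 or self.r_axial <= 0:
            raise ValueError("half-power radii must be > 0")
        b = np.asarray(self.beam_axis, dtype=float)
        n = float(np.linalg.norm(b))
        if n == 0:
            raise ValueError("beam_axis must be non-zero")
        object.__setattr__(self, "beam_axis", tuple(b / n))
        object.__setattr__(self, "focus", tuple(float(v) for v in self.focus))

    @classmethod
    def from_clinical(cls, p0_w_cm3, fwhm_width_mm, fwhm_height_mm, focus_mm,
                      beam_axis=(0.0, 0.0, -1.0)) -> "SourceSpec":
        """Construct from the units the treatment literature quotes.

        W/cm^3 -> W/m^3 (x1e6), mm -> m, FWHM -> half-power radius (/2).
        """
        return cls(
            p0=p0_w_cm3 * 1e6,
            r_trans=fwhm_width_mm * 1e-3 / 2,
            r_axial=fwhm_height_mm * 1e-3 / 2,
            focus=tuple(f * 1e-3 for f in focus_mm),
            beam_axis=beam_axis,
        )

    def at(self, focus) -> "SourceSpec":
        """Same beam re-aimed at a new focus (m)."""
        return replace(self, focus=tuple(float(v) for v in focus))

    def with_power(self, p0: float) -> "SourceSpec":
        return replace(self, p0=float(p0))

    def amplitude(self, points: np.ndarray) -> np.ndarray:
        """P at arbitrary points, shape (..., 3) in metres."""
        rel = np.asarray(points, dtype=float) - np.asarray(self.focus)
        b = np.asarray(self.beam_axis)
        u = rel @ b
        t2 = np.einsum("...i,...i", rel, rel) - u**2
        return self.p0 * np.exp(-_LN2 * (t2 / self.r_trans**2 + u**2 / self.r_axial**2))

    @property
    def integral(self) -> float:
        """Total deposited power integrated over all space, W.

        Closed form: P0 * (pi/ln2)^{3/2} * R_x * R_y * R_z.
        """
        return self.p0 * (np.pi / _LN2) ** 1.5 * self.r_trans**2 * self.r_axial


def power_field(src: SourceSpec, grid: Grid, warn_margin: bool = False) -> np.ndarray:
    """Evaluate the deposited power density (W/m^3) at every cell centre."""
    if grid.mode == "axisym":
        r = grid.axis_coords(0)[:, None]
        z = grid.axis_coords(1)[None, :]
        fz = src.focus[2]
        return src.p0 * np.exp(
            -_LN2 * (r**2 / src.r_trans**2 + (z - fz) ** 2 / src.r_axial**2)
        )
    X, Y, Z = grid.cell_centers()
    rel = (X - src.focus[0], Y - src.focus[1], Z - src.focus[2])
    b = np.asarray(src.beam_axis)
    u = rel[0] * b[0] + rel[1] * b[1] + rel[2] * b[2]
    rr = rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2
    t2 = np.maximum(rr - u**2, 0.0)
    return src.p0 * np.exp(-_LN2 * (t2 / src.r_trans**2 + u**2 / src.r_axial**2))


def single_vessel_source(focus, p0_w_cm3: float = 15.0) -> SourceSpec:
    """The source used in the single-vessel and vessel-pair experiments:
    half-power width 4 mm, height 30 mm, peak 15 W/cm^3."""
    return SourceSpec(p0=p0_w_cm3 * 1e6, r_trans=2e-3, r_axial=15e-3,
                      focus=tuple(focus))


def treatment_source(focus, p0_w_cm3: float = 16.5) -> SourceSpec:
    """The treatment-delivery source: half-power width 3.2 mm, height 24 mm.

    The fixed-power dose studies use a 16.5 W/cm^3 peak; the temperature
    snapshots of the random treatment use 17.5 W/cm^3. Both are plain
    arguments here.
    """
    return SourceSpec(p0=p0_w_cm3 * 1e6, r_trans=1.6e-3, r_axial=12e-3,
                      focus=tuple(focus))
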