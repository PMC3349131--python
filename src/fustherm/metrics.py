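"""Summary statistics of dose and temperature fields.

Masked dose statistics deliberately exclude the cool regions inside the
vessel lumens: the mean and standard deviation are taken only over midplane
voxels whose normalized dose exceeds a threshold (default 0.3), while the
peak is taken over the full plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grid import Grid

__all__ = ["DoseStatistics", "dose_stats", "peak_reduction", "plane_peak_rise"]


@dataclass(frozen=True)
class DoseStatistics:
    """Masked midplane dose summary (normalized dose units).

    ``mean``/``sd`` are over voxels above ``threshold``; ``peak`` is over the
    whole plane; ``n_masked`` counts the voxels in the mask. ``sd`` is the
    population standard deviation by default (see :func:`dose_stats`).
    """

    peak: float
    mean: float
    sd: float
    threshold: float
    n_masked: int

    def __post_init__(self) -> None:
        if self.n_masked > 0 and self.mean > self.peak + 1e-12:
            raise ValueError("masked mean cannot exceed the peak")


def dose_stats(normalized_midplane: np.ndarray, threshold: float = 0.3,
               sample_sd: bool = False) -> DoseStatistics:
    """Peak / masked mean / masked SD of a normalized midplane dose field.

    Parameters
    ----------
    normalized_midplane : 2-D array
        Dose in units of the necrosis threshold (240 eq-min).
    threshold : float
        Mask cut: statistics use voxels with dose strictly above it.
    sample_sd : bool
        Use the n-1 (sample) divisor instead of the population divisor. With
        thousands of masked voxels the difference is negligible; population
        is the default reading of a field statistic.

    Raises
    ------
    ValueError
        If no voxel exceeds the threshold (statistics undefined).
    """
    d = np.asarray(normalized_midplane, dtype=float)
    mask = d > threshold
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"no midplane voxel exceeds the dose threshold {threshold}"
        )
    vals = d[mask]
    ddof = 1 if (sample_sd and n > 1) else 0
    return DoseStatistics(
        peak=float(d.max()),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=ddof)),
        threshold=threshold,
        n_masked=n,
    )


def plane_peak_rise(T: np.ndarray, grid: Grid, z: float,
                    t_core: float = 37.0) -> float:
    """Peak temperature rise above ``t_core`` on the transverse plane nearest ``z``."""
    k = int(np.clip(round(z / grid.spacing[-1] - 0.5), 0, grid.shape[-1] - 1))
    return float(T[..., k].max() - t_core)


def peak_reduction(T_with: np.ndarray, T_without: np.ndarray, grid: Grid,
                   plane_offsets: Sequence[float] = (0.0,),
                   focal_z: Optional[float] = None,
                   t_core: float = 37.0) -> np.ndarray:
    """Percent reduction of plane-wise peak temperature rise due to vessels.

    For each requested plane z = focal_z + offset:

        100 * (dT_no_vessel - dT_vessel) / dT_no_vessel

    using the peak rise above ``t_core`` within that plane. Both runs must
    share the grid, source and duration.

    Raises
    ------
    ValueError
        If the baseline (no-vessel) rise on a plane is not positive.
    """
    if T_with.shape != T_without.shape:
        raise ValueError("fields must share a grid")
    if focal_z is None:
        focal_z = grid.extent[-1] / 2
    out = []
    for off in plane_offsets:
        z = focal_z + off
        base = plane_peak_rise(T_without, grid, z, t_core)
        if base <= 0:
            raise ValueError(f"no baseline temperature rise on plane z={z:g} m")
        vess = plane_peak_rise(T_with, grid, z, t_core)
        out.append(100.0 * (base - vess) / base)
    return np.asarray(out)
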