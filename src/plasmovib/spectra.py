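"""Stick-to-curve convolution, normalization and tabular output.

Vibrational stick spectra are broadened with area-normalized Lorentzians
(default fwhm 10 cm⁻¹), so each stick of height h contributes a peak value
2h/(π·fwhm) and an integrated area h. Curves can be max-normalized for
plotting. CSV writers and a JSON run manifest round out the I/O surface.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional

import numpy as np

__all__ = [
    "StickSpectrum",
    "CurveSpectrum",
    "lorentzian_convolve",
    "normalize",
    "write_curve_csv",
    "write_sticks_csv",
    "write_manifest",
    "DEFAULT_FWHM_CM",
]

DEFAULT_FWHM_CM = 10.0


@dataclass
class StickSpectrum:
    """Discrete vibrational/absorption sticks (positions sorted, heights ≥ 0)."""

    positions: np.ndarray
    heights: np.ndarray
    kind: str = "IR"        # IR | Raman | absorption

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).ravel()
        self.heights = np.asarray(self.heights, dtype=float).ravel()
        if len(self.positions) != len(self.heights):
            raise ValueError("positions and heights must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("stick positions must be finite")
        if np.any(self.heights < 0):
            raise ValueError("stick heights must be non-negative")
        order = np.argsort(self.positions, kind="stable")
        self.positions = self.positions[order]
        self.heights = self.heights[order]


@dataclass
class CurveSpectrum:
    """Convolved spectrum on a grid; remembers the fwhm used."""

    grid: np.ndarray
    values: np.ndarray
    fwhm: float
    normalized: bool = False


def lorentzian_convolve(
    sticks: StickSpectrum,
    grid: np.ndarray,
    fwhm: float = DEFAULT_FWHM_CM,
    max_normalize: bool = False,
) -> CurveSpectrum:
    """Broaden sticks with area-normalized Lorentzians of the given fwhm.

    curve(x) = Σ_k h_k·(γ/π)/((x−x_k)² + γ²) with γ = fwhm/2, so each
    component integrates to its stick height and peaks at 2h/(π·fwhm).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    grid = np.asarray(grid, dtype=float)
    if len(sticks.positions) == 0:
        warnings.warn("empty stick spectrum: returning a zero curve")
        curve = CurveSpectrum(grid, np.zeros_like(grid), fwhm)
        return normalize(curve) if max_normalize else curve
    gam = fwhm / 2.0
    diff = grid[:, None] - sticks.positions[None, :]
    vals = (sticks.heights[None, :] * (gam / np.pi) / (diff**2 + gam**2)).sum(axis=1)
    curve = CurveSpectrum(grid, vals, fwhm)
    return normalize(curve) if max_normalize else curve


def normalize(curve: CurveSpectrum) -> CurveSpectrum:
    """Scale a curve so its maximum is exactly 1."""
    m = curve.values.max() if len(curve.values) else 0.0
    if m <= 0:
        raise ValueError("cannot normalize an all-zero curve")
    return CurveSpectrum(curve.grid, curve.values / m, curve.fwhm, normalized=True)


def write_curve_csv(curve: CurveSpectrum, path, header=("grid", "value")) -> None:
    arr = np.column_stack([curve.grid, curve.values])
    np.savetxt(path, arr, delimiter=",", header=",".join(header), comments="")


def write_sticks_csv(sticks: StickSpectrum, path) -> None:
    arr = np.column_stack([sticks.positions, sticks.heights])
    np.savetxt(path, arr, delimiter=",", header="position,height", comments="")


def write_manifest(path, inputs: dict, parameters: dict,
                   seed: Optional[int] = None, outputs: Optional[dict] = None) -> None:
    """Machine-readable run manifest sufficient to reproduce a run."""
    from . import __version__

    doc = {
        "plasmovib_version": __version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": inputs,
        "parameters": parameters,
        "seed": seed,
        "outputs": outputs or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
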