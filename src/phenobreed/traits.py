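"""Derived phenotypic traits: light interception, vegetation indices, plot means.

Canopy light interception (iPAR) is computed from paired quantum-sensor
readings above and below the canopy as ``1 - P_below / P_above``, clipped to
[0, 1].  Vegetation indices are arithmetic combinations of canopy reflectance
at named wavelengths, evaluated by nearest-nanometre lookup on a measured
spectrum; the default registry ships canonical literature definitions (NDVI,
VREI2, RARSa/b, PRI, RDVI, NMDI) and is user-extensible with expression
strings such as ``"(R800 - R670) / (R800 + R670)"``.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralMeasurement",
    "VIRegistry",
    "default_vi_registry",
    "read_spectrum",
    "compute_ipar",
    "compute_vi",
    "aggregate_plot",
]


@dataclass
class SpectralMeasurement:
    """A per-plot reflectance spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D arrays of equal length")
        if len(self.wavelengths) < 2:
            raise ValueError("spectrum needs at least two samples")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        # white-reference normalization can push canopy reflectance slightly
        # above 1; anything beyond 1.5 (or negative) is a measurement fault
        if np.any(self.reflectance < 0) or np.any(self.reflectance > 1.5):
            raise ValueError("reflectance values must lie in [0, 1.5]")

    def at(self, nm: float) -> float:
        """Reflectance at the nearest sampled wavelength to ``nm``."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= nm <= hi):
            raise ValueError(f"wavelength {nm} nm outside spectrum span [{lo}, {hi}]")
        i = int(np.argmin(np.abs(self.wavelengths - nm)))
        return float(self.reflectance[i])


_R_NAME = re.compile(r"^R(\d+)$")


@dataclass
class VIRegistry:
    """Named vegetation-index formulas over ``R<nm>`` reflectance variables.

    Each entry is an arithmetic expression in variables like ``R800``; the
    registry extracts the required wavelengths from the expression and
    evaluates it with nearest-nm reflectance values.  ``sqrt`` is available.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def register(self, name: str, expression: str) -> None:
        if not self.wavelengths(expression):
            raise ValueError(f"formula for {name!r} references no R<nm> wavelengths")
        self.entries[name] = expression

    @staticmethod
    def wavelengths(expression: str) -> list[int]:
        return [int(m.group(1)) for m in (_R_NAME.match(tok) for tok in re.findall(r"R\d+", expression)) if m]

    def names(self) -> list[str]:
        return sorted(self.entries)


def default_vi_registry() -> VIRegistry:
    """Canonical definitions for the indices named in the trait registry."""
    reg = VIRegistry()
    reg.register("NDVI", "(R800 - R670) / (R800 + R670)")
    reg.register("VREI2", "(R734 - R747) / (R715 + R726)")
    reg.register("RARSa", "R675 / R700")
    reg.register("RARSb", "R675 / (R650 * R700)")
    reg.register("PRI", "(R531 - R570) / (R531 + R570)")
    reg.register("RDVI", "(R800 - R670) / sqrt(R800 + R670)")
    reg.register("NMDI", "(R860 - (R1640 - R2130)) / (R860 + (R1640 - R2130))")
    return reg


def read_spectrum(path) -> SpectralMeasurement:
    """Read a two-column delimited spectrum (wavelength_nm, reflectance)."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"spectrum file {path} needs two columns: wavelength_nm, reflectance")
    return SpectralMeasurement(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def compute_ipar(p_above: float, p_below: float) -> float:
    """Fraction of photosynthetically active radiation intercepted by the canopy.

    ``1 - p_below / p_above``, clipped to [0, 1].  Field noise occasionally
    yields below-canopy readings above the reference; those clip to 0 with a
    logged warning rather than failing.
    """
    if p_above <= 0:
        raise ValueError("p_above must be > 0")
    if p_below < 0:
        raise ValueError("p_below must be >= 0")
    if p_below > p_above:
        logger.warning("below-canopy PAR %.3g exceeds above-canopy %.3g; clipping iPAR to 0", p_below, p_above)
        return 0.0
    return float(min(1.0, max(0.0, 1.0 - p_below / p_above)))


_SAFE_EVAL_GLOBALS = {"__builtins__": {}, "sqrt": math.sqrt}


def compute_vi(spectrum: SpectralMeasurement, index: str, registry: VIRegistry | None = None) -> float:
    """Evaluate one vegetation index on a spectrum.

    Returns NaN (with a logged warning) on a zero denominator; raises for an
    unknown index, listing the registry contents.
    """
    registry = registry or default_vi_registry()
    if index not in registry.entries:
        raise KeyError(f"unknown vegetation index {index!r}; registry has {registry.names()}")
    expr = registry.entries[index]
    env = {f"R{nm}": spectrum.at(nm) for nm in registry.wavelengths(expr)}
    try:
        value = eval(expr, _SAFE_EVAL_GLOBALS, env)  # noqa: S307 - restricted namespace
    except ZeroDivisionError:
        logger.warning("division by zero evaluating %s; returning missing", index)
        return float("nan")
    return float(value)


def aggregate_plot(values, trait: str = "") -> float:
    """Arithmetic mean of the non-missing sensor readings for one plot.

    All-missing input returns NaN (missing marker) rather than raising.
    """
    arr = np.asarray([np.nan if v is None else v for v in values], dtype=float)
    if arr.size == 0 or np.all(np.isnan(arr)):
        logger.warning("no valid readings for trait %r; plot value missing", trait)
        return float("nan")
    return float(np.nanmean(arr))
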