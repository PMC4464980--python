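"""Spectrophotometric chlorophyll/carotenoid quantification.

Standard three-wavelength formulas for 80% (v/v) acetone extracts,
returning pigment concentrations in mg/L of extract:

    chl_a      = 12.21*A663 - 2.81*A647
    chl_b      = 20.13*A647 - 5.03*A663
    carotenoid = (1000*A470 - 3.27*chl_a - 104*chl_b) / 227

Negative results (blank/scatter artifacts) are returned as-is with a
warning rather than clipped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass


@dataclass(frozen=True)
class AbsorbanceReading:
    """Unitless absorbances at 663, 647 and 470 nm."""

    a663: float
    a647: float
    a470: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a663", "a647", "a470"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"absorbance {name} must be finite and >= 0")


@dataclass(frozen=True)
class PigmentConcentrations:
    """Pigment content in mg/L of extract."""

    chl_a: float
    chl_b: float
    carotenoid: float


def pigment_concentrations(
    r: AbsorbanceReading, dilution: float = 1.0
) -> PigmentConcentrations:
    """Evaluate the pigment formulas; ``dilution`` (e.g. 2 for a 1:2
    dilution) multiplies all three results."""
    if dilution <= 0:
        raise ValueError("dilution factor must be positive")
    chl_a = 12.21 * r.a663 - 2.81 * r.a647
    chl_b = 20.13 * r.a647 - 5.03 * r.a663
    carotenoid = (1000.0 * r.a470 - 3.27 * chl_a - 104.0 * chl_b) / 227.0
    values = PigmentConcentrations(
        chl_a=chl_a * dilution,
        chl_b=chl_b * dilution,
        carotenoid=carotenoid * dilution,
    )
    negatives = [
        n for n, v in (
            ("chl_a", values.chl_a),
            ("chl_b", values.chl_b),
            ("carotenoid", values.carotenoid),
        )
        if v < 0
    ]
    if negatives:
        warnings.warn(
            f"negative pigment concentration(s) for {negatives}: likely "
            "blank or scatter artifacts",
            stacklevel=2,
        )
    return values


def per_fresh_weight(
    c: PigmentConcentrations, extract_volume_ml: float, tissue_mass_g: float
) -> PigmentConcentrations:
    """Convert mg/L of extract to mg/g fresh weight."""
    if extract_volume_ml <= 0 or tissue_mass_g <= 0:
        raise ValueError("volume and mass must be positive")
    factor = (extract_volume_ml / 1000.0) / tissue_mass_g
    return PigmentConcentrations(
        chl_a=c.chl_a * factor,
        chl_b=c.chl_b * factor,
        carotenoid=c.carotenoid * factor,
    )
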