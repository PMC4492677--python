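"""Closed-form bench-assay arithmetic.

Small quantitation utilities that accompany the transcriptomic pipeline:
cytochrome concentrations from difference-spectra absorbances
(Beer–Lambert), viable counts from spot-plated dilutions, and doubling
times under a linear-growth convention (for anaerobic cultures whose
post-treatment growth is closer to linear than exponential, the doubling
time at the point of compound addition is the time for the OD to double at
the current constant slope, i.e. OD / slope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ExtinctionCoefficient:
    """A reduced-minus-oxidised wavelength pair with its extinction coefficient."""

    name: str
    wavelength_pair_nm: tuple[float, float]  # (peak, trough)
    epsilon_mM_cm: float

    def __post_init__(self) -> None:
        if self.epsilon_mM_cm <= 0:
            raise ValueError("epsilon_mM_cm must be positive")


#: Cytochrome b difference coefficient (560–575 nm).
CYTOCHROME_B = ExtinctionCoefficient("cytochrome b", (560.0, 575.0), 17.5)
#: Cytochrome d difference coefficient (630–655 nm).
CYTOCHROME_D = ExtinctionCoefficient("cytochrome d", (630.0, 655.0), 19.0)


def cytochrome_concentration(
    delta_a: float,
    coeff: ExtinctionCoefficient,
    path_cm: float = 1.0,
    protein_mg_per_ml: float = 1.0,
) -> float:
    """Cytochrome content in nmol per mg protein from a difference absorbance.

    Beer–Lambert gives the concentration in mM as
    ``delta_a / (epsilon_mM_cm * path_cm)``; 1 mM equals 1000 nmol/ml, so
    dividing by the protein concentration (mg/ml) yields
    ``1000 * conc_mM / protein_mg_per_ml`` nmol per mg.
    """
    if delta_a < 0:
        raise ValueError(
            "negative delta_A: oxidised baseline exceeds reduced (swapped spectra?)")
    if path_cm <= 0:
        raise ValueError("path_cm must be positive")
    if protein_mg_per_ml <= 0:
        raise ValueError("protein_mg_per_ml must be positive")
    conc_mM = delta_a / (coeff.epsilon_mM_cm * path_cm)
    return 1000.0 * conc_mM / protein_mg_per_ml


def cfu_per_ml(
    colony_count: int,
    spot_volume_ml: float = 0.01,
    dilution_factor: float = 1.0,
) -> float:
    """Colony-forming units per ml from a spot-plated dilution.

    ``dilution_factor`` is the dilution of the plated sample: 1e-6 means
    the original culture is a million times more concentrated than the
    plated spot.  The default spot volume is 0.01 ml (a 10 µl drop).
    """
    if colony_count < 0:
        raise ValueError("colony_count must be non-negative")
    if spot_volume_ml <= 0:
        raise ValueError("spot_volume_ml must be positive")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    return colony_count / spot_volume_ml / dilution_factor


def doubling_time_linear(od_at_addition: float, slope_od_per_h: float) -> float:
    """Doubling time (h) under linear growth kinetics.

    With a constant slope, the OD doubles after ``od_at_addition /
    slope_od_per_h`` hours.
    """
    if od_at_addition <= 0:
        raise ValueError("od_at_addition must be positive")
    if slope_od_per_h <= 0:
        raise ValueError("slope must be positive: doubling time undefined")
    return od_at_addition / slope_od_per_h


def growth_slope(times_h: Sequence[float], ods: Sequence[float]) -> float:
    """Ordinary-least-squares slope (OD per h) of a growth-curve window."""
    times_h = np.asarray(times_h, dtype=float)
    ods = np.asarray(ods, dtype=float)
    if times_h.shape != ods.shape or times_h.size < 2:
        raise ValueError("need matching series of at least 2 (time, OD) points")
    return float(stats.linregress(times_h, ods).slope)
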