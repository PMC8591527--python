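"""Chemostat physiology: uptake rates, yield and maintenance, unit conversions.

At steady state the dilution rate D fixes the growth rate; the substrate
uptake rate is q_S = D * (S_i - S_r) / c_bm in g substrate gDCW^-1 hr^-1.
Regressing q_S on the growth rate gives the biomass yield (inverse slope) and
the maintenance consumption (intercept), the classic Pirt relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import MEAN_RESIDUE_MASS


@dataclass
class ChemostatRecord:
    dilution_rate: float  # hr^-1
    substrate_feed: float  # S_i, g L^-1
    substrate_residual: float  # S_r, g L^-1
    biomass: float  # c_bm, gDCW L^-1
    condition: str = ""

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValueError("dilution rate must be positive")
        if self.substrate_residual > self.substrate_feed:
            raise ValueError("residual substrate exceeds feed")
        if self.biomass <= 0:
            raise ValueError("biomass concentration must be positive")


def substrate_uptake_rate(record: ChemostatRecord) -> float:
    """q_S = D * (S_i - S_r) / c_bm, g substrate gDCW^-1 hr^-1 (the culture
    volume cancels in the per-volume balance)."""
    return record.dilution_rate * (
        record.substrate_feed - record.substrate_residual
    ) / record.biomass


@dataclass
class YieldFit:
    yield_gdcw_per_g: float  # Y_X/S = 1 / slope
    maintenance: float  # intercept, g substrate gDCW^-1 hr^-1
    slope: float
    slope_stderr: float
    r_squared: float


def fit_yield(mu: np.ndarray, q_s: np.ndarray) -> YieldFit:
    """OLS of q_S on mu; biomass yield is the inverse slope, the intercept is
    maintenance substrate consumption."""
    mu = np.asarray(mu, dtype=float)
    q_s = np.asarray(q_s, dtype=float)
    if np.unique(mu).size < 2:
        raise ValueError("need >= 2 distinct growth rates")
    res = stats.linregress(mu, q_s)
    if res.slope <= 0:
        raise ValueError("non-positive slope: no meaningful yield")
    return YieldFit(
        yield_gdcw_per_g=1.0 / res.slope,
        maintenance=res.intercept,
        slope=res.slope,
        slope_stderr=res.stderr,
        r_squared=res.rvalue**2,
    )


def protein_pool_mmol(
    protein_mass: float, mean_residue_mass: float = MEAN_RESIDUE_MASS
) -> float:
    """Convert a protein pool from g gDCW^-1 to mmol amino acids gDCW^-1
    (0.68 g gDCW^-1 at 110 g mol^-1 per residue -> 6.18 mmol gDCW^-1)."""
    if protein_mass < 0 or mean_residue_mass <= 0:
        raise ValueError("inputs must be positive")
    return protein_mass * 1000.0 / mean_residue_mass


def retention_time(dilution_rate: float) -> tuple[float, float]:
    """Chemostat retention time t_R = 1/D and the 5*t_R sampling delay used to
    reach steady state (hr)."""
    if dilution_rate <= 0:
        raise ValueError("dilution rate must be positive")
    t_r = 1.0 / dilution_rate
    return t_r, 5.0 * t_r


@dataclass
class FractionFit:
    intercept: float
    slope: float
    stderr: float
    clipped: bool = False


def compartment_fraction_fit(mu: np.ndarray, fraction: np.ndarray) -> FractionFit:
    """Linear model of a compartment (or non-enzymatic) protein mass fraction
    against growth rate; predictions outside [0, 1] are clipped with a flag."""
    mu = np.asarray(mu, dtype=float)
    fraction = np.asarray(fraction, dtype=float)
    if np.any((fraction < 0) | (fraction > 1)):
        raise ValueError("fractions must be within [0, 1]")
    if np.unique(mu).size < 2:
        raise ValueError("need >= 2 distinct growth rates")
    res = stats.linregress(mu, fraction)
    pred = res.intercept + res.slope * mu
    clipped = bool(np.any((pred < 0) | (pred > 1)))
    if clipped:
        import logging

        logging.getLogger("necalloc").warning(
            "compartment fraction model leaves [0, 1] over the fitted range; "
            "evaluations are clipped"
        )
    return FractionFit(res.intercept, res.slope, res.stderr, clipped)
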