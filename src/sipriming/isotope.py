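"""Isotope algebra for ¹³C tracer mass balance.

Conversions between the three equivalent representations of a carbon
isotope measurement —

* ``delta``:   δ¹³C in per mil (‰) relative to the VPDB standard,
* ``ratio``:   the ¹³C/¹²C ratio R,
* ``fraction``: the atom fraction F = ¹³C / (¹³C + ¹²C),

together with the two-phase (headspace + dissolved) combination of CO₂
pools, excess-¹³C computation against an unlabelled background, and
attribution of CO₂ (or biomarker) carbon to a labelled substrate.

All arithmetic inside the pipeline is carried out in atom fractions;
δ values appear only at the I/O boundary.  Every function accepts
scalars or numpy arrays and is shape-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "R_VPDB",
    "delta_to_ratio",
    "ratio_to_delta",
    "ratio_to_fraction",
    "fraction_to_ratio",
    "delta_to_fraction",
    "fraction_to_delta",
    "combine_phases",
    "excess_13c",
    "tracer_carbon",
    "IsotopeValue",
    "VialMeasurement",
    "SubstrateSpec",
]

#: ¹³C/¹²C ratio of the Vienna Pee Dee Belemnite reference standard.
R_VPDB = 0.0112372

ArrayLike = Union[float, np.ndarray]


def _maybe_scalar(x: np.ndarray) -> ArrayLike:
    return float(x) if np.ndim(x) == 0 else x


def delta_to_ratio(delta: ArrayLike) -> ArrayLike:
    """Convert δ¹³C (‰ vs VPDB) to the isotope ratio R = ¹³C/¹²C.

    R = (δ/1000 + 1) × R_VPDB.  δ must exceed −1000 ‰, the point at
    which the ratio would become non-positive.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        bad = np.asarray(delta)[np.asarray(delta) <= -1000.0]
        raise ValueError(
            f"delta must be > -1000 per mil (ratio must stay positive); got {bad.ravel()[0]!r}"
        )
    return _maybe_scalar((delta / 1000.0 + 1.0) * R_VPDB)


def ratio_to_delta(ratio: ArrayLike) -> ArrayLike:
    """Inverse of :func:`delta_to_ratio`: δ = (R/R_VPDB − 1) × 1000."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0):
        raise ValueError("isotope ratio must be non-negative")
    return _maybe_scalar((ratio / R_VPDB - 1.0) * 1000.0)


def ratio_to_fraction(ratio: ArrayLike) -> ArrayLike:
    """Atom fraction F = R / (R + 1) of a ¹³C/¹²C ratio R ≥ 0."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0):
        raise ValueError("isotope ratio must be non-negative")
    return _maybe_scalar(ratio / (ratio + 1.0))


def fraction_to_ratio(fraction: ArrayLike) -> ArrayLike:
    """Inverse of :func:`ratio_to_fraction`: R = F / (1 − F), F ∈ [0, 1)."""
    fraction = np.asarray(fraction, dtype=float)
    if np.any((fraction < 0) | (fraction >= 1)):
        raise ValueError("atom fraction must lie in [0, 1)")
    return _maybe_scalar(fraction / (1.0 - fraction))


def delta_to_fraction(delta: ArrayLike) -> ArrayLike:
    """δ¹³C (‰) → atom fraction, composing the two conversions above."""
    return ratio_to_fraction(delta_to_ratio(delta))


def fraction_to_delta(fraction: ArrayLike) -> ArrayLike:
    """Atom fraction → δ¹³C (‰)."""
    return ratio_to_delta(fraction_to_ratio(fraction))


def combine_phases(
    gas_conc: ArrayLike,
    gas_delta: ArrayLike,
    water_conc: ArrayLike,
    water_delta: ArrayLike,
    gas_correction: float = 1.0,
) -> ArrayLike:
    """Concentration-weighted δ¹³C of total CO₂ from headspace + water.

    ``gas_correction`` (default +1 ‰) is a signed fractionation
    correction added to the gas-phase δ before weighting; it accounts
    for equilibrium fractionation between gaseous and aqueous CO₂.
    Both concentrations must be in the same unit; only their ratio
    matters (the result is invariant to rescaling both).
    """
    gas_conc = np.asarray(gas_conc, dtype=float)
    water_conc = np.asarray(water_conc, dtype=float)
    if np.any(gas_conc < 0) or np.any(water_conc < 0):
        raise ValueError("phase concentrations must be non-negative")
    total = gas_conc + water_conc
    if np.any(total <= 0):
        raise ValueError("no CO2 to combine: both phase concentrations are zero")
    gas_delta = np.asarray(gas_delta, dtype=float)
    water_delta = np.asarray(water_delta, dtype=float)
    out = ((gas_delta + gas_correction) * gas_conc + water_delta * water_conc) / total
    return _maybe_scalar(out)


def excess_13c(delta_sample: ArrayLike, delta_background: ArrayLike) -> ArrayLike:
    """Excess ¹³C: E = F(sample) − F(background), in atom-fraction units.

    Negative values (sample below background, possible from measurement
    noise) are returned as-is; clipping to zero would bias cumulative
    sums.  Callers that assemble tables log a warning instead.
    """
    fs = np.asarray(delta_to_fraction(delta_sample), dtype=float)
    fb = np.asarray(delta_to_fraction(delta_background), dtype=float)
    return _maybe_scalar(fs - fb)


def tracer_carbon(
    excess: ArrayLike, total_carbon: ArrayLike, substrate: "SubstrateSpec"
) -> ArrayLike:
    """Substrate-derived carbon: E × C_total / F_substrate.

    ``total_carbon`` is the total CO₂ carbon (or PLFA carbon) in any
    unit; the result is in the same unit.  ``substrate.atom_fraction_13c``
    is the fractional ¹³C abundance of the labelled substrate (0.97 for
    the lignocellulose used here).
    """
    if substrate.atom_fraction_13c <= 0:
        raise ValueError("substrate atom fraction must be positive")
    total_carbon = np.asarray(total_carbon, dtype=float)
    if np.any(total_carbon < 0):
        raise ValueError("total carbon must be non-negative")
    excess = np.asarray(excess, dtype=float)
    return _maybe_scalar(excess * total_carbon / substrate.atom_fraction_13c)


@dataclass(frozen=True)
class IsotopeValue:
    """One isotope measurement, stored internally as an atom fraction.

    Construct via :meth:`from_delta`, :meth:`from_ratio` or
    :meth:`from_fraction`; read any of the three representations as
    properties.  Round-trips are exact to floating-point precision.
    """

    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction < 1.0):
            raise ValueError(f"atom fraction must lie in [0, 1); got {self.fraction}")

    @classmethod
    def from_delta(cls, delta: float) -> "IsotopeValue":
        return cls(float(delta_to_fraction(delta)))

    @classmethod
    def from_ratio(cls, ratio: float) -> "IsotopeValue":
        return cls(float(ratio_to_fraction(ratio)))

    @classmethod
    def from_fraction(cls, fraction: float) -> "IsotopeValue":
        return cls(float(fraction))

    @property
    def ratio(self) -> float:
        return float(fraction_to_ratio(self.fraction))

    @property
    def delta(self) -> float:
        return float(fraction_to_delta(self.fraction))


@dataclass(frozen=True)
class VialMeasurement:
    """Headspace CO₂ and dissolved inorganic carbon of one vial at one day.

    Concentrations are carbon amounts per vial (μg C by default — the
    unit is declared in the run configuration and used consistently).
    """

    vial_id: str
    treatment: str
    day: float
    gas_conc: float
    gas_delta: float
    water_conc: float
    water_delta: float

    def __post_init__(self) -> None:
        if self.gas_conc < 0 or self.water_conc < 0:
            raise ValueError(f"vial {self.vial_id}: negative phase concentration")

    def combined_delta(self, gas_correction: float = 1.0) -> float:
        """δ¹³C of total CO₂ (gas + water), see :func:`combine_phases`."""
        return float(
            combine_phases(
                self.gas_conc,
                self.gas_delta,
                self.water_conc,
                self.water_delta,
                gas_correction,
            )
        )

    @property
    def total_conc(self) -> float:
        return self.gas_conc + self.water_conc


@dataclass(frozen=True)
class SubstrateSpec:
    """An added substrate pool: isotopic label strength, dose, and C/N.

    ``atom_fraction_13c`` is the fractional abundance of ¹³C (0.97 for
    the labelled wheat lignocellulose; natural abundance ≈ 0.0111 for
    unlabelled diatom detritus).  ``dose_mgc_per_ml`` is mg C per mL of
    wet sediment.
    """

    name: str
    atom_fraction_13c: float
    dose_mgc_per_ml: float
    cn_ratio: float | None = None
    labelled: bool = field(default=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.atom_fraction_13c < 1.0):
            raise ValueError(
                f"substrate {self.name}: atom fraction must be in (0, 1), got {self.atom_fraction_13c}"
            )
        if self.dose_mgc_per_ml < 0:
            raise ValueError(f"substrate {self.name}: dose must be non-negative")
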