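"""Piezoresistive strain-gauge physics and voltage-divider readout.

A semiconductor strain gauge changes resistance under strain through two
mechanisms: the geometric effect (captured by the Poisson ratio) and the
piezoresistive effect (bandgap shift changing carrier mobility), the latter
dominating in doped single-crystalline silicon. The gauge factor

    G = (dR/R) / (dL/L) = 1 + 2*nu + pi_l * E

relates relative resistance change to applied strain; ``nu`` is the Poisson
ratio, ``pi_l`` the longitudinal piezoresistive coefficient (1/Pa) and ``E``
the Young's modulus (Pa). The viscoelastic relaxation time of the gauge is
``tau = eta / E`` with ``eta`` the viscosity term (Pa*s) — stiff silicon
relaxes fast, which is what makes it usable for dynamic facial-strain
recording.

In the recording chain each gauge sits in a voltage divider fed from a fixed
supply, so the measured voltage encodes the gauge resistance. The divider
topology used throughout this package: gauge on the supply side, fixed
resistor to ground, voltage read across the fixed resistor.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "GaugeSpec",
    "DividerCircuit",
    "gauge_factor",
    "relaxation_time",
    "strain_to_relative_resistance",
    "resistance_to_voltage",
    "voltage_to_relative_resistance",
]

#: Elastic strain range the linearized transduction model is valid for.
MAX_STRAIN = 0.3


@dataclass(frozen=True)
class GaugeSpec:
    """Material and circuit constants of one strain gauge.

    Parameters
    ----------
    poisson_ratio : float
        Poisson ratio ``nu``, dimensionless, in [0, 0.5].
    piezo_coeff : float
        Longitudinal piezoresistive coefficient ``pi_l`` in 1/Pa.
    youngs_modulus : float
        Young's modulus ``E`` in Pa; > 0.
    viscosity : float
        Viscous behaviour term ``eta`` in Pa*s; >= 0.
    base_resistance : float
        Unstrained gauge resistance ``R0`` in Ohm; > 0.
    """

    poisson_ratio: float = 0.27
    piezo_coeff: float = 6.215e-10
    youngs_modulus: float = 1.6e11
    viscosity: float = 0.0
    base_resistance: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError(f"poisson_ratio must be in [0, 0.5], got {self.poisson_ratio}")
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if self.base_resistance <= 0:
            raise ValueError("base_resistance must be positive")
        if self.viscosity < 0:
            raise ValueError("viscosity must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GaugeSpec":
        return cls(**d)


@dataclass(frozen=True)
class DividerCircuit:
    """Voltage-divider readout: supply voltage and fixed resistor.

    The gauge is in the high-side position; ``V_in`` is read across the
    fixed resistor ``R_f``:  V_in = V_s * R_f / (R_gauge + R_f).
    """

    supply_voltage: float = 3.0
    fixed_resistance: float = 1000.0

    def __post_init__(self) -> None:
        if self.supply_voltage <= 0:
            raise ValueError("supply_voltage must be positive")
        if self.fixed_resistance <= 0:
            raise ValueError("fixed_resistance must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DividerCircuit":
        return cls(**d)


def gauge_factor(spec: GaugeSpec) -> float:
    """Gauge factor G = 1 + 2*nu + pi_l * E.

    ~2 for metals (geometric effect only), ~100 for doped silicon where the
    piezoresistive term dominates.
    """
    return 1.0 + 2.0 * spec.poisson_ratio + spec.piezo_coeff * spec.youngs_modulus


def relaxation_time(spec: GaugeSpec) -> float:
    """Strain relaxation time tau = eta / E, in seconds."""
    return spec.viscosity / spec.youngs_modulus


def strain_to_relative_resistance(spec: GaugeSpec, strain_trace) -> np.ndarray:
    """Linearized transduction dR/R = G * eps, elementwise.

    Valid for the elastic range |eps| <= 0.3; outside it the constant-G
    linearization is not trusted and a ValueError is raised.
    """
    eps = np.asarray(strain_trace, dtype=float)
    if np.any(np.abs(eps) > MAX_STRAIN):
        raise ValueError(f"strain outside the elastic range |eps| <= {MAX_STRAIN}")
    return gauge_factor(spec) * eps


def resistance_to_voltage(circuit: DividerCircuit, resistance_trace) -> np.ndarray:
    """Divider output V_in = V_s * R_f / (R + R_f) per sample."""
    r = np.asarray(resistance_trace, dtype=float)
    if np.any(r <= 0):
        raise ValueError("gauge resistance must be positive")
    return circuit.supply_voltage * circuit.fixed_resistance / (r + circuit.fixed_resistance)


def voltage_to_relative_resistance(circuit: DividerCircuit, voltage_trace, base_resistance: float) -> np.ndarray:
    """Invert the divider: R = R_f*(V_s - V)/V, then dR/R = (R - R0)/R0."""
    v = np.asarray(voltage_trace, dtype=float)
    if np.any((v <= 0) | (v >= circuit.supply_voltage)):
        raise ValueError("voltage must lie strictly inside (0, supply_voltage)")
    if base_resistance <= 0:
        raise ValueError("base_resistance must be positive")
    r = circuit.fixed_resistance * (circuit.supply_voltage - v) / v
    return (r - base_resistance) / base_resistance
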