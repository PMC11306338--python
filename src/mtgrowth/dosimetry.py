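"""Waveguide exposure dosimetry: power budget, peak field, SAR.

Arithmetic for a parallel-plate transmission-line exposure system driven by
a signal generator: dBm/mW conversion, the reflected/transmitted/absorbed
power budget from measured S-parameters, the peak electric field across the
plate gap of a matched line, linear interpolation of the field along the
exposure section, and the specific absorption rate SAR = sigma * E^2 / rho.

Conventions: powers in mW unless suffixed _dbm; S-parameters in dB (<= 0);
fields are *peak* values in V/m and are used in the SAR formula as
tabulated, without a peak-to-RMS reduction (see the methods note); SAR in
W/kg, reported to the nearest 100 W/kg in table form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

from .errors import InputError, SParameterWarning

__all__ = [
    "ExposureSetting",
    "MediumProps",
    "PowerBudget",
    "dbm_to_mw",
    "mw_to_dbm",
    "power_budget",
    "peak_field_nominal",
    "field_at_measurement",
    "sar",
    "round_sar",
    "guideline_ratio",
    "exposure_report",
]


@dataclass(frozen=True)
class ExposureSetting:
    """One exposure configuration (frequency, powers, losses, geometry)."""

    frequency_ghz: float
    source_power_dbm: float
    s11_db: float
    s21_db: float
    cable_loss_db: float = 0.8
    gap_m: float = 1e-3
    line_impedance_ohm: float = 50.0
    exposure_length_m: float = 0.025
    measurement_position: float = 0.5  # fraction along the exposure section

    def __post_init__(self):
        if self.gap_m <= 0:
            raise InputError("gap must be > 0")
        if self.line_impedance_ohm <= 0:
            raise InputError("line impedance must be > 0")
        if self.s11_db > 0 or self.s21_db > 0:
            raise InputError("S-parameters must be <= 0 dB")
        if not 0.0 <= self.measurement_position <= 1.0:
            raise InputError("measurement_position must lie in [0, 1]")

    @property
    def input_power_mw(self) -> float:
        """Power delivered to the waveguide after cable loss [mW]."""
        return dbm_to_mw(self.source_power_dbm - self.cable_loss_db)


@dataclass(frozen=True)
class MediumProps:
    """Electrical properties of the absorbing medium (sample buffer)."""

    conductivity_s_per_m: float = 0.8
    density_kg_per_m3: float = 1000.0

    def __post_init__(self):
        if self.conductivity_s_per_m <= 0 or self.density_kg_per_m3 <= 0:
            raise InputError("conductivity and density must be > 0")


def dbm_to_mw(p_dbm: float) -> float:
    """Power in mW from dBm: 10**(dBm/10)."""
    return 10.0 ** (p_dbm / 10.0)


def mw_to_dbm(p_mw: float) -> float:
    """Power in dBm from mW: 10*log10(mW)."""
    if p_mw <= 0:
        raise InputError("power must be > 0 to express in dBm")
    return 10.0 * math.log10(p_mw)


class PowerBudget(NamedTuple):
    reflected_mw: float
    transmitted_mw: float
    absorbed_mw: float


def power_budget(p_in_mw: float, s11_db: float, s21_db: float) -> PowerBudget:
    """Split input power into reflected, transmitted, absorbed parts.

    reflected = P * 10**(S11/10); transmitted = P * 10**(S21/10); absorbed
    is the remainder, so the three parts sum to the input exactly.  A
    negative remainder (inconsistent S-parameters) raises an
    :class:`SParameterWarning` but is still returned.
    """
    if p_in_mw < 0:
        raise InputError("input power must be >= 0")
    reflected = p_in_mw * 10.0 ** (s11_db / 10.0)
    transmitted = p_in_mw * 10.0 ** (s21_db / 10.0)
    absorbed = p_in_mw - reflected - transmitted
    if absorbed < 0:
        warnings.warn(
            f"S-parameters imply negative absorbed power ({absorbed:.3g} mW)",
            SParameterWarning,
            stacklevel=2,
        )
    return PowerBudget(reflected, transmitted, absorbed)


def peak_field_nominal(p_mw: float, impedance_ohm: float = 50.0,
                       gap_m: float = 1e-3) -> float:
    """Peak field [V/m] of a matched line carrying ``p_mw`` across a gap.

    ``E = sqrt(2 * P * Z) / d`` with P in watts: the peak voltage of a
    matched transmission line divided by the plate separation.  Quadrupling
    the power doubles the field.
    """
    if p_mw < 0 or impedance_ohm <= 0 or gap_m <= 0:
        raise InputError("power must be >= 0; impedance and gap > 0")
    return math.sqrt(2.0 * (p_mw / 1000.0) * impedance_ohm) / gap_m


def field_at_measurement(setting: ExposureSetting, interp: str = "field") -> float:
    """Peak field [V/m] at the measurement point along the exposure section.

    The power at the section entry is the input less the reflected part,
    ``P_in * (1 - 10**(S11/10))``; at the exit it is the transmitted part,
    ``P_in * 10**(S21/10)``.  Both are converted to fields across the gap
    and interpolated at ``measurement_position`` — linearly in field by
    default (``interp="field"``), or linearly in power with
    ``interp="power"``.
    """
    p_in = setting.input_power_mw
    p_entry = p_in * (1.0 - 10.0 ** (setting.s11_db / 10.0))
    p_exit = p_in * 10.0 ** (setting.s21_db / 10.0)
    pos = setting.measurement_position
    if interp == "field":
        e_entry = peak_field_nominal(p_entry, setting.line_impedance_ohm, setting.gap_m)
        e_exit = peak_field_nominal(p_exit, setting.line_impedance_ohm, setting.gap_m)
        return e_entry + (e_exit - e_entry) * pos
    if interp == "power":
        p_here = p_entry + (p_exit - p_entry) * pos
        return peak_field_nominal(p_here, setting.line_impedance_ohm, setting.gap_m)
    raise InputError(f"unknown interpolation basis {interp!r}")


def sar(medium: MediumProps, e_peak_v_per_m: float) -> float:
    """Specific absorption rate: sigma * E^2 / rho [W/kg]."""
    if e_peak_v_per_m < 0:
        raise InputError("field must be >= 0")
    return (medium.conductivity_s_per_m * e_peak_v_per_m ** 2
            / medium.density_kg_per_m3)


def round_sar(sar_w_per_kg: float) -> float:
    """Round a SAR to the nearest 100 W/kg (half away from zero)."""
    return math.floor(sar_w_per_kg / 100.0 + 0.5) * 100.0


def guideline_ratio(sar_value: float, guideline: float = 0.08) -> float:
    """Ratio of a SAR to an exposure guideline (default 0.08 W/kg whole-body)."""
    if sar_value < 0:
        raise InputError("SAR must be >= 0")
    if guideline <= 0:
        raise InputError("guideline must be > 0")
    return sar_value / guideline


def exposure_report(setting: ExposureSetting, medium: MediumProps,
                    interp: str = "field") -> dict:
    """Full dosimetry summary for one exposure configuration."""
    p_in = setting.input_power_mw
    budget = power_budget(p_in, setting.s11_db, setting.s21_db)
    e_nominal = peak_field_nominal(p_in, setting.line_impedance_ohm, setting.gap_m)
    e_meas = field_at_measurement(setting, interp=interp)
    sar_meas = sar(medium, e_meas)
    return {
        "frequency_ghz": setting.frequency_ghz,
        "source_power_dbm": setting.source_power_dbm,
        "input_power_mw": p_in,
        "reflected_mw": budget.reflected_mw,
        "transmitted_mw": budget.transmitted_mw,
        "absorbed_mw": budget.absorbed_mw,
        "peak_field_nominal_v_per_m": e_nominal,
        "peak_field_at_measurement_v_per_m": e_meas,
        "sar_w_per_kg": sar_meas,
        "sar_rounded_w_per_kg": round_sar(sar_meas),
        "whole_body_guideline_ratio": guideline_ratio(sar_meas),
    }
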