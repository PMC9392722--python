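"""Stimulus-waveform safety arithmetic for charge-balanced biphasic pulses.

Single-pulse electrical stimulation uses charge-balanced biphasic square waves
(two phases of equal duration and opposite polarity).  The quantities that
matter for tissue safety are the charge delivered per phase and the charge
density at the electrode surface.
"""

from __future__ import annotations

import math


def charge_per_phase_uc(current_ma: float, phase_ms: float) -> float:
    """Charge per phase in microcoulombs for a square current pulse.

    Q = I * t; 9 mA over a 0.2 ms phase delivers 1.8 uC/phase.
    """
    if current_ma <= 0 or phase_ms <= 0:
        raise ValueError("current and phase duration must be positive")
    return current_ma * 1e-3 * phase_ms * 1e-3 * 1e6


def biphasic_total_duration_ms(phase_ms: float, n_phases: int = 2,
                               interphase_ms: float = 0.0) -> float:
    """Total pulse duration: sum of phases plus any inter-phase gap."""
    if phase_ms <= 0 or n_phases < 1:
        raise ValueError("invalid pulse geometry")
    return n_phases * phase_ms + (n_phases - 1) * interphase_ms


def cylinder_contact_area_cm2(diameter_mm: float, length_mm: float) -> float:
    """Lateral surface area of a cylindrical depth-electrode contact, cm^2."""
    return math.pi * (diameter_mm / 10.0) * (length_mm / 10.0)


def charge_density_uc_per_cm2(current_ma: float, phase_ms: float,
                              area_cm2: float) -> float:
    """Charge density per phase at the contact surface."""
    if area_cm2 <= 0:
        raise ValueError("contact area must be positive")
    return charge_per_phase_uc(current_ma, phase_ms) / area_cm2
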