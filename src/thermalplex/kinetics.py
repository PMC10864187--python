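"""Hybridization kinetics over a heating protocol.

A single duplex obeys

    d(theta)/dt = k_on * c * (1 - theta) - k_off(T(t)) * theta

with a temperature-independent association rate ``k_on`` (default
1e6 1/(M s), a standard oligonucleotide magnitude) and a dissociation
rate slaved to the equilibrium constant, ``k_off(T) = k_on / K(T)``, so
the ODE's fixed point reproduces the two-state occupancy at every
temperature.  ``T(t)`` is piecewise linear over protocol segments
(about 5 s ramp to the spike setpoint, ~20 s cool-down to 30 deg C in
the standard protocol).

Two regimes matter for channel switching: dissociation at the spike is
fast (k_off of order 1/s a few degrees above Tm), while rebinding during
imaging is negligible because dissociated strands sit at femtomolar to
picomolar effective concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .spectrum import ThermalProbeSet
from .thermo import (
    BindingConditions,
    DuplexThermo,
    equilibrium_constant,
    fraction_bound,
)

__all__ = [
    "RateModel",
    "TempProtocol",
    "simulate_protocol",
    "rebinding_fraction",
    "dissociation_time",
]


@dataclass(frozen=True)
class RateModel:
    """Association/dissociation rates for one duplex."""

    thermo: DuplexThermo
    k_on: float = 1e6  # 1/(M s)

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValueError("k_on must be positive")

    def k_off(self, temp_C: float) -> float:
        """Dissociation rate (1/s) at temp_C, from detailed balance."""
        return self.k_on / equilibrium_constant(self.thermo, temp_C)


@dataclass(frozen=True)
class TempProtocol:
    """Piecewise-linear temperature schedule.

    ``segments`` is a list of (target_temp_C, ramp_s, hold_s): ramp
    linearly from the previous temperature to the target, then hold.
    """

    segments: Sequence[tuple]
    start_temp_C: float = 25.0
    imaging_temp_C: float = 30.0

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("protocol needs at least one segment")
        for tgt, ramp, hold in self.segments:
            if ramp < 0 or hold < 0:
                raise ValueError("ramp and hold durations must be >= 0")

    @property
    def total_s(self) -> float:
        return float(sum(r + h for _, r, h in self.segments))

    def temperature(self, t_s: float) -> float:
        """Temperature (deg C) at elapsed time t_s."""
        t = float(t_s)
        prev = self.start_temp_C
        for target, ramp, hold in self.segments:
            if t <= ramp:
                return prev + (target - prev) * (t / ramp if ramp > 0 else 1.0)
            t -= ramp
            if t <= hold:
                return float(target)
            t -= hold
            prev = target
        return float(prev)

    @classmethod
    def spike(
        cls,
        spike_temp_C: float,
        ramp_s: float = 5.0,
        hold_s: float = 10.0,
        cool_s: float = 20.0,
        start_temp_C: float = 25.0,
        imaging_temp_C: float = 30.0,
        imaging_hold_s: float = 30.0,
    ) -> "TempProtocol":
        """Standard heating spike: ramp up, hold, cool to imaging temp."""
        return cls(
            segments=[
                (spike_temp_C, ramp_s, hold_s),
                (imaging_temp_C, cool_s, imaging_hold_s),
            ],
            start_temp_C=start_temp_C,
            imaging_temp_C=imaging_temp_C,
        )


def simulate_protocol(
    probe: ThermalProbeSet,
    protocol: TempProtocol,
    k_on: float = 1e6,
    free_conc_M: float = 0.0,
    sample_hz: float = 20.0,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Integrate both duplex occupancies over a temperature protocol.

    ``free_conc_M`` is the concentration of dissociated strands available
    for rebinding (close to zero after wash-out).  Both duplexes start at
    their equilibrium occupancy at the protocol start temperature.
    Returns a data frame with columns t_s, temp_C, theta_barcode,
    theta_quencher sampled on a fixed grid of at least ``sample_hz``.

    Raises RuntimeError with the solver message if the integration fails.
    """
    if free_conc_M < 0:
        raise ValueError("free_conc_M must be >= 0")
    rates_b = RateModel(probe.barcode, k_on)
    rates_q = RateModel(probe.quencher, k_on)

    def rhs(t, y):
        T = protocol.temperature(t)
        out = np.empty(2)
        for idx, rates in enumerate((rates_b, rates_q)):
            theta = y[idx]
            out[idx] = k_on * free_conc_M * (1.0 - theta) - rates.k_off(T) * theta
        return out

    T0 = protocol.temperature(0.0)
    y0 = [
        fraction_bound(probe.barcode, probe.barcode_conditions, T0),
        fraction_bound(probe.quencher, probe.quencher_conditions, T0),
    ]
    # NB: the initial equilibrium uses the hybridization concentrations;
    # the ODE itself sees only the (post-wash) free concentration.
    total = protocol.total_s
    n = max(int(math.ceil(total * sample_hz)) + 1, 2)
    t_eval = np.linspace(0.0, total, n)
    sol = solve_ivp(
        rhs,
        (0.0, total),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        max_step=max(total / 50.0, 1e-3),
    )
    if not sol.success:
        raise RuntimeError(f"kinetic integration failed: {sol.message}")
    temps = np.array([protocol.temperature(t) for t in sol.t])
    return pd.DataFrame(
        {
            "t_s": sol.t,
            "temp_C": temps,
            "theta_barcode": np.clip(sol.y[0], 0.0, 1.0),
            "theta_quencher": np.clip(sol.y[1], 0.0, 1.0),
        }
    )


def rebinding_fraction(
    rates: RateModel,
    free_conc_M: float,
    duration_s: float,
    temp_C: float,
) -> float:
    """Fraction of sites rebound after ``duration_s`` at ``temp_C``.

    Pseudo-first-order estimate 1 - exp(-k_on c t), capped by the
    equilibrium occupancy at the imaging temperature (the occupancy the
    system relaxes toward).
    """
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    if free_conc_M < 0:
        raise ValueError("free_conc_M must be >= 0")
    if free_conc_M == 0 or duration_s == 0:
        return 0.0
    approach = 1.0 - math.exp(-rates.k_on * free_conc_M * duration_s)
    cond = BindingConditions(strand_conc_M=free_conc_M, temp_C=temp_C)
    eq = fraction_bound(rates.thermo, cond)
    return float(min(approach, eq))


def dissociation_time(
    rates: RateModel, temp_C: float, completion: float = 0.99
) -> float:
    """Time (s) for the bound fraction to fall to (1-completion) of its
    initial value at fixed temperature with no rebinding: t = -ln(1-f)/k_off."""
    if not (0 < completion < 1):
        raise ValueError("completion must be in (0, 1)")
    return -math.log(1.0 - completion) / rates.k_off(temp_C)
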