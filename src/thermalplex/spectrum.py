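"""Thermal spectra of two-domain probe sets.

A thermal probe set couples an imager strand (fluorophore) to a barcode
domain with melting temperature ``T_mb`` and prehybridizes a quencher
strand to the imager with melting temperature ``T_mq`` (``T_mq < T_mb``
for a useful probe).  Fluorescence appears only in the window where the
quencher has melted off but the imager is still bound, so the modeled
signal is the product of two independent two-state occupancies:

    signal(T) = theta_barcode(T) * (1 - theta_quencher(T))

The "thermal spectrum" is this curve on a temperature grid, summarized by
the signal temperature T_s (argmax), the yield (maximum), and the width W
(full width at half maximum, interpolated between grid points).

Sequential-protocol semantics: dissociated strands stay diffused and do
not rebind on cool-down at imaging concentrations, so the fluorescence
imaged at ~30 deg C after a heating spike equals the equilibrium signal at
the spike temperature, and spikes must be applied in increasing order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .thermo import (
    BindingConditions,
    DuplexThermo,
    duplex_thermo_from_sequence,
    fraction_bound,
    melting_temperature,
    thermo_from_tm,
)

__all__ = [
    "DEFAULT_DH_BARCODE",
    "DEFAULT_DH_QUENCHER",
    "ThermalProbeSet",
    "ThermalSpectrum",
    "thermal_spectrum",
    "probe_signal",
    "protocol_signal_matrix",
]

# Default domain formation enthalpies (kcal/mol) used when a domain is
# specified by melting temperature alone.  They correspond to typical
# barcode (~23 nt) and quencher (~19 nt) duplex lengths and set the
# steepness of the melting transitions; see docs/methods.md for how the
# five-channel design constrains them.
DEFAULT_DH_BARCODE = -180.0
DEFAULT_DH_QUENCHER = -150.0


@dataclass(frozen=True)
class ThermalProbeSet:
    """One barcode/imager/quencher triple.

    ``barcode`` is the imager-barcode duplex, ``quencher`` the
    quencher-imager duplex.  Each domain carries its own working
    conditions; the quencher strand is mixed at ``quencher_excess_ratio``
    times the imager concentration (1.2:1 by default) to guarantee
    complete quenching, which is reflected in its working concentration.
    """

    name: str
    barcode: DuplexThermo
    quencher: DuplexThermo
    barcode_conditions: BindingConditions
    quencher_conditions: BindingConditions
    fluor: str = "Alexa647"
    quencher_excess_ratio: float = 1.2

    def __post_init__(self) -> None:
        if self.quencher_excess_ratio < 1.0:
            raise ValueError("quencher_excess_ratio must be >= 1")

    @property
    def tmb_C(self) -> float:
        """Melting temperature of the imager-barcode duplex (deg C)."""
        return melting_temperature(self.barcode, self.barcode_conditions)

    @property
    def tmq_C(self) -> float:
        """Melting temperature of the quencher-imager duplex (deg C)."""
        return melting_temperature(self.quencher, self.quencher_conditions)

    @classmethod
    def from_tms(
        cls,
        name: str,
        tmb_C: float,
        tmq_C: float,
        conditions: Optional[BindingConditions] = None,
        dH_barcode: float = DEFAULT_DH_BARCODE,
        dH_quencher: float = DEFAULT_DH_QUENCHER,
        fluor: str = "Alexa647",
        quencher_excess_ratio: float = 1.2,
    ) -> "ThermalProbeSet":
        """Build a probe from the two domain melting temperatures.

        Each Tm is interpreted at the domain's working concentration (the
        quencher's includes the excess ratio), so the stated values are
        the operative melting temperatures of the assembled probe.
        """
        cond = conditions or BindingConditions()
        qcond = cond.replace(strand_conc_M=cond.strand_conc_M * quencher_excess_ratio)
        return cls(
            name=name,
            barcode=thermo_from_tm(tmb_C, dH_barcode, cond),
            quencher=thermo_from_tm(tmq_C, dH_quencher, qcond),
            barcode_conditions=cond,
            quencher_conditions=qcond,
            fluor=fluor,
            quencher_excess_ratio=quencher_excess_ratio,
        )

    @classmethod
    def from_sequences(
        cls,
        name: str,
        barcode_seq: str,
        quencher_seq: str,
        conditions: Optional[BindingConditions] = None,
        fluor: str = "Alexa647",
        quencher_excess_ratio: float = 1.2,
    ) -> "ThermalProbeSet":
        """Build a probe from the two domain sequences via the NN model."""
        cond = conditions or BindingConditions()
        qcond = cond.replace(strand_conc_M=cond.strand_conc_M * quencher_excess_ratio)
        return cls(
            name=name,
            barcode=duplex_thermo_from_sequence(barcode_seq, cond.salt_mM),
            quencher=duplex_thermo_from_sequence(quencher_seq, cond.salt_mM),
            barcode_conditions=cond,
            quencher_conditions=qcond,
            fluor=fluor,
            quencher_excess_ratio=quencher_excess_ratio,
        )


@dataclass
class ThermalSpectrum:
    """Signal-vs-temperature curve with its summary quantities."""

    temps_C: np.ndarray
    signal: np.ndarray
    ts_C: float
    signal_yield: float
    width_C: float
    probe: Optional[ThermalProbeSet] = None

    def signal_at(self, temp_C: float) -> float:
        """Signal at the nearest grid temperature."""
        i = int(np.argmin(np.abs(self.temps_C - temp_C)))
        return float(self.signal[i])


def probe_signal(probe: ThermalProbeSet, temps_C) -> np.ndarray:
    """Model signal theta_b(T) * (1 - theta_q(T)) at the given temperatures."""
    temps_C = np.asarray(temps_C, dtype=float)
    theta_b = fraction_bound(probe.barcode, probe.barcode_conditions, temps_C)
    theta_q = fraction_bound(probe.quencher, probe.quencher_conditions, temps_C)
    return theta_b * (1.0 - theta_q)


def _interp_crossing(t0, t1, s0, s1, level):
    if s1 == s0:
        return t0
    return t0 + (level - s0) * (t1 - t0) / (s1 - s0)


def thermal_spectrum(
    probe: ThermalProbeSet,
    t_min_C: float = 20.0,
    t_max_C: float = 80.0,
    step_C: float = 0.1,
) -> ThermalSpectrum:
    """Evaluate a probe's thermal spectrum on a uniform temperature grid.

    Width is the distance between the two half-maximum crossings, located
    by linear interpolation; when the signal stays above half maximum at a
    grid edge, the edge temperature is used for that crossing.
    """
    if not (t_min_C < t_max_C and step_C > 0):
        raise ValueError("need t_min < t_max and step > 0")
    n = int(round((t_max_C - t_min_C) / step_C)) + 1
    if n < 3:
        raise ValueError("temperature grid must have at least 3 points")
    temps = t_min_C + step_C * np.arange(n)
    sig = probe_signal(probe, temps)

    i_max = int(np.argmax(sig))
    peak = float(sig[i_max])
    half = peak / 2.0

    # left half-max crossing
    left = temps[0]
    for i in range(i_max, 0, -1):
        if sig[i - 1] < half <= sig[i]:
            left = _interp_crossing(temps[i - 1], temps[i], sig[i - 1], sig[i], half)
            break
    # right half-max crossing
    right = temps[-1]
    for i in range(i_max, len(temps) - 1):
        if sig[i] >= half > sig[i + 1]:
            right = _interp_crossing(temps[i], temps[i + 1], sig[i], sig[i + 1], half)
            break

    return ThermalSpectrum(
        temps_C=temps,
        signal=sig,
        ts_C=float(temps[i_max]),
        signal_yield=peak,
        width_C=float(right - left),
        probe=probe,
    )


def protocol_signal_matrix(
    panel: Sequence[ThermalProbeSet], spike_temps_C: Sequence[float]
) -> np.ndarray:
    """Predicted signal of each probe after each heating spike.

    Entry (i, j) is probe i's fluorescence imaged after spike j (and
    cool-down), which under the irreversible-melting semantics equals the
    equilibrium signal at the spike temperature.  Spikes must be strictly
    increasing, matching the sequential protocol.
    """
    spikes = np.asarray(spike_temps_C, dtype=float)
    if spikes.ndim != 1 or len(spikes) == 0:
        raise ValueError("spike_temps_C must be a non-empty 1-D sequence")
    if len(spikes) > 1 and not np.all(np.diff(spikes) > 0):
        raise ValueError(
            "spike temperatures must be strictly increasing: the sequential "
            "protocol cannot revisit lower temperatures"
        )
    return np.vstack([probe_signal(p, spikes) for p in panel])
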