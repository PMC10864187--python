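"""Nearest-neighbor duplex thermodynamics and two-state binding equilibria.

Every melting curve, design-space scan and kinetic simulation in this
package rests on the same physical model: a DNA duplex treated as a
two-state (all-or-none) system with formation enthalpy ``dH`` and entropy
``dS`` obtained either from a nearest-neighbor (NN) sum over the sequence
or back-derived from a stated melting temperature.

The binding convention is "free ligand": the fluorescent (or quencher)
strand is present in large excess at concentration ``c`` over its
surface-tethered target, so the bound fraction of target sites is

    theta(T) = c*K(T) / (1 + c*K(T)),   K(T) = exp(-(dH - T*dS)/(R*T))

and the melting temperature (theta = 1/2) has the closed form

    Tm = dH / (dS + R*ln c).

Temperatures are degrees Celsius at every public interface and Kelvin
internally; R = 1.987 cal/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "R_CAL",
    "CELSIUS_OFFSET",
    "DuplexThermo",
    "BindingConditions",
    "InvalidSequenceError",
    "duplex_thermo_from_sequence",
    "melting_temperature",
    "thermo_from_tm",
    "fraction_bound",
    "equilibrium_constant",
    "reverse_complement",
]

R_CAL = 1.987  # gas constant, cal/(mol K)
CELSIUS_OFFSET = 273.15

# Unified NN parameters for Watson-Crick DNA duplexes at 1 M NaCl.
# Keyed by the top-strand 5'->3' dinucleotide; values are (dH kcal/mol,
# dS cal/(mol K)).  A stack and its reverse complement share one entry.
NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

# Duplex initiation, per terminal base pair.
NN_INIT_GC = (0.1, -2.8)
NN_INIT_AT = (2.3, 4.1)
# Entropic penalty for a self-complementary duplex.
NN_SYMMETRY_DS = -1.4

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidSequenceError(ValueError):
    """Raised for sequences that cannot parameterize a duplex."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DuplexThermo:
    """Two-state formation thermodynamics of one duplex.

    Parameters
    ----------
    dH_kcal : formation enthalpy in kcal/mol (negative for a stable duplex).
    dS_cal : formation entropy in cal/(mol K) (negative).
    source : ``"from_sequence"`` if the values came from an NN sum,
        ``"from_tm"`` if back-derived from a stated melting temperature.
    """

    dH_kcal: float
    dS_cal: float
    source: str = "from_sequence"

    def __post_init__(self) -> None:
        if not (self.dH_kcal < 0 and self.dS_cal < 0):
            raise ValueError(
                f"duplex formation requires dH < 0 and dS < 0, got "
                f"dH={self.dH_kcal} kcal/mol, dS={self.dS_cal} cal/(mol K)"
            )
        if self.source not in ("from_sequence", "from_tm"):
            raise ValueError(f"unknown provenance {self.source!r}")


@dataclass(frozen=True)
class BindingConditions:
    """Solution conditions for one hybridization equilibrium.

    ``strand_conc_M`` is the molar concentration of the free (excess)
    strand; the reference value 250 nM matches the standard thermal-probe
    working concentration.  ``salt_mM`` is total monovalent cation.
    """

    strand_conc_M: float = 250e-9
    salt_mM: float = 195.0
    temp_C: float = 30.0

    def __post_init__(self) -> None:
        if self.strand_conc_M <= 0:
            raise ValueError("strand_conc_M must be positive")
        if self.salt_mM <= 0:
            raise ValueError("salt_mM must be positive")

    def replace(self, **kw) -> "BindingConditions":
        d = {"strand_conc_M": self.strand_conc_M, "salt_mM": self.salt_mM,
             "temp_C": self.temp_C}
        d.update(kw)
        return BindingConditions(**d)


def duplex_thermo_from_sequence(seq: str, salt_mM: float = 195.0) -> DuplexThermo:
    """NN-sum thermodynamics of a perfectly complementary duplex.

    Sums the unified NN stack parameters over the sequence, adds the two
    terminal initiation terms, the symmetry term when the sequence is
    self-reverse-complementary, and a monovalent-salt entropy correction
    of 0.368 * (N-1) * ln([Na+]) cal/(mol K) relative to 1 M.
    """
    seq = seq.strip().upper()
    if len(seq) < 2:
        raise InvalidSequenceError(
            f"need at least 2 nt to form a stacked duplex, got {seq!r}"
        )
    bad = set(seq) - set("ACGT")
    if bad:
        raise InvalidSequenceError(f"non-ACGT characters in sequence: {sorted(bad)}")

    dH = 0.0
    dS = 0.0
    for i in range(len(seq) - 1):
        h, s = NN_UNIFIED[seq[i : i + 2]]
        dH += h
        dS += s
    for terminal in (seq[0], seq[-1]):
        h, s = NN_INIT_GC if terminal in "GC" else NN_INIT_AT
        dH += h
        dS += s
    if seq == reverse_complement(seq):
        dS += NN_SYMMETRY_DS
    # entropic salt correction relative to the 1 M reference table
    dS += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    return DuplexThermo(dH_kcal=dH, dS_cal=dS, source="from_sequence")


def melting_temperature(thermo: DuplexThermo, cond: BindingConditions) -> float:
    """Melting temperature (deg C) under the free-ligand convention.

    The temperature at which ``fraction_bound`` is exactly one half:
    Tm = dH / (dS + R ln c), with dH in cal/mol.
    """
    denom = thermo.dS_cal + R_CAL * math.log(cond.strand_conc_M)
    if denom >= 0:
        raise ValueError(
            "nonphysical duplex: dS + R ln(c) must be negative "
            f"(got {denom:.3f} cal/(mol K))"
        )
    return thermo.dH_kcal * 1000.0 / denom - CELSIUS_OFFSET


def thermo_from_tm(
    tm_C: float, dH_kcal: float, cond: BindingConditions
) -> DuplexThermo:
    """Back-derive dS so the duplex melts at exactly ``tm_C`` under ``cond``."""
    if dH_kcal >= 0:
        raise ValueError("dH_kcal must be negative for a stable duplex")
    tm_K = tm_C + CELSIUS_OFFSET
    dS = dH_kcal * 1000.0 / tm_K - R_CAL * math.log(cond.strand_conc_M)
    return DuplexThermo(dH_kcal=dH_kcal, dS_cal=dS, source="from_tm")


def equilibrium_constant(
    thermo: DuplexThermo, temp_C: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Duplex formation constant K(T) = exp(-(dH - T dS)/(R T)), 1/M."""
    T = np.asarray(temp_C, dtype=float) + CELSIUS_OFFSET
    dG = thermo.dH_kcal * 1000.0 - T * thermo.dS_cal
    K = np.exp(-dG / (R_CAL * T))
    return float(K) if np.isscalar(temp_C) else K


def fraction_bound(
    thermo: DuplexThermo,
    cond: BindingConditions,
    temp_C: Union[float, np.ndarray, None] = None,
) -> Union[float, np.ndarray]:
    """Equilibrium bound fraction theta(T) = cK/(1 + cK).

    Evaluated at ``temp_C`` if given, else at ``cond.temp_C``.  Strictly
    decreasing in temperature for dH < 0; theta(Tm) = 1/2 exactly.
    """
    if temp_C is None:
        temp_C = cond.temp_C
    T = np.asarray(temp_C, dtype=float) + CELSIUS_OFFSET
    # theta = 1/(1 + exp(-x)) with x = ln(cK); compute in log space for
    # stability at temperatures far from Tm.
    x = (
        np.log(cond.strand_conc_M)
        - (thermo.dH_kcal * 1000.0 - T * thermo.dS_cal) / (R_CAL * T)
    )
    theta = 0.5 * (1.0 + np.tanh(0.5 * x))
    return float(theta) if np.isscalar(temp_C) else theta
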