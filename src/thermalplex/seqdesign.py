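"""Domain sequence generation and cross-hybridization screening.

``design_domain`` draws candidate sequences under composition constraints
and hill-climbs single-base changes toward a target melting temperature;
all randomness sits behind an explicit seed and infeasible specifications
fail loudly after a bounded number of attempts.

``orthogonality_screen`` is a conservative in silico hybridization test:
for every non-cognate strand pair it locates the strongest perfectly
complementary contiguous segment over all alignments (both orientations,
no internal loops or bulges) and reports that segment's NN-predicted
melting temperature.  A pair passes when the off-target Tm stays below a
threshold, by default the panel's wash temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .thermo import (
    BindingConditions,
    InvalidSequenceError,
    duplex_thermo_from_sequence,
    melting_temperature,
    reverse_complement,
)

__all__ = [
    "DomainSpec",
    "OrthogonalityReport",
    "FeasibilityError",
    "design_domain",
    "sequence_tm",
    "strongest_offtarget_tm",
    "orthogonality_screen",
]

BASES = "ACGT"


class FeasibilityError(RuntimeError):
    """No sequence satisfying the spec was found within the attempt budget."""


@dataclass(frozen=True)
class DomainSpec:
    """Constraints for one domain sequence."""

    target_tm_C: float
    tol_C: float = 1.0
    length_min: int = 10
    length_max: int = 30
    gc_min: float = 0.3
    gc_max: float = 0.7
    max_homopolymer: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.length_min < 2 or self.length_min > self.length_max:
            raise ValueError("need 2 <= length_min <= length_max")
        if not (0 <= self.gc_min <= self.gc_max <= 1):
            raise ValueError("GC bounds must satisfy 0 <= gc_min <= gc_max <= 1")
        if self.tol_C <= 0:
            raise ValueError("tol_C must be positive")


def sequence_tm(seq: str, cond: BindingConditions) -> float:
    """NN melting temperature of a sequence's perfect duplex under cond."""
    return melting_temperature(
        duplex_thermo_from_sequence(seq, cond.salt_mM), cond
    )


def _satisfies(seq: str, spec: DomainSpec) -> bool:
    gc = sum(b in "GC" for b in seq) / len(seq)
    if not (spec.gc_min <= gc <= spec.gc_max):
        return False
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > spec.max_homopolymer:
            return False
    return True


def _random_valid(rng: np.random.Generator, length: int, spec: DomainSpec,
                  tries: int = 200) -> Optional[str]:
    for _ in range(tries):
        seq = "".join(rng.choice(list(BASES), size=length))
        if _satisfies(seq, spec):
            return seq
    return None


def design_domain(
    spec: DomainSpec,
    cond: Optional[BindingConditions] = None,
    max_attempts: int = 40,
    max_steps: int = 400,
) -> str:
    """Generate one sequence meeting the spec, deterministically per seed.

    Each attempt draws a random valid sequence at a random allowed length
    and then walks single-base substitutions, accepting a change when it
    shrinks the Tm error without violating composition constraints.  The
    first sequence within ``tol_C`` of the target is returned.
    """
    cond = cond or BindingConditions()
    rng = np.random.default_rng(spec.rng_seed)
    lengths = np.arange(spec.length_min, spec.length_max + 1)

    for _ in range(max_attempts):
        length = int(rng.choice(lengths))
        seq = _random_valid(rng, length, spec)
        if seq is None:
            continue
        err = abs(sequence_tm(seq, cond) - spec.target_tm_C)
        for _ in range(max_steps):
            if err <= spec.tol_C:
                return seq
            pos = int(rng.integers(length))
            new_base = BASES[int(rng.integers(4))]
            if new_base == seq[pos]:
                continue
            cand = seq[:pos] + new_base + seq[pos + 1 :]
            if not _satisfies(cand, spec):
                continue
            cand_err = abs(sequence_tm(cand, cond) - spec.target_tm_C)
            if cand_err < err:
                seq, err = cand, cand_err
        if err <= spec.tol_C:
            return seq
    raise FeasibilityError(
        f"no sequence with Tm {spec.target_tm_C} +/- {spec.tol_C} deg C found "
        f"in {max_attempts} attempts (lengths {spec.length_min}-{spec.length_max})"
    )


def _match_runs(a: str, b: str):
    """Diagonal runs of exact matches between strings a and b (len >= 2)."""
    la, lb = len(a), len(b)
    prev = [0] * (lb + 1)
    for i in range(1, la + 1):
        cur = [0] * (lb + 1)
        for j in range(1, lb + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                # report maximal runs only: extendable runs are covered by
                # their longer continuation
                if i == la or j == lb or a[i] != b[j]:
                    if cur[j] >= 2:
                        yield a[i - cur[j] : i]
        prev = cur


def strongest_offtarget_tm(
    seq_a: str, seq_b: str, cond: BindingConditions
) -> float:
    """Tm of the strongest contiguous hybrid between two strands.

    Considers every perfectly complementary contiguous segment formable
    between the two strands in either relative orientation, evaluating
    all sub-segments of each maximal match run.  Returns -inf when no
    segment of >= 2 nt exists.
    """
    best = float("-inf")
    for b_oriented in (reverse_complement(seq_b), seq_b):
        for run in _match_runs(seq_a.upper(), b_oriented.upper()):
            L = len(run)
            for start in range(L - 1):
                for stop in range(start + 2, L + 1):
                    try:
                        tm = sequence_tm(run[start:stop], cond)
                    except (InvalidSequenceError, ValueError):
                        continue
                    best = max(best, tm)
    return best


@dataclass
class OrthogonalityReport:
    """Pairwise worst-case off-target duplex stability for a strand panel."""

    names: list
    tm_matrix: pd.DataFrame  # off-target Tm in deg C, NaN on the diagonal
    threshold_tm_C: float

    @property
    def pass_matrix(self) -> pd.DataFrame:
        return self.tm_matrix < self.threshold_tm_C

    @property
    def all_pass(self) -> bool:
        off = ~np.eye(len(self.names), dtype=bool)
        return bool((self.tm_matrix.values[off] < self.threshold_tm_C).all())

    def failing_pairs(self) -> list:
        out = []
        for i, a in enumerate(self.names):
            for j, b in enumerate(self.names):
                if i < j and self.tm_matrix.iloc[i, j] >= self.threshold_tm_C:
                    out.append((a, b, float(self.tm_matrix.iloc[i, j])))
        return out


def orthogonality_screen(
    strands: Dict[str, str],
    threshold_tm_C: float = 37.0,
    cond: Optional[BindingConditions] = None,
) -> OrthogonalityReport:
    """Screen a named strand panel for cross-hybridization.

    The report matrix holds, for each non-cognate pair, the NN-predicted
    Tm of the strongest contiguous complementary segment; the diagonal is
    excluded (NaN).  Duplicate names are rejected.
    """
    names = list(strands)
    if len(names) < 2:
        raise ValueError("need at least 2 strands to screen")
    if len(set(names)) != len(names):
        raise ValueError("duplicate strand names")
    cond = cond or BindingConditions()

    n = len(names)
    tm = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            t = strongest_offtarget_tm(strands[names[i]], strands[names[j]], cond)
            tm[i, j] = tm[j, i] = t
    return OrthogonalityReport(
        names=names,
        tm_matrix=pd.DataFrame(tm, index=names, columns=names),
        threshold_tm_C=threshold_tm_C,
    )
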