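"""Design-space scan and thermal-channel selection.

The design space is the plane of the two domain melting temperatures
(T_mb on one axis, T_mq on the other).  ``grid_scan`` evaluates the
thermal spectrum at every grid cell and records yield, signal temperature
and width maps.  Channels are mutually usable when each clears a yield
floor and every pair clears a crosstalk ceiling; the stock design rules
are yield > 0.8 and overlap < 0.12, with the lowest signal temperature
held above the post-hybridization wash condition (37 deg C floor).

Crosstalk between two spectra is, by default, the worst-case normalized
signal of one probe evaluated at the other's spike temperature:

    max( s_i(Ts_j)/yield_i , s_j(Ts_i)/yield_j )

Because imaging only happens at the spike temperatures this is
operationally exact for the sequential protocol.  An integral (Jaccard)
overlap of the normalized spectra is available as an alternative metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .spectrum import (
    DEFAULT_DH_BARCODE,
    DEFAULT_DH_QUENCHER,
    ThermalProbeSet,
    ThermalSpectrum,
    thermal_spectrum,
)
from .thermo import BindingConditions

__all__ = [
    "DesignGrid",
    "ChannelPanel",
    "DesignConstraints",
    "grid_scan",
    "crosstalk",
    "integral_overlap",
    "select_channels",
    "panel_at_signal_temps",
    "verify_panel",
]

PRINTED_SIGNAL_TEMPS = (39.0, 48.0, 57.0, 65.0, 72.0)


@dataclass(frozen=True)
class DesignConstraints:
    """Channel admission rules (see module docstring for defaults)."""

    yield_min: float = 0.8
    overlap_max: float = 0.12
    ts_floor_C: float = 37.0
    ts_ceiling_C: float = 75.0

    def __post_init__(self) -> None:
        if not (0 < self.yield_min <= 1):
            raise ValueError("yield_min must be in (0, 1]")
        if not (0 <= self.overlap_max <= 1):
            raise ValueError("overlap_max must be in [0, 1]")
        if self.ts_floor_C >= self.ts_ceiling_C:
            raise ValueError("ts_floor_C must be below ts_ceiling_C")


@dataclass
class DesignGrid:
    """Spectrum summaries over the (T_mb, T_mq) plane.

    Maps are indexed ``[i_tmb, i_tmq]``.  The grid remembers the model
    settings it was built with so individual cells can be re-instantiated
    as probes (``probe_at``) or full spectra (``spectrum_at``).
    """

    tmb_axis: np.ndarray
    tmq_axis: np.ndarray
    yield_map: np.ndarray
    ts_map: np.ndarray
    width_map: np.ndarray
    conditions: BindingConditions
    dH_barcode: float = DEFAULT_DH_BARCODE
    dH_quencher: float = DEFAULT_DH_QUENCHER
    spectrum_range: tuple = (20.0, 80.0, 0.1)
    _spectra: dict = field(default_factory=dict, repr=False)

    def probe_at(self, tmb_C: float, tmq_C: float, name: Optional[str] = None) -> ThermalProbeSet:
        return ThermalProbeSet.from_tms(
            name or f"probe_tmb{tmb_C:g}_tmq{tmq_C:g}",
            tmb_C,
            tmq_C,
            conditions=self.conditions,
            dH_barcode=self.dH_barcode,
            dH_quencher=self.dH_quencher,
        )

    def spectrum_at(self, tmb_C: float, tmq_C: float) -> ThermalSpectrum:
        key = (round(float(tmb_C), 6), round(float(tmq_C), 6))
        if key not in self._spectra:
            lo, hi, step = self.spectrum_range
            self._spectra[key] = thermal_spectrum(
                self.probe_at(tmb_C, tmq_C), lo, hi, step
            )
        return self._spectra[key]

    def cells(self):
        """Iterate (i, j, tmb, tmq) over the grid."""
        for i, tmb in enumerate(self.tmb_axis):
            for j, tmq in enumerate(self.tmq_axis):
                yield i, j, float(tmb), float(tmq)


@dataclass
class ChannelPanel:
    """A selected set of mutually compatible thermal channels."""

    probes: list
    signal_temps_C: np.ndarray
    yields: np.ndarray
    widths_C: np.ndarray
    overlap: np.ndarray
    constraints_used: DesignConstraints

    def __len__(self) -> int:
        return len(self.probes)


def grid_scan(
    tmb_range: Sequence[float] = (40.0, 80.0),
    tmq_range: Sequence[float] = (35.0, 75.0),
    step_C: float = 1.0,
    conditions: Optional[BindingConditions] = None,
    dH_barcode: float = DEFAULT_DH_BARCODE,
    dH_quencher: float = DEFAULT_DH_QUENCHER,
    spectrum_range: tuple = (20.0, 80.0, 0.1),
) -> DesignGrid:
    """Evaluate spectrum summaries at every (T_mb, T_mq) combination."""
    if step_C <= 0:
        raise ValueError("step_C must be positive")
    cond = conditions or BindingConditions()
    tmb_axis = np.arange(tmb_range[0], tmb_range[1] + 1e-9, step_C)
    tmq_axis = np.arange(tmq_range[0], tmq_range[1] + 1e-9, step_C)
    if len(tmb_axis) == 0 or len(tmq_axis) == 0:
        raise ValueError("empty melting-temperature range")

    grid = DesignGrid(
        tmb_axis=tmb_axis,
        tmq_axis=tmq_axis,
        yield_map=np.zeros((len(tmb_axis), len(tmq_axis))),
        ts_map=np.zeros((len(tmb_axis), len(tmq_axis))),
        width_map=np.zeros((len(tmb_axis), len(tmq_axis))),
        conditions=cond,
        dH_barcode=dH_barcode,
        dH_quencher=dH_quencher,
        spectrum_range=spectrum_range,
    )
    for i, j, tmb, tmq in grid.cells():
        spec = grid.spectrum_at(tmb, tmq)
        grid.yield_map[i, j] = spec.signal_yield
        grid.ts_map[i, j] = spec.ts_C
        grid.width_map[i, j] = spec.width_C
    return grid


def crosstalk(spec_i: ThermalSpectrum, spec_j: ThermalSpectrum) -> float:
    """Worst-case normalized signal of either probe at the other's spike."""
    if spec_i.signal_yield <= 0 or spec_j.signal_yield <= 0:
        raise ValueError("crosstalk is undefined for a zero-yield spectrum")
    if len(spec_i.temps_C) != len(spec_j.temps_C) or not np.allclose(
        spec_i.temps_C, spec_j.temps_C
    ):
        raise ValueError("spectra must share one temperature grid")
    a = spec_i.signal_at(spec_j.ts_C) / spec_i.signal_yield
    b = spec_j.signal_at(spec_i.ts_C) / spec_j.signal_yield
    return float(max(a, b))


def integral_overlap(spec_i: ThermalSpectrum, spec_j: ThermalSpectrum) -> float:
    """Jaccard overlap of the two peak-normalized spectra."""
    if spec_i.signal_yield <= 0 or spec_j.signal_yield <= 0:
        raise ValueError("overlap is undefined for a zero-yield spectrum")
    a = spec_i.signal / spec_i.signal_yield
    b = spec_j.signal / spec_j.signal_yield
    return float(np.minimum(a, b).sum() / np.maximum(a, b).sum())


def _overlap_fn(metric: str):
    if metric == "spike":
        return crosstalk
    if metric == "integral":
        return integral_overlap
    raise ValueError(f"unknown overlap metric {metric!r}")


def _build_panel(grid: DesignGrid, chosen, constraints: DesignConstraints,
                 metric: str) -> ChannelPanel:
    fn = _overlap_fn(metric)
    specs = [grid.spectrum_at(tmb, tmq) for tmb, tmq in chosen]
    n = len(specs)
    overlap = np.eye(n)
    for a, b in itertools.combinations(range(n), 2):
        overlap[a, b] = overlap[b, a] = fn(specs[a], specs[b])
    return ChannelPanel(
        probes=[s.probe for s in specs],
        signal_temps_C=np.array([s.ts_C for s in specs]),
        yields=np.array([s.signal_yield for s in specs]),
        widths_C=np.array([s.width_C for s in specs]),
        overlap=overlap,
        constraints_used=constraints,
    )


def select_channels(
    grid: DesignGrid,
    constraints: Optional[DesignConstraints] = None,
    metric: str = "spike",
) -> ChannelPanel:
    """Greedy floor-up selection of compatible thermal channels.

    Sweeping candidate cells by increasing signal temperature, a cell is
    admitted when its yield clears ``yield_min`` and its overlap with
    every already-admitted channel stays within ``overlap_max``.  Ties at
    equal signal temperature are broken by higher yield, then smaller
    width, then lower T_mb.  Returns an empty panel when no cell is
    feasible.
    """
    constraints = constraints or DesignConstraints()
    fn = _overlap_fn(metric)

    candidates = []
    for i, j, tmb, tmq in grid.cells():
        ts = grid.ts_map[i, j]
        if (
            grid.yield_map[i, j] >= constraints.yield_min
            and constraints.ts_floor_C <= ts <= constraints.ts_ceiling_C
        ):
            candidates.append(
                (ts, -grid.yield_map[i, j], grid.width_map[i, j], tmb, tmq)
            )
    candidates.sort()

    chosen: list[tuple[float, float]] = []
    for ts, negy, width, tmb, tmq in candidates:
        spec = grid.spectrum_at(tmb, tmq)
        if all(
            fn(spec, grid.spectrum_at(a, b)) <= constraints.overlap_max
            for a, b in chosen
        ):
            chosen.append((tmb, tmq))
    return _build_panel(grid, chosen, constraints, metric)


def panel_at_signal_temps(
    grid: DesignGrid,
    targets_C: Sequence[float] = PRINTED_SIGNAL_TEMPS,
    tol_C: float = 1.0,
    constraints: Optional[DesignConstraints] = None,
    metric: str = "spike",
) -> ChannelPanel:
    """Build one channel per requested signal temperature.

    For each target (ascending) the admitted cell is the narrowest-width
    cell whose signal temperature lies within ``tol_C`` of the target,
    whose yield clears the floor, and whose overlap with every channel
    already admitted stays within the ceiling (ties: higher yield, then
    lower T_mb).  Narrow cells sit on the high-yield diagonal of the
    design plane, which is exactly the region the design rules point to;
    picking by raw yield instead would admit wide plateau cells that
    overlap every other channel.

    Raises ``ValueError`` if some target has no compatible cell.
    """
    constraints = constraints or DesignConstraints()
    fn = _overlap_fn(metric)
    chosen: list[tuple[float, float]] = []
    for target in sorted(targets_C):
        best = None
        for i, j, tmb, tmq in grid.cells():
            if abs(grid.ts_map[i, j] - target) > tol_C:
                continue
            if grid.yield_map[i, j] < constraints.yield_min:
                continue
            spec = grid.spectrum_at(tmb, tmq)
            if any(
                fn(spec, grid.spectrum_at(a, b)) > constraints.overlap_max
                for a, b in chosen
            ):
                continue
            key = (grid.width_map[i, j], -grid.yield_map[i, j], tmb)
            if best is None or key < best[0]:
                best = (key, (tmb, tmq))
        if best is None:
            raise ValueError(
                f"no grid cell within {tol_C} deg C of target {target} deg C "
                "satisfies the yield and overlap rules"
            )
        chosen.append(best[1])
    return _build_panel(grid, chosen, constraints, metric)


def verify_panel(panel: ChannelPanel, metric: str = "spike") -> dict:
    """Re-evaluate every constraint from raw spectra (no self-certification).

    Returns a report dict with the recomputed quantities and a ``feasible``
    flag; spectra are recomputed from the probes at 0.1 deg C resolution.
    """
    fn = _overlap_fn(metric)
    specs = [thermal_spectrum(p) for p in panel.probes]
    ts = np.array([s.ts_C for s in specs])
    yields = np.array([s.signal_yield for s in specs])
    n = len(specs)
    max_overlap = 0.0
    for a, b in itertools.combinations(range(n), 2):
        max_overlap = max(max_overlap, fn(specs[a], specs[b]))
    c = panel.constraints_used
    feasible = (
        bool(np.all(yields >= c.yield_min))
        and max_overlap <= c.overlap_max
        and (n == 0 or ts.min() >= c.ts_floor_C)
        and (n == 0 or np.all(np.diff(np.sort(ts)) > 0))
    )
    return {
        "n_channels": n,
        "signal_temps_C": ts,
        "yields": yields,
        "max_overlap": max_overlap,
        "feasible": feasible,
    }
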