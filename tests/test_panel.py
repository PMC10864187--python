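"""Design-plane scan, crosstalk statistics, and channel selection."""

import itertools

import numpy as np
import pytest

from thermalplex.panel import (
    DesignConstraints,
    crosstalk,
    grid_scan,
    integral_overlap,
    panel_at_signal_temps,
    select_channels,
    verify_panel,
)
from thermalplex.spectrum import ThermalProbeSet, thermal_spectrum

PRINTED = (39.0, 48.0, 57.0, 65.0, 72.0)


def test_grid_cell_matches_direct_spectrum(default_grid):
    i = list(default_grid.tmb_axis).index(61.0)
    j = list(default_grid.tmq_axis).index(53.0)
    probe = ThermalProbeSet.from_tms(
        "x", 61.0, 53.0, conditions=default_grid.conditions
    )
    spec = thermal_spectrum(probe)
    assert default_grid.ts_map[i, j] == pytest.approx(spec.ts_C, abs=1e-12)
    assert default_grid.yield_map[i, j] == pytest.approx(spec.signal_yield, abs=1e-12)
    assert default_grid.width_map[i, j] == pytest.approx(spec.width_C, abs=1e-12)


def test_small_scan_equals_independent_spectra():
    """Brute-force oracle: a 3x3 scan is nine independent spectrum calls."""
    grid = grid_scan((55.0, 57.0), (45.0, 47.0), 1.0)
    for i, j, tmb, tmq in grid.cells():
        spec = thermal_spectrum(
            ThermalProbeSet.from_tms("x", tmb, tmq, conditions=grid.conditions)
        )
        assert grid.yield_map[i, j] == pytest.approx(spec.signal_yield, abs=1e-12)
        assert grid.ts_map[i, j] == pytest.approx(spec.ts_C, abs=1e-12)


def test_yield_grows_with_domain_separation(default_grid):
    tmb = list(default_grid.tmb_axis)
    tmq = list(default_grid.tmq_axis)
    wide = default_grid.yield_map[tmb.index(80.0), tmq.index(35.0)]
    tight = default_grid.yield_map[tmb.index(45.0), tmq.index(44.0)]
    assert wide > tight


def test_crosstalk_identity_and_symmetry(default_grid):
    sa = default_grid.spectrum_at(59.0, 53.0)
    sb = default_grid.spectrum_at(67.0, 61.0)
    assert crosstalk(sa, sa) == pytest.approx(1.0)
    assert crosstalk(sa, sb) == pytest.approx(crosstalk(sb, sa))
    assert 0 <= crosstalk(sa, sb) <= 1


def test_well_separated_probes_have_low_crosstalk(default_grid):
    sa = default_grid.spectrum_at(45.0, 37.0)
    sb = default_grid.spectrum_at(79.0, 71.0)
    assert abs(sa.ts_C - sb.ts_C) > 3 * max(sa.width_C, sb.width_C)
    assert crosstalk(sa, sb) < 0.12


def test_integral_overlap_behaves_like_a_similarity(default_grid):
    sa = default_grid.spectrum_at(59.0, 53.0)
    sb = default_grid.spectrum_at(75.0, 68.0)
    assert integral_overlap(sa, sa) == pytest.approx(1.0)
    assert 0 < integral_overlap(sa, sb) < integral_overlap(sa, sa)


def test_default_selection_covers_printed_channels(default_grid):
    """Stock design rules yield >= 5 channels covering 39/48/57/65/72 C."""
    panel = select_channels(default_grid)
    assert len(panel) >= 5
    for target in PRINTED:
        assert np.min(np.abs(panel.signal_temps_C - target)) <= 3.0
    report = verify_panel(panel)
    assert report["feasible"]


def test_selection_respects_constraints_post_hoc(default_grid):
    panel = select_channels(default_grid)
    off = ~np.eye(len(panel), dtype=bool)
    assert panel.overlap[off].max() <= 0.12
    assert panel.yields.min() >= 0.8
    assert panel.signal_temps_C.min() >= 37.0
    assert np.all(np.diff(panel.signal_temps_C) > 0)


def test_zero_overlap_budget_gives_single_channel(default_grid):
    panel = select_channels(
        default_grid, DesignConstraints(overlap_max=0.0)
    )
    assert len(panel) == 1


def test_channel_count_monotonicity(default_grid):
    loose = select_channels(default_grid, DesignConstraints(overlap_max=0.2))
    tight = select_channels(default_grid, DesignConstraints(overlap_max=0.05))
    assert len(tight) <= len(loose)
    easy = select_channels(default_grid, DesignConstraints(yield_min=0.7))
    hard = select_channels(default_grid, DesignConstraints(yield_min=0.9))
    assert len(hard) <= len(easy)


def test_greedy_matches_exhaustive_on_small_grid():
    """On a coarse 5x5 grid greedy channel count equals the best over all
    subsets (exhaustive enumeration oracle)."""
    grid = grid_scan((42.0, 74.0), (35.0, 67.0), 8.0)
    constraints = DesignConstraints()
    panel = select_channels(grid, constraints)

    feasible = [
        (tmb, tmq)
        for i, j, tmb, tmq in grid.cells()
        if grid.yield_map[i, j] >= constraints.yield_min
        and constraints.ts_floor_C <= grid.ts_map[i, j] <= constraints.ts_ceiling_C
    ]
    best = 0
    for r in range(len(feasible), 0, -1):
        for subset in itertools.combinations(feasible, r):
            specs = [grid.spectrum_at(a, b) for a, b in subset]
            if all(
                crosstalk(x, y) <= constraints.overlap_max
                for x, y in itertools.combinations(specs, 2)
            ):
                best = r
                break
        if best:
            break
    assert len(panel) == best


def test_anchored_panel_at_printed_temperatures(default_grid):
    panel = panel_at_signal_temps(default_grid, PRINTED)
    assert len(panel) == 5
    for ts, target in zip(panel.signal_temps_C, PRINTED):
        assert abs(ts - target) <= 1.0
    off = ~np.eye(5, dtype=bool)
    assert panel.overlap[off].max() <= 0.12
    assert panel.yields.min() >= 0.8


def test_infeasible_anchoring_raises(default_grid):
    with pytest.raises(ValueError):
        panel_at_signal_temps(default_grid, (57.0, 58.0))  # 1 deg apart


def test_malformed_constraints_rejected():
    with pytest.raises(ValueError):
        DesignConstraints(yield_min=0.0)
    with pytest.raises(ValueError):
        DesignConstraints(overlap_max=1.5)
    with pytest.raises(ValueError):
        grid_scan(step_C=-1.0)
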