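"""Puncta quantification for multi-round spot images.

The pipeline mirrors standard single-molecule FISH practice: maximum
Z-projection, global threshold to a binary image, 8-connected components
of at least ``min_area`` pixels as puncta (centroid, area, max-pixel
intensity), greedy one-to-one colocalization between channels, per-cell
counting against a label mask, expression-based cell exclusion filters,
and a flat coordinate table for multi-round overlay figures.  Rounds are
acquired on-scope without moving the sample, so no registration stage
exists anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "Punctum",
    "ColocalizationResult",
    "max_z_projection",
    "compute_threshold",
    "detect_puncta",
    "colocalize",
    "per_cell_counts",
    "filter_cells",
    "overlay_reconstruction",
]


@dataclass(frozen=True)
class Punctum:
    """One detected diffraction-limited spot."""

    centroid: Tuple[float, float]  # (row, col), 0-based
    intensity: float  # max pixel value over the spot's pixels
    area: int
    channel: Optional[str] = None
    round_index: Optional[int] = None


def max_z_projection(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the leading (plane) axis."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a 3-D stack with at least one plane")
    return stack.max(axis=0)


def compute_threshold(
    image: np.ndarray, spec: Union[float, str, Tuple[str, float]] = "mean+5sd"
) -> float:
    """Resolve a threshold spec to an absolute intensity.

    A number is used as-is; ``"mean+<k>sd"`` (or the tuple form
    ``("mean_sd", k)``) is the image mean plus k standard deviations.
    """
    if isinstance(spec, (int, float)):
        return float(spec)
    if isinstance(spec, tuple) and spec[0] == "mean_sd":
        k = float(spec[1])
    elif isinstance(spec, str) and spec.startswith("mean+") and spec.endswith("sd"):
        k = float(spec[len("mean+") : -len("sd")])
    else:
        raise ValueError(f"unrecognized threshold spec {spec!r}")
    return float(image.mean() + k * image.std())


def detect_puncta(
    image: np.ndarray,
    threshold: Union[float, str, Tuple[str, float]] = "mean+5sd",
    min_area_px: int = 2,
    channel: Optional[str] = None,
    round_index: Optional[int] = None,
) -> List[Punctum]:
    """Threshold, label 8-connected components, and measure puncta.

    Components smaller than ``min_area_px`` are discarded; spots touching
    the image border are kept.  Intensity is the maximum original pixel
    value over the component.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_puncta expects a 2-D image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    thr = compute_threshold(image, threshold)
    labels = cc_label(image > thr, connectivity=2)
    out: List[Punctum] = []
    for region in regionprops(labels, intensity_image=image):
        if region.area < min_area_px:
            continue
        out.append(
            Punctum(
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                intensity=float(region.intensity_max),
                area=int(region.area),
                channel=channel,
                round_index=round_index,
            )
        )
    return out


@dataclass
class ColocalizationResult:
    """Two-channel colocalization fractions and the matched pairing.

    Fractions are percentages of each channel's own total; for an empty
    channel they are ``None``.  ``pairs`` holds (index_a, index_b).
    """

    n_a: int
    n_b: int
    pairs: List[Tuple[int, int]]
    radius_px: float

    @property
    def n_both(self) -> int:
        return len(self.pairs)

    @property
    def pct_both_a(self) -> Optional[float]:
        return 100.0 * self.n_both / self.n_a if self.n_a else None

    @property
    def pct_both_b(self) -> Optional[float]:
        return 100.0 * self.n_both / self.n_b if self.n_b else None

    @property
    def pct_only_a(self) -> Optional[float]:
        return 100.0 - self.pct_both_a if self.n_a else None

    @property
    def pct_only_b(self) -> Optional[float]:
        return 100.0 - self.pct_both_b if self.n_b else None


def colocalize(
    a: Sequence[Punctum], b: Sequence[Punctum], radius_px: float = 2.0
) -> ColocalizationResult:
    """Greedy one-to-one nearest-pair matching within a radius.

    Candidate pairs within ``radius_px`` are taken in order of distance
    (ties broken by the first channel's row then column), each punctum
    used at most once.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    if not a or not b:
        return ColocalizationResult(len(a), len(b), [], radius_px)

    pa = np.array([p.centroid for p in a])
    pb = np.array([p.centroid for p in b])
    tree = cKDTree(pb)
    candidates = []
    for i, pt in enumerate(pa):
        for j in tree.query_ball_point(pt, radius_px):
            d = float(np.hypot(*(pt - pb[j])))
            candidates.append((d, pa[i][0], pa[i][1], i, j))
    candidates.sort()
    used_a: set = set()
    used_b: set = set()
    pairs = []
    for d, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return ColocalizationResult(len(a), len(b), pairs, radius_px)


def per_cell_counts(
    puncta_by_target: Dict[str, Sequence[Punctum]],
    masks: np.ndarray,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Count puncta per (cell, target) by centroid lookup in a label mask.

    Returns (counts, background) where ``counts`` is cells x targets and
    ``background`` tallies puncta whose centroid lies on label 0.
    Centroids are rounded to the nearest pixel; a punctum outside the
    mask frame raises.
    """
    masks = np.asarray(masks)
    if masks.ndim != 2:
        raise ValueError("masks must be a 2-D label image")
    cell_ids = sorted(int(v) for v in np.unique(masks) if v > 0)
    targets = list(puncta_by_target)
    counts = pd.DataFrame(0, index=cell_ids, columns=targets, dtype=int)
    background = pd.Series(0, index=targets, dtype=int)
    for target, puncta in puncta_by_target.items():
        for p in puncta:
            r = int(round(p.centroid[0]))
            c = int(round(p.centroid[1]))
            if not (0 <= r < masks.shape[0] and 0 <= c < masks.shape[1]):
                raise ValueError(
                    f"punctum centroid {p.centroid} outside mask frame "
                    f"{masks.shape}"
                )
            lbl = int(masks[r, c])
            if lbl == 0:
                background[target] += 1
            else:
                counts.loc[lbl, target] += 1
    counts.index.name = "cell"
    return counts, background


def filter_cells(
    counts: pd.DataFrame,
    class_of_target: Dict[str, str],
    thresholds: Optional[Dict[str, int]] = None,
) -> pd.DataFrame:
    """Apply per-target expression-based cell exclusion.

    For targets of class ``"high"`` cells with fewer than 5 copies are
    excluded (set to NA for that target); for class ``"low"`` the cutoff
    is 2 copies.  Exclusion is per target, matching per-target statistics
    on manually segmented cells.
    """
    thresholds = thresholds or {"high": 5, "low": 2}
    out = counts.astype(float)
    for target in counts.columns:
        cls = class_of_target.get(target)
        if cls not in thresholds:
            raise ValueError(f"unknown expression class {cls!r} for {target!r}")
        out.loc[counts[target] < thresholds[cls], target] = np.nan
    return out


def overlay_reconstruction(
    channels: Iterable[Tuple[str, int, str, Sequence[Punctum]]],
) -> pd.DataFrame:
    """Flatten puncta from all (target, round, fluor) channels to one table.

    All rounds share one coordinate frame (on-scope acquisition, no
    registration), so the output is directly plottable as a multi-target
    scatter overlay with columns row, col, target, round, fluor,
    intensity.
    """
    rows = []
    for target, round_index, fluor, puncta in channels:
        for p in puncta:
            rows.append(
                {
                    "row": p.centroid[0],
                    "col": p.centroid[1],
                    "target": target,
                    "round": round_index,
                    "fluor": fluor,
                    "intensity": p.intensity,
                }
            )
    return pd.DataFrame(
        rows, columns=["row", "col", "target", "round", "fluor", "intensity"]
    )
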