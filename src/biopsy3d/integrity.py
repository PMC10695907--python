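"""Per-specimen structural quality features.

Four features characterise a biopsy specimen segmented from a volumetric
scan:

* **volume** — foreground voxel count times the voxel volume, in mm³;
* **inner integrity** — the segmented volume divided by the volume after
  internal-rupture repair (closing, then hole filling); 1 means no inner
  cracks or voids;
* **outer integrity** — the surface-smoothed volume (opening) divided by
  the hole-filled volume; 1 means a smooth, cleanly cut surface;
* **compression score** — an ordinal 0/1/2 observer rating of crush
  artefacts at the forceps contact sites, aggregated by median.

Both ratios lie in (0, 1] and read identically: closer to 1 is a better
preserved specimen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .morphology import CUBE_27, StructuringElement, fill_holes, morph_close, morph_open
from .volumes import BinaryMask

__all__ = [
    "CompressionScores",
    "IntegritySummary",
    "compute_volume",
    "inner_integrity",
    "outer_integrity",
    "aggregate_compression",
    "summarize_specimen",
]


@dataclass(frozen=True)
class CompressionScores:
    """Ordinal compression ratings (0, 1 or 2) from independent observers."""

    per_observer: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.per_observer) == 0:
            raise ValueError("at least one observer score is required")
        for s in self.per_observer:
            if s not in (0, 1, 2):
                raise ValueError(f"compression scores must be in {{0, 1, 2}}, got {s}")

    @property
    def n_observers(self) -> int:
        return len(self.per_observer)


@dataclass(frozen=True)
class IntegritySummary:
    """Voxel counts at each morphological stage plus the derived features.

    ``n_seg <= n_closed <= n_filled_inner`` (closing and filling only add
    foreground) and ``n_smoothed <= n_filled_outer`` (opening only removes).
    ``opened_away`` flags the degenerate case of a specimen entirely removed
    by opening, for which the outer ratio is reported as 0.
    """

    n_seg: int
    n_closed: int
    n_filled_inner: int
    n_filled_outer: int
    n_smoothed: int
    volume_mm3: float
    inner_integrity: float
    outer_integrity: float
    compression_score: int | None = None
    opened_away: bool = False


def compute_volume(mask: BinaryMask) -> float:
    """Specimen volume in mm³: voxel count times the voxel volume."""
    return mask.n_foreground * mask.voxel_edge_um ** 3 * 1e-9


def inner_integrity(mask: BinaryMask, se: StructuringElement = CUBE_27,
                    background_connectivity: int = 6) -> tuple[int, int, int, float]:
    """Inner-rupture repair: close (1 iteration), then fill enclosed voids.

    Returns ``(n_seg, n_closed, n_filled_inner, ratio)`` with
    ``ratio = n_seg / n_filled_inner``.
    """
    n_seg = mask.n_foreground
    if n_seg == 0:
        raise ValueError("inner integrity is undefined for an empty mask")
    closed = morph_close(mask, se=se, iterations=1)
    filled = fill_holes(closed, background_connectivity=background_connectivity)
    n_closed = closed.n_foreground
    n_filled = filled.n_foreground
    return n_seg, n_closed, n_filled, n_seg / n_filled


def outer_integrity(mask: BinaryMask, se: StructuringElement = CUBE_27,
                    background_connectivity: int = 6) -> tuple[int, int, float, bool]:
    """Surface-roughness measure: fill enclosed voids, then open (1 iteration).

    Returns ``(n_filled_outer, n_smoothed, ratio, opened_away)`` with
    ``ratio = n_smoothed / n_filled_outer``.  Filling first stops inner
    cracks from contributing to the surface measure.
    """
    if mask.n_foreground == 0:
        raise ValueError("outer integrity is undefined for an empty mask")
    filled = fill_holes(mask, background_connectivity=background_connectivity)
    smoothed = morph_open(filled, se=se, iterations=1)
    n_filled = filled.n_foreground
    n_smoothed = smoothed.n_foreground
    opened_away = n_smoothed == 0
    if opened_away:
        warnings.warn("mask entirely removed by opening; outer integrity reported as 0",
                      stacklevel=2)
    return n_filled, n_smoothed, n_smoothed / n_filled, opened_away


def aggregate_compression(scores: CompressionScores) -> int:
    """Median observer score; the lower median for an even observer count.

    The lower median keeps the aggregate an attainable ordinal value.
    """
    ordered = sorted(scores.per_observer)
    return ordered[(len(ordered) - 1) // 2]


def summarize_specimen(mask: BinaryMask, se: StructuringElement = CUBE_27,
                       scores: CompressionScores | None = None,
                       background_connectivity: int = 6) -> IntegritySummary:
    """Compute all structural features of one segmented specimen."""
    n_seg, n_closed, n_filled_inner, inner = inner_integrity(
        mask, se=se, background_connectivity=background_connectivity)
    n_filled_outer, n_smoothed, outer, opened_away = outer_integrity(
        mask, se=se, background_connectivity=background_connectivity)
    return IntegritySummary(
        n_seg=n_seg,
        n_closed=n_closed,
        n_filled_inner=n_filled_inner,
        n_filled_outer=n_filled_outer,
        n_smoothed=n_smoothed,
        volume_mm3=compute_volume(mask),
        inner_integrity=inner,
        outer_integrity=outer,
        compression_score=None if scores is None else aggregate_compression(scores),
        opened_away=opened_away,
    )
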