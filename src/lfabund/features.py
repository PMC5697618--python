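"""Woody linear-feature classification and buffer-level covariates.

Linear boundary features of farmland (hedgerows, banks, ditches, tree
lines) are mapped as line segments with canopy-height summaries derived
from a surface-minus-terrain model.  A segment is called *woody* (a hedge
or tree line rather than a bank or ditch) when its canopy-height summary
statistics fall inside fixed thresholds.  Site-level covariates are the
total and woody lengths of linear features in a 1-km buffer, scaled by
100 000 m so they lie on [0, 1] like land-cover proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "SegmentCanopy",
    "BufferSummary",
    "WOODY_MEAN_MIN",
    "WOODY_MIN_EXCL",
    "WOODY_MAX_MAX",
    "LENGTH_SCALE_M",
    "classify_woody",
    "summarize_buffer",
    "scale_altitude",
    "exclusion_filter",
]

# Canopy-height thresholds (metres) of the woody classifier.  Strictness of
# each comparison is deliberate: mean is inclusive, minimum strict,
# maximum inclusive.
WOODY_MEAN_MIN = 0.58
WOODY_MIN_EXCL = -0.13
WOODY_MAX_MAX = 58.0

#: Divisor taking linear-feature lengths in metres onto the [0, 1] scale.
LENGTH_SCALE_M = 100_000.0

#: Altitude (m a.s.l.) above which sites are excluded: the woody model is
#: not predicted in uplands.
UPLAND_ALTITUDE_M = 450.0

#: Urban + suburban buffer proportion above which sites are excluded.
URBAN_PROPORTION_MAX = 0.10

#: Default woodland (broadleaf + conifer) proportion above which a site is
#: treated as forest and excluded.  The forest rule has no canonical
#: cutoff; this default is configurable and deliberately conservative.
FOREST_PROPORTION_DEFAULT = 0.5


@dataclass(frozen=True)
class SegmentCanopy:
    """Canopy-height summary of one linear-feature segment.

    Heights are in metres and may be slightly negative where the terrain
    model locally exceeds the surface model.
    """

    length_m: float
    canopy_mean: float
    canopy_min: float
    canopy_max: float

    def __post_init__(self) -> None:
        if self.length_m <= 0:
            raise ValueError(f"segment length must be > 0, got {self.length_m}")
        for name in ("canopy_mean", "canopy_min", "canopy_max"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if not (self.canopy_min <= self.canopy_mean <= self.canopy_max):
            raise ValueError(
                "require canopy_min <= canopy_mean <= canopy_max, got "
                f"({self.canopy_min}, {self.canopy_mean}, {self.canopy_max})"
            )


@dataclass(frozen=True)
class BufferSummary:
    """Total and woody linear-feature lengths within one 1-km buffer."""

    lf_total_m: float
    lf_woody_m: float

    @property
    def lf_total_scaled(self) -> float:
        return self.lf_total_m / LENGTH_SCALE_M

    @property
    def lf_woody_scaled(self) -> float:
        return self.lf_woody_m / LENGTH_SCALE_M


def classify_woody(seg: SegmentCanopy) -> bool:
    """Return True when a segment's canopy heights mark it as woody.

    Woody means mean canopy height >= 0.58 m, minimum canopy height
    strictly > -0.13 m and maximum canopy height <= 58 m.  The mixed
    strictness of the three comparisons is part of the rule.
    """
    return (
        seg.canopy_mean >= WOODY_MEAN_MIN
        and seg.canopy_min > WOODY_MIN_EXCL
        and seg.canopy_max <= WOODY_MAX_MAX
    )


def summarize_buffer(segments: Iterable[SegmentCanopy]) -> BufferSummary:
    """Sum segment lengths in a buffer, splitting out the woody subset.

    An empty segment list yields a zero summary rather than an error:
    buffers genuinely without boundary features exist.
    """
    total = 0.0
    woody = 0.0
    for seg in segments:
        total += seg.length_m
        if classify_woody(seg):
            woody += seg.length_m
    return BufferSummary(lf_total_m=total, lf_woody_m=woody)


def scale_altitude(altitude_m: float, max_altitude_m: float = UPLAND_ALTITUDE_M) -> float:
    """Scale altitude to [0, 1] by dividing by the study maximum."""
    if max_altitude_m <= 0:
        raise ValueError("max_altitude_m must be > 0")
    if not 0 <= altitude_m <= max_altitude_m:
        raise ValueError(
            f"altitude {altitude_m} m outside [0, {max_altitude_m}] m; "
            "upland sites should be removed by exclusion_filter first"
        )
    return altitude_m / max_altitude_m


def exclusion_filter(
    altitude_m: float,
    urban_proportion: float,
    forest_proportion: float = 0.0,
    *,
    forest_threshold: float = FOREST_PROPORTION_DEFAULT,
) -> bool:
    """Return True when a site is retained for analysis.

    Sites are dropped where the woody linear-feature model is not
    predicted: uplands (altitude > 450 m), urban areas (urban + suburban
    proportion > 0.10) and forests (woodland proportion above
    ``forest_threshold``; no canonical cutoff exists, default 0.5).
    """
    if altitude_m > UPLAND_ALTITUDE_M:
        return False
    if urban_proportion > URBAN_PROPORTION_MAX:
        return False
    if forest_proportion > forest_threshold:
        return False
    return True


def segments_to_frame(segments: Sequence[SegmentCanopy], site_id: str):
    """Tabulate segments as a DataFrame with the documented columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "site_id": site_id,
            "length_m": [s.length_m for s in segments],
            "canopy_mean": [s.canopy_mean for s in segments],
            "canopy_min": [s.canopy_min for s in segments],
            "canopy_max": [s.canopy_max for s in segments],
        }
    )
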