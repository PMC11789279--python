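"""Morphometry and dynamics of traced signalling protrusions.

Operates on manually traced filament polylines (filopodia/cytonemes of
radial glial cells, RGCs): summed path length, orientation relative to
the apicobasal axis with the stated sign convention (-90 deg apical,
i.e. towards the ventricle; +90 deg basal; 0 deg perpendicular),
per-cell protrusion density, time-lapse maximum extension and lifetime,
puncta counting along a trace, and median +/- i.q.r. summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

__all__ = [
    "FilamentTrace",
    "ProtrusionTrack",
    "CellOutline",
    "AxisFrame",
    "SummaryStats",
    "canonical_frame",
    "trace_length",
    "protrusion_angle",
    "protrusion_density",
    "track_dynamics",
    "summarise_median_iqr",
    "exclude_outliers",
    "count_dll1_puncta",
    "angle_length_bins",
]


@dataclass
class FilamentTrace:
    """Ordered 3D polyline of one protrusion at one time point (µm).

    ``points[base_index]`` is the point attached to the cell body; by
    convention traces start at the base (``base_index = 0``).
    """

    points: np.ndarray
    cell_id: int | str = 0
    side: str = "left"
    frame_time_min: Optional[float] = None
    base_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] == 2:  # allow planar traces, pad z = 0
            self.points = np.hstack(
                [self.points, np.zeros((self.points.shape[0], 1))]
            )
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if self.points.shape[0] < 2:
            raise ValueError("a filament trace needs at least 2 points")
        seg = np.diff(self.points, axis=0)
        if np.any(np.all(seg == 0, axis=1)):
            raise ValueError("consecutive trace points must be distinct")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass
class ProtrusionTrack:
    """Time-ordered filament snapshots of one protrusion.

    ``censored`` flags tracks truncated by the start or end of the movie;
    they are retained by default.
    """

    traces: list[FilamentTrace]
    frame_interval_min: float = 2.0
    censored: bool = False

    def __post_init__(self) -> None:
        if len(self.traces) < 1:
            raise ValueError("a track needs at least one frame")
        if not self.frame_interval_min > 0:
            raise ValueError("frame_interval_min must be > 0")
        times = [t.frame_time_min for t in self.traces]
        if any(t is None for t in times):
            raise ValueError("every trace in a track needs a frame time")
        diffs = np.diff(times)
        if len(diffs) and (
            np.any(diffs <= 0)
            or not np.allclose(diffs, self.frame_interval_min)
        ):
            raise ValueError(
                "frame times must increase uniformly by frame_interval_min"
            )

    @property
    def n_frames(self) -> int:
        return len(self.traces)


@dataclass
class CellOutline:
    """Traced apicobasal extent of one RGC with its attached protrusions."""

    cell_id: int | str
    apicobasal_path: np.ndarray
    protrusion_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.apicobasal_path = np.atleast_2d(
            np.asarray(self.apicobasal_path, dtype=float)
        )
        if self.path_length_um <= 0:
            raise ValueError("apicobasal path length must be > 0")

    @property
    def path_length_um(self) -> float:
        seg = np.diff(self.apicobasal_path, axis=0)
        return float(np.sqrt((seg**2).sum(axis=1)).sum())


@dataclass(frozen=True)
class AxisFrame:
    """Local tissue axes for one side of the ventricle.

    ``apical_dir`` is the unit vector pointing apically, i.e. towards the
    ventricle; ``dv_dir`` the dorsoventral unit vector.  The two must be
    orthonormal.  Because "towards the ventricle" points in opposite
    image directions on the two sides, a frame is side-specific.
    """

    apical_dir: tuple[float, float, float]
    dv_dir: tuple[float, float, float]
    side: str = "left"

    def __post_init__(self) -> None:
        a = np.asarray(self.apical_dir, float)
        d = np.asarray(self.dv_dir, float)
        if not (
            math.isclose(np.linalg.norm(a), 1.0, abs_tol=1e-9)
            and math.isclose(np.linalg.norm(d), 1.0, abs_tol=1e-9)
            and math.isclose(float(a @ d), 0.0, abs_tol=1e-9)
        ):
            raise ValueError("apical_dir and dv_dir must be orthonormal")


def canonical_frame(side: str) -> AxisFrame:
    """Frame for images laid out with the ventricle midline at high/low y.

    Convention: axis 0 is dorsoventral, axis 1 apicobasal, with cells on
    the left side apical towards +y and on the right side towards -y
    (mirror images across the ventricle).
    """
    if side == "left":
        return AxisFrame(apical_dir=(0.0, 1.0, 0.0), dv_dir=(1.0, 0.0, 0.0),
                         side="left")
    if side == "right":
        return AxisFrame(apical_dir=(0.0, -1.0, 0.0), dv_dir=(1.0, 0.0, 0.0),
                         side="right")
    raise ValueError("side must be 'left' or 'right'")


@dataclass(frozen=True)
class SummaryStats:
    median: float
    iqr: float
    n: int


# --------------------------------------------------------------------------
# morphometry


def trace_length(t: FilamentTrace) -> float:
    """Summed Euclidean length of the traced filament (µm)."""
    seg = np.diff(t.points, axis=0)
    return float(np.sqrt((seg**2).sum(axis=1)).sum())


def protrusion_angle(t: FilamentTrace, frame: AxisFrame) -> float:
    """Orientation of the base-to-tip chord, degrees in [-90, +90].

    -90 deg points apically (towards the ventricle), +90 deg basally,
    0 deg perpendicular to the apicobasal axis.  The basal component is
    signed; the in-plane (dorsoventral + out-of-plane) component enters
    as a magnitude, so mirror-image traces on the two sides map to the
    same angle when paired with their side's frame.
    """
    if t.side != frame.side:
        raise ValueError(
            f"trace side {t.side!r} does not match frame side {frame.side!r}"
        )
    chord = t.points[-1] - t.points[t.base_index]
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise ValueError("zero-length chord: angle undefined")
    apical = np.asarray(frame.apical_dir)
    basal_comp = -float(chord @ apical)
    perp = chord - (chord @ apical) * apical
    return math.degrees(math.atan2(basal_comp, float(np.linalg.norm(perp))))


def protrusion_density(cell: CellOutline) -> float:
    """Protrusions per µm of traced apicobasal cell length."""
    return len(cell.protrusion_ids) / cell.path_length_um


def track_dynamics(
    tr: ProtrusionTrack, frame: Optional[AxisFrame] = None
) -> tuple[float, float, float]:
    """(max length µm, lifetime min, angle at maximum extension deg).

    Lifetime is frames-observed x frame interval: a protrusion seen in a
    single 2 min frame has lifetime 2 min.  The angle is evaluated on
    the frame at which the trace length is maximal (first such frame on
    ties), in the given axis frame (default: the canonical frame for the
    track's side).
    """
    lengths = [trace_length(t) for t in tr.traces]
    i_max = int(np.argmax(lengths))
    max_length = lengths[i_max]
    lifetime = tr.n_frames * tr.frame_interval_min
    if frame is None:
        frame = canonical_frame(tr.traces[i_max].side)
    angle = protrusion_angle(tr.traces[i_max], frame)
    return max_length, lifetime, angle


def summarise_median_iqr(values: Iterable[float]) -> SummaryStats:
    """Median and interquartile range (linear-interpolation quantiles)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return SummaryStats(median=float(med), iqr=float(q3 - q1), n=arr.size)


def exclude_outliers(
    tracks: Sequence[ProtrusionTrack], lifetime_cap_min: float
) -> tuple[list[ProtrusionTrack], list[dict]]:
    """Drop tracks whose lifetime exceeds the cap; log every exclusion."""
    if not lifetime_cap_min > 0:
        raise ValueError("lifetime_cap_min must be > 0")
    kept, log = [], []
    for i, tr in enumerate(tracks):
        lifetime = tr.n_frames * tr.frame_interval_min
        if lifetime > lifetime_cap_min:
            log.append(
                {
                    "track_index": i,
                    "lifetime_min": lifetime,
                    "reason": f"lifetime {lifetime:g} min exceeds cap "
                    f"{lifetime_cap_min:g} min",
                }
            )
        else:
            kept.append(tr)
    return kept, log


def count_dll1_puncta(
    intensity_samples: Sequence[float],
    background_samples: Sequence[float],
    spacing_um: float = 1.0,
    k_mad: float = 3.0,
    min_sep_um: float = 1.0,
) -> int:
    """Count well-separated ligand puncta along a trace.

    A punctum is a strict local intensity maximum exceeding
    background median + ``k_mad`` x MAD that is at least ``min_sep_um``
    from any brighter punctum (closer maxima merge into one).
    """
    intensity = np.asarray(intensity_samples, dtype=float)
    background = np.asarray(background_samples, dtype=float)
    if intensity.size == 0 or background.size == 0:
        raise ValueError("intensity and background samples must be non-empty")
    mad = scipy.stats.median_abs_deviation(background, scale=1.0)
    threshold = np.median(background) + k_mad * mad
    distance = max(1.0, min_sep_um / spacing_um)
    peaks, _ = scipy.signal.find_peaks(
        intensity, height=np.nextafter(threshold, np.inf), distance=distance
    )
    return int(peaks.size)


def angle_length_bins(
    lengths_um: Sequence[float],
    angles_deg: Sequence[float],
    bin_width_deg: float = 15.0,
) -> pd.DataFrame:
    """Angle histograms per protrusion length class {<5, 5-10, >=10 µm}.

    Class edges are exactly 5 and 10 µm, right-open ([5, 10) holds 5.0
    but not 10.0).  Returns a tidy table with one row per protrusion:
    columns ``length_um``, ``angle_deg``, ``length_class``; per-class
    histograms follow from grouping on ``length_class`` (angle bins of
    ``bin_width_deg`` spanning [-90, 90]).
    """
    lengths = np.asarray(lengths_um, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    if lengths.size != angles.size:
        raise ValueError("lengths and angles must be paired")
    classes = pd.cut(
        lengths,
        bins=[-np.inf, 5.0, 10.0, np.inf],
        right=False,
        labels=["<5", "5-10", ">=10"],
    )
    df = pd.DataFrame(
        {"length_um": lengths, "angle_deg": angles, "length_class": classes}
    )
    df.attrs["angle_bin_edges"] = np.arange(-90.0, 90.0 + bin_width_deg,
                                            bin_width_deg)
    return df
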