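"""Idealised radial-glial packing and protrusion reach.

A to-scale schematic of RGC packing built from three measured widths
(apical endfoot 5.2 µm, radial process 1.6 µm, cell body 7.7 µm,
population means): cells are straight, not curved or intercalated, and
apical endfeet tile the ventricular surface so that nearest-neighbour
endfeet touch.  "Proximal" cells are those whose endfeet touch the
focal cell's endfoot; anything further is "distal".  A protrusion makes
a distal contact when it is strictly longer than the one intervening
structure it must cross: a neighbouring endfoot (from an endfoot) or a
neighbouring cell body (from a radial process).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PackingParams",
    "Layout",
    "ReachQuery",
    "required_reach",
    "reach_fraction",
    "neighbour_count",
    "contact_report",
]

#: endfeet touching the focal endfoot, by idealised packing of equal discs
_COORDINATION = {"hexagonal": 6, "square": 4, "linear": 2}


@dataclass(frozen=True)
class PackingParams:
    """Measured widths (µm) of the three RGC parts; defaults are the
    population means."""

    endfoot_w_um: float = 5.2
    process_w_um: float = 1.6
    body_w_um: float = 7.7

    def __post_init__(self) -> None:
        if min(self.endfoot_w_um, self.process_w_um, self.body_w_um) <= 0:
            raise ValueError("all widths must be > 0")
        if self.body_w_um < self.process_w_um:
            raise ValueError("body width must be >= process width")


@dataclass(frozen=True)
class Layout:
    """Idealised arrangement of equal-width apical endfeet.

    ``hexagonal`` is close packing on the 2D apical surface (the
    default); ``linear`` reproduces the 1D cross-section drawing;
    ``square`` is provided for comparison.  Neighbour relations depend
    only on the packing type (touching discs), not on the widths.
    """

    packing: str = "hexagonal"
    params: PackingParams = PackingParams()

    def __post_init__(self) -> None:
        if self.packing not in _COORDINATION:
            raise ValueError(
                f"packing must be one of {sorted(_COORDINATION)}"
            )

    def positions(self) -> np.ndarray:
        """Endfoot centres (µm) of the focal cell and its neighbours."""
        w = self.params.endfoot_w_um
        if self.packing == "linear":
            offs = [(-1, 0), (1, 0)]
        elif self.packing == "square":
            offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        else:  # hexagonal
            offs = [
                (np.cos(a), np.sin(a))
                for a in np.arange(6) * np.pi / 3.0
            ]
        return np.vstack([[0.0, 0.0]] + [[w * x, w * y] for x, y in offs])


@dataclass(frozen=True)
class ReachQuery:
    """Where the protrusion emanates from: 'endfoot' or 'process'."""

    origin: str
    params: PackingParams = PackingParams()

    def __post_init__(self) -> None:
        if self.origin not in ("endfoot", "process"):
            raise ValueError("origin must be 'endfoot' or 'process'")


def required_reach(q: ReachQuery) -> float:
    """Length (µm) a protrusion must exceed to contact a distal cell.

    From an apical endfoot it must cross one intervening endfoot
    (endfoot width); from a radial process it must cross one intervening
    cell body (body width).
    """
    if q.origin == "endfoot":
        return q.params.endfoot_w_um
    return q.params.body_w_um


def reach_fraction(lengths: Sequence[float], threshold_um: float) -> float:
    """Fraction of protrusions strictly longer than the threshold."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("lengths must be non-empty")
    return float(np.mean(arr > threshold_um))


def neighbour_count(layout: Layout) -> int:
    """Number of endfeet touching the focal cell's endfoot."""
    return _COORDINATION[layout.packing]


def contact_report(
    lengths: Sequence[float], params: PackingParams = PackingParams()
) -> pd.DataFrame:
    """Required reach and attainable fraction for both origin sites."""
    rows = []
    for origin in ("endfoot", "process"):
        reach = required_reach(ReachQuery(origin=origin, params=params))
        rows.append(
            {
                "origin": origin,
                "required_reach_um": reach,
                "fraction_reaching": reach_fraction(lengths, reach),
            }
        )
    return pd.DataFrame(rows)
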