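"""Western-blot densitometry normalization and reference-group scaling.

Band densities are normalized within-lane to the automated total-protein
measurement, then expressed as a percentage of a reference cohort mean —
the 4-month wildtype group, falling back to the 4-month homozygous group for
targets the wildtype does not express (human and pSer129 α-synuclein in a
human-transgene model are exactly zero in wildtype lanes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedReferenceError

TARGETS = ("human_asyn", "mouse_asyn", "pser129_asyn", "TH")


@dataclass(frozen=True)
class LaneRecord:
    animal_id: str
    genotype: str          # "WT" | "HOM"
    age: float             # months
    target: str
    band_density: float    # arbitrary units
    total_protein: float   # arbitrary units

    def __post_init__(self) -> None:
        if self.total_protein <= 0:
            raise InvalidParameterError("total_protein must be > 0")
        if self.band_density < 0:
            raise InvalidParameterError("band_density must be >= 0")


@dataclass(frozen=True)
class RelativeAbundance:
    normalized: float
    percent_of_reference: float
    reference_group: str


def normalize_lane(rec: LaneRecord) -> float:
    """Within-lane total-protein normalization: band density / TP."""
    return rec.band_density / rec.total_protein


def percent_of_reference(values: Sequence[float], groups: Sequence[str],
                         reference_group: str,
                         fallback_group: str | None = None,
                         zero_epsilon_frac: float = 1e-12,
                         ) -> list[RelativeAbundance]:
    """Express each value as a percentage of the reference-group mean.

    If the reference mean is indistinguishable from zero (below
    ``zero_epsilon_frac`` of the overall maximum — real densitometry never
    returns exact zeros, but the simulator does), the fallback group's mean
    is used instead and recorded in each result's ``reference_group``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    eps = zero_epsilon_frac * max(float(np.max(np.abs(values), initial=0.0)), 1.0)

    def group_mean(label: str) -> float:
        members = values[groups == label]
        if members.size == 0:
            raise UndefinedReferenceError(f"reference group {label!r} is empty")
        return float(members.mean())

    ref_label = reference_group
    ref_mean = group_mean(ref_label)
    if abs(ref_mean) <= eps:
        if fallback_group is None:
            raise UndefinedReferenceError(
                f"reference group {reference_group!r} mean is zero and no "
                "fallback group was given")
        ref_label = fallback_group
        ref_mean = group_mean(ref_label)
        if abs(ref_mean) <= eps:
            raise UndefinedReferenceError(
                "both reference and fallback group means are zero")
    return [RelativeAbundance(normalized=float(v),
                              percent_of_reference=100.0 * float(v) / ref_mean,
                              reference_group=ref_label)
            for v in values]


def total_alpha_syn(mouse: float, human: float, pser129: float) -> float:
    """Composite 'ALL' α-synuclein: sum of the three species on a common scale."""
    for name, v in (("mouse", mouse), ("human", human), ("pser129", pser129)):
        if v is None or not np.isfinite(v):
            raise InvalidParameterError(f"{name} α-SYN component missing/non-finite")
    return float(mouse + human + pser129)


def normalize_lane_table(lanes: pd.DataFrame) -> pd.DataFrame:
    """Vectorized lane normalization for a LaneRecord-shaped table.

    Expects columns ``animal_id, genotype, age, target, band_density,
    total_protein``; returns a copy with a ``normalized`` column.
    """
    if (lanes["total_protein"] <= 0).any():
        raise InvalidParameterError("total_protein must be > 0 in every lane")
    out = lanes.copy()
    out["normalized"] = out["band_density"] / out["total_protein"]
    return out
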