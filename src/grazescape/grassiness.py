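"""Grassiness index: weighted sum of gradient-class percentages in a buffer.

Each of the four woody-cover gradient classes contributes its buffer
percentage multiplied by an integer modifier — ×1 for closed deciduous
woodland up to ×4 for continuous grassland — so a fully grassy buffer scores
400 and a fully closed-woodland buffer scores 100. Non-gradient cover
(water, bare, built-up, agriculture, plantation) contributes zero and, in
the default mode, dilutes the index because percentages are taken over the
whole valid buffer area. ``renormalise_gradient=True`` instead rescales the
four gradient percentages to sum to 100 before weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .buffers import BufferProfile
from .scheme import ClassScheme, DEFAULT_SCHEME

__all__ = ["GrassinessValue", "grassiness_index", "grassiness_table"]


@dataclass(frozen=True)
class GrassinessValue:
    sample_id: object
    radius_m: float
    value: float


def grassiness_index(
    profile: BufferProfile,
    scheme: ClassScheme = DEFAULT_SCHEME,
    renormalise_gradient: bool = False,
) -> GrassinessValue:
    """Compute the 0–400 grassiness index for one buffer profile.

    Raises ``ValueError`` on a profile with no valid area, or (in
    renormalised mode) no gradient-class area at all.
    """
    if profile.empty:
        raise ValueError(
            f"profile for sample {profile.sample_id!r} at {profile.radius_m} m "
            "has zero valid area"
        )
    gradient = scheme.gradient_classes
    pcts = [profile.pct(c.code) for c in gradient]
    if renormalise_gradient:
        total = sum(pcts)
        if total <= 0:
            raise ValueError(
                f"sample {profile.sample_id!r}: no gradient-class area to renormalise"
            )
        pcts = [100.0 * p / total for p in pcts]
    value = sum(p * c.grassiness_modifier for p, c in zip(pcts, gradient))
    return GrassinessValue(profile.sample_id, profile.radius_m, value)


def grassiness_table(
    profiles: Iterable[BufferProfile],
    scheme: ClassScheme = DEFAULT_SCHEME,
    renormalise_gradient: bool = False,
    min_valid_fraction: Optional[float] = 0.5,
) -> pd.DataFrame:
    """Grassiness per sample × radius, excluding badly truncated buffers.

    Profiles whose ``valid_fraction`` falls below ``min_valid_fraction``
    (edge- or nodata-truncated beyond the configured tolerance) are dropped;
    pass ``None`` to keep everything.
    """
    records = []
    for p in profiles:
        if min_valid_fraction is not None and p.valid_fraction < min_valid_fraction:
            continue
        g = grassiness_index(p, scheme, renormalise_gradient)
        records.append(
            {
                "sample_id": p.sample_id,
                "radius_m": p.radius_m,
                "grassiness": g.value,
                "valid_fraction": p.valid_fraction,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["sample_id", "radius_m", "grassiness", "valid_fraction"]
    )
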