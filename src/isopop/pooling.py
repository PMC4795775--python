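"""Computational pooling of measurements into simulated mixed populations.

Summing two samples' MIDs channel-by-channel with weights (pA, 1-pA) is
exactly what a physical pool of the two cultures would measure, so pairs of
real (or simulated) one-state samples can stand in for two-subpopulation
experiments at arbitrary mixing ratios — the trick used to map inference
error over the (usage difference, minimum population size) plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .measurement import SampleMeasurement


@dataclass(frozen=True)
class PoolSpec:
    """Ground-truth annotation of one computational pool."""

    sample_a: str
    sample_b: str
    p_a: float
    usage_a: Optional[float] = None
    usage_b: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_a <= 1.0):
            raise ValueError("p_a must lie in [0, 1]")

    @property
    def min_population(self) -> float:
        return min(self.p_a, 1.0 - self.p_a)

    @property
    def delta_usage(self) -> Optional[float]:
        if self.usage_a is None or self.usage_b is None:
            return None
        return abs(self.usage_a - self.usage_b)


def pool(
    meas_a: SampleMeasurement,
    meas_b: SampleMeasurement,
    p_a: float,
    sample_id: Optional[str] = None,
) -> SampleMeasurement:
    """Channel-wise weighted sum pA*A + (1-pA)*B of two measurements."""
    if not (0.0 <= p_a <= 1.0):
        raise ValueError("p_a must lie in [0, 1]")
    if set(meas_a.mids) != set(meas_b.mids):
        raise ValueError("panel mismatch between pooled measurements")
    mids = {}
    for fid, a in meas_a.mids.items():
        b = meas_b.mids[fid]
        if a.shape != b.shape:
            raise ValueError(f"channel mismatch for fragment {fid}")
        mids[fid] = p_a * a + (1.0 - p_a) * b
    if sample_id is None:
        sample_id = f"pool({meas_a.sample_id},{meas_b.sample_id},{p_a:g})"
    return SampleMeasurement(sample_id, mids, replicate=meas_a.replicate)


def pooling_grid(
    library: Sequence[Tuple[SampleMeasurement, float]],
    p_a_values: Sequence[float],
    pairs: Optional[Sequence[Tuple[int, int]]] = None,
) -> List[Tuple[SampleMeasurement, PoolSpec]]:
    """Deterministic enumeration of annotated pools.

    ``library`` holds (measurement, ground-truth usage12c) pairs; the usage
    is typically the sample's one-state fit.  Every listed pair is pooled
    at every ``p_a``; by default all ordered pairs (a != b) are used.
    """
    if not library:
        raise ValueError("empty measurement library")
    if pairs is None:
        n = len(library)
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    out = []
    for i, j in pairs:
        meas_a, usage_a = library[i]
        meas_b, usage_b = library[j]
        for p_a in p_a_values:
            spec = PoolSpec(
                meas_a.sample_id, meas_b.sample_id, float(p_a), usage_a, usage_b
            )
            out.append((pool(meas_a, meas_b, p_a), spec))
    return out
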