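"""Replicate outlier screening on VCD trends.

A batch is flagged when its VCD trajectory lies outside the replicate
mean +/- k standard deviations (sample SD across that condition's replicates,
candidate included) on one consistent side at a majority of timepoints.
Identical replicates (zero SD) are never flagged: the band has zero width and
the comparison is strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gyflux.synth import CultureBatch

logger = logging.getLogger(__name__)


@dataclass
class BatchFlag:
    batch_id: str
    condition_id: str
    flagged: bool
    deviations: list[float]       # per-timepoint deviation in SD units
    fraction_outside: float       # on the dominant side
    dominant_side: int            # +1 / -1 / 0


@dataclass
class OutlierReport:
    band_k: float
    frac_threshold: float
    flags: list[BatchFlag] = field(default_factory=list)

    @property
    def flagged_ids(self) -> list[str]:
        return [f.batch_id for f in self.flags if f.flagged]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f.batch_id, f.condition_id, f.flagged, f.fraction_outside, f.dominant_side)
                for f in self.flags
            ],
            columns=["batch_id", "condition_id", "flagged", "fraction_outside", "dominant_side"],
        )


def detect_outliers(
    batches: list[CultureBatch],
    band_k: float = 1.0,
    frac_threshold: float = 0.5,
) -> OutlierReport:
    """Flag replicate batches whose VCD trend escapes the +/- k SD band.

    Batches are grouped by ``condition_id``; groups with fewer than two
    replicates are skipped with a warning (the rule needs a majority).
    """
    report = OutlierReport(band_k=band_k, frac_threshold=frac_threshold)
    conditions: dict[str, list[CultureBatch]] = {}
    for b in batches:
        conditions.setdefault(b.condition_id, []).append(b)

    for cond_id in sorted(conditions):
        group = sorted(conditions[cond_id], key=lambda b: b.batch_id)
        if len(group) < 2:
            logger.warning("condition %s has < 2 replicates; outlier rule skipped", cond_id)
            for b in group:
                report.flags.append(
                    BatchFlag(b.batch_id, cond_id, False, [], 0.0, 0)
                )
            continue
        days = group[0].days
        for b in group[1:]:
            if b.days != days:
                raise ValueError(f"replicates of {cond_id} have mismatched sampling days")
        vcd = np.array([b.vcd for b in group], dtype=float)  # replicates x timepoints
        mean = vcd.mean(axis=0)
        sd = vcd.std(axis=0, ddof=1)
        for i, b in enumerate(group):
            with np.errstate(divide="ignore", invalid="ignore"):
                dev = np.where(sd > 0, (vcd[i] - mean) / np.where(sd > 0, sd, 1.0), 0.0)
            above = dev > band_k       # strict: zero-width band never flags
            below = dev < -band_k
            frac_above = float(above.mean())
            frac_below = float(below.mean())
            if frac_above >= frac_below:
                frac, side = frac_above, +1
            else:
                frac, side = frac_below, -1
            flagged = frac >= frac_threshold and frac > 0
            report.flags.append(
                BatchFlag(
                    batch_id=b.batch_id,
                    condition_id=cond_id,
                    flagged=flagged,
                    deviations=[float(d) for d in dev],
                    fraction_outside=frac,
                    dominant_side=side if frac > 0 else 0,
                )
            )
    return report


def filter_outliers(
    batches: list[CultureBatch], report: OutlierReport
) -> list[CultureBatch]:
    """Drop flagged batches (the downstream-analysis dataset)."""
    bad = set(report.flagged_ids)
    return [b for b in batches if b.batch_id not in bad]
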