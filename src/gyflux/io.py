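"""Tidy CSV interchange for culture datasets.

Two files describe a dataset:

* measurements: ``batch_id, condition_id, day, variable, value`` (long form;
  variables are ``VCD`` (10^6 cells/mL), ``viability`` (%), ``titer`` (mg/L)
  and metabolite names in mM),
* feed events: ``batch_id, day, metabolite, added_concentration,
  bolus_fraction`` where ``added_concentration`` is the increment the bolus
  contributes in the post-bolus volume (mM).

UTF-8, dot decimal separator, deterministic float formatting so reruns under
a fixed seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from gyflux.synth import GLUCOSE_MW, CultureBatch, FeedEvent

FLOAT_FORMAT = "%.10g"


def batches_to_frame(batches: list[CultureBatch]) -> pd.DataFrame:
    rows = []
    for b in batches:
        for i, day in enumerate(b.days):
            rows.append((b.batch_id, b.condition_id, day, "VCD", b.vcd[i]))
            rows.append((b.batch_id, b.condition_id, day, "viability", b.viability[i]))
            rows.append((b.batch_id, b.condition_id, day, "titer", b.titer[i]))
            for met in sorted(b.conc):
                rows.append((b.batch_id, b.condition_id, day, met, b.conc[met][i]))
    return pd.DataFrame(rows, columns=["batch_id", "condition_id", "day", "variable", "value"])


def feeds_to_frame(batches: list[CultureBatch]) -> pd.DataFrame:
    rows = []
    for b in batches:
        for e in b.feed_events:
            for met in sorted(e.added):
                rows.append((b.batch_id, e.day, met, e.added[met], e.fraction))
    return pd.DataFrame(
        rows, columns=["batch_id", "day", "metabolite", "added_concentration", "bolus_fraction"]
    )


def write_dataset(
    batches: list[CultureBatch], measurements_path: str | Path, feeds_path: str | Path
) -> None:
    batches_to_frame(batches).to_csv(measurements_path, index=False, float_format=FLOAT_FORMAT)
    feeds_to_frame(batches).to_csv(feeds_path, index=False, float_format=FLOAT_FORMAT)


def read_dataset(
    measurements_path: str | Path,
    feeds_path: str | Path | None = None,
    glucose_unit: str = "mM",
) -> list[CultureBatch]:
    """Load a dataset written by :func:`write_dataset` (or equivalent).

    ``glucose_unit='g/L'`` converts glucose measurements to mM at ingest
    (molar mass 180.16 g/mol); all other metabolites are taken as mM.
    """
    if glucose_unit not in ("mM", "g/L"):
        raise ValueError("glucose_unit must be 'mM' or 'g/L'")
    meas = pd.read_csv(measurements_path)
    feeds = pd.read_csv(feeds_path) if feeds_path is not None else pd.DataFrame(
        columns=["batch_id", "day", "metabolite", "added_concentration", "bolus_fraction"]
    )
    if glucose_unit == "g/L":
        is_glc = meas["variable"] == "glucose"
        meas.loc[is_glc, "value"] = meas.loc[is_glc, "value"] / GLUCOSE_MW * 1000.0
        is_glc = feeds["metabolite"] == "glucose"
        feeds.loc[is_glc, "added_concentration"] = (
            feeds.loc[is_glc, "added_concentration"] / GLUCOSE_MW * 1000.0
        )

    batches = []
    for batch_id, grp in meas.groupby("batch_id", sort=True):
        condition_id = str(grp["condition_id"].iloc[0])
        wide = grp.pivot_table(index="day", columns="variable", values="value", sort=True)
        days = [float(d) for d in wide.index]
        mets = [c for c in wide.columns if c not in ("VCD", "viability", "titer")]
        fe = feeds[feeds["batch_id"] == batch_id]
        events = [
            FeedEvent(
                day=float(day),
                fraction=float(sub["bolus_fraction"].iloc[0]),
                added={str(r.metabolite): float(r.added_concentration) for r in sub.itertuples()},
            )
            for day, sub in fe.groupby("day", sort=True)
        ]
        batches.append(
            CultureBatch(
                batch_id=str(batch_id),
                condition_id=condition_id,
                days=days,
                vcd=[float(v) for v in wide["VCD"]],
                viability=[float(v) for v in wide["viability"]],
                titer=[float(v) for v in wide["titer"]],
                conc={m: [float(v) for v in wide[m]] for m in mets},
                feed_events=events,
            )
        )
    return batches
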