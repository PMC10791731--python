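"""Comparative flux analysis between GY-dose conditions.

Works on split (forward/backward) flux vectors from the ecFBA stage.  The
reference condition (the 0.5x optimum) sits in the numerator, so "more than
20 % higher flux in the reference" reads as a fold change FC > 1.2.
Reactions where both conditions carry less than a flux floor (default 0.0001
mmol/gDCW/h) are excluded as numerically off; a reaction active only in the
reference gets an infinite, flagged FC.

Pathway summaries mirror the figures of record for this kind of analysis:
total flux producing a redox cofactor (cytosolic NADPH, mitochondrial NADH,
FADH2), alpha-ketoglutarate drain through the amino-acid transaminases, and
the partitioning of a substrate (Glu, Gln, Asn, Asp) over its consuming
sinks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import inf

import pandas as pd

from gyflux.ecfba import FluxSolution
from gyflux.model import MetabolicModel

logger = logging.getLogger(__name__)

DEFAULT_FLUX_FLOOR = 0.0001   # mmol/gDCW/h
DEFAULT_FC_THRESHOLD = 1.2

#: default amino-acid transaminase set for the akg-consumption summary
TRANSAMINASE_IDS = ("ASPTA", "ALATA", "ORNTA", "LEUTA")

#: cofactor shorthand -> metabolite id
COFACTOR_IDS = {
    "nadph_c": "nadph[c]",
    "nadh_m": "nadh[m]",
    "fadh2_m": "fadh2[m]",
}


@dataclass
class FluxComparison:
    """Per-reaction fold changes of a reference vs. another condition."""

    reference_id: str
    other_id: str
    fc: dict[str, float]                     # FC = v_ref / v_other (may be inf)
    v_ref: dict[str, float]
    v_other: dict[str, float]
    excluded: dict[str, str] = field(default_factory=dict)  # reaction -> reason
    floor: float = DEFAULT_FLUX_FLOOR

    def to_frame(self, model: MetabolicModel | None = None,
                 fc_threshold: float = DEFAULT_FC_THRESHOLD) -> pd.DataFrame:
        selected = select_distinct(self, fc_threshold)
        rows = []
        for rid in sorted(self.fc):
            sub = model.reactions[rid].subsystem if model and rid in model.reactions else ""
            rows.append(
                (rid, self.v_ref[rid], self.v_other[rid], self.fc[rid], rid in selected, sub)
            )
        return pd.DataFrame(
            rows, columns=["reaction", "v_ref", "v_other", "FC", "selected", "subsystem"]
        )


def fold_changes(
    v_ref: dict[str, float],
    v_other: dict[str, float],
    floor: float = DEFAULT_FLUX_FLOOR,
    reference_id: str = "ref",
    other_id: str = "other",
) -> FluxComparison:
    """Elementwise FC = v_ref / v_other over a common split reaction set.

    Reactions with both fluxes below ``floor`` are excluded ("below floor");
    ``v_other`` below floor with ``v_ref`` at/above floor yields FC = +inf
    (kept and flagged by its infiniteness).
    """
    if set(v_ref) != set(v_other):
        missing = set(v_ref) ^ set(v_other)
        raise ValueError(f"flux vectors cover different reactions, e.g. {sorted(missing)[:5]}")
    fc: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for rid in v_ref:
        a, b = abs(v_ref[rid]), abs(v_other[rid])
        if a < floor and b < floor:
            excluded[rid] = "below floor"
        elif b < floor:
            fc[rid] = inf
        else:
            fc[rid] = a / b
    return FluxComparison(
        reference_id=reference_id,
        other_id=other_id,
        fc=fc,
        v_ref={r: v_ref[r] for r in fc},
        v_other={r: v_other[r] for r in fc},
        excluded=excluded,
        floor=floor,
    )


def compare_solutions(
    ref: FluxSolution,
    other: FluxSolution,
    floor: float = DEFAULT_FLUX_FLOOR,
    reference_id: str = "ref",
    other_id: str = "other",
) -> FluxComparison:
    return fold_changes(ref.fluxes, other.fluxes, floor, reference_id, other_id)


def select_distinct(cmp: FluxComparison, fc_threshold: float = DEFAULT_FC_THRESHOLD
                    ) -> set[str]:
    """Reactions distinctly more active in the reference: FC strictly > threshold."""
    return {rid for rid, fc in cmp.fc.items() if fc > fc_threshold}


DEFAULT_TALLY_EXCLUDE = ("Exchange", "Transport", "Demand")


def intersect_comparisons(
    set_a: set[str],
    set_b: set[str],
    model: MetabolicModel,
    exclude_subsystems: tuple[str, ...] = DEFAULT_TALLY_EXCLUDE,
) -> tuple[set[str], pd.DataFrame]:
    """Reactions repeatedly selected in both comparisons, tallied by subsystem.

    Returns the full intersection and a subsystem tally sorted descending
    (ties broken alphabetically).  Boundary, transport and demand
    pseudo-reactions are excluded from the tally by default: they mirror the
    metabolic changes rather than carrying pathway membership of their own.
    """
    common = set_a & set_b
    tally: dict[str, int] = {}
    for rid in common:
        base = rid[:-2] if rid.endswith(("_f", "_b")) else rid
        sub = ""
        if rid in model.reactions:
            sub = model.reactions[rid].subsystem
        elif base in model.reactions:
            sub = model.reactions[base].subsystem
        if sub in exclude_subsystems:
            continue
        tally[sub or "(none)"] = tally.get(sub or "(none)", 0) + 1
    df = pd.DataFrame(
        sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["subsystem", "n_reactions"],
    )
    return common, df


def cofactor_summary(
    solution: FluxSolution, model: MetabolicModel | None = None, cofactor: str = "nadph_c"
) -> float:
    """Total flux producing a redox cofactor (split fluxes, producers only).

    ``cofactor`` is a shorthand (``nadph_c``, ``nadh_m``, ``fadh2_m``) or a
    metabolite id; the result is the sum of (stoichiometric coefficient x
    flux) over reactions with a positive coefficient for that metabolite.
    """
    model = model or solution.model
    met_id = COFACTOR_IDS.get(cofactor, cofactor)
    if met_id not in model.metabolites:
        raise KeyError(f"unknown cofactor metabolite {met_id!r}")
    total = 0.0
    for rid, v in solution.fluxes.items():
        coef = model.reactions[rid].stoichiometry.get(met_id, 0.0)
        if coef > 0:
            total += coef * v
    return total


def akg_by_transaminases(
    solution: FluxSolution,
    model: MetabolicModel | None = None,
    transaminase_ids: tuple[str, ...] = TRANSAMINASE_IDS,
    akg_id: str = "akg[c]",
) -> pd.DataFrame:
    """Alpha-ketoglutarate drain per transaminase and its share of the total.

    ``transaminase_ids`` name net reactions; on the split basis the
    akg-consuming direction of each is used (e.g. ``ASPTA_f``).  Raises if a
    listed reaction has no akg-consuming direction in the model.
    """
    model = model or solution.model
    rows = []
    for tid in transaminase_ids:
        candidates = [tid, tid + "_f", tid + "_b"]
        consuming = [
            rid
            for rid in candidates
            if rid in model.reactions and model.reactions[rid].stoichiometry.get(akg_id, 0) < 0
        ]
        if not consuming:
            raise KeyError(f"reaction {tid!r} does not consume {akg_id} in this model")
        drain = sum(
            -model.reactions[rid].stoichiometry[akg_id] * solution.fluxes.get(rid, 0.0)
            for rid in consuming
        )
        rows.append((tid, drain))
    total = sum(d for _, d in rows)
    df = pd.DataFrame(rows, columns=["transaminase", "akg_consumption"])
    df["fraction"] = df["akg_consumption"] / total if total > 0 else float("nan")
    return df


def substrate_partition(
    solution: FluxSolution,
    substrate: str,
    sinks: dict[str, str],
    model: MetabolicModel | None = None,
) -> pd.DataFrame:
    """Partition of a substrate's total consumption over named sinks.

    ``sinks`` maps display labels to (net) reaction ids; consumption is
    |stoichiometric coefficient| x flux of each akg/substrate-consuming split
    direction.  Total available substrate is the summed consumption over all
    reactions that consume it; the unlisted remainder is reported as
    ``other/secreted``.  Fractions plus the remainder sum to 1.
    """
    model = model or solution.model
    total = 0.0
    consumption: dict[str, float] = {}
    for rid, v in solution.fluxes.items():
        coef = model.reactions[rid].stoichiometry.get(substrate, 0.0)
        if coef < 0 and v > 0:
            consumption[rid] = -coef * v
            total += -coef * v
    rows = []
    if total <= 0:
        logger.warning("no consumption of %s; partition undefined", substrate)
        for label in sinks:
            rows.append((label, 0.0, float("nan")))
        return pd.DataFrame(rows, columns=["sink", "flux", "fraction"])
    accounted = 0.0
    for label, rid in sinks.items():
        drain = sum(
            consumption.get(cand, 0.0) for cand in (rid, rid + "_f", rid + "_b")
        )
        accounted += drain
        rows.append((label, drain, drain / total))
    rows.append(("other/secreted", total - accounted, (total - accounted) / total))
    return pd.DataFrame(rows, columns=["sink", "flux", "fraction"])
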