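"""Stoichiometric metabolic models: containers, I/O, and model construction.

Holds the reduced CHO-like network machinery used by the ecFBA stage:

* :class:`Metabolite` / :class:`Reaction` / :class:`MetabolicModel`
  containers with bounds, reversibility, subsystems and optional enzyme
  parameters (kcat, MW),
* JSON (documented dialect) and SBML Level 3 + FBC read/write,
* GY-dipeptide augmentation: uptake ``EX_glytyr(e)``, PepT1-style transport
  ``GLYTYRPEPT1t`` and intracellular hydrolysis ``GLYTYRHYDRO``
  (``h2o[c] + glytyr[c] -> gly[c] + tyr_L[c]``),
* IgG synthesis reaction built from the antibody's amino-acid composition
  (mol %), with a configurable ATP cost per peptide bond,
* reversible-reaction splitting for forward/backward flux accounting.

Reaction and metabolite identifiers follow the BiGG-like style of CHO
genome-scale models (``glc_D[c]``, ``G6PDH``, ``ASPTA``, ...), with
compartments ``e`` (extracellular), ``c`` (cytosol), ``m`` (mitochondria).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

COMPARTMENTS = ("e", "c", "m")

#: IgG1 heavy+light chain amino-acid composition in mol % as derived from the
#: antibody sequence; the printed values sum to 100.10 and are renormalized to
#: a proper simplex when the synthesis reaction is built.
IGG_COMPOSITION_MOLPCT: dict[str, float] = {
    "serine": 13.25,
    "valine": 8.89,
    "threonine": 8.28,
    "lysine": 7.38,
    "proline": 7.23,
    "leucine": 6.87,
    "glycine": 6.63,
    "alanine": 5.87,
    "glutamate": 4.67,
    "tyrosine": 4.67,
    "glutamine": 4.52,
    "asparagine": 3.92,
    "aspartate": 3.46,
    "phenylalanine": 3.01,
    "cysteine": 2.41,
    "arginine": 2.11,
    "isoleucine": 2.11,
    "histidine": 1.96,
    "tryptophan": 1.96,
    "methionine": 0.90,
}

#: amino-acid name -> cytosolic metabolite id
AA_METABOLITES: dict[str, str] = {
    "alanine": "ala_L[c]",
    "arginine": "arg_L[c]",
    "asparagine": "asn_L[c]",
    "aspartate": "asp_L[c]",
    "cysteine": "cys_L[c]",
    "glutamine": "gln_L[c]",
    "glutamate": "glu_L[c]",
    "glycine": "gly[c]",
    "histidine": "his_L[c]",
    "isoleucine": "ile_L[c]",
    "leucine": "leu_L[c]",
    "lysine": "lys_L[c]",
    "methionine": "met_L[c]",
    "phenylalanine": "phe_L[c]",
    "proline": "pro_L[c]",
    "serine": "ser_L[c]",
    "threonine": "thr_L[c]",
    "tryptophan": "trp_L[c]",
    "tyrosine": "tyr_L[c]",
    "valine": "val_L[c]",
}

_COMP_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[a-z])\]$")


@dataclass
class Metabolite:
    """A compartmentalized species, e.g. ``glytyr[c]``."""

    id: str
    name: str = ""
    compartment: str = ""  # inferred from the id tag when empty

    def __post_init__(self) -> None:
        m = _COMP_RE.match(self.id)
        if not m:
            raise ValueError(f"metabolite id {self.id!r} lacks a compartment tag like '[c]'")
        tag = m.group("comp")
        if self.compartment and tag != self.compartment:
            raise ValueError(
                f"metabolite {self.id!r}: compartment field {self.compartment!r} "
                f"does not match id tag {tag!r}"
            )
        self.compartment = tag
        if not self.name:
            self.name = m.group("base")


@dataclass
class Reaction:
    """A (possibly reversible) reaction with bounds in mmol/gDCW/h.

    ``stoichiometry`` maps metabolite id to coefficient (negative = consumed).
    ``kcat`` (1/h) and ``mw`` (g/mmol) feed the pooled enzyme-capacity
    constraint when annotated.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lb: float = 0.0
    ub: float = 1000.0
    subsystem: str = ""
    name: str = ""
    kcat: float | None = None
    mw: float | None = None

    def __post_init__(self) -> None:
        self.stoichiometry = {m: float(c) for m, c in self.stoichiometry.items() if c != 0}
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}")
        if not self.reversible and self.lb < 0:
            raise ValueError(f"irreversible reaction {self.id!r} cannot have lb < 0")

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions: a single metabolite crossing the system edge."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            reversible=self.reversible,
            lb=self.lb,
            ub=self.ub,
            subsystem=self.subsystem,
            name=self.name,
            kcat=self.kcat,
            mw=self.mw,
        )


class MetabolicModel:
    """A stoichiometric network with bounds, objective and enzyme budget."""

    def __init__(
        self,
        model_id: str = "model",
        metabolites: list[Metabolite] | None = None,
        reactions: list[Reaction] | None = None,
        objective: str | None = None,
        p_total: float | None = None,
    ):
        self.id = model_id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective = objective
        self.p_total = p_total  # enzyme budget, g/gDCW
        for m in metabolites or []:
            self.add_metabolite(m)
        for r in reactions or []:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise KeyError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            model_id=self.id,
            metabolites=[Metabolite(m.id, m.name, m.compartment) for m in self.metabolites.values()],
            reactions=[r.copy() for r in self.reactions.values()],
            objective=self.objective,
            p_total=self.p_total,
        )

    # -- views -------------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def exchanges(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def s_matrix(self) -> tuple[np.ndarray, dict[str, int], dict[str, int]]:
        """Dense stoichiometric matrix with metabolite/reaction index maps."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        rxn_index = {r: j for j, r in enumerate(self.reactions)}
        S = np.zeros((len(met_index), len(rxn_index)))
        for rid, rxn in self.reactions.items():
            for mid, coef in rxn.stoichiometry.items():
                S[met_index[mid], rxn_index[rid]] = coef
        return S, met_index, rxn_index

    # -- JSON dialect ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "objective": self.objective,
            "p_total": self.p_total,
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment}
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": dict(sorted(r.stoichiometry.items())),
                    "reversible": r.reversible,
                    "lb": r.lb,
                    "ub": r.ub,
                    "subsystem": r.subsystem,
                    **({"kcat": r.kcat} if r.kcat is not None else {}),
                    **({"mw": r.mw} if r.mw is not None else {}),
                }
                for r in self.reactions.values()
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MetabolicModel":
        model = cls(
            model_id=data.get("id", "model"),
            objective=data.get("objective"),
            p_total=data.get("p_total"),
        )
        for m in data["metabolites"]:
            model.add_metabolite(
                Metabolite(id=m["id"], name=m.get("name", ""), compartment=m.get("compartment", ""))
            )
        for r in data["reactions"]:
            model.add_reaction(
                Reaction(
                    id=r["id"],
                    stoichiometry=r["stoichiometry"],
                    reversible=r.get("reversible", False),
                    lb=r.get("lb", 0.0),
                    ub=r.get("ub", 1000.0),
                    subsystem=r.get("subsystem", ""),
                    name=r.get("name", ""),
                    kcat=r.get("kcat"),
                    mw=r.get("mw"),
                )
            )
        return model


def read_model(path: str | Path, fmt: str | None = None) -> MetabolicModel:
    """Read a model from JSON or SBML (format auto-detected by extension)."""
    path = Path(path)
    fmt = fmt or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"ill-formed model JSON at {path}: {exc}") from exc
        return MetabolicModel.from_dict(data)
    if fmt == "sbml":
        from gyflux.sbml_io import read_sbml

        return read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str | Path, fmt: str | None = None) -> None:
    """Write a model to JSON or SBML L3+FBC (auto-detected by extension)."""
    path = Path(path)
    fmt = fmt or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        path.write_text(json.dumps(model.to_dict(), indent=1, sort_keys=False) + "\n")
    elif fmt == "sbml":
        from gyflux.sbml_io import write_sbml

        write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


GY_REACTION_IDS = ("EX_glytyr(e)", "GLYTYRPEPT1t", "GLYTYRHYDRO")


def augment_with_gy(model: MetabolicModel, inplace: bool = False) -> MetabolicModel:
    """Add GY-dipeptide uptake, transport and intracellular hydrolysis.

    Exactly three reactions: ``EX_glytyr(e)`` (``glytyr[e] <->``),
    ``GLYTYRPEPT1t`` (``glytyr[e] <-> glytyr[c]``) and ``GLYTYRHYDRO``
    (``h2o[c] + glytyr[c] -> gly[c] + tyr_L[c]``, irreversible).  Requires
    ``gly[c]``, ``tyr_L[c]`` and ``h2o[c]`` in the host model.  Idempotent:
    re-augmenting is a no-op with a warning.
    """
    out = model if inplace else model.copy()
    if all(rid in out.reactions for rid in GY_REACTION_IDS):
        logger.warning("model already contains the GY reactions; augmentation skipped")
        return out
    for required in ("gly[c]", "tyr_L[c]", "h2o[c]"):
        if required not in out.metabolites:
            raise KeyError(f"cannot augment with GY: missing metabolite {required!r}")
    if "glytyr[e]" not in out.metabolites:
        out.add_metabolite(Metabolite("glytyr[e]", "glycyl-L-tyrosine", "e"))
    if "glytyr[c]" not in out.metabolites:
        out.add_metabolite(Metabolite("glytyr[c]", "glycyl-L-tyrosine", "c"))
    out.add_reaction(
        Reaction(
            id="EX_glytyr(e)",
            stoichiometry={"glytyr[e]": -1.0},
            reversible=True,
            lb=-1000.0,
            ub=1000.0,
            subsystem="Exchange",
            name="GY dipeptide exchange",
        )
    )
    out.add_reaction(
        Reaction(
            id="GLYTYRPEPT1t",
            stoichiometry={"glytyr[e]": -1.0, "glytyr[c]": 1.0},
            reversible=True,
            lb=-1000.0,
            ub=1000.0,
            subsystem="Transport",
            name="GY dipeptide transport (PepT1)",
        )
    )
    out.add_reaction(
        Reaction(
            id="GLYTYRHYDRO",
            stoichiometry={
                "h2o[c]": -1.0,
                "glytyr[c]": -1.0,
                "gly[c]": 1.0,
                "tyr_L[c]": 1.0,
            },
            reversible=False,
            lb=0.0,
            ub=1000.0,
            subsystem="Dipeptide metabolism",
            name="GY dipeptide hydrolysis",
        )
    )
    return out


def build_igg_reaction(
    composition: dict[str, float] | None = None,
    energy_cost: float = 4.3,
    reaction_id: str = "IGG_SYNTH",
) -> Reaction:
    """Build the IgG synthesis reaction from amino-acid mol % composition.

    Coefficients are the mol % values normalized to sum exactly to 1 (the
    printed composition sums to 100.10).  The reaction consumes the free
    cytosolic amino acids and ``energy_cost`` ATP-equivalents per residue
    (hydrolyzed to ADP + Pi) and produces one unit of the ``igg[c]``
    pseudo-metabolite; flux unit is mmol residues/gDCW/h.
    """
    composition = composition if composition is not None else IGG_COMPOSITION_MOLPCT
    missing = sorted(set(IGG_COMPOSITION_MOLPCT) - set(composition))
    if missing:
        raise ValueError(f"IgG composition missing amino acids: {missing}")
    if any(v < 0 for v in composition.values()):
        raise ValueError("IgG composition has negative mol% entries")
    if energy_cost < 0:
        raise ValueError("energy_cost must be non-negative")
    total = sum(composition.values())
    stoich: dict[str, float] = {}
    for aa, pct in composition.items():
        if aa not in AA_METABOLITES:
            raise ValueError(f"unknown amino acid {aa!r} in IgG composition")
        if pct > 0:
            stoich[AA_METABOLITES[aa]] = -pct / total
    if energy_cost > 0:
        stoich["atp[c]"] = -energy_cost
        stoich["h2o[c]"] = stoich.get("h2o[c]", 0.0) - energy_cost
        stoich["adp[c]"] = energy_cost
        stoich["pi[c]"] = energy_cost
    stoich["igg[c]"] = 1.0
    return Reaction(
        id=reaction_id,
        stoichiometry=stoich,
        reversible=False,
        lb=0.0,
        ub=1000.0,
        subsystem="Antibody synthesis",
        name="IgG synthesis (per residue)",
    )


def split_reversible(
    model: MetabolicModel,
) -> tuple[MetabolicModel, dict[str, tuple[str, str | None]]]:
    """Replace reversible reactions by forward/backward irreversible copies.

    Returns the split model and a mapping ``original id -> (forward id,
    backward id or None)`` for net-flux reassembly
    (``v_net = v_fwd - v_bwd``).  Irreversible reactions pass through
    unchanged.  Forward copies keep enzyme annotations; backward copies share
    them (same enzyme catalyses both directions).
    """
    out = MetabolicModel(
        model_id=model.id + "_split",
        metabolites=[Metabolite(m.id, m.name, m.compartment) for m in model.metabolites.values()],
        objective=model.objective,
        p_total=model.p_total,
    )
    mapping: dict[str, tuple[str, str | None]] = {}
    for rxn in model.reactions.values():
        if not rxn.reversible and rxn.lb >= 0:
            out.add_reaction(rxn.copy())
            mapping[rxn.id] = (rxn.id, None)
            continue
        fwd = rxn.copy()
        fwd.id = rxn.id + "_f"
        fwd.reversible = False
        fwd.lb = max(0.0, rxn.lb)
        fwd.ub = max(0.0, rxn.ub)
        bwd = rxn.copy()
        bwd.id = rxn.id + "_b"
        bwd.reversible = False
        bwd.stoichiometry = {m: -c for m, c in rxn.stoichiometry.items()}
        bwd.lb = max(0.0, -rxn.ub)
        bwd.ub = max(0.0, -rxn.lb)
        out.add_reaction(fwd)
        out.add_reaction(bwd)
        mapping[rxn.id] = (fwd.id, bwd.id)
    return out, mapping


def net_fluxes(
    split_fluxes: dict[str, float], mapping: dict[str, tuple[str, str | None]]
) -> dict[str, float]:
    """Reassemble net fluxes of the original model from split fluxes."""
    out = {}
    for rid, (fwd, bwd) in mapping.items():
        v = split_fluxes.get(fwd, 0.0)
        if bwd is not None:
            v -= split_fluxes.get(bwd, 0.0)
        out[rid] = v
    return out
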