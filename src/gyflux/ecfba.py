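"""Enzyme-capacity-constrained flux balance analysis (ecFBA).

The flux state of one culture condition over one phase is estimated by a
linear program on the split (irreversible) network:

    maximize   v_biomass
    subject to S v = 0
               lb <= v <= ub          (measured exchange rates +/- 20 %)
               v_IgG = measured Qp    (fixed antibody synthesis)
               sum_i (MW_i / kcat_i) v_i <= P_total   (pooled enzyme budget)

followed by a parsimonious second stage that minimizes total flux at the
fixed biomass optimum, so every solve returns one well-defined
representative flux vector (fold-change comparison on a degenerate LP
optimum would be meaningless).  LPs are solved with HiGHS through
:func:`scipy.optimize.linprog`, which is deterministic for a fixed problem
ordering.

Measured specific rates arrive in per-cell units (pmol/cell/day from the
rates stage) and are converted to mmol/gDCW/h with a configurable cell dry
weight (default 250 pg/cell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from gyflux.model import MetabolicModel, net_fluxes, split_reversible
from gyflux.rates import PhaseRates

logger = logging.getLogger(__name__)

#: default relaxation of measured rates used as bounds
DEFAULT_RELAXATION = 0.20
#: absolute widening for zero measured rates, mmol/gDCW/h
ZERO_RATE_EPS = 1e-6
#: default cell dry weight, pg/cell
DEFAULT_DCW_PG = 250.0
#: mean amino-acid residue mass used to convert IgG mass to residue flux, g/mmol
RESIDUE_MASS_G_PER_MMOL = 0.110

#: culture metabolite name -> exchange reaction id in the reduced network
METABOLITE_EXCHANGES = {
    "glucose": "EX_glc_D(e)",
    "lactate": "EX_lac_L(e)",
    "ammonia": "EX_nh4(e)",
    "alanine": "EX_ala_L(e)",
    "arginine": "EX_arg_L(e)",
    "asparagine": "EX_asn_L(e)",
    "aspartate": "EX_asp_L(e)",
    "cysteine": "EX_cys_L(e)",
    "glutamine": "EX_gln_L(e)",
    "glutamate": "EX_glu_L(e)",
    "glycine": "EX_gly(e)",
    "histidine": "EX_his_L(e)",
    "isoleucine": "EX_ile_L(e)",
    "leucine": "EX_leu_L(e)",
    "lysine": "EX_lys_L(e)",
    "methionine": "EX_met_L(e)",
    "phenylalanine": "EX_phe_L(e)",
    "proline": "EX_pro_L(e)",
    "serine": "EX_ser_L(e)",
    "threonine": "EX_thr_L(e)",
    "tryptophan": "EX_trp_L(e)",
    "tyrosine": "EX_tyr_L(e)",
    "valine": "EX_val_L(e)",
    "ornithine": "EX_orn(e)",
}


def per_cell_to_specific(rate: float, dcw_per_cell: float = DEFAULT_DCW_PG) -> float:
    """Convert pmol/cell/day to mmol/gDCW/h (sign preserved).

    ``rate * 1e-9 mmol/pmol / (dcw * 1e-12 g/cell) / 24 h/day``.
    """
    if dcw_per_cell <= 0:
        raise ValueError("cell dry weight must be positive")
    return rate * 1e-9 / (dcw_per_cell * 1e-12) / 24.0


def qp_to_igg_flux(
    qp: float,
    dcw_per_cell: float = DEFAULT_DCW_PG,
    residue_mass: float = RESIDUE_MASS_G_PER_MMOL,
) -> float:
    """Convert Qp (pg IgG/cell/day) to IgG synthesis flux (mmol residues/gDCW/h)."""
    if dcw_per_cell <= 0 or residue_mass <= 0:
        raise ValueError("cell dry weight and residue mass must be positive")
    g_per_gdcw_h = qp / dcw_per_cell / 24.0
    return g_per_gdcw_h / residue_mass


def apply_rate_bounds(
    model: MetabolicModel,
    rates: dict[str, float],
    relaxation: float = DEFAULT_RELAXATION,
    zero_eps: float = ZERO_RATE_EPS,
    inplace: bool = False,
) -> MetabolicModel:
    """Constrain exchange reactions to measured rates relaxed by +/- ``relaxation``.

    ``rates`` maps exchange reaction ids to measured rates in mmol/gDCW/h
    (uptake negative).  Bounds become ``[r - rel*|r|, r + rel*|r|]``
    intersected with the reaction's physical bounds; an exactly zero rate is
    widened by ``+/- zero_eps`` to avoid artificial infeasibility.
    """
    if relaxation < 0:
        raise ValueError("relaxation must be non-negative")
    out = model if inplace else model.copy()
    for rxn_id, r in rates.items():
        if rxn_id not in out.reactions:
            raise KeyError(f"no exchange reaction {rxn_id!r} in model")
        rxn = out.reactions[rxn_id]
        half = relaxation * abs(r) if r != 0 else zero_eps
        # relaxed window intersected with the physical bounds
        lb = max(rxn.lb, r - half)
        ub = min(rxn.ub, r + half)
        if lb > ub:
            raise ValueError(
                f"measured rate {r} for {rxn_id!r} is incompatible with physical "
                f"bounds [{rxn.lb}, {rxn.ub}]"
            )
        # bounds narrow; the reaction's physical reversibility is unchanged so
        # the split model keeps both directions available for reconciliation
        rxn.lb, rxn.ub = lb, ub
    return out


def rate_bounds_from_phase(
    phase_rates: PhaseRates,
    exchange_map: dict[str, str] | None = None,
    dcw_per_cell: float = DEFAULT_DCW_PG,
    model: MetabolicModel | None = None,
) -> dict[str, float]:
    """Map measured Qm (pmol/cell/day) to exchange rates (mmol/gDCW/h).

    Only metabolites present in ``exchange_map`` (and, if ``model`` is given,
    whose exchange exists in the model) are constrained — the pipeline bounds
    exactly the measured set provided.
    """
    exchange_map = exchange_map or METABOLITE_EXCHANGES
    out = {}
    for met, qm in phase_rates.qm.items():
        if met not in exchange_map:
            continue
        ex = exchange_map[met]
        if model is not None and ex not in model.reactions:
            continue
        out[ex] = per_cell_to_specific(qm, dcw_per_cell)
    return out


def apply_enzyme_capacity(model: MetabolicModel, p_total: float, inplace: bool = False
                          ) -> MetabolicModel:
    """Set the pooled enzyme budget sum(MW_i/kcat_i * v_i) <= ``p_total``.

    The constraint row itself is materialized at solve time on the split
    model over all kcat/MW-annotated reactions; models without annotations
    get a warning and no constraint.
    """
    out = model if inplace else model.copy()
    n_annotated = sum(
        1 for r in out.reactions.values() if r.kcat is not None and r.mw is not None
    )
    if n_annotated == 0:
        logger.warning("no kcat/MW annotations in model; enzyme capacity not applied")
        out.p_total = None
        return out
    out.p_total = p_total
    return out


@dataclass
class FluxSolution:
    """One representative flux state (split/irreversible reaction basis)."""

    fluxes: dict[str, float]          # per split reaction, mmol/gDCW/h (>= 0)
    objective: float                  # biomass, 1/h
    status: str
    total_flux: float                 # sum of split fluxes after parsimony
    model: MetabolicModel             # the split model the fluxes live on
    mapping: dict[str, tuple[str, str | None]] = field(default_factory=dict)
    relaxed_bounds: dict[str, float] = field(default_factory=dict)  # reaction -> slack used

    def net(self) -> dict[str, float]:
        """Net fluxes on the original (pre-split) reaction basis."""
        return net_fluxes(self.fluxes, self.mapping)

    def summary(self, top: int = 10) -> str:
        lines = [
            "ecFBA flux solution",
            "=" * 40,
            f"status:        {self.status}",
            f"biomass (1/h): {self.objective:.6f}",
            f"total |flux|:  {self.total_flux:.4f} mmol/gDCW/h",
            "",
            f"top {top} fluxes:",
        ]
        for rid, v in sorted(self.fluxes.items(), key=lambda kv: -abs(kv[1]))[:top]:
            sub = self.model.reactions[rid].subsystem
            lines.append(f"  {rid:<18s} {v:10.4f}  {sub}")
        return "\n".join(lines)


class EcFBAProblem:
    """Enzyme-capacity FBA problem for one condition/phase.

    Parameters
    ----------
    model :
        The (net) metabolic model, already exchange-bounded via
        :func:`apply_rate_bounds`.
    igg_flux :
        Measured antibody synthesis flux (mmol residues/gDCW/h); fixed.
    growth_rate_cap :
        Optional upper bound on biomass flux (1/h); by default growth is free
        and maximized.
    growth_rate_floor :
        Optional lower bound on biomass flux (1/h), typically the measured
        SGR less the relaxation; anchors bound reconciliation to the measured
        physiological state instead of a zero-growth solution.
    p_total :
        Pooled enzyme budget (g/gDCW); defaults to ``model.p_total``; pass
        ``None`` explicitly after setting ``model.p_total = None`` to drop
        the constraint.
    """

    def __init__(
        self,
        model: MetabolicModel,
        igg_flux: float = 0.0,
        growth_rate_cap: float | None = None,
        growth_rate_floor: float | None = None,
        p_total: float | None = None,
        igg_reaction: str = "IGG_SYNTH",
    ):
        if model.objective is None:
            raise ValueError("model has no objective reaction")
        self.base_model = model
        self.igg_flux = igg_flux
        self.growth_rate_cap = growth_rate_cap
        self.growth_rate_floor = growth_rate_floor
        self.p_total = p_total if p_total is not None else model.p_total
        self.igg_reaction = igg_reaction
        self.split, self.mapping = split_reversible(model)

    # -- LP assembly -------------------------------------------------------
    def _problem_arrays(self):
        S, met_idx, rxn_idx = self.split.s_matrix()
        n = len(rxn_idx)
        lb = np.zeros(n)
        ub = np.zeros(n)
        for rid, j in rxn_idx.items():
            rxn = self.split.reactions[rid]
            lb[j], ub[j] = rxn.lb, rxn.ub

        if self.igg_reaction in self.mapping:
            fwd, _ = self.mapping[self.igg_reaction]
            j = rxn_idx[fwd]
            if not (self.split.reactions[fwd].lb - 1e-9 <= self.igg_flux
                    <= self.split.reactions[fwd].ub + 1e-9):
                raise ValueError(
                    f"igg_flux {self.igg_flux} outside bounds of {self.igg_reaction!r}"
                )
            lb[j] = ub[j] = self.igg_flux
        elif self.igg_flux != 0:
            raise KeyError(f"no IgG reaction {self.igg_reaction!r} in model")

        obj_fwd, _ = self.mapping[self.base_model.objective]
        j_obj = rxn_idx[obj_fwd]
        if self.growth_rate_cap is not None:
            ub[j_obj] = min(ub[j_obj], self.growth_rate_cap)
        if self.growth_rate_floor is not None:
            lb[j_obj] = max(lb[j_obj], min(self.growth_rate_floor, ub[j_obj]))

        A_ub, b_ub = None, None
        if self.p_total is not None:
            row = np.zeros(n)
            for rid, j in rxn_idx.items():
                rxn = self.split.reactions[rid]
                if rxn.kcat is not None and rxn.mw is not None and rxn.kcat > 0:
                    row[j] = rxn.mw / rxn.kcat
            if np.any(row != 0):
                A_ub = row[None, :]
                b_ub = np.array([self.p_total])
            else:
                logger.warning("enzyme budget set but no annotated reactions; skipped")
        return S, rxn_idx, lb, ub, j_obj, A_ub, b_ub

    def solve(self, reconcile: bool = True) -> FluxSolution:
        """Maximize biomass, then minimize total flux at the fixed optimum.

        If the measured-rate bounds are mutually infeasible (noisy measured
        rates can, e.g., demand secretion of an amino acid the network cannot
        synthesize), an L1-minimal relaxation of the exchange bounds restores
        feasibility first; the slack used per exchange is reported in
        ``relaxed_bounds``.  Set ``reconcile=False`` to fail instead.
        """
        S, rxn_idx, lb, ub, j_obj, A_ub, b_ub = self._problem_arrays()
        n = len(lb)
        b_eq = np.zeros(S.shape[0])

        relaxed: dict[str, float] = {}
        c = np.zeros(n)
        c[j_obj] = -1.0
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=b_eq,
            bounds=list(zip(lb, ub)), method="highs",
        )
        if res.status != 0 and reconcile:
            lb, ub, relaxed = self._reconcile_bounds(S, rxn_idx, lb, ub, A_ub, b_ub)
            if relaxed:
                logger.warning(
                    "measured bounds relaxed to restore feasibility: %s",
                    {k: round(v, 6) for k, v in sorted(relaxed.items())},
                )
            res = linprog(
                c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=b_eq,
                bounds=list(zip(lb, ub)), method="highs",
            )
        if res.status != 0:
            raise RuntimeError(self._infeasibility_report(res, lb, ub, rxn_idx))
        opt = -res.fun

        # parsimony: pin biomass at its optimum, minimize total flux
        lb2, ub2 = lb.copy(), ub.copy()
        slack = 1e-9 * max(1.0, abs(opt))
        lb2[j_obj] = max(lb[j_obj], opt - slack)
        res2 = linprog(
            np.ones(n), A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=b_eq,
            bounds=list(zip(lb2, ub2)), method="highs",
        )
        if res2.status != 0:  # fall back to the first-stage vertex
            logger.warning("parsimony stage failed (%s); using FBA vertex", res2.message)
            v = res.x
        else:
            v = res2.x

        # project solver-tolerance bound violations (HiGHS works to ~1e-7)
        # onto the box, then verify the stated solution tolerances strictly
        if np.any(v < lb2 - 1e-6) or np.any(v > ub2 + 1e-6):
            raise RuntimeError("bound violation beyond solver tolerance in LP solution")
        v = np.clip(v, lb2, ub2)

        fluxes = {rid: float(v[j]) for rid, j in rxn_idx.items()}
        self._check_solution(S, v, lb2, ub2)
        # the biomass optimum comes from the first stage; the parsimonious
        # vector may sit on the (1e-9-slackened) pin below it
        return FluxSolution(
            fluxes=fluxes,
            objective=float(opt),
            status="optimal" if not relaxed else "optimal (bounds reconciled)",
            total_flux=float(v.sum()),
            model=self.split,
            mapping=self.mapping,
            relaxed_bounds=relaxed,
        )

    def _reconcile_bounds(self, S, rxn_idx, lb, ub, A_ub, b_ub):
        """L1-minimal widening of exchange bounds that restores feasibility.

        Solves min sum(s) over [v; s] with S v = 0, lb - s <= v <= ub + s,
        slacks allowed only on exchange reactions; returns widened bounds and
        the per-exchange slack actually needed (above tolerance).
        """
        n = len(lb)
        ex_js = [j for rid, j in rxn_idx.items() if self.split.reactions[rid].is_exchange]
        m = len(ex_js)
        # rows: v_j - s_k <= ub_j ; -v_j - s_k <= -lb_j
        A_rows = []
        b_rows = []
        for k, j in enumerate(ex_js):
            row = np.zeros(n + m)
            row[j] = 1.0
            row[n + k] = -1.0
            A_rows.append(row)
            b_rows.append(ub[j])
            row = np.zeros(n + m)
            row[j] = -1.0
            row[n + k] = -1.0
            A_rows.append(row)
            b_rows.append(-lb[j])
        A = np.array(A_rows)
        b = np.array(b_rows)
        if A_ub is not None:
            A = np.vstack([A, np.hstack([A_ub, np.zeros((A_ub.shape[0], m))])])
            b = np.concatenate([b, b_ub])
        S_ext = np.hstack([S, np.zeros((S.shape[0], m))])
        bounds = [
            ((0.0, None) if j in set(ex_js) else (lb[j], ub[j])) for j in range(n)
        ] + [(0.0, None)] * m
        c = np.concatenate([np.zeros(n), np.ones(m)])
        res = linprog(c, A_ub=A, b_ub=b, A_eq=S_ext, b_eq=np.zeros(S.shape[0]),
                      bounds=bounds, method="highs")
        if res.status != 0:
            raise RuntimeError(f"bound reconciliation failed: {res.message}")
        lb2, ub2 = lb.copy(), ub.copy()
        relaxed: dict[str, float] = {}
        inv = {j: rid for rid, j in rxn_idx.items()}
        for k, j in enumerate(ex_js):
            s = float(res.x[n + k])
            if s > 1e-9:
                margin = s * (1.0 + 1e-6) + 1e-12
                lb2[j] = min(lb[j], lb[j] - margin) if res.x[j] < lb[j] else lb[j]
                ub2[j] = max(ub[j], ub[j] + margin) if res.x[j] > ub[j] else ub[j]
                relaxed[inv[j]] = s
        return lb2, ub2, relaxed

    @staticmethod
    def _check_solution(S, v, lb, ub, tol_eq: float = 1e-6, tol_bounds: float = 1e-8) -> None:
        resid = np.abs(S @ v).max() if len(v) else 0.0
        if resid > tol_eq:
            raise RuntimeError(f"steady-state violation |S v| = {resid:.3g} > {tol_eq}")
        if np.any(v < lb - tol_bounds) or np.any(v > ub + tol_bounds):
            raise RuntimeError("bound violation in LP solution")

    def _infeasibility_report(self, res, lb, ub, rxn_idx) -> str:
        forced = [
            rid
            for rid, j in rxn_idx.items()
            if lb[j] > 0 and (self.split.reactions[rid].is_exchange or lb[j] == ub[j])
        ]
        return (
            f"ecFBA infeasible ({res.message}); "
            f"forced-flux constraints to inspect: {sorted(forced)}"
        )


def solve_ecfba(
    model: MetabolicModel,
    igg_flux: float = 0.0,
    growth_rate_cap: float | None = None,
    growth_rate_floor: float | None = None,
    p_total: float | None = None,
) -> FluxSolution:
    """One-call ecFBA: build the problem and return the parsimonious optimum."""
    return EcFBAProblem(
        model,
        igg_flux=igg_flux,
        growth_rate_cap=growth_rate_cap,
        growth_rate_floor=growth_rate_floor,
        p_total=p_total,
    ).solve()


def condition_flux(
    replicate_rates: list[PhaseRates],
    model: MetabolicModel,
    dcw_per_cell: float = DEFAULT_DCW_PG,
    relaxation: float = DEFAULT_RELAXATION,
    exchange_map: dict[str, str] | None = None,
    growth_cap_factor: float | None = None,
    growth_floor_factor: float | None = 0.8,
) -> FluxSolution:
    """Condition-level flux state: solve per replicate, average reaction-wise.

    Each replicate's phase rates become exchange bounds (+/- relaxation), its
    Qp a fixed IgG flux, and its measured SGR (scaled by
    ``growth_floor_factor``, default 1 - relaxation) a biomass floor so that
    bound reconciliation targets the measured physiological state.
    Infeasible replicates are skipped with a warning; the returned solution
    carries the arithmetic mean flux per (split) reaction.
    """
    if not replicate_rates:
        raise ValueError("no replicate rates supplied")
    solutions = []
    for pr in replicate_rates:
        bounds = rate_bounds_from_phase(pr, exchange_map, dcw_per_cell, model)
        m = apply_rate_bounds(model, bounds, relaxation=relaxation)
        cap = None
        if growth_cap_factor is not None:
            cap = max(pr.sgr, 0.0) / 24.0 * growth_cap_factor
        floor = None
        if growth_floor_factor is not None:
            floor = max(pr.sgr, 0.0) / 24.0 * growth_floor_factor
        try:
            solutions.append(
                solve_ecfba(m, igg_flux=qp_to_igg_flux(max(pr.qp, 0.0), dcw_per_cell),
                            growth_rate_cap=cap, growth_rate_floor=floor)
            )
        except (RuntimeError, ValueError) as exc:
            logger.warning("replicate %s infeasible, skipped: %s", pr.batch_id, exc)
    if not solutions:
        raise RuntimeError("all replicates infeasible for this condition")
    first = solutions[0]
    mean_fluxes = {
        rid: float(np.mean([s.fluxes[rid] for s in solutions])) for rid in first.fluxes
    }
    return FluxSolution(
        fluxes=mean_fluxes,
        objective=float(np.mean([s.objective for s in solutions])),
        status=f"mean of {len(solutions)} replicate(s)",
        total_flux=float(np.mean([s.total_flux for s in solutions])),
        model=first.model,
        mapping=first.mapping,
    )
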