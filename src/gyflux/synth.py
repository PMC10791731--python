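"""Synthetic fed-batch CHO culture generator.

Produces culture datasets with the statistical and temporal structure the
downstream rate/QC/PLS/FBA stages expect: a 14-day fed-batch with sampling on
days {0, 2, 4, 5, 6, 7, 8, 10, 12, 14}, 4 % (v/v) feed boluses every second
day from day 4, glucose setpoint top-ups, several GY-dipeptide dose conditions
with a unimodal optimum at 0.5x, replicates that differ only by multiplicative
lognormal measurement noise, and plantable ground truth (outlier batches,
nutrient-titer correlations).

Cell growth is phenomenological (logistic growth to a peak near day 8, then
first-order decline, simulated on a 0.1-day grid); metabolite and product mass
balances are advanced per sampling interval using the trapezoidal integrated
viable cell density of the emitted VCD values, so that with zero noise the
planted specific rates are exactly recoverable by the rates module.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

SAMPLING_DAYS = [0, 2, 4, 5, 6, 7, 8, 10, 12, 14]
#: default bolus days: feeding at 4 % (v/v) starts on day 4, every 2 days
BOLUS_DAYS = [4, 6, 8, 10, 12]

GLUCOSE_MW = 180.16  # g/mol, used to convert glucose g/L <-> mM

#: metabolites measured in the culture supernatant (glucose, lactate, ammonia
#: and the 20 proteinogenic amino acids plus ornithine)
AMINO_ACIDS = [
    "alanine", "arginine", "asparagine", "aspartate", "cysteine",
    "glutamine", "glutamate", "glycine", "histidine", "isoleucine",
    "leucine", "lysine", "methionine", "phenylalanine", "proline",
    "serine", "threonine", "tryptophan", "tyrosine", "valine",
]
MEASURED_METABOLITES = ["glucose", "lactate", "ammonia"] + AMINO_ACIDS + ["ornithine"]

#: default specific rates, pmol/cell/day; negative = net consumption
DEFAULT_BASE_RATES = {
    "glucose": -3.0,
    "lactate": 1.2,        # switches to net consumption after day 4 (see _rate_at)
    "ammonia": 0.25,
    "alanine": 0.20,
    "arginine": -0.08,
    "asparagine": -0.30,
    "aspartate": -0.12,
    "cysteine": -0.03,
    "glutamine": -0.20,
    "glutamate": -0.10,
    "glycine": -0.02,
    "histidine": -0.04,
    "isoleucine": -0.12,
    "leucine": -0.18,
    "lysine": -0.10,
    "methionine": -0.04,
    "phenylalanine": -0.07,
    "proline": -0.06,
    "serine": -0.15,
    "threonine": -0.10,
    "tryptophan": -0.03,
    "tyrosine": -0.08,
    "valine": -0.14,
    "ornithine": -0.005,
}

#: initial concentrations in basal medium, mM (glucose 6 g/L)
DEFAULT_INITIAL_CONC = {
    "glucose": 6.0 / GLUCOSE_MW * 1000.0,
    "lactate": 0.0,
    "ammonia": 0.5,
    "alanine": 0.5,
    "arginine": 2.0,
    "asparagine": 3.0,
    "aspartate": 1.0,
    "cysteine": 0.8,
    "glutamine": 8.0,
    "glutamate": 2.5,
    "glycine": 1.0,
    "histidine": 1.0,
    "isoleucine": 2.0,
    "leucine": 3.0,
    "lysine": 2.5,
    "methionine": 1.0,
    "phenylalanine": 1.5,
    "proline": 2.0,
    "serine": 3.0,
    "threonine": 2.5,
    "tryptophan": 0.8,
    "tyrosine": 1.2,
    "valine": 2.5,
    "ornithine": 0.3,
}

#: concentrated feed composition, mM (glucose handled via setpoints; ornithine
#: absent from the feed, present only in the basal medium)
DEFAULT_FEED_COMPOSITION = {
    "alanine": 5.0,
    "arginine": 20.0,
    "asparagine": 40.0,
    "aspartate": 15.0,
    "cysteine": 8.0,
    "glutamine": 0.0,
    "glutamate": 20.0,
    "glycine": 20.0,
    "histidine": 10.0,
    "isoleucine": 25.0,
    "leucine": 35.0,
    "lysine": 25.0,
    "methionine": 10.0,
    "phenylalanine": 15.0,
    "proline": 20.0,
    "serine": 35.0,
    "threonine": 25.0,
    "tryptophan": 8.0,
    "tyrosine": 12.0,
    "valine": 28.0,
}


@dataclass
class FeedSchedule:
    """Bolus feed plan: days, volume fraction, composition, glucose setpoints.

    ``glucose_setpoints`` maps inclusive day ranges to the post-feed glucose
    target in g/L (bolus glucose is added only up to the setpoint).
    """

    bolus_days: list[int] = field(default_factory=lambda: list(BOLUS_DAYS))
    bolus_fraction: float = 0.04
    feed_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEED_COMPOSITION)
    )
    glucose_setpoints: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(4, 8): 6.0, (9, 12): 7.0}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.bolus_fraction < 1.0:
            raise ValueError(f"bolus_fraction must be in (0, 1), got {self.bolus_fraction}")
        ranges = sorted(self.glucose_setpoints)
        for (a1, b1), (a2, b2) in zip(ranges, ranges[1:]):
            if a2 <= b1:
                raise ValueError(f"glucose setpoint ranges overlap: {(a1, b1)} and {(a2, b2)}")

    def glucose_setpoint(self, day: float) -> float | None:
        """Target post-feed glucose (g/L) applicable on ``day``, if any."""
        for (a, b), target in self.glucose_setpoints.items():
            if a <= day <= b:
                return target
        return None


@dataclass
class ConditionSpec:
    """One GY-dose culture condition and its phenomenological kinetics.

    ``gy_dose`` is the unitless GY multiplier (1.0 = the Tyr-equivalent molar
    level of the reference feed).  ``mu_max`` (1/day), ``decline_rate``
    (1/day) and ``qp_max`` (pg/cell/day) are the kinetic ceilings reached at
    the optimal dose; the realized values are scaled by a unimodal
    dose-response peaking at 0.5x.  ``base_rates`` are specific metabolite
    rates in pmol/cell/day (negative = consumption).
    """

    condition_id: str
    gy_dose: float
    mu_max: float = 1.0
    decline_rate: float = 0.08
    qp_max: float = 20.0
    base_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    noise_cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0
    mu_tau: float = 7.0          # e-folding time (days) of the growth-rate decline
    t_peak: float = 8.0          # growth-to-decline switch day
    rate_decay: bool = True      # attenuate specific rates with culture age
    decay_t50: float = 2.0       # culture age (days) halving the specific rates
    rate_heterogeneity: float = 1.0  # CV of condition-level lognormal rate scatter
    # internal: per-metabolite additive rate offsets planted by
    # plant_titer_correlation (pmol/cell/day)
    rate_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.gy_dose <= 0:
            raise ValueError("gy_dose must be positive")


@dataclass
class FeedEvent:
    """One bolus: day, volume fraction, and per-metabolite concentration added.

    ``added`` holds the concentration increment each metabolite contributes in
    the post-bolus volume (mM), i.e. f*C_stock/(1+f) for a fixed-composition
    feed plus any glucose setpoint top-up.
    """

    day: float
    fraction: float
    added: dict[str, float]


@dataclass
class CultureBatch:
    """One bioreactor's sampled time series plus its feed events."""

    batch_id: str
    condition_id: str
    days: list[float]
    vcd: list[float]          # 10^6 cells/mL
    viability: list[float]    # %
    titer: list[float]        # mg/L
    conc: dict[str, list[float]]  # metabolite -> mM per sampling day
    feed_events: list[FeedEvent] = field(default_factory=list)
    volume: list[float] = field(default_factory=list)  # mL at each sampling day

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("sampling days must be strictly increasing")
        if np.any(np.asarray(self.vcd) < 0):
            raise ValueError("VCD must be non-negative")
        v = np.asarray(self.viability, dtype=float)
        if np.any((v < 0) | (v > 100)):
            raise ValueError("viability must lie in [0, 100]")
        if self.volume and np.any(np.asarray(self.volume) <= 0):
            raise ValueError("working volume must be positive")

    def value_at(self, variable: str, day: float) -> float:
        i = self.days.index(day)
        if variable == "VCD":
            return self.vcd[i]
        if variable == "viability":
            return self.viability[i]
        if variable == "titer":
            return self.titer[i]
        return self.conc[variable][i]


def growth_multiplier(gy_dose: float) -> float:
    """Unimodal dose-response factor for growth, peaking at 0.5x GY.

    Asymmetric in log-dose: Tyr starvation below the optimum hits growth much
    harder than dipeptide excess above it.
    """
    l2 = np.log2(gy_dose / 0.5)
    a = 0.10 if l2 < 0 else 0.03
    return float(max(0.2, 1.0 - a * l2 * l2))


def qp_multiplier(gy_dose: float) -> float:
    """Unimodal dose-response factor for specific productivity (peak 0.5x)."""
    l2 = np.log2(gy_dose / 0.5)
    a = 0.12 if l2 < 0 else 0.06
    return float(max(0.15, 1.0 - a * l2 * l2))


def default_conditions(
    doses: tuple[float, ...] = (0.125, 0.25, 0.5, 1.0, 2.0),
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> list[ConditionSpec]:
    """The study layout: 5 GY dose conditions with replicate bioreactors."""
    return [
        ConditionSpec(
            condition_id=f"GY{d:g}x",
            gy_dose=d,
            n_replicates=n_replicates,
            noise_cv=noise_cv,
            seed=seed,
        )
        for d in doses
    ]


def default_schedule() -> FeedSchedule:
    return FeedSchedule()


def _rate_at(cond: ConditionSpec, metabolite: str, phase_start: float) -> float:
    """Planted specific rate (pmol/cell/day) for a phase starting at a day.

    Uptake/secretion scales with the condition's growth multiplier (faster
    growing cultures turn over more nutrient) and, when ``rate_decay`` is on,
    attenuates with culture age (stationary-phase cells cycle nutrients far
    slower than exponential ones); lactate shows the canonical
    production-then-consumption shift after day 4; per-cell glucose uptake is
    dose-independent because glucose is controlled to a setpoint.
    """
    base = cond.base_rates.get(metabolite, 0.0)
    gm = growth_multiplier(cond.gy_dose)
    if metabolite == "lactate":
        rate = base * gm if phase_start < 4 else -0.25 * abs(base) * gm
    elif metabolite == "glucose":
        rate = base  # setpoint-fed; per-cell glucose uptake is dose-independent
    else:
        rate = base * gm
    # condition-level biological scatter (media lots, clone state): a
    # deterministic lognormal factor per (condition, metabolite); metabolites
    # carrying a planted correlation stay scatter-free so the planted ground
    # truth is exact
    if cond.rate_heterogeneity > 0 and metabolite not in cond.rate_offsets:
        h = np.random.default_rng(
            [cond.seed, zlib.crc32(cond.condition_id.encode()),
             zlib.crc32(metabolite.encode())]
        )
        sigma = float(np.sqrt(np.log1p(cond.rate_heterogeneity**2)))
        rate *= float(np.exp(h.normal(0.0, sigma)))
    rate += cond.rate_offsets.get(metabolite, 0.0)
    if cond.rate_decay:
        rate /= 1.0 + phase_start / cond.decay_t50
    return rate


def planted_phase_rates(
    condition: ConditionSpec, schedule: FeedSchedule | None = None
) -> dict[tuple[float, float], dict[str, float]]:
    """The exact per-phase specific rates the generator plants (ground truth).

    Keys are the sampling phases [t1, t2); values map metabolite name to the
    planted Qm in pmol/cell/day (the value the rates module should recover at
    zero noise).
    """
    mets = sorted(set(DEFAULT_INITIAL_CONC) | set(condition.base_rates))
    return {
        (float(t1), float(t2)): {m: _rate_at(condition, m, t1) for m in mets}
        for t1, t2 in zip(SAMPLING_DAYS, SAMPLING_DAYS[1:])
    }


def _simulate_vcd_grid(
    cond: ConditionSpec, schedule: FeedSchedule, t_peak: float = 8.0, dt: float = 0.1
) -> dict[float, float]:
    """Noise-free VCD (10^6 cells/mL) at sampling days.

    The specific growth rate declines exponentially with culture age
    (``mu(t) = mu_max * gm * exp(-t / mu_tau)``) until ``t_peak``, then
    first-order death takes over; this keeps the phase-wise SGR graded by GY
    dose through the whole growth phase, the way the dose conditions separate
    in practice.  Dynamics run on a ``dt``-day grid with a log-space update
    (exact for piecewise-constant rates); each bolus dilutes the suspension
    by 1/(1+f).  Inoculation at 0.3e6 cells/mL.
    """
    gm = growth_multiplier(cond.gy_dose)
    decline = cond.decline_rate
    f = schedule.bolus_fraction
    bolus_days = set(schedule.bolus_days)

    vcd = 0.3
    out: dict[float, float] = {}
    n_steps = int(round(14.0 / dt))
    for i in range(n_steps + 1):
        t = round(i * dt, 10)
        if t in SAMPLING_DAYS and t not in out:
            out[float(t)] = vcd  # sample first ...
        if t in bolus_days:
            vcd /= 1.0 + f      # ... then feed
        if i < n_steps:
            if t < t_peak:
                rate = cond.mu_max * gm * float(np.exp(-t / cond.mu_tau))
            else:
                rate = -decline
            vcd *= float(np.exp(rate * dt))
    return out


def _viability_profile(cond: ConditionSpec, days: list[float], t_peak: float = 8.0) -> list[float]:
    gm = growth_multiplier(cond.gy_dose)
    out = []
    for t in days:
        v = 98.0 if t <= t_peak else 98.0 * np.exp(-(2.0 - gm) * cond.decline_rate * (t - t_peak))
        out.append(float(min(v, 100.0)))
    return out


def _trapz_ivcd(v1: float, v2: float, t1: float, t2: float) -> float:
    return 0.5 * (v1 + v2) * (t2 - t1)


def simulate_fedbatch(
    condition: ConditionSpec,
    schedule: FeedSchedule | None = None,
    initial_conc: dict[str, float] | None = None,
    initial_volume: float = 12.0,
) -> list[CultureBatch]:
    """Simulate one condition's replicate fed-batch bioreactors.

    Returns ``condition.n_replicates`` batches that share one noise-free
    trajectory and differ only by multiplicative lognormal measurement noise
    (CV = ``condition.noise_cv``).  Deterministic for a fixed
    ``condition.seed``.
    """
    schedule = schedule or default_schedule()
    conc0 = dict(initial_conc or DEFAULT_INITIAL_CONC)

    vcd_true = _simulate_vcd_grid(condition, schedule, t_peak=condition.t_peak)
    days = [float(d) for d in SAMPLING_DAYS]
    viab_true = _viability_profile(condition, days, t_peak=condition.t_peak)

    gm = growth_multiplier(condition.gy_dose)
    qp = condition.qp_max * qp_multiplier(condition.gy_dose)

    f = schedule.bolus_fraction
    # feed tyrosine and glycine scale with the GY dose (the dipeptide carries
    # both residues); the rest of the composition is dose-independent
    feed_comp = dict(schedule.feed_composition)
    for met in ("tyrosine", "glycine"):
        if met in feed_comp:
            feed_comp[met] = feed_comp[met] * condition.gy_dose

    # noise-free balance at sampling days
    mets = sorted(set(conc0) | set(condition.base_rates))
    conc = {m: [conc0.get(m, 0.0)] for m in mets}
    titer = [0.0]
    volume = [initial_volume]
    feed_events: list[FeedEvent] = []

    cur = {m: conc0.get(m, 0.0) for m in mets}
    cur_titer = 0.0
    cur_vol = initial_volume
    for t1, t2 in zip(days, days[1:]):
        # bolus events inside [t1, t2): sample-then-feed, so an event on day t1
        # applies after the t1 measurement
        for d in schedule.bolus_days:
            if t1 <= d < t2:
                added: dict[str, float] = {}
                for m in mets:
                    add = f * feed_comp.get(m, 0.0) / (1.0 + f)
                    cur[m] = cur[m] / (1.0 + f) + add
                    if add > 0:
                        added[m] = add
                sp = schedule.glucose_setpoint(d)
                if sp is not None:
                    sp_mm = sp / GLUCOSE_MW * 1000.0
                    top_up = max(0.0, sp_mm - cur["glucose"])
                    cur["glucose"] += top_up
                    if top_up > 0:
                        added["glucose"] = added.get("glucose", 0.0) + top_up
                cur_titer /= 1.0 + f
                cur_vol *= 1.0 + f
                feed_events.append(FeedEvent(day=float(d), fraction=f, added=added))

        ivcd = _trapz_ivcd(vcd_true[t1], vcd_true[t2], t1, t2)  # 10^6 cell*day/mL
        for m in mets:
            # 1 pmol/cell/day * 1e6 cells/mL * day = 1e6 pmol/mL = 1 mM
            new = cur[m] + _rate_at(condition, m, t1) * ivcd
            if new < 0:
                logger.warning(
                    "%s: %s depleted in phase [%g, %g); clipped to 0",
                    condition.condition_id, m, t1, t2,
                )
                new = 0.0
            cur[m] = new
            conc[m].append(new)
        # 1 pg/cell/day * 1e6 cells/mL * day = 1e6 pg/mL = 1 mg/L
        cur_titer += qp * ivcd
        titer.append(cur_titer)
        volume.append(cur_vol)

    vcd_series = [vcd_true[t] for t in days]

    batches: list[CultureBatch] = []
    for rep in range(condition.n_replicates):
        rng = np.random.default_rng(
            [condition.seed, zlib.crc32(condition.condition_id.encode()), rep]
        )
        sigma = float(np.sqrt(np.log1p(condition.noise_cv**2)))

        def noisy(values: list[float]) -> list[float]:
            if condition.noise_cv == 0:
                return [float(v) for v in values]
            factors = np.exp(rng.normal(0.0, sigma, size=len(values)))
            return [float(v * c) for v, c in zip(values, factors)]

        batches.append(
            CultureBatch(
                batch_id=f"{condition.condition_id}#{rep + 1}",
                condition_id=condition.condition_id,
                days=days,
                vcd=noisy(vcd_series),
                viability=[min(v, 100.0) for v in noisy(viab_true)],
                titer=noisy(titer),
                conc={m: noisy(conc[m]) for m in mets},
                feed_events=[FeedEvent(e.day, e.fraction, dict(e.added)) for e in feed_events],
                volume=list(volume),
            )
        )
    return batches


def simulate_study(
    conditions: list[ConditionSpec],
    schedule: FeedSchedule | None = None,
    **kwargs,
) -> list[CultureBatch]:
    """Simulate a full multi-condition study (concatenated batches)."""
    out: list[CultureBatch] = []
    for cond in conditions:
        out.extend(simulate_fedbatch(cond, schedule, **kwargs))
    return out


def plant_outlier(
    batches: list[CultureBatch], target_batch_id: str, scale: float
) -> list[CultureBatch]:
    """Scale one batch's whole VCD trajectory to create a known QC outlier."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    ids = [b.batch_id for b in batches]
    if target_batch_id not in ids:
        raise KeyError(f"unknown batch id {target_batch_id!r}")
    out = []
    for b in batches:
        if b.batch_id == target_batch_id:
            b = replace(b, vcd=[v * scale for v in b.vcd])
        out.append(b)
    return out


def plant_titer_correlation(
    conditions: list[ConditionSpec],
    metabolite: str,
    sign: int,
    strength: float,
) -> list[ConditionSpec]:
    """Plant a nutrient-titer correlation of known sign across conditions.

    The metabolite's specific rate is shifted per condition in proportion to
    the condition's expected relative titer score ``s`` (centred across
    conditions), by ``sign * strength * 2 * |base rate| * (s - mean s)``
    pmol/cell/day.  With ``sign = -1`` high-titer conditions consume more, so
    the terminal residual concentration correlates negatively with final
    titer; ``strength = 1`` modulates the rate by roughly +/- 100 % of its
    base magnitude across the dose range.
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    # anchor the plant to each condition's realized (noise-free) final titer
    scores = []
    for c in conditions:
        probe = replace(c, noise_cv=0.0, n_replicates=1)
        scores.append(simulate_fedbatch(probe)[0].titer[-1])
    scores = np.asarray(scores)
    scores = scores / scores.max()
    centred = scores - scores.mean()
    out = []
    for cond, s in zip(conditions, centred):
        base = abs(cond.base_rates.get(metabolite, 0.0)) or 0.1
        offsets = dict(cond.rate_offsets)
        offsets[metabolite] = offsets.get(metabolite, 0.0) + sign * strength * 2.0 * base * s
        out.append(replace(cond, rate_offsets=offsets))
    return out
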