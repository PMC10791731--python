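"""End-to-end orchestration: synth -> rates -> qc -> pls -> ecfba -> compare.

A :class:`PipelineConfig` (typically loaded from YAML) drives the stages and
every numeric constant of the analysis — SD band width, VIP threshold, bound
relaxation, flux floor, FC threshold, cell dry weight, analysis phase — is a
config parameter with the study's defaults.  All outputs are CSV/JSON under
one run directory with deterministic formatting, so a rerun under the same
seed is byte-identical; ``manifest.json`` records the config hash, seed and
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import gyflux
from gyflux import io as gio
from gyflux.compare import (
    compare_solutions,
    akg_by_transaminases,
    cofactor_summary,
    intersect_comparisons,
    select_distinct,
    substrate_partition,
)
from gyflux.ecfba import condition_flux
from gyflux.model import augment_with_gy, read_model
from gyflux.pls import BatchLevelPLS, unfold_batch_level
from gyflux.qc import detect_outliers, filter_outliers
from gyflux.rates import compute_phase_rates, rates_to_frame
from gyflux.synth import default_conditions, default_schedule, plant_outlier, \
    plant_titer_correlation, simulate_study
from gyflux.toynet import toy_cho_network

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class SynthConfig:
    enabled: bool = True
    doses: list[float] = field(default_factory=lambda: [0.125, 0.25, 0.5, 1.0, 2.0])
    n_replicates: int = 3
    noise_cv: float = 0.05
    plant_metabolite: str | None = None
    plant_sign: int = -1
    plant_strength: float = 1.0
    outlier_batch: str | None = None
    outlier_scale: float = 0.5


@dataclass
class PipelineConfig:
    output_dir: str = "gyflux_run"
    seed: int = 0
    measurements: str | None = None      # existing dataset (skip synth)
    feeds: str | None = None
    model_path: str | None = None        # SBML/JSON model; default: toy network
    synth: SynthConfig = field(default_factory=SynthConfig)
    # analysis parameters (study defaults)
    band_k: float = 1.0
    frac_threshold: float = 0.5
    vip_threshold: float = 1.00
    n_components: int | None = None
    relaxation: float = 0.20
    flux_floor: float = 0.0001
    fc_threshold: float = 1.2
    dcw_per_cell: float = 250.0
    phase: list[float] = field(default_factory=lambda: [6.0, 7.0])
    reference_condition: str = "GY0.5x"
    compare_conditions: list[str] = field(default_factory=lambda: ["GY0.125x", "GY1x"])
    p_total: float | None = 0.05
    eq2_strict: bool = False
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "rates", "qc", "mvda", "fba", "compare"]
    )

    def __post_init__(self) -> None:
        if isinstance(self.synth, dict):
            self.synth = _build(SynthConfig, self.synth)
        if not 0 <= self.frac_threshold <= 1:
            raise ValueError("frac_threshold must lie in [0, 1]")
        for name, lo in (("band_k", 0.0), ("relaxation", 0.0), ("flux_floor", 0.0),
                         ("fc_threshold", 0.0), ("dcw_per_cell", 0.0)):
            if getattr(self, name) < lo:
                raise ValueError(f"{name} must be >= {lo}")
        if len(self.phase) != 2 or self.phase[0] >= self.phase[1]:
            raise ValueError("phase must be [start, end] with start < end")
        unknown = set(self.stages) - {"simulate", "rates", "qc", "mvda", "fba", "compare"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


def _dose_condition_id(dose: float) -> str:
    return f"GY{dose:g}x"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a manifest-style result dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "gyflux",
        "version": gyflux.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(
                {k: v for k, v in config.to_dict().items() if k != "output_dir"},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "stages_completed": [],
    }
    stages = config.stages

    def done(stage: str) -> None:
        manifest["stages_completed"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    try:
        # ------------------------------------------------------ simulate --
        schedule = default_schedule()
        if "simulate" in stages and config.measurements is None:
            conditions = default_conditions(
                doses=tuple(config.synth.doses),
                n_replicates=config.synth.n_replicates,
                noise_cv=config.synth.noise_cv,
                seed=config.seed,
            )
            if config.synth.plant_metabolite:
                conditions = plant_titer_correlation(
                    conditions,
                    config.synth.plant_metabolite,
                    config.synth.plant_sign,
                    config.synth.plant_strength,
                )
            batches = simulate_study(conditions, schedule)
            if config.synth.outlier_batch:
                batches = plant_outlier(
                    batches, config.synth.outlier_batch, config.synth.outlier_scale
                )
            gio.write_dataset(batches, out / "measurements.csv", out / "feeds.csv")
            done("simulate")
        else:
            if config.measurements is None:
                raise ValueError("no dataset: enable the simulate stage or set measurements")
            batches = gio.read_dataset(config.measurements, config.feeds)

        # ---------------------------------------------------------- rates --
        all_rates = {}
        if "rates" in stages or "fba" in stages:
            all_rates = {
                b.batch_id: compute_phase_rates(b, eq2_strict=config.eq2_strict)
                for b in batches
            }
            frames = [rates_to_frame(r) for r in all_rates.values()]
            import pandas as pd

            pd.concat(frames, ignore_index=True).to_csv(
                out / "rates.csv", index=False, float_format=FLOAT_FORMAT
            )
            done("rates")

        # ------------------------------------------------------------- qc --
        if "qc" in stages:
            report = detect_outliers(
                batches, band_k=config.band_k, frac_threshold=config.frac_threshold
            )
            report.to_frame().to_csv(out / "qc_report.csv", index=False,
                                     float_format=FLOAT_FORMAT)
            batches = filter_outliers(batches, report)
            gio.write_dataset(
                batches, out / "filtered_measurements.csv", out / "filtered_feeds.csv"
            )
            done("qc")

        # ----------------------------------------------------------- mvda --
        if "mvda" in stages:
            matrix = unfold_batch_level(batches)
            results = BatchLevelPLS.from_matrix(matrix).fit(
                n_components=config.n_components
            )
            results.scores_table().to_csv(out / "pls_scores.csv",
                                          float_format=FLOAT_FORMAT)
            results.vip.rename("VIP").reset_index().to_csv(
                out / "pls_vip.csv", index=False, float_format=FLOAT_FORMAT
            )
            results.coefficient_table().to_csv(out / "pls_coefficients.csv",
                                               float_format=FLOAT_FORMAT)
            ranking = results.rank_nutrients(vip_threshold=config.vip_threshold)
            ranking.to_csv(out / "pls_ranking.csv", index=False,
                           float_format=FLOAT_FORMAT)
            (out / "pls_summary.txt").write_text(results.summary() + "\n")
            done("mvda")

        # ------------------------------------------------------------ fba --
        solutions = {}
        if "fba" in stages:
            if config.model_path:
                model = read_model(config.model_path)
            else:
                model = augment_with_gy(toy_cho_network(p_total=config.p_total or 0.05))
            model.p_total = config.p_total
            phase = (config.phase[0], config.phase[1])
            wanted = [config.reference_condition] + list(config.compare_conditions)
            import pandas as pd

            flux_rows = []
            for cond in wanted:
                phase_rates = [
                    next(r for r in rates if r.phase == phase)
                    for bid, rates in all_rates.items()
                    if bid in {b.batch_id for b in batches}
                    and next(iter(b for b in batches if b.batch_id == bid)).condition_id == cond
                ]
                if not phase_rates:
                    raise ValueError(f"no replicate rates for condition {cond!r}")
                solutions[cond] = condition_flux(
                    phase_rates,
                    model,
                    dcw_per_cell=config.dcw_per_cell,
                    relaxation=config.relaxation,
                )
                for rid, v in sorted(solutions[cond].fluxes.items()):
                    flux_rows.append(
                        (cond, rid, v, solutions[cond].model.reactions[rid].subsystem)
                    )
            pd.DataFrame(
                flux_rows, columns=["condition", "reaction", "flux", "subsystem"]
            ).to_csv(out / "fluxes.csv", index=False, float_format=FLOAT_FORMAT)
            done("fba")

        # -------------------------------------------------------- compare --
        result_tables = {}
        if "compare" in stages and solutions:
            import pandas as pd

            ref = config.reference_condition
            split_model = solutions[ref].model
            selected_sets = {}
            for cond in config.compare_conditions:
                cmp = compare_solutions(
                    solutions[ref], solutions[cond], floor=config.flux_floor,
                    reference_id=ref, other_id=cond,
                )
                df = cmp.to_frame(split_model, fc_threshold=config.fc_threshold)
                df.to_csv(out / f"comparison_{cond}_vs_{ref}.csv", index=False,
                          float_format=FLOAT_FORMAT)
                selected_sets[cond] = select_distinct(cmp, config.fc_threshold)
                result_tables[cond] = df
            if len(selected_sets) >= 2:
                conds = list(selected_sets)
                common, tally = intersect_comparisons(
                    selected_sets[conds[0]], selected_sets[conds[1]], split_model
                )
                tally.to_csv(out / "intersection_subsystems.csv", index=False)
                manifest["n_selected"] = {c: len(s) for c, s in selected_sets.items()}
                manifest["n_repeated"] = len(common)

            cof_rows = []
            for cond, sol in solutions.items():
                for cof in ("nadph_c", "nadh_m", "fadh2_m"):
                    cof_rows.append((cond, cof, cofactor_summary(sol, cofactor=cof)))
            pd.DataFrame(cof_rows, columns=["condition", "cofactor", "producing_flux"]).to_csv(
                out / "cofactor_summary.csv", index=False, float_format=FLOAT_FORMAT
            )

            akg_rows = []
            for cond, sol in solutions.items():
                df = akg_by_transaminases(sol)
                df.insert(0, "condition", cond)
                akg_rows.append(df)
            pd.concat(akg_rows, ignore_index=True).to_csv(
                out / "akg_transaminases.csv", index=False, float_format=FLOAT_FORMAT
            )

            part_rows = []
            glu_sinks = {
                "Gln synthesis (GLNS)": "GLNS",
                "4abut synthesis (GLUDC)": "GLUDC",
                "protein (biomass)": "BIOMASS_cho",
                "antibody (IgG)": "IGG_SYNTH",
            }
            asn_sinks = {"Asp via ASNN": "ASNN", "protein (biomass)": "BIOMASS_cho",
                         "antibody (IgG)": "IGG_SYNTH"}
            for cond, sol in solutions.items():
                for substrate, sinks in (("glu_L[c]", glu_sinks), ("asn_L[c]", asn_sinks)):
                    df = substrate_partition(sol, substrate, sinks)
                    df.insert(0, "substrate", substrate)
                    df.insert(0, "condition", cond)
                    part_rows.append(df)
            pd.concat(part_rows, ignore_index=True).to_csv(
                out / "substrate_partitions.csv", index=False, float_format=FLOAT_FORMAT
            )
            done("compare")
    except Exception as exc:
        manifest["failed_stage"] = exc.__class__.__name__ + ": " + str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
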