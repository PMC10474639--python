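"""End-to-end orchestration: simulate, emulate, weight, estimate, summarize.

Each run is driven by a :class:`RunConfig`.  All randomness flows from one
root seed, split deterministically per stage with ``numpy.random
.SeedSequence``, so two runs with identical config and seed produce identical
output bundles and individual stages are reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, effects, emulate, io, ipcw, multistate
from .errors import CloneWeightError, ConfigurationError
from .simulate import DESIGN_COLUMNS, SimulationConfig, generate_cohort
from .states import default_structure

logger = logging.getLogger("cloneweight")

STAGE_SEEDS = ("simulate", "bootstrap")


@dataclass
class RunConfig:
    """Settings for a full pipeline run."""

    cohort_path: str | None = None
    output_dir: str = "cloneweight_output"
    grace_days: int = 5
    admin_censor_day: int = 45
    stabilize: bool = False
    truncation_quantile: float = 1.0
    covariates: tuple[str, ...] = DESIGN_COLUMNS
    evaluation_days: tuple[int, ...] = (20, 30, 45)
    variant: str = "five_level"
    n_bootstrap: int = 1000
    seed: int = 0
    simulation: SimulationConfig | None = None

    def stage_seed(self, stage: str) -> int:
        base = np.random.SeedSequence([int(self.seed), STAGE_SEEDS.index(stage)])
        return int(base.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        d = {
            "cohort_path": self.cohort_path,
            "output_dir": str(self.output_dir),
            "grace_days": int(self.grace_days),
            "admin_censor_day": int(self.admin_censor_day),
            "stabilize": bool(self.stabilize),
            "truncation_quantile": float(self.truncation_quantile),
            "covariates": list(self.covariates),
            "evaluation_days": list(int(d) for d in self.evaluation_days),
            "variant": self.variant,
            "n_bootstrap": int(self.n_bootstrap),
            "seed": int(self.seed),
        }
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = d.get("simulation")
        return cls(
            cohort_path=d.get("cohort_path"),
            output_dir=d.get("output_dir", "cloneweight_output"),
            grace_days=int(d.get("grace_days", 5)),
            admin_censor_day=int(d.get("admin_censor_day", 45)),
            stabilize=bool(d.get("stabilize", False)),
            truncation_quantile=float(d.get("truncation_quantile", 1.0)),
            covariates=tuple(d.get("covariates", DESIGN_COLUMNS)),
            evaluation_days=tuple(d.get("evaluation_days", (20, 30, 45))),
            variant=d.get("variant", "five_level"),
            n_bootstrap=int(d.get("n_bootstrap", 1000)),
            seed=int(d.get("seed", 0)),
            simulation=SimulationConfig.from_dict(sim) if sim else None,
        )


def _write_meta(path: Path, config: RunConfig, extra: dict | None = None) -> None:
    meta = {"version": __version__, "seed": int(config.seed), "config": config.to_dict()}
    if extra:
        meta.update(extra)
    io.dump_yaml(meta, path)


def cmd_simulate(config: RunConfig, cohort_out: str | None = None) -> Path:
    """Simulate a cohort and write it with a metadata sidecar."""
    if config.simulation is None:
        raise ConfigurationError("simulation settings are required for cmd_simulate")
    sim = config.simulation
    sim.seed = config.stage_seed("simulate")
    cohort = generate_cohort(sim)
    out = Path(cohort_out or config.cohort_path or Path(config.output_dir) / "cohort.csv")
    out.parent.mkdir(parents=True, exist_ok=True)
    io.write_cohort(cohort, out)
    _write_meta(out.with_suffix(out.suffix + ".meta.yaml"), config, {"n_patients": len(cohort)})
    logger.info("simulated %d patients -> %s", len(cohort), out)
    return out


def cmd_emulate_estimate(config: RunConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Run the full emulation and estimation bundle, writing every artifact.

    Returns a dict of the in-memory results keyed by artifact name.  Stage
    failures other than per-day effect estimation are propagated with the
    stage name; per-day effect failures are caught and reported in the
    effects table.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name: str, fn):
        try:
            return fn()
        except CloneWeightError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    if cohort is None:
        if config.cohort_path is None:
            raise ConfigurationError("cohort_path is required when no cohort is given")
        cohort = stage("read_cohort", lambda: io.read_cohort(config.cohort_path))

    emu = emulate.EmulationConfig(config.grace_days, config.admin_censor_day)

    eligible, exclusion_log = stage("eligibility", lambda: emulate.apply_eligibility(cohort))
    logger.info("eligibility: %d of %d retained (%s)", len(eligible), len(cohort), exclusion_log)
    pd.DataFrame(
        [{"rule": k, "excluded": v} for k, v in exclusion_log.items()]
    ).to_csv(outdir / "exclusion_log.csv", index=False)
    results["exclusion_log"] = exclusion_log

    clones = stage("cloning", lambda: emulate.clone_and_censor(eligible, emu))
    logger.info("cloning: %d clones from %d patients", len(clones), len(eligible))
    io.write_clones(clones, outdir / "clones.csv")
    results["clones"] = clones

    wm = ipcw.CensoringWeightModel(
        covariates=config.covariates,
        grace_days=config.grace_days,
        admin_censor_day=config.admin_censor_day,
        stabilize=config.stabilize,
        truncation_quantile=config.truncation_quantile,
        on_no_events="degenerate",
    )
    weight_table = stage("weights", lambda: wm.fit(clones).transform(clones))
    weight_table.to_csv(outdir / "weights.csv", index=False)
    results["weight_table"] = weight_table
    results["weight_model"] = wm

    balance = stage("balance", lambda: wm.balance(clones))
    balance.to_csv(outdir / "balance.csv", index=False)
    results["balance"] = balance
    logger.info("balance: max weighted SMD %.4f", balance["smd_weighted"].max())

    structure = default_structure()
    cumhaz_rows = []
    occ_rows = []
    for arm in ipcw.ARMS:
        sub = clones.loc[clones["arm"] == arm]
        wt = weight_table.loc[weight_table["arm"] == arm]
        long = stage(
            f"long_format[{arm}]",
            lambda sub=sub, wt=wt: multistate.build_long_format(
                sub, wt, structure, config.admin_censor_day
            ),
        )
        est = stage(
            f"estimate[{arm}]",
            lambda long=long: multistate.WeightedAalenJohansen(
                structure, horizon=config.admin_censor_day
            ).fit(long),
        )
        ch = est.cumhaz_.table.copy()
        ch.insert(0, "arm", arm)
        ch["transition"] = (
            ch["from_state"].astype(int).astype(str) + "->" + ch["to_state"].astype(int).astype(str)
        )
        cumhaz_rows.append(ch[["arm", "transition", "day", "increment", "cumulative"]])
        occ = est.occupation_.reset_index().melt(
            id_vars="day", var_name="state", value_name="probability"
        )
        occ.insert(0, "arm", arm)
        occ_rows.append(occ)
        results[f"aalen_johansen_{arm}"] = est
    cumhaz = pd.concat(cumhaz_rows, ignore_index=True)
    occupation = pd.concat(occ_rows, ignore_index=True)
    cumhaz.to_csv(outdir / "cumulative_hazards.csv", index=False)
    occupation.to_csv(outdir / "occupation_probabilities.csv", index=False)
    results["cumulative_hazards"] = cumhaz
    results["occupation"] = occupation

    effect_rows = []
    boot_seed = config.stage_seed("bootstrap")
    for i, day in enumerate(config.evaluation_days):
        try:
            est = effects.bootstrap_pipeline(
                eligible,
                B=config.n_bootstrap,
                seed=boot_seed + i,
                evaluation_day=int(day),
                variant=config.variant,
                emulation=emu,
                covariates=config.covariates,
                stabilize=config.stabilize,
            )
            effect_rows.append(
                {
                    "evaluation_day": day,
                    "odds_ratio": est.odds_ratio,
                    "ci_lower": est.ci_lower,
                    "ci_upper": est.ci_upper,
                    "n_bootstrap": est.n_bootstrap,
                    "n_failed": est.n_failed,
                    "seed": est.seed,
                    "error": "",
                }
            )
            results[f"effect_day{day}"] = est
        except CloneWeightError as exc:
            logger.warning("effects at day %s failed: %s", day, exc)
            effect_rows.append(
                {
                    "evaluation_day": day,
                    "odds_ratio": float("nan"),
                    "ci_lower": float("nan"),
                    "ci_upper": float("nan"),
                    "n_bootstrap": config.n_bootstrap,
                    "n_failed": config.n_bootstrap,
                    "seed": boot_seed + i,
                    "error": str(exc),
                }
            )
    effect_table = pd.DataFrame(effect_rows)
    effect_table.to_csv(outdir / "effects.csv", index=False)
    with open(outdir / "effects.txt", "w", encoding="utf-8") as fh:
        for row in effect_rows:
            if row["error"]:
                fh.write(f"day {row['evaluation_day']}: estimation failed ({row['error']})\n")
            else:
                fh.write(
                    f"day {row['evaluation_day']}: OR {row['odds_ratio']:.3f} "
                    f"(95% CI {row['ci_lower']:.3f}-{row['ci_upper']:.3f}; "
                    f"B={row['n_bootstrap']}, dropped {row['n_failed']}, "
                    f"seed {row['seed']})\n"
                )
    results["effects"] = effect_table

    _write_meta(outdir / "run_meta.yaml", config, {"n_patients": len(cohort), "n_clones": len(clones)})
    with open(outdir / "run_meta.json", "w", encoding="utf-8") as fh:
        json.dump({"version": __version__, "seed": int(config.seed)}, fh)
    return results


def run_all(config: RunConfig) -> dict:
    """Simulate (when configured) then emulate and estimate."""
    cohort = None
    if config.simulation is not None:
        path = cmd_simulate(config)
        cohort = io.read_cohort(path)
    return cmd_emulate_estimate(config, cohort=cohort)
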