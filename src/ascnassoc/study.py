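"""Scenario-grid power and type-I-error engine.

Runs the full simulation pipeline — draw a case-control cohort, optionally
degrade it to bi-allelic calls and/or inject CNV calling errors, fit the
requested strategies — across a grid of frequency scenarios × risk models,
and aggregates rejection fractions (power or type-I error), Monte-Carlo
standard errors and the joint-model odds-ratio recovery summaries.

Reproducibility contract: one master seed; each (scenario, risk) cell and
each replicate within it receives its own ``numpy.random.SeedSequence``
child, so results are bit-identical for a fixed master seed regardless of
evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import RiskModel, ScenarioSpec, scenario_from_dict
from .simulate import (
    CallTable,
    Cohort,
    ErrorSpec,
    default_call_table,
    simulate_cohort,
    degrade_to_genotypes,
    inject_errors,
)
from . import assoc

logger = logging.getLogger("ascnassoc")

#: Replicate-count presets: "full" matches the study design; "desk" is a
#: reduced preset for interactive reproduction.
REPLICATE_PRESETS = {"full": 10_000, "desk": 1_000}


@dataclass
class StudyConfig:
    """Configuration of one power/type-I-error study."""

    scenarios: Sequence[ScenarioSpec]
    risks: Sequence[RiskModel]
    n_cases: int = 1000
    n_controls: int = 1000
    n_replicates: int = REPLICATE_PRESETS["desk"]
    alpha: float = 0.05
    strategies: Sequence[str] = ("cn", "allele_multi", "joint")
    error_spec: ErrorSpec | None = None
    call_table: CallTable | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.strategies) - set(assoc.STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        scenarios, risks = [], []
        for d in raw["scenarios"]:
            spec, _ = scenario_from_dict(d)
            scenarios.append(spec)
        for d in raw["risks"]:
            risks.append(
                RiskModel(float(d.get("rr_cn", 1)), float(d.get("rr_allele", 1)))
            )
        err = raw.get("errors")
        call_table = raw.get("call_table")
        return cls(
            scenarios=scenarios,
            risks=risks,
            n_cases=int(raw.get("n_cases", 1000)),
            n_controls=int(raw.get("n_controls", 1000)),
            n_replicates=int(raw.get("n_replicates", REPLICATE_PRESETS["desk"])),
            alpha=float(raw.get("alpha", 0.05)),
            strategies=tuple(raw.get("strategies", ("cn", "allele_multi", "joint"))),
            error_spec=(
                ErrorSpec(float(err["sensitivity"]), float(err["specificity"]))
                if err
                else None
            ),
            call_table=CallTable.from_tsv(call_table) if call_table else None,
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class PowerTable:
    """Aggregated study results.

    ``power`` has one row per (scenario, risk, strategy) with the rejection
    fraction among converged replicates, its Monte-Carlo standard error and
    the replicate accounting; ``estimates`` has one row per (scenario, risk)
    summarizing the transformed joint-model odds ratios.
    """

    power: pd.DataFrame
    estimates: pd.DataFrame
    alpha: float = 0.05

    def relative_power(self, strategy: str, reference_strategy: str) -> pd.DataFrame:
        """Per-cell power(strategy) / power(reference_strategy).

        Cells where the reference power is zero get NaN and are flagged in
        the ``undefined`` column.
        """
        keys = ["f_norm", "cnv_type", "f_b", "rr_cn", "rr_allele"]
        for name in (strategy, reference_strategy):
            if name not in set(self.power["strategy"]):
                raise ValueError(f"strategy {name!r} not in table")
        a = self.power[self.power["strategy"] == strategy].set_index(keys)
        b = self.power[self.power["strategy"] == reference_strategy].set_index(keys)
        out = pd.DataFrame(index=a.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = a["power"] / b["power"]
        out["power"] = a["power"]
        out["reference_power"] = b["power"]
        out["ratio"] = ratio.where(b["power"] > 0)
        out["undefined"] = b["power"] == 0
        return out.reset_index()


def _mc_se(phat: float, n: int) -> float:
    return float(np.sqrt(phat * (1.0 - phat) / n)) if n else float("nan")


def run_replicate(
    spec: ScenarioSpec,
    risk: RiskModel,
    config: StudyConfig,
    seed,
) -> list[assoc.AssocFit]:
    """One replicate of the pipeline: simulate → degrade/corrupt → fit."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_sim, s_deg, s_err = ss.spawn(3)
    cohort = simulate_cohort(
        spec, risk, config.n_cases, config.n_controls, np.random.default_rng(s_sim)
    )
    if "allele_bi" in config.strategies:
        table = config.call_table or default_call_table()
        cohort = degrade_to_genotypes(cohort, table, np.random.default_rng(s_deg))
    if config.error_spec is not None:
        cohort = inject_errors(cohort, config.error_spec, np.random.default_rng(s_err))
    return [assoc.fit_strategy(cohort, name) for name in config.strategies]


def run_study(config: StudyConfig) -> PowerTable:
    """Execute the full grid and aggregate power / estimate summaries.

    A replicate whose fit fails to converge counts into ``n_failed`` for that
    strategy and is excluded from the rejection-fraction denominator; raised
    exceptions are logged, counted, and never silently dropped.
    """
    master = np.random.SeedSequence(config.seed)
    cell_seeds = master.spawn(len(config.scenarios) * len(config.risks))
    power_rows: list[dict] = []
    est_rows: list[dict] = []
    cell_i = 0
    for spec in config.scenarios:
        for risk in config.risks:
            cell_ss = cell_seeds[cell_i]
            cell_i += 1
            rep_seeds = cell_ss.spawn(config.n_replicates)
            rejected = dict.fromkeys(config.strategies, 0)
            converged = dict.fromkeys(config.strategies, 0)
            failed = dict.fromkeys(config.strategies, 0)
            or_cn_list: list[float] = []
            or_allele_list: list[float] = []
            for rep_ss in rep_seeds:
                try:
                    fits = run_replicate(spec, risk, config, rep_ss)
                except Exception:  # pragma: no cover - defensive
                    logger.exception(
                        "replicate failed in scenario %s risk %s", spec, risk
                    )
                    for name in config.strategies:
                        failed[name] += 1
                    continue
                for name, fit in zip(config.strategies, fits):
                    if not fit.converged or fit.p_value is None:
                        failed[name] += 1
                        continue
                    converged[name] += 1
                    if fit.p_value < config.alpha:
                        rejected[name] += 1
                    if name == "joint" and fit.or_cn is not None:
                        or_cn_list.append(fit.or_cn)
                        or_allele_list.append(fit.or_allele)
            base = {**spec.to_dict(), **risk.to_dict()}
            for name in config.strategies:
                phat = rejected[name] / converged[name] if converged[name] else np.nan
                power_rows.append(
                    {
                        **base,
                        "strategy": name,
                        "n_replicates": config.n_replicates,
                        "n_converged": converged[name],
                        "n_failed": failed[name],
                        "n_rejected": rejected[name],
                        "power": phat,
                        "mc_se": _mc_se(phat, converged[name]),
                    }
                )
            if or_cn_list:
                est_rows.append(
                    {
                        **base,
                        **estimate_summary(or_cn_list, or_allele_list, risk),
                    }
                )
    return PowerTable(
        power=pd.DataFrame(power_rows),
        estimates=pd.DataFrame(est_rows),
        alpha=config.alpha,
    )


def estimate_summary(
    or_cn: Sequence[float], or_allele: Sequence[float], risk: RiskModel
) -> dict:
    """Median / mean / MSE (against the simulated values) of the joint ORs."""
    oc = np.asarray(or_cn, dtype=float)
    oa = np.asarray(or_allele, dtype=float)
    if oc.size == 0:
        raise ValueError("no converged replicates to summarize")
    return {
        "n_converged": int(oc.size),
        "or_cn_median": float(np.median(oc)),
        "or_cn_mean": float(np.mean(oc)),
        "or_cn_mse": float(np.mean((oc - risk.rr_cn) ** 2)),
        "or_allele_median": float(np.median(oa)),
        "or_allele_mean": float(np.mean(oa)),
        "or_allele_mse": float(np.mean((oa - risk.rr_allele) ** 2)),
    }


def write_outputs(table: PowerTable, out_dir: str | Path) -> None:
    """Write power.tsv and estimates.tsv under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.power.to_csv(out / "power.tsv", sep="\t", index=False)
    table.estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
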