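"""End-to-end driver: simulate (or load) a cohort, run every analysis stage,
and write a structured, checksummed report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import apply_exclusion_cascade, default_generating_model, generate_cohort
from .dediff import communality_curve, communality_delta, fit_losem, fit_moderated_factor
from .factors import (
    add_residual_covariances,
    eigen_spectrum,
    factor_scores,
    fit_gtr,
    fit_one_factor,
    fit_pathway_models,
)
from .mediation import bootstrap_enet_select, fit_multiple_mediator, thalamus_increment
from .table import TractMetricTable
from .tract_effects import fit_tract_regression
from .tracts import make_tract_catalog

__all__ = ["RunConfig", "RunReport", "run_full_pipeline"]

ALL_STAGES = [
    "tract_effects",
    "factors",
    "pathways",
    "mediation",
    "prediction",
    "dedifferentiation",
]


@dataclass
class RunConfig:
    seed: int = 0
    n_raw: int = 5455
    measures: Sequence[str] = ("FA", "MD", "ICVF", "ISOVF", "OD")
    stages: Sequence[str] = tuple(ALL_STAGES)
    out_dir: str = "dediffwm_run"
    p_significant: float = 0.001
    loading_cutoff: float = 0.3
    enet_threshold: float = 0.60
    n_boot: int = 1000
    mediation_boot: int = 2000
    losem_targets: int = 300
    losem_bandwidth: float = 2.0
    run_losem: bool = False
    max_residual_pairs: int = 3
    moderation_mode: str = "invariant"
    weak_factor_threshold: float = 0.15
    input_dir: Optional[str] = None  # read a user-supplied table instead

    def __post_init__(self):
        for name, v in (
            ("p_significant", self.p_significant),
            ("loading_cutoff", self.loading_cutoff),
            ("enet_threshold", self.enet_threshold),
        ):
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if len(set(self.measures)) != len(list(self.measures)):
            raise ValueError("measure labels must be unique")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["measures"] = list(self.measures)
        d["stages"] = list(self.stages)
        return d


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)   # name -> {"status", "seconds", ...}
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    warnings: List[str] = field(default_factory=list)
    exclusion_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Logger:
    def __init__(self, path: Path):
        self.fh = path.open("w")

    def log(self, **kv):
        kv["time"] = round(time.time(), 2)
        self.fh.write(json.dumps(kv, default=str) + "\n")
        self.fh.flush()


def run_full_pipeline(config: RunConfig, table: Optional[TractMetricTable] = None) -> RunReport:
    """Run every enabled stage on a synthetic (or supplied) cohort.

    Stage failures are recorded in the report and later independent stages
    still run.  Deterministic given the config seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Logger(out / "run_log.jsonl")
    report = RunReport(config=config.to_dict())

    if table is None and config.input_dir:
        table = TractMetricTable.read(config.input_dir)
    if table is None:
        gm = default_generating_model(measures=tuple(config.measures))
        subjects, table = generate_cohort(gm, n_raw=config.n_raw, seed=config.seed)
        retained, counts = apply_exclusion_cascade(subjects)
        report.exclusion_counts = dict(counts)
        table = table.subset_subjects(retained["subject_id"])
        table.write(out / "cohort", manifest={"seed": config.seed})
        log.log(stage="simulate", n_raw=config.n_raw, n_final=len(retained))
    else:
        for col in ("age", "sex"):
            if col not in table.covariates.columns:
                raise ValueError(f"covariate table is missing required column {col!r}")

    scores: dict[str, pd.Series] = {}
    fits: dict[str, object] = {}

    def run_stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.time()
        try:
            extra = fn() or {}
            report.stages[name] = {"status": "complete", "seconds": round(time.time() - t0, 2), **extra}
            log.log(stage=name, status="complete", seconds=round(time.time() - t0, 2))
        except Exception as exc:  # stage isolation: later stages still run
            report.stages[name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            log.log(stage=name, status="failed", error=str(exc))

    # ------------------------------------------------------- tract effects
    def _tract_effects():
        rows = []
        catalog = {t.name for t in make_tract_catalog()}
        present = sorted(set(table.long["tract"]) & catalog)
        for m in config.measures:
            for tract in present:
                try:
                    res = fit_tract_regression(table, tract, m)
                except ValueError:
                    continue
                for term, row in res.coefficients.iterrows():
                    rows.append({"measure": m, "tract": tract, "form": res.form,
                                 "term": term, "beta": row["beta"], "se": row["se"],
                                 "p": row["p"], "significant": bool(row["p"] < config.p_significant),
                                 "n": res.n})
        df = pd.DataFrame(rows)
        df.to_csv(out / "tract_effects.tsv", sep="\t", index=False)
        return {"n_models": int(df[["measure", "tract"]].drop_duplicates().shape[0])}

    # -------------------------------------------------------------- factors
    def _factors():
        summary = {}
        for m in config.measures:
            spec = eigen_spectrum(table, m, weak_threshold=config.weak_factor_threshold)
            summary[m] = {"first_factor_share": spec.first_factor_share,
                          "weak_first_factor": spec.weak_first_factor}
            if spec.weak_first_factor:
                report.warnings.append(
                    f"{m}: weak first factor (share {spec.first_factor_share:.3f}); "
                    "no factor score extracted"
                )
                continue
            fit = fit_one_factor(table, m)
            if config.max_residual_pairs > 0:
                fit = add_residual_covariances(table, m, fit, max_pairs=config.max_residual_pairs)
            fits[m] = fit
            scores[f"g{m}"] = factor_scores(fit, keep=("age_z", "age_z2"))
            (out / f"factor_{m}.json").write_text(json.dumps(fit.to_dict(), indent=2))
            summary[m]["variance_explained"] = fit.variance_explained_
            summary[m]["n_residual_pairs"] = len(fit.pairs_)
        if scores:
            pd.DataFrame(scores).rename_axis("subject_id").to_csv(out / "factor_scores.tsv", sep="\t")
        return {"measures": summary}

    # ------------------------------------------------------------- pathways
    def _pathways():
        results = {}
        for m in config.measures:
            if m not in fits:
                continue
            cmp_ = fit_pathway_models(table, m, max_selected=5)
            results[m] = {
                "fits": {k: {kk: float(vv) for kk, vv in v.items()} for k, v in cmp_.fits.items()},
                "selected_paths": cmp_.selected_paths,
                "preferred_aic": cmp_.preferred_aic,
                "preferred_bic": cmp_.preferred_bic,
            }
        (out / "pathways.json").write_text(json.dumps(results, indent=2))
        return {"n_measures": len(results)}

    # ------------------------------------------------------------ mediation
    def _mediation():
        needed = {"gFA", "gICVF", "gOD"}
        if not needed <= set(scores):
            raise ValueError(f"mediation needs factor scores {sorted(needed)}")
        df = pd.DataFrame(scores).join(table.covariates["age"]).dropna()
        res = fit_multiple_mediator(
            df["age"], df["gFA"], df[["gICVF", "gOD"]],
            n_boot=config.mediation_boot, seed=config.seed,
        )
        payload = {
            "total": res.total, "direct": res.direct,
            "indirect": res.indirect.tolist(),
            "indirect_ci": res.indirect_ci.tolist(),
            "proportion_mediated": res.proportion_mediated,
            "proportion_ci": list(res.proportion_ci),
            "n": res.n,
        }
        (out / "mediation.json").write_text(json.dumps(payload, indent=2))
        return {"proportion_mediated": res.proportion_mediated}

    # ----------------------------------------------------------- prediction
    def _prediction():
        if table.volumetrics is None or not scores:
            raise ValueError("prediction needs volumetrics and factor scores")
        cand = pd.DataFrame(scores).join(table.volumetrics).dropna()
        age = table.covariates.loc[cand.index, "age"]
        sel = bootstrap_enet_select(
            cand, age.to_numpy(), n_boot=config.n_boot,
            freq_threshold=config.enet_threshold, split_seed=config.seed,
        )
        sel.inclusion_frequency.rename_axis("predictor").to_csv(out / "enet_frequencies.tsv", sep="\t")
        if sel.train_table is not None:
            sel.train_table.rename_axis("predictor").to_csv(out / "enet_train.tsv", sep="\t")
            sel.test_table.rename_axis("predictor").to_csv(out / "enet_test.tsv", sep="\t")
        extra = {"selected": sel.selected, "train_r2": sel.train_r2, "test_r2": sel.test_r2}
        if "ThalV" in cand.columns or "thalamic_volume" in cand.columns:
            thal_col = "thalamic_volume" if "thalamic_volume" in cand.columns else "ThalV"
            gtr = fit_gtr(table, "MD")["scores"].reindex(cand.index)
            inc = thalamus_increment(
                cand[thal_col], gtr, cand.get("total_brain_volume", cand.iloc[:, 0]), age
            )
            inc.to_csv(out / "thalamus_increment.tsv", sep="\t", index=False)
        return extra

    # ----------------------------------------------------- dedifferentiation
    def _dediff():
        results = {}
        for m in config.measures:
            if m not in fits:
                continue
            mfit = fit_moderated_factor(
                table, m, mode=config.moderation_mode, base_fit=fits[m]
            )
            curve = communality_curve(mfit)
            delta, delta_se = communality_delta(mfit)
            curve.to_frame().to_csv(out / f"communality_{m}.tsv", sep="\t", index=False)
            results[m] = {
                "loading_moderation": mfit.loading_moderation_.to_dict(),
                "unique_moderation": mfit.unique_moderation_.to_dict(),
                "communality_delta_45_75_pp": delta,
                "communality_delta_se": delta_se,
            }
            if config.run_losem:
                losem = fit_losem(
                    table, m, n_targets=config.losem_targets,
                    bandwidth=config.losem_bandwidth,
                )
                losem.communality.rename_axis("age").to_csv(out / f"losem_{m}.tsv", sep="\t")
        (out / "dedifferentiation.json").write_text(json.dumps(results, indent=2))
        return {"n_measures": len(results)}

    run_stage("tract_effects", _tract_effects)
    run_stage("factors", _factors)
    run_stage("pathways", _pathways)
    run_stage("mediation", _mediation)
    run_stage("prediction", _prediction)
    run_stage("dedifferentiation", _dediff)

    for f in sorted(out.rglob("*")):
        # the JSON-lines log carries wall-clock timestamps; everything else
        # must be byte-identical across reruns with the same config
        if f.is_file() and f.name not in ("report.json", "run_log.jsonl"):
            report.outputs[str(f.relative_to(out))] = _sha256(f)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, default=str))
    return report
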