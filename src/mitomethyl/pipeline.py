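"""End-to-end orchestration: simulate -> ingest -> filter -> test -> index ->
clock -> classify -> report.

Every stage communicates through serialized artifacts (TSV/JSON) under the
output directory, so a run can be inspected or restarted stage by stage, and a
second run with the same config and seed is byte-identical. The sensitivity
sweep re-runs the selection/index/score stages across P-value thresholds and
sequence-context subsets and summarizes whether the qualitative conclusions
(direction of the brain-area contrast, sign of the median age acceleration,
classifier AUC) persist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, simulate as sim
from .indices import (
    BrainAreaIndex,
    DrugUseClassifier,
    MethylationClock,
    acceleration_contrast,
    venn_overlap,
)
from .stats import chi_square_independence, mann_whitney, paired_wilcoxon, results_to_frame

logger = logging.getLogger("mitomethyl")

AGE_COVARIATES = ["batch", "collector", "alcohol", "pmi_class"]
DU_COVARIATES = ["age"] + AGE_COVARIATES

__all__ = ["RunConfig", "run_pipeline", "cohort_summary", "sensitivity_sweep"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` (a :class:`~mitomethyl.simulate.SimulationConfig`)
    or ``input_dir`` (a directory holding ``reference.fa``, ``cohort.tsv`` and
    ``reports/<id>_<area>.tsv``) must be provided. Selection alphas default to
    the primary 0.05 threshold; the sweep exposes 0.02 and 0.005.
    """

    simulation: sim.SimulationConfig | None = None
    input_dir: str | None = None
    min_coverage: int = 30
    alpha_ba: float = 0.05
    alpha_age: float = 0.05
    alpha_du: float = 0.05
    context_subset: str = "all"
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        for a in (self.alpha_ba, self.alpha_age, self.alpha_du):
            if not 0 < a < 1:
                raise ValueError("alphas must be in (0, 1)")
        if self.context_subset not in ("all", "CpG_only", "nonCpG_only"):
            raise ValueError(f"invalid context_subset {self.context_subset!r}")
        if self.simulation is None and self.input_dir is None:
            raise ValueError("provide a simulation block or an input directory")
        if self.simulation is not None:
            self.simulation.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = sim.SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_json_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir")  # where artifacts land does not change what they contain
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _materialize_data(config: RunConfig, outdir: Path) -> Path:
    """Simulate and serialize the dataset, or point at the provided inputs."""
    if config.input_dir is not None:
        return Path(config.input_dir)
    data_dir = outdir / "data"
    reference, cohort, truth, calls = sim.simulate_dataset(config.simulation)
    sim.write_reference(reference, data_dir / "reference.fa")
    sim.write_cohort(cohort, data_dir / "cohort.tsv", overwrite=True)
    sim.write_truth(truth, data_dir / "truth.json", overwrite=True)
    sim.write_call_sets(calls, data_dir / "reports", overwrite=True)
    logger.info("simulated %d report files", len(calls))
    return data_dir


def _load_matrices(data_dir: Path, config: RunConfig):
    cohort = sim.read_cohort(data_dir / "cohort.tsv")
    genome_length = len(sim.read_reference(data_dir / "reference.fa"))
    matrices = {}
    for area in sim.AREAS:
        call_sets = {}
        for pid in cohort["id"]:
            path = data_dir / "reports" / f"{pid}_{area}.tsv"
            if path.exists():
                call_sets[pid] = core.read_cytosine_report(path, genome_length=genome_length)
        matrix = core.build_matrix(call_sets, min_coverage=config.min_coverage, area=area)
        n_before = matrix.n_sites
        matrix = matrix.subset_context(config.context_subset)
        logger.info(
            "%s: %d samples, %d sites after coverage/presence filter (%d after context subset)",
            area, len(call_sets), n_before, matrix.n_sites,
        )
        matrices[area] = matrix
    return cohort, matrices


def _covariate_frame(cohort: pd.DataFrame, ids, columns) -> pd.DataFrame:
    meta = cohort.set_index("id").loc[list(ids), columns].copy()
    return meta


def _ba_stage(cohort, matrices, config, outdir) -> dict:
    """Brain-area contrast: select/weight on controls, score both groups."""
    meta = cohort.set_index("id")
    control_ids = [i for i in meta.index[meta["group"] == "control"]]
    drug_ids = [i for i in meta.index[meta["group"] == "drug"]]
    nacc, pfc = matrices["NAcc"], matrices["PFC"]
    shared = core.overlap_sites(nacc, pfc)

    def paired_rows(ids):
        both = [i for i in ids if i in nacc.levels.index and i in pfc.levels.index]
        return (
            nacc.levels.loc[both, shared],
            pfc.levels.loc[both, shared],
        )

    a_ctrl, b_ctrl = paired_rows(control_ids)
    model = BrainAreaIndex(alpha=config.alpha_ba).fit(a_ctrl, b_ctrl)
    results_to_frame(model.results_).to_csv(outdir / "ba_site_tests.tsv", sep="\t", index=False)
    (outdir / "ba_index.json").write_text(model.index_.to_json())

    a_drug, b_drug = paired_rows(drug_ids)
    scores = {
        ("control", "NAcc"): model.transform(a_ctrl),
        ("control", "PFC"): model.transform(b_ctrl),
        ("drug", "NAcc"): model.transform(nacc.levels.loc[[i for i in drug_ids if i in nacc.levels.index], shared]),
        ("drug", "PFC"): model.transform(pfc.levels.loc[[i for i in drug_ids if i in pfc.levels.index], shared]),
    }
    rows = []
    for (group, area), s in scores.items():
        for pid, val in s.items():
            rows.append({"id": pid, "group": group, "area": area, "ba_score": val})
    pd.DataFrame(rows).to_csv(outdir / "ba_scores.tsv", sep="\t", index=False)

    ctrl_pair = paired_wilcoxon(scores[("control", "NAcc")], scores[("control", "PFC")])
    drug_pair = paired_wilcoxon(
        model.transform(a_drug), model.transform(b_drug)
    )
    _, p_nacc_groups = mann_whitney(
        scores[("drug", "NAcc")], scores[("control", "NAcc")]
    )
    _, p_pfc_groups = mann_whitney(scores[("drug", "PFC")], scores[("control", "PFC")])
    return {
        "n_shared_sites": len(shared),
        "n_selected": model.n_sites_,
        "control_paired_p": ctrl_pair.p_value,
        "control_median_diff": float(
            np.median(scores[("control", "NAcc")].to_numpy() - scores[("control", "PFC")].to_numpy())
        ),
        "drug_paired_p": drug_pair.p_value,
        "nacc_group_p": p_nacc_groups,
        "pfc_group_p": p_pfc_groups,
        "_model": model,
    }


def _age_stage(cohort, matrices, config, outdir) -> dict:
    """Per-area epigenetic clock on controls; acceleration contrasts."""
    meta = cohort.set_index("id")
    out = {}
    for area, matrix in matrices.items():
        ids = list(matrix.levels.index)
        control_ids = [i for i in ids if meta.loc[i, "group"] == "control"]
        cov = _covariate_frame(cohort, control_ids, AGE_COVARIATES)
        clock = MethylationClock(alpha=config.alpha_age)
        clock.fit(
            matrix.levels.loc[control_ids],
            meta.loc[control_ids, "age"].astype(float),
            covariates=cov,
        )
        results_to_frame(clock.results_).to_csv(
            outdir / f"age_site_tests_{area}.tsv", sep="\t", index=False
        )
        (outdir / f"age_index_{area}.json").write_text(clock.index_.to_json())
        (outdir / f"clock_{area}.json").write_text(clock.clock_.to_json())

        accel = clock.acceleration(matrix.levels, meta.loc[ids, "age"].astype(float))
        accel_df = pd.DataFrame(
            {
                "id": accel.index,
                "group": meta.loc[accel.index, "group"].to_numpy(),
                "age": meta.loc[accel.index, "age"].to_numpy(),
                "predicted_age": clock.predict(matrix.levels),
                "acceleration": accel.to_numpy(),
            }
        )
        accel_df.to_csv(outdir / f"age_acceleration_{area}.tsv", sep="\t", index=False)

        groups = meta.loc[accel.index, "group"]
        heroin = meta.loc[accel.index, "heroin"]
        contrasts = {"drug": acceleration_contrast(accel, groups, heroin)}
        for sub in ("ketamine", "ats"):
            mask = meta.loc[accel.index, sub]
            if bool(mask[groups == "drug"].any()):
                contrasts[sub] = acceleration_contrast(accel, groups, heroin, drug_mask=mask)
        out[area] = {
            "n_selected": clock.n_sites_,
            "r_squared": clock.r_squared_,
            "clock_p": clock.clock_.p_value,
            "contrasts": contrasts,
            "_model": clock,
        }
    return out


def _du_stage(cohort, matrices, config, outdir) -> dict:
    """Per-area drug-use classifier with threshold rule and ROC."""
    meta = cohort.set_index("id")
    out = {}
    for area, matrix in matrices.items():
        ids = list(matrix.levels.index)
        y = meta.loc[ids, "group"].to_numpy()
        cov = _covariate_frame(cohort, ids, DU_COVARIATES)
        clf = DrugUseClassifier(alpha=config.alpha_du)
        clf.fit(matrix.levels, y, covariates=cov)
        results_to_frame(clf.results_).to_csv(
            outdir / f"du_site_tests_{area}.tsv", sep="\t", index=False
        )
        (outdir / f"du_index_{area}.json").write_text(clf.index_.to_json())
        ev = clf.evaluate(matrix.levels, y)
        ev.roc_points.to_csv(outdir / f"du_roc_{area}.tsv", sep="\t", index=False)
        scores = clf.transform(matrix.levels)
        pd.DataFrame(
            {"id": scores.index, "group": y, "du_score": scores.to_numpy()}
        ).to_csv(outdir / f"du_scores_{area}.tsv", sep="\t", index=False)
        _, p_groups = mann_whitney(
            scores.to_numpy()[y == "drug"], scores.to_numpy()[y == "control"]
        )
        out[area] = {
            "n_selected": clf.n_sites_,
            "threshold": clf.threshold_,
            "group_p": p_groups,
            "eval": ev.to_dict(),
            "_model": clf,
        }
    return out


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Group-comparison summary of the cohort metadata.

    Age by Mann-Whitney; alcohol, PMI class and cause of death by Pearson
    chi-square on the group-by-category count tables. Counts are reported as
    n and percent, ages as mean (SD).
    """
    groups = ("control", "drug")
    if set(cohort["group"]) != set(groups):
        raise ValueError("both groups must be present")
    by = {g: cohort[cohort["group"] == g] for g in groups}
    out: dict = {"n": {g: int(len(by[g])) for g in groups}}
    out["age"] = {
        g: {"mean": float(by[g]["age"].mean()), "sd": float(by[g]["age"].std(ddof=1))}
        for g in groups
    }
    _, out["age"]["p_value"] = mann_whitney(by["control"]["age"], by["drug"]["age"])

    def two_by_two(flag_series):
        return [
            [int(flag_series[g].sum()), int((~flag_series[g]).sum())] for g in groups
        ]

    def chi2_p(table):
        # a zero marginal (e.g. no drinker in either group) leaves the
        # comparison undefined rather than failing the whole summary
        try:
            return chi_square_independence(table)[2]
        except ValueError:
            return None

    alcohol = {g: by[g]["alcohol"].astype(bool) for g in groups}
    p_alc = chi2_p(two_by_two(alcohol))
    pmi = {g: by[g]["pmi_class"] == "le6h" for g in groups}
    p_pmi = chi2_p(two_by_two(pmi))
    out["alcohol"] = {
        g: {"n": int(alcohol[g].sum()), "pct": float(100 * alcohol[g].mean())} for g in groups
    }
    out["alcohol"]["p_value"] = p_alc
    out["pmi_le6h"] = {
        g: {"n": int(pmi[g].sum()), "pct": float(100 * pmi[g].mean())} for g in groups
    }
    out["pmi_le6h"]["p_value"] = p_pmi

    levels = sorted(set(cohort["cause_of_death"]))
    table = [[int((by[g]["cause_of_death"] == lv).sum()) for lv in levels] for g in groups]
    out["cause_of_death"] = {"levels": levels, "counts": table, "p_value": chi2_p(table)}
    return out


def _strip_private(obj):
    if isinstance(obj, dict):
        return {k: _strip_private(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_strip_private(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run report.

    Stages run in the study's order: brain-area contrast, epigenetic clock and
    age acceleration, drug-use classification, index overlap, cohort summary.
    All artifacts land under ``config.outdir``; the report itself is written
    as ``report.json`` and returned (with fitted models attached under keys
    starting with ``_``, which are stripped from the serialized report).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_dir = _materialize_data(config, outdir)
    cohort, matrices = _load_matrices(data_dir, config)

    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "context_subset": config.context_subset,
        "n_sites": {area: m.n_sites for area, m in matrices.items()},
        "context_counts": {
            area: m.sites["context"].value_counts().to_dict() for area, m in matrices.items()
        },
    }
    stage = "brain_area"
    try:
        report["brain_area"] = _ba_stage(cohort, matrices, config, outdir)
        stage = "age_clock"
        report["age_clock"] = _age_stage(cohort, matrices, config, outdir)
        stage = "drug_use"
        report["drug_use"] = _du_stage(cohort, matrices, config, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    models = {
        "BA": report["brain_area"]["_model"].index_,
        "Age_NAcc": report["age_clock"]["NAcc"]["_model"].index_,
        "Age_PFC": report["age_clock"]["PFC"]["_model"].index_,
        "DU_NAcc": report["drug_use"]["NAcc"]["_model"].index_,
        "DU_PFC": report["drug_use"]["PFC"]["_model"].index_,
    }
    report["venn"] = venn_overlap(models)
    pd.DataFrame(
        sorted(report["venn"].items()), columns=["cell", "count"]
    ).to_csv(outdir / "venn_counts.tsv", sep="\t", index=False)
    report["cohort_summary"] = cohort_summary(cohort)

    serializable = _strip_private(report)
    (outdir / "report.json").write_text(json.dumps(serializable, indent=1, sort_keys=True))
    report_clean = dict(serializable)
    report_clean["_models"] = models
    return report_clean


def sensitivity_sweep(
    config: RunConfig,
    alphas: tuple[float, ...] = (0.05, 0.02, 0.005),
    contexts: tuple[str, ...] = ("all", "CpG_only", "nonCpG_only"),
) -> dict:
    """Re-run the selection/index/score stages across thresholds and contexts.

    Reports, per setting, the selected-site counts and the qualitative
    conclusions (direction and significance of the brain-area contrast, sign
    of the median drug-group age acceleration, classifier AUC), verifies that
    selected-site sets are nested across decreasing alphas within each
    context, and records settings where an index comes out empty instead of
    failing.
    """
    if len(alphas) * len(contexts) < 2:
        raise ValueError("a sweep needs at least 2 settings")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_dir = _materialize_data(config, outdir)

    settings = {}
    sites_by_context: dict[str, dict[float, dict[str, set]]] = {}
    for context in contexts:
        ctx_cfg = dataclasses.replace(config, context_subset=context)
        cohort, matrices = _load_matrices(data_dir, ctx_cfg)
        for alpha in alphas:
            run_cfg = dataclasses.replace(
                ctx_cfg, alpha_ba=alpha, alpha_age=alpha, alpha_du=alpha
            )
            sub = outdir / f"sweep_{context}_alpha{alpha:g}"
            sub.mkdir(exist_ok=True)
            entry: dict = {"alpha": alpha, "context": context}
            sets: dict[str, set] = {}
            try:
                ba = _ba_stage(cohort, matrices, run_cfg, sub)
                entry["ba"] = {
                    "n_selected": ba["n_selected"],
                    "control_paired_p": ba["control_paired_p"],
                    "direction": "NAcc>PFC" if ba["control_median_diff"] > 0 else "NAcc<PFC",
                }
                sets["BA"] = set(ba["_model"].index_.sites)
            except ValueError as exc:
                entry["ba"] = {"empty": str(exc)}
            try:
                age = _age_stage(cohort, matrices, run_cfg, sub)
                entry["age"] = {
                    area: {
                        "n_selected": v["n_selected"],
                        "r_squared": v["r_squared"],
                        "median_shift": v["contrasts"]["drug"]["median_shift"],
                    }
                    for area, v in age.items()
                }
                for area, v in age.items():
                    sets[f"Age_{area}"] = set(v["_model"].index_.sites)
            except ValueError as exc:
                entry["age"] = {"empty": str(exc)}
            try:
                du = _du_stage(cohort, matrices, run_cfg, sub)
                entry["du"] = {
                    area: {"n_selected": v["n_selected"], "auc": v["eval"]["auc"]}
                    for area, v in du.items()
                }
                for area, v in du.items():
                    sets[f"DU_{area}"] = set(v["_model"].index_.sites)
            except ValueError as exc:
                entry["du"] = {"empty": str(exc)}
            settings[f"{context}@{alpha:g}"] = entry
            sites_by_context.setdefault(context, {})[alpha] = sets

    nested = True
    for context, per_alpha in sites_by_context.items():
        ordered = sorted(per_alpha)  # ascending alpha
        for lo, hi in zip(ordered, ordered[1:]):
            for name, lo_sites in per_alpha[lo].items():
                if not lo_sites <= per_alpha[hi].get(name, set()):
                    nested = False
    summary = {"settings": settings, "nesting_across_alphas": nested}
    directions = {
        k: v["ba"].get("direction")
        for k, v in settings.items()
        if "direction" in v.get("ba", {})
    }
    summary["ba_direction_stable"] = len(set(directions.values())) <= 1
    (outdir / "sweep_summary.json").write_text(
        json.dumps(_strip_private(summary), indent=1, sort_keys=True)
    )
    return summary
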