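"""End-to-end orchestration of the averaging analyses.

Per subject: optional reliability-based unit selection, the unit-level
slope analysis, the pattern-averaging statistic (split-half and
noise-normalized for run-resolved data, plain correlation for activation
matrices), the weighted-average sweep, and the near/far linkage.  Across
subjects: t-tests against the averaging baselines with Benjamini-Hochberg
correction within explicit families.

Outputs are a machine-readable report (JSON) plus per-subject CSVs; the
whole run is a pure function of the configuration and input files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .dataset import ResponseDataset
from .design import ConditionTable
from .inference import StatTest, adjust_families, between_subject_ci, one_sample_t, paired_t
from .linkage import classify_units, groupwise_pattern_averaging, pooled_proportion_near
from .patterns import noiseless_pattern_averaging, split_half_pattern_ratio, weight_sweep
from .reliability import select_top_units
from .synth import CoefficientSpec, DistributionSpec, GeneratorConfig, generate_cohort
from .unit_slope import condition_means, per_unit_slopes, population_slope, responsive_unit_mask

logger = logging.getLogger(__name__)

STAGES = ("slope", "pattern", "link")


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything that determines a pipeline run.

    Defaults carry the canonical analysis constants: 75 selected units,
    slope baselines 0.5 (perfect averaging) and 0.55 (macaque IT), near/far
    bounds 0.45/0.55, a 10%-step weight grid, a one-tailed test of the
    noise-normalized ratio against 1.
    """

    generator: GeneratorConfig | None = None
    dataset_path: str | None = None
    condition_table_path: str | None = None
    select_top_n: int | None = 75
    slope_baselines: tuple[float, ...] = (0.5, 0.55)
    near_lo: float = 0.45
    near_hi: float = 0.55
    weight_step: float = 0.1
    sweep_score: str = "ratio"
    actual_r_threshold: float = 0.05
    fisher_z: bool = False
    ratio_tail: str = "less"
    output_dir: str | None = None
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.dataset_path is None):
            raise ValueError("configure exactly one input: a generator or a dataset path")

    # -- (de)serialization ---------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        gen = d.pop("generator", None)
        if gen is not None:
            gen = dict(gen)
            if "tuning" in gen:
                gen["tuning"] = DistributionSpec(**gen["tuning"])
            if "coefficient" in gen:
                gen["coefficient"] = CoefficientSpec(**gen["coefficient"])
            gen = GeneratorConfig(**gen)
        if "slope_baselines" in d:
            d["slope_baselines"] = tuple(d["slope_baselines"])
        return cls(generator=gen, **d)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(config: AnalysisConfig) -> list[ResponseDataset]:
    if config.generator is not None:
        gen = config.generator
        if config.seed is not None:
            gen = dataclasses.replace(gen, seed=config.seed)
        return generate_cohort(gen)
    table: ConditionTable | None = None
    if config.condition_table_path:
        table = pio.read_condition_table(config.condition_table_path)
    subjects = pio.read_dataset(config.dataset_path, table=table)
    if not subjects:
        raise ValueError("the dataset contains no subjects")
    return list(subjects.values())


def _analyze_subject(ds: ResponseDataset, config: AnalysisConfig, stages) -> dict:
    table = ds.table
    n_total = ds.n_units
    if ds.has_runs and config.select_top_n:
        ds = select_top_units(ds, config.select_top_n)
    means = condition_means(ds)
    mask = responsive_unit_mask(means, table)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("subject %s: excluding %d unresponsive unit(s)", ds.subject_id, n_dropped)

    out: dict = {
        "subject": ds.subject_id,
        "n_units_total": n_total,
        "n_units_analyzed": int(mask.sum()),
        "mode": "split_half" if ds.has_runs else "noiseless",
    }
    frames: dict[str, pd.DataFrame] = {}

    slopes = None
    if "slope" in stages or "link" in stages:
        slope_res = population_slope(means, table, mask)
        slopes = slope_res.per_unit_slope
        out["population_slope"] = slope_res.population_slope
        out["population_intercept"] = slope_res.population_intercept
        frames["scatter"] = slope_res.scatter_frame(ds.unit_ids)

    if "pattern" in stages:
        if ds.has_runs:
            pat = split_half_pattern_ratio(
                ds,
                unit_mask=mask,
                actual_r_threshold=config.actual_r_threshold,
                fisher_z=config.fisher_z,
            )
            out["mean_ratio"] = pat.mean_ratio
            out["ratio_of_means"] = pat.ratio_of_means
            sweep = weight_sweep(
                ds,
                mode="split_half",
                step=config.weight_step,
                score=config.sweep_score,
                unit_mask=mask,
                actual_r_threshold=config.actual_r_threshold,
                fisher_z=config.fisher_z,
            )
        else:
            pat = noiseless_pattern_averaging(means, table, unit_mask=mask)
            sweep = weight_sweep(
                means, table, mode="noiseless", step=config.weight_step, unit_mask=mask
            )
        out["mean_averaged_r"] = pat.mean_averaged_r
        out["pattern_score"] = pat.score
        out["argmax_weight"] = sweep.argmax_weight
        frames["pattern"] = pat.to_frame()
        frames["sweep"] = sweep.to_frame()

    if "link" in stages:
        cls = classify_units(slopes, config.near_lo, config.near_hi)
        data = ds if ds.has_runs else means
        group = groupwise_pattern_averaging(
            data,
            table,
            cls,
            mode="split_half" if ds.has_runs else "noiseless",
            unit_mask=mask,
            **(
                {"actual_r_threshold": config.actual_r_threshold, "fisher_z": config.fisher_z}
                if ds.has_runs
                else {}
            ),
        )
        out["proportion_near"] = cls.proportion_near
        out["n_near"] = cls.n_near
        out["n_far"] = cls.n_far
        out["near_score"] = None if group.pattern_near is None else group.pattern_near.score
        out["far_score"] = None if group.pattern_far is None else group.pattern_far.score
        out["_classification"] = cls
        frames["labels"] = cls.to_frame(ds.unit_ids, slopes)

    out["_frames"] = frames
    return out


def _cohort_inference(subjects: list[dict], config: AnalysisConfig) -> list[StatTest]:
    tests: list[StatTest] = []

    def collect(key):
        vals = [s[key] for s in subjects if s.get(key) is not None]
        return np.array(vals, dtype=float)

    slopes = collect("population_slope")
    if slopes.size >= 2:
        for mu in config.slope_baselines:
            tests.append(
                one_sample_t(slopes, mu, "two", name=f"slope_vs_{mu}", family_id="slope_baselines")
            )
    scores = collect("pattern_score")
    if scores.size >= 2 and subjects[0].get("mode") == "split_half":
        tests.append(
            one_sample_t(scores, 1.0, config.ratio_tail, name="ratio_vs_1", family_id="pattern_vs_1")
        )
    near = collect("near_score")
    far = collect("far_score")
    if near.size >= 2 and near.size == far.size:
        tests.append(paired_t(near, far, "two", name="near_vs_far", family_id="near_far"))
    return adjust_families(tests)


def run_pipeline(config: AnalysisConfig, stages=STAGES) -> dict:
    """Run the configured stages on every subject and summarize the cohort.

    Returns the report as a dict; writes ``report.json``, per-subject CSVs
    and a flat ``stats.csv`` under ``config.output_dir`` when set.  A stage
    failure for one subject is logged with the stage and subject id, and the
    run continues with the remaining subjects.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    datasets = _load_inputs(config)
    stages = tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")

    subject_results: list[dict] = []
    errors: list[dict] = []
    for ds in datasets:
        try:
            subject_results.append(_analyze_subject(ds, config, stages))
        except Exception as exc:  # keep going across subjects
            logger.error("subject %s failed: %s", ds.subject_id, exc)
            errors.append({"subject": ds.subject_id, "error": str(exc)})
    if not subject_results:
        raise RuntimeError(f"every subject failed: {errors}")

    tests = _cohort_inference(subject_results, config)
    cohort: dict = {"n_subjects": len(subject_results)}
    for key in ("population_slope", "pattern_score", "proportion_near"):
        vals = np.array([s[key] for s in subject_results if s.get(key) is not None], dtype=float)
        if vals.size:
            cohort[f"mean_{key}"] = float(vals.mean())
            if vals.size >= 2:
                cohort[f"ci95_{key}"] = between_subject_ci(vals)
    classifications = [s["_classification"] for s in subject_results if "_classification" in s]
    if classifications:
        cohort["pooled_proportion_near"] = pooled_proportion_near(classifications)
    cohort["tests"] = [t.to_record() for t in tests]

    report = {
        "config": config.to_dict(),
        "stages": list(stages),
        "subjects": [
            {k: v for k, v in s.items() if not k.startswith("_")} for s in subject_results
        ],
        "cohort": cohort,
        "errors": errors,
    }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
        for s in subject_results:
            for name, frame in s["_frames"].items():
                frame.to_csv(outdir / f"{s['subject']}_{name}.csv", index=False)
        if tests:
            pd.DataFrame([t.to_record() for t in tests]).to_csv(
                outdir / "stats.csv", index=False
            )
    return report
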