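"""Stage orchestration: simulate -> classify -> filter -> fit / lambda /
endo, each writing TSV outputs plus a run manifest into an output
directory. Stages are deterministic under a fixed seed; `all` reproduces
the full case-control and endophenotype analysis on a simulated cohort.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .cohort import assign_groups_frame, filter_frame
from .endophenotype import kruskal_wallis, linear_trait_model, pairwise_group_tests
from .firth import FirthOptions, fit_group_model
from .inflation import marker_panel_lambda
from .simulate import (
    DiseaseModelConfig,
    simulate_cohort,
    simulate_neutral_markers,
)

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "classify", "filter", "fit", "lambda", "endo", "all")
log = logging.getLogger("albistat")


class StageError(RuntimeError):
    """A stage refused to run (missing prerequisite or bad input)."""


def _read_stage(out_dir: Path, name: str, prior_stage: str) -> pd.DataFrame:
    path = out_dir / name
    if not path.exists():
        raise StageError(
            f"{path.name} not found in {out_dir}; run the '{prior_stage}' "
            "stage first (or 'all')")
    return pd.read_csv(path, sep="\t")


def stage_simulate(config: DiseaseModelConfig, seed: int, out_dir: Path) -> None:
    cfg_seed = int(seed)
    rng = np.random.default_rng(cfg_seed)
    cohort = simulate_cohort(config, rng=rng, with_traits=True)
    markers = simulate_neutral_markers(cohort.frame, m=35, rng=rng)
    frame = cohort.frame.drop(columns=["group", "modifier_count"])
    frame.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    markers.insert(0, "individual_id", cohort.frame["individual_id"].to_numpy())
    markers.to_csv(out_dir / "markers.tsv", sep="\t", index=False)
    log.info("simulate: %d individuals (%d cases), %d lambda markers",
             len(frame), int((frame["label"] == "case").sum()),
             markers.shape[1] - 1)
    aio.write_manifest(out_dir, "simulate", config, cfg_seed, [],
                       ["cohort.tsv", "markers.tsv"])


def stage_classify(config, seed: int, out_dir: Path,
                   cohort_path: Path | None = None) -> None:
    frame = (pd.read_csv(cohort_path, sep="\t") if cohort_path
             else _read_stage(out_dir, "cohort.tsv", "simulate"))
    classified = assign_groups_frame(frame)
    classified.to_csv(out_dir / "classified.tsv", sep="\t", index=False)
    counts = classified["group"].value_counts().to_dict()
    log.info("classify: group counts %s", counts)
    aio.write_manifest(out_dir, "classify", config, seed,
                       ["cohort.tsv"], ["classified.tsv"])


def stage_filter(config, seed: int, out_dir: Path) -> None:
    frame = _read_stage(out_dir, "classified.tsv", "classify")
    kept, exclusions = filter_frame(frame)
    kept.to_csv(out_dir / "filtered.tsv", sep="\t", index=False)
    exclusions.to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
    log.info("filter: %d in, %d retained, %d excluded",
             len(frame), len(kept), int(exclusions["excluded"].sum()))
    aio.write_manifest(out_dir, "filter", config, seed,
                       ["classified.tsv"], ["filtered.tsv", "exclusions.tsv"])


def stage_fit(config, seed: int, out_dir: Path,
              options: FirthOptions | None = None) -> pd.DataFrame:
    frame = _read_stage(out_dir, "filtered.tsv", "filter")
    assigned = frame[frame["group"] != "unassigned"]
    table, _ = fit_group_model(assigned, options=options)
    table.to_csv(out_dir / "group_model.tsv", sep="\t", index=False)
    log.info("fit: %d rows; OR(D)=%s", len(assigned),
             table.loc[table["group"] == "D", "OR"].squeeze()
             if (table["group"] == "D").any() else "n/a")
    aio.write_manifest(out_dir, "fit", config, seed,
                       ["filtered.tsv"], ["group_model.tsv"])
    return table


def stage_lambda(config, seed: int, out_dir: Path) -> float:
    frame = _read_stage(out_dir, "cohort.tsv", "simulate")
    markers = _read_stage(out_dir, "markers.tsv", "simulate")
    panel = markers.drop(columns=["individual_id"])
    result = marker_panel_lambda(frame, panel)
    per = pd.DataFrame([{"marker_id": s.marker_id, "chisq": s.chisq}
                        for s in result.per_marker])
    per.to_csv(out_dir / "lambda_markers.tsv", sep="\t", index=False)
    (out_dir / "lambda.tsv").write_text(
        "lambda_median\tn_markers\n"
        f"{result.lambda_median:.6f}\t{result.n_markers}\n")
    log.info("lambda: median inflation factor %.4f over %d markers",
             result.lambda_median, result.n_markers)
    aio.write_manifest(out_dir, "lambda", config, seed,
                       ["cohort.tsv", "markers.tsv"],
                       ["lambda_markers.tsv", "lambda.tsv"])
    return result.lambda_median


def stage_endo(config, seed: int, out_dir: Path) -> None:
    frame = _read_stage(out_dir, "filtered.tsv", "filter")
    frame = frame[frame["group"].isin(list("ABCD"))]
    outputs = []
    for trait in ("logmar", "crt_um"):
        if trait not in frame.columns:
            continue
        by_group = {g: sub[trait].to_numpy()
                    for g, sub in frame.groupby("group", observed=True)}
        kw = kruskal_wallis(by_group)
        pairwise = pairwise_group_tests(by_group)
        linear = linear_trait_model(frame, trait)
        summary = pd.DataFrame(
            [{"test": "kruskal_wallis", "H": kw.H, "df": kw.df, "p": kw.p}])
        summary.to_csv(out_dir / f"endo_{trait}_kw.tsv", sep="\t", index=False)
        pairwise.to_csv(out_dir / f"endo_{trait}_pairwise.tsv", sep="\t",
                        index=False)
        linear.to_csv(out_dir / f"endo_{trait}_linear.tsv", sep="\t", index=False)
        outputs += [f"endo_{trait}_kw.tsv", f"endo_{trait}_pairwise.tsv",
                    f"endo_{trait}_linear.tsv"]
        log.info("endo: %s Kruskal-Wallis H=%.3f p=%.3g", trait, kw.H, kw.p)
    aio.write_manifest(out_dir, "endo", config, seed, ["filtered.tsv"], outputs)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "filter": stage_filter,
    "fit": stage_fit,
    "lambda": stage_lambda,
    "endo": stage_endo,
}


def run_pipeline(
    config: DiseaseModelConfig,
    seed: int,
    out_dir: str | Path,
    stage: str = "all",
    firth_options: FirthOptions | None = None,
) -> None:
    """Run one stage or the whole analysis into ``out_dir``."""
    if stage not in STAGES:
        raise StageError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = ["simulate", "classify", "filter", "fit", "lambda", "endo"] \
        if stage == "all" else [stage]
    for st in order:
        if st == "fit":
            _STAGE_FUNCS[st](config, seed, out, options=firth_options)
        else:
            _STAGE_FUNCS[st](config, seed, out)
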