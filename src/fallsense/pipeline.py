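"""End-to-end composition: simulate -> filter -> segment -> extract -> model."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd

from .config import PipelineConfig
from .config_search import named_configs, search
from .features import assemble_feature_table
from .io import write_feature_table, write_manifest
from .modeling import ABLATION_MODES, run_ablation, forward_select
from .simulate import generate_cohort

log = logging.getLogger("fallsense")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None,
                 do_train: bool = True, do_ablate: bool = False,
                 do_search: bool = False,
                 search_configs=None) -> Dict[str, object]:
    """Execute the configured stages; artifacts land in ``out_dir``.

    Fails fast with the failing stage named; every output directory gets the
    resolved config and its hash for provenance.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: Dict[str, object] = {"config_hash": config.content_hash(),
                                 "seed": config.seed, "timings_s": {}}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        bundle["timings_s"][name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, bundle["timings_s"][name])
        return result

    spec = config.cohort_spec()
    profiles, trials, annotations, clinical = stage(
        "simulate", lambda: generate_cohort(spec))
    bundle["n_subjects"] = len(profiles)
    bundle["n_trials"] = len(trials)
    clinical.to_csv(out / "clinical.csv", index=False)

    filter_spec = config.filter_spec(spec.fs_hz)
    seg_params = config.segmentation_params()
    table = stage("extract", lambda: assemble_feature_table(
        profiles, trials, filter_spec, seg_params))
    write_feature_table(table, out / "features.csv", out / "features.schema.json")
    bundle["feature_table_shape"] = list(table.shape)

    model_spec = config.model_spec()
    if do_train:
        result = stage("train", lambda: forward_select(table, model_spec))
        (out / "evaluation.json").write_text(json.dumps(result.to_dict(), indent=1))
        bundle["evaluation"] = {
            "accuracy": result.accuracy, "sensitivity": result.sensitivity,
            "specificity": result.specificity,
            "selected_features": result.selected_features,
        }
    if do_ablate:
        abl = {}
        for mode in ABLATION_MODES:
            res = stage(f"ablate:{mode}",
                        lambda m=mode: run_ablation(table, m, model_spec))
            abl[mode] = {"accuracy": res.accuracy,
                         "sensitivity": res.sensitivity,
                         "specificity": res.specificity,
                         "selected_features": res.selected_features}
        (out / "ablations.json").write_text(json.dumps(abl, indent=1))
        bundle["ablations"] = abl
    if do_search:
        configs = search_configs or named_configs(max_slots=1)
        report = stage("search", lambda: search(
            table, configs,
            max_tests=int(config.search.get("max_tests", 1)),
            spec=model_spec))
        report.to_csv(out / "search.csv", index=False)
        bundle["search_rows"] = len(report)

    write_manifest(out / "manifest.json", profiles,
                   trial_files=[],
                   extra={"config_hash": bundle["config_hash"],
                          "seed": config.seed})
    config.to_yaml(out / "config.resolved.yaml")
    (out / "run.json").write_text(json.dumps(bundle, indent=1))
    return bundle
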