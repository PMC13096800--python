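"""Config-driven orchestration of the three named analyses.

Wires the library stages into reproducible end-to-end runs:

* ``kinetics``  — glycoprotein median-centering -> max-normalization ->
  background filter -> log-time ET50 fit -> group comparisons,
* ``drug_panel`` / ``two_pulse`` differential — identification filters ->
  imputation or pseudocounting -> NB test (optionally against the
  across-condition mean reference) or moderated t -> BH adjustment ->
  abundance changes.

Every bundle carries provenance (config hash, seed, parameter echo)
sufficient to re-run bit-identically, and a structured JSON-lines log.
Differential contrasts are restricted to samples of a single processing
batch; requesting a cross-batch contrast is an error.
"""

from __future__ import annotations

import hashlib
import json
import os
import tomllib
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import differential, kinetics, preprocess
from .containers import QuantMatrix
from .io_formats import write_results

__all__ = [
    "RunConfig",
    "load_config",
    "run_kinetics_analysis",
    "run_differential_analysis",
]


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    analysis: str  # kinetics | drug_panel | two_pulse
    seed: int = 0
    matrix_path: str | None = None
    meta_path: str | None = None
    glyco_path: str | None = None
    groups: dict[str, list[str]] = field(default_factory=dict)
    filter_params: preprocess.FilterParams = field(
        default_factory=preprocess.FilterParams
    )
    impute_params: preprocess.ImputeParams | None = None
    pseudocount: float | str | None = None
    background_threshold: float = 0.5
    method: str = "nbm"  # nbm | modt
    ref_mean: bool = False
    group_a: str | None = None
    group_b: str | None = None
    conditions: list[str] = field(default_factory=list)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.analysis not in ("kinetics", "drug_panel", "two_pulse"):
            raise ValueError(f"unknown analysis {self.analysis!r}")
        for path in (self.matrix_path, self.meta_path, self.glyco_path):
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(path)

    def provenance(self) -> dict[str, Any]:
        payload = {
            "analysis": self.analysis,
            "seed": self.seed,
            "filter_params": asdict(self.filter_params),
            "impute_params": (
                None if self.impute_params is None else asdict(self.impute_params)
            ),
            "pseudocount": self.pseudocount,
            "background_threshold": self.background_threshold,
            "method": self.method,
            "ref_mean": self.ref_mean,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "conditions": self.conditions,
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return {"config_hash": digest, **payload}


def load_config(path: str | os.PathLike) -> RunConfig:
    """Load a TOML or YAML run configuration."""
    text = open(path, "rb").read()
    if str(path).endswith((".yaml", ".yml")):
        raw = yaml.safe_load(text)
    else:
        raw = tomllib.loads(text.decode())
    filt = preprocess.FilterParams(**raw.pop("filter", {}))
    imp = raw.pop("impute", None)
    impute = None if imp is None else preprocess.ImputeParams(**imp)
    return RunConfig(filter_params=filt, impute_params=impute, **raw)


class _JsonLog:
    def __init__(self) -> None:
        self.events: list[dict[str, Any]] = []

    def emit(self, stage: str, **info: Any) -> None:
        self.events.append({"stage": stage, **info})

    def dump(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for event in self.events:
                fh.write(json.dumps(event, default=str) + "\n")


def _stage(log: _JsonLog, name: str, fn, *args, **kwargs):
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        log.emit(name, error=str(exc))
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    log.emit(name, ok=True)
    return out


def run_kinetics_analysis(
    cfg: RunConfig, qm: QuantMatrix, glyco: set[str] | None = None
) -> dict[str, Any]:
    """Run the ET50 time-course analysis on a prepared matrix.

    ``glyco`` is the glycoprotein reference accession set for
    median-centering; an empty/None set falls back to all-protein centering
    with a warning in the log.
    """
    log = _JsonLog()
    log.emit("start", **cfg.provenance())
    reference = glyco if glyco else None
    if not glyco:
        log.emit("median_center", warning="empty glycoprotein list; "
                 "falling back to all-protein centering")
    centered = _stage(log, "median_center", preprocess.median_center,
                      qm, reference)
    results = _stage(log, "estimate_et50", kinetics.estimate_all,
                     centered, cfg.background_threshold)
    comparisons = []
    groups = {k: set(v) for k, v in cfg.groups.items()}
    if groups:
        comparisons = _stage(log, "compare_groups", kinetics.compare_groups,
                             results, groups)
    frame = kinetics.results_frame(results)
    bundle = {
        "results": results,
        "results_frame": frame,
        "comparisons": comparisons,
        "provenance": cfg.provenance(),
        "log": log.events,
    }
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        write_results(frame, os.path.join(cfg.out_dir, "et50_results.tsv"))
        if comparisons:
            comp_frame = pd.DataFrame([asdict(c) for c in comparisons])
            write_results(
                comp_frame, os.path.join(cfg.out_dir, "group_comparisons.tsv")
            )
        log.dump(os.path.join(cfg.out_dir, "run_log.jsonl"))
    return bundle


def _check_within_batch(qm: QuantMatrix, conditions: list[str]) -> None:
    batches = set()
    for cond in conditions:
        for i in qm.samples_for(cond):
            batches.add(qm.samples[i].batch)
    if len(batches) > 1:
        raise ValueError(
            f"contrast spans batches {sorted(batches)}; differential testing "
            "is restricted to within-batch comparisons"
        )


def run_differential_analysis(
    cfg: RunConfig, qm: QuantMatrix
) -> dict[str, Any]:
    """Run a differential-interactome contrast on a prepared matrix."""
    log = _JsonLog()
    log.emit("start", **cfg.provenance())
    if cfg.group_a is None or cfg.group_b is None:
        raise ValueError("differential analysis needs group_a and group_b")
    conditions = cfg.conditions or sorted(
        {s.condition for s in qm.samples}
    )
    if len(conditions) < 2:
        raise ValueError("differential analysis needs >= 2 conditions")
    _check_within_batch(qm, [c for c in (cfg.group_a, cfg.group_b)
                             if c != differential.MEAN_REFERENCE_CONDITION])

    filtered = _stage(log, "filter_identifications",
                      preprocess.filter_identifications, qm, cfg.filter_params)
    if cfg.method == "nbm":
        if cfg.pseudocount is not None:
            filtered = _stage(log, "add_pseudocount",
                              preprocess.add_pseudocount, filtered,
                              cfg.pseudocount)
        if cfg.impute_params is not None:
            filtered = _stage(log, "impute_missing",
                              preprocess.impute_missing, filtered,
                              cfg.impute_params)
        if cfg.ref_mean:
            filtered = _stage(log, "build_mean_reference",
                              differential.build_mean_reference, filtered,
                              conditions)
        results = _stage(log, "nbm_test", differential.nbm_test,
                         filtered, cfg.group_a, cfg.group_b)
    elif cfg.method == "modt":
        impute = cfg.impute_params or preprocess.ImputeParams(seed=cfg.seed)
        imputed = _stage(log, "impute_missing", preprocess.impute_missing,
                         filtered, impute)
        logged = imputed.with_intensities(np.log2(imputed.intensities))
        results = _stage(log, "moderated_t_test",
                         differential.moderated_t_test, logged,
                         cfg.group_a, cfg.group_b)
    else:
        raise ValueError(f"unknown differential method {cfg.method!r}")
    changes = _stage(log, "abundance_change", differential.abundance_change,
                     filtered, cfg.group_a, cfg.group_b)
    frame = differential.results_frame(results)
    bundle = {
        "results": results,
        "results_frame": frame,
        "abundance_change": changes,
        "provenance": cfg.provenance(),
        "log": log.events,
    }
    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        write_results(
            frame,
            os.path.join(
                cfg.out_dir, f"differential_{cfg.group_a}_vs_{cfg.group_b}.tsv"
            ),
        )
        write_results(changes, os.path.join(cfg.out_dir, "abundance_change.tsv"))
        log.dump(os.path.join(cfg.out_dir, "run_log.jsonl"))
    return bundle
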