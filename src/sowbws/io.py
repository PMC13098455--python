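"""Survey CSV formats, pipeline configuration, and the end-to-end run.

The response file is one wide row per respondent (matching survey-platform
exports): ``respondent_id``, the five demographic columns, then
``task_<i>_best`` / ``task_<i>_worst`` holding attribute codes, one pair per
task in the bound design.  A long-format converter is provided for
interoperability with choice-modelling tools that expect one row per task.

``run_pipeline`` ties design -> simulate (or ingest) -> count -> fit ->
subgroup fits, writing CSV outputs plus a JSON run log carrying the seed,
config hash and design hash needed to reproduce any output byte for byte.
"""

from __future__ import annotations

import csv
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    AttributeSet,
    ChoiceTask,
    NURSE_SOW_ATTRIBUTES,
    bind_attributes,
    construct_bibd,
    read_design_csv,
    write_design_csv,
)
from .cohort import (
    DEFAULT_STRATA,
    DEFAULT_UTILITIES,
    DEMOGRAPHIC_FIELDS,
    BWResponse,
    Respondent,
    SurveyDataset,
    UtilityProfile,
    simulate_choices,
    simulate_respondents,
)
from .counting import score_distribution, summarize, tally
from .clm import SubgroupSpec, fit, subgroup_table

__all__ = [
    "PipelineConfig",
    "ResponseValidationError",
    "read_responses",
    "write_responses",
    "responses_to_long",
    "run_pipeline",
]


class ResponseValidationError(ValueError):
    """Raised when a response CSV fails validation; carries itemized errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__(
            "response file failed validation:\n  " + "\n  ".join(errors)
        )


def write_responses(dataset: SurveyDataset, path) -> None:
    """Write the wide one-row-per-respondent survey CSV."""
    task_ids = [t.task_id for t in dataset.design]
    header = ["respondent_id", *DEMOGRAPHIC_FIELDS]
    for tid in task_ids:
        header += [f"task_{tid + 1}_best", f"task_{tid + 1}_worst"]
    by_resp: dict[str, dict[int, BWResponse]] = {}
    for resp in dataset.responses:
        by_resp.setdefault(resp.respondent_id, {})[resp.task_id] = resp
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for person in dataset.roster:
            row = [person.id] + [getattr(person, v) for v in DEMOGRAPHIC_FIELDS]
            for tid in task_ids:
                r = by_resp[person.id][tid]
                row += [r.best, r.worst]
            writer.writerow(row)


def read_responses(path, design: list[ChoiceTask]) -> SurveyDataset:
    """Read and validate a wide survey CSV against a bound design.

    All row-level problems (unknown codes, best == worst, picks outside the
    task, duplicate ids, missing cells) are collected and reported together
    with line numbers; nothing is loaded partially.
    """
    task_ids = [t.task_id for t in design]
    task_attrs = {t.task_id: set(t.attributes) for t in design}
    known_codes = {c for t in design for c in t.attributes}
    errors: list[str] = []
    roster: list[Respondent] = []
    responses: list[BWResponse] = []
    seen_ids: set[str] = set()

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        expected = {"respondent_id", *DEMOGRAPHIC_FIELDS}
        for tid in task_ids:
            expected |= {f"task_{tid + 1}_best", f"task_{tid + 1}_worst"}
        got = set(reader.fieldnames or [])
        if got != expected:
            missing, extra = expected - got, got - expected
            parts = []
            if missing:
                parts.append(f"missing columns {sorted(missing)}")
            if extra:
                parts.append(f"unexpected columns {sorted(extra)}")
            raise ResponseValidationError([f"header: {'; '.join(parts)}"])

        for lineno, row in enumerate(reader, start=2):
            rid = row["respondent_id"]
            if rid in seen_ids:
                errors.append(f"line {lineno}: duplicate respondent_id {rid!r}")
                continue
            seen_ids.add(rid)
            try:
                person = Respondent(
                    id=rid, **{v: row[v] for v in DEMOGRAPHIC_FIELDS}
                )
            except (TypeError, ValueError) as exc:
                errors.append(f"line {lineno}: bad demographics: {exc}")
                continue
            roster.append(person)
            for tid in task_ids:
                best = row[f"task_{tid + 1}_best"].strip()
                worst = row[f"task_{tid + 1}_worst"].strip()
                where = f"line {lineno}, task {tid + 1}"
                if not best or not worst:
                    errors.append(f"{where}: missing best/worst pick")
                    continue
                bad = [c for c in (best, worst) if c not in known_codes]
                if bad:
                    errors.append(f"{where}: unknown attribute code(s) {bad}")
                    continue
                if best == worst:
                    errors.append(f"{where}: best equals worst ({best})")
                    continue
                if best not in task_attrs[tid] or worst not in task_attrs[tid]:
                    errors.append(
                        f"{where}: picks ({best}, {worst}) outside task "
                        f"{sorted(task_attrs[tid])}"
                    )
                    continue
                responses.append(
                    BWResponse(respondent_id=rid, task_id=tid, best=best, worst=worst)
                )

    if errors:
        raise ResponseValidationError(errors)
    dataset = SurveyDataset(roster=roster, design=list(design), responses=responses)
    try:
        dataset.validate()
    except ValueError as exc:
        raise ResponseValidationError([str(exc)]) from exc
    return dataset


def responses_to_long(dataset: SurveyDataset) -> pd.DataFrame:
    """One row per (respondent, task): respondent_id, task_id, best, worst."""
    return pd.DataFrame(
        [
            {
                "respondent_id": r.respondent_id,
                "task_id": r.task_id,
                "best": r.best,
                "worst": r.worst,
            }
            for r in dataset.responses
        ]
    )


_ALLOWED_KEYS = {
    "v", "k", "lam", "design_file", "attributes", "labels", "n_respondents",
    "strata", "utilities", "seed", "mode", "reference", "subgroups",
    "responses_file", "outdir",
}


@dataclass
class PipelineConfig:
    """Validated configuration for an end-to-end run.

    Either design parameters (v, k, lam) or a ``design_file`` path; either a
    synthetic cohort (n_respondents, strata, utilities, seed) or a
    ``responses_file`` to ingest.
    """

    v: int = 7
    k: int = 3
    lam: int = 1
    design_file: str | None = None
    attributes: tuple[str, ...] = NURSE_SOW_ATTRIBUTES.codes
    labels: tuple[str, ...] = NURSE_SOW_ATTRIBUTES.labels
    n_respondents: int = 51
    strata: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_STRATA
    )
    utilities: Mapping[str, Any] = field(default_factory=lambda: dict(DEFAULT_UTILITIES))
    seed: int = 0
    mode: str = "quota"
    reference: str | None = None
    subgroups: tuple[str, ...] = DEMOGRAPHIC_FIELDS
    responses_file: str | None = None
    outdir: str = "bws_output"

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("attributes", "labels", "subgroups"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def canonical_json(self) -> str:
        payload = {
            key: getattr(self, key)
            for key in sorted(_ALLOWED_KEYS)
        }
        return json.dumps(payload, sort_keys=True, default=list)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _resolve_utilities(config: PipelineConfig, reference: str):
    """Build the utility resolver for simulate_choices from config.

    ``utilities`` is either a flat {code: value} mapping (homogeneous
    cohort) or {"variable=category": {code: value}, ...} per-stratum.
    """
    util = dict(config.utilities)
    if util and all(isinstance(v, (int, float)) for v in util.values()):
        return UtilityProfile(utilities=util, reference=reference)
    resolved: dict[tuple[str, str], UtilityProfile] = {}
    for key, vec in util.items():
        variable, _, category = key.partition("=")
        if not category:
            raise ValueError(
                f"per-stratum utility key {key!r} must look like 'variable=category'"
            )
        resolved[(variable, category)] = UtilityProfile(
            utilities=dict(vec), reference=reference
        )
    return resolved


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run design -> data -> counting -> estimation, writing all outputs.

    Returns a mapping of artifact names to written paths.  Identical config
    and seed produce byte-identical statistical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- design ---------------------------------------------------------
    if config.design_file:
        tasks = read_design_csv(config.design_file)
    else:
        design = construct_bibd(config.v, config.k, config.lam)
        attrs = AttributeSet(labels=tuple(config.labels), codes=tuple(config.attributes))
        tasks = bind_attributes(design, attrs)
    paths["design"] = outdir / "design.csv"
    write_design_csv(tasks, paths["design"])
    design_hash = hashlib.sha256(
        json.dumps([[t.task_id, *t.attributes] for t in tasks]).encode()
    ).hexdigest()[:16]

    # --- data: ingest or simulate --------------------------------------
    if config.responses_file:
        dataset = read_responses(config.responses_file, tasks)
    else:
        roster = simulate_respondents(
            config.n_respondents, config.strata, seed=config.seed, mode=config.mode
        )
        reference_for_sim = config.reference or "P"
        dataset = simulate_choices(
            roster, tasks, _resolve_utilities(config, reference_for_sim),
            seed=config.seed,
        )
    paths["responses"] = outdir / "responses.csv"
    write_responses(dataset, paths["responses"])

    # --- counting -------------------------------------------------------
    B, W, scores = tally(dataset)
    summary = summarize(
        B, W,
        n_respondents=dataset.n_respondents,
        appearances=sum(B.index[0] in t.attributes for t in dataset.design),
        attribute_codes=list(B.index),
        continuity_correction=bool((B == 0).any() or (W == 0).any()),
    )
    paths["counting"] = outdir / "counting.csv"
    summary.table.to_csv(paths["counting"])
    dist = score_distribution(scores, appearances=summary.appearances, dataset=dataset)
    paths["score_distribution"] = outdir / "score_distribution.csv"
    dist.to_long().to_csv(paths["score_distribution"], index=False)

    # --- pooled conditional logit ---------------------------------------
    clm = fit(dataset, reference=config.reference)
    paths["clm"] = outdir / "clm_fit.csv"
    clm.to_frame().to_csv(paths["clm"])
    paths["clm_stats"] = outdir / "clm_stats.csv"
    pd.Series(clm.summary_rows()).to_csv(paths["clm_stats"], header=False)

    # --- subgroup fits ---------------------------------------------------
    if config.subgroups:
        specs = [
            SubgroupSpec(
                variable=v, categories=tuple(config.strata[v])  # type: ignore[arg-type]
            )
            for v in config.subgroups
        ]
        table = subgroup_table(dataset, specs, reference=clm.reference)
        paths["subgroups"] = outdir / "subgroups.csv"
        table.to_csv(paths["subgroups"], index=False)

    # --- run log ----------------------------------------------------------
    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "design_hash": design_hash,
        "n_respondents": dataset.n_respondents,
        "n_responses": dataset.n_tasks,
        "reference": clm.reference,
        "config": json.loads(config.canonical_json()),
    }
    paths["run_log"] = outdir / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=2), encoding="utf-8")
    return paths
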