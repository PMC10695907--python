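"""End-to-end orchestration: generate/load → segment → measure → compare.

A run is described by one :class:`PipelineConfig`, read from a YAML file or
built in code.  Exactly one of two input modes is active:

* ``cohort`` — generate phantom cohorts from damage-profile presets with a
  base seed (every parameter and noise draw flows from it), or
* ``inputs`` — a manifest of volume files with per-volume seed points,
  group labels and optional observer compression scores.

Every parameter the analysis depends on (region-growing tolerance and
connectivity, structuring element, hole-fill connectivity, exact-test cap,
significance level) lives in the config, so a report is a complete audit
record: the log carries the voxel count at every morphological stage of
every specimen, and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .integrity import CompressionScores, IntegritySummary, summarize_specimen
from .morphology import se_by_name
from .phantom import PRESETS, generate_group_cohort
from .segmentation import SeedPoint, SegmentationParams, region_grow
from .stats import (FeatureSample, GroupComparison, check_set_poolability,
                    cutting_success, load_procedure_records, procedural_success)
from .volumes import read_volume

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineError",
    "run_pipeline",
    "demo_config",
    "load_config",
]

#: features compared between groups, in report order
FEATURES = ("volume_mm3", "compression_score", "inner_integrity", "outer_integrity")

SPECIMEN_COLUMNS = [
    "specimen_id", "group", "set_id", "n_seg", "n_closed", "n_filled_inner",
    "n_filled_outer", "n_smoothed", "volume_mm3", "inner_integrity",
    "outer_integrity", "compression_score",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the specimen and stage."""


@dataclass(frozen=True)
class CohortGroup:
    group: str
    preset: str
    n: int


@dataclass
class PipelineConfig:
    output_dir: str
    cohort: list[CohortGroup] | None = None
    base_seed: int = 42
    inputs: list[dict] | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    structuring_element: str = "cube27"
    background_connectivity: int = 6
    control_group: str = "CN"
    stats_method: str = "auto"
    exact_cap: int = 200_000
    alpha: float = 0.05
    set_size: int | None = 6
    procedure_records: str | None = None

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.inputs is None):
            raise ValueError(
                "config must contain exactly one of a cohort block or an "
                "input manifest")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.cohort is not None:
            for blk in self.cohort:
                if blk.preset not in PRESETS:
                    raise ValueError(f"unknown preset {blk.preset!r} for group "
                                     f"{blk.group!r}; choose from {PRESETS}")

    def echo(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


@dataclass
class RunReport:
    """Tables and decisions of one pipeline run."""

    specimens: pd.DataFrame
    comparisons: pd.DataFrame
    poolability: dict[str, bool]
    poolability_p_values: dict[str, list[float]]
    success: dict[str, dict]
    config_echo: dict
    log: list[str]


def load_config(path: str) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _config_from_dict(raw)


def _config_from_dict(raw: dict) -> PipelineConfig:
    seg = SegmentationParams(**raw.get("segmentation", {}))
    cohort = raw.get("cohort")
    if cohort is not None:
        cohort = [CohortGroup(**blk) for blk in cohort]
    stats = raw.get("stats", {})
    return PipelineConfig(
        output_dir=raw["output_dir"],
        cohort=cohort,
        base_seed=int(raw.get("base_seed", 42)),
        inputs=raw.get("inputs"),
        segmentation=seg,
        structuring_element=raw.get("structuring_element", "cube27"),
        background_connectivity=int(raw.get("background_connectivity", 6)),
        control_group=raw.get("control_group", "CN"),
        stats_method=stats.get("method", "auto"),
        exact_cap=int(stats.get("exact_cap", 200_000)),
        alpha=float(stats.get("alpha", 0.05)),
        set_size=raw.get("set_size", 6),
        procedure_records=raw.get("procedure_records"),
    )


def demo_config(output_dir: str, base_seed: int = 42) -> PipelineConfig:
    """The bundled demo: 18 B1-like + 18 B2-like + 6 control-like phantoms."""
    return PipelineConfig(
        output_dir=output_dir,
        cohort=[CohortGroup("B1", "b1_like", 18),
                CohortGroup("B2", "b2_like", 18),
                CohortGroup("CN", "cn_like", 6)],
        base_seed=base_seed,
    )


# ---------------------------------------------------------------------------


@dataclass
class _Specimen:
    specimen_id: str
    group: str
    set_id: int | None
    volume: Any
    seed: SeedPoint
    scores: CompressionScores | None


def _collect_specimens(config: PipelineConfig, log: list[str]) -> list[_Specimen]:
    specimens: list[_Specimen] = []
    if config.cohort is not None:
        for gi, blk in enumerate(config.cohort):
            group_seed = config.base_seed + 10_000 * gi
            log.append(f"generate: group {blk.group} preset {blk.preset} "
                       f"n={blk.n} base_seed={group_seed}")
            for i, cs in enumerate(generate_group_cohort(blk.preset, blk.n, group_seed)):
                set_id = (i // config.set_size) if config.set_size else None
                specimens.append(_Specimen(
                    specimen_id=f"{blk.group}-{i:03d}", group=blk.group,
                    set_id=set_id, volume=cs.volume,
                    seed=SeedPoint(*cs.seed_point),
                    scores=CompressionScores(cs.observer_scores)))
    else:
        for entry in config.inputs:  # type: ignore[union-attr]
            path = entry["path"]
            if not os.path.exists(path):
                raise PipelineError(f"input volume does not exist: {path!r}")
            vol = read_volume(path, voxel_edge_um=entry.get("voxel_edge_um"))
            seeds = entry["seeds"]
            scores = entry.get("scores")
            base = entry.get("specimen_id", os.path.splitext(os.path.basename(path))[0])
            for k, s in enumerate(seeds):
                sid = base if len(seeds) == 1 else f"{base}-{k}"
                specimens.append(_Specimen(
                    specimen_id=sid, group=entry["group"],
                    set_id=entry.get("set_id"), volume=vol,
                    seed=SeedPoint(*s),
                    scores=None if scores is None else CompressionScores(tuple(scores))))
    return specimens


def _measure(config: PipelineConfig, specimens: list[_Specimen],
             log: list[str]) -> pd.DataFrame:
    se = se_by_name(config.structuring_element)
    rows = []
    masks_by_volume: dict[int, list] = {}
    for sp in specimens:
        try:
            mask = region_grow(sp.volume, sp.seed, config.segmentation)
        except Exception as exc:
            raise PipelineError(
                f"specimen {sp.specimen_id!r}, stage segmentation: {exc}") from exc
        # specimens grown from the same volume must not overlap
        prev = masks_by_volume.setdefault(id(sp.volume), [])
        for prev_id, prev_mask in prev:
            if (mask.data & prev_mask.data).any():
                raise PipelineError(
                    f"specimen {sp.specimen_id!r}, stage segmentation: grown "
                    f"region overlaps specimen {prev_id!r}")
        prev.append((sp.specimen_id, mask))
        try:
            summary: IntegritySummary = summarize_specimen(
                mask, se=se, scores=sp.scores,
                background_connectivity=config.background_connectivity)
        except Exception as exc:
            raise PipelineError(
                f"specimen {sp.specimen_id!r}, stage integrity_metrics: {exc}") from exc
        log.append(
            f"measure: {sp.specimen_id} n_seg={summary.n_seg} "
            f"n_closed={summary.n_closed} n_filled_inner={summary.n_filled_inner} "
            f"n_filled_outer={summary.n_filled_outer} n_smoothed={summary.n_smoothed} "
            f"inner={summary.inner_integrity:.6f} outer={summary.outer_integrity:.6f}")
        rows.append({
            "specimen_id": sp.specimen_id, "group": sp.group, "set_id": sp.set_id,
            "n_seg": summary.n_seg, "n_closed": summary.n_closed,
            "n_filled_inner": summary.n_filled_inner,
            "n_filled_outer": summary.n_filled_outer,
            "n_smoothed": summary.n_smoothed, "volume_mm3": summary.volume_mm3,
            "inner_integrity": summary.inner_integrity,
            "outer_integrity": summary.outer_integrity,
            "compression_score": summary.compression_score,
        })
    return pd.DataFrame(rows, columns=SPECIMEN_COLUMNS)


def compare_groups(specimens: pd.DataFrame, control_group: str,
                   method: str = "auto", exact_cap: int = 200_000) -> pd.DataFrame:
    """Mann–Whitney comparison of every feature, each group vs the control."""
    from .stats import mann_whitney

    groups = sorted(g for g in specimens["group"].unique() if g != control_group)
    control = specimens[specimens["group"] == control_group]
    if control.empty:
        raise PipelineError(f"control group {control_group!r} has no specimens")
    rows = []
    for group in groups:
        sample = specimens[specimens["group"] == group]
        for feature in FEATURES:
            a = sample[feature].dropna()
            b = control[feature].dropna()
            if a.empty or b.empty:
                continue
            cmp_: GroupComparison = mann_whitney(a.to_numpy(), b.to_numpy(),
                                                 method=method, exact_cap=exact_cap)
            rows.append({
                "feature": feature, "group_a": group, "group_b": control_group,
                "n_a": cmp_.n_a, "n_b": cmp_.n_b, "u_statistic": cmp_.u_statistic,
                "p_two_sided": cmp_.p_two_sided, "method": cmp_.method,
                "tie_corrected": cmp_.tie_corrected,
            })
    return pd.DataFrame(rows, columns=["feature", "group_a", "group_b", "n_a",
                                       "n_b", "u_statistic", "p_two_sided",
                                       "method", "tie_corrected"])


def _poolability(config: PipelineConfig,
                 specimens: pd.DataFrame) -> tuple[dict[str, bool], dict[str, list[float]]]:
    approved: dict[str, bool] = {}
    p_values: dict[str, list[float]] = {}
    if specimens["set_id"].isna().any():
        return approved, p_values
    # only groups with at least two sets of >= 2 specimens are testable
    n_sets = specimens.groupby("group")["set_id"].nunique()
    testable = set(n_sets[n_sets >= 2].index)
    for feature in FEATURES:
        samples = []
        ok = bool(testable)
        for (group, set_id), chunk in specimens.groupby(["group", "set_id"]):
            if group not in testable:
                continue
            values = chunk[feature].dropna()
            if len(values) < 2:
                ok = False
                break
            samples.append(FeatureSample(group=str(group), set_id=int(set_id),
                                         values=tuple(values)))
        if not ok:
            continue
        decision = check_set_poolability(samples, alpha=config.alpha,
                                         method=config.stats_method,
                                         exact_cap=config.exact_cap)
        approved[feature] = decision.approved
        p_values[feature] = list(decision.p_values)
    return approved, p_values


def _write_outputs(config: PipelineConfig, report: RunReport) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    report.specimens.to_csv(os.path.join(out, "specimens.csv"), index=False)
    report.comparisons.to_csv(os.path.join(out, "comparisons.csv"), index=False)
    payload = {
        "config": report.config_echo,
        "poolability": report.poolability,
        "poolability_p_values": report.poolability_p_values,
        "success": report.success,
        "comparisons": report.comparisons.to_dict(orient="records"),
    }
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(out, "run.log"), "w") as fh:
        fh.write("\n".join(report.log) + "\n")


def run_pipeline(config: PipelineConfig, write: bool = True) -> RunReport:
    """Execute the full pipeline and (optionally) write the report files.

    Deterministic: all randomness flows from ``config.base_seed``.  Any
    stage failure raises :class:`PipelineError` naming the specimen and
    stage; the per-specimen table accumulated so far is flushed to
    ``output_dir`` before the error propagates.
    """
    log: list[str] = [f"biopsy3d {__version__}",
                      f"config: {json.dumps(config.echo(), sort_keys=True)}"]
    specimens = _collect_specimens(config, log)
    try:
        table = _measure(config, specimens, log)
    except PipelineError:
        if write:
            os.makedirs(config.output_dir, exist_ok=True)
            pd.DataFrame([], columns=SPECIMEN_COLUMNS).to_csv(
                os.path.join(config.output_dir, "specimens.csv"), index=False)
        raise
    comparisons = compare_groups(table, config.control_group,
                                 method=config.stats_method,
                                 exact_cap=config.exact_cap)
    for row in comparisons.itertuples():
        log.append(f"compare: {row.feature} {row.group_a} vs {row.group_b} "
                   f"U={row.u_statistic} p={row.p_two_sided:.6g} ({row.method})")
    poolability, pool_p = _poolability(config, table)
    success: dict[str, dict] = {}
    if config.procedure_records:
        records = load_procedure_records(config.procedure_records)
        success["cutting_success"] = {
            b: {"mean_pct": s.mean_pct, "sd_pct": s.sd_pct, "n_animals": s.n_animals}
            for b, s in cutting_success(records).items()}
        success["procedural_success"] = procedural_success(records)
    report = RunReport(specimens=table, comparisons=comparisons,
                       poolability=poolability, poolability_p_values=pool_p,
                       success=success, config_echo=config.echo(), log=log)
    if write:
        _write_outputs(config, report)
    return report
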