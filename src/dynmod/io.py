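"""Delimited-text readers/writers, pipeline configuration and the end-to-end run.

All artifacts are plain delimited text (tab by default, comma accepted on
input) or JSON, chosen so that every output table can be re-read by the
readers in this module.  ``run_pipeline`` ties the stages together:
windowed graphs -> per-window partitions (and optional nulls) -> dwell-time
profiles -> co-assignment/meta-modules -> sub-network dwell and group
comparison, with every seed echoed into the run log.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import atlas
from .dynamics import (
    DwellTimeProfile,
    coassignment,
    meta_modules,
    modular_dwell_time,
    module_count_series,
)
from .group_stats import compare_groups, subnetwork_dwell_time
from .signed_modularity import Partition, detect_modules, null_model, qstar
from .synthetic_bold import RoiTimeSeries, SwitchingGroundTruth
from .windows import WindowConfig, dynamic_graphs
from .window_selection import qstar_variance_curve, select_window

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "write_graphs",
    "write_partitions",
    "read_partitions",
    "write_dwell_profiles",
    "read_dwell_profiles",
    "write_matrix",
    "read_matrix",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Time series and manifests
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_timeseries(path: str | Path, tr_seconds: float = 3.0, subject_id: str | None = None) -> RoiTimeSeries:
    """Read a volumes x regions block with a header row of region ids.

    The delimiter (tab or comma) is auto-detected.  Ragged rows, non-numeric
    cells and duplicate region ids raise a parse error naming the offending
    line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    region_ids = [c.strip() for c in lines[0].split(sep)]
    if len(set(region_ids)) != len(region_ids):
        dupes = sorted({r for r in region_ids if region_ids.count(r) > 1})
        raise ValueError(f"{path}, line 1: duplicate region ids {dupes}")
    n = len(region_ids)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(sep)
        if len(cells) != n:
            raise ValueError(f"{path}, line {lineno}: expected {n} columns, found {len(cells)}")
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: non-numeric cell ({exc})") from None
    return RoiTimeSeries(
        data=np.asarray(rows),
        tr_seconds=tr_seconds,
        region_ids=region_ids,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    """Write a series as tab-delimited text: header of region ids, one row per volume."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(ts.region_ids) + "\n")
        for row in ts.data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def write_manifest(rows: Sequence[tuple], path: str | Path) -> None:
    """Write a cohort manifest: subject_id, group, file path (tab-delimited)."""
    df = pd.DataFrame(rows, columns=["subject_id", "group", "path"])
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: manifest must have columns {sorted(required)}")
    if df.empty:
        raise ValueError(f"{path}: manifest is empty")
    return df


# ---------------------------------------------------------------------------
# Graphs, partitions, profiles, matrices
# ---------------------------------------------------------------------------

def write_graphs(dyn, path: str | Path) -> None:
    """One tab-delimited N x N block per window, preceded by a window header line."""
    with Path(path).open("w") as fh:
        for g in dyn.graphs:
            fh.write(f"# window {g.window_index} center {g.center_volume}\n")
            for row in g.weights:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def write_graphs_long(dyn, path: str | Path) -> None:
    """Flattened long-format edge table: window, i, j, weight (upper triangle)."""
    records = []
    for g in dyn.graphs:
        iu, ju = np.triu_indices(g.n_nodes, 1)
        for i, j in zip(iu, ju):
            records.append((g.window_index, int(i), int(j), g.weights[i, j]))
    pd.DataFrame(records, columns=["window", "i", "j", "weight"]).to_csv(path, sep="\t", index=False)


def write_partitions(rows: Sequence[tuple], path: str | Path) -> None:
    """Per-node module labels: subject, window, node, label (tab-delimited)."""
    pd.DataFrame(rows, columns=["subject", "window", "node", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_partitions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summary(rows: Sequence[dict], path: str | Path) -> None:
    """Per-window summary: subject, window, n_modules, qstar (and null_qstar if computed)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dwell_profiles(profiles: Sequence[DwellTimeProfile], path: str | Path) -> None:
    rows = [
        (p.subject_id, key, pct)
        for p in profiles
        for key, pct in sorted(p.percentages.items(), key=lambda kv: str(kv[0]))
    ]
    pd.DataFrame(rows, columns=["subject", "key", "percentage"]).to_csv(path, sep="\t", index=False)


def read_dwell_profiles(path: str | Path) -> list:
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for subject, sub in df.groupby("subject", sort=False):
        pct = {}
        for _, row in sub.iterrows():
            key = row["key"]
            try:
                key = int(key)
            except (TypeError, ValueError):
                key = str(key)
            pct[key] = float(row["percentage"])
        profiles.append(DwellTimeProfile(subject_id=str(subject), percentages=pct))
    return profiles


def write_variance_curve(curve, path: str | Path) -> None:
    """Q*-variance scan as a table: length, sd_qstar, relative_pct."""
    pd.DataFrame(
        {
            "length": curve.window_lengths,
            "sd_qstar": curve.sd_qstar,
            "relative_pct": curve.relative_variance_pct,
        }
    ).to_csv(path, sep="\t", index=False)


def write_module_count_curve(curve, path: str | Path) -> None:
    """Module-count proportions as a long table: length, count, proportion."""
    rows = [
        (length, count, prop)
        for length in curve.window_lengths
        for count, prop in sorted(curve.proportions[length].items())
    ]
    pd.DataFrame(rows, columns=["length", "count", "proportion"]).to_csv(
        path, sep="\t", index=False
    )


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(matrix)).to_csv(path, sep="\t", index=False, header=False)


def read_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Knobs for the end-to-end run; "auto" window length triggers selection."""

    window_length: int | str = "auto"
    stride: int = 1
    n_restarts: int = 10
    null_passes: int = 10
    compute_nulls: bool = False
    seed: int = 0
    weight_mode: str = "signed"  # z-scores on signed or positive-only weights
    strict_variance: bool = True
    meta_k: int = 5
    variance_cutoff_pct: float = 10.0
    scan_lengths: list = field(default_factory=list)  # empty -> odd 9..T/2
    tr_seconds: float = 3.0
    max_failure_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.window_length != "auto":
            self.window_length = int(self.window_length)
            if self.window_length < 1 or self.window_length % 2 == 0:
                raise ValueError("window_length must be 'auto' or an odd positive integer")
        for name in ("stride", "n_restarts", "null_passes", "meta_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.weight_mode not in ("signed", "positive"):
            raise ValueError("weight_mode must be 'signed' or 'positive'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run computed."""

    selected_window: int
    partitions: dict  # subject -> list[Partition]
    dwell_profiles: list
    subnetwork_profiles: list
    meta_assignment: object
    comparisons: dict  # subnetwork name -> GroupComparisonResult
    summary_rows: list
    run_log: dict


def _load_cohort(manifest: pd.DataFrame, base_dir: Path, tr_seconds: float) -> list:
    cohort = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base_dir / p
        ts = read_timeseries(p, tr_seconds=tr_seconds, subject_id=str(row["subject_id"]))
        cohort.append((ts, str(row["group"])))
    return cohort


def run_pipeline(
    manifest_path: str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis over a cohort manifest.

    Identical (manifest, config) input gives identical outputs.  Per-subject
    failures are logged; the run aborts if their fraction exceeds
    ``config.max_failure_fraction``.
    """
    config = config or PipelineConfig()
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    cohort = _load_cohort(manifest, manifest_path.parent, config.tr_seconds)
    T = cohort[0][0].n_volumes
    n_nodes = cohort[0][0].n_regions
    for ts, _ in cohort:
        if ts.n_regions != n_nodes:
            raise ValueError(f"subject {ts.subject_id}: region count {ts.n_regions} != {n_nodes}")

    rng = np.random.default_rng(config.seed)
    if config.window_length == "auto":
        lengths = config.scan_lengths or list(range(9, T // 2 + 1, 2))
        curve = qstar_variance_curve(
            [ts for ts, _ in cohort], lengths, seed=config.seed, n_restarts=config.n_restarts
        )
        L = select_window(curve, cutoff_pct=config.variance_cutoff_pct)
    else:
        L = int(config.window_length)
    wconfig = WindowConfig(length_volumes=L, stride_volumes=config.stride)

    partitions: dict = {}
    dwell_profiles = []
    subnet_profiles = []
    summary_rows = []
    groups: dict = {}
    failures = []
    subnets = atlas.dmn_subnetworks() if n_nodes == 68 else []
    fixed = atlas.final_assignment() if n_nodes == 68 else None
    for ts, group in cohort:
        try:
            dyn = dynamic_graphs(ts, wconfig, strict=config.strict_variance)
            parts = []
            for g in dyn.graphs:
                part = detect_modules(g, n_restarts=config.n_restarts, seed=rng)
                parts.append(part)
                row = {
                    "subject": ts.subject_id,
                    "window": g.window_index,
                    "n_modules": part.n_modules,
                    "qstar": part.qstar,
                }
                if config.compute_nulls:
                    nm = null_model(g, seed=rng, n_passes=config.null_passes)
                    row["null_qstar"] = detect_modules(
                        nm, n_restarts=config.n_restarts, seed=rng
                    ).qstar
                summary_rows.append(row)
            partitions[ts.subject_id] = parts
            dwell_profiles.append(
                modular_dwell_time(module_count_series(parts), subject_id=ts.subject_id)
            )
            if fixed is not None:
                prof = subnetwork_dwell_time(dyn, fixed, subnets, weight_mode=config.weight_mode)
                subnet_profiles.append(prof)
                groups.setdefault(group, []).append(prof)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation is the contract
            logger.error("subject %s failed: %s", ts.subject_id, exc)
            failures.append((ts.subject_id, str(exc)))
    if failures and len(failures) / len(cohort) > config.max_failure_fraction:
        raise RuntimeError(f"{len(failures)}/{len(cohort)} subjects failed: {failures}")

    pooled = [p for parts in partitions.values() for p in parts]
    coassign = coassignment(pooled)
    meta = meta_modules(coassign, k=min(config.meta_k, n_nodes))

    comparisons = {}
    if len(groups) == 2 and all(len(v) >= 2 for v in groups.values()):
        ga, gb = sorted(groups)
        for subnet in subnets:
            va = [p.percentages[subnet.name] for p in groups[ga]]
            vb = [p.percentages[subnet.name] for p in groups[gb]]
            comparisons[subnet.name] = compare_groups(va, vb, labels=(ga, gb))

    run_log = {
        "config": config.to_dict(),
        "selected_window": L,
        "n_subjects": len(cohort),
        "n_windows_per_subject": (T - L) // config.stride + 1,
        "failures": failures,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    result = PipelineResult(
        selected_window=L,
        partitions=partitions,
        dwell_profiles=dwell_profiles,
        subnetwork_profiles=subnet_profiles,
        meta_assignment=meta,
        comparisons=comparisons,
        summary_rows=summary_rows,
        run_log=run_log,
    )
    if outdir is not None:
        _write_outputs(result, coassign, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, coassign, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    part_rows = [
        (subject, w, node, int(lab))
        for subject, parts in sorted(result.partitions.items())
        for w, part in enumerate(parts)
        for node, lab in enumerate(part.labels)
    ]
    write_partitions(part_rows, outdir / "partitions.tsv")
    write_summary(result.summary_rows, outdir / "window_summary.tsv")
    write_dwell_profiles(result.dwell_profiles, outdir / "modular_dwell.tsv")
    if result.subnetwork_profiles:
        write_dwell_profiles(result.subnetwork_profiles, outdir / "subnetwork_dwell.tsv")
    write_matrix(coassign.frequencies, outdir / "coassignment.tsv")
    pd.DataFrame(
        {"node": np.arange(1, result.meta_assignment.labels.size + 1),
         "meta_module": result.meta_assignment.labels}
    ).to_csv(outdir / "meta_modules.tsv", sep="\t", index=False)
    if result.comparisons:
        rows = []
        for name, res in result.comparisons.items():
            row = {"metric": f"{name} dwell time", "p_value": res.p_value, "test": res.test_name}
            for label, (med, q1, q3) in res.group_medians_iqr.items():
                row[f"{label}_median"] = med
                row[f"{label}_q1"] = q1
                row[f"{label}_q3"] = q3
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "group_comparison.tsv", sep="\t", index=False)
    (outdir / "run_log.json").write_text(json.dumps(result.run_log, indent=1))
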