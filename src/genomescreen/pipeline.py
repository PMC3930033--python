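"""End-to-end screen: sampling → alignment → assignment → adapter → report.

One in-process pipeline per run; datasets are screened independently, so
one dataset's failure is reported without aborting the others (unless
strict mode is requested). A run log records versions, seed, and the
effective parameter set so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import sys
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .adapter_screen import AlignmentScoring, screen_adapters
from .assignment import assign_reads, make_role_map, rank_units, summarize
from .panel import PanelError, ReferencePanel, load_adapters, load_panel
from .report import control_check, render_report
from .sampling import SamplingPlan, mean_quality, sample_fastq
from .species_align import DEFAULT_MAX_MISMATCHES, align_sample


@dataclass(frozen=True)
class DatasetConfig:
    dataset_id: str
    fastq: tuple[str, ...]
    target: str | None = None
    expected_control_fraction: float | None = None


@dataclass
class ScreenConfig:
    """Everything one screen run needs."""

    panel_config: str
    adapter_fasta: str
    datasets: list[DatasetConfig]
    plan: SamplingPlan = field(default_factory=SamplingPlan)
    max_mismatches: int = DEFAULT_MAX_MISMATCHES
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    out_dir: str = "mga_report"
    strict: bool = False
    seed_k: int = 12

    def __post_init__(self):
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("dataset ids must be unique")
        if not self.datasets:
            raise ValueError("no datasets configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        path = Path(path)
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        base = path.parent

        def resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        datasets = [
            DatasetConfig(
                dataset_id=str(d["id"]),
                fastq=tuple(resolve(f) for f in d["fastq"]),
                target=d.get("target"),
                expected_control_fraction=d.get("expected_control_fraction"),
            )
            for d in raw.get("datasets", [])
        ]
        plan = SamplingPlan(
            sample_size=raw.get("sample_size", 100_000),
            trim_length=raw.get("trim_length", 36),
            seed=raw.get("seed", 0),
        )
        return cls(
            panel_config=resolve(raw["panel"]),
            adapter_fasta=resolve(raw["adapters"]),
            datasets=datasets,
            plan=plan,
            max_mismatches=raw.get("max_mismatches", DEFAULT_MAX_MISMATCHES),
            out_dir=raw.get("out_dir", "mga_report"),
        )


def screen_dataset(
    dataset: DatasetConfig,
    panel: ReferencePanel,
    adapters,
    plan: SamplingPlan,
    max_mismatches: int,
    scoring: AlignmentScoring,
):
    """Run the full screen for a single dataset, returning its summary."""
    reads = sample_fastq(dataset.fastq, plan, dataset_id=dataset.dataset_id)
    alignment_set = align_sample(reads, panel, max_mismatches)
    ranking = rank_units(
        alignment_set,
        target_units={dataset.target} if dataset.target else None,
    )
    assignments = assign_reads(alignment_set, ranking)
    roles = make_role_map(
        sorted(panel.units), dataset.target, panel.control_units
    )
    summary = summarize(
        alignment_set,
        assignments,
        roles,
        expected_control_fraction=dataset.expected_control_fraction,
        mean_quality=mean_quality(reads),
        trim_length=plan.trim_length,
    )
    hits = screen_adapters(reads, adapters, scoring)
    summary.adapter_count = len(hits)
    return summary


def run_screen(config: ScreenConfig) -> int:
    """Execute the screen for every configured dataset and render the
    report. Returns a process exit status (nonzero when any dataset
    failed and strict mode is on, or when every dataset failed)."""
    panel = load_panel(config.panel_config)
    panel.build_indexes(config.seed_k)
    adapters = load_adapters(config.adapter_fasta)
    summaries = []
    failures: dict[str, str] = {}
    for dataset in config.datasets:
        try:
            summaries.append(
                screen_dataset(
                    dataset, panel, adapters, config.plan,
                    config.max_mismatches, config.scoring,
                )
            )
        except Exception as exc:  # per-dataset independence
            failures[dataset.dataset_id] = str(exc)
            if config.strict:
                print(
                    f"error: dataset {dataset.dataset_id!r} failed: {exc}",
                    file=sys.stderr,
                )
                return 1
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.plan.seed,
        "sample_size": config.plan.sample_size,
        "trim_length": config.plan.trim_length,
        "max_mismatches": config.max_mismatches,
        "seed_k": config.seed_k,
        "scoring": asdict(config.scoring),
        "datasets": [d.dataset_id for d in config.datasets],
        "failures": failures,
        "control_checks": {s.dataset_id: control_check(s) for s in summaries},
    }
    (out_dir / "mga_run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    if summaries:
        render_report(summaries, out_dir)
    if failures:
        for dataset_id, msg in failures.items():
            print(f"warning: dataset {dataset_id!r} failed: {msg}",
                  file=sys.stderr)
        if not summaries:
            return 1
    return 0
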