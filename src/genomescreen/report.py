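"""Tabular and graphical screen reports.

Each dataset (lane) becomes one stacked bar whose segments are the reads
assigned to each reporting unit, colored by role — green for the target
species, orange for the spike-in control, red for any other species —
with a grey segment for unmapped reads. Segment opacity decreases with
the unit's mismatch rate, so confident (low-error) contamination stands
out as a solid red block. Adapter contamination overlaps with species
counts, so it is drawn as a separate thin mauve companion bar.
"""

from __future__ import annotations

import base64
import io
import string
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .assignment import ROLE_CONTROL, ROLE_TARGET, DatasetSummary

COLOR_CLASSES = {
    ROLE_TARGET: "green",
    ROLE_CONTROL: "orange",
    "other": "red",
    "adapter": "mauve",
    "unmapped": "grey",
}
_RGB = {
    "green": (0.18, 0.62, 0.25),
    "orange": (0.95, 0.60, 0.10),
    "red": (0.80, 0.15, 0.15),
    "mauve": (0.72, 0.47, 0.70),
    "grey": (0.55, 0.55, 0.55),
}
MIN_OPACITY = 0.25

TABLE_COLUMNS = [
    "dataset", "unit", "role", "aligned", "assigned", "pct_assigned",
    "error_rate", "adapter_count", "pct_adapter", "unmapped",
]

CONTROL_OK = "ok"
CONTROL_LOW_YIELD_SAMPLE = "low_yield_sample_issue"
CONTROL_LOW_YIELD_SEQUENCING = "low_yield_sequencing_issue"
CONTROL_UNEXPECTED = "unexpected_control"


@dataclass(frozen=True)
class BarSegment:
    """One portion of a dataset's report bar."""

    dataset_id: str
    unit_id: str
    height: int
    color_class: str
    opacity: float


def _opacity(error_rate: float, ceiling: float) -> float:
    """Linear fade with mismatch rate, floored so segments never vanish."""
    if ceiling <= 0:
        return 1.0
    return max(MIN_OPACITY, 1.0 - error_rate / ceiling)


def build_segments(summary: DatasetSummary) -> list[BarSegment]:
    """Segments for one dataset: assigned units in descending-count order,
    then unmapped; adapter last, as the separate companion bar."""
    ceiling = summary.max_mismatches / summary.trim_length
    segments = []
    units = [u for u in summary.unit_summaries if u.assigned_count > 0]
    units.sort(key=lambda u: (-u.assigned_count, u.unit_id))
    for u in units:
        segments.append(
            BarSegment(
                dataset_id=summary.dataset_id,
                unit_id=u.unit_id,
                height=u.assigned_count,
                color_class=COLOR_CLASSES[u.role],
                opacity=_opacity(u.assigned_error_rate, ceiling),
            )
        )
    segments.append(
        BarSegment(summary.dataset_id, "unmapped", summary.unmapped_count,
                   "grey", 1.0)
    )
    segments.append(
        BarSegment(summary.dataset_id, "adapter", summary.adapter_count,
                   "mauve", 1.0)
    )
    return segments


def summary_table(summaries: list[DatasetSummary]) -> pd.DataFrame:
    """Per-dataset, per-unit summary with the fixed documented columns."""
    rows = []
    for s in summaries:
        for u in s.unit_summaries:
            rows.append({
                "dataset": s.dataset_id,
                "unit": u.unit_id,
                "role": u.role,
                "aligned": u.aligned_count,
                "assigned": u.assigned_count,
                "pct_assigned": round(100.0 * u.assigned_count / s.sampled_count, 4),
                "error_rate": round(u.assigned_error_rate, 6),
                "adapter_count": s.adapter_count,
                "pct_adapter": round(100.0 * s.adapter_fraction, 4),
                "unmapped": s.unmapped_count,
            })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def control_check(
    summary: DatasetSummary,
    relative_tolerance: float = 0.5,
    low_yield_threshold: float = 0.5,
) -> str:
    """Compare observed vs expected spike-in control fraction.

    An unbalanced control loading scheme (e.g. 1% in most lanes, 5% in
    one) lets the control percentage diagnose low yield: if the control
    fraction is as expected, low yield points to clustering/sequencing;
    if it is off, to library quantification on the sample side. A lane
    is considered low-yield when the target's assigned fraction falls
    below ``low_yield_threshold``. Without an expectation the check
    returns ok.
    """
    expected = summary.expected_control_fraction
    if expected is None:
        return CONTROL_OK
    observed = summary.control_fraction
    in_band = abs(observed - expected) <= relative_tolerance * expected
    low_yield = summary.target_fraction < low_yield_threshold
    if in_band:
        return CONTROL_LOW_YIELD_SEQUENCING if low_yield else CONTROL_OK
    return CONTROL_LOW_YIELD_SAMPLE if low_yield else CONTROL_UNEXPECTED


def plot_chart(summaries: list[DatasetSummary], path: str | Path) -> None:
    """Stacked bar chart, one main bar plus a thin adapter bar per lane."""
    fig, ax = plt.subplots(figsize=(max(6, 1.6 * len(summaries)), 5))
    main_width, adapter_width = 0.55, 0.15
    for x, s in enumerate(summaries):
        bottom = 0
        for seg in build_segments(s):
            color = _RGB[seg.color_class] + (seg.opacity,)
            if seg.unit_id == "adapter":
                ax.bar(x + (main_width + adapter_width) / 2 + 0.05, seg.height,
                       width=adapter_width, color=color)
            else:
                ax.bar(x, seg.height, width=main_width, bottom=bottom,
                       color=color)
                bottom += seg.height
    ax.set_xticks(range(len(summaries)))
    ax.set_xticklabels([s.dataset_id for s in summaries], rotation=30, ha="right")
    ax.set_ylabel("sampled reads")
    ax.set_title("Multi-genome alignment contamination screen")
    handles = [plt.Rectangle((0, 0), 1, 1, color=_RGB[c]) for c in
               ("green", "orange", "red", "grey", "mauve")]
    ax.legend(handles, ["target", "control", "other species", "unmapped",
                        "adapter"], loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


_HTML_TEMPLATE = string.Template("""<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>Contamination screen report</title>
<style>
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; font-size: 0.85em; }
th, td { border: 1px solid #999; padding: 3px 8px; text-align: right; }
th { background: #eee; }
td.text { text-align: left; }
</style></head>
<body>
<h1>Multi-genome alignment contamination screen</h1>
<img src="data:image/png;base64,$chart" alt="stacked bar chart"/>
<h2>Per-dataset summary</h2>
$table
<h2>Control checks</h2>
$controls
</body></html>
""")


def render_report(summaries: list[DatasetSummary], out_dir: str | Path) -> dict:
    """Write the chart (PNG), the TSV summary table, and a self-contained
    HTML page embedding both. Deterministic for fixed input (the TSV is
    byte-identical across re-renders)."""
    if not summaries:
        raise ValueError("no datasets to report")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}")
    chart_path = out_dir / "mga_chart.png"
    table_path = out_dir / "mga_summary.tsv"
    html_path = out_dir / "mga_report.html"
    plot_chart(summaries, chart_path)
    table = summary_table(summaries)
    table.to_csv(table_path, sep="\t", index=False)
    rows = []
    for s in summaries:
        status = control_check(s)
        expected = (
            "-" if s.expected_control_fraction is None
            else f"{100 * s.expected_control_fraction:.2f}%"
        )
        rows.append(
            f"<tr><td class='text'>{s.dataset_id}</td><td>{expected}</td>"
            f"<td>{100 * s.control_fraction:.2f}%</td>"
            f"<td class='text'>{status}</td></tr>"
        )
    controls_html = (
        "<table><tr><th>dataset</th><th>expected control</th>"
        "<th>observed control</th><th>status</th></tr>" + "".join(rows) + "</table>"
    )
    chart_b64 = base64.b64encode(chart_path.read_bytes()).decode("ascii")
    html = _HTML_TEMPLATE.substitute(
        chart=chart_b64,
        table=table.to_html(index=False, border=0),
        controls=controls_html,
    )
    html_path.write_text(html)
    return {"chart": chart_path, "table": table_path, "html": html_path}
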