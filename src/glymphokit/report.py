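"""Report assembly: collect stage outputs into one deterministic bundle.

The pipeline stages (volumetry, diffusion, DCE, T1/phantom, group statistics)
each write CSV/JSON tables into their own directory; :func:`build_report`
gathers whatever is present into a Markdown report plus a JSON summary.
Missing stages are listed explicitly and never abort the report.  Output is
byte-identical across re-runs on the same inputs (no timestamps).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

STAGES = ("volumetry", "diffusion", "dce", "t1_phantom", "group_stats")


def build_report(config: dict) -> dict:
    """Assemble per-stage tables into ``<out>/report.md`` and ``report.json``.

    ``config`` needs ``stages_dir`` (root containing one subdirectory per
    stage) and ``out``.  Returns the summary dict.  Stage outputs are read
    only, never mutated.
    """
    stages_dir = Path(config["stages_dir"])
    out_dir = Path(config["out"])
    out_dir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"stages": {}, "missing": []}
    lines = ["# Glymphatic MRI pipeline report", ""]
    for stage in STAGES:
        sdir = stages_dir / stage
        if not sdir.is_dir():
            summary["missing"].append(stage)
            continue
        tables = {}
        for f in sorted(sdir.glob("*.csv")):
            tables[f.stem] = pd.read_csv(f)
        blobs = {}
        for f in sorted(sdir.glob("*.json")):
            blobs[f.stem] = json.loads(f.read_text())
        summary["stages"][stage] = {
            "tables": {k: v.to_dict(orient="list") for k, v in tables.items()},
            "json": blobs,
        }
        lines.append(f"## {stage}")
        lines.append("")
        for name, df in tables.items():
            lines.append(f"### {name}")
            lines.append("")
            lines.append("```")
            lines.append(df.to_string(index=False))
            lines.append("```")
            lines.append("")
        for name, blob in blobs.items():
            lines.append(f"### {name}")
            lines.append("")
            lines.append("```json")
            lines.append(json.dumps(blob, indent=2, sort_keys=True))
            lines.append("```")
            lines.append("")
    if summary["missing"]:
        lines.append("## Missing stages")
        lines.append("")
        for stage in summary["missing"]:
            lines.append(f"- {stage}: no output directory found")
        lines.append("")

    (out_dir / "report.md").write_text("\n".join(lines))
    (out_dir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
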