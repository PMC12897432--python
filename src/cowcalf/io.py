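"""Structured output writing: per-year tables, scenario summaries, the
marginal-mean tables, and a machine-readable run manifest.

All tables are comma-delimited UTF-8 with a header row and period decimal
separator; the manifest is JSON (full configuration plus seeds), which
together are sufficient to reproduce a run bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from .config import SimulationConfig
from .engine import StackResult
from .experiment import make_tables, summarize_scenarios

__all__ = ["write_outputs", "read_manifest"]


def write_outputs(result: StackResult, out_dir: str | Path,
                  config: SimulationConfig,
                  base_seed: Optional[int] = None) -> dict:
    """Write the standard output file set for a run; returns written paths.

    Files: ``per_year.csv`` (one row per scenario x replicate x production
    year), ``scenario_summary.csv`` (one row per genotype x DMI level),
    ``table_repro_by_genotype.csv`` / ``table_repro_by_level.csv`` /
    ``table_progeny.csv`` (marginal-mean tables), ``events.csv`` and
    ``manifest.json``.
    """
    if result.per_year.empty:
        raise ValueError("no results to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    per_year = result.per_year
    paths["per_year"] = out / "per_year.csv"
    per_year.to_csv(paths["per_year"], index=False)

    summary = summarize_scenarios(per_year, config)
    paths["scenario_summary"] = out / "scenario_summary.csv"
    summary.to_csv(paths["scenario_summary"], index=False)

    tables = make_tables(summary)
    for name, df in tables.items():
        key = {"by_genotype": "table_repro_by_genotype",
               "by_level": "table_repro_by_level",
               "progeny": "table_progeny"}[name]
        paths[key] = out / f"{key}.csv"
        df.to_csv(paths[key], index=False)

    paths["events"] = out / "events.csv"
    result.events.to_csv(paths["events"], index=False)

    manifest = {
        "config": config.model_dump(mode="json"),
        "base_seed": config.rng_seed if base_seed is None else base_seed,
        "n_herds": int(result.entrants.size),
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    mpath = out / "manifest.json"
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = mpath
    return paths


def read_manifest(out_dir: str | Path) -> dict:
    with open(Path(out_dir) / "manifest.json", "r", encoding="utf-8") as fh:
        return json.load(fh)
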