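"""Result serialization: delimited summary tables and run metadata."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .economics import CEResult, FrontierResult, incremental

__all__ = ["format_percent", "summary_table", "write_results"]


def format_percent(fraction: float) -> str:
    """Render a rate at the published precision: integers at or above 10%,
    one decimal below."""
    pct = 100.0 * fraction
    if pct >= 10.0:
        return f"{pct:.0f}"
    return f"{pct:.1f}"


def summary_table(
    results: dict[int, CEResult],
    frontier: FrontierResult | None = None,
    comparator_id: int = 1,
) -> pd.DataFrame:
    """Per-pathway summary mirroring the headline results layout."""
    inc = incremental(results, comparator_id=comparator_id)
    rows = []
    for pid in sorted(results):
        r = results[pid]
        dq, dc = inc[pid]
        icer_txt = ""
        if frontier is not None:
            if pid in frontier.dominated:
                icer_txt = "D"
            elif pid in frontier.extendedly_dominated:
                icer_txt = "ED"
            elif pid in frontier.icers:
                comp, icer = frontier.icers[pid]
                icer_txt = f"{icer:,.0f} (vs P{comp})"
        rows.append(
            {
                "pathway": pid,
                "detection_pct": format_percent(r.detection_rate or 0.0),
                "referral_pct": format_percent(r.referral_rate),
                "dqaly_per_1000": round(dq, 2) if pid != comparator_id else "",
                "dcost_per_1000": round(dc, 0) if pid != comparator_id else "",
                "icer": icer_txt,
                "qalys_per_1000": r.qalys_per_1000,
                "costs_per_1000": r.costs_per_1000,
            }
        )
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(
    results: dict[int, CEResult],
    frontier: FrontierResult | None,
    out_dir: str | Path,
    config: RunConfig | None = None,
    ceac_table: pd.DataFrame | None = None,
    sweep_table: pd.DataFrame | None = None,
    label: str = "base_case",
) -> dict[str, Path]:
    """Write delimited result tables plus a run-metadata file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary = summary_table(results, frontier)
    paths["summary"] = out / f"{label}_summary.tsv"
    summary.to_csv(paths["summary"], sep="\t", index=False)

    breakdown = pd.DataFrame(
        [{"pathway": pid, **results[pid].cost_breakdown} for pid in sorted(results)]
    )
    paths["cost_breakdown"] = out / f"{label}_cost_breakdown.tsv"
    breakdown.to_csv(paths["cost_breakdown"], sep="\t", index=False)

    if ceac_table is not None:
        paths["ceac"] = out / f"{label}_ceac.tsv"
        ceac_table.to_csv(paths["ceac"], sep="\t", index=False)
    if sweep_table is not None:
        paths["sweep"] = out / f"{label}_threshold_sweep.tsv"
        sweep_table.to_csv(paths["sweep"], sep="\t", index=False)

    config = config or RunConfig()
    meta = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": asdict(config),
    }
    paths["metadata"] = out / f"{label}_metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths
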