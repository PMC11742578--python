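"""Report assembly: CSV/JSON artifacts, plots, and run manifests."""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .cea import CEAResult
from .config import ModelConfig, config_to_json
from .engine import StrategyOutcome
from .sensitivity import PSAResult, TornadoEntry, ceac, tornado_to_dataframe

__all__ = [
    "config_hash",
    "write_manifest",
    "write_base_case_report",
    "write_traces",
    "write_tornado",
    "write_psa",
]


def config_hash(config: ModelConfig) -> str:
    """Deterministic hash of the full parameter set (order-stable JSON)."""
    canonical = json.dumps(json.loads(config_to_json(config)), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(
    out_dir: Path,
    command: str,
    config: ModelConfig,
    outputs: Sequence[Path],
    seed: Optional[int] = None,
) -> Path:
    """Record what was run, from which inputs, and what it produced."""
    manifest = {
        "command": command,
        "config_hash": config_hash(config),
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "currency_note": (
            f"costs in USD at a fixed rate of {config.settings.irr_per_usd:,.0f} IRR/USD"
        ),
        "outputs": sorted(str(p.relative_to(out_dir)) for p in outputs),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def write_base_case_report(out_dir: Path, result: CEAResult) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "cea_results.csv"
    result.to_dataframe().to_csv(csv_path, index=False)
    json_path = out_dir / "cea_results.json"
    payload = {
        "intervention": result.intervention,
        "comparator": result.comparator,
        "cost": result.cost,
        "qalys": result.qalys,
        "incremental_cost": result.incremental_cost,
        "incremental_qalys": result.incremental_qalys,
        "icer": result.icer,
        "dominance": result.dominance,
        "wtp": result.wtp,
        "nmb": result.nmb,
    }
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    return [csv_path, json_path]


def write_traces(out_dir: Path, outcomes: Sequence[StrategyOutcome]) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for outcome in outcomes:
        path = out_dir / f"trace_{outcome.strategy}.csv"
        outcome.trace.to_dataframe().to_csv(path, index=False)
        paths.append(path)
    return paths


def write_tornado(
    out_dir: Path, entries: Sequence[TornadoEntry], base_icer: float, plot: bool = True
) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    df = tornado_to_dataframe(entries)
    csv_path = out_dir / "tornado.csv"
    df.to_csv(csv_path, index=False)
    paths = [csv_path]
    if plot and len(df):
        shown = df.head(15).iloc[::-1]
        fig, ax = plt.subplots(figsize=(8, 0.4 * len(shown) + 1.5))
        lows = shown[["icer_low", "icer_high"]].min(axis=1)
        highs = shown[["icer_low", "icer_high"]].max(axis=1)
        ax.barh(shown["parameter"], highs - lows, left=lows, color="#4878b0")
        ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
        ax.set_xlabel("ICER (USD/QALY)")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        png_path = out_dir / "tornado.png"
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
        paths.append(png_path)
    return paths


def write_psa(
    out_dir: Path,
    psa: PSAResult,
    wtp: float,
    lambda_grid: Optional[Sequence[float]] = None,
    plot: bool = True,
) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    draws_path = out_dir / "psa_draws.csv"
    psa.draws.to_csv(draws_path, index=False)
    if lambda_grid is None:
        lambda_grid = [wtp * f for f in (0.0, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)]
    curve = ceac(psa, lambda_grid)
    ceac_path = out_dir / "ceac.csv"
    curve.to_csv(ceac_path, index=False)
    paths = [draws_path, ceac_path]
    if plot:
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(
            psa.draws["incremental_qalys"], psa.draws["incremental_cost"], s=6, alpha=0.4
        )
        xs = ax.get_xlim()
        ax.plot(xs, [wtp * x for x in xs], "r--", lw=1, label=f"WTP = {wtp:,.0f} USD/QALY")
        ax.set_xlim(xs)
        ax.axhline(0, color="k", lw=0.5)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("incremental QALYs")
        ax.set_ylabel("incremental cost (USD)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        scatter_path = out_dir / "psa_scatter.png"
        fig.savefig(scatter_path, dpi=150)
        plt.close(fig)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve["wtp"], curve["p_cost_effective"], marker="o", ms=3)
        ax.set_xlabel("willingness-to-pay (USD/QALY)")
        ax.set_ylabel(f"P({psa.intervention} cost-effective)")
        ax.set_ylim(-0.02, 1.02)
        fig.tight_layout()
        ceac_png = out_dir / "ceac.png"
        fig.savefig(ceac_png, dpi=150)
        plt.close(fig)
        paths += [scatter_path, ceac_png]
    return paths
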