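"""Uniform result envelope: TSV tables + JSON metadata sidecar, minimal plots.

Every analysis can be wrapped in an :class:`AnalyzedResult` — the analysis
name, its tables, and an annotation echoing the parameters (including the
seed) — which round-trips losslessly through ``save_result``/``load_result``
and can be rendered with :func:`plot`. Plots are deliberately minimal: they
are derived entirely from the saved tables, so they are optional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import CapabilityError, EpochsFormatError

__all__ = ["AnalyzedResult", "save_result", "load_result", "plot"]

_REQUIRED_ANNOTATION_KEYS = ("seed",)


@dataclass
class AnalyzedResult:
    """Analysis name + tables + parameter annotation (must include 'seed')."""

    analysis_name: str
    tables: dict[str, pd.DataFrame]
    annotation: dict
    plot_defaults: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in _REQUIRED_ANNOTATION_KEYS:
            if key not in self.annotation:
                raise EpochsFormatError(f"annotation is missing required key {key!r}")


def save_result(envelope: AnalyzedResult, directory: str | Path) -> Path:
    """Write the envelope into a directory: one TSV per table + a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table_files = {}
    for name, table in envelope.tables.items():
        filename = f"{envelope.analysis_name}_{name}.tsv"
        table.to_csv(directory / filename, sep="\t", index=False)
        table_files[name] = filename
    sidecar = {
        "analysis_name": envelope.analysis_name,
        "annotation": envelope.annotation,
        "plot_defaults": envelope.plot_defaults,
        "tables": table_files,
    }
    sidecar_path = directory / f"{envelope.analysis_name}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True, default=_jsonify))
    return sidecar_path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_result(sidecar_path: str | Path) -> AnalyzedResult:
    """Load an envelope from its JSON sidecar (tables resolved relative to it)."""
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise EpochsFormatError(f"result sidecar not found: {sidecar_path}")
    doc = json.loads(sidecar_path.read_text())
    for key in ("analysis_name", "annotation", "tables"):
        if key not in doc:
            raise EpochsFormatError(f"result sidecar is missing key {key!r}")
    tables = {}
    for name, filename in doc["tables"].items():
        path = sidecar_path.parent / filename
        if not path.exists():
            raise EpochsFormatError(f"result table file missing: {path}")
        tables[name] = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return AnalyzedResult(
        analysis_name=doc["analysis_name"],
        tables=tables,
        annotation=doc["annotation"],
        plot_defaults=doc.get("plot_defaults", {}),
    )


# --------------------------------------------------------------------------
# Minimal plotting
# --------------------------------------------------------------------------

def plot(envelope: AnalyzedResult, out_path: str | Path) -> Path:
    """Render a minimal figure for a recognised payload type.

    * ``gfp`` — group GFP curves with SEM bands per condition;
    * ``tanova`` / ``classification`` — p-value vs time strip;
    * ``sensor_topography`` — significant-sensor count strip.
    """
    out_path = Path(out_path)
    name = envelope.analysis_name
    if name == "gfp" and "group" in envelope.tables:
        table = envelope.tables["group"]
        fig, ax = plt.subplots(figsize=(7, 3.2))
        for condition, chunk in table.groupby("condition"):
            ax.plot(chunk["time_ms"], chunk["gfp_mean_uV"], label=str(condition))
            ax.fill_between(
                chunk["time_ms"],
                chunk["gfp_mean_uV"] - chunk["gfp_sem_uV"],
                chunk["gfp_mean_uV"] + chunk["gfp_sem_uV"],
                alpha=0.3,
            )
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("GFP (µV)")
        ax.legend()
    elif name in ("tanova", "classification") and "result" in envelope.tables:
        table = envelope.tables["result"]
        if table.empty or table["p"].dropna().empty:
            raise CapabilityError("empty p-value series: nothing to plot")
        fig, ax = plt.subplots(figsize=(7, 2.8))
        mid = (table["window_start"] + table["window_end"]) / 2.0
        ax.plot(mid, table["p"], marker=".", lw=1)
        ax.axhline(0.05, color="gray", ls="--", lw=0.8)
        if "significant_corrected" in table.columns:
            sig = table["significant_corrected"].astype(bool)
            ax.plot(mid[sig], table["p"][sig], "r.", ms=8)
        ax.set_yscale("log")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("p")
    elif name == "sensor_topography" and "counts" in envelope.tables:
        table = envelope.tables["counts"]
        fig, ax = plt.subplots(figsize=(7, 1.8))
        ax.imshow(
            table["sig_count"].to_numpy()[None, :],
            aspect="auto",
            cmap="viridis",
            extent=(
                float(table["window_start"].min()),
                float(table["window_end"].max()),
                0,
                1,
            ),
        )
        ax.set_yticks([])
        ax.set_xlabel("time (ms)")
    else:
        raise CapabilityError(f"no plot rule for analysis {name!r} with tables {list(envelope.tables)}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100, metadata={"Software": "topostat"})
    plt.close(fig)
    return out_path
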