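"""File output: CSVs, figures, and a manifest tying artifacts to config+seed."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import RunConfig, config_hash
from .experiments import CONSUMABLE, PHASES, CycleResult, SelectivityGrid


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _grid_frame(grid: SelectivityGrid, item: str) -> pd.DataFrame:
    return pd.DataFrame(
        grid.outcomes[item],
        index=pd.Index(grid.satiation_axis, name="satiation"),
        columns=pd.Index(grid.re_axis, name="reward_experience"),
    )


def write_selectivity_grid(
    grid: SelectivityGrid, out_dir: str | Path, make_plots: bool = True
) -> list[Path]:
    """One CSV matrix (rows = satiation, cols = RE) plus heatmap per item."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for item in grid.outcomes:
        frame = _grid_frame(grid, item)
        csv_path = out_dir / f"selectivity_{item}_{grid.state_label}.csv"
        frame.to_csv(csv_path)
        written.append(csv_path)
        if make_plots:
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.pcolormesh(
                grid.re_axis,
                grid.satiation_axis,
                grid.outcomes[item],
                cmap="RdYlGn",
                vmin=-1,
                vmax=1,
                shading="nearest",
            )
            ax.set_xlabel("reward experience")
            ax.set_ylabel("satiation")
            ax.set_title(f"{item} ({grid.state_label}): approach=+1, avoid=-1")
            fig.colorbar(im, ax=ax)
            png_path = out_dir / f"selectivity_{item}_{grid.state_label}.png"
            fig.savefig(png_path, dpi=100)
            plt.close(fig)
            written.append(png_path)
    return written


def cycle_frames(result: CycleResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format timecourse and per-phase summary of a cycle result."""
    phase_names = [PHASES[c] for c in result.phase]
    rows = {
        "tick": result.ticks,
        "phase": phase_names,
        "reward_experience": result.re,
        "v_pos_drug": result.v_pos_drug,
    }
    for sp in CONSUMABLE:
        rows[f"cum_{sp}"] = result.cum_consumed[sp]
    if result.re_sem is not None:
        rows["reward_experience_sem"] = result.re_sem
        for sp in CONSUMABLE:
            rows[f"cum_{sp}_sem"] = result.cum_sem[sp]
    timecourse = pd.DataFrame(rows)
    summary = (
        timecourse.groupby("phase", sort=False)
        .agg(
            ticks=("tick", "size"),
            re_mean=("reward_experience", "mean"),
            **{
                f"{sp}_consumed": (f"cum_{sp}", lambda c: c.iloc[-1] - c.iloc[0])
                for sp in CONSUMABLE
            },
        )
        .reset_index()
    )
    return timecourse, summary


def write_cycle_result(
    result: CycleResult, out_dir: str | Path, make_plots: bool = True
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timecourse, summary = cycle_frames(result)
    paths = [out_dir / "cycle_timecourse.csv", out_dir / "cycle_summary.csv"]
    timecourse.to_csv(paths[0], index=False, float_format="%.10g")
    summary.to_csv(paths[1], index=False, float_format="%.10g")
    if make_plots:
        fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
        axes[0].plot(result.ticks, result.re, lw=0.6)
        axes[0].axhline(0.0, color="k", lw=0.4)
        axes[0].set_ylabel("reward experience")
        for sp in CONSUMABLE:
            axes[1].plot(result.ticks, result.cum_consumed[sp], label=sp)
        bounds = np.nonzero(np.diff(result.phase))[0]
        for ax in axes:
            for b in bounds:
                ax.axvline(b, color="grey", ls=":", lw=0.6)
        axes[1].set_xlabel("tick")
        axes[1].set_ylabel("cumulative consumed")
        axes[1].legend()
        png = out_dir / "cycle_timecourse.png"
        fig.savefig(png, dpi=100)
        plt.close(fig)
        paths.append(png)
    return paths


def write_outputs(
    result,
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
    make_plots: bool = True,
) -> dict:
    """Write a result's artifacts plus a manifest; returns the manifest.

    The manifest records every artifact with its SHA-256 digest, the config
    hash, and the seed, so byte-identical reruns are verifiable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(result, SelectivityGrid):
        files = write_selectivity_grid(result, out_dir, make_plots)
    elif isinstance(result, CycleResult):
        files = write_cycle_result(result, out_dir, make_plots)
    else:
        raise TypeError(f"cannot write result of type {type(result).__name__}")
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "files": [
            {"name": p.name, "sha256": _sha256(p)} for p in sorted(files)
        ],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
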