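"""Static figure rendering for the three statistics tables.

Deterministic output: fixed ordering, fixed SVG hash salt, no embedded
timestamps.  These are desk-scale analogues of the repository time
series, the release-by-model change matrix and the paired change-type /
entity-kind boxplots.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "modelevo"

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = [
    "plot_repo_evolution",
    "plot_change_matrix",
    "plot_delta_composition",
    "render_all",
]

_SAVE_KW = {"format": "svg", "metadata": {"Date": None}}


def plot_repo_evolution(repo_evolution: pd.DataFrame, out_path: str | Path) -> Path:
    """Model count (left) and mean nodes per model (right) over time."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for repo, grp in repo_evolution.groupby("repository"):
        dates = pd.to_datetime(grp["date"])
        style = "--" if repo == "combined" else "-"
        ax1.plot(dates, grp["models"], style, label=repo)
        mean_nodes = np.where(
            grp["models"] > 0, grp["nodes"] / grp["models"].clip(lower=1), 0.0
        )
        ax2.plot(dates, mean_nodes, style, label=repo)
    ax1.set_ylabel("models")
    ax2.set_ylabel("mean nodes per model")
    for ax in (ax1, ax2):
        ax.legend(fontsize=7)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    out = Path(out_path)
    fig.savefig(out, **_SAVE_KW)
    plt.close(fig)
    return out


def plot_change_matrix(diffstats: pd.DataFrame, out_path: str | Path) -> Path:
    """Release (version_to) x model heat matrix of operation counts."""
    fig, ax = plt.subplots(figsize=(8, 4))
    if not diffstats.empty:
        total = (
            diffstats["bives_inserts"] + diffstats["bives_deletes"]
            + diffstats["bives_updates"] + diffstats["bives_moves"]
        )
        matrix = diffstats.assign(total_ops=total).pivot_table(
            index="version_to", columns="model_id", values="total_ops",
            aggfunc="sum", fill_value=0,
        ).sort_index()
        im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="Blues")
        ax.set_xticks(range(len(matrix.columns)))
        ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(matrix.index)))
        ax.set_yticklabels(matrix.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="operations")
    ax.set_xlabel("model")
    ax.set_ylabel("release")
    fig.tight_layout()
    out = Path(out_path)
    fig.savefig(out, **_SAVE_KW)
    plt.close(fig)
    return out


def plot_delta_composition(
    diffstats: pd.DataFrame,
    filestats: pd.DataFrame,
    out_path: str | Path,
) -> Path:
    """Paired boxplots: op-type fractions per transition, split by format."""
    fmt_of = dict(zip(filestats["model_id"], filestats["format"]))
    fig, ax = plt.subplots(figsize=(8, 4))
    ops = ["bives_inserts", "bives_deletes", "bives_updates", "bives_moves"]
    labels, data = [], []
    for fmt in sorted(set(fmt_of.values())):
        sub = diffstats[diffstats["model_id"].map(fmt_of) == fmt]
        total = sub[ops].sum(axis=1)
        nz = total > 0
        for op in ops:
            frac = (sub.loc[nz, op] / total[nz]) if nz.any() else pd.Series(dtype=float)
            labels.append(f"{fmt}\n{op.replace('bives_', '')}")
            data.append(frac.to_numpy())
    if data:
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("fraction of operations per transition")
        ax.tick_params(axis="x", labelsize=6)
    fig.tight_layout()
    out = Path(out_path)
    fig.savefig(out, **_SAVE_KW)
    plt.close(fig)
    return out


def render_all(
    filestats: pd.DataFrame,
    diffstats: pd.DataFrame,
    repo_evolution: pd.DataFrame,
    out_dir: str | Path,
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [
        plot_repo_evolution(repo_evolution, out_dir / "repo-evolution.svg"),
        plot_change_matrix(diffstats, out_dir / "change-matrix.svg"),
        plot_delta_composition(diffstats, filestats, out_dir / "delta-composition.svg"),
    ]
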