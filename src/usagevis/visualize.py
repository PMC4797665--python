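"""The four stacked sequence plot types, rendered with matplotlib.

* **normal** — one horizontal lane per participant, each run drawn as a
  contiguous bar of ``blocks`` 30-s blocks in its page group's color;
  participants ordered by sequence length (least time at the bottom).
* **frequency** — total blocks per page group across all participants, as a
  sorted horizontal bar chart.
* **clustered** — normal lanes grouped contiguously by usage-pattern cluster
  (Ward agglomerative clustering on L2-normalized per-group block totals),
  clusters separated by rule lines.
* **group** — one normal-style panel per level of a categorical user
  variable (e.g. trial arm), sharing the x scale.

Rendering contracts are testable on the scene graph: number of bar patches
per lane equals the run count, lane extent equals total_blocks.  SVG output
is byte-reproducible under a fixed hash salt.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # headless; set before pyplot import

import matplotlib.pyplot as plt
import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .dataio import ColorMap, Dataset, UsageDataError
from .sequences import BLOCK_SECONDS, BinnedSequence, order_participants

LANE_HEIGHT = 0.8  # fraction of unit lane spacing occupied by bars


@dataclass
class PlotSpec:
    """What to draw and how; one spec drives any of the four plot types."""

    plot_type: str = "normal"
    block_seconds: int = BLOCK_SECONDS
    sort_direction: str = "ascending"
    facet_variable: str | None = None
    cluster_k: int | str = "auto"
    strict_colors: bool = False
    title: str | None = None
    figsize: tuple[float, float] = (10.0, 6.0)
    output: str | None = None

    def __post_init__(self):
        if self.plot_type not in ("normal", "frequency", "clustered", "group"):
            raise ValueError(f"unknown plot_type {self.plot_type!r}")
        if self.plot_type == "group" and not self.facet_variable:
            raise ValueError("group plots require facet_variable")
        if isinstance(self.cluster_k, int) and self.cluster_k < 2:
            raise ValueError("cluster_k must be >= 2")


def _legend(ax, codes_present, colors: ColorMap, coding, strict: bool):
    handles = []
    for code in sorted(codes_present):
        color = colors.color_for(code, strict=strict)
        label = coding.label_for_code(code) if coding is not None else str(code)
        handles.append(plt.Rectangle((0, 0), 1, 1, facecolor=color, label=label))
    if handles:
        ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(1.01, 1.0),
                  fontsize=8, frameon=False)


def _draw_lanes(ax, sequences, colors: ColorMap, strict: bool, y0: int = 0):
    """Draw one lane per sequence starting at row y0; returns codes seen."""
    codes = set()
    for lane, seq in enumerate(sequences):
        left = 0
        for code, blocks in seq.runs:
            ax.barh(
                y0 + lane,
                blocks,
                left=left,
                height=LANE_HEIGHT,
                color=colors.color_for(code, strict=strict),
                edgecolor="none",
                align="center",
            )
            left += blocks
            codes.add(code)
    return codes


def render_normal(
    sequences: list[BinnedSequence],
    colors: ColorMap,
    spec: PlotSpec | None = None,
    coding=None,
):
    """Stacked per-participant sequence plot (the default view).

    Returns the matplotlib Figure; lanes run bottom-to-top in the order
    given by ``spec.sort_direction``.
    """
    spec = spec or PlotSpec()
    ordered = order_participants(sequences, spec.sort_direction)
    fig, ax = plt.subplots(figsize=spec.figsize)
    codes = _draw_lanes(ax, ordered, colors, spec.strict_colors)
    ax.set_xlabel(f"viewing time ({spec.block_seconds}-s blocks)")
    ax.set_ylabel("participants")
    ax.set_yticks([])
    if ordered:
        ax.set_ylim(-1, len(ordered))
    if spec.title:
        ax.set_title(spec.title)
    _legend(ax, codes, colors, coding, spec.strict_colors)
    fig.tight_layout()
    return fig


def render_frequency(
    sequences: list[BinnedSequence],
    colors: ColorMap,
    spec: PlotSpec | None = None,
    coding=None,
):
    """Aggregate page-group usage: summed blocks per code across all
    participants, sorted most-used first."""
    spec = spec or PlotSpec(plot_type="frequency")
    totals: dict[int, int] = {}
    for seq in sequences:
        for code, blocks in seq.runs:
            totals[code] = totals.get(code, 0) + blocks
    # most-used at the top; ties by ascending code for determinism
    order = sorted(totals, key=lambda c: (-totals[c], c))
    fig, ax = plt.subplots(figsize=spec.figsize)
    for i, code in enumerate(order):
        ax.barh(
            len(order) - 1 - i,
            totals[code],
            height=LANE_HEIGHT,
            color=colors.color_for(code, strict=spec.strict_colors),
            edgecolor="none",
            align="center",
        )
    ax.set_yticks(range(len(order)))
    labels = [
        coding.label_for_code(c) if coding is not None else str(c)
        for c in reversed(order)
    ]
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel(f"total viewing time ({spec.block_seconds}-s blocks)")
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    return fig


def usage_feature_matrix(sequences: list[BinnedSequence]):
    """Per-user feature vectors: total blocks per code, L2-normalized.

    Returns (matrix, code list); row order follows ``sequences``.
    """
    codes = sorted({code for s in sequences for code, _ in s.runs})
    index = {c: j for j, c in enumerate(codes)}
    X = np.zeros((len(sequences), len(codes)))
    for i, seq in enumerate(sequences):
        for code, blocks in seq.runs:
            X[i, index[code]] += blocks
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms, codes


def cluster_usage(
    sequences: list[BinnedSequence], k: int | str = "auto", seed: int = 0
) -> np.ndarray:
    """Group participants into statistically similar usage patterns.

    Ward-linkage agglomerative clustering on the L2-normalized per-group
    block totals.  With ``k='auto'`` the cluster count in 2..8 maximizing
    mean silhouette is chosen.  The procedure is deterministic given the
    input order; ``seed`` is accepted for interface stability.
    """
    if len(sequences) < 2:
        raise ValueError("clustering requires at least 2 sequences")
    X, _ = usage_feature_matrix(sequences)
    if k == "auto":
        best_k, best_score = 2, -np.inf
        for kk in range(2, min(8, len(sequences) - 1) + 1):
            labels = AgglomerativeClustering(n_clusters=kk, linkage="ward").fit_predict(X)
            if len(set(labels)) < 2:
                continue
            score = silhouette_score(X, labels)
            if score > best_score + 1e-12:
                best_k, best_score = kk, score
        k = best_k
    if not isinstance(k, int) or k < 2:
        raise ValueError(f"k must be an integer >= 2 or 'auto', got {k!r}")
    if len(sequences) < k:
        raise ValueError(f"cannot form {k} clusters from {len(sequences)} users")
    return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)


def render_clustered(
    sequences: list[BinnedSequence],
    colors: ColorMap,
    spec: PlotSpec | None = None,
    coding=None,
    seed: int = 0,
):
    """Normal-style lanes grouped contiguously by usage cluster, with rule
    lines between clusters; within-cluster ordering by sequence length."""
    spec = spec or PlotSpec(plot_type="clustered")
    labels = cluster_usage(sequences, spec.cluster_k, seed=seed)
    by_cluster: dict[int, list[BinnedSequence]] = {}
    for seq, lab in zip(sequences, labels):
        by_cluster.setdefault(int(lab), []).append(seq)
    # clusters ordered by mean total_blocks, least-used cluster at the bottom
    cluster_order = sorted(
        by_cluster,
        key=lambda c: (float(np.mean([s.total_blocks for s in by_cluster[c]])), c),
    )
    fig, ax = plt.subplots(figsize=spec.figsize)
    codes = set()
    y0 = 0
    for ci, cluster in enumerate(cluster_order):
        members = order_participants(by_cluster[cluster], spec.sort_direction)
        codes |= _draw_lanes(ax, members, colors, spec.strict_colors, y0=y0)
        y0 += len(members)
        if ci < len(cluster_order) - 1:
            ax.axhline(y0 - 0.5, color="black", linewidth=0.8)
    ax.set_xlabel(f"viewing time ({spec.block_seconds}-s blocks)")
    ax.set_ylabel("participants (grouped by usage cluster)")
    ax.set_yticks([])
    ax.set_ylim(-1, max(y0, 1))
    if spec.title:
        ax.set_title(spec.title)
    _legend(ax, codes, colors, coding, spec.strict_colors)
    fig.tight_layout()
    return fig


def render_group(
    sequences: list[BinnedSequence],
    colors: ColorMap,
    spec: PlotSpec,
    users,
    coding=None,
):
    """One normal-style panel per level of a categorical user variable,
    shared x scale; empty levels keep an empty, labeled panel."""
    var = spec.facet_variable
    if var is None or var not in users.columns:
        raise UsageDataError(f"facet variable {var!r} not in user table")
    levels = sorted(users[var].dropna().astype(str).unique())
    if not levels:
        raise UsageDataError(f"facet variable {var!r} has no levels")
    membership = users[var].astype(str).to_dict()
    max_x = max((s.total_blocks for s in sequences), default=1)
    fig, axes = plt.subplots(
        1, len(levels), figsize=spec.figsize, sharex=True, squeeze=False
    )
    codes = set()
    for ax, level in zip(axes[0], levels):
        members = [s for s in sequences if membership.get(s.user_id) == level]
        members = order_participants(members, spec.sort_direction)
        codes |= _draw_lanes(ax, members, colors, spec.strict_colors)
        ax.set_title(str(level), fontsize=9)
        ax.set_yticks([])
        ax.set_xlim(0, max_x * 1.02)
        ax.set_ylim(-1, max(len(members), 1))
    axes[0][0].set_ylabel("participants")
    for ax in axes[0]:
        ax.set_xlabel(f"viewing time ({spec.block_seconds}-s blocks)")
    _legend(axes[0][-1], codes, colors, coding, spec.strict_colors)
    fig.tight_layout()
    return fig


def render(dataset: Dataset, spec: PlotSpec, sequences=None, seed: int = 0):
    """Dispatch on ``spec.plot_type`` from an assembled dataset."""
    from .sequences import build_sequences

    seqs = sequences if sequences is not None else build_sequences(dataset, spec.block_seconds)
    if spec.plot_type == "normal":
        return render_normal(seqs, dataset.colors, spec, dataset.coding)
    if spec.plot_type == "frequency":
        return render_frequency(seqs, dataset.colors, spec, dataset.coding)
    if spec.plot_type == "clustered":
        return render_clustered(seqs, dataset.colors, spec, dataset.coding, seed=seed)
    return render_group(seqs, dataset.colors, spec, dataset.users, dataset.coding)


def save_figure(fig, path, seed: int = 0) -> None:
    """Save to SVG/PNG by extension.  SVG output is byte-reproducible:
    element ids are derived from a fixed hash salt and the date metadata is
    suppressed."""
    path = str(path)
    if path.endswith(".svg"):
        with plt.rc_context({"svg.hashsalt": str(seed)}):
            fig.savefig(path, format="svg", metadata={"Date": None})
    else:
        fig.savefig(path)
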