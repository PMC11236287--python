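"""Figures and the consolidated HTML report.

Produces the three standard views of a clustered family — the cluster-size
frequency spectrum, the triangular physical/evolutionary distance heatmap
with cluster extents outlined on the diagonal, and the physical-vs-
evolutionary scatter — plus a single self-contained HTML report embedding
every figure (base64) and table, with the run parameters and the method
conventions (distance definition, D_C pooling rule) stated inline.

Physical distances are stored in bp and converted to Mb only at render
time. Figure output is deterministic for a fixed input (no timestamps in
image metadata).
"""

from __future__ import annotations

import base64
import html as _html
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.patches as mpatches
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clustering import ClusterSet, PhysDistMatrix
from .coords import FamilyTable
from .errors import ConsistencyError
from .evolution import EvolDistMatrix

#: colour-blind-safe qualitative palette for per-scaffold colouring
PALETTE = ["#0072B2", "#E69F00", "#009E73", "#CC79A7", "#56B4E9",
           "#D55E00", "#F0E442", "#999999"]
CLUSTER_OUTLINE = "#E69F00"  # orange
CLUSTER_OUTLINE_B = "#D55E00"  # red, second family in joint mode

_SAVE_KW = dict(dpi=110, metadata={"Date": None})

plt.rcParams["svg.hashsalt"] = "famcluster"


def save_figure(fig: plt.Figure, stem: str | Path) -> list[Path]:
    """Write PNG and SVG next to each other; returns the paths."""
    stem = Path(stem)
    paths = []
    for ext in ("png", "svg"):
        p = stem.with_suffix(f".{ext}")
        fig.savefig(p, **_SAVE_KW)
        paths.append(p)
    plt.close(fig)
    return paths


def _placeholder(message: str) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.text(0.5, 0.5, message, ha="center", va="center", wrap=True)
    ax.set_axis_off()
    return fig


# ---------------------------------------------------------------------------
# spectrum

def plot_spectrum(spectrum: pd.DataFrame) -> plt.Figure:
    """Bar plot of the cluster-size frequency spectrum.

    One colour per scaffold, grouped by cluster size, with the pooled
    genome-wide counts as a second panel.
    """
    if spectrum.empty:
        return _placeholder("empty cluster-size spectrum")
    per_scaffold = spectrum[spectrum["scope"] != "genome"]
    pooled = spectrum[spectrum["scope"] == "genome"]
    scaffolds = list(dict.fromkeys(per_scaffold["scope"]))
    sizes = sorted(spectrum["size"].unique())
    fig, (ax1, ax2) = plt.subplots(
        1, 2, figsize=(9, 3.6), sharey=True,
        gridspec_kw={"width_ratios": [2, 1]},
    )
    width = 0.8 / max(1, len(scaffolds))
    for k, scf in enumerate(scaffolds):
        sub = per_scaffold[per_scaffold["scope"] == scf].set_index("size")["count"]
        xs = [i + k * width for i in range(len(sizes))]
        ys = [int(sub.get(s, 0)) for s in sizes]
        ax1.bar(xs, ys, width=width, label=scf,
                color=PALETTE[k % len(PALETTE)])
    ax1.set_xticks([i + 0.4 - width / 2 for i in range(len(sizes))])
    ax1.set_xticklabels(sizes)
    ax1.set_xlabel("cluster size")
    ax1.set_ylabel("frequency")
    ax1.set_title("per scaffold")
    ax1.legend(fontsize=8)
    pooled_counts = pooled.set_index("size")["count"]
    ax2.bar(range(len(sizes)), [int(pooled_counts.get(s, 0)) for s in sizes],
            color="#444444")
    ax2.set_xticks(range(len(sizes)))
    ax2.set_xticklabels(sizes)
    ax2.set_xlabel("cluster size")
    ax2.set_title("genome-wide")
    fig.tight_layout()
    return fig


# ---------------------------------------------------------------------------
# heatmap

def _ordered_ids(table: FamilyTable, scaffold: str) -> list[str]:
    return [r.gene_id for r in table.records if r.scaffold == scaffold]


def plot_distance_heatmap(
    phys: PhysDistMatrix,
    evol: EvolDistMatrix | None,
    clusters: ClusterSet,
    table: FamilyTable,
    scaffold: str,
    second_clusters: ClusterSet | None = None,
) -> plt.Figure:
    """Triangular heatmap for one scaffold, genes in genomic order.

    Lower triangle: physical distances (Mb). Upper triangle: evolutionary
    distances (replacements/site) when available, else the mirrored
    physical distances. Cluster extents are outlined as squares on the
    diagonal (a second family's clusters, in joint mode, in a distinct
    colour).
    """
    ids = _ordered_ids(table, scaffold)
    if len(ids) < 2:
        return _placeholder(f"fewer than two genes on {scaffold}")
    pidx = {g: i for i, g in enumerate(phys.gene_ids)}
    missing = [g for g in ids if g not in pidx]
    if missing:
        raise ConsistencyError(f"genes missing from physical matrix: {missing}")
    order = [pidx[g] for g in ids]
    pm = phys.values[np.ix_(order, order)] / 1e6  # bp -> Mb
    n = len(ids)
    if evol is not None:
        em = evol.reorder(ids).values
        upper_label = "evolutionary distance (replacements/site)"
    else:
        em = pm
        upper_label = "physical distance (Mb)"
    lower = np.tril(np.ones((n, n), dtype=bool), k=-1)
    display_low = np.where(lower, pm, np.nan)
    display_up = np.where(lower.T, em, np.nan)
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im1 = ax.imshow(display_low, cmap="viridis", interpolation="nearest")
    im2 = ax.imshow(display_up, cmap="magma", interpolation="nearest")
    for cs, colour in ((clusters, CLUSTER_OUTLINE),
                       (second_clusters, CLUSTER_OUTLINE_B)):
        if cs is None:
            continue
        for cl in cs.clusters_on(scaffold):
            pos = [ids.index(g) for g in cl.members if g in ids]
            if not pos:
                continue
            lo, hi = min(pos), max(pos)
            ax.add_patch(mpatches.Rectangle(
                (lo - 0.5, lo - 0.5), hi - lo + 1, hi - lo + 1,
                fill=False, edgecolor=colour, linewidth=1.8,
            ))
    ax.set_xticks(range(n))
    ax.set_yticks(range(n))
    ax.set_xticklabels(ids, rotation=90, fontsize=6)
    ax.set_yticklabels(ids, fontsize=6)
    ax.set_title(scaffold, fontsize=10)
    cb1 = fig.colorbar(im1, ax=ax, shrink=0.75, pad=0.02)
    cb1.set_label("physical distance (Mb)", fontsize=8)
    cb2 = fig.colorbar(im2, ax=ax, shrink=0.75, pad=0.08)
    cb2.set_label(upper_label, fontsize=8)
    fig.tight_layout()
    return fig


# ---------------------------------------------------------------------------
# scatter

def plot_phys_vs_evol(
    phys: PhysDistMatrix,
    evol: EvolDistMatrix,
    clusters: ClusterSet,
) -> plt.Figure:
    """Physical (Mb) vs evolutionary distance for all same-scaffold pairs.

    Within-cluster pairs are coloured; all other pairs are grey.
    """
    ids = phys.gene_ids
    em = evol.reorder(ids).values
    member = clusters.membership()
    xs_in, ys_in, xs_out, ys_out = [], [], [], []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if not phys.same_scaffold[i, j]:
                continue
            x = phys.values[i, j] / 1e6
            y = em[i, j]
            ci, cj = member.get(ids[i]), member.get(ids[j])
            if ci is not None and ci == cj:
                xs_in.append(x)
                ys_in.append(y)
            else:
                xs_out.append(x)
                ys_out.append(y)
    if not (xs_in or xs_out):
        return _placeholder("no same-scaffold gene pairs")
    fig, ax = plt.subplots(figsize=(5.5, 4.2))
    ax.scatter(xs_out, ys_out, s=14, c="#b0b0b0", label="unclustered pairs",
               alpha=0.7, linewidths=0)
    ax.scatter(xs_in, ys_in, s=18, c=CLUSTER_OUTLINE, label="within-cluster pairs",
               alpha=0.9, linewidths=0)
    ax.set_xlabel("physical distance (Mb)")
    ax.set_ylabel("evolutionary distance (replacements/site)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


# ---------------------------------------------------------------------------
# HTML report

@dataclass
class ReportBundle:
    """Everything the HTML report embeds."""

    title: str
    metadata: dict = field(default_factory=dict)
    tables: dict[str, Path] = field(default_factory=dict)  # name -> TSV path
    figures: dict[str, Path] = field(default_factory=dict)  # name -> PNG path


def render_html_report(bundle: ReportBundle, path: str | Path) -> list[str]:
    """Write a single self-contained HTML file; returns warnings.

    Figures are embedded as base64 PNG so the file opens with no external
    fetches. A missing figure or table produces an inline warning block
    (and a non-empty warning list for the caller to exit non-zero on).
    """
    warnings_: list[str] = []
    parts: list[str] = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{_html.escape(bundle.title)}</title>",
        "<style>body{font-family:sans-serif;max-width:1100px;margin:2em auto;}"
        "table{border-collapse:collapse;font-size:13px;}"
        "td,th{border:1px solid #ccc;padding:3px 8px;}"
        ".warn{background:#fee;border:1px solid #c00;padding:8px;margin:8px 0;}"
        "img{max-width:100%;}</style></head><body>",
        f"<h1>{_html.escape(bundle.title)}</h1>",
        "<h2>Run parameters and conventions</h2><table>",
    ]
    for key, val in bundle.metadata.items():
        parts.append(
            f"<tr><th>{_html.escape(str(key))}</th>"
            f"<td>{_html.escape(str(val))}</td></tr>"
        )
    parts.append("</table>")
    for name, tsv in bundle.tables.items():
        parts.append(f"<h2>{_html.escape(name)}</h2>")
        if not Path(tsv).exists():
            warnings_.append(f"missing table: {tsv}")
            parts.append(f"<div class='warn'>missing table: {_html.escape(str(tsv))}</div>")
            continue
        df = pd.read_csv(tsv, sep="\t", comment="#")
        parts.append(df.to_html(index=False, border=0, na_rep=""))
    for name, png in bundle.figures.items():
        parts.append(f"<h2>{_html.escape(name)}</h2>")
        png = Path(png)
        if not png.exists():
            warnings_.append(f"missing figure: {png}")
            parts.append(f"<div class='warn'>missing figure: {_html.escape(str(png))}</div>")
            continue
        data = base64.b64encode(png.read_bytes()).decode("ascii")
        parts.append(f"<img alt='{_html.escape(name)}' src='data:image/png;base64,{data}'>")
    parts.append("</body></html>")
    Path(path).write_text("\n".join(parts))
    return warnings_
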