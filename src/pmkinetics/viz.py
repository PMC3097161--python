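"""Vector figures for every analysis module.

All figures are written in a vector format (postscript by default, with
pdf and svg as options) so they can be zoomed and used in publications.
Multi-panel outputs land in a single file: PDF documents are genuinely
multi-page; the postscript and SVG backends write one page, so those
formats pack all panels onto one page grid.  Categorical shading (by
phenotype, strain, or both) uses a deterministic palette keyed on sorted
category labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")  # headless; vector output only
matplotlib.rcParams["svg.hashsalt"] = "pmkinetics"  # deterministic svg ids

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.backends.backend_pdf import PdfPages
from matplotlib.colors import TwoSlopeNorm

from .analysis import ClusterResult, CorrelationMatrix, ProfileMatch, ProfilePattern
from .compare import ComparisonResult
from .curves import resample_set
from .model import RecordSet
from .qc import QuantileCurves

__all__ = [
    "PlotSpec",
    "bar_plots",
    "plot_quantiles",
    "plot_correlation_intensity",
    "plot_profile_matches",
    "plot_clusters",
    "plot_heatmap",
]

log = logging.getLogger(__name__)

VECTOR_FORMATS = ("ps", "pdf", "svg")
SHADING_MODES = ("by_phenotype", "by_strain", "by_both")


@dataclass(frozen=True)
class PlotSpec:
    """Where and how to draw a figure."""

    path: Union[str, Path]
    format: str = "ps"
    shading: str = "by_phenotype"
    panels_per_page: int = 8

    def __post_init__(self) -> None:
        if self.format not in VECTOR_FORMATS:
            raise ValueError(
                f"format {self.format!r} is not a vector format {VECTOR_FORMATS}"
            )
        if self.shading not in SHADING_MODES:
            raise ValueError(f"unknown shading mode {self.shading!r}")
        if self.panels_per_page < 1:
            raise ValueError("panels_per_page must be >= 1")

    @property
    def out(self) -> Path:
        p = Path(self.path)
        if p.suffix.lstrip(".") != self.format:
            p = p.with_suffix(f".{self.format}")
        return p


def _savefig(fig, path: Path, fmt: str) -> None:
    # strip volatile timestamp metadata so identical inputs give identical files
    metadata = {"Date": None} if fmt in ("svg", "ps") else {"CreationDate": None}
    try:
        fig.savefig(path, format=fmt, metadata=metadata)
    except TypeError:
        fig.savefig(path, format=fmt)
    plt.close(fig)


def _category(record, shading: str) -> str:
    if shading == "by_phenotype":
        return record.phenotype
    if shading == "by_strain":
        return record.strain
    return f"{record.strain}/{record.phenotype}"


def _palette(categories: Sequence[str]) -> dict[str, tuple]:
    cats = sorted(set(categories))
    cmap = plt.get_cmap("tab20")
    return {c: cmap(i % 20) for i, c in enumerate(cats)}


def _paginate(n_panels: int, per_page: int, fmt: str) -> list[tuple[int, int]]:
    """(start, stop) panel ranges per page; single page for ps/svg."""
    if fmt == "pdf":
        return [
            (i, min(i + per_page, n_panels)) for i in range(0, n_panels, per_page)
        ]
    return [(0, n_panels)]


def _grid_axes(fig, n: int):
    ncols = 2 if n > 1 else 1
    nrows = math.ceil(n / ncols)
    return [fig.add_subplot(nrows, ncols, i + 1) for i in range(n)]


def bar_plots(rs: RecordSet, spec: PlotSpec) -> Path:
    """One bar panel per record: bar height = intensity at each time point.

    All panels are written to a single file (multi-page for PDF);
    shading follows the spec's category mode.
    """
    records = list(rs)
    if not records:
        raise ValueError("bar_plots requires a non-empty RecordSet")
    colors = _palette([_category(r, spec.shading) for r in records])
    pages = _paginate(len(records), spec.panels_per_page, spec.format)

    def draw_page(fig, chunk):
        axes = _grid_axes(fig, len(chunk))
        for ax, rec in zip(axes, chunk):
            t = rec.curve.times / 60.0
            width = np.min(np.diff(t)) if len(t) > 1 else 0.2
            ax.bar(
                t,
                rec.curve.values,
                width=width,
                color=colors[_category(rec, spec.shading)],
                linewidth=0,
            )
            ax.set_title(
                f"{rec.strain} {rec.phenotype} {rec.plate}/{rec.well} rep{rec.replicate}",
                fontsize=7,
            )
            ax.set_xlabel("hours", fontsize=6)
            ax.set_ylabel("intensity", fontsize=6)
            ax.tick_params(labelsize=6)

    out = spec.out
    if spec.format == "pdf":
        with PdfPages(out) as pdf:
            for start, stop in pages:
                chunk = records[start:stop]
                fig = plt.figure(figsize=(8.5, 2.5 * math.ceil(len(chunk) / 2)))
                draw_page(fig, chunk)
                fig.tight_layout()
                pdf.savefig(fig)
                plt.close(fig)
    else:
        fig = plt.figure(figsize=(8.5, 2.5 * math.ceil(len(records) / 2)))
        draw_page(fig, records)
        fig.tight_layout()
        _savefig(fig, out, spec.format)
    log.info("wrote %d bar panels to %s", len(records), out)
    return out


def plot_quantiles(
    qc: QuantileCurves, spec: PlotSpec, overlay: Optional[QuantileCurves] = None
) -> Path:
    """Quantile curves of negative controls with candidate-threshold lines."""
    fig, ax = plt.subplots(figsize=(8, 5))
    t = qc.grid.times / 60.0
    for level, curve, thr in zip(qc.levels, qc.curves, qc.candidate_thresholds):
        (line,) = ax.plot(t, curve, label=f"q{level:g}")
        ax.axhline(thr, color=line.get_color(), linestyle=":", linewidth=0.8)
    if overlay is not None:
        for level, curve in zip(overlay.levels, overlay.curves):
            ax.plot(
                overlay.grid.times / 60.0,
                curve,
                linestyle="--",
                alpha=0.6,
                label=f"non-neg q{level:g}",
            )
    ax.set_xlabel("hours")
    ax.set_ylabel("intensity")
    ax.set_title("negative-control quantile curves (dotted: candidate thresholds)")
    ax.legend(fontsize=7)
    out = spec.out
    _savefig(fig, out, spec.format)
    return out


def plot_correlation_intensity(cm: CorrelationMatrix, spec: PlotSpec) -> Path:
    """Intensity plot of the pairwise correlation matrix."""
    if len(cm.labels) == 0:
        raise ValueError("empty correlation matrix")
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(cm.matrix, vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title(f"pairwise correlation ({len(cm.labels)} records)")
    ax.set_xlabel("record index")
    ax.set_ylabel("record index")
    out = spec.out
    _savefig(fig, out, spec.format)
    return out


def plot_profile_matches(
    rs: RecordSet,
    pattern: ProfilePattern,
    matches: Sequence[ProfileMatch],
    spec: PlotSpec,
) -> Path:
    """One panel per record: its curve overlaid with the search pattern.

    Each panel is annotated with the record's correlation to the pattern
    and the p-value; panels appear in match rank order.
    """
    if not matches:
        raise ValueError("no profile matches to plot")
    by_label = {r.label: r for r in rs}
    ordered = [by_label[m.label] for m in matches]
    colors = _palette([_category(r, spec.shading) for r in ordered])
    pages = _paginate(len(matches), spec.panels_per_page, spec.format)

    def draw_page(fig, chunk):
        axes = _grid_axes(fig, len(chunk))
        for ax, m in zip(axes, chunk):
            rec = by_label[m.label]
            ax.plot(
                rec.curve.times / 60.0,
                rec.curve.values,
                color=colors[_category(rec, spec.shading)],
                label="record",
            )
            ax.plot(
                pattern.times / 60.0,
                pattern.values,
                "k--",
                label="pattern",
            )
            ax.set_title(
                f"#{m.rank} {'|'.join(map(str, m.label))}  r={m.r:.3f} p={m.p:.3g}",
                fontsize=7,
            )
            ax.tick_params(labelsize=6)
            ax.legend(fontsize=6)

    out = spec.out
    if spec.format == "pdf":
        with PdfPages(out) as pdf:
            for start, stop in pages:
                chunk = matches[start:stop]
                fig = plt.figure(figsize=(8.5, 2.5 * math.ceil(len(chunk) / 2)))
                draw_page(fig, chunk)
                fig.tight_layout()
                pdf.savefig(fig)
                plt.close(fig)
    else:
        fig = plt.figure(figsize=(8.5, 2.5 * math.ceil(len(matches) / 2)))
        draw_page(fig, list(matches))
        fig.tight_layout()
        _savefig(fig, out, spec.format)
    return out


def plot_clusters(cr: ClusterResult, spec: PlotSpec) -> Path:
    """One panel per cluster: member z-scored curves plus the centroid."""
    if not cr.memberships:
        raise ValueError("empty cluster result")
    t = cr.grid.times / 60.0
    fig = plt.figure(figsize=(8.5, 2.8 * math.ceil(cr.k / 2)))
    axes = _grid_axes(fig, cr.k)
    for c, ax in enumerate(axes, start=1):
        n_members = 0
        for label, cluster in cr.memberships.items():
            if cluster != c:
                continue
            ax.plot(t, cr.scaled_vectors[label], alpha=0.4, linewidth=0.7)
            n_members += 1
        ax.plot(t, cr.centroids[c - 1], "k-", linewidth=2, label="centroid")
        ax.set_title(f"cluster {c} (n={n_members})", fontsize=8)
        ax.set_xlabel("hours", fontsize=6)
        ax.set_ylabel("z-scored intensity", fontsize=6)
        ax.tick_params(labelsize=6)
        ax.legend(fontsize=6)
    fig.tight_layout()
    out = spec.out
    _savefig(fig, out, spec.format)
    return out


def plot_heatmap(result: ComparisonResult, spec: PlotSpec) -> Path:
    """Wells × plates fold-change heat map per test strain.

    Rows are the 96 wells A01..H12, columns the plates; the colour
    encodes sign(FC)·log2|FC| on a diverging scale centred at no change
    (|FC| = 1), green for growth promotion, with a horizontal fold-change
    colour bar at the bottom.  Reported numbers stay on the FC scale.
    """
    strains = result.test_strains()
    if not strains:
        raise ValueError("empty comparison result")
    fig, axes = plt.subplots(
        1, len(strains), figsize=(1.2 + 4.5 * len(strains), 10), squeeze=False
    )
    for ax, strain in zip(axes[0], strains):
        mat, wells, plates = result.fc_matrix(strain)
        signed_log = np.sign(mat) * np.log2(np.abs(mat))
        lim = max(2.0, float(np.nanmax(np.abs(signed_log))) if np.isfinite(signed_log).any() else 2.0)
        im = ax.imshow(
            signed_log,
            cmap="PiYG",
            norm=TwoSlopeNorm(vcenter=0.0, vmin=-lim, vmax=lim),
            aspect="auto",
        )
        ax.set_title(f"{strain} vs {result.parent_strain}", fontsize=9)
        ax.set_xticks(range(len(plates)))
        ax.set_xticklabels(plates, rotation=90, fontsize=5)
        ax.set_yticks(range(0, len(wells), 8))
        ax.set_yticklabels(wells[::8], fontsize=5)
        cb = fig.colorbar(
            im, ax=ax, orientation="horizontal", pad=0.08, fraction=0.04
        )
        # ticks outside the norm's range map to infinity; drop them
        ticks = [v for v in cb.get_ticks() if -lim <= v <= lim]
        cb.set_ticks(ticks)
        cb.set_ticklabels(
            [f"{np.sign(v) * 2 ** abs(v):+.1f}" if v else "±1" for v in ticks],
            fontsize=6,
        )
        cb.set_label("fold change", fontsize=7)
    fig.tight_layout()
    out = spec.out
    _savefig(fig, out, spec.format)
    return out
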