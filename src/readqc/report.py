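"""Report generation from snapshots: the four standard panels (length
violins, length density, inverse cumulative length, length-vs-quality
density) plus a summary table, rendered to static HTML/PDF or an
interactive HTML page.

Reports are built from snapshot statistics only; the original read files
are never touched.  Interactive pages embed the figures as SVG with each
dataset's artists tagged, and a small script toggles datasets and exports
the current view as PNG.
"""

from __future__ import annotations

import base64
import html
import io
import logging
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.backends.backend_pdf import PdfPages
from matplotlib.figure import Figure
from scipy.stats import gaussian_kde

from .errors import ConfigurationError
from .metrics import DatasetStats

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_COLORS = plt.rcParams["axes.prop_cycle"].by_key()["color"]


def _color(i: int) -> str:
    return _COLORS[i % len(_COLORS)]


def _usable(snapshots, labels):
    out = []
    for i, (s, lab) in enumerate(zip(snapshots, labels)):
        if s.n_reads == 0:
            logger.warning("snapshot %s has no reads, skipped in plots", lab)
            continue
        out.append((i, s, lab))
    return out


def _tag(artists, gid: str) -> None:
    for a in np.atleast_1d(artists):
        a.set_gid(gid)


def plot_length_violin(
    snapshots: Sequence[DatasetStats],
    labels: Optional[Sequence[str]] = None,
    log_scale: bool = False,
) -> Figure:
    """One violin of the per-read length distribution per snapshot."""
    labels = labels or [f"dataset {i + 1}" for i in range(len(snapshots))]
    usable = _usable(snapshots, labels)
    if not usable:
        raise ConfigurationError("no non-empty snapshot to plot")
    fig, ax = plt.subplots(figsize=(1.8 + 1.4 * len(usable), 4.2))
    data = [s.lengths for _, s, _ in usable]
    if log_scale:
        data = [np.log10(np.maximum(d, 1)) for d in data]
    parts = ax.violinplot(data, showmedians=True, widths=0.8)
    for j, body in enumerate(parts["bodies"]):
        i = usable[j][0]
        body.set_facecolor(_color(i))
        body.set_alpha(0.6)
        _tag(body, f"ds-{i}")
    for key in ("cbars", "cmins", "cmaxes", "cmedians"):
        parts[key].set_color("0.3")
    ax.set_xticks(range(1, len(usable) + 1), [lab for _, _, lab in usable])
    ax.set_ylabel("log10 read length (bp)" if log_scale else "read length (bp)")
    ax.set_title("Read length distribution")
    fig.tight_layout()
    return fig


def _fd_bins(values: np.ndarray) -> int:
    """Freedman-Diaconis bin count, clamped to a sane range."""
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    if iqr <= 0:
        return 20
    width = 2 * iqr / len(values) ** (1 / 3)
    span = values.max() - values.min()
    return int(np.clip(np.ceil(span / width) if width > 0 else 20, 5, 400))


def plot_length_density(
    snapshots: Sequence[DatasetStats],
    labels: Optional[Sequence[str]] = None,
) -> Figure:
    """Per-snapshot read length density histograms (Freedman-Diaconis bins)."""
    labels = labels or [f"dataset {i + 1}" for i in range(len(snapshots))]
    usable = _usable(snapshots, labels)
    if not usable:
        raise ConfigurationError("no non-empty snapshot to plot")
    fig, ax = plt.subplots(figsize=(6.4, 4.2))
    for i, s, lab in usable:
        vals = s.lengths.astype(float)
        _, _, patches = ax.hist(
            vals,
            bins=_fd_bins(vals),
            density=True,
            histtype="stepfilled",
            alpha=0.45,
            color=_color(i),
            label=lab,
        )
        _tag(patches, f"ds-{i}")
    ax.set_xlabel("read length (bp)")
    ax.set_ylabel("density")
    ax.set_title("Read length density")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_inverse_cumulative(
    snapshots: Sequence[DatasetStats],
    labels: Optional[Sequence[str]] = None,
) -> Figure:
    """Cumulative bases contained in reads at least x bp long, one step
    curve per snapshot; the value at x=0 is the dataset total."""
    labels = labels or [f"dataset {i + 1}" for i in range(len(snapshots))]
    usable = _usable(snapshots, labels)
    if not usable:
        raise ConfigurationError("no non-empty snapshot to plot")
    fig, ax = plt.subplots(figsize=(6.4, 4.2))
    for i, s, lab in usable:
        thresholds, cumulative = s.inverse_cumulative_curve()
        # bases-in-reads->=t is constant on the left-open interval between
        # successive distinct lengths, hence a "pre" step
        (line,) = ax.step(
            thresholds, cumulative, where="pre", color=_color(i), label=lab
        )
        _tag(line, f"ds-{i}")
    ax.set_xlabel("read length threshold (bp)")
    ax.set_ylabel("bases in reads ≥ threshold")
    ax.set_title("Inverse cumulative read length distribution")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_length_vs_quality(
    snapshots: Sequence[DatasetStats],
    labels: Optional[Sequence[str]] = None,
    grid: int = 120,
) -> Figure:
    """2D density contours of (read length, per-read mean Q), one layer per
    snapshot.  Quality-absent reads are excluded (count logged)."""
    labels = labels or [f"dataset {i + 1}" for i in range(len(snapshots))]
    usable = _usable(snapshots, labels)
    fig, ax = plt.subplots(figsize=(6.4, 4.6))
    plotted = 0
    for i, s, lab in usable:
        present = ~np.isnan(s.mean_qs)
        excluded = int((~present).sum())
        if excluded:
            logger.info("%s: %d quality-absent reads excluded from L-Q plot",
                        lab, excluded)
        L = s.lengths[present].astype(float)
        Q = s.mean_qs[present]
        if L.size == 0:
            continue
        if L.size < 3 or np.ptp(L) == 0 or np.ptp(Q) == 0:
            pts = ax.scatter(L, Q, s=12, color=_color(i), label=lab)
            _tag(pts, f"ds-{i}")
            plotted += 1
            continue
        kde = gaussian_kde(np.vstack([L, Q]))
        xi = np.linspace(L.min(), L.max(), grid)
        yi = np.linspace(Q.min(), Q.max(), grid)
        xx, yy = np.meshgrid(xi, yi)
        zz = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
        cs = ax.contour(xx, yy, zz, levels=6, colors=[_color(i)], linewidths=1.0)
        _tag(cs.get_children() if hasattr(cs, "get_children") else cs.collections,
             f"ds-{i}")
        ax.plot([], [], color=_color(i), label=lab)
        plotted += 1
    if plotted == 0:
        plt.close(fig)
        raise ConfigurationError(
            "no snapshot carries quality values; length-vs-quality plot "
            "needs per-read mean Q"
        )
    ax.set_xlabel("read length (bp)")
    ax.set_ylabel("mean read quality (Phred)")
    ax.set_title("Read length vs mean quality density")
    ax.legend()
    fig.tight_layout()
    return fig


# ---------------------------------------------------------------------------
# report assembly

_PANEL_BUILDERS = (
    ("Read length violin", plot_length_violin),
    ("Read length density", plot_length_density),
    ("Inverse cumulative length", plot_inverse_cumulative),
    ("Length vs quality", plot_length_vs_quality),
)


def _summary_rows(
    snapshots: Sequence[DatasetStats], labels: Sequence[str]
) -> List[Tuple[str, List[str]]]:
    rows = []
    for s, lab in zip(snapshots, labels):
        table = dict(s.summary_table())
        rows.append(
            (
                lab,
                [
                    table["n_reads"],
                    table["total_bases"],
                    table["min_length"],
                    table["mean_length"],
                    table["max_length"],
                    table["n50"],
                    table["gc"],
                    table["mean_q"],
                ],
            )
        )
    return rows


_SUMMARY_COLS = (
    "reads", "total bases", "min len", "mean len", "max len", "N50", "GC", "mean Q"
)


def _figures(snapshots, labels) -> List[Tuple[str, Figure]]:
    figs = []
    for title, builder in _PANEL_BUILDERS:
        try:
            figs.append((title, builder(snapshots, labels)))
        except ConfigurationError as exc:
            logger.warning("panel %r skipped: %s", title, exc)
    return figs


def _summary_html(snapshots, labels) -> str:
    head = "".join(f"<th>{html.escape(c)}</th>" for c in ("dataset",) + _SUMMARY_COLS)
    body = ""
    for lab, cells in _summary_rows(snapshots, labels):
        tds = "".join(f"<td>{html.escape(c)}</td>" for c in cells)
        body += f"<tr><td>{html.escape(lab)}</td>{tds}</tr>\n"
    return (
        f"<table class='summary'><thead><tr>{head}</tr></thead>"
        f"<tbody>{body}</tbody></table>"
    )


_CSS = """
body { font-family: sans-serif; margin: 2em auto; max-width: 70em; }
table.summary { border-collapse: collapse; margin-bottom: 1.5em; }
table.summary th, table.summary td { border: 1px solid #999; padding: 4px 10px; }
.panel { margin-bottom: 2em; }
.controls { margin-bottom: 1em; }
"""

_TOGGLE_JS = """
function toggleDataset(i, on) {
  document.querySelectorAll('[id^="ds-' + i + '"]').forEach(function (el) {
    el.style.display = on ? '' : 'none';
  });
}
function exportPanelPNG(panelId) {
  var svg = document.querySelector('#' + panelId + ' svg');
  if (!svg) return;
  var xml = new XMLSerializer().serializeToString(svg);
  var img = new Image();
  img.onload = function () {
    var canvas = document.createElement('canvas');
    canvas.width = img.width * 2; canvas.height = img.height * 2;
    var ctx = canvas.getContext('2d');
    ctx.fillStyle = 'white';
    ctx.fillRect(0, 0, canvas.width, canvas.height);
    ctx.scale(2, 2);
    ctx.drawImage(img, 0, 0);
    var a = document.createElement('a');
    a.download = panelId + '.png';
    a.href = canvas.toDataURL('image/png');
    a.click();
  };
  img.src = 'data:image/svg+xml;base64,' + btoa(unescape(encodeURIComponent(xml)));
}
"""


def _fig_png_b64(fig: Figure) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _fig_svg(fig: Figure) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="svg")
    svg = buf.getvalue().decode("utf-8")
    return svg[svg.index("<svg") :]


def render_report(
    snapshots: Sequence[DatasetStats],
    out: PathLike,
    labels: Optional[Sequence[str]] = None,
    mode: str = "static",
    fmt: str = "html",
) -> Path:
    """Render snapshots into a self-contained report file.

    ``mode`` is ``static`` or ``interactive``; ``fmt`` is ``html`` or
    ``pdf`` (PDF is only available for static reports).  Every number in
    the summary table is taken directly from the DatasetStats fields.
    """
    if mode not in ("static", "interactive"):
        raise ConfigurationError(f"unknown report mode {mode!r}")
    if fmt not in ("html", "pdf"):
        raise ConfigurationError(f"unknown report format {fmt!r}")
    if mode == "interactive" and fmt == "pdf":
        raise ConfigurationError("interactive reports can only be rendered to HTML")
    labels = list(labels or [f"dataset {i + 1}" for i in range(len(snapshots))])
    out = Path(out)
    figs = _figures(snapshots, labels)
    try:
        if fmt == "pdf":
            _render_pdf(snapshots, labels, figs, out)
        else:
            _render_html(snapshots, labels, figs, out, interactive=(mode == "interactive"))
    finally:
        for _, fig in figs:
            plt.close(fig)
    return out


def _render_pdf(snapshots, labels, figs, out: Path) -> None:
    with PdfPages(out) as pdf:
        tfig, ax = plt.subplots(figsize=(8.5, 1.2 + 0.35 * len(labels)))
        ax.axis("off")
        rows = _summary_rows(snapshots, labels)
        tab = ax.table(
            cellText=[[lab] + cells for lab, cells in rows],
            colLabels=("dataset",) + _SUMMARY_COLS,
            loc="center",
        )
        tab.scale(1, 1.4)
        ax.set_title("Read dataset summary")
        pdf.savefig(tfig)
        plt.close(tfig)
        for _, fig in figs:
            pdf.savefig(fig)


def _render_html(snapshots, labels, figs, out: Path, interactive: bool) -> None:
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Read dataset report</title>",
        f"<style>{_CSS}</style>",
    ]
    if interactive:
        parts.append(f"<script>{_TOGGLE_JS}</script>")
    parts.append("</head><body><h1>Read dataset report</h1>")
    parts.append(_summary_html(snapshots, labels))
    if interactive:
        boxes = "".join(
            f"<label><input type='checkbox' checked "
            f"onchange=\"toggleDataset({i}, this.checked)\"> "
            f"{html.escape(lab)}</label> "
            for i, lab in enumerate(labels)
        )
        parts.append(f"<div class='controls'>Show datasets: {boxes}</div>")
    for k, (title, fig) in enumerate(figs):
        panel_id = f"panel-{k}"
        parts.append(f"<div class='panel' id='{panel_id}'><h2>{html.escape(title)}</h2>")
        if interactive:
            parts.append(_fig_svg(fig))
            parts.append(
                f"<br><button onclick=\"exportPanelPNG('{panel_id}')\">"
                "Export PNG</button>"
            )
        else:
            parts.append(
                f"<img alt='{html.escape(title)}' "
                f"src='data:image/png;base64,{_fig_png_b64(fig)}'>"
            )
        parts.append("</div>")
    parts.append("</body></html>")
    out.write_text("".join(parts), encoding="utf-8")
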