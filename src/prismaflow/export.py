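"""Save flow diagrams to files: html, zip-html, svg, dot, pdf, png, ps, webp.

The textual channels (svg, html, dot) come straight from the render module
and are byte-deterministic.  The standalone html file embeds its style and
script; the ``zip-html`` flavour stores them as separate archive members
(``index.html``, ``style.css``, ``script.js``) that render identically when
unpacked.  Vector/raster outputs (pdf, png, ps, webp) are drawn from the
same positioned geometry with matplotlib (webp written through Pillow), so
they show exactly what the SVG shows, minus interactivity.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .diagram_model import ArmConfig, DiagramGraph, KIND_SIDE_BAR, build_graph
from .flow_data import FlowData
from .layout_engine import PositionedDiagram, StyleSpec, layout
from .render import PAGE_CSS, PAGE_JS, render_dot, render_html, render_svg

__all__ = ["FORMATS", "SaveRequest", "UnsupportedFormatError", "infer_format", "save"]

FORMATS = ("html", "zip-html", "svg", "dot", "pdf", "png", "ps", "webp")

_EXTENSIONS = {
    ".html": "html",
    ".htm": "html",
    ".zip": "zip-html",
    ".svg": "svg",
    ".dot": "dot",
    ".gv": "dot",
    ".pdf": "pdf",
    ".png": "png",
    ".ps": "ps",
    ".webp": "webp",
}


class UnsupportedFormatError(ValueError):
    def __init__(self, what: str):
        super().__init__(
            f"unsupported output format {what!r}; supported: {', '.join(FORMATS)}"
        )


@dataclass(frozen=True)
class SaveRequest:
    """Where and how to save: target path, format tag, raster scale factor."""

    target_path: Union[str, Path]
    format: str = "infer"
    scale: float = 1.0


def infer_format(path: Union[str, Path]) -> str:
    """Map a file extension to a format tag (pure, total on the known set)."""
    ext = Path(path).suffix.lower()
    try:
        return _EXTENSIONS[ext]
    except KeyError:
        raise UnsupportedFormatError(ext or str(path)) from None


def _zip_html(pd: PositionedDiagram) -> bytes:
    doc = render_html(pd, embed_assets=False)
    interactive = pd.config.interactive
    members = [("index.html", doc.content), ("style.css", PAGE_CSS)]
    if interactive:
        members.append(("script.js", PAGE_JS))
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, text in members:
            # fixed timestamp keeps archives reproducible run-to-run
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, text)
    return buf.getvalue()


def _draw_matplotlib(pd: PositionedDiagram, path: Path, fmt: str, scale: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon, Rectangle

    style = pd.style
    w, h = pd.canvas
    fig = plt.figure(figsize=(w / 72.0, h / 72.0))
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)  # canvas origin is top-left
    ax.axis("off")

    for pn in pd.placed_nodes:
        ax.add_patch(
            Rectangle(
                (pn.x, pn.y),
                pn.width,
                pn.height,
                facecolor=style.fill_for(pn.spec.kind),
                edgecolor=style.box_border,
                linewidth=1.0,
            )
        )
        if pn.spec.kind == KIND_SIDE_BAR:
            cx = pn.label_x if pn.label_x is not None else pn.center[0]
            cy = pn.label_y if pn.label_y is not None else pn.center[1]
            ax.text(
                cx, cy, pn.text_lines[0],
                rotation=pn.label_rotation or 90, rotation_mode="anchor",
                ha="center", va="center",
                fontsize=style.font_size, family="sans-serif",
            )
        else:
            centered = pn.spec.kind != "data-box"
            for i, line in enumerate(pn.text_lines):
                ty = pn.y + style.padding + (i + 0.5) * style.line_height
                if centered:
                    ax.text(pn.center[0], ty, line, ha="center", va="center",
                            fontsize=style.font_size, family="sans-serif")
                else:
                    ax.text(pn.x + style.padding, ty, line, ha="left", va="center",
                            fontsize=style.font_size, family="sans-serif")

    head = 7.0
    for ep in pd.edge_paths:
        xs = [p[0] for p in ep.points]
        ys = [p[1] for p in ep.points]
        ax.plot(xs, ys, color=style.box_border, linewidth=1.0, solid_capstyle="butt")
        if style.arrow_head != "none":
            (x0, y0), (x1, y1) = ep.points[-2], ep.points[-1]
            dx, dy = x1 - x0, y1 - y0
            norm = max((dx * dx + dy * dy) ** 0.5, 1e-9)
            ux, uy = dx / norm, dy / norm
            px, py = -uy, ux
            base = (x1 - head * ux, y1 - head * uy)
            tri = [
                (x1, y1),
                (base[0] + 0.45 * head * px, base[1] + 0.45 * head * py),
                (base[0] - 0.45 * head * px, base[1] - 0.45 * head * py),
            ]
            ax.add_patch(Polygon(tri, closed=True, facecolor=style.box_border,
                                 edgecolor="none"))

    dpi = 72.0 * scale
    if fmt == "webp":
        buf = io.BytesIO()
        fig.savefig(buf, format="png", dpi=dpi)
        plt.close(fig)
        from PIL import Image

        buf.seek(0)
        Image.open(buf).convert("RGB").save(path, format="WEBP")
        return
    fig.savefig(path, format=fmt, dpi=dpi)
    plt.close(fig)


def save(
    fd: FlowData,
    config: ArmConfig | None = None,
    style: StyleSpec | None = None,
    req: SaveRequest | Union[str, Path, None] = None,
) -> Path:
    """Run the whole pipeline and write the diagram to ``req.target_path``.

    ``req`` may be a SaveRequest or simply a path (format inferred from the
    extension).  Returns the written path.  Validation errors surface as
    :class:`~prismaflow.diagram_model.ValidationError` from build_graph.
    """
    if req is None:
        req = SaveRequest(target_path="prisma_flowdiagram.html")
    if isinstance(req, (str, Path)):
        req = SaveRequest(target_path=req)
    config = config or ArmConfig()
    fmt = req.format if req.format != "infer" else infer_format(req.target_path)
    if fmt not in FORMATS:
        raise UnsupportedFormatError(fmt)

    path = Path(req.target_path)
    graph: DiagramGraph = build_graph(fd, config)
    pd = layout(graph, style)

    if fmt == "svg":
        path.write_text(render_svg(pd).content, encoding="utf-8")
    elif fmt == "dot":
        path.write_text(render_dot(graph, style).content, encoding="utf-8")
    elif fmt == "html":
        path.write_text(render_html(pd).content, encoding="utf-8")
    elif fmt == "zip-html":
        path.write_bytes(_zip_html(pd))
    else:
        _draw_matplotlib(pd, path, fmt, req.scale)
    return path
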