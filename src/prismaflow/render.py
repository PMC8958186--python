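"""Serialize a positioned diagram to SVG, interactive HTML, or DOT.

Three output channels with deliberately different capabilities:

* **SVG** — the static picture.  Tooltips use the format's native hover
  ``<title>`` elements (SVG cannot run scripts); there are never hyperlinks.
* **HTML** — the interactive page.  The same SVG is embedded inline in a
  self-contained HTML5 document; boxes with a ``url`` are wrapped in anchor
  elements so a click navigates to the linked methods/results page, and
  tooltips appear on mouse-over.  Styling and the (tiny) hover script are
  embedded, so a standalone file references nothing external.
* **DOT** — a compatibility export carrying the same labels and edges with
  explicit node positions (``pos="x,y!"``) and the orthogonal-splines
  directive, for external graph-layout engines.

All three are byte-deterministic for a given positioned diagram.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass

from .diagram_model import DiagramGraph, KIND_SIDE_BAR
from .layout_engine import PositionedDiagram, StyleSpec, layout

__all__ = ["RenderedDocument", "render_svg", "render_html", "render_dot"]

_SVG_NS = "http://www.w3.org/2000/svg"


@dataclass(frozen=True)
class RenderedDocument:
    """An output artifact: format tag plus the document text."""

    format: str  # svg | html | dot
    content: str
    assets_embedded: bool = True


# ---------------------------------------------------------------------------
# SVG
# ---------------------------------------------------------------------------


def _marker(defs: ET.Element, marker_id: str, shape: str, color: str) -> None:
    if shape == "none":
        return
    m = ET.SubElement(
        defs,
        "marker",
        {
            "id": marker_id,
            "viewBox": "0 0 10 10",
            "refX": "9",
            "refY": "5",
            "markerWidth": "8",
            "markerHeight": "8",
            "orient": "auto-start-reverse",
        },
    )
    if shape == "dot":
        ET.SubElement(m, "circle", {"cx": "5", "cy": "5", "r": "4", "fill": color})
    elif shape == "vee":
        ET.SubElement(
            m, "path", {"d": "M 0 0 L 10 5 L 0 10", "fill": "none",
                        "stroke": color, "stroke-width": "1.5"}
        )
    else:  # normal: filled triangle
        ET.SubElement(m, "path", {"d": "M 0 0 L 10 5 L 0 10 z", "fill": color})


def _fmt(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


def _svg_tree(pd: PositionedDiagram, with_anchors: bool) -> ET.Element:
    style = pd.style
    w, h = pd.canvas
    svg = ET.Element(
        "svg",
        {
            "xmlns": _SVG_NS,
            "width": _fmt(w),
            "height": _fmt(h),
            "viewBox": f"0 0 {_fmt(w)} {_fmt(h)}",
            "font-family": style.font_family,
            "font-size": _fmt(style.font_size),
        },
    )
    defs = ET.SubElement(svg, "defs")
    _marker(defs, "arrow-head", style.arrow_head, style.box_border)
    _marker(defs, "arrow-tail", style.arrow_tail, style.box_border)
    ET.SubElement(
        svg, "rect",
        {"x": "0", "y": "0", "width": _fmt(w), "height": _fmt(h), "fill": "#FFFFFF"},
    )

    for pn in pd.placed_nodes:
        parent = svg
        if with_anchors and pn.spec.url is not None:
            parent = ET.SubElement(svg, "a", {"href": pn.spec.url})
        g = ET.SubElement(
            parent, "g", {"id": pn.spec.node_id, "class": f"box {pn.spec.kind}"}
        )
        if pn.spec.tooltip is not None:
            title = ET.SubElement(g, "title")
            title.text = pn.spec.tooltip
        ET.SubElement(
            g,
            "rect",
            {
                "x": _fmt(pn.x),
                "y": _fmt(pn.y),
                "width": _fmt(pn.width),
                "height": _fmt(pn.height),
                "fill": style.fill_for(pn.spec.kind),
                "stroke": style.box_border,
                "stroke-width": "1",
            },
        )
        if pn.spec.kind == KIND_SIDE_BAR:
            cx, cy = pn.label_x, pn.label_y
            if cx is None or cy is None:
                cx, cy = pn.center
            text = ET.SubElement(
                g,
                "text",
                {
                    "x": _fmt(cx),
                    "y": _fmt(cy),
                    "text-anchor": "middle",
                    "dominant-baseline": "central",
                    "transform": f"rotate(-{pn.label_rotation or 90} {_fmt(cx)} {_fmt(cy)})",
                },
            )
            text.text = pn.text_lines[0]
        else:
            centered = pn.spec.kind != "data-box"
            for i, line in enumerate(pn.text_lines):
                ty = pn.y + style.padding + (i + 0.78) * style.line_height
                attrs = {"y": _fmt(ty)}
                if centered:
                    attrs["x"] = _fmt(pn.x + pn.width / 2.0)
                    attrs["text-anchor"] = "middle"
                else:
                    attrs["x"] = _fmt(pn.x + style.padding)
                    attrs["xml:space"] = "preserve"
                text = ET.SubElement(g, "text", attrs)
                text.text = line

    for ep in pd.edge_paths:
        d = "M " + " L ".join(f"{_fmt(px)} {_fmt(py)}" for px, py in ep.points)
        attrs = {
            "class": "edge",
            "d": d,
            "fill": "none",
            "stroke": style.box_border,
            "stroke-width": "1",
        }
        if style.arrow_head != "none":
            attrs["marker-end"] = "url(#arrow-head)"
        if style.arrow_tail != "none":
            attrs["marker-start"] = "url(#arrow-tail)"
        ET.SubElement(svg, "path", attrs)
    return svg


def render_svg(pd: PositionedDiagram) -> RenderedDocument:
    """Static SVG 1.1: hover-title tooltips, no hyperlinks, no scripting."""
    tree = _svg_tree(pd, with_anchors=False)
    content = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        + ET.tostring(tree, encoding="unicode")
        + "\n"
    )
    return RenderedDocument(format="svg", content=content)


# ---------------------------------------------------------------------------
# HTML
# ---------------------------------------------------------------------------

#: Page styling; kept small and embedded (or shipped as style.css in the
#: zip flavour of the export module).
PAGE_CSS = """\
body { margin: 1em; background: #FFFFFF; }
svg { max-width: 100%; height: auto; }
svg a { cursor: pointer; }
svg a:hover rect { stroke-width: 2; }
"""

#: Hover helper: thickens a box's outline while the pointer is over it, so
#: linked boxes are discoverable. Tooltips themselves are native <title>s.
PAGE_JS = """\
document.querySelectorAll('svg g.box').forEach(function (g) {
  g.addEventListener('mouseenter', function () { g.setAttribute('opacity', '0.9'); });
  g.addEventListener('mouseleave', function () { g.removeAttribute('opacity'); });
});
"""

_HTML_TEMPLATE = """\
<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<title>PRISMA 2020 flow diagram</title>
{head}
</head>
<body>
{svg}
{script}
</body>
</html>
"""


def render_html(
    pd: PositionedDiagram,
    embed_assets: bool = True,
    css_href: str = "style.css",
    js_src: str = "script.js",
) -> RenderedDocument:
    """Self-contained interactive HTML page.

    Boxes with a ``url`` are wrapped in anchors (click-through) and boxes
    with a tooltip show it on mouse-over; boxes with neither are inert.
    Anchors are emitted only for interactive configurations — a page built
    from a non-interactive configuration is the static picture on a page.
    With ``embed_assets`` (the default) styles and script are inlined and
    the document references no external file; otherwise it links the given
    stylesheet/script names (used by the zip export).
    """
    with_anchors = pd.config.interactive
    svg_text = ET.tostring(_svg_tree(pd, with_anchors=with_anchors), encoding="unicode")
    if embed_assets:
        head = f"<style>\n{PAGE_CSS}</style>"
        script = f"<script>\n{PAGE_JS}</script>" if with_anchors else ""
    else:
        head = f'<link rel="stylesheet" href="{css_href}"/>'
        script = f'<script src="{js_src}"></script>' if with_anchors else ""
    content = _HTML_TEMPLATE.format(head=head, svg=svg_text, script=script)
    return RenderedDocument(format="html", content=content, assets_embedded=embed_assets)


# ---------------------------------------------------------------------------
# DOT
# ---------------------------------------------------------------------------


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def render_dot(g: DiagramGraph, style: StyleSpec | None = None) -> RenderedDocument:
    """DOT digraph with explicit positions and orthogonal splines.

    Semantic content (labels, tooltips, edges) matches the native SVG path;
    positions come from the same layout engine, converted to DOT's
    bottom-left origin in points.
    """
    style = style or StyleSpec()
    pd = layout(g, style)
    _, canvas_h = pd.canvas
    lines = [
        "digraph prisma {",
        '  graph [layout=neato, splines=ortho];',
        f'  node [shape=box, fontname="{_dot_escape(style.font_family)}", '
        f"fontsize={_fmt(style.font_size)}];",
    ]
    for pn in pd.placed_nodes:
        cx, cy = pn.center
        label = _dot_escape("\n".join(pn.text_lines)).replace("\n", "\\n")
        attrs = [
            f'label="{label}"',
            f'pos="{_fmt(cx)},{_fmt(canvas_h - cy)}!"',
            f"width={_fmt(pn.width / 72.0)}",
            f"height={_fmt(pn.height / 72.0)}",
            'style=filled',
            f'fillcolor="{pd.style.fill_for(pn.spec.kind)}"',
        ]
        if pn.spec.tooltip is not None:
            attrs.append(f'tooltip="{_dot_escape(pn.spec.tooltip)}"')
        if pn.spec.kind == KIND_SIDE_BAR:
            attrs.append("orientation=90")
        lines.append(f"  {pn.spec.node_id} [{', '.join(attrs)}];")
    for e in g.edges:
        lines.append(f"  {e.from_node} -> {e.to_node};")
    lines.append("}")
    return RenderedDocument(format="dot", content="\n".join(lines) + "\n")
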