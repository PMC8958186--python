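"""Grid placement and orthogonal edge routing for the flow diagram.

The diagram is a fixed template, so no general-purpose graph layout is
needed: boxes live on a small logical grid (columns for the side bars, the
optional previous-studies arm, the main arm and its exclusions, the optional
other-methods arm and its exclusions; rows for the title band and the six
review stages).  The engine:

* word-wraps each box's lines to its column width and sizes the box from the
  wrapped line count (taller boxes re-space their whole row, so rectangles
  never overlap);
* collapses the columns and rows of disabled arms, shrinking the canvas;
* stretches each blue side bar over the grid rows of its review stage and
  centres a 90-degree-rotated label in it;
* routes every edge as an axis-aligned polyline — straight when the two box
  anchors already align, otherwise with a single elbow.

Coordinates are abstract canvas units (interpreted as points by renderers,
72 per inch).  Origin is the top-left corner, y grows downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .diagram_model import (
    ArmConfig,
    COL_OF_BOX,
    DiagramGraph,
    EdgeSpec,
    KIND_SIDE_BAR,
    KIND_TITLE_GREY,
    KIND_TITLE_YELLOW,
    NodeSpec,
    ROW_OF_BOX,
    TITLE_COL_SPAN,
    active_side_bar_span,
)

__all__ = ["StyleSpec", "PlacedNode", "EdgePath", "PositionedDiagram",
           "layout", "rotate_side_labels"]


def _default_fills() -> dict[str, str]:
    return {
        "data-box": "#FFFFFF",
        "title-box-grey": "#BFBFBF",
        "title-box-yellow": "#FFD966",
        "side-bar-blue": "#9DC3E6",
    }


@dataclass(frozen=True)
class StyleSpec:
    """Visual parameters: fonts, fills, arrows and grid spacing.

    All lengths are canvas units (points).  Every box kind has a fill after
    construction; arrow head/tail accept the DOT marker vocabulary
    (``normal``, ``vee``, ``dot``, ``none``).
    """

    font_family: str = "Helvetica"
    font_size: float = 11.0
    box_fill: dict[str, str] = field(default_factory=_default_fills)
    box_border: str = "#000000"
    arrow_head: str = "normal"
    arrow_tail: str = "none"
    column_gap: float = 50.0
    row_gap: float = 36.0
    box_width: float = 230.0
    bar_width: float = 36.0
    line_height: float = 15.0
    padding: float = 8.0
    margin: float = 20.0

    def __post_init__(self) -> None:
        fills = _default_fills()
        fills.update(self.box_fill)
        object.__setattr__(self, "box_fill", fills)

    def fill_for(self, kind: str) -> str:
        return self.box_fill[kind]


@dataclass(frozen=True)
class PlacedNode:
    """A NodeSpec with its rectangle and pre-wrapped text lines.

    ``text_lines`` are the final strings renderers draw (counts appended as
    ``(n = N)``, reason lines indented).  Side bars use ``label_*`` instead:
    a single label rotated ``label_rotation`` degrees about its centre.
    """

    spec: NodeSpec
    x: float
    y: float
    width: float
    height: float
    text_lines: tuple[str, ...]
    label_rotation: int = 0
    label_x: float | None = None
    label_y: float | None = None

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)


@dataclass(frozen=True)
class EdgePath:
    edge: EdgeSpec
    points: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class PositionedDiagram:
    placed_nodes: tuple[PlacedNode, ...]
    edge_paths: tuple[EdgePath, ...]
    canvas: tuple[float, float]
    style: StyleSpec
    config: ArmConfig

    def placed(self, node_id: str) -> PlacedNode:
        for pn in self.placed_nodes:
            if pn.spec.node_id == node_id:
                return pn
        raise KeyError(node_id)


# ---------------------------------------------------------------------------
# Text wrapping
# ---------------------------------------------------------------------------

_INDENT = "    "


def _wrap(text: str, budget: int) -> list[str]:
    """Greedy word wrap; words longer than the budget stand alone."""
    words = text.split()
    if not words:
        return [""]
    lines: list[str] = []
    current = words[0]
    for word in words[1:]:
        if len(current) + 1 + len(word) <= budget:
            current += " " + word
        else:
            lines.append(current)
            current = word
    lines.append(current)
    return lines


def _line_strings(spec: NodeSpec, width: float, style: StyleSpec) -> tuple[str, ...]:
    budget = max(12, int((width - 2 * style.padding) / (style.font_size * 0.55)))
    out: list[str] = []
    for line in spec.lines:
        text = line.text
        if line.count is not None:
            text = f"{text} (n = {line.count})"
        prefix = _INDENT if line.indent else ""
        wrapped = _wrap(text, budget - (len(_INDENT) if line.indent else 0))
        out.extend(prefix + w for w in wrapped)
    return tuple(out) if out else ("",)


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------


def layout(g: DiagramGraph, style: StyleSpec | None = None) -> PositionedDiagram:
    """Place every node of ``g`` on the grid and route every edge.

    Deterministic: identical (graph, style) inputs give a field-for-field
    identical PositionedDiagram.
    """
    style = style or StyleSpec()
    active_boxes = {n.box_id for n in g.nodes}

    cols = [0]
    if g.config.include_previous:
        cols.append(1)
    cols.extend([2, 3])
    if g.config.include_other:
        cols.extend([4, 5])
    col_width = {c: (style.bar_width if c == 0 else style.box_width) for c in cols}
    col_x: dict[int, float] = {}
    x = style.margin
    for c in cols:
        col_x[c] = x
        x += col_width[c] + style.column_gap
    canvas_w = x - style.column_gap + style.margin

    rows = list(range(7 if g.config.include_previous else 6))

    # Box widths (titles may span two columns), wrapped text, heights.
    box_nodes = [n for n in g.nodes if n.kind != KIND_SIDE_BAR]
    widths: dict[str, float] = {}
    texts: dict[str, tuple[str, ...]] = {}
    heights: dict[str, float] = {}
    for n in box_nodes:
        if n.kind in (KIND_TITLE_GREY, KIND_TITLE_YELLOW):
            c0, c1 = TITLE_COL_SPAN[n.box_id]
            c1 = c1 if c1 in col_x else c0
            w = col_x[c1] + col_width[c1] - col_x[c0]
        else:
            w = col_width[COL_OF_BOX[n.box_id]]
        widths[n.box_id] = w
        texts[n.box_id] = _line_strings(n, w, style)
        heights[n.box_id] = 2 * style.padding + len(texts[n.box_id]) * style.line_height

    min_row_h = 2 * style.padding + style.line_height
    row_h = {
        r: max(
            [min_row_h]
            + [heights[b] for b in active_boxes if ROW_OF_BOX.get(b) == r]
        )
        for r in rows
    }
    row_y: dict[int, float] = {}
    y = style.margin
    for r in rows:
        row_y[r] = y
        y += row_h[r] + style.row_gap
    canvas_h = y - style.row_gap + style.margin

    placed: list[PlacedNode] = []
    for n in g.nodes:
        if n.kind == KIND_SIDE_BAR:
            first, last = active_side_bar_span(g, n.box_id)
            by = row_y[first]
            bh = row_y[last] + row_h[last] - by
            placed.append(
                PlacedNode(
                    spec=n,
                    x=col_x[0],
                    y=by,
                    width=style.bar_width,
                    height=bh,
                    text_lines=(n.lines[0].text if n.lines else "",),
                )
            )
        else:
            r = ROW_OF_BOX[n.box_id]
            c = TITLE_COL_SPAN[n.box_id][0] if n.box_id in TITLE_COL_SPAN else COL_OF_BOX[n.box_id]
            h = heights[n.box_id]
            placed.append(
                PlacedNode(
                    spec=n,
                    x=col_x[c],
                    y=row_y[r] + (row_h[r] - h) / 2.0,
                    width=widths[n.box_id],
                    height=h,
                    text_lines=texts[n.box_id],
                )
            )

    by_id = {pn.spec.node_id: pn for pn in placed}
    edge_paths = tuple(
        EdgePath(edge=e, points=_route(e, by_id[e.from_node], by_id[e.to_node]))
        for e in g.edges
    )

    pd = PositionedDiagram(
        placed_nodes=tuple(placed),
        edge_paths=edge_paths,
        canvas=(canvas_w, canvas_h),
        style=style,
        config=g.config,
    )
    return rotate_side_labels(pd)


def _route(
    e: EdgeSpec, src: PlacedNode, dst: PlacedNode
) -> tuple[tuple[float, float], ...]:
    """Axis-aligned polyline from the source boundary to the target boundary."""
    scx, scy = src.center
    tcx, tcy = dst.center
    if e.exit_side == "right" and e.enter_side == "left":
        start = (src.x + src.width, scy)
        end = (dst.x, tcy)
        if abs(scy - tcy) < 1e-9:
            return (start, end)
        mx = (start[0] + end[0]) / 2.0
        return (start, (mx, scy), (mx, tcy), end)
    if e.exit_side == "bottom" and e.enter_side == "top":
        start = (scx, src.y + src.height)
        end = (tcx, dst.y)
        if abs(scx - tcx) < 1e-9:
            return (start, end)
        my = (start[1] + end[1]) / 2.0
        return (start, (scx, my), (tcx, my), end)
    if e.exit_side == "bottom" and e.enter_side == "right":
        # drop down from the source, then left into the target's right side
        return ((scx, src.y + src.height), (scx, tcy), (dst.x + dst.width, tcy))
    if e.exit_side == "bottom" and e.enter_side == "left":
        # drop down the source's column, then right into the target's left side
        return ((scx, src.y + src.height), (scx, tcy), (dst.x, tcy))
    raise ValueError(f"unsupported edge sides {e.exit_side!r}->{e.enter_side!r}")


def rotate_side_labels(pd: PositionedDiagram) -> PositionedDiagram:
    """Mark every blue-bar label as rotated 90° and centred in its bar.

    Label coordinates are recomputed from the bar's placed rectangle, so
    they track the bar as arms are toggled.  Idempotent.
    """
    new_nodes = tuple(
        replace(
            pn,
            label_rotation=90,
            label_x=pn.x + pn.width / 2.0,
            label_y=pn.y + pn.height / 2.0,
        )
        if pn.spec.kind == KIND_SIDE_BAR
        else pn
        for pn in pd.placed_nodes
    )
    return replace(pd, placed_nodes=new_nodes)
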