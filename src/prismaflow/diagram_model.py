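"""PRISMA 2020 diagram topology: nodes, boxes, arms, edges.

The flow diagram is a fixed template of 22 nodes.  Ten data boxes plus the
yellow title box form the *main* arm (records identified via databases and
registers); three nodes form the optional *previous-studies* arm (studies
carried over from an earlier version of the review, including the final
totals box); six form the optional *other-methods* arm (records from
websites, organisations and citation searching); and three blue side bars
mark the identification / screening / included stages.  :func:`build_graph`
derives the active subgraph for any combination of the two optional arms —
nodes of a disabled arm disappear, and every edge with a missing endpoint is
dropped with them.

Box membership of the CSV rows is fixed by data key (`BOX_MEMBERS`), so the
structural columns of the template are documentation, not configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

from .flow_data import (
    FlowData,
    PLACEHOLDER,
    ReasonBreakdown,
    TITLE_BOX_IDS,
    validate,
)

__all__ = [
    "ArmConfig",
    "BoxLine",
    "NodeSpec",
    "EdgeSpec",
    "DiagramGraph",
    "ValidationError",
    "build_graph",
    "active_side_bar_span",
    "BOXES",
    "BOX_MEMBERS",
    "EDGES",
    "ROW_OF_BOX",
    "COL_OF_BOX",
    "KIND_DATA",
    "KIND_TITLE_GREY",
    "KIND_TITLE_YELLOW",
    "KIND_SIDE_BAR",
]

KIND_DATA = "data-box"
KIND_TITLE_GREY = "title-box-grey"
KIND_TITLE_YELLOW = "title-box-yellow"
KIND_SIDE_BAR = "side-bar-blue"

ARM_MAIN = "main"
ARM_PREVIOUS = "previous"
ARM_OTHER = "other"
ARM_SPINE = "spine"


class ValidationError(ValueError):
    """Raised by build_graph when validation reports blocking errors."""

    def __init__(self, report):
        self.report = report
        details = "; ".join(f"{ref}: {msg}" for ref, msg in report.errors)
        super().__init__(f"template failed validation: {details}")


@dataclass(frozen=True)
class ArmConfig:
    """Which optional arms to draw, and whether output is interactive.

    ``interactive`` affects rendering (tooltips become styled, boxes get
    hyperlinks in HTML output); it never changes the node/edge topology.
    """

    include_previous: bool = True
    include_other: bool = True
    interactive: bool = False


@dataclass(frozen=True)
class BoxLine:
    """One display line of a box: text, optional count, reason indent flag."""

    text: str
    count: int | str | None = None  # int, 'xxx' placeholder, or no count
    indent: bool = False


@dataclass(frozen=True)
class NodeSpec:
    node_id: str
    box_id: str
    kind: str
    arm: str
    lines: tuple[BoxLine, ...]
    tooltip: str | None = None
    url: str | None = None


@dataclass(frozen=True)
class EdgeSpec:
    from_node: str
    to_node: str
    exit_side: str  # bottom | right | left
    enter_side: str  # top | left | right


@dataclass(frozen=True)
class DiagramGraph:
    nodes: tuple[NodeSpec, ...]
    edges: tuple[EdgeSpec, ...]
    config: ArmConfig

    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def node_by_box(self, box_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.box_id == box_id:
                return n
        raise KeyError(box_id)


# ---------------------------------------------------------------------------
# The fixed 22-node inventory: (box_id, node_id, kind, arm)
# ---------------------------------------------------------------------------

BOXES: tuple[tuple[str, str, str, str], ...] = (
    ("prevstud", "node4", KIND_TITLE_GREY, ARM_PREVIOUS),
    ("box1", "node5", KIND_DATA, ARM_PREVIOUS),
    ("newstud", "node6", KIND_TITLE_YELLOW, ARM_MAIN),
    ("box2", "node7", KIND_DATA, ARM_MAIN),
    ("othstud", "node16", KIND_TITLE_GREY, ARM_OTHER),
    ("box11", "node17", KIND_DATA, ARM_OTHER),
    ("box3", "node8", KIND_DATA, ARM_MAIN),
    ("box4", "node9", KIND_DATA, ARM_MAIN),
    ("box5", "node10", KIND_DATA, ARM_MAIN),
    ("box6", "node11", KIND_DATA, ARM_MAIN),
    ("box7", "node12", KIND_DATA, ARM_MAIN),
    ("box12", "node18", KIND_DATA, ARM_OTHER),
    ("box13", "node19", KIND_DATA, ARM_OTHER),
    ("box8", "node13", KIND_DATA, ARM_MAIN),
    ("box9", "node14", KIND_DATA, ARM_MAIN),
    ("box14", "node20", KIND_DATA, ARM_OTHER),
    ("box15", "node21", KIND_DATA, ARM_OTHER),
    ("box10", "node15", KIND_DATA, ARM_MAIN),
    ("box16", "node22", KIND_DATA, ARM_PREVIOUS),
    ("identification", "node1", KIND_SIDE_BAR, ARM_SPINE),
    ("screening", "node2", KIND_SIDE_BAR, ARM_SPINE),
    ("included", "node3", KIND_SIDE_BAR, ARM_SPINE),
)

#: Template data keys feeding each box, in display order.
BOX_MEMBERS: dict[str, tuple[str, ...]] = {
    "box1": ("previous_studies", "previous_reports"),
    "box2": ("database_results", "register_results"),
    "box3": ("duplicates", "excluded_automatic", "excluded_other"),
    "box4": ("records_screened",),
    "box5": ("records_excluded",),
    "box6": ("dbr_sought_reports",),
    "box7": ("dbr_notretrieved_reports",),
    "box8": ("dbr_assessed",),
    "box9": ("dbr_excluded",),
    "box10": ("new_studies", "new_reports"),
    "box11": ("website_results", "organisation_results", "citations_results"),
    "box12": ("other_sought_reports",),
    "box13": ("other_notretrieved_reports",),
    "box14": ("other_assessed",),
    "box15": ("other_excluded",),
    "box16": ("total_studies", "total_reports"),
    "identification": ("identification",),
    "screening": ("screening",),
    "included": ("included",),
    "prevstud": (),
    "newstud": (),
    "othstud": (),
}

#: Directed edges on box ids (full configuration): (from, to, exit, enter).
EDGES: tuple[tuple[str, str, str, str], ...] = (
    ("box2", "box3", "right", "left"),
    ("box2", "box4", "bottom", "top"),
    ("box4", "box5", "right", "left"),
    ("box4", "box6", "bottom", "top"),
    ("box6", "box7", "right", "left"),
    ("box6", "box8", "bottom", "top"),
    ("box8", "box9", "right", "left"),
    ("box8", "box10", "bottom", "top"),
    ("box11", "box12", "bottom", "top"),
    ("box12", "box13", "right", "left"),
    ("box12", "box14", "bottom", "top"),
    ("box14", "box15", "right", "left"),
    ("box14", "box10", "bottom", "right"),
    ("box10", "box16", "bottom", "top"),
    ("box1", "box16", "bottom", "left"),
)

# Logical grid shared with the layout engine.  Rows: 0 titles,
# 1 identification, 2 screening, 3 retrieval, 4 assessment, 5 inclusion,
# 6 totals.  Columns: 0 side bars, 1 previous arm, 2 main, 3 main
# exclusions, 4 other arm, 5 other exclusions.
ROW_OF_BOX: dict[str, int] = {
    "prevstud": 0, "newstud": 0, "othstud": 0,
    "box1": 1, "box2": 1, "box3": 1, "box11": 1,
    "box4": 2, "box5": 2,
    "box6": 3, "box7": 3, "box12": 3, "box13": 3,
    "box8": 4, "box9": 4, "box14": 4, "box15": 4,
    "box10": 5,
    "box16": 6,
}

COL_OF_BOX: dict[str, int] = {
    "prevstud": 1, "newstud": 2, "othstud": 4,
    "box1": 1,
    "box2": 2, "box4": 2, "box6": 2, "box8": 2, "box10": 2, "box16": 2,
    "box3": 3, "box5": 3, "box7": 3, "box9": 3,
    "box11": 4, "box12": 4, "box14": 4,
    "box13": 5, "box15": 5,
}

#: Title boxes span two grid columns (their arm's box + exclusion columns).
TITLE_COL_SPAN: dict[str, tuple[int, int]] = {
    "prevstud": (1, 1),
    "newstud": (2, 3),
    "othstud": (4, 5),
}

_ARM_ACTIVE = {
    ARM_MAIN: lambda cfg: True,
    ARM_SPINE: lambda cfg: True,
    ARM_PREVIOUS: lambda cfg: cfg.include_previous,
    ARM_OTHER: lambda cfg: cfg.include_other,
}


def _box_lines(fd: FlowData, box_id: str, kind: str) -> tuple[BoxLine, ...]:
    if kind in (KIND_TITLE_GREY, KIND_TITLE_YELLOW):
        row = fd.title_row(box_id)
        return (BoxLine(text=row.boxtext),) if row is not None else ()
    lines: list[BoxLine] = []
    by_key = fd.by_key
    for key in BOX_MEMBERS[box_id]:
        row = by_key.get(key)
        if row is None:
            continue
        if kind == KIND_SIDE_BAR:
            lines.append(BoxLine(text=row.boxtext))
            continue
        value = row.count
        if isinstance(value, ReasonBreakdown):
            lines.append(BoxLine(text=row.boxtext))
            for label, count in value.reasons:
                lines.append(BoxLine(text=label, count=count, indent=True))
        elif value is None:
            lines.append(BoxLine(text=row.boxtext))
        else:  # int or placeholder
            lines.append(BoxLine(text=row.boxtext, count=value))
    return tuple(lines)


def _box_tooltip_url(fd: FlowData, box_id: str, kind: str) -> tuple[str | None, str | None]:
    """First non-absent tooltip/url among the box's rows wins."""
    if box_id in TITLE_BOX_IDS:
        row = fd.title_row(box_id)
        rows = (row,) if row is not None else ()
    else:
        by_key = fd.by_key
        rows = tuple(
            by_key[k] for k in BOX_MEMBERS[box_id] if k in by_key
        )
    tooltip = next((r.tooltip for r in rows if r.tooltip is not None), None)
    url = next((r.url for r in rows if r.url is not None), None)
    return tooltip, url


def build_graph(fd: FlowData, config: ArmConfig) -> DiagramGraph:
    """Derive the active node/edge subgraph for ``config`` from ``fd``.

    Raises :class:`ValidationError` if :func:`~prismaflow.flow_data.validate`
    reports blocking errors for this configuration (draft mode: placeholder
    counts are allowed and rendered verbatim).
    """
    report = validate(fd, config, strict=False)
    if not report.ok:
        raise ValidationError(report)

    nodes: list[NodeSpec] = []
    active_boxes: set[str] = set()
    for box_id, node_id, kind, arm in BOXES:
        if not _ARM_ACTIVE[arm](config):
            continue
        tooltip, url = _box_tooltip_url(fd, box_id, kind)
        nodes.append(
            NodeSpec(
                node_id=node_id,
                box_id=box_id,
                kind=kind,
                arm=arm,
                lines=_box_lines(fd, box_id, kind),
                tooltip=tooltip,
                url=url,
            )
        )
        active_boxes.add(box_id)

    node_of_box = {n.box_id: n.node_id for n in nodes}
    edges = tuple(
        EdgeSpec(
            from_node=node_of_box[src],
            to_node=node_of_box[dst],
            exit_side=exit_side,
            enter_side=enter_side,
        )
        for src, dst, exit_side, enter_side in EDGES
        if src in active_boxes and dst in active_boxes
    )
    return DiagramGraph(nodes=tuple(nodes), edges=edges, config=config)


#: Boxes covered by each blue bar (stage spans; rows shrink with arms).
_BAR_BOXES: dict[str, tuple[str, ...]] = {
    "identification": ("box1", "box2", "box3", "box11"),
    "screening": ("box4", "box5", "box6", "box7", "box8", "box9",
                  "box12", "box13", "box14", "box15"),
    "included": ("box10", "box16"),
}


def active_side_bar_span(g: DiagramGraph, bar: str) -> tuple[int, int]:
    """Inclusive (first_row, last_row) grid rows a blue bar stretches over.

    Identification covers the records-identified row; screening covers the
    screening, retrieval and assessment rows; included covers the inclusion
    row and, when the previous-studies arm is active, the totals row.
    """
    if bar not in _BAR_BOXES:
        raise KeyError(f"unknown side bar {bar!r}")
    active = {n.box_id for n in g.nodes}
    rows = sorted(
        ROW_OF_BOX[b] for b in _BAR_BOXES[bar] if b in active
    )
    if not rows:  # cannot happen: every bar covers main-arm boxes
        raise ValueError(f"side bar {bar!r} spans no active rows")
    return rows[0], rows[-1]
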