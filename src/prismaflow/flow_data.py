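"""Read, validate, generate and round-trip the PRISMA 2020 template CSV.

Every number and string that appears in a PRISMA 2020 flow diagram comes from
a single small CSV file with eight columns::

    data, node, box, description, boxtext, tooltips, url, n

and thirty rows: one row per *line* of a diagram box (a box such as "Records
identified from:" holds one line per source), three title rows
(``prevstud``/``newstud``/``othstud``) and three rows for the blue stage bars
(``identification``/``screening``/``included``).  Users edit only the
``boxtext``, ``tooltips``, ``url`` and ``n`` columns; the remaining columns
identify rows and document the schema.  Values are assigned to diagram boxes
by exact match on the ``data`` key, never by position, so reordering rows or
editing the structural columns cannot change the rendered output.

The ``n`` column accepts three shapes:

* a non-negative integer — the count displayed as ``(n = N)``;
* the literal placeholder ``xxx`` — legal while drafting, rejected in strict
  validation;
* a reason list such as ``"Wrong population, 15; Wrong outcome, 7"`` —
  semicolon-separated ``label, count`` pairs used by the full-text exclusion
  boxes.  The *last* comma in each segment splits label from count, so labels
  may themselves contain commas.

The literal string ``NA`` and the empty cell both mean "absent".
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, TYPE_CHECKING, Iterable, Union

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .diagram_model import ArmConfig

__all__ = [
    "COLUMNS",
    "COUNT_DATA_KEYS",
    "BAR_DATA_KEYS",
    "TITLE_BOX_IDS",
    "PLACEHOLDER",
    "TemplateRow",
    "ReasonBreakdown",
    "FlowData",
    "ValidationReport",
    "TemplateError",
    "SchemaError",
    "DuplicateKeyError",
    "CountParseError",
    "ReasonParseError",
    "parse_reasons",
    "parse_count",
    "read_template",
    "write_template",
    "blank_template",
    "generate_blank_template",
    "generate_example_data",
    "validate",
]

#: Column names of the template CSV, in order.
COLUMNS = ("data", "node", "box", "description", "boxtext", "tooltips", "url", "n")

#: The 24 count-bearing data keys of the template, in file order.
COUNT_DATA_KEYS = (
    "previous_studies",
    "previous_reports",
    "database_results",
    "register_results",
    "website_results",
    "organisation_results",
    "citations_results",
    "duplicates",
    "excluded_automatic",
    "excluded_other",
    "records_screened",
    "records_excluded",
    "dbr_sought_reports",
    "dbr_notretrieved_reports",
    "other_sought_reports",
    "other_notretrieved_reports",
    "dbr_assessed",
    "dbr_excluded",
    "other_assessed",
    "other_excluded",
    "new_studies",
    "new_reports",
    "total_studies",
    "total_reports",
)

#: Structural keys of the three blue side bars (their n is never displayed).
BAR_DATA_KEYS = ("identification", "screening", "included")

#: Box ids of the three keyless title rows.
TITLE_BOX_IDS = ("prevstud", "newstud", "othstud")

#: Draft-mode placeholder accepted in the ``n`` column.
PLACEHOLDER = "xxx"

_NA = "NA"


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class TemplateError(ValueError):
    """Base class for template parsing problems."""


class SchemaError(TemplateError):
    """The CSV header is missing or renames a required column."""


class DuplicateKeyError(TemplateError):
    """The same data key appears on more than one row."""


class CountParseError(TemplateError):
    """An ``n`` cell is neither an integer, ``xxx`` nor a reason list."""


class ReasonParseError(CountParseError):
    """A reason-list segment cannot be split into label and count."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


#: A parsed count: an integer, the ``xxx`` placeholder, a ReasonBreakdown or
#: None (absent cell).
CountValue = Union[int, str, "ReasonBreakdown", None]


@dataclass(frozen=True)
class ReasonBreakdown:
    """Ordered ``(label, count)`` pairs parsed from a reason-list string.

    Counts are non-negative integers or the ``xxx`` placeholder.  Input order
    is preserved; labels are whitespace-trimmed and may contain commas.
    """

    reasons: tuple[tuple[str, Union[int, str]], ...]

    def __len__(self) -> int:
        return len(self.reasons)

    def total(self) -> Union[int, None]:
        """Sum of the counts, or None if any count is a placeholder."""
        if any(not isinstance(c, int) for _, c in self.reasons):
            return None
        return sum(c for _, c in self.reasons)


@dataclass(frozen=True)
class TemplateRow:
    """One parsed row of the template CSV.

    ``None`` fields correspond to ``NA``/empty cells.  ``n_raw`` keeps the
    verbatim cell so a file can be written back unchanged; the parsed value
    is available through :attr:`count`.
    """

    data_key: str | None
    node_id: str | None
    box_id: str
    description: str | None
    boxtext: str
    tooltip: str | None
    url: str | None
    n_raw: str | None

    @property
    def count(self) -> CountValue:
        """The parsed ``n`` cell (raises CountParseError if malformed)."""
        return parse_count(self.n_raw)

    @property
    def is_count_bearing(self) -> bool:
        return self.data_key in COUNT_DATA_KEYS


@dataclass(frozen=True)
class FlowData:
    """A validated-for-shape collection of template rows.

    ``rows`` preserves file order; ``by_key`` indexes rows by data key and
    ``by_node`` maps each node id to all rows sharing that row's box.
    """

    rows: tuple[TemplateRow, ...]

    @property
    def by_key(self) -> dict[str, TemplateRow]:
        return {r.data_key: r for r in self.rows if r.data_key is not None}

    @property
    def by_node(self) -> dict[str, tuple[TemplateRow, ...]]:
        out: dict[str, tuple[TemplateRow, ...]] = {}
        for r in self.rows:
            if r.node_id is not None:
                out[r.node_id] = tuple(
                    s for s in self.rows if s.box_id == r.box_id
                )
        return out

    def get(self, data_key: str) -> TemplateRow | None:
        return self.by_key.get(data_key)

    def title_row(self, box_id: str) -> TemplateRow | None:
        """The keyless title row for ``prevstud``/``newstud``/``othstud``."""
        for r in self.rows:
            if r.data_key is None and r.box_id == box_id:
                return r
        return None

    def with_counts(self, counts: dict[str, str]) -> "FlowData":
        """Return a copy with the ``n`` cell replaced for the given keys."""
        new_rows = tuple(
            replace(r, n_raw=counts[r.data_key])
            if r.data_key in counts
            else r
            for r in self.rows
        )
        return FlowData(rows=new_rows)


@dataclass
class ValidationReport:
    """Errors (blocking) and warnings (advisory) from :func:`validate`.

    An empty ``errors`` list means the data is accepted for rendering.
    Arithmetic inconsistencies between stages are always warnings: every
    number in the diagram is a user-supplied display value.
    """

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, row_ref: str, message: str) -> None:
        self.errors.append((row_ref, message))

    def warn(self, row_ref: str, message: str) -> None:
        self.warnings.append((row_ref, message))


# ---------------------------------------------------------------------------
# Count / reason parsing
# ---------------------------------------------------------------------------


def _parse_count_token(token: str, segment: str) -> Union[int, str]:
    token = token.strip()
    if token == PLACEHOLDER:
        return PLACEHOLDER
    try:
        return int(token)
    except ValueError:
        raise ReasonParseError(
            f"cannot parse count {token!r} in segment {segment!r}"
        ) from None


def parse_reasons(raw: str) -> ReasonBreakdown:
    """Parse a semicolon-separated ``label, count`` reason list.

    Segments are split on ``;``; within each segment the *last* comma
    separates the label from the count, so labels may contain commas.  A
    bare integer (or ``xxx``) segment yields a pair with an empty label.
    Empty segments are dropped.
    """
    pairs: list[tuple[str, Union[int, str]]] = []
    for segment in raw.split(";"):
        segment = segment.strip()
        if not segment:
            continue
        if "," in segment:
            label, _, token = segment.rpartition(",")
            pairs.append((label.strip(), _parse_count_token(token, segment)))
        else:
            pairs.append(("", _parse_count_token(segment, segment)))
    return ReasonBreakdown(reasons=tuple(pairs))


def parse_count(raw: str | None) -> CountValue:
    """Parse an ``n`` cell: integer, ``xxx``, reason list or absent."""
    if raw is None:
        return None
    text = raw.strip()
    if text == "" or text == _NA:
        return None
    if text == PLACEHOLDER:
        return PLACEHOLDER
    try:
        return int(text)
    except ValueError:
        pass
    if ";" in text or "," in text:
        return parse_reasons(text)
    raise CountParseError(
        f"count cell {raw!r} is not an integer, {PLACEHOLDER!r} or a reason list"
    )


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------


def _absent(cell: str) -> str | None:
    cell = cell.strip()
    return None if cell == "" or cell == _NA else cell


def _open_source(source: Union[str, Path, IO[str]]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        p = Path(source)
        if isinstance(source, str) and "\n" in source:
            return io.StringIO(source), True
        return p.open("r", encoding="utf-8", newline=""), True
    return source, False


def read_template(source: Union[str, Path, IO[str]]) -> FlowData:
    """Read a template CSV into a :class:`FlowData`.

    ``source`` may be a path, a text stream, or a string containing CSV text
    (detected by an embedded newline).  ``NA`` and empty cells map to absent.
    Raises :class:`SchemaError` for a missing/renamed header column and
    :class:`DuplicateKeyError` for a repeated data key.  A file containing
    only the header yields an empty FlowData (missing rows are a *validation*
    concern, not a read error).
    """
    stream, should_close = _open_source(source)
    try:
        reader = csv.reader(stream)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: expected a header row") from None
        header = [h.strip() for h in header]
        for col in COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column {col!r}")
        if tuple(header) != COLUMNS:
            extra = [h for h in header if h not in COLUMNS]
            if extra:
                raise SchemaError(f"unexpected column(s) {extra!r}")
        rows: list[TemplateRow] = []
        seen_keys: set[str] = set()
        for lineno, cells in enumerate(reader, start=2):
            if not cells or all(c.strip() == "" for c in cells):
                continue
            if len(cells) != len(COLUMNS):
                raise SchemaError(
                    f"line {lineno}: expected {len(COLUMNS)} fields, got {len(cells)}"
                )
            rec = dict(zip(header, cells))
            data_key = _absent(rec["data"])
            if data_key is not None:
                if data_key in seen_keys:
                    raise DuplicateKeyError(f"duplicate data key {data_key!r}")
                seen_keys.add(data_key)
            box_id = rec["box"].strip()
            if not box_id:
                raise SchemaError(f"line {lineno}: every row needs a box id")
            rows.append(
                TemplateRow(
                    data_key=data_key,
                    node_id=_absent(rec["node"]),
                    box_id=box_id,
                    description=_absent(rec["description"]),
                    boxtext=rec["boxtext"],
                    tooltip=_absent(rec["tooltips"]),
                    url=_absent(rec["url"]),
                    n_raw=_absent(rec["n"]),
                )
            )
        return FlowData(rows=tuple(rows))
    finally:
        if should_close:
            stream.close()


def write_template(fd: FlowData, sink: Union[str, Path, IO[str], None] = None) -> str:
    """Serialize ``fd`` back to template CSV text (and optionally a file).

    Absent fields are written as ``NA``; quoting is minimal, the line
    terminator is ``\\n``.  Reading the blank template and writing it back is
    byte-identical.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerow(COLUMNS)
    for r in fd.rows:
        writer.writerow(
            [
                r.data_key if r.data_key is not None else _NA,
                r.node_id if r.node_id is not None else _NA,
                r.box_id,
                r.description if r.description is not None else _NA,
                r.boxtext,
                r.tooltip if r.tooltip is not None else _NA,
                r.url if r.url is not None else _NA,
                r.n_raw if r.n_raw is not None else _NA,
            ]
        )
    text = buf.getvalue()
    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(text, encoding="utf-8")
        else:
            sink.write(text)
    return text


# ---------------------------------------------------------------------------
# The canonical blank template
# ---------------------------------------------------------------------------

_REASON_PLACEHOLDER = "Reason1, xxx; Reason2, xxx; Reason3, xxx"
_EXCL_NOTE = (
    "[separate reasons and numbers using; e.g., "
    "Reason1, xxx; Reason2, xxx; Reason3, xxx"
)

# (data, node, box, description, boxtext, tooltips, url, n); "NA" == absent.
_TEMPLATE_ROWS: tuple[tuple[str, ...], ...] = (
    ("NA", "node4", "prevstud", "Grey title box; Previous studies", "Previous studies", "Grey title box; Previous studies", "prevstud.html", "xxx"),
    ("previous_studies", "node5", "box 1", "Studies included in previous version of review", "Studies included in previous version of review", "Studies included in previous version of review", "previous_studies.html", "xxx"),
    ("previous_reports", "NA", "box 1", "Reports of studies included in previous version of review", "Reports of studies included in previous version of review", "NA", "previous_reports.html", "xxx"),
    ("NA", "node6", "newstud", "Yellow title box; Identification of new studies via databases and registers", "Identification of new studies via databases and registers", "Yellow title box; Identification of new studies via databases and registers", "newstud.html", "xxx"),
    ("database_results", "node7", "box 2", "Records identified from: Databases", "Databases", "Records identified from: Databases", "database_results.html", "xxx"),
    ("register_results", "NA", "box 2", "Records identified from: Registers", "Registers", "NA", "NA", "xxx"),
    ("NA", "node16", "othstud", "Grey title box; Identification of new studies via other methods", "Identification of new studies via other methods", "Grey title box; Identification of new studies via other methods", "othstud.html", "xxx"),
    ("website_results", "node17", "box 11", "Records identified from: Websites", "Websites", "Records identified from: Websites", "website_results.html", "xxx"),
    ("organisation_results", "NA", "box 11", "Records identified from: Organisations", "Organisations", "NA", "NA", "xxx"),
    ("citations_results", "NA", "box 11", "Records identified from: Citation searching", "Citation searching", "NA", "NA", "xxx"),
    ("duplicates", "node8", "box 3", "Duplicate records", "Duplicate records", "Duplicate records", "duplicates.html", "xxx"),
    ("excluded_automatic", "NA", "box 3", "Records marked as ineligible by automation tools", "Records marked as ineligible by automation tools", "NA", "NA", "xxx"),
    ("excluded_other", "NA", "box 3", "Records removed for other reasons", "Records removed for other reasons", "NA", "NA", "xxx"),
    ("records_screened", "node9", "box 4", "Records screened (databases and registers)", "Records screened", "Records screened (databases and registers)", "records_screened.html", "xxx"),
    ("records_excluded", "node10", "box 5", "Records excluded (databases and registers)", "Records excluded", "Records excluded (databases and registers)", "records_excluded.html", "xxx"),
    ("dbr_sought_reports", "node11", "box 6", "Reports sought for retrieval (databases and registers)", "Reports sought for retrieval", "Reports sought for retrieval (databases and registers)", "dbr_sought_reports.html", "xxx"),
    ("dbr_notretrieved_reports", "node12", "box 7", "Reports not retrieved (databases and registers)", "Reports not retrieved", "Reports not retrieved (databases and registers)", "dbr_notretrieved_reports.html", "xxx"),
    ("other_sought_reports", "node18", "box 12", "Reports sought for retrieval (other)", "Reports sought for retrieval", "Reports sought for retrieval (other)", "other_sought_reports.html", "xxx"),
    ("other_notretrieved_reports", "node19", "box 13", "Reports not retrieved (other)", "Reports not retrieved", "Reports not retrieved (other)", "other_notretrieved_reports.html", "xxx"),
    ("dbr_assessed", "node13", "box 8", "Reports assessed for eligibility (databases and registers)", "Reports assessed for eligibility", "Reports assessed for eligibility (databases and registers)", "dbr_assessed.html", "xxx"),
    ("dbr_excluded", "node14", "box 9", f"Reports excluded (databases and registers): {_EXCL_NOTE}", "Reports excluded:", f"Reports excluded (databases and registers): {_EXCL_NOTE}", "dbrexcludedrecords.html", _REASON_PLACEHOLDER),
    ("other_assessed", "node20", "box 14", "Reports assessed for eligibility (other)", "Reports assessed for eligibility", "Reports assessed for eligibility (other)", "other_assessed.html", "xxx"),
    ("other_excluded", "node21", "box 15", f"Reports excluded (other): {_EXCL_NOTE}", "Reports excluded:", f"Reports excluded (other): {_EXCL_NOTE}", "other_excluded.html", _REASON_PLACEHOLDER),
    ("new_studies", "node15", "box 10", "New studies included in review", "New studies included in review", "New studies included in review", "new_studies.html", "xxx"),
    ("new_reports", "NA", "box 10", "Reports of new included studies", "Reports of new included studies", "NA", "NA", "xxx"),
    ("total_studies", "node22", "box 16", "Total studies included in review", "Total studies included in review", "Total studies included in review", "total_studies.html", "xxx"),
    ("total_reports", "NA", "box 16", "Reports of total included studies", "Reports of total included studies", "NA", "NA", "xxx"),
    ("identification", "node1", "identification", "Blue identification box", "Identification", "Blue identification box", "identification.html", "xxx"),
    ("screening", "node2", "screening", "Blue screening box", "Screening", "Blue screening box", "screening.html", "xxx"),
    ("included", "node3", "included", "Blue included box", "Included", "Blue included box", "included.html", "xxx"),
)


def blank_template() -> FlowData:
    """The canonical 30-row blank template as a FlowData."""
    rows = tuple(
        TemplateRow(
            data_key=_absent(data),
            node_id=_absent(node),
            box_id=box,
            description=_absent(desc),
            boxtext=boxtext,
            tooltip=_absent(tooltip),
            url=_absent(url),
            n_raw=_absent(n),
        )
        for data, node, box, desc, boxtext, tooltip, url, n in _TEMPLATE_ROWS
    )
    return FlowData(rows=rows)


def generate_blank_template(sink: Union[str, Path, IO[str], None] = None) -> str:
    """Emit the canonical blank template CSV (placeholder counts, NA cells)."""
    return write_template(blank_template(), sink)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

# Data keys belonging to each optional arm; everything else is always active.
PREVIOUS_ARM_KEYS = frozenset(
    {"previous_studies", "previous_reports", "total_studies", "total_reports"}
)
OTHER_ARM_KEYS = frozenset(
    {
        "website_results",
        "organisation_results",
        "citations_results",
        "other_sought_reports",
        "other_notretrieved_reports",
        "other_assessed",
        "other_excluded",
    }
)


def _active_keys(include_previous: bool, include_other: bool) -> list[str]:
    keys = []
    for k in COUNT_DATA_KEYS:
        if k in PREVIOUS_ARM_KEYS and not include_previous:
            continue
        if k in OTHER_ARM_KEYS and not include_other:
            continue
        keys.append(k)
    return keys


def _int_or_none(value: CountValue) -> int | None:
    return value if isinstance(value, int) else None


def _reason_total(value: CountValue) -> int | None:
    if isinstance(value, ReasonBreakdown):
        return value.total()
    return _int_or_none(value)


def validate(
    fd: FlowData, config: "ArmConfig", strict: bool = False
) -> ValidationReport:
    """Check ``fd`` against an arm configuration.

    Errors: data keys required by the active arms that are missing; counts
    that are negative or unparseable; placeholder counts when ``strict``;
    urls containing whitespace.  Warnings: arithmetic inconsistencies between
    stages (counts are display values, so these never block rendering).
    """
    report = ValidationReport()
    by_key = fd.by_key

    required = _active_keys(config.include_previous, config.include_other)
    for key in required:
        if key not in by_key:
            report.error(key, f"missing required data key {key!r}")
    for key in BAR_DATA_KEYS:
        if key not in by_key:
            report.error(key, f"missing side-bar row {key!r}")
    title_required = ["newstud"]
    if config.include_previous:
        title_required.append("prevstud")
    if config.include_other:
        title_required.append("othstud")
    for box_id in title_required:
        if fd.title_row(box_id) is None:
            report.error(box_id, f"missing title row for box {box_id!r}")

    active = set(required)
    for row in fd.rows:
        ref = row.data_key or row.box_id
        if row.url is not None and any(c.isspace() for c in row.url):
            report.error(ref, f"malformed url {row.url!r} (contains whitespace)")
        if not row.is_count_bearing or row.data_key not in active:
            continue
        try:
            value = row.count
        except CountParseError as exc:
            report.error(ref, str(exc))
            continue
        if isinstance(value, int):
            if value < 0:
                report.error(ref, f"negative count {value}")
        elif value == PLACEHOLDER:
            if strict:
                report.error(ref, "placeholder count 'xxx' not allowed in strict mode")
            else:
                report.warn(ref, "placeholder count 'xxx' (draft)")
        elif isinstance(value, ReasonBreakdown):
            for label, count in value.reasons:
                if isinstance(count, int) and count < 0:
                    report.error(ref, f"negative count for reason {label!r}")
                elif count == PLACEHOLDER:
                    if strict:
                        report.error(
                            ref,
                            f"placeholder count for reason {label!r} in strict mode",
                        )
                    else:
                        report.warn(ref, f"placeholder count for reason {label!r}")

    _arithmetic_warnings(fd, config, report)
    return report


def _arithmetic_warnings(
    fd: FlowData, config: "ArmConfig", report: ValidationReport
) -> None:
    """Advisory stage-to-stage accounting checks (never errors)."""

    def val(key: str) -> int | None:
        row = fd.get(key)
        if row is None:
            return None
        try:
            return _int_or_none(row.count)
        except CountParseError:
            return None

    def excl_total(key: str) -> int | None:
        row = fd.get(key)
        if row is None:
            return None
        try:
            return _reason_total(row.count)
        except CountParseError:
            return None

    def check(ref: str, lhs: int | None, rhs: int | None, what: str) -> None:
        if lhs is not None and rhs is not None and lhs != rhs:
            report.warn(ref, f"{what}: {lhs} != {rhs}")

    identified = _sum(val("database_results"), val("register_results"))
    removed = _sum(val("duplicates"), val("excluded_automatic"), val("excluded_other"))
    check(
        "records_screened",
        val("records_screened"),
        _sub(identified, removed),
        "records screened should equal records identified minus records removed before screening",
    )
    check(
        "dbr_sought_reports",
        val("dbr_sought_reports"),
        _sub(val("records_screened"), val("records_excluded")),
        "reports sought should equal records screened minus records excluded",
    )
    check(
        "dbr_assessed",
        val("dbr_assessed"),
        _sub(val("dbr_sought_reports"), val("dbr_notretrieved_reports")),
        "reports assessed should equal reports sought minus reports not retrieved",
    )
    new_from_dbr = _sub(val("dbr_assessed"), excl_total("dbr_excluded"))
    if config.include_other:
        check(
            "other_sought_reports",
            val("other_sought_reports"),
            _sum(
                val("website_results"),
                val("organisation_results"),
                val("citations_results"),
            ),
            "reports sought (other) should equal records identified via other methods",
        )
        check(
            "other_assessed",
            val("other_assessed"),
            _sub(val("other_sought_reports"), val("other_notretrieved_reports")),
            "reports assessed (other) should equal reports sought minus not retrieved",
        )
        new_from_other = _sub(val("other_assessed"), excl_total("other_excluded"))
        expected_new = _sum(new_from_dbr, new_from_other)
    else:
        expected_new = new_from_dbr
    check(
        "new_reports",
        val("new_reports"),
        expected_new,
        "new included reports should equal reports assessed minus reports excluded",
    )
    if config.include_previous:
        check(
            "total_studies",
            val("total_studies"),
            _sum(val("previous_studies"), val("new_studies")),
            "total studies should equal previous plus new studies",
        )
        check(
            "total_reports",
            val("total_reports"),
            _sum(val("previous_reports"), val("new_reports")),
            "total reports should equal previous plus new reports",
        )


def _sum(*values: int | None) -> int | None:
    if any(v is None for v in values):
        return None
    return sum(values)  # type: ignore[arg-type]


def _sub(a: int | None, b: int | None) -> int | None:
    if a is None or b is None:
        return None
    return a - b


# ---------------------------------------------------------------------------
# Example-data generator
# ---------------------------------------------------------------------------

_REASON_POOL = (
    "Wrong population",
    "Wrong intervention",
    "Wrong outcome",
    "Wrong study design",
    "Not in English",
    "Conference abstract only",
)


def _reason_string(rng: random.Random, total: int) -> str:
    """Split ``total`` across 2-4 named reasons, reason-list formatted."""
    k = rng.randint(2, min(4, max(2, total)))
    labels = rng.sample(_REASON_POOL, k)
    cuts = sorted(rng.sample(range(1, total), k - 1)) if total > k else []
    if len(cuts) == k - 1:
        bounds = [0, *cuts, total]
        counts = [bounds[i + 1] - bounds[i] for i in range(k)]
    else:  # tiny totals: give everything to the first reason
        counts = [total] + [0] * (k - 1)
    return "; ".join(f"{lab}, {cnt}" for lab, cnt in zip(labels, counts))


def generate_example_data(seed: int) -> FlowData:
    """A filled template with arithmetically consistent pseudo-random counts.

    The counts respect the stage accounting used by :func:`validate` (e.g.
    records screened = identified - removed before screening) and each
    full-text exclusion box carries 2-4 named reasons.  The same seed always
    yields the same FlowData.
    """
    rng = random.Random(seed)
    db = rng.randint(400, 2000)
    reg = rng.randint(20, 300)
    identified = db + reg
    dup = rng.randint(50, identified // 4)
    auto = rng.randint(0, 100)
    other_rm = rng.randint(0, 50)
    screened = identified - dup - auto - other_rm
    excluded = rng.randint(screened // 2, screened - 40)
    sought = screened - excluded
    notretrieved = rng.randint(0, sought // 5)
    assessed = sought - notretrieved
    dbr_excl_total = rng.randint(assessed // 2, assessed - 10)
    new_from_dbr = assessed - dbr_excl_total

    web = rng.randint(5, 60)
    org = rng.randint(0, 40)
    cit = rng.randint(0, 40)
    other_sought = web + org + cit
    other_notret = rng.randint(0, other_sought // 5)
    other_assessed = other_sought - other_notret
    other_excl_total = rng.randint(other_assessed // 2, max(other_assessed - 2, other_assessed // 2))
    new_from_other = other_assessed - other_excl_total

    new_reports = new_from_dbr + new_from_other
    new_studies = max(1, new_reports - rng.randint(0, new_reports // 3))
    prev_studies = rng.randint(2, 30)
    prev_reports = prev_studies + rng.randint(0, 10)

    counts = {
        "previous_studies": str(prev_studies),
        "previous_reports": str(prev_reports),
        "database_results": str(db),
        "register_results": str(reg),
        "website_results": str(web),
        "organisation_results": str(org),
        "citations_results": str(cit),
        "duplicates": str(dup),
        "excluded_automatic": str(auto),
        "excluded_other": str(other_rm),
        "records_screened": str(screened),
        "records_excluded": str(excluded),
        "dbr_sought_reports": str(sought),
        "dbr_notretrieved_reports": str(notretrieved),
        "other_sought_reports": str(other_sought),
        "other_notretrieved_reports": str(other_notret),
        "dbr_assessed": str(assessed),
        "dbr_excluded": _reason_string(rng, dbr_excl_total),
        "other_assessed": str(other_assessed),
        "other_excluded": _reason_string(rng, other_excl_total),
        "new_studies": str(new_studies),
        "new_reports": str(new_reports),
        "total_studies": str(prev_studies + new_studies),
        "total_reports": str(prev_reports + new_reports),
    }
    return blank_template().with_counts(counts)
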