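# Methods and design notes

## The diagram as a fixed template

A PRISMA 2020 flow diagram is not a general graph: it is a fixed inventory
of 22 nodes whose only degrees of freedom are (a) whether the
previous-studies and other-methods arms are drawn, (b) the text, counts,
tooltips and links supplied in the template CSV, and (c) cosmetics (fonts,
fills, arrow markers). `prismaflow` therefore contains no graph auto-layout:
`diagram_model` owns the inventory, the arm memberships and the 15-edge
connection table, and `layout_engine` places everything on a small logical
grid — columns for the side bars, the previous arm, the main chain, the main
exclusions, the other arm and its exclusions; rows for the title band and
the six review stages (identification, screening, retrieval, assessment,
inclusion, totals). The other-methods arm skips the screening row by
design: records found by hand go straight to full-text retrieval.

Arm memberships: the previous arm is the grey "Previous studies" title,
box 1 and the totals box 16 — totals are meaningless without the
previous-review counts, so the databases-and-registers-only layout ends at
"New studies included in review". The other arm is the grey "other methods"
title plus boxes 11–15. The yellow "new studies" title and the three blue
bars are always drawn. This yields 22/19/16/13 active nodes over the four
arm combinations. Enabling an arm is monotone: it adds nodes and edges and
never re-texts or moves main-arm content relative to its own grid.

## Data contract

Rows bind to boxes by exact `data`-key match. The `node`, `box` and
`description` columns are documentation: editing them cannot change the
rendered output (a property test asserts this), which protects users who
reorganise or annotate their CSV. The three title rows are keyless and are
located by their `box` cell. `NA` and the empty cell both mean absent.

The `n` grammar: integer, the `xxx` placeholder, or a reason list split on
`;` with the *last* comma in each segment separating label from count. The
last-comma rule is the most permissive reading of the published example
grammar — it lets labels like "Too old, too small" pass through unquoted.
A bare integer segment yields an unlabelled pair; anything else that is
neither integer nor `xxx` is a parse error naming the offending segment.

Validation distinguishes *errors* (missing keys required by the active
arms, negative or unparseable counts, whitespace in URLs, placeholders in
strict mode) from *warnings*. All stage arithmetic — screened = identified
− removed; sought = screened − excluded; assessed = sought − not retrieved;
new reports = assessed − excluded per arm; totals = previous + new — is
advisory only, because the diagram displays author-reported values and
legitimate reviews sometimes have counts that do not reconcile exactly
(e.g. reports feeding multiple studies).

## The example generator

`generate_example_data(seed)` emulates the filled template of a completed
medium-sized review: 400–2000 database hits, a smaller register yield,
removal of duplicates/automated exclusions before screening, a 50–90 %
title-abstract exclusion rate, a small retrieval failure rate, and 2–4
named full-text exclusion reasons per arm whose counts partition the
excluded total. All stage identities hold *exactly* by construction, so
generated data passes strict validation with zero warnings. What it does
not emulate: inconsistent or missing counts, studies-vs-reports mismatches,
non-ASCII text, very long reason labels, or empty arms — tests that need
those construct them explicitly. Passing tests on generated data therefore
demonstrate the pipeline's behaviour on well-formed input; the hostile-input
properties (markup escaping, CSV round-tripping, malformed counts) are
exercised by dedicated fuzz tests instead.

## Geometry and numerical choices

Canvas units are abstract and interpreted as points (72/inch) by the
renderers. Defaults: 230 pt box columns, 36 pt bar column, 50/36 pt
column/row gaps, 11 pt text on 15 pt lines, 8 pt box padding. Text is
greedily word-wrapped to a character budget of ``(width − 2·padding) /
(0.55·font size)`` — a width heuristic, not font metrics, so extreme font
substitutions can over- or under-fill boxes (a known limitation). Box
height grows linearly with wrapped line count; each grid row takes the
height of its tallest box, so a box gaining reason lines re-spaces its row
and overlap-freedom is preserved (property-tested across all 8
configurations × fuzzed reason counts).

Edges exit bottom→top or right→left as straight segments when their anchors
align (guaranteed within a column/row by construction); the two cross-column
edges — other arm into "New studies included" and box 1 down the previous
column into the totals box — use a single elbow at the target row's centre
line, entering the target's right and left side respectively. In this fixed
template no two edges share a routing channel, so no offsetting is needed;
the router would fall back to a mid-gap elbow if anchors ever misaligned.

Side-bar labels are rotated 90° and centred on the bar rectangle's midpoint;
`rotate_side_labels` recomputes the centre from placed geometry, so labels
track their bars as arms collapse, and the operation is idempotent. Bars
span fixed stage rows: identification row 1; screening rows 2–4; included
row 5, extending to the totals row 6 only while the previous arm is active.

Default colours are chosen to be recognisably grey (`#BFBFBF`), yellow
(`#FFD966`) and blue (`#9DC3E6`) rather than claimed to match any published
rendering bit-for-bit; all are overridable through `StyleSpec`.

## Rendering channels

SVG is the static ground truth: one `<g>` per box (rect + text lines, hover
`<title>` tooltips — SVG cannot script richer popups), one marker-tipped
path per edge, byte-deterministic. The interactive HTML page embeds the
same SVG inline; boxes with a `url` are wrapped in declarative `<a>`
anchors and a small embedded script adds hover feedback. No
script-injection machinery is needed because the anchors and titles are
part of the document itself. The standalone file embeds its style and
script; the zip flavour stores `index.html`, `style.css` and (when
interactive) `script.js` as separate members with fixed timestamps so the
archive is reproducible. DOT output carries the same labels, tooltips and
edges with explicit `pos="x,y!"` positions and `splines=ortho`, for users
who want to re-layout with an external engine.

PDF, PNG, PS and WEBP are drawn from the identical `PositionedDiagram`
geometry with matplotlib (WEBP written through Pillow), so the static
exports show exactly what the SVG shows; interactivity is inherently
dropped in these formats. Raster size scales with the `scale` factor
(dpi = 72·scale). Vector/raster bytes are not guaranteed stable across
library versions; the text formats (svg/html/dot/zip) are.

## Known limitations

- Text measurement is heuristic (see above); no automatic font embedding.
- One hyperlink and one tooltip per box: where several CSV rows share a
  box, the first non-absent value wins (the shipped template only ever
  sets them on a box's first row).
- No xlsx input, no computation of counts from reference-manager exports,
  no web front end — the CSV and the CLI are the interfaces.
- PDF output carries no hyperlinks; interactivity is an HTML-only feature.
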