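# prismaflow

PRISMA 2020-compliant systematic-review flow diagrams from a CSV template —
static (SVG, PDF, PNG, PS, WEBP, DOT) and interactive (self-contained HTML
with per-box tooltips and hyperlinks).

## The problem

Systematic reviews are expected to report the fate of every record they
handle: how many were identified in databases and registers, how many were
removed before screening, screened, excluded, sought and retrieved in full
text, assessed for eligibility (with named exclusion reasons), and finally
included. The PRISMA 2020 reporting guideline standardises this as a flow
diagram with two optional arms — studies carried over from a *previous
version* of the review, and records found via *other methods* (websites,
organisations, citation searching) — flanked by vertical bars marking the
identification, screening and inclusion stages.

`prismaflow` turns a small template CSV of these counts into that diagram.
Because the input is a data file rather than a drawing, the figure is
reproducible, shareable and updateable; and because boxes can carry
hyperlinks and tooltips, the diagram doubles as an interactive site map of
the review: readers click a box to reach the underlying methods, data or
search results.

## The model

The diagram is a fixed template of 22 nodes: 16 data boxes (`box 1` ...
`box 16`), three title boxes and three blue stage bars. Every node's text,
count, tooltip and link come from one 30-row, 8-column CSV
(`data,node,box,description,boxtext,tooltips,url,n`); values are matched to
boxes by their `data` key, never by row position. The `n` column holds a
non-negative integer, the draft placeholder `xxx`, or a reason list

```
Wrong population, 15; Wrong outcome, 7
```

whose segments split on `;` and whose *last* comma separates label from
count (labels may contain commas). Disabling an arm removes its nodes —
22 / 19 / 16 / 13 nodes with both arms / no previous / no other / neither —
and every arrow touching them; boxes are placed on a fixed grid and arrows
are routed as axis-aligned polylines. Stage arithmetic (e.g. records
screened = records identified − records removed before screening) is checked
but only ever *warns*: the numbers in a flow diagram are the author's
reported values.

## Worked example

```python
import prismaflow as pf

fd = pf.generate_example_data(seed=1)       # or pf.read_template("review.csv")
config = pf.ArmConfig(include_previous=True, include_other=True)
g = pf.build_graph(fd, config)
print(len(g.nodes), len(g.edges))           # 22 15
pf.save(fd, config, req="flow_full.svg")
```

Running `python examples/02_static_svg.py` prints:

```
wrote flow_full.svg
boxes drawn: 22  arrows drawn: 15
canvas: 1476 x 683 points
records identified: 727
records screened:   566
new studies included: 32
```

727 records entered the review (675 database + 52 register hits), 566
survived de-duplication and automated triage to be screened, and 32 new
studies made it into the review; each box in `flow_full.svg` shows the count
for its stage, and the exclusion boxes list the per-reason breakdown.
`examples/04_arm_configurations.py` shows the four layouts, and
`examples/03_interactive_html.py` builds the clickable, tooltipped HTML
version. The equivalent shell commands:

```
prismaflow template --out blank.csv        # the CSV to fill in
prismaflow example --seed 1 --out demo.csv
prismaflow draw --csv demo.csv --out flow.html --interactive
prismaflow draw --csv demo.csv --out flow.pdf --no-previous
```

## Layout

- `src/prismaflow/flow_data.py` — template CSV I/O, reason parsing,
  validation, the seeded example generator
- `src/prismaflow/diagram_model.py` — the 22-node topology and arm logic
- `src/prismaflow/layout_engine.py` — grid placement, box sizing,
  orthogonal edge routing, rotated bar labels
- `src/prismaflow/render.py` — SVG / interactive HTML / DOT serialization
- `src/prismaflow/export.py`, `src/prismaflow/cli.py` — the save pipeline
  (all 8 formats) and the `prismaflow` command
- `docs/methods.md` — design notes: model, defaults, numerical choices,
  limitations
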