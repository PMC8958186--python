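"""Build the interactive HTML flow diagram: tooltips plus per-box hyperlinks.

Each box that carries a `url` in the template becomes a clickable link (to a
methods page, a data file, a repository deposit...), and each `tooltips`
entry appears on mouse-over. The page is fully self-contained: open it
offline in any browser.
"""

import re

import prismaflow as pf

fd = pf.generate_example_data(seed=1)
config = pf.ArmConfig(interactive=True)

path = pf.save(fd, config, req="flow_interactive.html")
html = path.read_text(encoding="utf-8")

anchors = re.findall(r'<a href="([^"]*)">', html)
tooltips = html.count("<title>")
print(f"wrote {path}")
print(f"clickable boxes: {len(anchors)} (first three: {anchors[:3]})")
print(f"hover tooltips:  {tooltips}")
# Every box with a url in the template is wrapped in an anchor; boxes
# without one are inert. A static save (svg/pdf/png) drops the links.
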