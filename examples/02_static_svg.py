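"""Render a static SVG flow diagram from seeded example data.

The example generator fills the template with arithmetically consistent
counts (screened = identified - removed before screening, and so on), which
is what a finished review's template looks like.
"""

import prismaflow as pf

fd = pf.generate_example_data(seed=1)
config = pf.ArmConfig(include_previous=True, include_other=True)

g = pf.build_graph(fd, config)
pd = pf.layout(g)
path = pf.save(fd, config, req="flow_full.svg")

print(f"wrote {path}")
print(f"boxes drawn: {len(g.nodes)}  arrows drawn: {len(g.edges)}")
print(f"canvas: {pd.canvas[0]:.0f} x {pd.canvas[1]:.0f} points")
v = fd.by_key
print(f"records identified: {int(v['database_results'].count) + int(v['register_results'].count)}")
print(f"records screened:   {v['records_screened'].count}")
print(f"new studies included: {v['new_studies'].count}")
# 22 boxes / 15 arrows is the full layout with both optional arms; the counts
# flow top-to-bottom from identification to the included studies.
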