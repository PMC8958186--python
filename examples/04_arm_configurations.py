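"""Toggle the previous-studies and other-methods arms.

An updated review carries studies over from its previous version (previous
arm, with the totals box); reviews that searched websites, organisations or
citation lists report those separately (other-methods arm). Either arm can
be switched off and the layout collapses around what remains.
"""

import prismaflow as pf

fd = pf.generate_example_data(seed=1)

for prev, other, label in [
    (True, True, "full"),
    (False, True, "no previous arm"),
    (True, False, "no other-methods arm"),
    (False, False, "databases and registers only"),
]:
    config = pf.ArmConfig(include_previous=prev, include_other=other)
    g = pf.build_graph(fd, config)
    pd = pf.layout(g)
    name = f"flow_{label.replace(' ', '_')}.svg"
    pf.save(fd, config, req=name)
    span = pf.active_side_bar_span(g, "included")
    print(f"{label:30s} boxes={len(g.nodes):2d} arrows={len(g.edges):2d} "
          f"width={pd.canvas[0]:4.0f}pt included-bar rows={span}")
# Node counts 22/19/16/13: disabling an arm removes its boxes and every
# arrow touching them; the blue 'Included' bar shrinks to a single row once
# the totals box (previous arm) is gone.
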