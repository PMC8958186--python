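"""Save one diagram in every supported output format.

svg/html/dot are native text documents; zip-html stores the page with its
style and script as separate archive members; pdf/png/ps/webp are drawn from
the same geometry (interactivity is dropped, as raster/print formats cannot
carry it).
"""

import prismaflow as pf

fd = pf.generate_example_data(seed=1)
config = pf.ArmConfig(interactive=True)

ext = {"zip-html": "zip"}
for fmt in pf.FORMATS:
    path = pf.save(fd, config,
                   req=pf.SaveRequest(f"flow.{ext.get(fmt, fmt)}", format=fmt))
    print(f"{fmt:9s} -> {path} ({path.stat().st_size} bytes)")
# The format is normally inferred from the extension: pf.save(fd, req='x.pdf')
# is enough. Unknown extensions fail loudly with the supported list.
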