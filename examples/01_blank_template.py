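"""Emit the blank template CSV and look at what a review author must fill in.

The template is the single input to every diagram: 30 rows, 8 columns, with
`xxx` placeholders in the `n` column where the review's record counts go.
"""

import io

import prismaflow as pf

text = pf.generate_blank_template("blank_template.csv")
fd = pf.read_template(io.StringIO(text))

print(f"wrote blank_template.csv: {len(fd.rows)} rows")
print("count-bearing keys a review author fills in:")
for key in pf.flow_data.COUNT_DATA_KEYS:
    print(f"  {key:28s} -> {fd.by_key[key].boxtext}")

report = pf.validate(fd, pf.ArmConfig(), strict=False)
print(f"\ndraft validation: {len(report.errors)} errors, "
      f"{len(report.warnings)} placeholder warnings")
# Zero errors with warnings only: the blank template is drawable as a draft,
# every 'xxx' will appear verbatim in the boxes until real counts replace it.
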