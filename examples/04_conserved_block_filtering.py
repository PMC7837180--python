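"""Select conserved alignment blocks with the default filtering rules.

A 40-column status string (H = highly conserved, C = conserved,
N = nonconserved, g = gap column) is pushed through the four selection
rules; the retained ranges and a human-readable track are printed.
"""

from phylocore.blockfilter import BlockFilterParams, report_text, select_blocks

# defaults for 10 sequences: IS=6, FS=9, CP=8, BL=10, no gaps allowed
params = BlockFilterParams.defaults(10)
status = "H" * 10 + "N" * 9 + "H" * 10 + "g" + "N" + "H" * 9

blocks = select_blocks(status, params)
print(report_text(status, blocks))
print(f"retained ranges (0-based, half-open): {blocks}")
print(f"columns kept: {sum(b - a for a, b in blocks)} of {len(status)}")
# The 9-column nonconserved run exceeds the 8-column stretch limit, the
# gap column drags its neighboring nonconserved column down with it, and
# the trailing 9-column block fails the 10-column minimum length.
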