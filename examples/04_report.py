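"""Render an HTML report comparing two platforms from snapshots alone.

Builds statistics for a HiFi-like and an ONT-ultralong-like dataset and
renders the standard four panels (length violins, length density,
inverse cumulative length, length-vs-quality contours) plus the summary
table into one self-contained file.
"""

import tempfile
from pathlib import Path

from readqc import aggregate, generate_summaries
from readqc.report import render_report

hifi = aggregate(generate_summaries("hifi", 2000, seed=1))
ont = aggregate(generate_summaries("ont_ul", 2000, seed=2))

out = Path(tempfile.mkdtemp()) / "report.html"
render_report([hifi, ont], out, labels=["HiFi-like", "ONT-UL-like"],
              mode="interactive")
print(f"report written: {out} ({out.stat().st_size} bytes)")
print(f"HiFi N50 {hifi.n50} bp vs ONT-UL N50 {ont.n50} bp")
# Open the file in a browser: checkboxes toggle datasets on every panel
# and each panel can be exported as PNG.
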