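"""Homopolymer-compress reads and measure the shrinkage.

Collapses every run of identical bases to one copy (the usual assembly
preprocessing) and reports the fractional base-count reduction.  On
i.i.d. uniform sequence the expected reduction is 25% (a base repeats
its predecessor with probability 1/4); repeat-enriched sequence shrinks
more.
"""

from dataclasses import replace

from readqc import generate_records, hc_size_reduction
from readqc.simulate import get_profile

plain = list(generate_records("hifi", 100, seed=5))
print(f"i.i.d. uniform sequence:  {hc_size_reduction(iter(plain), 1):.1%}")

enriched_profile = replace(get_profile("hifi"), repeat_prob=0.35)
enriched = list(generate_records(enriched_profile, 100, seed=5))
print(f"repeat-enriched sequence: {hc_size_reduction(iter(enriched), 1):.1%}")
# Each maximal run contributes one base after collapse, so the reduction
# equals 1 - (number of runs) / (number of bases).
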