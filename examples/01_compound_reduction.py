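"""Reduce a raw 45-peak glucosinolate screen to the analysis compound set.

Builds a synthetic flag table shaped like a real HPLC-MS screen (some
peaks unconfirmed as GS, some late-eluting likely dimers, some
indistinguishable co-eluters) and applies the reduction rules.
"""

from chemosignal.profiles import CompoundRecord, reduce_compound_list
from chemosignal.simulate import example_compound_flags

flags = example_compound_flags()
records = [
    CompoundRecord(r.compound, r.retention_time_min, r.identified_as_gs,
                   r.merge_group or None)
    for r in flags.itertuples()
]
retained, merges = reduce_compound_list(records)

print(f"detected peaks:      {len(records)}")
print(f"retained compounds:  {len(retained)}")
print(f"co-elution merges:   {merges}")
print()
print("Retained compounds enter every downstream profile, distance and")
print("dendrogram computation; merged co-eluters are summed, so total GS")
print("mass is conserved through the reduction.")
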