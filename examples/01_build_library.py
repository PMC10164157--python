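"""Build a combinatorial guide library and inspect its pair classes.

A dual-cassette library is the full cross product of two guide lists.  The
default design targets 10 core-essential (CE) and 10 tumor-suppressor (TS)
genes with 4 guides each, plus 80 non-targeting (NHT) controls per cassette:
160 x 160 = 25,600 guide combinations.
"""

from duoscreen import SimulationConfig, pam_filter, synthetic_library

library = synthetic_library(SimulationConfig(design="multiSPAS"), seed=0)

print(f"design: {library.design.name}")
print(f"guides per cassette: {len(library.guides_pos1)} x {len(library.guides_pos2)}")
print(f"combinations: {library.n_combinations}")
print("\npair-class tallies (who targets what):")
print(library.class_counts().to_string())

# AsCas12a guides carry an upstream PAM context; TTTV is the canonical motif
cas12a_guides = library.guides_pos2
tttv = pam_filter(cas12a_guides, "TTTV")
print(f"\nAsCas12a guides with canonical TTTV PAM: {len(tttv)} / {len(cas12a_guides)}")
print("(analyses can be restricted to this subset to compare nuclease variants)")
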