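"""Dimer/hairpin screen of the published 24-marker primer panel.

Scores every primer pair combination (self, cross and hairpin) by the
maximum ungapped complementarity (matches minus mismatches) and reports
combinations at or above the conservative threshold of 7 - candidates to
avoid when building multiplex PCR sets.
"""

from camkit import flag_incompatible, load_paper_fixtures

panel = load_paper_fixtures().primer_panel()
flags = flag_incompatible(panel)

print(f"{len(panel)} primers screened; {len(flags)} flagged at threshold 7")
for f in flags:
    print(f"  {f.name1} x {f.name2}  kind={f.kind}  score={f.score}  offset={f.offset}")
print()
print("Flagged combinations should not be co-multiplexed without empirical checks.")
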