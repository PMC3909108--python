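"""Enumerate candidate phospho-configurations and their site-determining ions.

For a mono-phosphorylated peptide with two candidate sites, build both
theoretical ladders and show which fragment ions can actually discriminate
between the placements.
"""

from phosloc import (
    apply_coincidence_rules,
    build_ladders,
    enumerate_configurations,
    flag_site_determining,
    parse_label,
)

hit = parse_label("PQS*VLTK", precursor_charge=2)
cset = enumerate_configurations(hit)
print("candidate configurations:", ", ".join(c.label for c in cset.configurations))

build_ladders(cset)
flag_site_determining(cset, tolerance=0.05)
apply_coincidence_rules(cset, tolerance=0.05)

for config, ladder, targets in zip(
    cset.configurations, cset.ladders, cset.scoring_targets
):
    sd = sorted({f"{i.spec.series}{i.spec.index}" for i in ladder if i.site_determining})
    n_sd_targets = sum(t.site_determining for t in targets)
    print(f"{config.label}: site-determining series {sd}, "
          f"{n_sd_targets} scoring targets after coincidence filtering")

print(f"{len(cset.discarded_ions)} theoretical ions were discarded because "
      "coincident m/z values cannot attribute intensity to one placement.")
# Site-determining ions lie between the two candidate sites (b3-b5, y2-y4):
# only peaks in that stretch of the ladder carry localization evidence.
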