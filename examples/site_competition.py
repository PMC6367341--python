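"""Locate the ligand's binding site by marker displacement.

Simulates fluorescence of the ligand-protein complex titrated with site
probes: the site-I marker displaces strongly, the site-II marker barely,
and the site-III dansyl probe shows the step-then-flat cooperative
pattern that is excluded from the verdict.
"""

from albind import assign_site
from albind.synthetic import gen_competition

curves = gen_competition(noise=0.005, seed=4)
site, ranking, ambiguous = assign_site(curves, min_drop=0.10)

for row in ranking:
    tag = " (cooperative, excluded)" if row["step_then_flat"] else ""
    print(f"{row['probe']:>20}: drop {row['drop']:5.1%}, "
          f"slope {row['slope']:+.3f}/ratio{tag}")
print(f"assigned site: {site}  (ambiguous: {ambiguous})")
# The top-ranked monotone probe is the site-I marker with a ~35% intensity
# drop, well clear of the other sites: the ligand binds at Sudlow site I.
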