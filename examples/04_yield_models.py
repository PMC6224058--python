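"""Test cultivar and species effects on forage yield with mixed models.

Simulates four years of annual dry-matter yields for the 14-plot trial and
runs the three hypothesis tests: ryegrass cultivar and clover presence
(compositions 1-4), ryegrass component (3-5) and clover component (5-7),
each by a likelihood-ratio test on ML mixed-model fits with random replicate
and year intercepts.
"""

import swardpop as sp

yields = sp.simulate_yield(seed=5)  # defaults: clover +2 t/ha, Meloni +1
print(yields.groupby("seed_composition")["dmw_total"].mean().round(2)
      .to_string())
print("compositions with clover (3-7) outyield the pure-ryegrass plots.")

for hyp in ("H1a", "H1b", "H1c", "H2a", "H3a"):
    got = sp.test_hypothesis(yields, hyp)
    print(f"{hyp}: {got['tested_term']:25s} chi2 = {got['chi2']:7.2f} "
          f"df = {got['df']}  p = {got['p']:.2e}")
print("the clover-presence and cultivar terms are strongly supported; the "
      "interaction (H1a) is null by construction in the generator defaults.")

dmw = sp.dry_matter_weight(10.8, 450, 90, area_ha=10.8e-4)
print(f"worked DMW example: 10.8 kg fresh, 20% dry matter on a 6 x 1.8 m "
      f"plot -> {dmw:.1f} t/ha")
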