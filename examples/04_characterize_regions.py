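"""Cross-contrast classification and composition summaries of mtDMRs.

Builds a small fixture of regions across the four contrasts and prints the
between-sex Venn view (lost / gained / remained under stress), the a-d
class of each merged region identity, and CpN absence fractions.
"""

from mtmedip.characterize import cpn_absence_fraction, cross_contrast, direction_balance
from mtmedip.dmr import MtDMR
from mtmedip.synthetic import SimulationConfig, make_genome

genome = make_genome(SimulationConfig(seed=5, genome_length=6000))
regions = {
    "MCvsFC": [MtDMR("MCvsFC", 100, 150, direction="hypo"),
               MtDMR("MCvsFC", 1000, 1050, direction="hyper")],
    "MSvsFS": [MtDMR("MSvsFS", 120, 170, direction="hypo"),
               MtDMR("MSvsFS", 4000, 4040, direction="hypo")],
    "MCvsMS": [MtDMR("MCvsMS", 2500, 2550, direction="hypo")],
    "FCvsFS": [MtDMR("FCvsFS", 2510, 2560, direction="hyper")],
}

print("hypo:hyper per contrast:", direction_balance(regions))
classifications, counts = cross_contrast(regions)
print(f"lost {counts['lost']}, gained {counts['gained']}, remained {counts['remained']}"
      f" (between-sex comparisons before vs after stress)")
for c in classifications:
    print(f"  {c.start}-{c.end}: contrasts {c.contrasts_present} -> class {c.dmr_class},"
          f" venn {c.venn_status}")
absence = cpn_absence_fraction([r for rs in regions.values() for r in rs], genome)
print("percent of regions lacking each context entirely:", absence)
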