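"""Gap-scan clustering of significant CpN positions into mtDMRs.

Uses the published scan summary — four stable plateaus of the region-count
step function — to show the consecutive-index selection rule, then clusters
a toy position set at the chosen gap length.  Printed: each plateau's CI,
the selected gap length x (the smallest x of the lowest-CI plateau, here
127), and the regions a toy set of positions merges into.
"""

from mtmedip.dmr import Plateau, cluster_positions, gap_scan, select_gap_length

plateaus = [Plateau(127, 179, 21), Plateau(210, 284, 16),
            Plateau(389, 522, 11), Plateau(659, 882, 6)]
for p in plateaus:
    print(f"x in [{p.x_min}, {p.x_max}]: {p.region_count} regions, CI = {p.ci}")
x_star = select_gap_length(plateaus)
print(f"selected gap length x = {x_star}")

positions = [100, 140, 190, 1500, 1580, 1610, 5000]
print(f"\ntoy scan of positions {positions}:")
for p in gap_scan(positions, x_max=600):
    print(f"  x in [{p.x_min}, {p.x_max}]: {p.region_count} regions (CI {p.ci})")
for start, end, members in cluster_positions(positions, x_star):
    print(f"region {start}-{end} with {len(members)} member sites")
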