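"""Reproduce reference-genome statistics on externally supplied data.

The repository bundles no reference sequences, so this script takes paths
to files the user downloads themselves and re-runs the library code paths
on them:

* a mitochondrial reference FASTA (e.g. galGal6 chrMT, expected 16,775 bp
  with base composition near A 30.3 / T 23.8 / C 32.5 / G 13.5 %);
* optionally one or more PWM files (JASPAR PFM or MEME minimal text, e.g.
  the ATF4 / ZNF324 / HNF4A matrices) scanned at p < 1e-4 with hit counts
  and heavy/light strand percentages printed per matrix;
* optionally an mtDMR BED file whose regions are then summarised for
  per-context CpN absence fractions.

Usage:
    python examples/real_data_repro.py --genome chrMT.fa \
        [--pwm ATF4.pfm --pwm ZNF324.pfm] [--regions mtdmrs.bed]
"""

import argparse
import sys
from pathlib import Path


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--genome", required=True, help="mitochondrial reference FASTA")
    ap.add_argument("--pwm", action="append", default=[], help="PWM file (repeatable)")
    ap.add_argument("--regions", default=None, help="mtDMR BED file")
    ap.add_argument("--motif-p", type=float, default=1e-4)
    args = ap.parse_args(argv)

    for path in [args.genome, *args.pwm, *( [args.regions] if args.regions else [])]:
        if not Path(path).exists():
            print(f"error: input file not found: {path}", file=sys.stderr)
            return 2

    from mtmedip.characterize import cpn_absence_fraction
    from mtmedip.dmr import MtDMR
    from mtmedip.genome_io import base_composition, find_cpn_sites, read_features, read_genome
    from mtmedip.motifs import read_pwm, scan, strand_summary

    genome = read_genome(args.genome)
    comp = base_composition(genome)
    print(f"genome {genome.id}: {len(genome)} bp")
    print("base composition (%): " + ", ".join(
        f"{b} {100 * v:.1f}" for b, v in comp.as_dict().items()))
    print(f"CpN sites on the plus strand: {len(find_cpn_sites(genome))}")

    for pwm_path in args.pwm:
        pwm = read_pwm(pwm_path)
        hits = scan(genome, pwm, p_threshold=args.motif_p)
        split = strand_summary(hits)
        split_txt = "n/a" if split is None else (
            f"{split['heavy']}% heavy / {split['light']}% light")
        print(f"{pwm.name}: {len(hits)} hits at p<{args.motif_p:g} ({split_txt})")

    if args.regions:
        feats = read_features(args.regions)
        regions = [MtDMR(contrast="all", start=f.start, end=f.end) for f in feats]
        absence = cpn_absence_fraction(regions, genome)
        print(f"{len(regions)} regions; CpN absence (%): " + ", ".join(
            f"{k} {v:.1f}" for k, v in absence.items()))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
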