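"""Genome and annotation IO, CpN-site enumeration, base composition.

Coordinates are 1-based and inclusive throughout, matching the convention
used for mitochondrial region reports (e.g. "bp 7499-7717").  BED input is
0-based half-open and converted on read.  Mitochondrial genomes are circular
by default; the topology flag controls interval fetching and, downstream,
read simulation and alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "CircularGenome",
    "GenomeFeature",
    "CpNSite",
    "BaseComposition",
    "read_genome",
    "read_features",
    "write_fasta",
    "base_composition",
    "find_cpn_sites",
    "reverse_complement",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: GFF/GTF feature types collapsed onto the small kind vocabulary used here.
_KIND_MAP = {
    "cds": "CDS",
    "gene": "CDS",
    "trna": "tRNA",
    "rrna": "rRNA",
    "d_loop": "control_region",
    "d-loop": "control_region",
    "control_region": "control_region",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CpNSite:
    """A plus-strand cytosine and the identity of its 3' neighbour."""

    position: int  # 1-based index of the C
    context: str  # one of CpA, CpT, CpC, CpG


@dataclass(frozen=True)
class GenomeFeature:
    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "heavy"  # heavy | light
    kind: str = "other"  # CDS | tRNA | rRNA | control_region | other

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad feature coordinates {self.start}..{self.end}")
        if self.strand not in ("heavy", "light"):
            raise ValueError(f"strand must be heavy or light, got {self.strand!r}")


@dataclass
class BaseComposition:
    freq_A: float
    freq_T: float
    freq_C: float
    freq_G: float

    def as_dict(self) -> dict[str, float]:
        return {"A": self.freq_A, "T": self.freq_T, "C": self.freq_C, "G": self.freq_G}


@dataclass
class CircularGenome:
    """A nucleotide sequence with topology flag and strand-annotated features.

    ``plus_is_heavy`` records which physical mtDNA strand the FASTA plus
    strand represents; it only affects strand *labels* (heavy/light), never
    coordinates.
    """

    id: str
    sequence: str
    circular: bool = True
    features: list[GenomeFeature] = field(default_factory=list)
    plus_is_heavy: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"genome {self.id!r} contains non-nucleotide characters: {sorted(bad)}"
            )
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(f"feature {f.name} extends past genome end")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence for 1-based inclusive [start, end], wrapping if circular.

        ``end`` may exceed L on a circular genome, meaning wrap past the
        origin (fetch(L-1, L+2) is the last two bases followed by the first
        two).
        """
        L = len(self.sequence)
        if start < 1 or start > L or end < start:
            raise ValueError(f"bad interval {start}..{end} on genome of length {L}")
        if end <= L:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ValueError(f"interval {start}..{end} runs off a linear genome")
        if end - start + 1 > L:
            raise ValueError("interval longer than the genome")
        return self.sequence[start - 1 :] + self.sequence[: end - L]

    def strand_label(self, strand: str) -> str:
        """Map an alignment strand ('+'/'-') to a heavy/light label."""
        if strand not in "+-":
            raise ValueError(f"strand must be + or -, got {strand!r}")
        if self.plus_is_heavy:
            return "heavy" if strand == "+" else "light"
        return "light" if strand == "+" else "heavy"


def read_genome(
    path: str | Path,
    annotation: str | Path | None = None,
    circular: bool = True,
    plus_is_heavy: bool = True,
) -> CircularGenome:
    """Read a single-record FASTA (case-normalised) plus optional GFF3/BED."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(f"expected a single record in {path}, found {len(records)}")
    rec = records[0]
    features = read_features(annotation) if annotation is not None else []
    return CircularGenome(
        id=rec.id,
        sequence=str(rec.seq),
        circular=circular,
        features=features,
        plus_is_heavy=plus_is_heavy,
    )


def read_genomes(path: str | Path, circular: bool = False) -> list[CircularGenome]:
    """Read a multi-record FASTA (e.g. nuclear decoy contigs)."""
    return [
        CircularGenome(id=r.id, sequence=str(r.seq), circular=circular)
        for r in SeqIO.parse(str(path), "fasta")
    ]


def _classify_kind(feature_type: str, name: str) -> str:
    k = _KIND_MAP.get(feature_type.lower())
    if k:
        return k
    n = name.lower()
    if n.startswith("trna"):
        return "tRNA"
    if "rrna" in n or re.match(r"^(12s|16s)", n):
        return "rRNA"
    if "d-loop" in n or "control" in n:
        return "control_region"
    return "other"


def _strand_to_label(s: str, plus_is_heavy: bool = True) -> str:
    if s == "-":
        return "light" if plus_is_heavy else "heavy"
    return "heavy" if plus_is_heavy else "light"


def read_features(path: str | Path, plus_is_heavy: bool = True) -> list[GenomeFeature]:
    """Read features from GFF3 or BED, sniffing the format.

    BED (3 or 6 columns, 0-based half-open) is converted to the 1-based
    inclusive convention used everywhere else.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".bed":
        return _parse_bed(text, plus_is_heavy)
    if path.suffix.lower() in (".gff", ".gff3", ".gtf"):
        return _parse_gff(text, plus_is_heavy)
    # sniff: GFF data lines have 9 tab-separated columns
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        ncol = len(line.split("\t"))
        return _parse_gff(text, plus_is_heavy) if ncol >= 8 else _parse_bed(text, plus_is_heavy)
    return []


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def _parse_gff(text: str, plus_is_heavy: bool) -> list[GenomeFeature]:
    feats = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 8:
            raise ValueError(f"malformed GFF line: {line!r}")
        ftype, start, end, strand = cols[2], int(cols[3]), int(cols[4]), cols[6]
        attrs = dict(_GFF_ATTR.findall(cols[8])) if len(cols) > 8 else {}
        name = attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or ftype
        feats.append(
            GenomeFeature(
                name=name,
                start=start,
                end=end,
                strand=_strand_to_label(strand, plus_is_heavy),
                kind=_classify_kind(ftype, name),
            )
        )
    return feats


def _parse_bed(text: str, plus_is_heavy: bool) -> list[GenomeFeature]:
    feats = []
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.rstrip("\n").split("\t")
        chrom_start, chrom_end = int(cols[1]), int(cols[2])
        name = cols[3] if len(cols) > 3 else f"region_{chrom_start}"
        strand = cols[5] if len(cols) > 5 else "+"
        feats.append(
            GenomeFeature(
                name=name,
                start=chrom_start + 1,  # BED is 0-based half-open
                end=chrom_end,
                strand=_strand_to_label(strand, plus_is_heavy),
                kind=_classify_kind("", name),
            )
        )
    return feats


def write_fasta(genomes: CircularGenome | Iterable[CircularGenome], path: str | Path) -> None:
    if isinstance(genomes, CircularGenome):
        genomes = [genomes]
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i : i + 70] + "\n")


def base_composition(genome: CircularGenome | str) -> BaseComposition:
    """A/T/C/G fractions; N bases are excluded from the denominator."""
    seq = genome.sequence if isinstance(genome, CircularGenome) else genome.upper()
    counts = {b: seq.count(b) for b in "ATCG"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return BaseComposition(
        freq_A=counts["A"] / total,
        freq_T=counts["T"] / total,
        freq_C=counts["C"] / total,
        freq_G=counts["G"] / total,
    )


def find_cpn_sites(genome: CircularGenome | str, wrap: bool = False) -> list[CpNSite]:
    """Enumerate plus-strand CpN sites in ascending position order.

    A site is a C whose successor is an unambiguous base; a C followed by N
    is not a site.  By default the final base is never a site (no circular
    wrap); with ``wrap=True`` on a circular genome a terminal C pairs with
    base 1.
    """
    seq = genome.sequence if isinstance(genome, CircularGenome) else genome.upper()
    if len(seq) < 2:
        raise ValueError("sequence too short for dinucleotide enumeration")
    sites = [
        CpNSite(position=i + 1, context=f"Cp{seq[i + 1]}")
        for i in range(len(seq) - 1)
        if seq[i] == "C" and seq[i + 1] in "ACGT"
    ]
    if wrap:
        circular = genome.circular if isinstance(genome, CircularGenome) else True
        if circular and seq[-1] == "C" and seq[0] in "ACGT":
            sites.append(CpNSite(position=len(seq), context=f"Cp{seq[0]}"))
    return sites
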