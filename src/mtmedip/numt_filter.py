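"""Nuclear-mitochondrial-pseudogene (NUMT) read decontamination.

NUMTs — nuclear copies of mtDNA — attract reads that would otherwise be
(mis)assigned to the mitochondrial chromosome and can fake mitochondrial
methylation signal.  The control is a four-step re-alignment scheme:

1. keep reads that align to exactly one place in the whole genome
   (mtDNA plus nuclear contigs);
2. re-align those unique reads to the genome *without* the mitochondrial
   chromosome;
3. keep the reads that do not align anywhere nuclear;
4. re-align the survivors to the mitochondrial sequence alone and keep
   the aligned ones.

Survivors therefore map uniquely, and only, to mtDNA.  A toy exhaustive
Hamming-distance aligner makes the step semantics testable end-to-end on
synthetic data; real alignments are accepted as SAM/BAM via pysam, where
"unique" is approximated by primary alignments with MAPQ > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .genome_io import CircularGenome, reverse_complement

__all__ = [
    "AlignmentHit",
    "FilterReport",
    "toy_align",
    "filter_numts",
    "unique_read_ids_sam",
    "filter_numts_sam",
]


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    target_id: str
    position: int  # 1-based start of the match on the target plus strand
    strand: str  # + | -
    mismatches: int

    def __post_init__(self) -> None:
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")


@dataclass
class FilterReport:
    n_input: int
    n_unique: int
    n_nuclear_aligned: int
    n_survivors: int

    @property
    def retained_fraction(self) -> float:
        return self.n_survivors / self.n_input if self.n_input else 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("n_input\tn_unique\tn_nuclear_aligned\tn_survivors\tretained_fraction\n")
            fh.write(
                f"{self.n_input}\t{self.n_unique}\t{self.n_nuclear_aligned}\t"
                f"{self.n_survivors}\t{self.retained_fraction:.6g}\n"
            )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def toy_align(
    reads: Mapping[str, str],
    genomes: Sequence[CircularGenome],
    max_mismatch: int = 2,
) -> list[AlignmentHit]:
    """Exhaustive Hamming-distance alignment of reads against genomes.

    Every occurrence of each read on either strand with at most
    ``max_mismatch`` substitutions is reported; circular targets are
    searched across the origin.  No indels (reads are simulated fragments
    of the same targets).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    hits: list[AlignmentHit] = []
    prepared = []
    for g in genomes:
        L = len(g)
        max_read = max((len(s) for s in reads.values()), default=0)
        ext = g.sequence + (g.sequence[: max_read - 1] if g.circular and max_read > 1 else "")
        prepared.append((g, L, _encode(ext)))
    for read_id, seq in reads.items():
        w = len(seq)
        for g, L, target in prepared:
            if w > L:
                raise ValueError(f"read {read_id} longer than target {g.id}")
            n_windows = (L if g.circular else L - w + 1)
            windows = np.lib.stride_tricks.sliding_window_view(target, w)[:n_windows]
            for strand, query in (("+", seq), ("-", reverse_complement(seq))):
                q = _encode(query)
                mism = (windows != q).sum(axis=1)
                for pos0 in np.flatnonzero(mism <= max_mismatch):
                    hits.append(
                        AlignmentHit(
                            read_id=read_id,
                            target_id=g.id,
                            position=int(pos0) + 1,
                            strand=strand,
                            mismatches=int(mism[pos0]),
                        )
                    )
    return hits


def _hits_by_read(hits: Sequence[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    out: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        out.setdefault(h.read_id, []).append(h)
    return out


def filter_numts(
    reads: Mapping[str, str],
    mt_genome: CircularGenome,
    nuclear_genomes: Sequence[CircularGenome],
    max_mismatch: int = 2,
    aligner: Callable[..., list[AlignmentHit]] = toy_align,
    wg_hits: Sequence[AlignmentHit] | None = None,
) -> tuple[set[str], FilterReport]:
    """Run the four-step NUMT control; returns surviving read ids + report.

    ``wg_hits`` may supply precomputed whole-genome alignments (step 1
    input); otherwise the aligner produces them.
    """
    n_input = len(reads)
    if n_input == 0:
        return set(), FilterReport(0, 0, 0, 0)
    if wg_hits is None:
        wg_hits = aligner(reads, [mt_genome, *nuclear_genomes], max_mismatch)
    by_read = _hits_by_read(wg_hits)
    # step 1: unique reads — exactly one whole-genome hit
    unique_ids = {rid for rid, hs in by_read.items() if len(hs) == 1}
    unique_reads = {rid: reads[rid] for rid in unique_ids}
    # steps 2+3: realign to the nuclear-only index, keep unaligned reads
    if nuclear_genomes and unique_reads:
        nuc_hits = aligner(unique_reads, list(nuclear_genomes), max_mismatch)
        nuclear_aligned = {h.read_id for h in nuc_hits}
    else:
        nuclear_aligned = set()
    non_nuclear = {rid: s for rid, s in unique_reads.items() if rid not in nuclear_aligned}
    # step 4: realign to mtDNA alone, keep aligned reads
    if non_nuclear:
        mt_hits = aligner(non_nuclear, [mt_genome], max_mismatch)
        survivors = {h.read_id for h in mt_hits}
    else:
        survivors = set()
    report = FilterReport(
        n_input=n_input,
        n_unique=len(unique_ids),
        n_nuclear_aligned=len(nuclear_aligned),
        n_survivors=len(survivors),
    )
    return survivors, report


# ---------------------------------------------------------------------------
# SAM/BAM path for real alignments
# ---------------------------------------------------------------------------


def _primary_records(path: str | Path):
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            yield rec


def unique_read_ids_sam(path: str | Path, min_mapq: int = 1) -> set[str]:
    """Read ids of primary alignments with MAPQ >= min_mapq.

    MAPQ > 0 with no secondary/supplementary records approximates the
    "aligned to no more than one region" extraction used on real data.
    """
    seen: dict[str, int] = {}
    quals: dict[str, int] = {}
    for rec in _primary_records(path):
        seen[rec.query_name] = seen.get(rec.query_name, 0) + 1
        quals[rec.query_name] = rec.mapping_quality
    return {rid for rid, n in seen.items() if n == 1 and quals[rid] >= min_mapq}


def filter_numts_sam(
    whole_genome: str | Path,
    nuclear_only: str | Path,
    mt_only: str | Path,
    min_mapq: int = 1,
) -> tuple[set[str], FilterReport]:
    """Four-step control over three pre-computed alignment files.

    The caller aligns the same reads to (a) the whole genome including the
    mitochondrial chromosome, (b) the genome without it, and (c) the
    mitochondrial sequence alone; the steps are then pure set operations.
    """
    all_ids = {rec.query_name for rec in _primary_records(whole_genome)}
    unique = unique_read_ids_sam(whole_genome, min_mapq)
    nuclear_aligned = {rec.query_name for rec in _primary_records(nuclear_only)}
    mt_aligned = {rec.query_name for rec in _primary_records(mt_only)}
    survivors = (unique - nuclear_aligned) & mt_aligned
    report = FilterReport(
        n_input=len(all_ids),
        n_unique=len(unique),
        n_nuclear_aligned=len(unique & nuclear_aligned),
        n_survivors=len(survivors),
    )
    return survivors, report
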