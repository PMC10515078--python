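"""Delimit mitochondrial differentially methylated regions (mtDMRs).

Significant CpN sites are merged into regions whenever adjacent sites are at
most ``x`` bp apart.  Because the region count as a function of ``x`` is a
non-increasing step function, scanning ``x`` over a range partitions it into
plateaus of constant region count.  The length of a plateau is its
*consecutive index* (CI): a long plateau means the clustering is insensitive
to the exact gap threshold there, while a short one sits at the edge of a
re-arrangement.  The working gap length is the smallest ``x`` of the
lowest-CI plateau — the most conservative scale at which the clustering is
sharply defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .diffmeth import DMCpN

__all__ = [
    "Plateau",
    "MtDMR",
    "compute_ci",
    "cluster_positions",
    "gap_scan",
    "select_gap_length",
    "build_mtdmrs",
    "write_mtdmr_tsv",
    "write_mtdmr_bed",
]


def compute_ci(x_min: int, x_max: int) -> int:
    """Consecutive index of a plateau: the inclusive count of gap lengths
    over which the region count stays constant (x_max - x_min + 1)."""
    if x_max < x_min:
        raise ValueError(f"x_max {x_max} < x_min {x_min}")
    return x_max - x_min + 1


@dataclass(frozen=True)
class Plateau:
    x_min: int
    x_max: int
    region_count: int

    @property
    def ci(self) -> int:
        return compute_ci(self.x_min, self.x_max)


@dataclass
class MtDMR:
    """A gap-merged run of significant CpN sites from one contrast.

    ``end`` extends one base past the last member C so the region covers
    that site's dinucleotide; hence a singleton region has length 2.
    """

    contrast: str
    start: int
    end: int
    members: list[DMCpN] = field(default_factory=list)
    direction: str = "hypo"  # hypo | hyper, sign of mean member log2fc

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "MtDMR", min_bp: int = 1) -> bool:
        return min(self.end, other.end) - max(self.start, other.start) + 1 >= min_bp


def cluster_positions(
    positions: Sequence[int], max_gap: int
) -> list[tuple[int, int, list[int]]]:
    """Maximal runs of positions with adjacent differences <= max_gap.

    Returns (start, end, member indices) triples; the gap between adjacent
    positions is the plain positional difference p[i+1] - p[i].
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    positions = list(positions)
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be strictly increasing")
    if not positions:
        return []
    regions = []
    run_start = 0
    for i in range(1, len(positions)):
        if positions[i] - positions[i - 1] > max_gap:
            regions.append(
                (positions[run_start], positions[i - 1], list(range(run_start, i)))
            )
            run_start = i
    regions.append(
        (positions[run_start], positions[-1], list(range(run_start, len(positions))))
    )
    return regions


def region_count(positions: Sequence[int], max_gap: int) -> int:
    """Number of merged regions at a given gap threshold (O(n))."""
    gaps = np.diff(np.asarray(positions, dtype=np.int64))
    if (gaps <= 0).any():
        raise ValueError("positions must be strictly increasing")
    return int((gaps > max_gap).sum()) + 1 if len(positions) else 0


def gap_scan(positions: Sequence[int], x_max: int = 1962, x_min: int = 1) -> list[Plateau]:
    """Plateaus of the region-count step function over x in [x_min, x_max].

    The count is non-increasing in x with breakpoints exactly at the
    distinct adjacent-gap values, so the plateaus can be read off the sorted
    gap multiset without evaluating every x individually.
    """
    if x_max < x_min or x_min < 1:
        raise ValueError("need 1 <= x_min <= x_max")
    positions = list(positions)
    if not positions:
        return []
    gaps = np.diff(np.asarray(positions, dtype=np.int64))
    if len(gaps) and (gaps <= 0).any():
        raise ValueError("positions must be strictly increasing")
    # counts for all x in the range, then maximal constant runs
    xs = np.arange(x_min, x_max + 1)
    counts = 1 + (gaps[None, :] > xs[:, None]).sum(axis=1) if len(gaps) else np.ones_like(xs)
    plateaus: list[Plateau] = []
    run_start = 0
    for i in range(1, len(xs) + 1):
        if i == len(xs) or counts[i] != counts[run_start]:
            plateaus.append(Plateau(int(xs[run_start]), int(xs[i - 1]), int(counts[run_start])))
            run_start = i
    assert all(a.region_count > b.region_count for a, b in zip(plateaus, plateaus[1:]))
    return plateaus


def select_gap_length(
    plateaus: Sequence[Plateau],
    min_x: int = 2,
    top: int | None = 4,
    min_ci: int | None = None,
) -> int:
    """Smallest gap length of the lowest-CI plateau among the stable ones.

    A raw scan of noisy position sets is littered with CI = 1 plateaus in
    the fragmenting regime at tiny x, so candidates are restricted first:
    plateaus entirely below ``min_x`` are dropped, then either plateaus
    with CI below ``min_ci`` are dropped (when given) or only the ``top``
    largest-CI plateaus — the prominent constant ranges of the scan — are
    kept.  Among candidates the lowest CI wins (the scale where the region
    count is most sharply pinned down); ties go to the smaller x_min, and
    the plateau's smallest x is returned as the most conservative choice.
    """
    candidates = [p for p in plateaus if p.x_max >= min_x]
    if min_ci is not None:
        candidates = [p for p in candidates if p.ci >= min_ci]
    elif top is not None:
        candidates = sorted(candidates, key=lambda p: (-p.ci, p.x_min))[:top]
    if not candidates:
        raise ValueError("no candidate plateaus")
    best = min(candidates, key=lambda p: (p.ci, p.x_min))
    return best.x_min


def build_mtdmrs(
    dmcpns_by_contrast: Mapping[str, Sequence[DMCpN]],
    max_gap: int,
    min_members: int = 1,
) -> dict[str, list[MtDMR]]:
    """Cluster significant sites per contrast into mtDMRs at gap length x.

    Direction is hypo when the mean member log2 fold-change is negative,
    hyper otherwise.
    """
    out: dict[str, list[MtDMR]] = {}
    for contrast, dmcpns in dmcpns_by_contrast.items():
        sig = sorted((d for d in dmcpns if d.significant), key=lambda d: d.site.position)
        regions: list[MtDMR] = []
        if sig:
            positions = [d.site.position for d in sig]
            for start, last, idx in cluster_positions(positions, max_gap):
                members = [sig[i] for i in idx]
                if len(members) < min_members:
                    continue
                mean_fc = float(np.mean([m.log2fc for m in members]))
                regions.append(
                    MtDMR(
                        contrast=contrast,
                        start=start,
                        end=last + 1,  # cover the final dinucleotide
                        members=members,
                        direction="hypo" if mean_fc < 0 else "hyper",
                    )
                )
        out[contrast] = regions
    return out


def write_mtdmr_tsv(mtdmrs_by_contrast: Mapping[str, Sequence[MtDMR]], path) -> None:
    with open(path, "w") as fh:
        fh.write("contrast\tstart\tend\tlength\tn_members\tdirection\tmean_log2fc\n")
        for contrast in mtdmrs_by_contrast:
            for r in mtdmrs_by_contrast[contrast]:
                mean_fc = float(np.mean([m.log2fc for m in r.members])) if r.members else 0.0
                fh.write(
                    f"{contrast}\t{r.start}\t{r.end}\t{r.length}\t"
                    f"{len(r.members)}\t{r.direction}\t{mean_fc:.4f}\n"
                )


def write_mtdmr_bed(
    mtdmrs_by_contrast: Mapping[str, Sequence[MtDMR]], path, chrom: str = "chrMT"
) -> None:
    """BED output (0-based half-open) with contrast:direction as the name."""
    with open(path, "w") as fh:
        for contrast in mtdmrs_by_contrast:
            for r in mtdmrs_by_contrast[contrast]:
                fh.write(f"{chrom}\t{r.start - 1}\t{r.end}\t{contrast}:{r.direction}\n")
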