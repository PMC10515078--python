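"""Synthetic inputs for the full pipeline: genome, NUMT decoys, reads, counts.

The generator emulates the study design the package targets: a ~16.8 kb
circular mitochondrial genome with the avian base composition (A 30.3%,
T 23.8%, C 32.5%, G 13.5%), nuclear contigs carrying diverged mtDNA copies
(NUMTs), single-end fragments with a 350 bp mean length size-selected to
200-400 bp at ~170x mean depth, and negative-binomial CpN coverage for
twelve samples (3 replicates in each of MC, MS, FC, FS) with region-level
log2 fold-changes planted per contrast.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .diffmeth import CONTRASTS, CpNCountMatrix, Sample
from .genome_io import CircularGenome, CpNSite, reverse_complement

__all__ = [
    "PlantedDMR",
    "SimulationConfig",
    "SimRead",
    "make_genome",
    "make_nuclear_decoy",
    "simulate_reads",
    "simulate_counts",
    "default_samples",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedDMR:
    """Ground-truth differential region: ``log2fc`` is applied
    multiplicatively to the *second* group of each affected contrast
    (FC, FS, MS, FS for MCvsFC, MSvsFS, MCvsMS, FCvsFS respectively)."""

    start: int
    end: int
    log2fc: float
    affected_contrasts: tuple[str, ...] = ("MCvsMS",)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")
        if not np.isfinite(self.log2fc):
            raise ValueError("log2fc must be finite")
        unknown = set(self.affected_contrasts) - set(CONTRASTS)
        if unknown:
            raise ValueError(f"unknown contrasts {sorted(unknown)}")


@dataclass
class SimulationConfig:
    genome_length: int = 16775
    base_freqs: tuple[float, float, float, float] = (0.303, 0.325, 0.135, 0.238)  # A,C,G,T
    planted_motifs: list[tuple[str, int, str]] = field(default_factory=list)
    numt_blocks: list[tuple[int, int, float]] = field(default_factory=list)
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    size_select: tuple[int, int] = (200, 400)
    mean_depth: float = 170.0
    nb_dispersion: float = 0.05
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    n_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.base_freqs))
        if not np.isclose(total, 1.0, atol=0.01):
            raise ValueError("base frequencies must sum to 1")
        # printed compositions often carry rounding (e.g. percentages summing
        # to 100.1); renormalise exactly
        self.base_freqs = tuple(f / total for f in self.base_freqs)
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.size_select
        if not 0 < lo <= hi < self.genome_length:
            raise ValueError("size_select must lie within (0, genome_length)")


@dataclass(frozen=True)
class SimRead:
    id: str
    sequence: str
    origin: str  # genome id the fragment was drawn from
    start: int  # 1-based start on the origin genome
    length: int


def default_samples(n_per_group: int = 3) -> list[Sample]:
    """Twelve samples in fixed order: MC x3, MS x3, FC x3, FS x3."""
    samples = []
    for cell, sex, group in (
        ("MC", "M", "control"),
        ("MS", "M", "stress"),
        ("FC", "F", "control"),
        ("FS", "F", "stress"),
    ):
        samples.extend(
            Sample(id=f"{cell}{k + 1}", sex=sex, group=group) for k in range(n_per_group)
        )
    return samples


def make_genome(config: SimulationConfig, genome_id: str = "chrMT_sim") -> CircularGenome:
    """I.i.d. bases at the configured frequencies, then planted motif
    consensus sequences written over the stated positions/strands."""
    rng = np.random.default_rng(config.seed)
    seq = rng.choice(_BASES, size=config.genome_length, p=list(config.base_freqs))
    occupied: list[tuple[int, int]] = []
    for motif, pos, strand in config.planted_motifs:
        end = pos + len(motif) - 1
        if pos < 1 or end > config.genome_length:
            raise ValueError(f"planted motif at {pos} runs off the genome")
        for a, b in occupied:
            if pos <= b and end >= a:
                raise ValueError(f"planted motifs overlap at {pos}..{end}")
        occupied.append((pos, end))
        inserted = motif.upper() if strand == "+" else reverse_complement(motif.upper())
        seq[pos - 1 : end] = list(inserted)
    return CircularGenome(id=genome_id, sequence="".join(seq), circular=True)


def make_nuclear_decoy(
    genome: CircularGenome,
    block: tuple[int, int, float],
    seed: int,
    flank: int = 500,
    decoy_id: str | None = None,
) -> CircularGenome:
    """A linear nuclear contig carrying a diverged copy of an mtDNA segment.

    Each base of the copied segment is substituted independently at the
    divergence rate (always to a different base); the segment is embedded
    between random flanks drawn at the genome's base composition.
    """
    start, end, divergence = block
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    if not 1 <= start <= end <= len(genome):
        raise ValueError("block outside genome")
    rng = np.random.default_rng(seed)
    segment = np.array(list(genome.fetch(start, end)))
    mutate = rng.random(len(segment)) < divergence
    for i in np.flatnonzero(mutate):
        alternatives = [b for b in "ACGT" if b != segment[i]]
        segment[i] = alternatives[rng.integers(len(alternatives))]
    from .genome_io import base_composition

    comp = base_composition(genome)
    p = [comp.freq_A, comp.freq_C, comp.freq_G, comp.freq_T]
    left = rng.choice(_BASES, size=flank, p=p)
    right = rng.choice(_BASES, size=flank, p=p)
    seq = "".join(left) + "".join(segment) + "".join(right)
    return CircularGenome(
        id=decoy_id or f"numt_{start}_{end}",
        sequence=seq,
        circular=False,
    )


def _fragment_lengths(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.size_select
    a = (lo - config.fragment_mean) / config.fragment_sd
    b = (hi - config.fragment_mean) / config.fragment_sd
    lengths = truncnorm.rvs(
        a, b, loc=config.fragment_mean, scale=config.fragment_sd, size=n, random_state=rng
    )
    return np.round(lengths).astype(int).clip(lo, hi)


def simulate_reads(
    genomes: Sequence[CircularGenome],
    config: SimulationConfig,
    n_reads: int | None = None,
    weights: Sequence[float] | None = None,
    read_prefix: str = "read",
) -> list[SimRead]:
    """Draw single-end fragments uniformly from a set of genomes.

    Fragment starts are uniform on each genome (wrapping on circular ones);
    lengths follow a truncated normal clipped to the size-selection window.
    When ``n_reads`` is omitted it is chosen so the first genome reaches
    the configured mean depth.  Each read records its true origin.
    """
    rng = np.random.default_rng(config.seed + 1)
    if n_reads is None:
        n_reads = int(round(config.mean_depth * len(genomes[0]) / config.fragment_mean))
    if weights is None:
        weights = [len(g) for g in genomes]
    w = np.asarray(weights, float)
    w = w / w.sum()
    choice = rng.choice(len(genomes), size=n_reads, p=w)
    lengths = _fragment_lengths(n_reads, config, rng)
    reads: list[SimRead] = []
    for i in range(n_reads):
        g = genomes[choice[i]]
        length = int(min(lengths[i], len(g)))
        if g.circular:
            start = int(rng.integers(1, len(g) + 1))
        else:
            start = int(rng.integers(1, len(g) - length + 2))
        seq = g.fetch(start, start + length - 1)
        reads.append(
            SimRead(
                id=f"{read_prefix}_{i}",
                sequence=seq,
                origin=g.id,
                start=start,
                length=length,
            )
        )
    return reads


def write_fastq(reads: Sequence[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id} origin={r.origin} start={r.start}\n{r.sequence}\n+\n")
            fh.write("I" * len(r.sequence) + "\n")


def _cell_multipliers(config: SimulationConfig, positions: np.ndarray) -> dict[str, np.ndarray]:
    """Per-cell, per-site mean multipliers implied by the planted DMRs."""
    mult = {cell: np.ones(len(positions)) for cell in ("MC", "MS", "FC", "FS")}
    for dmr in config.planted_dmrs:
        inside = (positions >= dmr.start) & (positions <= dmr.end)
        for contrast in dmr.affected_contrasts:
            second = CONTRASTS[contrast][1]
            mult[second][inside] *= 2.0 ** dmr.log2fc
    return mult


def simulate_counts(
    sites: Sequence[CpNSite],
    config: SimulationConfig,
    samples: Sequence[Sample] | None = None,
) -> CpNCountMatrix:
    """NB-distributed coverage counts at CpN sites with planted effects.

    Baseline mean is the configured depth at every site; a planted DMR
    multiplies the mean of the second group of each affected contrast by
    2**log2fc at its member sites.  Counts are gamma-Poisson draws with
    dispersion phi (Poisson when phi = 0); deterministic under the seed.
    """
    if config.n_per_group < 2:
        raise ValueError("need >= 2 replicates per group")
    positions = np.array([s.position for s in sites], dtype=np.int64)
    if len(positions) > 1 and (np.diff(positions) <= 0).any():
        raise ValueError("sites must be sorted by position")
    if samples is None:
        samples = default_samples(config.n_per_group)
    rng = np.random.default_rng(config.seed + 2)
    mult = _cell_multipliers(config, positions)
    phi = config.nb_dispersion
    counts = np.empty((len(sites), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        mu = config.mean_depth * mult[sample.cell]
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    return CpNCountMatrix(sites=list(sites), counts=counts, samples=list(samples))
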