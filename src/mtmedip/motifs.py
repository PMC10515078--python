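"""PWM scanning of mitochondrial genomes with exact p-values.

A position weight matrix is scored as log2 odds against a 0-order
background; window scores are discretised onto an integer grid and the
exact null distribution of the total score under the background is obtained
by dynamic programming (the same construction FIMO uses), giving a p-value
for every achievable score.  Hits at p below a threshold (1e-4 by default)
are reported on both strands with plus-strand coordinates, mapped to
heavy/light labels via the genome's strand convention flag.

Also provided: intersection of hits with mtDMRs, per-strand hit summaries,
and extraction of cross-species conservation windows around orthologous
hits (hit plus flanking sequence, majority consensus per column).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_io import CircularGenome, reverse_complement

__all__ = [
    "PWM",
    "MotifHit",
    "ConservedWindow",
    "ScoreDistribution",
    "read_pwm",
    "pwm_from_counts",
    "log_odds",
    "score_pvalues",
    "scan",
    "strand_summary",
    "motifs_in_regions",
    "conserved_window",
]

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class PWM:
    name: str
    matrix: np.ndarray  # 4 x w column-stochastic probabilities (rows = ACGT)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("matrix must be 4 x w (rows A,C,G,T)")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    genome_id: str
    motif: str
    start: int  # 1-based inclusive, plus-strand coordinates
    end: int
    strand: str  # + | -
    strand_label: str  # heavy | light
    score: float  # log2 odds
    p_value: float
    matched: str  # sequence in motif orientation
    features: tuple[str, ...] = ()


@dataclass
class ConservedWindow:
    windows: dict[str, str]  # species -> window sequence (motif orientation)
    consensus: str  # per-column consensus, '.' where below threshold
    fractions: list[float]  # per-column agreement of the majority base


# ---------------------------------------------------------------------------
# PWM construction and IO
# ---------------------------------------------------------------------------


def pwm_from_counts(
    name: str,
    counts: np.ndarray,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
    source: str = "",
) -> PWM:
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    probs = counts + pseudocount
    colsum = probs.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("a column has zero total count and zero pseudocount")
    return PWM(
        name=name,
        matrix=probs / colsum,
        background=np.full(4, 0.25) if background is None else background,
        source=source,
    )


_JASPAR_ROW = re.compile(r"^\s*([ACGT])\s*\[?\s*([\d.\seE+-]+?)\s*\]?\s*$")


def read_pwm(path: str | Path, pseudocount: float = 0.1) -> PWM:
    """Read one motif from JASPAR PFM or MEME minimal matrix text."""
    text = Path(path).read_text()
    if "letter-probability matrix" in text:
        return _parse_meme(text, pseudocount)
    return _parse_jaspar(text, pseudocount)


def _parse_jaspar(text: str, pseudocount: float) -> PWM:
    name = "motif"
    rows: dict[str, list[float]] = {}
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            continue
        m = _JASPAR_ROW.match(line)
        if m:
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    if set(rows) != set("ACGT"):
        raise ValueError("JASPAR matrix must have A, C, G and T rows")
    counts = np.array([rows[b] for b in "ACGT"])
    return pwm_from_counts(name, counts, pseudocount)


def _parse_meme(text: str, pseudocount: float) -> PWM:
    lines = text.splitlines()
    name = "motif"
    bg = np.full(4, 0.25)
    i = 0
    rows: list[list[float]] = []
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else name
        elif line.startswith("Background letter frequencies"):
            vals = re.findall(r"([ACGT])\s+([\d.eE+-]+)", lines[i + 1])
            if len(vals) == 4:
                bg = np.array([float(v) for _, v in sorted(vals)])
                i += 1
        elif line.startswith("letter-probability matrix"):
            m = re.search(r"nsites=\s*(\d+)", line)
            nsites = int(m.group(1)) if m else 20
            i += 1
            while i < len(lines) and re.match(r"^\s*[\d.]", lines[i]):
                rows.append([float(x) for x in lines[i].split()])
                i += 1
            counts = np.array(rows).T * nsites  # back to counts for pseudocounting
            return pwm_from_counts(name, counts, pseudocount, background=bg)
        i += 1
    raise ValueError("no letter-probability matrix found in MEME text")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def log_odds(pwm: PWM, background: np.ndarray | None = None) -> np.ndarray:
    """log2(p(b, i) / background(b)) score matrix."""
    bg = pwm.background if background is None else np.asarray(background, float)
    if (bg <= 0).any():
        raise ValueError("background must be strictly positive")
    if (pwm.matrix <= 0).any():
        raise ValueError("PWM has zero cells; use a pseudocount")
    return np.log2(pwm.matrix / bg[:, None])


class ScoreDistribution:
    """Discretised exact null distribution of the total window score.

    Scores are shifted and scaled onto an integer grid of ``granularity``
    bins; the distribution of the integer total under the 0-order
    background follows by dynamic programming over motif positions.
    p(x) = P(score >= x) is monotone non-increasing by construction.
    """

    def __init__(
        self,
        scores: np.ndarray,
        background: np.ndarray,
        granularity: int = 1000,
    ):
        if granularity < 100:
            raise ValueError("granularity must be >= 100 bins")
        scores = np.asarray(scores, dtype=float)
        col_min = scores.min(axis=0)
        total_range = float((scores.max(axis=0) - col_min).sum())
        if total_range <= 0:
            raise ValueError("degenerate score matrix with zero range")
        self.delta = total_range / granularity
        self.offset = float(col_min.sum())
        self.int_matrix = np.round((scores - col_min) / self.delta).astype(np.int64)
        max_total = int(self.int_matrix.max(axis=0).sum())
        dist = np.zeros(max_total + 1)
        dist[0] = 1.0
        for i in range(scores.shape[1]):
            new = np.zeros_like(dist)
            for b in range(4):
                s = self.int_matrix[b, i]
                new[s:] += background[b] * dist[: len(dist) - s if s else None]
            dist = new
        self.pmf = dist
        self.tail = np.cumsum(dist[::-1])[::-1]  # tail[k] = P(int score >= k)

    def int_score(self, base_indices: np.ndarray) -> int:
        w = self.int_matrix.shape[1]
        return int(self.int_matrix[base_indices, np.arange(w)].sum())

    def pvalue_int(self, k: int) -> float:
        k = max(0, min(int(k), len(self.tail) - 1))
        return float(self.tail[k])

    def pvalue(self, score: float) -> float:
        """p-value of a real-valued score (mapped onto the integer grid)."""
        k = int(round((score - self.offset) / self.delta))
        if k >= len(self.tail):
            return 0.0
        return self.pvalue_int(k)


def score_pvalues(
    scores: np.ndarray, background: np.ndarray, granularity: int = 1000
) -> ScoreDistribution:
    return ScoreDistribution(scores, background, granularity)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _encode_indices(seq: str) -> np.ndarray:
    idx = np.full(len(seq), 4, dtype=np.int64)  # 4 = ambiguous
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        idx[arr == ord(b)] = i
    return idx


def _window_int_scores(idx: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Integer score of every window; windows containing N score -1."""
    w = int_matrix.shape[1]
    n_win = len(idx) - w + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    padded = np.vstack([int_matrix, np.full((1, w), -(10**9), dtype=np.int64)])
    total = np.zeros(n_win, dtype=np.int64)
    for i in range(w):
        total += padded[idx[i : i + n_win], i]
    return np.maximum(total, -1)


def scan(
    genome: CircularGenome,
    pwm: PWM,
    p_threshold: float = 1e-4,
    strands: str = "both",
    background: str | np.ndarray = "genome",
    granularity: int = 1000,
    circular: bool = False,
    annotate: bool = True,
) -> list[MotifHit]:
    """Report motif occurrences with exact p <= threshold on the genome.

    The background is estimated from the scanned sequence by default
    ('genome'), or uniform ('uniform'), or given explicitly.  Minus-strand
    windows are scored on their reverse complement against the same motif
    and null distribution; their coordinates are reported on the plus
    strand.  ``circular=True`` appends the first w-1 bases so windows across
    the origin are scanned too.
    """
    w = pwm.width
    L = len(genome)
    if w > L:
        raise ValueError(f"motif width {w} exceeds genome length {L}")
    if isinstance(background, str):
        if background == "genome":
            counts = np.array([genome.sequence.count(b) for b in "ACGT"], float)
            bg = counts / counts.sum()
            if strands == "both":
                bg = (bg + bg[::-1]) / 2  # strand-symmetrised (A<->T, C<->G)
        elif background == "uniform":
            bg = np.full(4, 0.25)
        else:
            raise ValueError(f"unknown background {background!r}")
    else:
        bg = np.asarray(background, float)
        bg = bg / bg.sum()
    bg = np.clip(bg, 1e-6, None)
    bg = bg / bg.sum()

    scores = log_odds(pwm, bg)
    dist = ScoreDistribution(scores, bg, granularity)
    # a minus-strand window is scored on its reverse complement, equivalent
    # to scoring the window itself with the rc matrix; unless the background
    # is complement-symmetric this has its own null distribution
    rc_dist = ScoreDistribution(scores[::-1, ::-1], bg, granularity)
    seq = genome.sequence + (genome.sequence[: w - 1] if circular and genome.circular else "")
    idx = _encode_indices(seq)

    hits: list[MotifHit] = []
    jobs = []
    if strands in ("both", "+"):
        jobs.append(("+", dist))
    if strands in ("both", "-"):
        jobs.append(("-", rc_dist))
    for strand, sdist in jobs:
        mat = sdist.int_matrix
        w_scores = np.zeros(len(idx) - w + 1, dtype=np.int64)
        padded = np.vstack([mat, np.full((1, w), -(10**9), dtype=np.int64)])
        for i in range(w):
            w_scores += padded[idx[i : i + len(w_scores)], i]
        for pos0 in np.flatnonzero(w_scores >= 0):
            p = sdist.pvalue_int(int(w_scores[pos0]))
            if p > p_threshold:
                continue
            start = int(pos0) % L + 1 if circular else int(pos0) + 1
            end = start + w - 1
            window = seq[pos0 : pos0 + w]
            matched = window if strand == "+" else reverse_complement(window)
            feats = ()
            if annotate:
                feats = tuple(
                    f.name
                    for f in genome.features
                    if min(end, f.end) - max(start, f.start) >= 0
                )
            hits.append(
                MotifHit(
                    genome_id=genome.id,
                    motif=pwm.name,
                    start=start,
                    end=end,
                    strand=strand,
                    strand_label=genome.strand_label(strand),
                    score=float(w_scores[pos0] * sdist.delta + sdist.offset),
                    p_value=p,
                    matched=matched,
                    features=feats,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def strand_summary(hits: Sequence[MotifHit]) -> dict[str, float] | None:
    """Percent of hits per heavy/light label (1 decimal); None when empty."""
    if not hits:
        return None
    out: dict[str, float] = {}
    for label in ("heavy", "light"):
        n = sum(1 for h in hits if h.strand_label == label)
        out[label] = round(100.0 * n / len(hits), 1)
    return out


def motifs_in_regions(hits: Sequence[MotifHit], mtdmrs_by_contrast: Mapping) -> "object":
    """Presence table: one row per mtDMR, one boolean column per motif.

    A motif is present when its hit span shares >= 1 bp with the region.
    """
    import pandas as pd

    motif_names = sorted({h.motif for h in hits})
    rows = []
    for contrast, regions in mtdmrs_by_contrast.items():
        for r in regions:
            row: dict = {"contrast": contrast, "start": r.start, "end": r.end}
            for m in motif_names:
                row[m] = any(
                    h.motif == m and min(h.end, r.end) - max(h.start, r.start) >= 0
                    for h in hits
                )
            rows.append(row)
    return pd.DataFrame(rows)


def conserved_window(
    hits_by_species: Mapping[str, MotifHit],
    genomes_by_species: Mapping[str, CircularGenome],
    flank: int = 20,
    consensus_threshold: float = 0.70,
) -> ConservedWindow:
    """Extract hit +/- flank per species (motif orientation) and build the
    per-column majority consensus at the agreement threshold."""
    windows: dict[str, str] = {}
    for species, hit in hits_by_species.items():
        g = genomes_by_species[species]
        L = len(g)
        start, end = hit.start - flank, hit.end + flank
        if g.circular:
            while start < 1:
                start += L
                end += L
            seq = g.fetch(start, end)
        else:
            seq = g.sequence[max(0, start - 1) : min(L, end)]
        windows[species] = seq if hit.strand == "+" else reverse_complement(seq)
    lengths = {len(s) for s in windows.values()}
    if len(lengths) != 1:
        raise ValueError("windows have unequal lengths (hit too close to a linear end?)")
    width = lengths.pop()
    consensus = []
    fractions = []
    n = len(windows)
    for col in range(width):
        col_bases = [s[col] for s in windows.values()]
        best = max(set(col_bases), key=col_bases.count)
        frac = col_bases.count(best) / n
        fractions.append(frac)
        consensus.append(best if frac >= consensus_threshold else ".")
    return ConservedWindow(windows=windows, consensus="".join(consensus), fractions=fractions)


def write_hits_tsv(hits: Sequence[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tmotif\tstart\tend\tstrand\tstrand_label\tscore\tp\tmatched\tfeatures\n")
        for h in hits:
            fh.write(
                f"{h.genome_id}\t{h.motif}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.strand_label}\t{h.score:.4f}\t{h.p_value:.3g}\t{h.matched}\t"
                f"{','.join(h.features)}\n"
            )


def write_hits_gff3(hits: Sequence[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            fh.write(
                f"{h.genome_id}\tmtmedip\tTF_binding_site\t{h.start}\t{h.end}\t"
                f"{h.score:.3f}\t{h.strand}\t.\tName={h.motif};pvalue={h.p_value:.3g}\n"
            )
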