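"""Per-CpN differential coverage testing for mitochondrial MeDIP-seq.

MeDIP-seq measures methylation through immunoprecipitation enrichment, so
the unit of evidence is read coverage at each CpN site, not a per-base
methylation call.  Coverage counts are modelled as negative binomial with a
common dispersion shared across sites.  For each of the four sex x stress
contrasts (MC vs FC, MS vs FS, MC vs MS, FC vs FS) sites are tested with a
two-sided conditional NB exact test on library-size-equalised group sums,
after TMM between-sample normalisation (weighted trimmed mean of log
ratios) and a minimum-row-total filter.

Everything operates on a :class:`CpNCountMatrix` (CpN sites x samples, with
sex/group metadata).  Library sizes and TMM factors combine into effective
library sizes; counts are never themselves rescaled except inside the
pseudo-count equalisation of the dispersion estimator and exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .genome_io import CircularGenome, CpNSite

__all__ = [
    "Sample",
    "CpNCountMatrix",
    "DMCpN",
    "QCReport",
    "CONTRASTS",
    "count_coverage",
    "cpg_enrichment_score",
    "filter_low_counts",
    "tmm_factors",
    "estimate_common_dispersion",
    "exact_test",
    "run_contrasts",
]

#: The four pairwise contrasts; each maps to (first cell, second cell).
#: Reported log2 fold-changes are log2(second / first).
CONTRASTS: dict[str, tuple[str, str]] = {
    "MCvsFC": ("MC", "FC"),
    "MSvsFS": ("MS", "FS"),
    "MCvsMS": ("MC", "MS"),
    "FCvsFS": ("FC", "FS"),
}


@dataclass(frozen=True)
class Sample:
    id: str
    sex: str  # M | F
    group: str  # control | stress

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.group not in ("control", "stress"):
            raise ValueError(f"group must be control or stress, got {self.group!r}")

    @property
    def cell(self) -> str:
        """MC, MS, FC or FS."""
        return self.sex + ("C" if self.group == "control" else "S")


@dataclass
class CpNCountMatrix:
    sites: list[CpNSite]
    counts: np.ndarray  # sites x samples, non-negative integers
    samples: list[Sample]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CpNCountMatrix":
        idx = [i for i, s in enumerate(self.samples) if s.id in set(sample_ids)]
        return CpNCountMatrix(
            sites=self.sites,
            counts=self.counts[:, idx],
            samples=[self.samples[i] for i in idx],
        )

    def cells(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for j, s in enumerate(self.samples):
            out.setdefault(s.cell, []).append(j)
        return out

    # ---- TSV round-trip (sites as rows, '#' metadata header lines) ----

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.samples:
                fh.write(f"# sample\t{s.id}\t{s.sex}\t{s.group}\n")
            fh.write("position\tcontext\t" + "\t".join(s.id for s in self.samples) + "\n")
            for i, site in enumerate(self.sites):
                row = "\t".join(str(int(c)) for c in self.counts[i])
                fh.write(f"{site.position}\t{site.context}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CpNCountMatrix":
        samples: list[Sample] = []
        sites: list[CpNSite] = []
        rows: list[list[int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# sample\t"):
                    _, sid, sex, group = line.split("\t")
                    samples.append(Sample(sid, sex, group))
                    continue
                if line.startswith("#") or not line.strip():
                    continue
                cols = line.split("\t")
                if cols[0] == "position":
                    continue
                sites.append(CpNSite(position=int(cols[0]), context=cols[1]))
                rows.append([int(c) for c in cols[2:]])
        return cls(sites=sites, counts=np.array(rows, dtype=np.int64), samples=samples)


@dataclass(frozen=True)
class DMCpN:
    """One CpN site tested in one contrast."""

    site: CpNSite
    contrast: str
    log2fc: float
    p_value: float
    significant: bool


@dataclass
class QCReport:
    enrichment_scores: dict[str, float]
    reference_score: float = 1.0


# ---------------------------------------------------------------------------
# coverage counting and enrichment QC
# ---------------------------------------------------------------------------


def count_coverage(
    intervals_by_sample: Mapping[str, Sequence[tuple[int, int]]],
    sites: Sequence[CpNSite],
    genome_length: int,
    samples: Sequence[Sample],
    circular: bool = True,
) -> CpNCountMatrix:
    """Count, per sample, the reads whose interval covers each site's C.

    ``intervals_by_sample`` maps sample id to (start, length) pairs with
    1-based starts; an interval running past position L wraps to the origin
    when the genome is circular.
    """
    positions = np.array([s.position for s in sites], dtype=np.int64)
    if len(positions) and (positions.max() > genome_length or positions.min() < 1):
        raise ValueError("site outside genome")
    counts = np.zeros((len(sites), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        delta = np.zeros(genome_length + 1, dtype=np.int64)
        for start, length in intervals_by_sample.get(sample.id, ()):
            end = start + length - 1
            if end <= genome_length:
                delta[start - 1] += 1
                delta[end] -= 1
            else:
                if not circular:
                    raise ValueError("interval runs off a linear genome")
                delta[start - 1] += 1
                delta[genome_length] -= 1
                delta[0] += 1
                delta[end - genome_length] -= 1
        coverage = np.cumsum(delta[:-1])
        if len(positions):
            counts[:, j] = coverage[positions - 1]
    return CpNCountMatrix(sites=list(sites), counts=counts, samples=list(samples))


def _cpg_relative_freq(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    n = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
    return n / len(seq)


def cpg_enrichment_score(
    covered_regions: Sequence[tuple[int, int]], genome: CircularGenome
) -> float:
    """CpG enrichment of a covered set relative to the whole genome.

    score = (CpG count / covered length) / (CpG count / L over the genome).
    Values near 1 indicate no enrichment; a successful methyl-DNA pulldown
    yields CpG-rich fragments and a score well above 1.
    """
    if not covered_regions:
        raise ValueError("empty covered set")
    cpg = 0
    length = 0
    for start, end in covered_regions:
        seq = genome.fetch(start, end)
        cpg += sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
        length += len(seq)
    if length == 0:
        raise ValueError("covered length is zero")
    ref = _cpg_relative_freq(genome.sequence)
    if ref == 0:
        raise ValueError("genome contains no CpG dinucleotides")
    return (cpg / length) / ref


# ---------------------------------------------------------------------------
# filtering and normalisation
# ---------------------------------------------------------------------------


def filter_low_counts(matrix: CpNCountMatrix, min_total: int = 10) -> CpNCountMatrix:
    """Drop sites whose count summed across all samples is below min_total."""
    keep = matrix.counts.sum(axis=1) >= min_total
    return CpNCountMatrix(
        sites=[s for s, k in zip(matrix.sites, keep) if k],
        counts=matrix.counts[keep],
        samples=matrix.samples,
    )


def tmm_factors(
    matrix: CpNCountMatrix,
    reference: str | int | None = None,
    log_ratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """TMM normalisation factors (weighted trimmed mean of M-values).

    For each sample a scaling factor is the weighted mean of per-site
    log2 ratios against a reference sample, after symmetric trimming of the
    most extreme 30% of log ratios and 5% of abundances, with
    inverse-asymptotic-variance weights.  Factors are rescaled to geometric
    mean 1.  The reference defaults to the sample whose upper-quartile
    count fraction is closest to the mean upper quartile.
    """
    y = matrix.counts.astype(float)
    n_sites, n_samples = y.shape
    if n_samples < 2:
        raise ValueError("need at least two samples")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("a sample has zero total counts")

    if reference is None:
        uq = np.quantile(y / lib, 0.75, axis=0)
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    elif isinstance(reference, str):
        ref = [s.id for s in matrix.samples].index(reference)
    else:
        ref = int(reference)

    log_factors = np.zeros(n_samples)
    yr, nr = y[:, ref], lib[ref]
    for j in range(n_samples):
        if j == ref:
            continue
        yj, nj = y[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(
                f"sample {matrix.samples[j].id} shares no positive sites with the reference"
            )
        m = np.log2((yj[ok] / nj) / (yr[ok] / nr))
        a = 0.5 * np.log2((yj[ok] / nj) * (yr[ok] / nr))
        v = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        n = ok.sum()
        lo_m = math.floor(n * log_ratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * abundance_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = m.argsort().argsort() + 1
        rank_a = a.argsort().argsort() + 1
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any() and np.isfinite(v[keep]).all() and (v[keep] > 0).all():
            log_factors[j] = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
        else:
            log_factors[j] = 0.0
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# dispersion and the exact test
# ---------------------------------------------------------------------------


def _pseudo_counts(counts: np.ndarray, eff_lib: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale counts to the geometric-mean effective library size."""
    common = float(np.exp(np.mean(np.log(eff_lib))))
    return counts * (common / eff_lib), common


def _cond_loglik(pseudo: np.ndarray, group_idx: list[np.ndarray], phi: float) -> float:
    """NB conditional log-likelihood given per-site group totals.

    The conditional distribution of replicate counts given their sum under
    a common dispersion phi is free of the site means, so summing it over
    sites profiles them out.
    """
    r = 1.0 / phi
    ll = 0.0
    for idx in group_idx:
        if len(idx) < 2:
            continue
        yg = pseudo[:, idx]
        z = yg.sum(axis=1)
        n = len(idx)
        ll += float(
            np.sum(gammaln(yg + r))
            - np.sum(gammaln(yg + 1))
            - yg.shape[0] * n * gammaln(r)
            + np.sum(gammaln(n * r) - gammaln(z + n * r) + gammaln(z + 1))
        )
    return ll


def estimate_common_dispersion(
    matrix: CpNCountMatrix,
    groups: Sequence[str] | None = None,
    phi_max: float = 5.0,
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Counts are first equalised to a common library size (pseudo-counts);
    the conditional likelihood of replicates given their per-site group sum
    is then maximised over phi.  Returns 0 when within-group variability is
    at or below Poisson.  Requires at least one group with >= 2 replicates.
    """
    if groups is None:
        groups = [s.cell for s in matrix.samples]
    labels = list(dict.fromkeys(groups))
    group_idx = [np.array([i for i, g in enumerate(groups) if g == lab]) for lab in labels]
    if not any(len(idx) >= 2 for idx in group_idx):
        raise ValueError(
            "no group has replicates; supply a dispersion estimate explicitly"
        )
    eff_lib = matrix.lib_sizes.astype(float)
    pseudo, _ = _pseudo_counts(matrix.counts.astype(float), eff_lib)

    def neg_ll(log_phi: float) -> float:
        return -_cond_loglik(pseudo, group_idx, math.exp(log_phi))

    res = minimize_scalar(
        neg_ll, bounds=(math.log(1e-6), math.log(phi_max)), method="bounded",
        options={"xatol": 1e-6},
    )
    phi_hat = math.exp(res.x)
    # boundary check: if the likelihood keeps improving toward phi -> 0, clip
    if neg_ll(math.log(1e-8)) <= res.fun + 1e-9 or phi_hat <= 2e-6:
        return 0.0
    return phi_hat


def _nb_logpmf(x: np.ndarray, mu: float, phi: float) -> np.ndarray:
    """NB log pmf, continuous in x via the gamma function (phi=0 -> Poisson)."""
    x = np.asarray(x, dtype=float)
    if mu <= 0:
        return np.where(x == 0, 0.0, -np.inf)
    if phi <= 0:
        return x * math.log(mu) - mu - gammaln(x + 1)
    r = 1.0 / phi
    return (
        gammaln(x + r)
        - gammaln(r)
        - gammaln(x + 1)
        + r * math.log(r / (r + mu))
        + x * math.log(mu / (r + mu))
    )


def exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    eff_lib_a: np.ndarray,
    eff_lib_b: np.ndarray,
    phi: float,
    prior_count: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided NB exact test per site, conditioning on the site total.

    Replicate counts are equalised to a common library size and summed per
    group; the group sums are NB with dispersion phi/n.  Conditional on
    the total, the p-value is the sum of the probabilities of all splits at
    most as probable as the observed one (normalised over splits).  At
    phi = 0 this is exactly the two-sided conditional binomial test.

    Returns (log2fc, p) arrays; log2fc = log2 of the normalised mean of
    group B over group A, with a 0.5 prior count per group.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    n_sites = counts_a.shape[0]
    na, nb = counts_a.shape[1], counts_b.shape[1]
    eff = np.concatenate([np.asarray(eff_lib_a, float), np.asarray(eff_lib_b, float)])
    common = float(np.exp(np.mean(np.log(eff))))
    pa = counts_a * (common / np.asarray(eff_lib_a, float))
    pb = counts_b * (common / np.asarray(eff_lib_b, float))
    sa, sb = pa.sum(axis=1), pb.sum(axis=1)

    mean_a = sa / na
    mean_b = sb / nb
    log2fc = np.log2(mean_b + prior_count) - np.log2(mean_a + prior_count)

    pvals = np.ones(n_sites)
    frac_a = na / (na + nb)
    for i in range(n_sites):
        # snap pseudo-sums that are integers up to float error so the
        # enumeration grid lands exactly on them
        za = round(sa[i]) if abs(sa[i] - round(sa[i])) < 1e-6 else sa[i]
        zb = round(sb[i]) if abs(sb[i] - round(sb[i])) < 1e-6 else sb[i]
        t = za + zb
        if t <= 0:
            pvals[i] = 1.0
            continue
        k = np.arange(0, math.floor(t + 1e-9) + 1, dtype=float)
        mu_a, mu_b = t * frac_a, t * (1 - frac_a)
        # group sums of n iid NB(mu, phi) are NB(n*mu, phi/n)
        la = _nb_logpmf(k, mu_a, phi / na)
        lb = _nb_logpmf(t - k, mu_b, phi / nb)
        joint = la + lb
        obs = float(
            _nb_logpmf(np.array([za]), mu_a, phi / na)[0]
            + _nb_logpmf(np.array([zb]), mu_b, phi / nb)[0]
        )
        total = logsumexp(joint)
        tail = joint[joint <= obs + 1e-8]
        pvals[i] = min(1.0, float(np.exp(logsumexp(tail) - total))) if len(tail) else 1.0
    return log2fc, pvals


def run_contrasts(
    matrix: CpNCountMatrix,
    alpha: float = 0.05,
    min_total: int = 10,
    phi: float | None = None,
    adjust: str | None = None,
) -> list[DMCpN]:
    """Test every retained site in all four contrasts.

    Per contrast: subset the two cells, apply the minimum-row-total filter,
    compute TMM factors and (unless given) the common dispersion, then run
    the exact test site by site.  Significance is the unadjusted p <= alpha
    by default; ``adjust='BH'`` applies Benjamini-Hochberg first.
    """
    cells = matrix.cells()
    results: list[DMCpN] = []
    for contrast, (cell_a, cell_b) in CONTRASTS.items():
        if not cells.get(cell_a) or not cells.get(cell_b):
            raise ValueError(f"contrast {contrast}: no samples in {cell_a} or {cell_b}")
        idx = cells[cell_a] + cells[cell_b]
        sub = CpNCountMatrix(
            sites=matrix.sites,
            counts=matrix.counts[:, idx],
            samples=[matrix.samples[i] for i in idx],
        )
        sub = filter_low_counts(sub, min_total)
        if not sub.sites:
            continue
        factors = tmm_factors(sub)
        eff_lib = sub.lib_sizes * factors
        phi_c = phi if phi is not None else estimate_common_dispersion(sub)
        ia = [j for j, s in enumerate(sub.samples) if s.cell == cell_a]
        ib = [j for j, s in enumerate(sub.samples) if s.cell == cell_b]
        log2fc, p = exact_test(
            sub.counts[:, ia], sub.counts[:, ib], eff_lib[ia], eff_lib[ib], phi_c
        )
        sig = _significance(p, alpha, adjust)
        results.extend(
            DMCpN(site=s, contrast=contrast, log2fc=float(f), p_value=float(pv),
                  significant=bool(s_))
            for s, f, pv, s_ in zip(sub.sites, log2fc, p, sig)
        )
    return results


def _significance(p: np.ndarray, alpha: float, adjust: str | None) -> np.ndarray:
    if adjust is None:
        return p <= alpha
    if adjust.upper() == "BH":
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        return adj <= alpha
    raise ValueError(f"unknown adjustment {adjust!r}")


def write_dmcpn_tsv(dmcpns: Sequence[DMCpN], path: str | Path, params: str = "") -> None:
    with open(path, "w") as fh:
        if params:
            fh.write(f"# {params}\n")
        fh.write("position\tcontext\tcontrast\tlog2fc\tp\tsignificant\n")
        for d in dmcpns:
            fh.write(
                f"{d.site.position}\t{d.site.context}\t{d.contrast}\t"
                f"{d.log2fc:.6g}\t{d.p_value:.6g}\t{int(d.significant)}\n"
            )
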