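"""Summaries of called mtDMRs: direction balance, composition, annotation,
and cross-contrast classification.

Regions called independently in the four contrasts are linked into a single
identity whenever they share at least one base (with transitive merging);
identities are then classified by which contrasts they appear in:

* class a — present in both between-sex contrasts (MC vs FC and MS vs FS)
  and in neither within-sex contrast: a sex difference independent of stress;
* class b — present in both within-sex contrasts (MC vs MS and FC vs FS):
  the same stress response in both sexes;
* class c — present in exactly one within-sex contrast: a stress response
  confined to one sex;
* class d — present in all four comparisons.

The between-sex Venn view labels identities lost (MC vs FC only), gained
(MS vs FS only) or remained (both) upon stress.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dmr import MtDMR
from .genome_io import CircularGenome

__all__ = [
    "CompositionTest",
    "ContrastClassification",
    "direction_balance",
    "composition_tests",
    "cpn_absence_fraction",
    "annotate_regions",
    "cross_contrast",
    "summary_json",
]

_CONTEXTS = ("CpA", "CpT", "CpC", "CpG")
_SEX_CONTRASTS = ("MCvsFC", "MSvsFS")
_WITHIN_CONTRASTS = ("MCvsMS", "FCvsFS")


@dataclass
class CompositionTest:
    contrast: str
    kind: str  # base | cpn
    categories: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    p_value: float


@dataclass
class ContrastClassification:
    start: int
    end: int
    contrasts_present: tuple[str, ...]
    venn_status: str  # lost | gained | remained | n/a
    dmr_class: str  # a | b | c | d | n/a
    directions: dict[str, str] = field(default_factory=dict)


def direction_balance(
    mtdmrs_by_contrast: Mapping[str, Sequence[MtDMR]]
) -> dict[str, tuple[int, int]]:
    """Per-contrast (hypo, hyper) region tallies."""
    out = {}
    for contrast, regions in mtdmrs_by_contrast.items():
        hypo = sum(1 for r in regions if r.direction == "hypo")
        out[contrast] = (hypo, len(regions) - hypo)
    return out


def _count_dinucleotides(seq: str) -> dict[str, int]:
    counts = dict.fromkeys(_CONTEXTS, 0)
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] in "ACGT":
            counts[f"Cp{seq[i + 1]}"] += 1
    return counts


def _gof(observed: np.ndarray, expected: np.ndarray) -> tuple[float, float]:
    """Chi-squared GOF dropping zero-expectation categories; an observation
    in a zero-expectation category is impossible under the null (p = 0)."""
    mask = expected > 0
    if (observed[~mask] > 0).any():
        return float("inf"), 0.0
    if mask.sum() < 2:
        return 0.0, 1.0
    chi2, p = stats.chisquare(observed[mask], expected[mask])
    return float(chi2), float(p)


def composition_tests(
    mtdmrs_by_contrast: Mapping[str, Sequence[MtDMR]],
    genome: CircularGenome,
) -> list[CompositionTest]:
    """Chi-squared goodness-of-fit of pooled region composition per contrast.

    Two families of tests: single-base composition (A/T/C/G) of the pooled
    region sequence against genome base proportions, and CpN context counts
    against genome-wide CpN proportions.
    """
    genome_base = np.array([genome.sequence.count(b) for b in "ATCG"], float)
    genome_cpn_counts = _count_dinucleotides(genome.sequence)
    genome_cpn = np.array([genome_cpn_counts[c] for c in _CONTEXTS], float)
    results: list[CompositionTest] = []
    for contrast, regions in mtdmrs_by_contrast.items():
        seqs = [genome.fetch(r.start, r.end) for r in regions]
        pooled = "".join(seqs)
        if not pooled:
            continue
        obs_base = np.array([pooled.count(b) for b in "ATCG"], float)
        exp_base = genome_base / genome_base.sum() * obs_base.sum()
        chi2, p = _gof(obs_base, exp_base)
        results.append(
            CompositionTest(contrast, "base", tuple("ATCG"), obs_base, exp_base,
                            float(chi2), float(p))
        )
        cpn_counts = dict.fromkeys(_CONTEXTS, 0)
        for s in seqs:
            for ctx, n in _count_dinucleotides(s).items():
                cpn_counts[ctx] += n
        obs_cpn = np.array([cpn_counts[c] for c in _CONTEXTS], float)
        if obs_cpn.sum() > 0 and genome_cpn.sum() > 0:
            exp_cpn = genome_cpn / genome_cpn.sum() * obs_cpn.sum()
            chi2, p = _gof(obs_cpn, exp_cpn)
            results.append(
                CompositionTest(contrast, "cpn", _CONTEXTS, obs_cpn, exp_cpn,
                                float(chi2), float(p))
            )
    return results


def cpn_absence_fraction(
    mtdmrs: Sequence[MtDMR] | Mapping[str, Sequence[MtDMR]],
    genome: CircularGenome,
) -> dict[str, float]:
    """Percent of regions containing zero occurrences of each CpN context.

    A context absent from a region cannot be driving that region's coverage
    difference, so high absence marks contexts dispensable for the signal.
    """
    if isinstance(mtdmrs, Mapping):
        regions = [r for rs in mtdmrs.values() for r in rs]
    else:
        regions = list(mtdmrs)
    if not regions:
        raise ValueError("no regions")
    absent = dict.fromkeys(_CONTEXTS, 0)
    for r in regions:
        counts = _count_dinucleotides(genome.fetch(r.start, r.end))
        for ctx in _CONTEXTS:
            if counts[ctx] == 0:
                absent[ctx] += 1
    return {ctx: 100.0 * n / len(regions) for ctx, n in absent.items()}


def annotate_regions(
    mtdmrs: Sequence[MtDMR],
    features: Sequence,
) -> tuple[list[tuple[MtDMR, list[str]]], dict[str, int]]:
    """Overlapping feature names per region plus per-feature region counts.

    Overlap means >= 1 shared bp in 1-based inclusive arithmetic; a region
    spanning a boundary annotates to every feature it touches.
    """
    annotated = []
    per_gene: dict[str, int] = {}
    for r in mtdmrs:
        names = [
            f.name for f in features if min(r.end, f.end) - max(r.start, f.start) >= 0
        ]
        annotated.append((r, names))
        for n in names:
            per_gene[n] = per_gene.get(n, 0) + 1
    return annotated, per_gene


def _merge_identities(
    regions: list[tuple[str, MtDMR]], min_overlap: int
) -> list[list[tuple[str, MtDMR]]]:
    """Group regions across contrasts by >= min_overlap bp shared, with
    transitive closure (single-linkage over intervals)."""
    order = sorted(range(len(regions)), key=lambda i: regions[i][1].start)
    groups: list[list[tuple[str, MtDMR]]] = []
    current: list[int] = []
    current_end = -(10**9)
    for i in order:
        r = regions[i][1]
        if current and r.start <= current_end - min_overlap + 1:
            current.append(i)
            current_end = max(current_end, r.end)
        else:
            if current:
                groups.append([regions[j] for j in current])
            current = [i]
            current_end = r.end
    if current:
        groups.append([regions[j] for j in current])
    return groups


def _classify(present: set[str]) -> str:
    within = set(_WITHIN_CONTRASTS) & present
    sex = set(_SEX_CONTRASTS) & present
    if len(present) == 4:
        return "d"
    if len(within) == 2:
        return "b"
    if len(within) == 1:
        return "c"
    if len(sex) == 2:
        return "a"
    return "n/a"


def cross_contrast(
    mtdmrs_by_contrast: Mapping[str, Sequence[MtDMR]],
    min_overlap: int = 1,
) -> tuple[list[ContrastClassification], dict[str, int]]:
    """Merge per-contrast regions into identities and classify each.

    Returns the classification list and a summary with the between-sex Venn
    counts (lost/gained/remained), class tallies, and both region
    accountings (merged identities vs per-contrast instances).
    """
    flat = [(c, r) for c, rs in mtdmrs_by_contrast.items() for r in rs]
    classifications: list[ContrastClassification] = []
    for group in _merge_identities(flat, min_overlap):
        present = {c for c, _ in group}
        start = min(r.start for _, r in group)
        end = max(r.end for _, r in group)
        if "MCvsFC" in present and "MSvsFS" in present:
            venn = "remained"
        elif "MCvsFC" in present:
            venn = "lost"
        elif "MSvsFS" in present:
            venn = "gained"
        else:
            venn = "n/a"
        directions: dict[str, str] = {}
        for c, r in group:
            directions[c] = r.direction
        classifications.append(
            ContrastClassification(
                start=start,
                end=end,
                contrasts_present=tuple(sorted(present)),
                venn_status=venn,
                dmr_class=_classify(present),
                directions=directions,
            )
        )
    counts = {
        "lost": sum(1 for c in classifications if c.venn_status == "lost"),
        "gained": sum(1 for c in classifications if c.venn_status == "gained"),
        "remained": sum(1 for c in classifications if c.venn_status == "remained"),
        "n_identities": len(classifications),
        "n_instances": len(flat),
        "n_shared": sum(1 for c in classifications if len(c.contrasts_present) >= 2),
        "n_unique": sum(1 for c in classifications if len(c.contrasts_present) == 1),
    }
    for cls in "abcd":
        counts[f"class_{cls}"] = sum(1 for c in classifications if c.dmr_class == cls)
    return classifications, counts


def summary_json(
    mtdmrs_by_contrast: Mapping[str, Sequence[MtDMR]],
    genome: CircularGenome,
    path: str | Path | None = None,
) -> dict:
    """Machine-readable characterization summary (optionally written out)."""
    balance = direction_balance(mtdmrs_by_contrast)
    classifications, venn = cross_contrast(mtdmrs_by_contrast)
    all_regions = [r for rs in mtdmrs_by_contrast.values() for r in rs]
    out = {
        "n_mtdmrs": {c: len(rs) for c, rs in mtdmrs_by_contrast.items()},
        "direction_balance": {c: {"hypo": h, "hyper": y} for c, (h, y) in balance.items()},
        "cross_contrast": venn,
        "cpn_absence_percent": (
            cpn_absence_fraction(all_regions, genome) if all_regions else None
        ),
        "composition_p_values": {
            f"{t.contrast}:{t.kind}": t.p_value
            for t in composition_tests(mtdmrs_by_contrast, genome)
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
    return out
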