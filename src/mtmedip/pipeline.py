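"""End-to-end orchestration: simulate -> filter -> test -> cluster ->
characterize -> scan, with a single plain-text config and one seed."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .characterize import summary_json
from .diffmeth import run_contrasts, write_dmcpn_tsv
from .dmr import build_mtdmrs, gap_scan, select_gap_length, write_mtdmr_bed, write_mtdmr_tsv
from .genome_io import find_cpn_sites, read_genome, write_fasta
from .motifs import read_pwm, scan, write_hits_tsv
from .synthetic import PlantedDMR, SimulationConfig, make_genome, simulate_counts

log = logging.getLogger("mtmedip")


@dataclass
class PipelineConfig:
    genome: str | None = None  # FASTA path; simulate when omitted
    annotation: str | None = None
    counts: str | None = None  # CpN count matrix TSV; simulate when omitted
    motif_files: list[str] = field(default_factory=list)
    alpha: float = 0.05
    min_total: int = 10
    gap_length: int | str = "auto"
    scan_max: int = 1962
    motif_p: float = 1e-4
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if not 0 < self.motif_p <= 1:
            raise ValueError("motif p threshold must be in (0, 1]")
        if self.min_total < 0 or self.scan_max < 1:
            raise ValueError("bad threshold")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sim_config(cfg: PipelineConfig) -> SimulationConfig:
    sim = dict(cfg.simulation)
    planted = [PlantedDMR(**d) if isinstance(d, dict) else d for d in sim.pop("planted_dmrs", [])]
    return SimulationConfig(seed=cfg.seed, planted_dmrs=planted, **sim)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage and write its tables under ``outdir``.

    TSV outputs carry the parameters used in '#' header lines and are
    byte-identical across reruns with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if cfg.genome:
            genome = read_genome(cfg.genome, annotation=cfg.annotation)
        else:
            stage = "simulate"
            genome = make_genome(_sim_config(cfg))
            write_fasta(genome, outdir / "genome.fa")
        sites = find_cpn_sites(genome)
        log.info("genome %s: %d bp, %d CpN sites", genome.id, len(genome), len(sites))

        stage = "counts"
        if cfg.counts:
            from .diffmeth import CpNCountMatrix

            matrix = CpNCountMatrix.from_tsv(cfg.counts)
        else:
            matrix = simulate_counts(sites, _sim_config(cfg))
            matrix.to_tsv(outdir / "counts.tsv")

        stage = "diffmeth"
        dmcpns = run_contrasts(matrix, alpha=cfg.alpha, min_total=cfg.min_total)
        write_dmcpn_tsv(
            dmcpns, outdir / "dmcpns.tsv",
            params=f"mtmedip {__version__} alpha={cfg.alpha} min_total={cfg.min_total} seed={cfg.seed}",
        )

        stage = "cluster"
        by_contrast = {}
        for d in dmcpns:
            by_contrast.setdefault(d.contrast, []).append(d)
        sig_positions = sorted(
            {d.site.position for d in dmcpns if d.significant}
        )
        if cfg.gap_length == "auto":
            if len(sig_positions) >= 2:
                plateaus = gap_scan(sig_positions, x_max=cfg.scan_max)
                x_star = select_gap_length(plateaus)
                with open(outdir / "gap_scan.tsv", "w") as fh:
                    fh.write("x_min\tx_max\tregion_count\tci\n")
                    for p in plateaus:
                        fh.write(f"{p.x_min}\t{p.x_max}\t{p.region_count}\t{p.ci}\n")
            else:
                x_star = 1
        else:
            x_star = int(cfg.gap_length)
        log.info("gap length x = %d", x_star)
        mtdmrs = build_mtdmrs(by_contrast, x_star)
        write_mtdmr_tsv(mtdmrs, outdir / "mtdmrs.tsv")
        write_mtdmr_bed(mtdmrs, outdir / "mtdmrs.bed", chrom=genome.id)

        stage = "characterize"
        summary = summary_json(mtdmrs, genome, outdir / "characterization.json")
        summary["gap_length"] = x_star
        (outdir / "characterization.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )

        stage = "scan-motifs"
        all_hits = []
        for mf in cfg.motif_files:
            pwm = read_pwm(mf)
            all_hits.extend(scan(genome, pwm, p_threshold=cfg.motif_p))
        write_hits_tsv(all_hits, outdir / "motif_hits.tsv")
    except Exception as exc:  # noqa: BLE001 — stage-named abort per contract
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def plot_significance(dmcpns, path: str | Path, alpha: float = 0.05) -> None:
    """Simple position-vs-significance scatter, one panel per contrast."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_contrast: dict[str, list] = {}
    for d in dmcpns:
        by_contrast.setdefault(d.contrast, []).append(d)
    fig, axes = plt.subplots(len(by_contrast) or 1, 1, figsize=(9, 2.2 * max(1, len(by_contrast))),
                             sharex=True, squeeze=False)
    for ax, (contrast, ds) in zip(axes.ravel(), sorted(by_contrast.items())):
        x = [d.site.position for d in ds]
        y = [-np.log10(max(d.p_value, 1e-300)) for d in ds]
        sig = [d.significant for d in ds]
        ax.scatter(x, y, c=["#c0392b" if s else "#95a5a6" for s in sig], s=4)
        ax.axhline(-np.log10(alpha), ls="--", lw=0.8, color="k")
        ax.set_ylabel("-log10 p")
        ax.set_title(contrast, fontsize=9)
    axes.ravel()[-1].set_xlabel("mtDNA position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
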