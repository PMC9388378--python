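"""End-to-end orchestration: simulate (or load) a cohort, run the three scans,
classify sweep regions, and write a reproducible run directory.

Every run writes its resolved configuration next to its outputs, and all
randomness flows from the single configured seed, so a repeated run with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diffscan, genio, haploscan, scanstats, simdata, sweeps

log = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    window: int = 100_000
    step: int = 50_000
    min_snps: int = 10
    quantile: float = 0.005
    merge_gap: int = 5000
    ehh_cutoff: float = 0.05
    xpehh_threshold: float = 4.0
    maf: float = 0.05
    xpehh_max_extension: int = 1_000_000


@dataclass
class RunConfig:
    out_dir: str = "drysweep_run"
    vcf: str | None = None  # if None, a cohort is simulated
    panel: str | None = None
    genes: str | None = None
    chrom_lengths: dict[str, int] | None = None
    xpehh_chrom: str | None = None  # default: chromosome of the first sweep
    scan: ScanConfig = field(default_factory=ScanConfig)
    sim: simdata.SimulationParams | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        scan = ScanConfig(**raw.pop("scan", {}))
        sim_raw = raw.pop("sim", None)
        sim = None
        if sim_raw is not None:
            sweeps_raw = sim_raw.pop("sweeps", None)
            sim = simdata.SimulationParams(**sim_raw)
            if sweeps_raw is not None:
                sim.sweeps = [
                    simdata.SweepSpec(s["chrom"], s["core"], s["half_width"],
                                      frozenset(s["target_breeds"]),
                                      s.get("frequency", 0.95))
                    for s in sweeps_raw
                ]
                sim.__post_init__()
        return cls(scan=scan, sim=sim, **raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"]["sweeps"] = [
                {"chrom": s.chrom, "core": s.core, "half_width": s.half_width,
                 "target_breeds": sorted(s.target_breeds), "frequency": s.frequency}
                for s in self.sim.sweeps
            ]
        return d


def run_all(config: RunConfig) -> Path:
    """Run simulate -> Hp scans -> F_ST contrasts -> XP-EHH -> classify -> report.

    Returns the run directory. Deterministic given (inputs, seed).
    """
    out = Path(config.out_dir)
    if config.vcf is not None and config.panel is None:
        raise ValueError("a VCF input requires a panel path")
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=False)

    rng = np.random.default_rng(config.seed)
    truth: simdata.TruthSet = []
    if config.vcf is None:
        sim = config.sim or simdata.SimulationParams(seed=config.seed,
                                                     sweeps=simdata.default_sweeps())
        vt, panel, truth = simdata.simulate_cohort(sim)
        lengths = {sim.chrom_name(i): sim.chrom_length
                   for i in range(sim.n_chromosomes)}
        genio.write_vcf(vt, out / "cohort.vcf", lengths)
        genio.write_panel(panel, out / "panel.tsv")
        simdata.write_truth_bed(truth, out / "truth.bed")
    else:
        panel = genio.read_panel(config.panel)
        vt = genio.read_vcf(config.vcf, panel)
        lengths = config.chrom_lengths or {
            c: int(vt.pos[vt.chrom == c].max()) for c in vt.chromosomes()}
    log.info("cohort: %d sites, %d samples, %d breeds",
             vt.n_sites, vt.n_samples, len(panel.breeds))

    vt_f = genio.filter_maf(vt, config.scan.maf)
    log.info("MAF >= %.3g filter: %d -> %d sites", config.scan.maf,
             vt.n_sites, vt_f.n_sites)
    windows = genio.make_windows(lengths, config.scan.window, config.scan.step)

    # per-breed ZHp scans over all zebu breeds (the within-breed diversity scan)
    zebu = panel.breeds_in(sweeps.SUDANESE_GROUP, *sweeps.NON_SUDANESE_ZEBU_GROUPS)
    hp_tracks = {}
    for breed in zebu:
        track = scanstats.window_hp(vt_f, windows, breed, panel)
        track, _ = scanstats.z_transform(track, config.scan.min_snps)
        track = scanstats.select_outliers(track, config.scan.quantile, tail="low")
        hp_tracks[breed] = track
        genio.write_track(track, out / f"hp_{breed}.tsv")
        log.info("ZHp %s: %d retained, %d outliers", breed,
                 int(track["retained"].sum()), int(track["outlier"].sum()))

    fst_tracks = diffscan.run_contrasts(vt_f, windows, panel,
                                        config.scan.min_snps, config.scan.quantile)
    for name, track in fst_tracks.items():
        genio.write_track(track, out / f"fst_{name}.tsv")
        log.info("ZF_ST %s: %d retained, %d outliers", name,
                 int(track["retained"].sum()), int(track["outlier"].sum()))

    regions = sweeps.sharing_classify(hp_tracks, panel, config.scan.merge_gap)
    regions = sweeps.specificity_classify(regions, fst_tracks, panel)
    if config.genes:
        genes = sweeps.read_genes(config.genes)
        regions = sweeps.gene_overlap(regions, genes)
    table, summary = sweeps.report(regions)
    table.to_csv(out / "regions.tsv", sep="\t", index=False)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    sweeps.write_regions_bed(regions, out / "regions.bed")
    log.info("regions: %d (%d unique_sudanese)", len(regions),
             sum(r.sharing == sweeps.UNIQUE for r in regions))

    # XP-EHH confirmation scan on one chromosome: Sudanese (minus Fulani) vs Fulani
    xchrom = config.xpehh_chrom
    if xchrom is None and truth:
        xchrom = truth[0][0]
    if xchrom is not None and vt.phased:
        sudanese = panel.breeds_in(sweeps.SUDANESE_GROUP)
        fulani = [b for b in sudanese if b.lower() in {"fln", "fulani"}]
        if fulani and len(sudanese) > len(fulani):
            block = haploscan.block_from_variant_table(vt_f, panel, xchrom)
            xp = haploscan.xpehh(
                block, set(sudanese) - set(fulani), set(fulani),
                max_extension=config.scan.xpehh_max_extension,
                cutoff=config.scan.ehh_cutoff,
                threshold=config.scan.xpehh_threshold)
            xp.to_csv(out / f"xpehh_{xchrom}.tsv", sep="\t", index=False)
            log.info("XP-EHH %s: %d cores, %d significant", xchrom, len(xp),
                     int(xp["significant"].sum()))
    return out


def detected_truth_sweeps(regions: list, truth: simdata.TruthSet,
                          slop: int = 200_000,
                          require: tuple[str, str] | None = None) -> int:
    """Count implanted sweeps with a detected region within `slop` bp.

    If `require` = (sharing, specificity), only regions carrying those labels
    count as detections.
    """
    n = 0
    for chrom, start, end, _ in truth:
        for r in regions:
            if r.chrom != chrom:
                continue
            if require and (r.sharing, r.specificity) != require:
                continue
            if r.start < end + slop and start - slop < r.end:
                n += 1
                break
    return n
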