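"""Seeded synthetic multi-breed cohorts with known differentiation and
implanted hard sweeps, plus the matching truth set.

Allele frequencies follow a two-level Balding-Nichols hierarchy: an ancestral
frequency per SNP (Uniform(0.05, 0.95)), a group frequency drawn around it
with the group's differentiation parameter F, and a breed frequency drawn
around the group's with a within-group F. Pairwise breed F_ST is then
approximately the mean of the two breeds' total divergences from the
ancestral pool, which lets the defaults reproduce the empirical cattle
gradient (~0.015 within Sudanese zebu, ~0.1 vs Gir, ~0.3 vs taurine).

Haplotypes are founder mosaics: each breed gets a pool of founder haplotypes
sampled from its frequencies, and every sampled haplotype copies a founder,
switching founders with a per-SNP-interval probability. This produces
realistic haplotype blocks and linkage without coalescent machinery. A sweep
is implanted by biasing mosaic sampling toward one designated founder in the
target breeds: a carrier haplotype (drawn with the sweep frequency) copies
the sweep founder over a span that shrinks with the carrier's draw, so the
sweep-haplotype frequency equals the specified value at the core and decays
linearly to zero at +/- half-width — yielding both the diversity trough and
the extended-homozygosity plateau the scans detect.

All randomness flows from a single seeded generator in documented order:
positions, ancestral frequencies, group then breed frequencies, founder
haplotypes, per-individual mosaics (breed by breed, individual by
individual), sweep carrier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import PanelMap, VariantTable

DEFAULT_GROUP_F = {
    "sudanese_zebu": 0.01,
    "east_african_zebu": 0.04,
    "sanga": 0.06,
    "gir": 0.16,
    "african_taurine": 0.55,
    "european_taurine": 0.55,
}


@dataclass(frozen=True)
class SweepSpec:
    chrom: str
    core: int  # bp
    half_width: int  # bp
    target_breeds: frozenset[str]
    frequency: float = 0.95  # sweep-haplotype frequency at the core

    def __post_init__(self) -> None:
        if not (0 < self.frequency <= 1):
            raise ValueError("sweep frequency must be in (0, 1]")
        if self.half_width <= 0:
            raise ValueError("sweep half-width must be positive")

    @property
    def interval(self) -> tuple[int, int]:
        return (max(self.core - self.half_width, 0), self.core + self.half_width)


@dataclass
class SimulationParams:
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    snp_density: float = 1.0  # expected SNPs per kb
    breeds: list[tuple[str, str, int]] = field(default_factory=list)  # (name, group, n_diploids)
    group_divergence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_F))
    breed_divergence: float = 0.015  # within-group Balding-Nichols F
    n_founder_haplotypes: int = 500
    switch_rate: float = 0.01  # founder-mosaic crossover probability per SNP interval
    sweeps: list[SweepSpec] = field(default_factory=list)
    keep_monomorphic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.breeds:
            self.breeds = default_breeds()
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        names = {b for b, _, _ in self.breeds}
        for g, f in self.group_divergence.items():
            if not (0 <= f < 1):
                raise ValueError(f"group {g}: F must be in [0, 1)")
        if not (0 <= self.breed_divergence < 1):
            raise ValueError("breed_divergence must be in [0, 1)")
        chroms = {self.chrom_name(i) for i in range(self.n_chromosomes)}
        for sw in self.sweeps:
            if sw.chrom not in chroms:
                raise ValueError(f"sweep chromosome {sw.chrom!r} not simulated")
            if not (0 <= sw.core < self.chrom_length):
                raise ValueError(f"sweep core {sw.core} outside chromosome")
            if not sw.target_breeds <= names:
                raise ValueError(
                    f"sweep targets not in panel: {sorted(sw.target_breeds - names)}")
        # overlapping sweeps on one chromosome sharing a target breed are ambiguous
        by_chrom: dict[str, list[SweepSpec]] = {}
        for sw in self.sweeps:
            by_chrom.setdefault(sw.chrom, []).append(sw)
        for chrom, sws in by_chrom.items():
            for i, s1 in enumerate(sws):
                for s2 in sws[i + 1:]:
                    a1, b1 = s1.interval
                    a2, b2 = s2.interval
                    if a1 < b2 and a2 < b1 and (s1.target_breeds & s2.target_breeds):
                        raise ValueError(
                            f"overlapping sweeps on {chrom} share target breeds")

    def chrom_name(self, i: int) -> str:
        return f"chr{i + 1}"


def default_breeds() -> list[tuple[str, str, int]]:
    """Eleven breeds, six diploids each: six Sudanese zebu, two East African
    zebu, one sanga, Gir, and one taurine outgroup."""
    sud = ["GAS", "ARY", "BTN", "KEN", "BAG", "FLN"]
    return (
        [(b, "sudanese_zebu", 6) for b in sud]
        + [("OGD", "east_african_zebu", 6), ("BOR", "east_african_zebu", 6)]
        + [("ANK", "sanga", 6), ("GIR", "gir", 6), ("NDA", "african_taurine", 6)]
    )


def default_sweeps() -> list[SweepSpec]:
    """Three hard sweeps in five Sudanese breeds (all but Fulani), emulating a
    250 kb sweep geometry."""
    targets = frozenset({"GAS", "ARY", "BTN", "KEN", "BAG"})
    return [
        SweepSpec("chr1", 3_000_000, 250_000, targets, 0.95),
        SweepSpec("chr1", 7_500_000, 250_000, targets, 0.95),
        SweepSpec("chr2", 5_000_000, 250_000, targets, 0.95),
    ]


TruthSet = list  # of (chrom, start, end, frozenset of target breeds)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    if f == 0:
        return p.copy()
    # frequencies already fixed (possible after an earlier high-F draw) stay fixed
    interior = (p > 0) & (p < 1)
    k = (1 - f) / f
    out = p.copy()
    out[interior] = rng.beta(k * p[interior], k * (1 - p[interior]))
    return out


def simulate_cohort(params: SimulationParams):
    """Generate (VariantTable, PanelMap, TruthSet) for one seeded cohort.

    Genotypes are returned phased. Sites monomorphic across the whole cohort
    are dropped unless params.keep_monomorphic is set.
    """
    rng = np.random.default_rng(params.seed)
    panel = PanelMap(
        {f"{b}_{i:02d}": b for b, _, n in params.breeds for i in range(n)},
        {b: g for b, g, _ in params.breeds},
    )
    groups = list(dict.fromkeys(g for _, g, _ in params.breeds))
    for g in groups:
        if g not in params.group_divergence:
            raise ValueError(f"no divergence parameter for group {g!r}")

    all_chrom, all_pos, all_geno = [], [], []
    for ci in range(params.n_chromosomes):
        chrom = params.chrom_name(ci)
        n_snps = rng.poisson(params.chrom_length * params.snp_density / 1000.0)
        pos = np.sort(rng.choice(params.chrom_length, size=n_snps, replace=False)) + 1
        p_anc = rng.uniform(0.05, 0.95, size=n_snps)
        p_group = {g: _balding_nichols(rng, p_anc, params.group_divergence[g])
                   for g in groups}
        haps_by_breed: dict[str, np.ndarray] = {}
        for breed, group, n_dip in params.breeds:
            p_breed = _balding_nichols(rng, p_group[group], params.breed_divergence)
            founders = (rng.random((params.n_founder_haplotypes, n_snps))
                        < p_breed).astype(np.uint8)
            sweeps_here = [s for s in params.sweeps
                           if s.chrom == chrom and breed in s.target_breeds]
            haps = np.empty((2 * n_dip, n_snps), dtype=np.uint8)
            for h in range(2 * n_dip):
                # founder mosaic: geometric segments over SNP indices
                switch = rng.random(n_snps) < params.switch_rate
                switch[0] = True
                seg_id = np.cumsum(switch) - 1
                choice = rng.integers(0, params.n_founder_haplotypes,
                                      size=seg_id[-1] + 1)
                src = choice[seg_id]
                hap = founders[src, np.arange(n_snps)]
                for sw in sweeps_here:
                    u = rng.random()
                    if u < sw.frequency:
                        # carrier: copy the sweep founder (index 0) over a span
                        # shrinking with u, so carrier frequency at distance d
                        # from the core is frequency * (1 - d / half_width);
                        # frequency 1.0 denotes a completed sweep, fixed across
                        # the whole interval
                        if sw.frequency == 1.0:
                            span = sw.half_width
                        else:
                            span = sw.half_width * (1 - u / sw.frequency)
                        d = np.abs(pos - (sw.core + 1))
                        m = d <= span
                        hap[m] = founders[0, np.flatnonzero(m)]
                haps[h] = hap
            haps_by_breed[breed] = haps
        geno = np.concatenate([haps_by_breed[b] for b, _, _ in params.breeds])
        # haplotype rows are (breed-major, two per diploid: rows 2i, 2i+1)
        n_total = geno.shape[0] // 2
        gt = np.empty((n_snps, n_total, 2), dtype=np.int8)
        gt[:, :, 0] = geno[0::2].T
        gt[:, :, 1] = geno[1::2].T
        all_chrom.append(np.full(n_snps, chrom, dtype=object))
        all_pos.append(pos)
        all_geno.append(gt)

    vt = VariantTable(
        chrom=np.concatenate(all_chrom),
        pos=np.concatenate(all_pos),
        ref=np.full(sum(len(p) for p in all_pos), "A", dtype=object),
        alt=np.full(sum(len(p) for p in all_pos), "G", dtype=object),
        genotypes=np.concatenate(all_geno),
        samples=panel.samples,
        phased=True,
    )
    if not params.keep_monomorphic:
        alt = np.count_nonzero(vt.genotypes == 1, axis=(1, 2))
        total = 2 * vt.n_samples
        vt = vt.take_sites((alt > 0) & (alt < total))
    truth: TruthSet = [
        (sw.chrom, max(sw.core - sw.half_width, 0),
         min(sw.core + sw.half_width, params.chrom_length), sw.target_breeds)
        for sw in params.sweeps
    ]
    return vt, panel, truth


def write_truth_bed(truth: TruthSet, path) -> None:
    """BED3+ truth file: 0-based half-open, column 4 = comma-joined targets."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttarget_breeds\n")
        for chrom, start, end, breeds in truth:
            fh.write(f"{chrom}\t{start}\t{end}\t{','.join(sorted(breeds))}\n")


def read_truth_bed(path) -> TruthSet:
    truth: TruthSet = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, breeds = line.rstrip("\n").split("\t")[:4]
            truth.append((chrom, int(start), int(end), frozenset(breeds.split(","))))
    return truth
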