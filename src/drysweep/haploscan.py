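"""Extended haplotype homozygosity on phased haplotypes: EHH decay curves,
integrated iHH, and the cross-population XP-EHH score with genome-wide
standardization and normal-tail -log10 p-values.

EHH at a flanking site x is the probability that two randomly drawn focal
haplotypes are identical over the extension between the core and x (the core
site itself is excluded from the extension, so EHH(core) = 1 under every
focal-allele convention, including the "all haplotypes" form that XP-EHH
uses). Distances are physical bp; no genetic map is interpolated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genio import PanelMap, VariantTable

log = logging.getLogger(__name__)


@dataclass
class HaplotypeBlock:
    """Binary haplotype matrix (haplotypes x SNPs) for one chromosome.

    Alleles are 0 = ref, 1 = alt; no missing values (phased input required).
    """

    chrom: str
    pos: np.ndarray  # bp, ascending
    haplotypes: np.ndarray  # (n_hap, n_snps) uint8
    labels: list[str]  # population label per haplotype

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if np.any(np.diff(self.pos) < 0):
            raise ValueError("positions must be ascending")
        if self.haplotypes.shape != (len(self.labels), len(self.pos)):
            raise ValueError("haplotype matrix shape mismatch")

    def subset(self, hap_mask: np.ndarray) -> "HaplotypeBlock":
        return HaplotypeBlock(self.chrom, self.pos, self.haplotypes[hap_mask],
                              [l for l, m in zip(self.labels, hap_mask) if m])


def block_from_variant_table(vt: VariantTable, panel: PanelMap,
                             chrom: str) -> HaplotypeBlock:
    """Split phased diploid genotypes of one chromosome into haplotypes,
    labelled by breed."""
    if not vt.phased:
        raise ValueError("haplotype statistics require phased genotypes")
    on = np.flatnonzero(vt.chrom == chrom)
    if len(on) == 0:
        raise ValueError(f"no sites on chromosome {chrom!r}")
    g = vt.genotypes[on]  # (sites, samples, 2)
    if np.any(g < 0):
        raise ValueError("missing alleles present; EHH requires complete phased data")
    haps = np.concatenate([g[:, :, 0].T, g[:, :, 1].T])  # 2*n_samples x n_sites
    labels = [panel.sample_to_breed[s] for s in vt.samples] * 2
    return HaplotypeBlock(chrom, vt.pos[on], haps.astype(np.uint8), labels)


@dataclass
class EhhCurve:
    core_index: int
    core_pos: int
    focal: object  # 0, 1, or "all"
    distance: np.ndarray  # signed bp from core, sorted ascending; 0 included
    ehh: np.ndarray
    n_haplotypes: int
    left_edge: bool = False  # chromosome end reached before max_extension
    right_edge: bool = False

    def side(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Points of one side ordered core-outward, core (0, 1.0) included."""
        if which == "left":
            m = self.distance <= 0
            return -self.distance[m][::-1], self.ehh[m][::-1]
        m = self.distance >= 0
        return self.distance[m], self.ehh[m]


def _pairs(counts: np.ndarray) -> float:
    return float(np.sum(counts * (counts - 1) / 2))


def ehh(block: HaplotypeBlock, core_index: int, focal=1,
        max_extension: int = 1_000_000, min_ehh: float = 0.0) -> EhhCurve:
    """EHH decay curve around one core SNP.

    focal 0/1 restricts to haplotypes carrying that allele at the core;
    focal "all" uses every haplotype (the XP-EHH convention). The curve is
    computed outward in both directions until max_extension bp or the
    chromosome end; it is non-increasing outward by construction. A nonzero
    min_ehh stops a direction one point after the curve falls below it (EHH
    cannot recover outward, so points past the first sub-threshold one are
    never used by the integrator).
    """
    H = block.haplotypes
    if focal == "all":
        carriers = np.arange(H.shape[0])
    else:
        carriers = np.flatnonzero(H[:, core_index] == focal)
    n = len(carriers)
    if n < 2:
        raise ValueError(f"focal allele {focal!r} has {n} carriers (< 2)")
    denom = n * (n - 1) / 2
    core_pos = int(block.pos[core_index])

    dists, vals = [0], [1.0]
    edges = {}
    for direction in (+1, -1):
        gid = np.zeros(n, dtype=np.int64)
        j = core_index
        reached_end = True  # until proven otherwise by hitting max_extension
        while True:
            j += direction
            if j < 0 or j >= H.shape[1]:
                break
            d = abs(int(block.pos[j]) - core_pos)
            if d > max_extension:
                reached_end = False
                break
            key = gid * 2 + H[carriers, j]
            _, gid, cnt = np.unique(key, return_inverse=True, return_counts=True)
            dists.append(direction * d)
            v = _pairs(cnt) / denom
            vals.append(v)
            if v < min_ehh:
                reached_end = False
                break
        edges[direction] = reached_end

    order = np.argsort(dists, kind="stable")
    return EhhCurve(core_index, core_pos, focal,
                    np.asarray(dists)[order], np.asarray(vals, dtype=float)[order],
                    n, left_edge=edges[-1], right_edge=edges[+1])


@dataclass
class IhhResult:
    value: float
    edge: bool  # chromosome end reached before EHH fell below cutoff


def ihh(curve: EhhCurve, cutoff: float = 0.05) -> IhhResult:
    """Integrated EHH: trapezoids over bp distance, left + right of the core.

    Each side stops before the first point whose EHH is below the cutoff (no
    partial trapezoid to the crossing). If a side ends at the chromosome edge
    without reaching the cutoff, the result carries an edge flag.
    """
    total, edge = 0.0, False
    for which, side_edge in (("left", curve.left_edge), ("right", curve.right_edge)):
        d, e = curve.side(which)
        stop = np.flatnonzero(e < cutoff)
        if len(stop):
            d, e = d[: stop[0]], e[: stop[0]]
        elif side_edge:
            edge = True
        if len(d) > 1:
            total += float(np.trapezoid(e, d))
    return IhhResult(total, edge)


def xpehh(block: HaplotypeBlock, pop_a: set[str] | list[str],
          pop_b: set[str] | list[str], cores: np.ndarray | None = None,
          max_extension: int = 1_000_000, cutoff: float = 0.05,
          threshold: float = 4.0, drop_edge: bool = False) -> pd.DataFrame:
    """Cross-population EHH scan between two breed-label sets.

    Per core SNP the unstandardized score is ln(iHH_A / iHH_B) with focal
    allele "all"; scores are standardized genome-wide (mean 0, population
    sigma 1 over all cores) and converted to two-sided standard-normal
    -log10 p-values. Positive scores mean longer haplotype homozygosity in
    population A. Cores where either iHH is zero are dropped (count logged).
    """
    labels = np.asarray(block.labels)
    mask_a = np.isin(labels, list(pop_a))
    mask_b = np.isin(labels, list(pop_b))
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each population needs >= 2 haplotypes")
    sub_a, sub_b = block.subset(mask_a), block.subset(mask_b)

    if cores is None:
        cores = np.arange(len(block.pos))
    rows, n_dropped = [], 0
    for core in cores:
        ia = ihh(ehh(sub_a, int(core), "all", max_extension, min_ehh=cutoff), cutoff)
        ib = ihh(ehh(sub_b, int(core), "all", max_extension, min_ehh=cutoff), cutoff)
        if ia.value <= 0 or ib.value <= 0:
            n_dropped += 1
            continue
        rows.append((int(block.pos[core]), math.log(ia.value / ib.value),
                     ia.edge or ib.edge))
    if n_dropped:
        log.info("xpehh: dropped %d cores with zero iHH", n_dropped)
    df = pd.DataFrame(rows, columns=["pos", "score_raw", "edge"])
    if drop_edge:
        df = df[~df["edge"]].reset_index(drop=True)
    if len(df) == 0:
        df["score_std"] = df["neglog10_p"] = df["significant"] = []
        return df
    raw = df["score_raw"].to_numpy()
    sigma = raw.std(ddof=0)
    if sigma == 0:
        std = np.zeros_like(raw)
    else:
        std = (raw - raw.mean()) / sigma
    df["score_std"] = std
    # -log10 of the two-sided normal p, computed in log space for deep tails
    df["neglog10_p"] = -(np.log(2.0) + norm.logsf(np.abs(std))) / np.log(10.0)
    df["significant"] = df["neglog10_p"] > threshold
    return df


def neglog10_two_sided_p(z: float) -> float:
    """-log10 of the two-sided standard-normal p-value of a z-score."""
    return float(-(math.log(2.0) + norm.logsf(abs(z))) / math.log(10.0))


def decay_report(block: HaplotypeBlock, core_pos: int,
                 populations: dict[str, set[str] | list[str]],
                 max_extension: int = 1_000_000) -> pd.DataFrame:
    """Per-population, per-core-allele EHH decay curves around one position.

    The reference allele is labelled ancestral and the alternate derived (a
    documented proxy; no outgroup polarization is attempted). Allele curves
    with fewer than two carriers in a population are omitted with a note.
    Returns a tidy frame: population, allele, distance, pos, ehh.
    """
    hits = np.flatnonzero(block.pos == core_pos)
    if len(hits) == 0:
        raise ValueError(f"core position {core_pos} not in block")
    core = int(hits[0])
    labels = np.asarray(block.labels)
    frames = []
    for name, breeds in populations.items():
        sub = block.subset(np.isin(labels, list(breeds)))
        for allele, tag in ((0, "ancestral"), (1, "derived")):
            if int((sub.haplotypes[:, core] == allele).sum()) < 2:
                log.info("decay_report: %s allele %s has <2 carriers in %s; omitted",
                         core_pos, tag, name)
                continue
            cur = ehh(sub, core, allele, max_extension)
            frames.append(pd.DataFrame({
                "population": name, "allele": tag,
                "distance": cur.distance, "pos": core_pos + cur.distance,
                "ehh": cur.ehh,
            }))
    if not frames:
        return pd.DataFrame(columns=["population", "allele", "distance", "pos", "ehh"])
    return pd.concat(frames, ignore_index=True)


def plot_decay(report: pd.DataFrame, path) -> None:
    """Optional EHH-decay plot (one panel per population); needs matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pops = report["population"].unique()
    fig, axes = plt.subplots(1, max(len(pops), 1), figsize=(4 * max(len(pops), 1), 3),
                             sharey=True, squeeze=False)
    for ax, pop in zip(axes[0], pops):
        sub = report[report["population"] == pop]
        for allele, grp in sub.groupby("allele"):
            ax.plot(grp["distance"] / 1e3, grp["ehh"], label=allele)
        ax.set_title(pop)
        ax.set_xlabel("distance from core (kb)")
        ax.legend()
    axes[0][0].set_ylabel("EHH")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
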