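"""Variant and panel I/O, the sliding-window grid, and per-breed allele bookkeeping.

Coordinate convention: VCF positions are 1-based; every internal window and
all BED output are 0-based half-open. The conversion happens exactly once, at
ingest (`read_vcf`) or emission (`write_vcf`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = frozenset("ACGT")


@dataclass
class VariantTable:
    """Bi-allelic SNP sites with per-sample diploid genotypes.

    genotypes has shape (n_sites, n_samples, 2) with allele codes
    0 = ref, 1 = alt, -1 = missing. Positions are 1-based (VCF convention)
    and strictly increasing within a chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    phased: bool = False

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (self.n_sites, self.n_samples, 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{self.n_sites} sites x {self.n_samples} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return np.array([lookup[n] for n in names], dtype=np.intp)

    def take_sites(self, mask_or_index) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[mask_or_index],
            pos=self.pos[mask_or_index],
            ref=self.ref[mask_or_index],
            alt=self.alt[mask_or_index],
            genotypes=self.genotypes[mask_or_index],
            samples=list(self.samples),
            phased=self.phased,
        )

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites on `chrom` with 0-based position in [start, end)."""
        on = np.flatnonzero(self.chrom == chrom)
        pos0 = self.pos[on] - 1
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        return on[lo:hi]


@dataclass
class PanelMap:
    """sample -> breed and breed -> group assignments."""

    sample_to_breed: dict[str, str]
    breed_to_group: dict[str, str]

    def __post_init__(self) -> None:
        unknown = {b for b in self.sample_to_breed.values() if b not in self.breed_to_group}
        if unknown:
            raise ValueError(f"breeds without a group assignment: {sorted(unknown)}")

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_breed)

    @property
    def breeds(self) -> list[str]:
        return list(self.breed_to_group)

    def samples_of(self, breed: str) -> list[str]:
        if breed not in self.breed_to_group:
            raise KeyError(f"unknown breed {breed!r}")
        return [s for s, b in self.sample_to_breed.items() if b == breed]

    def breeds_in(self, *groups: str) -> list[str]:
        return [b for b, g in self.breed_to_group.items() if g in groups]

    def group_of(self, breed: str) -> str:
        return self.breed_to_group[breed]


def read_panel(path) -> PanelMap:
    """Read a 3-column TSV: sample, breed, group (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["sample", "breed", "group"], dtype=str)
    if df.iloc[0].tolist() == ["sample", "breed", "group"]:
        df = df.iloc[1:]
    s2b = dict(zip(df["sample"], df["breed"]))
    b2g = dict(zip(df["breed"], df["group"]))
    return PanelMap(s2b, b2g)


def write_panel(panel: PanelMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tbreed\tgroup\n")
        for s, b in panel.sample_to_breed.items():
            fh.write(f"{s}\t{b}\t{panel.breed_to_group[b]}\n")


# ---------------------------------------------------------------------------
# VCF I/O

def read_vcf(path, panel: PanelMap | None = None) -> VariantTable:
    """Load bi-allelic SNPs from a VCF.

    Multi-allelic and non-SNP records are dropped (counts logged). If a panel
    is given, samples are reordered to panel order and every panel sample must
    be present in the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    if panel is not None:
        absent = [s for s in panel.samples if s not in vcf_samples]
        if absent:
            raise ValueError(f"panel samples missing from VCF: {absent}")
        order = np.array([vcf_samples.index(s) for s in panel.samples], dtype=np.intp)
        samples = panel.samples
    else:
        order = np.arange(len(vcf_samples), dtype=np.intp)
        samples = vcf_samples

    chroms, poss, refs, alts, gts = [], [], [], [], []
    n_dropped = 0
    phased = True
    for rec in vcf:
        if len(rec.ALT) != 1 or rec.REF not in _BASES or rec.ALT[0] not in _BASES:
            n_dropped += 1
            continue
        g = np.asarray(rec.genotype.array(), dtype=np.int16)
        if g.shape[1] < 2:
            raise ValueError(f"malformed GT (haploid?) at {rec.CHROM}:{rec.POS}")
        alleles = g[order, :2].astype(np.int8)
        if np.any(alleles > 1):
            raise ValueError(f"malformed GT allele code at {rec.CHROM}:{rec.POS}")
        alleles[alleles < 0] = MISSING
        called = alleles[:, 0] >= 0
        if np.any(called & (g[order, 2] == 0)):  # phase flag, missing exempt
            phased = False
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gts.append(alleles)
    if n_dropped:
        log.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)

    return VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=(np.stack(gts) if gts else np.empty((0, len(samples), 2), np.int8)),
        samples=list(samples),
        phased=phased,
    )


def write_vcf(vt: VariantTable, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a VCFv4.2 file; phased genotypes use '|', unphased '/'."""
    sep = "|" if vt.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=drysweep\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.samples) + "\n")
        for i in range(vt.n_sites):
            g = vt.genotypes[i]
            cells = [
                "./." if g[j, 0] == MISSING or g[j, 1] == MISSING
                else f"{g[j, 0]}{sep}{g[j, 1]}"
                for j in range(vt.n_samples)
            ]
            fh.write(f"{vt.chrom[i]}\t{vt.pos[i]}\t.\t{vt.ref[i]}\t{vt.alt[i]}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Window grid

def make_windows(chrom_lengths: dict[str, int], window_size: int = 100_000,
                 step: int = 50_000) -> pd.DataFrame:
    """Sliding windows: starts at 0, step, 2*step, ... while start < length.

    Returns a DataFrame with columns chrom, start, end, partial; 0-based
    half-open. Trailing windows shorter than window_size are flagged partial.
    """
    if not (window_size >= step > 0):
        raise ValueError("require window_size >= step > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"nonpositive length for {chrom}")
        start = 0
        while start < length:
            end = min(start + window_size, length)
            rows.append((chrom, start, end, end - start < window_size))
            start += step
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])
    df.index.name = "window"
    return df


# ---------------------------------------------------------------------------
# Allele counting and summaries

def breed_allele_counts(
    vt: VariantTable,
    panel: PanelMap,
    breed: str,
    sample_subset_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-site ref/alt and major/minor allele counts within one breed.

    Missing genotypes are excluded. Major = max(ref, alt) with ties resolved
    as major := ref (inert for Hp, which is symmetric). Optional seeded
    subsampling to `sample_subset_size` individuals before counting.
    """
    names = panel.samples_of(breed)
    if not names:
        raise ValueError(f"breed {breed!r} has no samples")
    if sample_subset_size is not None:
        if sample_subset_size > len(names):
            raise ValueError(f"subset size {sample_subset_size} exceeds breed size {len(names)}")
        rng = rng or np.random.default_rng()
        names = [names[i] for i in rng.choice(len(names), sample_subset_size, replace=False)]
    idx = vt.sample_indices(names)
    g = vt.genotypes[:, idx, :]
    ref = np.count_nonzero(g == 0, axis=(1, 2))
    alt = np.count_nonzero(g == 1, axis=(1, 2))
    major = np.maximum(ref, alt)
    minor = np.minimum(ref, alt)
    return pd.DataFrame({"ref": ref, "alt": alt, "major": major, "minor": minor})


def summarize_variants(vt: VariantTable, panel: PanelMap) -> pd.DataFrame:
    """Per-breed segregating sites, het / hom-alt counts, Het/Hom and Ts/Tv ratios.

    A site segregates in a breed when at least one member carries an alternate
    allele; transitions are A<->G and C<->T. Het/Hom is NaN when no non-ref
    homozygote exists.
    """
    is_ts = np.array([(r, a) in _TRANSITIONS for r, a in zip(vt.ref, vt.alt)])
    rows = []
    for breed in panel.breeds:
        idx = vt.sample_indices(panel.samples_of(breed))
        g = vt.genotypes[:, idx, :]
        has_alt = np.any(g == 1, axis=(1, 2))
        het = np.count_nonzero((g[:, :, 0] != g[:, :, 1])
                               & (g[:, :, 0] >= 0) & (g[:, :, 1] >= 0))
        hom_alt = np.count_nonzero((g[:, :, 0] == 1) & (g[:, :, 1] == 1))
        ts = int(np.count_nonzero(has_alt & is_ts))
        tv = int(np.count_nonzero(has_alt & ~is_ts))
        rows.append({
            "breed": breed,
            "segregating_sites": int(has_alt.sum()),
            "het": int(het),
            "hom_alt": int(hom_alt),
            "het_hom_ratio": het / hom_alt if hom_alt > 0 else float("nan"),
            "transitions": ts,
            "transversions": tv,
            "ts_tv_ratio": ts / tv if tv > 0 else float("nan"),
        })
    return pd.DataFrame(rows).set_index("breed")


def filter_maf(vt: VariantTable, min_maf: float = 0.05) -> VariantTable:
    """Drop sites with cohort-wide minor allele frequency < min_maf.

    Frequencies are computed over non-missing alleles only.
    """
    if not (0 <= min_maf < 0.5):
        raise ValueError("require 0 <= min_maf < 0.5")
    if min_maf == 0:
        return vt
    g = vt.genotypes
    alt = np.count_nonzero(g == 1, axis=(1, 2))
    called = np.count_nonzero(g >= 0, axis=(1, 2))
    with np.errstate(invalid="ignore"):
        af = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
    maf = np.minimum(af, 1 - af)
    return vt.take_sites(maf >= min_maf)


def write_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
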