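"""From per-breed outlier windows to merged, classified sweep regions.

Candidate windows are grid windows flagged as ZHp outliers in at least two
Sudanese zebu breeds (evaluated on exact window-grid coordinates — the shared
grid makes this well-defined). Neighbouring candidates within 5 kb are merged
into regions. A region is "shared" if any non-Sudanese zebu breed has an
overlapping outlier window, otherwise "unique_sudanese". Lineage specificity
is then assigned from the F_ST contrast overlaps; "overlap" everywhere means
any shared bp (the BEDTools intersect default), never a fraction threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genio import PanelMap

log = logging.getLogger(__name__)

SUDANESE_GROUP = "sudanese_zebu"
NON_SUDANESE_ZEBU_GROUPS = ("east_african_zebu", "sanga", "gir")
GIR_GROUP = "gir"
AFRICAN_ZEBU_GROUPS = ("east_african_zebu", "sanga")

SHARED = "shared"
UNIQUE = "unique_sudanese"

SPEC_SUDANESE = "sudanese"
SPEC_BOS_INDICUS = "bos_indicus"
SPEC_AFRICAN_ZEBU = "african_zebu"
SPEC_UNCLASSIFIED = "unclassified"


@dataclass
class SweepRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    breeds_detected: frozenset[str]
    source_windows: tuple[tuple[int, int], ...] = ()
    sharing: str | None = None
    specificity: str | None = None
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def gene_rich(self) -> bool:
        return len(self.genes) >= 5

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def merge_windows(windows: pd.DataFrame, max_gap: int = 5000) -> list[SweepRegion]:
    """Merge overlapping windows and windows separated by <= max_gap bp.

    `windows` needs columns chrom, start, end and optionally `breeds` (a
    set/frozenset per row); breeds_detected is the union over merged windows.
    Merging is order-independent and idempotent; output regions are pairwise
    separated by more than max_gap.
    """
    if len(windows) == 0:
        return []
    has_breeds = "breeds" in windows.columns
    df = windows.sort_values(["chrom", "start", "end"], kind="stable")
    regions: list[SweepRegion] = []
    cur = None
    for row in df.itertuples(index=False):
        breeds = frozenset(getattr(row, "breeds")) if has_breeds else frozenset()
        if (cur is not None and row.chrom == cur.chrom
                and row.start - cur.end <= max_gap):
            cur = replace(
                cur,
                end=max(cur.end, row.end),
                breeds_detected=cur.breeds_detected | breeds,
                source_windows=cur.source_windows + ((row.start, row.end),),
            )
        else:
            if cur is not None:
                regions.append(cur)
            cur = SweepRegion(row.chrom, int(row.start), int(row.end), breeds,
                              ((int(row.start), int(row.end)),))
    regions.append(cur)
    return regions


def _outlier_windows(track: pd.DataFrame) -> pd.DataFrame:
    return track.loc[track["outlier"], ["chrom", "start", "end"]]


def sharing_classify(hp_tracks: dict[str, pd.DataFrame], panel: PanelMap,
                     max_gap: int = 5000) -> list[SweepRegion]:
    """Candidate regions from per-breed ZHp outlier tracks, with sharing labels.

    hp_tracks maps breed name to its outlier-called window track (all tracks
    share one window grid). Requires >= 2 Sudanese zebu breeds. Non-Sudanese
    zebu breeds detecting an overlapping outlier window are added to
    breeds_detected and make the region "shared".
    """
    sudanese = [b for b in hp_tracks if panel.group_of(b) == SUDANESE_GROUP]
    if len(sudanese) < 2:
        raise ValueError(f"need >= 2 Sudanese zebu tracks, got {len(sudanese)}")
    others = [b for b in hp_tracks
              if panel.group_of(b) in NON_SUDANESE_ZEBU_GROUPS]

    # per grid window, which Sudanese breeds flag it
    per_window: dict[tuple[str, int, int], set[str]] = {}
    for breed in sudanese:
        for row in _outlier_windows(hp_tracks[breed]).itertuples(index=False):
            per_window.setdefault((row.chrom, row.start, row.end), set()).add(breed)
    cand = [(c, s, e, frozenset(bs)) for (c, s, e), bs in per_window.items()
            if len(bs) >= 2]
    if not cand:
        return []
    cand_df = pd.DataFrame(cand, columns=["chrom", "start", "end", "breeds"])
    regions = merge_windows(cand_df, max_gap=max_gap)

    trees: dict[tuple[str, str], IntervalTree] = {}
    for breed in others:
        for row in _outlier_windows(hp_tracks[breed]).itertuples(index=False):
            trees.setdefault((breed, row.chrom), IntervalTree()).addi(row.start, row.end)
    out = []
    for reg in regions:
        hit_breeds = {b for b in others
                      if (b, reg.chrom) in trees
                      and trees[(b, reg.chrom)].overlap(reg.start, reg.end)}
        out.append(replace(
            reg,
            breeds_detected=reg.breeds_detected | hit_breeds,
            sharing=SHARED if hit_breeds else UNIQUE,
        ))
    return out


def _track_tree(track: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in _outlier_windows(track).itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def specificity_classify(regions: list[SweepRegion],
                         fst_tracks: dict[str, pd.DataFrame],
                         panel: PanelMap) -> list[SweepRegion]:
    """Assign lineage specificity from F_ST-contrast outlier overlaps.

    Decision table (precedence sudanese > bos_indicus > african_zebu):
      sudanese     — detected only in Sudanese breeds and the region overlaps
                     any contrast's outlier windows;
      bos_indicus  — detected in Gir and >= 1 (non-Gir) African zebu, overlaps
                     the vs-taurine contrast (A3) only;
      african_zebu — detected in >= 1 Sudanese and >= 1 non-Gir African zebu
                     but not Gir, overlaps A3 only;
      unclassified otherwise.
    """
    for name in ("A1", "A2", "A3"):
        if name not in fst_tracks:
            raise ValueError(f"missing F_ST track {name!r}")
    trees = {name: _track_tree(tr) for name, tr in fst_tracks.items()}
    sudanese = set(panel.breeds_in(SUDANESE_GROUP))
    gir = set(panel.breeds_in(GIR_GROUP))
    african_zebu = set(panel.breeds_in(*AFRICAN_ZEBU_GROUPS))

    out = []
    for reg in regions:
        hits = {name: (reg.chrom in t and bool(t[reg.chrom].overlap(reg.start, reg.end)))
                for name, t in trees.items()}
        det = reg.breeds_detected
        a3_only = hits["A3"] and not hits["A1"] and not hits["A2"]
        if det <= sudanese and any(hits.values()):
            spec = SPEC_SUDANESE
        elif (det & gir) and (det & african_zebu) and a3_only:
            spec = SPEC_BOS_INDICUS
        elif (det & sudanese) and (det & african_zebu) and not (det & gir) and a3_only:
            spec = SPEC_AFRICAN_ZEBU
        else:
            spec = SPEC_UNCLASSIFIED
        out.append(replace(reg, specificity=spec))
    return out


# ---------------------------------------------------------------------------
# Gene annotation

def read_genes(path, protein_coding_only: bool = True,
               gff_id_attr: str = "gene_id") -> pd.DataFrame:
    """Load genes from BED (4+ columns) or GFF3 into chrom/start/end/gene_id/biotype.

    GFF3 rows with feature type 'gene' are used; coordinates are converted to
    0-based half-open. The biotype filter applies only where a biotype is
    present (BED input carries none).
    """
    path = str(path)
    rows = []
    is_gff = path.endswith((".gff", ".gff3", ".gtf"))
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if is_gff:
                if f[2] != "gene":
                    continue
                attrs = {}
                for kv in f[8].replace("; ", ";").split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                    elif " " in kv.strip():
                        k, v = kv.strip().split(" ", 1)
                    else:
                        continue
                    attrs[k.strip()] = v.strip().strip('"')
                gid = attrs.get(gff_id_attr) or attrs.get("ID") or attrs.get("Name")
                biotype = attrs.get("biotype") or attrs.get("gene_biotype") or ""
                rows.append((f[0], int(f[3]) - 1, int(f[4]), gid,
                             f[6], biotype))
            else:
                gid = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                strand = f[5] if len(f) > 5 else "."
                biotype = f[6] if len(f) > 6 else ""
                rows.append((f[0], int(f[1]), int(f[2]), gid, strand, biotype))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id",
                                        "strand", "biotype"])
    if protein_coding_only:
        genes = genes[(genes["biotype"] == "protein_coding") | (genes["biotype"] == "")]
    return genes.reset_index(drop=True)


def gene_overlap(regions: list[SweepRegion], genes: pd.DataFrame) -> list[SweepRegion]:
    """Attach any-overlap gene lists; gene_rich means >= 5 genes."""
    if len(genes) and regions:
        reg_chroms = {r.chrom for r in regions}
        if not (reg_chroms & set(genes["chrom"])):
            raise ValueError(
                f"no shared chromosome names between regions {sorted(reg_chroms)} "
                f"and genes {sorted(set(genes['chrom']))}")
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.gene_id)
    out = []
    for reg in regions:
        hits = sorted({iv.data for iv in trees.get(reg.chrom, IntervalTree())
                       .overlap(reg.start, reg.end)})
        out.append(replace(reg, genes=tuple(hits)))
    return out


# ---------------------------------------------------------------------------
# Reporting

def regions_table(regions: list[SweepRegion]) -> pd.DataFrame:
    """Annotated region table (BED-style coordinates plus an Mb display column)."""
    return pd.DataFrame([{
        "chrom": r.chrom,
        "start": r.start,
        "end": r.end,
        "region_mb": f"{r.chrom}:{r.start / 1e6:.2f}-{r.end / 1e6:.2f} Mb",
        "n_breeds": len(r.breeds_detected),
        "breeds_detected": ",".join(sorted(r.breeds_detected)),
        "sharing": r.sharing or "",
        "specificity": r.specificity or "",
        "n_genes": len(r.genes),
        "gene_rich": r.gene_rich,
        "genes": ",".join(r.genes),
    } for r in regions])


def report(regions: list[SweepRegion],
           gene_sets: dict[str, set[str]] | None = None
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region table plus a set-overlap summary (sharing/specificity counts and,
    if gene_sets are given, pairwise gene-set intersection counts)."""
    table = regions_table(regions)
    rows = []
    for label in (SHARED, UNIQUE):
        rows.append(("sharing", label, sum(r.sharing == label for r in regions)))
    for label in (SPEC_SUDANESE, SPEC_BOS_INDICUS, SPEC_AFRICAN_ZEBU, SPEC_UNCLASSIFIED):
        rows.append(("specificity", label, sum(r.specificity == label for r in regions)))
    rows.append(("regions", "gene_rich", sum(r.gene_rich for r in regions)))
    rows.append(("regions", "total", len(regions)))
    if gene_sets:
        names = sorted(gene_sets)
        for i, n1 in enumerate(names):
            rows.append(("gene_set", n1, len(gene_sets[n1])))
            for n2 in names[i + 1:]:
                rows.append(("gene_set_intersection", f"{n1}&{n2}",
                             len(gene_sets[n1] & gene_sets[n2])))
    summary = pd.DataFrame(rows, columns=["category", "label", "count"])
    return table, summary


def write_regions_bed(regions: list[SweepRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for r in regions:
            name = f"{r.sharing or 'region'}|{r.specificity or 'NA'}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")
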