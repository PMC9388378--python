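import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drysweep import sweeps
from drysweep.genio import PanelMap
from drysweep.sweeps import (SPEC_AFRICAN_ZEBU, SPEC_BOS_INDICUS, SPEC_SUDANESE,
                             SPEC_UNCLASSIFIED, SHARED, UNIQUE, SweepRegion)


def wdf(rows, breeds=None):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if breeds is not None:
        df["breeds"] = breeds
    return df


TOY_PANEL = PanelMap(
    {"s0": "S1", "s1": "S2", "s2": "G", "s3": "E"},
    {"S1": "sudanese_zebu", "S2": "sudanese_zebu", "G": "gir",
     "E": "east_african_zebu"},
)


def grid_track(outliers, n=40, chrom="chr1"):
    """A toy outlier-called track on a shared 100 kb / 50 kb grid."""
    starts = np.arange(n) * 50_000
    df = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + 100_000,
        "n_snps": 50, "value": 0.1, "retained": True, "z": 0.0,
        "outlier": False,
    })
    for s in outliers:
        df.loc[df["start"] == s, "outlier"] = True
    return df


class TestMergeWindows:
    def test_overlap_merges(self):
        regs = sweeps.merge_windows(wdf([("chr1", 100_000, 200_000),
                                         ("chr1", 150_000, 250_000)]))
        assert [(r.start, r.end) for r in regs] == [(100_000, 250_000)]

    def test_gap_boundary_inclusive_at_5000(self):
        merged = sweeps.merge_windows(wdf([("chr1", 100_000, 200_000),
                                           ("chr1", 205_000, 305_000)]))
        assert len(merged) == 1
        split = sweeps.merge_windows(wdf([("chr1", 100_000, 200_000),
                                          ("chr1", 205_001, 305_001)]))
        assert len(split) == 2

    def test_chromosomes_never_merge(self):
        regs = sweeps.merge_windows(wdf([("chr1", 0, 100), ("chr2", 50, 200)]))
        assert len(regs) == 2

    def test_breed_union_and_source_window_bookkeeping(self):
        regs = sweeps.merge_windows(wdf(
            [("chr1", 0, 100_000), ("chr1", 50_000, 150_000)],
            breeds=[{"GAS"}, {"ARY", "KEN"}]))
        assert regs[0].breeds_detected == frozenset({"GAS", "ARY", "KEN"})
        assert len(regs[0].source_windows) == 2

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(1, 6)),
                    min_size=1, max_size=12),
           st.randoms(use_true_random=False))
    def test_order_independent_idempotent_and_gap_correct(self, spans, rnd):
        rows = [("chr1", s * 10_000, (s + w) * 10_000) for s, w in spans]
        shuffled = rows[:]
        rnd.shuffle(shuffled)
        a = sweeps.merge_windows(wdf(rows))
        b = sweeps.merge_windows(wdf(shuffled))
        assert [(r.chrom, r.start, r.end) for r in a] == \
               [(r.chrom, r.start, r.end) for r in b]
        # idempotence: merging the merged intervals changes nothing
        again = sweeps.merge_windows(wdf([(r.chrom, r.start, r.end) for r in a]))
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in a]
        # output pairwise gaps exceed the merge gap
        for r1, r2 in zip(a, a[1:]):
            if r1.chrom == r2.chrom:
                assert r2.start - r1.end > 5000
        # every source window is contained in exactly one region
        for chrom, s, e in rows:
            hits = [r for r in a if r.chrom == chrom and r.start <= s and e <= r.end]
            assert len(hits) == 1

    def test_agrees_with_bedtools_merge(self, tmp_path):
        if shutil.which("bedtools") is None:
            pytest.skip("bedtools unavailable")
        rng = np.random.default_rng(19)
        starts = np.sort(rng.choice(4000, 60, replace=False)) * 1000
        rows = [("chr1", int(s), int(s + rng.integers(1, 120) * 1000))
                for s in starts]
        bed = tmp_path / "in.bed"
        bed.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in sorted(rows)))
        out = subprocess.run(["bedtools", "merge", "-d", "5000", "-i", str(bed)],
                             capture_output=True, text=True, check=True).stdout
        expected = [tuple(l.split("\t")) for l in out.strip().split("\n")]
        expected = [(c, int(s), int(e)) for c, s, e in expected]
        ours = [(r.chrom, r.start, r.end) for r in sweeps.merge_windows(wdf(rows))]
        assert ours == expected


class TestSharingClassify:
    def test_single_sudanese_breed_window_is_not_candidate(self):
        tracks = {"S1": grid_track([500_000]), "S2": grid_track([]),
                  "G": grid_track([])}
        assert sweeps.sharing_classify(tracks, TOY_PANEL) == []

    def test_two_sudanese_breeds_make_candidate_unique(self):
        tracks = {"S1": grid_track([500_000]), "S2": grid_track([500_000]),
                  "G": grid_track([])}
        regs = sweeps.sharing_classify(tracks, TOY_PANEL)
        assert len(regs) == 1
        assert regs[0].sharing == UNIQUE
        assert regs[0].breeds_detected == frozenset({"S1", "S2"})

    def test_any_overlap_with_non_sudanese_outlier_marks_shared(self):
        # Gir outlier window [550000, 650000) overlaps the candidate by 50 kb;
        # the any-shared-bp rule also catches a 1 bp overlap via the grid.
        tracks = {"S1": grid_track([500_000]), "S2": grid_track([500_000]),
                  "G": grid_track([550_000])}
        regs = sweeps.sharing_classify(tracks, TOY_PANEL)
        assert regs[0].sharing == SHARED
        assert "G" in regs[0].breeds_detected

    def test_requires_two_sudanese_tracks(self):
        with pytest.raises(ValueError, match="Sudanese"):
            sweeps.sharing_classify({"S1": grid_track([]), "G": grid_track([])},
                                    TOY_PANEL)

    def test_adjacent_candidate_windows_merge_into_one_region(self):
        tracks = {"S1": grid_track([500_000, 550_000, 600_000]),
                  "S2": grid_track([500_000, 550_000, 600_000]),
                  "G": grid_track([])}
        regs = sweeps.sharing_classify(tracks, TOY_PANEL)
        assert [(r.start, r.end) for r in regs] == [(500_000, 700_000)]


def expected_specificity(detected, hits, sudanese={"S1", "S2"}, gir={"G"},
                         african_zebu={"E"}):
    """Hand-written truth table for the lineage-specificity decision."""
    a3_only = hits["A3"] and not hits["A1"] and not hits["A2"]
    if detected <= sudanese and any(hits.values()):
        return SPEC_SUDANESE
    if detected & gir and detected & african_zebu and a3_only:
        return SPEC_BOS_INDICUS
    if (detected & sudanese and detected & african_zebu
            and not detected & gir and a3_only):
        return SPEC_AFRICAN_ZEBU
    return SPEC_UNCLASSIFIED


class TestSpecificityClassify:
    def fst_tracks(self, hits):
        # outlier window at the region's span iff that contrast "hits"
        return {name: grid_track([500_000] if hit else [])
                for name, hit in hits.items()}

    @pytest.mark.parametrize("detected", [
        frozenset(s) for n in (1, 2, 3, 4)
        for s in itertools.combinations(["S1", "S2", "G", "E"], n)
    ])
    @pytest.mark.parametrize("hit_combo", list(itertools.product([False, True],
                                                                 repeat=3)))
    def test_exhaustive_against_truth_table(self, detected, hit_combo):
        hits = dict(zip(["A1", "A2", "A3"], hit_combo))
        region = SweepRegion("chr1", 500_000, 600_000, detected)
        out = sweeps.specificity_classify([region], self.fst_tracks(hits),
                                          TOY_PANEL)[0]
        assert out.specificity == expected_specificity(detected, hits)

    def test_region_missing_track_errors(self):
        region = SweepRegion("chr1", 0, 100, frozenset({"S1"}))
        with pytest.raises(ValueError, match="A3"):
            sweeps.specificity_classify(
                [region], {"A1": grid_track([]), "A2": grid_track([])}, TOY_PANEL)

    def test_no_fst_overlap_is_unclassified(self):
        region = SweepRegion("chr1", 2_000_000, 2_100_000, frozenset({"S1", "S2"}))
        out = sweeps.specificity_classify(
            [region], self.fst_tracks({"A1": True, "A2": True, "A3": True}),
            TOY_PANEL)[0]
        assert out.specificity == SPEC_UNCLASSIFIED  # outliers all at 0.5-0.6 Mb


GFF = """\
##gff-version 3
chr1\tens\tgene\t{s}\t{e}\t.\t+\t.\tID=gene:{gid};biotype={bt};gene_id={gid}
"""


class TestGeneOverlap:
    def genes_df(self, intervals, biotype="protein_coding"):
        return pd.DataFrame([
            {"chrom": c, "start": s, "end": e, "gene_id": f"g{i}",
             "strand": "+", "biotype": biotype}
            for i, (c, s, e) in enumerate(intervals)])

    def test_gene_rich_threshold_at_five(self):
        seven = self.genes_df([("chr1", 10_000 * i, 10_000 * i + 5000)
                               for i in range(7)])
        region = SweepRegion("chr1", 0, 100_000, frozenset({"S1"}))
        out = sweeps.gene_overlap([region], seven)[0]
        assert len(out.genes) == 7 and out.gene_rich
        four = self.genes_df([("chr1", 10_000 * i, 10_000 * i + 5000)
                              for i in range(4)])
        assert not sweeps.gene_overlap([region], four)[0].gene_rich

    def test_empty_gene_set(self):
        region = SweepRegion("chr1", 0, 100_000, frozenset({"S1"}))
        out = sweeps.gene_overlap([region], self.genes_df([]))[0]
        assert out.genes == ()

    def test_chromosome_mismatch_errors_with_names(self):
        region = SweepRegion("chr1", 0, 100_000, frozenset({"S1"}))
        genes = self.genes_df([("16", 0, 1000)])
        with pytest.raises(ValueError, match="16"):
            sweeps.gene_overlap([region], genes)

    def test_gff3_reader_filters_biotype(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(GFF.format(s=1001, e=2000, gid="PC1", bt="protein_coding")
                     + GFF.format(s=3001, e=4000, gid="LNC", bt="lncRNA")
                         .split("\n", 1)[1])
        genes = sweeps.read_genes(p, protein_coding_only=True)
        assert list(genes["gene_id"]) == ["PC1"]
        assert genes.loc[0, "start"] == 1000  # GFF 1-based -> BED 0-based


class TestReport:
    def regions(self):
        return [
            SweepRegion("chr1", 0, 100_000, frozenset({"S1", "S2"}),
                        sharing=SHARED, specificity=SPEC_SUDANESE),
            SweepRegion("chr1", 500_000, 600_000, frozenset({"S1", "S2", "G"}),
                        sharing=SHARED, specificity=SPEC_UNCLASSIFIED),
            SweepRegion("chr2", 0, 100_000, frozenset({"S1", "S2"}),
                        sharing=UNIQUE, specificity=SPEC_SUDANESE,
                        genes=tuple(f"g{i}" for i in range(6))),
        ]

    def test_sharing_counts(self):
        _, summary = sweeps.report(self.regions())
        get = lambda cat, lab: int(summary.query(
            "category == @cat and label == @lab")["count"].iloc[0])
        assert get("sharing", SHARED) == 2
        assert get("sharing", UNIQUE) == 1
        assert get("regions", "gene_rich") == 1
        assert get("regions", "total") == 3

    def test_gene_set_intersections_match_set_algebra(self):
        sets = {"hp": {"a", "b", "c"}, "fst": {"b", "c", "d"}, "xp": {"x"}}
        _, summary = sweeps.report(self.regions(), gene_sets=sets)
        inter = {r["label"]: r["count"] for _, r in summary.iterrows()
                 if r["category"] == "gene_set_intersection"}
        assert inter == {"fst&hp": len(sets["fst"] & sets["hp"]),
                         "fst&xp": 0, "hp&xp": 0}

    def test_region_table_has_display_column(self):
        table, _ = sweeps.report(self.regions())
        assert table.loc[0, "region_mb"] == "chr1:0.00-0.10 Mb"
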