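# Methods

## Scope and data model

drysweep detects candidate selective sweeps in a structured cohort of diploid
individuals grouped into breeds and breed groups. Input is a bi-allelic SNP
VCF (phased for the haplotype scan), a sample→breed→group panel TSV, and
optionally a gene annotation (BED or GFF3). Internally, VCF positions
(1-based) are converted once at ingest; every window, region and BED output is
0-based half-open. Multi-allelic and non-SNP records are dropped at read time;
missing genotypes are excluded from all counts, never imputed. A cohort-wide
minor-allele-frequency filter (default 0.05, computed over called alleles)
precedes the scans.

## Window grid

All windowed statistics share one grid: 100 kb windows stepped every 50 kb,
starts at 0, 50 k, 100 k, … while the start lies inside the chromosome;
trailing windows shorter than 100 kb are emitted and flagged partial (they are
usually removed by the SNP-count filter anyway). Windows with fewer than 10
SNPs are excluded from standardization and outlier calling.

## Within-breed diversity: Hp and π

Pooled heterozygosity per window is
`Hp = 2·ΣnMAJ·ΣnMIN / (ΣnMAJ + ΣnMIN)²`, where nMAJ/nMIN are the per-SNP
major/minor allele counts in the breed and the sums run over SNPs in the
window. Counting is on called genotype alleles (two per diploid); the
statistic's original formulation counted sequencing reads, but with called
genotypes the allele count is the natural analogue. Ties (ref count = alt
count) assign major := ref — Hp is symmetric, so the choice is inert.
Hp ∈ [0, 0.5], maximal when major and minor sums balance; hard sweeps drive it
toward 0.

Nucleotide diversity per window is
`π = Σ_sites 2·c_ref·c_alt / (n·(n−1)) / L`, with n the called allele count at
the site and L the window length (including the truncated length of partial
windows). An optional seeded subsample (e.g. 5 individuals per breed) equalizes
sample sizes across breeds for diversity comparisons; default is all samples.

## Z-standardization and outlier windows

Each track is standardized genome-wide over retained windows:
`Z = (x − μ)/σ` with the *population* σ convention (divide by N); μ and σ are
pooled across all chromosomes, not per chromosome. Exactly
`k = floor(0.005 · N_retained)` windows are flagged as outliers — the smallest
ZHp (diversity troughs) or the largest ZF_ST (differentiation peaks).
Boundary ties are broken by ordering on (z, chrom, start), which makes the
selection deterministic and idempotent. With ~49,800 retained windows, as on a
full bovine autosome set, the rule yields a constant 249 outliers per track.
An all-equal track raises an explicit "degenerate track" error rather than
producing infinities.

## Population differentiation: Weir–Cockerham F_ST

Per site, the Weir & Cockerham (1984) diploid variance components a (among
populations), b (among individuals within populations) and c (within
individuals) are computed with r = 2 populations, each contrast side pooled
into a single population — the contrasts compare combined breed sets. Sites
where either side has fewer than two called diploids are uninformative
(b and c are undefined there); sites monomorphic across both sides contribute
a = b = c = 0 and are skipped in ratios. Windowed "weighted" F_ST is the
ratio of sums `Σa / Σ(a+b+c)` over informative sites — not the mean of
per-site ratios. Negative values are kept (not clamped) before
Z-standardization; clamping would distort the null tail. Windows with a zero
denominator are treated as empty.

The three standard contrasts are built from panel groups: A1 = all Sudanese
zebu vs the zebu/sanga reference (East African zebu + sanga + Gir); A2 =
Sudanese minus Fulani vs that reference plus Fulani; A3 = Sudanese minus
Fulani vs all taurine. The Fulani breed is auto-detected by name (FLN/Fulani)
or named explicitly; without one, A2/A3 fall back to the full Sudanese set
with a logged warning.

## Haplotype homozygosity: EHH, iHH, XP-EHH

EHH at a flanking site x is the probability that two randomly drawn focal
haplotypes are identical at every SNP strictly between the core and x
(inclusive of x). Excluding the core site itself makes EHH(core) = 1 under
both conventions — focal-allele curves (carriers already share the core
allele, so the exclusion is inert) and the "all haplotypes" form used by
XP-EHH. Curves are non-increasing outward by construction and are computed by
iterative prefix-group refinement, verified exactly against a brute-force
pair-counting oracle in the tests.

iHH integrates the curve by trapezoids over physical bp, left and right of
the core summed. Integration stops before the first point whose EHH falls
below the cutoff (default 0.05) — no partial trapezoid to the crossing; the
rule is applied identically to both populations, so its small bias cancels in
the ratio to first order. Cores whose curve hits the chromosome end before
reaching the cutoff are flagged (and can be dropped in a strict mode).

XP-EHH per core is `ln(iHH_A / iHH_B)`; scores are standardized globally
(mean 0, population σ 1 over all scanned cores), not in frequency bins —
XP-EHH is approximately frequency-independent and the global form keeps the
scan assumption-light. Significance is the two-sided standard-normal tail of
the standardized score, reported as −log10 p (computed in log space, so deep
tails are exact); the default significance threshold is −log10 p > 4.
Positive scores mean longer homozygosity in population A. Decay reports
around a chosen core emit one curve per population per core allele, labelling
the reference allele ancestral and the alternate derived (a proxy — no
outgroup polarization is attempted); allele classes with fewer than two
carriers are omitted.

## Region building and classification

Per-breed ZHp outlier windows are compared on exact grid coordinates (the
shared grid makes "the same window" well-defined). Windows flagged in at
least two Sudanese zebu breeds become candidates; candidates within 5,000 bp
(inclusive — "up to 5 kb") are merged, unioning the detecting breeds. A
region is *shared* if any non-Sudanese zebu breed (East African zebu, sanga
or Gir groups) has an overlapping outlier window — overlap always means any
shared bp — else *unique_sudanese*.

Lineage specificity is a pure function of (breeds detected, contrast-outlier
overlaps), applied with precedence sudanese > bos_indicus > african_zebu:

| class | breeds detected | F_ST overlap |
|---|---|---|
| sudanese | only Sudanese breeds | any of A1/A2/A3 |
| bos_indicus | Gir and ≥1 other African zebu | A3 only |
| african_zebu | ≥1 Sudanese and ≥1 non-Gir African zebu, not Gir | A3 only |
| unclassified | anything else | — |

The table is one consistent concretization of a narrative rule; the
precedence puts the Sudanese-specific call first because it is the focal
hypothesis. Gene overlap is any-overlap against protein-coding genes
(configurable); regions with ≥5 genes are gene-rich. The threshold is ≥5, the
stricter of the two phrasings in circulation ("minimum of five" vs "more than
five"), and is configurable.

## Synthetic cohorts

The simulator emulates a multi-breed cattle panel with a known truth set.

**Allele frequencies.** Per SNP an ancestral frequency is drawn
Uniform(0.05, 0.95) — bounding the MAF avoids near-fixed ancestral sites that
destabilize Balding–Nichols beta sampling. Each group's frequency is drawn
Beta(p(1−F)/F, (1−p)(1−F)/F) around the ancestral value with the group's
divergence F; each breed's frequency is drawn the same way around its group's
with a within-group F (default 0.015). Divergences from the ancestral pool
are approximately additive, and pairwise breed F_ST is approximately the mean
of the two breeds' total divergences. The default group values
(sudanese_zebu 0.01, east_african_zebu 0.04, sanga 0.06, gir 0.16, taurine
0.55) were chosen so the default panel reproduces the empirical cattle
gradient: ~0.015 within Sudanese zebu, ~0.04 vs East African zebu, ~0.1 vs
Gir, ~0.3 vs taurine.

**Haplotypes.** Each breed receives a founder pool (default 500 haplotypes)
sampled i.i.d. from its frequencies; each sampled haplotype is a founder
mosaic that switches founders with probability 0.01 per SNP interval
(geometric segments, ~100 SNPs ≈ 100 kb at default density). This yields
haplotype-block structure and within-breed LD without coalescent machinery.
The finite founder pool adds ≈ 1/n_founders of extra drift to every pairwise
F_ST; 500 founders keep that term (≈0.002) negligible even against the
smallest simulated divergence.

**Sweeps.** A sweep biases mosaic sampling toward founder 0 in the target
breeds: each haplotype draws u ~ Uniform(0,1) and, if u < f (the sweep
frequency), copies founder 0 wherever |pos − core| ≤ W·(1 − u/f). The carrier
frequency at distance d from the core is then exactly f·(1 − d/W): f at the
core, decaying linearly to zero at the half-width W. Frequency 1.0 is treated
as a completed sweep — every target haplotype carries the sweep founder across
the whole interval, with no decay (there are no non-carriers to decay into). This produces the
diversity trough (Hp, π), the differentiation peak (the swept founder
haplotype is breed-set-specific) and the extended-homozygosity plateau
(nested carrier spans) that the three scans look for — without forward
simulation. Overlapping sweeps on one chromosome sharing a target breed are
rejected as ambiguous. Sites monomorphic across the whole cohort are dropped
unless requested.

**Randomness.** A single seeded generator drives every draw in documented
order (positions, ancestral frequencies, group then breed frequencies,
founders, per-individual mosaics, sweep carrier draws), so identical
parameters and seed give byte-identical output.

**What the simulator does not emulate.** Mutation-rate heterogeneity,
recombination maps, genotyping error and missingness, admixture between
breeds, background selection, and time-resolved selection dynamics. Passing
end-to-end tests therefore demonstrates that the statistics and the
region-building logic behave correctly on data with the stated covariance
structure — not that the pipeline's power on real resequencing data matches
any particular study.

## Default problem sizes

The default validation cohort is 2 chromosomes × 10 Mb at ~1 SNP/kb with
11 breeds × 6 diploids and three implanted sweeps (frequency 0.95, half-width
250 kb, five Sudanese target breeds) — ~20,000 SNPs and 400 grid windows,
chosen as the smallest configuration in which all three scans, the 0.5%
outlier rule (2 windows per track) and the classification stack still
exercise every code path meaningfully. Divergence-recovery checks use one
10-diploid breed pair on a 6 Mb chromosome (~6,000 informative SNPs). The
end-to-end seeded checks ask for two of the three sweeps to be recovered with
full labels: with only two outlier windows available per track, the third
sweep's F_ST support can fall below the classification bar — that headroom is
deliberate, not slack in the statistics.

## Numerical conventions

- Population σ (divide by N) everywhere a Z-score or standardized score is
  formed; the difference from sample σ is negligible at genome scale but must
  be fixed for exact tests.
- Outlier and merge tie-breaks are deterministic (documented sort orders).
- Hp of an empty or monomorphic window is 0 with retained = false; π of an
  empty window is 0; a window whose F_ST denominator is 0 is excluded via
  n_snps = 0.
- −log10 p from z-scores uses the log-space survival function
  (`log(2) + logsf(|z|)`), accurate far beyond double-precision tail
  underflow.
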