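"""Weir & Cockerham (1984) F_ST variance components and the three windowed
population contrasts used to classify sweep specificity.

Each contrast side is pooled into a single population (r = 2) before the
components are computed — the contrasts compare *combined* breed sets, not
individual breeds. Windowed "weighted" F_ST is the ratio-of-sums
sum(a) / sum(a + b + c), the vcftools convention; negative values are kept
(not clamped) ahead of Z-transformation so the null tail is undistorted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import PanelMap, VariantTable
from .scanstats import _new_track, select_outliers, z_transform

log = logging.getLogger(__name__)

SUDANESE = "sudanese_zebu"
ZEBU_REFERENCE_GROUPS = ("east_african_zebu", "sanga", "gir")
TAURINE_GROUPS = ("african_taurine", "european_taurine")
_FULANI_NAMES = {"fln", "fulani"}


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    pop1: frozenset[str]
    pop2: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pop1 or not self.pop2:
            raise ValueError(f"contrast {self.name}: both sides must be nonempty")
        if self.pop1 & self.pop2:
            raise ValueError(f"contrast {self.name}: sides overlap: {sorted(self.pop1 & self.pop2)}")


@dataclass
class SiteFstComponents:
    a: float  # among-population variance component
    b: float  # among-individuals-within-population
    c: float  # within-individual
    informative: bool

    @property
    def fst(self) -> float:
        denom = self.a + self.b + self.c
        return self.a / denom if denom != 0 else float("nan")


def _pop_site_stats(vt: VariantTable, sample_idx: np.ndarray):
    """Per-site (n non-missing diploids, alt allele freq, observed het freq)."""
    g = vt.genotypes[:, sample_idx, :]
    called = (g[:, :, 0] >= 0) & (g[:, :, 1] >= 0)
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, g[:, :, 0] == 1, False).sum(axis=1) \
        + np.where(called, g[:, :, 1] == 1, False).sum(axis=1)
    het = np.where(called, g[:, :, 0] != g[:, :, 1], False).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def wc_components(vt: VariantTable, panel: PanelMap,
                  contrast: ContrastSpec) -> pd.DataFrame:
    """Per-site a, b, c for the two pooled populations of `contrast`.

    Sites where either side has fewer than two called diploids are marked
    uninformative (b and c are then undefined). Sites monomorphic across both
    sides get a = b = c = 0 and are skipped in downstream ratios.
    """
    idx1 = vt.sample_indices([s for b in sorted(contrast.pop1)
                              for s in panel.samples_of(b)])
    idx2 = vt.sample_indices([s for b in sorted(contrast.pop2)
                              for s in panel.samples_of(b)])
    n1, p1, h1 = _pop_site_stats(vt, idx1)
    n2, p2, h2 = _pop_site_stats(vt, idx2)

    informative = (n1 >= 2) & (n2 >= 2)
    # guard: compute with dummies where uninformative, zero out after
    n1s, n2s = np.where(informative, n1, 2.0), np.where(informative, n2, 2.0)
    p1s, p2s = np.nan_to_num(p1), np.nan_to_num(p2)
    h1s, h2s = np.nan_to_num(h1), np.nan_to_num(h2)

    r = 2.0
    S = n1s + n2s
    nbar = S / r
    nc = S - (n1s**2 + n2s**2) / S
    pbar = (n1s * p1s + n2s * p2s) / S
    s2 = (n1s * (p1s - pbar) ** 2 + n2s * (p2s - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1s * h1s + n2s * h2s) / S

    pq = pbar * (1 - pbar)
    a = (nbar / nc) * (s2 - (pq - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pq - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2

    mono = informative & ((pbar == 0) | (pbar == 1))
    for arr in (a, b, c):
        arr[~informative] = 0.0
        arr[mono] = 0.0
    return pd.DataFrame({"a": a, "b": b, "c": c,
                         "informative": informative & ~mono})


def wc_site_components(vt: VariantTable, site: int, panel: PanelMap,
                       contrast: ContrastSpec) -> SiteFstComponents:
    """Single-site convenience wrapper around `wc_components`."""
    comp = wc_components(vt.take_sites(slice(site, site + 1)), panel, contrast)
    return SiteFstComponents(float(comp["a"][0]), float(comp["b"][0]),
                             float(comp["c"][0]), bool(comp["informative"][0]))


def window_fst(vt: VariantTable, windows: pd.DataFrame, panel: PanelMap,
               contrast: ContrastSpec) -> pd.DataFrame:
    """Windowed weighted F_ST = sum(a)/sum(a+b+c) over informative sites.

    n_snps counts informative sites; windows whose denominator is zero are
    given n_snps = 0 so the min-SNP retention rule excludes them.
    """
    comp = wc_components(vt, panel, contrast)
    inf = comp["informative"].to_numpy()
    a = np.where(inf, comp["a"].to_numpy(), 0.0)
    abc = np.where(inf, (comp["a"] + comp["b"] + comp["c"]).to_numpy(), 0.0)
    from .scanstats import _site_window_sums
    sums, _ = _site_window_sums(vt, windows, np.column_stack([a, abc, inf.astype(float)]))
    num, den, n_inf = sums[:, 0], sums[:, 1], sums[:, 2].astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den != 0, num / np.where(den != 0, den, 1.0), 0.0)
    n_snps = np.where(den != 0, n_inf, 0)
    return _new_track(windows, n_snps, fst)


def standard_contrasts(panel: PanelMap, fulani: str | None = None) -> list[ContrastSpec]:
    """Build the three standard contrasts from panel groups.

    A1: all Sudanese zebu vs the zebu/sanga reference (East African zebu,
    sanga, Gir). A2: Sudanese minus Fulani vs that reference plus Fulani.
    A3: Sudanese minus Fulani vs all taurine. If no Fulani breed is present,
    A2 and A3 fall back to the full Sudanese set with a logged warning.
    """
    sudanese = panel.breeds_in(SUDANESE)
    if not sudanese:
        raise ValueError(f"panel lacks group {SUDANESE!r}")
    zebu_ref = panel.breeds_in(*ZEBU_REFERENCE_GROUPS)
    if not zebu_ref:
        raise ValueError(f"panel lacks all of groups {ZEBU_REFERENCE_GROUPS}")
    taurine = panel.breeds_in(*TAURINE_GROUPS)
    if not taurine:
        raise ValueError(f"panel lacks all of groups {TAURINE_GROUPS}")

    if fulani is None:
        hits = [b for b in sudanese if b.lower() in _FULANI_NAMES]
        fulani = hits[0] if hits else None
    if fulani is None:
        log.warning("no Fulani breed in panel; A2/A3 use all Sudanese breeds")
        sud_no_fln = sudanese
        a2_ref = zebu_ref
    else:
        sud_no_fln = [b for b in sudanese if b != fulani]
        a2_ref = zebu_ref + [fulani]
    return [
        ContrastSpec("A1", frozenset(sudanese), frozenset(zebu_ref)),
        ContrastSpec("A2", frozenset(sud_no_fln), frozenset(a2_ref)),
        ContrastSpec("A3", frozenset(sud_no_fln), frozenset(taurine)),
    ]


def run_contrasts(vt: VariantTable, windows: pd.DataFrame, panel: PanelMap,
                  min_snps: int = 10, quantile: float = 0.005,
                  fulani: str | None = None) -> dict[str, pd.DataFrame]:
    """The three genome-wide F_ST scans, Z-transformed, high-tail outlier-called."""
    tracks = {}
    for spec in standard_contrasts(panel, fulani):
        track = window_fst(vt, windows, panel, spec)
        track, _ = z_transform(track, min_snps=min_snps)
        track = select_outliers(track, quantile=quantile, tail="high")
        track.insert(0, "contrast", spec.name)
        tracks[spec.name] = track
    return tracks
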