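"""Within-breed windowed scans: nucleotide diversity pi, pooled heterozygosity Hp,
genome-wide Z-transformation and extreme-tail outlier calling.

Hp follows the pooled-heterozygosity statistic of Rubin et al.:
Hp = 2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))^2, with per-SNP
major/minor allele counts summed over the window; low Hp marks candidate
sweeps. Counting is on called genotype alleles (two per diploid), not reads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import PanelMap, VariantTable, breed_allele_counts

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["chrom", "start", "end", "n_snps", "value", "retained", "z", "outlier"]


@dataclass
class ZScoreParams:
    mu: float
    sigma: float  # population convention (divide by N)


def _site_window_sums(vt: VariantTable, windows: pd.DataFrame,
                      per_site: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-site columns of `per_site` over each window; also count sites.

    per_site: (n_sites, k) array. Returns (n_windows, k) sums and (n_windows,)
    site counts. Sites with all-zero rows still count as sites.
    """
    sums = np.zeros((len(windows), per_site.shape[1]))
    counts = np.zeros(len(windows), dtype=np.int64)
    for chrom, sub in windows.groupby("chrom", sort=False):
        on = np.flatnonzero(vt.chrom == chrom)
        pos0 = vt.pos[on] - 1
        lo = np.searchsorted(pos0, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos0, sub["end"].to_numpy(), side="left")
        cum = np.vstack([np.zeros((1, per_site.shape[1])),
                         np.cumsum(per_site[on], axis=0)])
        sums[sub.index.to_numpy()] = cum[hi] - cum[lo]
        counts[sub.index.to_numpy()] = hi - lo
    return sums, counts


def _new_track(windows: pd.DataFrame, n_snps: np.ndarray, value: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": windows["chrom"].to_numpy(),
        "start": windows["start"].to_numpy(),
        "end": windows["end"].to_numpy(),
        "n_snps": n_snps,
        "value": value,
        "retained": False,
        "z": np.nan,
        "outlier": False,
    })


def window_pi(vt: VariantTable, windows: pd.DataFrame, breed: str,
              panel: PanelMap, sample_subset_size: int | None = None,
              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Windowed nucleotide diversity.

    Per window, pi = sum over sites of 2*c_ref*c_alt / (n*(n-1)) divided by the
    window length (end - start, including the short length of partial windows),
    where n is the non-missing allele count at the site.
    """
    counts = breed_allele_counts(vt, panel, breed, sample_subset_size, rng)
    c_ref = counts["ref"].to_numpy(dtype=float)
    c_alt = counts["alt"].to_numpy(dtype=float)
    n = c_ref + c_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = np.where(n > 1, 2.0 * c_ref * c_alt / (n * (n - 1)), 0.0)
    sums, n_snps = _site_window_sums(vt, windows, per_site[:, None])
    length = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    return _new_track(windows, n_snps, sums[:, 0] / length)


def window_hp(vt: VariantTable, windows: pd.DataFrame, breed: str,
              panel: PanelMap, sample_subset_size: int | None = None,
              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Windowed pooled heterozygosity Hp in one breed (0 <= Hp <= 0.5)."""
    counts = breed_allele_counts(vt, panel, breed, sample_subset_size, rng)
    per_site = counts[["major", "minor"]].to_numpy(dtype=float)
    sums, n_snps = _site_window_sums(vt, windows, per_site)
    maj, mino = sums[:, 0], sums[:, 1]
    tot = maj + mino
    with np.errstate(divide="ignore", invalid="ignore"):
        hp = np.where(tot > 0, 2.0 * maj * mino / np.square(tot), 0.0)
    return _new_track(windows, n_snps, hp)


def z_transform(track: pd.DataFrame, min_snps: int = 10) -> tuple[pd.DataFrame, ZScoreParams]:
    """Genome-wide Z-transform over retained windows (n_snps >= min_snps).

    mu and sigma (population convention, divide by N) are pooled across all
    chromosomes; z is defined only for retained windows.
    """
    track = track.copy()
    retained = track["n_snps"].to_numpy() >= min_snps
    vals = track.loc[retained, "value"].to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError("fewer than 2 retained windows")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=0))
    if sigma == 0:
        raise ValueError("degenerate track: all retained window values identical")
    track["retained"] = retained
    track["z"] = np.nan
    track.loc[retained, "z"] = (vals - mu) / sigma
    track["outlier"] = False
    return track, ZScoreParams(mu, sigma)


def select_outliers(track: pd.DataFrame, quantile: float = 0.005,
                    tail: str = "low") -> pd.DataFrame:
    """Flag the floor(quantile * N_retained) most extreme retained windows.

    tail="low" flags the smallest z (the ZHp convention), tail="high" the
    largest (the ZF_ST convention). Boundary ties are broken by ordering on
    (z, chrom, start), making the selection deterministic and idempotent.
    """
    if tail not in ("low", "high"):
        raise ValueError("tail must be 'low' or 'high'")
    track = track.copy()
    track["outlier"] = False
    ret = track[track["retained"]]
    k = int(np.floor(quantile * len(ret)))
    if k == 0:
        warnings.warn(f"quantile {quantile} of {len(ret)} retained windows selects 0 outliers")
        return track
    asc = [True, True, True] if tail == "low" else [False, True, True]
    chosen = ret.sort_values(["z", "chrom", "start"], ascending=asc).index[:k]
    track.loc[chosen, "outlier"] = True
    return track


def outlier_count(n_retained: int, quantile: float = 0.005) -> int:
    """The constant per-track outlier count: floor(quantile * N_retained)."""
    return int(np.floor(quantile * n_retained))
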