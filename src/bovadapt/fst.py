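"""Windowed Weir–Cockerham F_ST between two populations.

Per-site variance components a (among populations), b (among individuals
within populations) and c (within individuals) follow Weir & Cockerham
(1984) for two populations, computed from diploid genotype counts so that
observed heterozygosity enters the estimator. Windows slide by a fixed step
(defaults 10 kb window, 5 kb step); the windowed estimate is the "weighted"
ratio of sums sum(a)/sum(a+b+c) alongside the mean of per-site ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def site_components(n: np.ndarray, p: np.ndarray, h: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham variance components for r=2 populations, vectorised.

    Parameters are per-site arrays of shape (n_sites, 2): ``n`` diploid
    sample sizes with called genotypes, ``p`` alt-allele frequencies, ``h``
    observed heterozygote frequencies.
    """
    r = 2
    nbar = n.mean(axis=1)
    nc = (r * nbar - (n ** 2).sum(axis=1) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=1) / (r * nbar)
    s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=1) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    return a, b, c


@dataclass
class FstWindow:
    chrom: str
    start: int
    end: int
    n_snps: int
    weighted_fst: float
    mean_fst: float


def _pop_genotype_stats(table, samples_idx: np.ndarray):
    g = table.genotypes[:, samples_idx]
    called = g >= 0
    n = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(g > 0, g, 0).sum(axis=1) / (2 * n), np.nan)
        h = np.where(n > 0, (g == 1).sum(axis=1) / n, np.nan)
    return n, p, h


def windowed_fst(table, popA: str, popB: str, *, window: int = 10000,
                 step: int = 5000, min_samples: int = 2) -> list[FstWindow]:
    """Sliding-window Weir–Cockerham F_ST from a genotyped SiteTable.

    Sites with fewer than ``min_samples`` called diploids in either
    population are excluded; windows without usable SNPs are omitted.
    """
    if table.genotypes is None:
        raise ValueError("windowed_fst requires per-sample genotypes")
    if window < step:
        log.warning("window (%d) smaller than step (%d): gaps between windows",
                    window, step)
    ja, jb = table.pop_index(popA), table.pop_index(popB)
    idxA = np.flatnonzero(table.sample_pops == ja)
    idxB = np.flatnonzero(table.sample_pops == jb)
    nA, pA, hA = _pop_genotype_stats(table, idxA)
    nB, pB, hB = _pop_genotype_stats(table, idxB)
    usable = (nA >= min_samples) & (nB >= min_samples)

    n = np.column_stack([nA, nB]).astype(float)
    p = np.column_stack([pA, pB])
    h = np.column_stack([hA, hB])
    a, b, c = site_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = a / (a + b + c)

    out: list[FstWindow] = []
    pos0 = table.pos0()
    chroms = table.sites["chrom"].astype(str).to_numpy()
    for chrom in pd.unique(chroms):
        on = (chroms == chrom) & usable
        if not on.any():
            continue
        cp = pos0[on]
        ca, cb, cc, cf = a[on], b[on], c[on], per_site[on]
        last = cp.max()
        n_windows = int(last // step) + 1
        for k in range(n_windows):
            ws, we = k * step, k * step + window
            sel = (cp >= ws) & (cp < we)
            if not sel.any():
                continue
            denom = (ca[sel] + cb[sel] + cc[sel]).sum()
            weighted = ca[sel].sum() / denom if denom != 0 else np.nan
            mean = float(np.nanmean(cf[sel]))
            out.append(FstWindow(chrom=str(chrom), start=ws, end=we,
                                 n_snps=int(sel.sum()),
                                 weighted_fst=float(weighted), mean_fst=mean))
    return out


def windows_to_frame(windows: list[FstWindow]) -> pd.DataFrame:
    """vcftools-style window table."""
    return pd.DataFrame(
        [(w.chrom, w.start, w.end, w.n_snps, w.weighted_fst, w.mean_fst)
         for w in windows],
        columns=["CHROM", "BIN_START", "BIN_END", "N_VARIANTS",
                 "WEIGHTED_FST", "MEAN_FST"])


def top_percent(windows: list[FstWindow], fraction: float = 0.01,
                by: str = "mean") -> list[FstWindow]:
    """The ceiling(fraction x N) windows with the highest F_ST.

    Ties break deterministically by (chrom, start).
    """
    if not windows:
        raise ValueError("no windows")
    k = math.ceil(fraction * len(windows))
    key = (lambda w: (-(w.mean_fst if by == "mean" else w.weighted_fst),
                      w.chrom, w.start))
    return sorted(windows, key=key)[:k]
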