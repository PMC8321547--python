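"""f3 and D admixture statistics with block-jackknife Z-scores.

Frequency-based estimators over population allele frequencies:

* ``f3(X; A, B) = mean_l (x - a)(x - b)`` — significantly negative values
  imply X is admixed between populations related to A and B;
* ``D(A, B, X, Y) = sum (a-b)(x-y) / sum (a+b-2ab)(x+y-2xy)`` — non-zero
  values indicate asymmetric allele sharing under the unrooted tree
  ((A,B),(X,Y)).

Standard errors come from a delete-one block jackknife over contiguous
genomic blocks (default 5 Mb), which is robust to linkage. The admixture
significance convention follows the source analyses: f3 Z < -2 flags
admixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BLOCK_SIZE = 5_000_000


@dataclass(frozen=True)
class PopStatResult:
    statistic: str
    value: float
    se: float
    z: float
    n_blocks: int
    populations: tuple[str, ...]

    @property
    def significant_admixture(self) -> bool:
        """Admixture call: negative statistic with Z below -2."""
        return self.statistic == "f3" and self.z < -2


def _blocks(table, ok: np.ndarray, block_size: int) -> np.ndarray:
    """Contiguous genomic block index per (usable) site."""
    chroms = table.sites["chrom"].astype(str).to_numpy()[ok]
    pos = table.sites["pos"].to_numpy(dtype=np.int64)[ok]
    block = np.zeros(ok.sum(), dtype=np.int64)
    next_id = 0
    for c in dict.fromkeys(chroms):  # preserves order
        on = chroms == c
        b = pos[on] // block_size
        uniq, inv = np.unique(b, return_inverse=True)
        block[on] = inv + next_id
        next_id += len(uniq)
    return block


def _jackknife_ratio(num: np.ndarray, den: np.ndarray, block: np.ndarray
                     ) -> tuple[float, float, int]:
    """Delete-one-block jackknife for a ratio-of-sums estimator."""
    n_blocks = int(block.max()) + 1 if block.size else 0
    if n_blocks < 2:
        raise ValueError("need at least 2 non-empty blocks for the jackknife")
    num_b = np.bincount(block, weights=num, minlength=n_blocks)
    den_b = np.bincount(block, weights=den, minlength=n_blocks)
    tot_n, tot_d = num_b.sum(), den_b.sum()
    if tot_d == 0:
        raise ValueError("zero denominator over all blocks")
    theta = tot_n / tot_d
    loo_d = tot_d - den_b
    if np.any(loo_d == 0):
        raise ValueError("a leave-one-out denominator is zero")
    loo = (tot_n - num_b) / loo_d
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2)))
    return float(theta), se, n_blocks


def f3(table, X: str, A: str, B: str,
       block_size: int = DEFAULT_BLOCK_SIZE) -> PopStatResult:
    """Three-population statistic f3(X; A, B) with jackknife Z."""
    x, a, b = (table.freq(p) for p in (X, A, B))
    ok = np.isfinite(x) & np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("no sites with defined frequencies in all populations")
    terms = (x[ok] - a[ok]) * (x[ok] - b[ok])
    block = _blocks(table, ok, block_size)
    value, se, nb = _jackknife_ratio(terms, np.ones_like(terms), block)
    z = value / se if se > 0 else 0.0
    return PopStatResult("f3", value, se, float(z), nb, (X, A, B))


def d_stat(table, A: str, B: str, X: str, Y: str,
           block_size: int = DEFAULT_BLOCK_SIZE) -> PopStatResult:
    """Patterson's D(A, B, X, Y) with jackknife Z."""
    a, b, x, y = (table.freq(p) for p in (A, B, X, Y))
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        raise ValueError("no sites with defined frequencies in all populations")
    a, b, x, y = a[ok], b[ok], x[ok], y[ok]
    num = (a - b) * (x - y)
    den = (a + b - 2 * a * b) * (x + y - 2 * x * y)
    block = _blocks(table, ok, block_size)
    value, se, nb = _jackknife_ratio(num, den, block)
    z = value / se if se > 0 else 0.0
    return PopStatResult("D", value, se, float(z), nb, (A, B, X, Y))
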