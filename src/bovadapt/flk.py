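"""Single-marker FLK selection scan with robust calibration.

Pipeline: Reynolds distances between populations → neighbour-joining tree,
midpoint-rooted → drift kinship matrix F (branch drift t = −ln(1−d),
summed over the shared root-to-tip path) → per-site FLK statistic

    T = (p − p̂0·1)ᵀ F⁻¹ (p − p̂0·1) / (p̂0 (1 − p̂0)),
    p̂0 = (1ᵀ F⁻¹ p) / (1ᵀ F⁻¹ 1),

approximately chi-squared with (n_pops − 1) degrees of freedom under
neutral drift. Genome-wide calibration assumes selected regions are a small
outlying fraction: a robust (Huber) normal fit of the statistic gives
Z-scores and upper-tail p-values, Storey's method gives q-values, and
selection intervals are called with a q < 0.01 seed extended to the first
markers with q > 0.1.

The haplotype-cluster layer of hapFLK is deliberately not implemented; the
single-marker statistic feeds the same downstream calibration. Because T is
chi-squared rather than normal under the null, the default calibration
variance-stabilises it first (Wilson–Hilferty cube-root transform); fitting
a normal to the raw chi-squared scan would make heavy-tail null markers
look like signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Reynolds distances


def reynolds_distance(table, popX: str, popY: str,
                      source: str = "observed") -> float:
    """Reynolds coancestry distance between two populations.

    Biallelic ratio-of-sums form:
    ``D = sum_l (pX - pY)^2 / sum_l (1 - pX pY - qX qY)``.
    Sites with undefined frequency in either population are excluded.
    """
    px = table.freq(popX, source=source)
    py = table.freq(popY, source=source)
    ok = np.isfinite(px) & np.isfinite(py)
    if not ok.any():
        raise ValueError("no sites with defined frequencies in both populations")
    px, py = px[ok], py[ok]
    num = np.sum((px - py) ** 2)
    den = np.sum(1.0 - px * py - (1 - px) * (1 - py))
    if den <= 0:
        return 0.0
    return float(num / den)


def distance_matrix(table, populations: list[str] | None = None,
                    source: str = "observed") -> pd.DataFrame:
    """Symmetric Reynolds distance matrix over populations."""
    pops = populations or table.populations
    D = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            D[i, j] = D[j, i] = reynolds_distance(table, pops[i], pops[j],
                                                  source=source)
    return pd.DataFrame(D, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# Kinship from a midpoint-rooted NJ tree


def build_kinship(dist: pd.DataFrame) -> tuple[object, pd.DataFrame]:
    """Population tree and drift kinship matrix from Reynolds distances.

    Neighbour-joining on the distances (negative branch lengths clamped to
    zero), midpoint rooting, branch drift t = −ln(1 − d), and kinship
    F_ij = summed drift over the shared root-to-tip path (F_ii = total
    root-to-tip drift). Returns (tree, F).
    """
    from skbio import DistanceMatrix as SkbioDM, TreeNode
    from skbio.tree import nj

    pops = list(dist.columns)
    D = np.asarray(dist, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if len(pops) < 2:
        raise ValueError("need at least two populations")

    if len(pops) == 2:
        half = D[0, 1] / 2.0
        tree = TreeNode.read([f"({pops[0]}:{half},{pops[1]}:{half});"])
    else:
        tree = nj(SkbioDM(D, ids=pops))
        for node in tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                node.length = 0.0
        tree = tree.root_at_midpoint()

    # shared root-path drift
    paths: dict[str, list[tuple[int, float]]] = {}
    for tip in tree.tips():
        path = []
        node = tip
        while node.parent is not None:
            d = min(max(node.length or 0.0, 0.0), 1.0 - 1e-12)
            path.append((id(node), -np.log1p(-d)))
            node = node.parent
        paths[tip.name] = list(reversed(path))

    F = np.zeros((len(pops), len(pops)))
    for i, a in enumerate(pops):
        ids_a = {nid for nid, _ in paths[a]}
        F[i, i] = sum(t for _, t in paths[a])
        for j, b in enumerate(pops):
            if j <= i:
                continue
            shared = sum(t for nid, t in paths[b] if nid in ids_a)
            F[i, j] = F[j, i] = shared
    return tree, pd.DataFrame(F, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# FLK statistic


@dataclass
class FlkResult:
    """Per-site FLK scan output."""

    sites: pd.DataFrame          # chrom, pos
    T: np.ndarray                # FLK statistic, NaN where undefined
    p0: np.ndarray               # estimated ancestral frequency
    dof: int
    excluded: np.ndarray         # sites flagged out (monomorphic / boundary p0)

    def chi2_pvalues(self) -> np.ndarray:
        """Upper-tail p-values from the chi-squared null reference."""
        return stats.chi2.sf(self.T, self.dof)


def flk(table, F: pd.DataFrame, source: str = "observed",
        jitter: float = 1e-9) -> FlkResult:
    """Single-marker FLK statistic for every site with defined frequencies."""
    pops = list(F.columns)
    Fm = np.asarray(F, dtype=float).copy()
    n = len(pops)
    try:
        Fi = np.linalg.inv(Fm)
    except np.linalg.LinAlgError:
        log.info("kinship singular; adding %g jitter to the diagonal", jitter)
        Fm[np.diag_indices(n)] += jitter
        Fi = np.linalg.inv(Fm)  # raises if still singular

    P = np.column_stack([table.freq(p, source=source) for p in pops])
    ok = np.all(np.isfinite(P), axis=1)
    w = Fi @ np.ones(n)
    wsum = w.sum()
    p0 = np.full(table.n_sites, np.nan)
    p0[ok] = P[ok] @ w / wsum

    boundary = ok & ((p0 <= 0) | (p0 >= 1))
    good = ok & ~boundary
    T = np.full(table.n_sites, np.nan)
    resid = P[good] - p0[good, None]
    quad = np.einsum("ij,jk,ik->i", resid, Fi, resid)
    T[good] = quad / (p0[good] * (1 - p0[good]))
    return FlkResult(sites=table.sites[["chrom", "pos"]].copy(), T=T,
                     p0=p0, dof=n - 1, excluded=~good)


# ---------------------------------------------------------------------------
# Robust calibration → p, q


def storey_qvalues(p: np.ndarray, lambdas=None) -> np.ndarray:
    """Storey q-values with the smoother pi0 estimate.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a 0.05..0.95 grid,
    smoothed by a cubic fit and evaluated at the largest lambda; falls back
    to Benjamini–Hochberg (pi0 = 1) when the estimate is unusable.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    try:
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas[-1]))
    except Exception:
        pi0 = 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        log.info("pi0 estimation failed; falling back to Benjamini-Hochberg")
        pi0 = 1.0
    pi0 = min(pi0, 1.0)

    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.clip(q, 0, 1)


@dataclass
class CalibratedScan:
    """Robust-normal calibration of a genome scan statistic."""

    sites: pd.DataFrame
    stat: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    location: float
    scale: float
    meta: dict = field(default_factory=dict)


def calibrate(stat: np.ndarray, sites: pd.DataFrame | None = None, *,
              transform: str | None = None, dof: int | None = None,
              two_sided: bool = False, huber_c: float = 1.345,
              max_iter: int = 50, tol: float = 1e-8) -> CalibratedScan:
    """Robust Z-transform of a scan statistic and q-values.

    Location and scale come from Huber's joint M-estimate (tuning constant
    1.345, mirroring the default of R's ``MASS::rlm``), so that the small
    outlying fraction of selected markers does not inflate the null fit.
    ``transform="chisq"`` (with ``dof``) applies the Wilson–Hilferty
    cube-root normalisation first — appropriate for the FLK statistic.
    p-values are upper-tail normal by default.
    """
    from statsmodels.robust.scale import Huber

    stat = np.asarray(stat, dtype=float)
    ok = np.isfinite(stat)
    if ok.sum() < 100:
        raise ValueError("need at least 100 finite markers to calibrate")
    y = stat.copy()
    if transform == "chisq":
        if dof is None:
            raise ValueError("chisq transform requires dof")
        with np.errstate(invalid="ignore"):
            y = np.where(ok, np.cbrt(np.maximum(stat, 0) / dof), np.nan)
    elif transform is not None:
        raise ValueError(f"unknown transform: {transform}")

    vals = y[ok]
    if np.ptp(vals) == 0:
        raise ValueError("constant statistic: zero scale")
    huber = Huber(c=huber_c, tol=tol, maxiter=max_iter)
    try:
        mu, sigma = huber(vals)
    except ValueError:
        # Huber scale iteration can fail on near-degenerate input
        mu, sigma = np.median(vals), stats.median_abs_deviation(vals, scale="normal")
    mu, sigma = float(mu), float(sigma)
    if sigma <= 0:
        raise ValueError("robust scale is zero")

    z = (y - mu) / sigma
    p = 2 * stats.norm.sf(np.abs(z)) if two_sided else stats.norm.sf(z)
    q = np.full_like(p, np.nan)
    q[ok] = storey_qvalues(p[ok])
    if sites is None:
        sites = pd.DataFrame({"chrom": "1", "pos": np.arange(1, stat.size + 1)})
    return CalibratedScan(sites=sites.reset_index(drop=True), stat=stat, z=z,
                          p=p, q=q, location=mu, scale=sigma,
                          meta={"transform": transform, "dof": dof})


def calibrate_flk(result: FlkResult, **kwargs) -> CalibratedScan:
    """Calibrate an FLK scan (chi-squared variance stabilisation built in)."""
    return calibrate(result.T, sites=result.sites, transform="chisq",
                     dof=result.dof, **kwargs)


# ---------------------------------------------------------------------------
# Interval calling


@dataclass(frozen=True)
class SelectionInterval:
    chrom: str
    start: int
    end: int
    n_markers: int
    min_q: float


def call_intervals(scan: CalibratedScan, seed_q: float = 0.01,
                   boundary_q: float = 0.1) -> list[SelectionInterval]:
    """Hysteresis interval calling on the q-value track.

    Each maximal run of markers with q <= ``boundary_q`` containing at least
    one marker with q < ``seed_q`` becomes an interval; the boundaries are
    the outermost such markers (the first marker with q > boundary_q on
    either side is excluded). Overlapping intervals merge by construction.
    """
    out: list[SelectionInterval] = []
    df = scan.sites.copy()
    df["q"] = scan.q
    for chrom, ch in df.groupby("chrom", sort=False):
        pos = ch["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"markers on {chrom} are not position-sorted")
        q = ch["q"].to_numpy()
        below = q <= boundary_q
        i = 0
        n = len(q)
        while i < n:
            if not below[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            run_q = q[i:j + 1]
            if np.nanmin(run_q) < seed_q:
                out.append(SelectionInterval(
                    chrom=str(chrom), start=int(pos[i]), end=int(pos[j]),
                    n_markers=j - i + 1, min_q=float(np.nanmin(run_q))))
            i = j + 1
    return out


def scan_to_frame(scan: CalibratedScan) -> pd.DataFrame:
    df = scan.sites.copy()
    df["T"] = scan.stat
    df["Z"] = scan.z
    df["p"] = scan.p
    df["q"] = scan.q
    return df
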