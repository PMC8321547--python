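"""Convergent-residue association tests across a species phylogeny.

Tests whether a binary amino-acid state X (e.g. His vs Gln at a convergent
residue) is associated with a binary phenotype Y (torpor/hibernation)
across species:

* a 2x2 contingency table with odds ratio and a two-sided exact
  (hypergeometric) p-value, ignoring phylogeny;
* phylogenetic logistic regression: logit P(Y=1) = b0 + b1 X with
  phylogenetically correlated binary residuals. The working correlation
  between tips decays as exp(-alpha * d_ij) in patristic distance, alpha
  estimated from standardised-residual products; coefficients solve the
  generalised estimating equations, so a large alpha (no signal) recovers
  ordinary logistic regression. Standard errors and the p-value for b1 come
  from a parametric bootstrap (small unbalanced tables make analytic SEs
  unreliable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .synthetic import PhyloTraitData

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Contingency statistics


@dataclass
class ContingencyResult:
    table: np.ndarray  # rows: X=0/1, cols: Y=0/1
    odds_ratio: float
    p_exact: float
    continuity_corrected: bool = False


def contingency(data: PhyloTraitData | np.ndarray) -> ContingencyResult:
    """2x2 residue-by-phenotype table, odds ratio and exact p.

    The odds ratio is (n11 * n00) / (n10 * n01); with a zero cell a
    continuity-corrected (+0.5) estimate is reported and flagged. The exact
    p is the two-sided conditional hypergeometric (Fisher) probability.
    """
    if isinstance(data, PhyloTraitData):
        x, y = data.residue, data.phenotype
        if len(set(x)) < 2:
            raise ValueError("both residue states must be present")
        tab = np.array([[np.sum((x == i) & (y == j)) for j in (0, 1)]
                        for i in (0, 1)], dtype=float)
    else:
        tab = np.asarray(data, dtype=float)
    n00, n01 = tab[0]
    n10, n11 = tab[1]
    corrected = False
    if n10 * n01 == 0 or n11 * n00 == 0:
        t = tab + 0.5
        odds = (t[1, 1] * t[0, 0]) / (t[1, 0] * t[0, 1])
        corrected = True
    else:
        odds = (n11 * n00) / (n10 * n01)
    _, p = stats.fisher_exact(tab.astype(int), alternative="two-sided")
    return ContingencyResult(tab.astype(int), float(odds), float(p), corrected)


# ---------------------------------------------------------------------------
# Phylogenetic logistic regression


@dataclass
class PhyloLogitFit:
    b0: float
    b1: float
    alpha: float
    se_b0: float
    se_b1: float
    p_b1: float
    r2_tjur: float
    r2_mcfadden: float
    converged: bool
    n_boot: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "diagnostics"}
        return d


_BETA_CAP = 15.0


def _gee_beta(Xd: np.ndarray, y: np.ndarray, Rinv: np.ndarray,
              beta: np.ndarray, max_iter: int = 50, tol: float = 1e-9,
              ridge: float = 0.0) -> tuple[np.ndarray, bool]:
    """Fisher-scoring solution of the logistic estimating equations.

    ``Rinv`` is the inverse working correlation (factorised once by the
    caller). ``ridge`` adds a weak quadratic shrinkage of the coefficients
    toward zero (a vague normal prior), which keeps quasi-separated data
    sets — common with strongly clustered binary traits — from diverging.
    """
    converged = False
    eye = np.eye(Xd.shape[1])
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = expit(eta)
        s = np.sqrt(np.clip(mu * (1 - mu), 1e-10, None))
        Xs = Xd * s[:, None]
        RiXs = Rinv @ Xs
        H = Xs.T @ RiXs + ridge * eye
        U = RiXs.T @ ((y - mu) / s) - ridge * beta
        try:
            delta = np.linalg.solve(H, U)
        except np.linalg.LinAlgError:
            break
        step = np.clip(delta, -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if np.any(np.abs(beta) > _BETA_CAP):
        beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
        converged = False
    return beta, converged


def _threshold_factor(mu: np.ndarray) -> np.ndarray:
    """Linearised attenuation of latent correlation by binarisation.

    For binary variables thresholded from latent Gaussians, the binary
    correlation is approximately ``rho * c_i * c_j`` with
    ``c = phi(Phi^-1(mu)) / sqrt(mu (1-mu))``.
    """
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    z = stats.norm.ppf(mu)
    return stats.norm.pdf(z) / np.sqrt(mu * (1 - mu))


def _working_R(D: np.ndarray, alpha: float, mu: np.ndarray) -> np.ndarray:
    """Binary-scale working correlation implied by latent decay rate alpha."""
    c = _threshold_factor(mu)
    R = np.exp(-alpha * D) * np.outer(c, c)
    np.fill_diagonal(R, 1.0)
    return R


def _inv(R: np.ndarray) -> np.ndarray:
    return np.linalg.inv(R + 1e-9 * np.eye(len(R)))


def _estimate_alpha(Xd: np.ndarray, y: np.ndarray, D: np.ndarray,
                    beta: np.ndarray) -> float:
    """Moment estimate of the latent correlation decay rate alpha.

    Matches products of standardised residuals to the binary correlation
    ``exp(-alpha d_ij) c_i c_j`` implied by the latent model over tip
    pairs (least squares in alpha).
    """
    mu = expit(np.clip(Xd @ beta, -30, 30))
    e = (y - mu) / np.sqrt(np.clip(mu * (1 - mu), 1e-10, None))
    c = _threshold_factor(mu)
    iu = np.triu_indices(len(y), k=1)
    prod = (e[:, None] * e[None, :])[iu]
    cc = (c[:, None] * c[None, :])[iu]
    d = D[iu]

    def objective(u):
        return float(np.sum((prod - cc * np.exp(-np.exp(u) * d)) ** 2))

    res = minimize_scalar(objective, bounds=(-10.0, 8.0), method="bounded")
    return float(np.exp(res.x))


def _fit_beta_alpha(Xd, y, D, alpha=None, n_outer=4, ridge=0.0, a_init=1.0):
    beta = np.zeros(Xd.shape[1])
    mu = np.full(len(y), y.mean() if 0 < y.mean() < 1 else 0.5)
    if alpha is not None:
        beta, conv = _gee_beta(Xd, y, _inv(_working_R(D, alpha, mu)), beta,
                               ridge=ridge)
        beta, conv = _gee_beta(
            Xd, y, _inv(_working_R(D, alpha, expit(Xd @ beta))), beta,
            ridge=ridge)
        return beta, float(alpha), conv
    a = float(a_init)
    conv = False
    for _ in range(n_outer):
        beta, conv = _gee_beta(Xd, y, _inv(_working_R(D, a, mu)), beta,
                               ridge=ridge)
        mu = expit(np.clip(Xd @ beta, -30, 30))
        a_new = _estimate_alpha(Xd, y, D, beta)
        if np.isclose(a_new, a, rtol=1e-3):
            a = a_new
            break
        a = a_new
    beta, conv = _gee_beta(Xd, y, _inv(_working_R(D, a, mu)), beta,
                           ridge=ridge)
    return beta, float(a), conv


def _simulate_copula(rng, mu, L):
    z = L @ rng.standard_normal(len(mu))
    return (z < stats.norm.ppf(np.clip(mu, 1e-12, 1 - 1e-12))).astype(float)


def phylo_logit(data: PhyloTraitData, n_boot: int = 200, *,
                alpha: float | None = None, ridge: float = 0.25,
                seed: int = 0) -> PhyloLogitFit:
    """Fit the phylogenetic logistic regression of phenotype on residue.

    ``alpha=None`` estimates the signal parameter from the data; passing a
    large fixed alpha together with ``ridge=0`` reduces the fit to ordinary
    logistic regression. The default weak shrinkage (``ridge=0.25``, a
    vague normal prior with sd 2 on the logit scale) stabilises
    quasi-separated data sets. ``n_boot=0`` skips the bootstrap (point
    estimates only; SEs/p are NaN).
    """
    x = np.asarray(data.residue, dtype=float)
    y = np.asarray(data.phenotype, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 species")
    Xd = np.column_stack([np.ones_like(x), x])
    D = data.patristic()
    if np.any(D[np.triu_indices(len(x), 1)] <= 0):
        log.warning("non-positive patristic distances present")

    beta, a_hat, converged = _fit_beta_alpha(Xd, y, D, alpha=alpha,
                                             ridge=ridge)
    b0, b1 = float(beta[0]), float(beta[1])
    mu_hat = expit(np.clip(Xd @ beta, -30, 30))

    # pseudo-R^2 (independence likelihoods)
    eps = 1e-12
    ll_fit = float(np.sum(y * np.log(mu_hat + eps)
                          + (1 - y) * np.log(1 - mu_hat + eps)))
    ybar = y.mean()
    ll_null = float(len(y) * (ybar * np.log(ybar + eps)
                              + (1 - ybar) * np.log(1 - ybar + eps)))
    r2_mcfadden = 1.0 - ll_fit / ll_null if ll_null != 0 else np.nan
    has_both = 0 < ybar < 1
    r2_tjur = (float(mu_hat[y == 1].mean() - mu_hat[y == 0].mean())
               if has_both else np.nan)

    se_b0 = se_b1 = p_b1 = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        # latent copula correlation for simulation; binary-scale working
        # correlation (threshold-attenuated) for refitting
        R_lat = np.exp(-a_hat * D)
        np.fill_diagonal(R_lat, 1.0)
        L = np.linalg.cholesky(R_lat + 1e-8 * np.eye(len(x)))
        Rinv_fit = _inv(_working_R(D, a_hat, mu_hat))

        # bootstrap SEs from the fitted model
        boots = []
        for _ in range(n_boot):
            yb = _simulate_copula(rng, mu_hat, L)
            bb, _ = _gee_beta(Xd, yb, Rinv_fit, beta.copy(), ridge=ridge)
            boots.append(bb)
        boots = np.array(boots)
        se_b0, se_b1 = boots.std(axis=0, ddof=1)

        # parametric bootstrap p for b1 under the no-association null
        beta_null, _ = _gee_beta(Xd[:, :1], y, Rinv_fit, np.zeros(1),
                                 ridge=ridge)
        mu_null = expit(np.clip(Xd[:, :1] @ beta_null, -30, 30))
        # each null resample is refit in full (alpha re-estimated), so the
        # p-value reflects the variability of the whole procedure
        count = 0
        for _ in range(n_boot):
            yb = _simulate_copula(rng, mu_null, L)
            bb, _, _ = _fit_beta_alpha(Xd, yb, D, ridge=ridge, n_outer=2,
                                       a_init=a_hat)
            if abs(bb[1]) >= abs(b1):
                count += 1
        p_b1 = (1 + count) / (n_boot + 1)

    return PhyloLogitFit(b0=b0, b1=b1, alpha=a_hat, se_b0=float(se_b0),
                         se_b1=float(se_b1), p_b1=float(p_b1),
                         r2_tjur=r2_tjur, r2_mcfadden=r2_mcfadden,
                         converged=converged, n_boot=n_boot)


def read_trait_table(tree_path, trait_path, *, alt_residue: str,
                     drop_residues: tuple[str, ...] = ()) -> PhyloTraitData:
    """Assemble PhyloTraitData from a Newick tree and a trait TSV.

    The TSV needs columns species, residue, phenotype. Tips without trait
    data (or with residues in ``drop_residues``) are pruned and logged;
    ``alt_residue`` codes X=1, every other retained residue codes X=0.
    """
    from skbio import TreeNode

    tree = TreeNode.read(str(tree_path))
    df = pd.read_csv(trait_path, sep="\t", dtype={"species": str})
    df = df[~df["residue"].isin(drop_residues)]
    tips = {t.name for t in tree.tips()}
    df = df[df["species"].isin(tips)]
    missing = tips - set(df["species"])
    if missing:
        log.info("pruning %d tips without trait data", len(missing))
        tree = tree.shear(sorted(set(df["species"])))
    species = [t.name for t in tree.tips()]
    df = df.set_index("species").loc[species]
    return PhyloTraitData(
        tree=tree, species=species,
        residue=(df["residue"] == alt_residue).to_numpy(dtype=np.int64),
        phenotype=df["phenotype"].to_numpy(dtype=np.int64))
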