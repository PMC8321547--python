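"""Context-dependent dN/dS selection test per gene.

A simplified dNdScv-style procedure: the neutral mutation spectrum is
estimated from synonymous variants only, stratified by the 96
strand-collapsed trinucleotide-context single-base changes and normalised
by the genome-wide opportunity (the number of possible synonymous changes
in each context class). Per gene, observed synonymous and missense counts
are compared with their context-adjusted expectations:

    omega_hat = (n_mis / E_mis) / (n_syn / E_syn)

with a Poisson likelihood-ratio test of omega = 1 (one-sided p for each
direction, Benjamini–Hochberg q across genes per direction). The full
dNdScv machinery (negative-binomial gene random effects, covariates) is
intentionally not reproduced; this is a principled, testable equivalent
for frequency-stratified breed variant sets. Nonsense variants are counted
but not tested by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import GeneAnnotation

log = logging.getLogger(__name__)

_BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(_BASES)}
_COMP = str.maketrans("ACGT", "TGCA")

SYN, MIS, NON = 0, 1, 2


def _codon_table() -> dict[str, str]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    return aa


_AA = _codon_table()


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def context_class(left: str, center: str, right: str, alt: str) -> int:
    """Index (0..95) of a strand-collapsed trinucleotide change.

    Changes with a purine central base are mapped to the reverse-complement
    strand so every class has a pyrimidine (C/T) centre.
    """
    if center in "AG":
        left, center, right = (right.translate(_COMP), center.translate(_COMP),
                               left.translate(_COMP))
        alt = alt.translate(_COMP)
    alts = [b for b in _BASES if b != center]
    return ((_B2I[left] * 4 + _B2I[right]) * 2
            + (1 if center == "T" else 0)) * 3 + alts.index(alt)


N_CONTEXT_CLASSES = 96


@dataclass
class GeneOpportunities:
    """All possible single-base coding changes of one gene."""

    gene_id: str
    chrom: str
    pos: np.ndarray        # 1-based genomic position of each change
    ref: np.ndarray        # reference base (genome strand)
    alt: np.ndarray        # alternative base (genome strand)
    impact: np.ndarray     # SYN / MIS / NON
    context: np.ndarray    # context class index


def classify_codon_change(codon: str, offset: int, alt_base: str) -> int:
    """Synonymous / missense / nonsense for one base change in a codon."""
    new = codon[:offset] + alt_base + codon[offset + 1:]
    aa0, aa1 = _AA[codon], _AA[new]
    if aa1 == aa0:
        return SYN
    if aa1 == "*":
        return NON
    return MIS


def gene_opportunities(gene: GeneAnnotation, genome: dict[str, str]
                       ) -> GeneOpportunities:
    """Enumerate every possible coding change of a gene with its context.

    The trinucleotide context is read from the genome strand (strand
    collapse makes the class independent of which strand is read); the
    amino-acid consequence is evaluated in the coding frame. Changes at
    contig edges (no flanking base) are skipped.
    """
    seq = genome[gene.chrom]
    if gene.cds_length % 3 != 0:
        raise ValueError(f"gene {gene.gene_id}: CDS length not divisible by 3")
    # map coding index -> genomic position (0-based)
    gpos = np.concatenate([np.arange(s, e) for s, e, _ in gene.cds])
    cds = "".join(seq[s:e] for s, e, _ in gene.cds)
    if gene.strand == "-":
        cds = revcomp(cds)
        gpos = gpos[::-1]

    pos_l, ref_l, alt_l, imp_l, ctx_l = [], [], [], [], []
    for i, base in enumerate(cds):
        g = int(gpos[i])
        if g == 0 or g + 1 >= len(seq):
            continue
        codon = cds[3 * (i // 3): 3 * (i // 3) + 3]
        offset = i % 3
        left, center, right = seq[g - 1], seq[g], seq[g + 1]
        for alt_c in _BASES:
            if alt_c == base:
                continue
            impact = classify_codon_change(codon, offset, alt_c)
            alt_g = alt_c if gene.strand == "+" else alt_c.translate(_COMP)
            pos_l.append(g + 1)
            ref_l.append(center)
            alt_l.append(alt_g)
            imp_l.append(impact)
            ctx_l.append(context_class(left, center, right, alt_g))
    return GeneOpportunities(
        gene_id=gene.gene_id, chrom=gene.chrom,
        pos=np.asarray(pos_l, dtype=np.int64), ref=np.asarray(ref_l),
        alt=np.asarray(alt_l), impact=np.asarray(imp_l, dtype=np.int64),
        context=np.asarray(ctx_l, dtype=np.int64))


@dataclass
class ContextRates:
    """Relative substitution rate per strand-collapsed context class."""

    rates: np.ndarray            # length 96
    observed_syn: np.ndarray
    opportunity_syn: np.ndarray


def estimate_rates(variants: pd.DataFrame,
                   opportunities: list[GeneOpportunities]) -> ContextRates:
    """Estimate context rates from synonymous variants only.

    ``variants`` needs columns chrom, pos (1-based), ref, alt. Rates are
    observed synonymous counts per class over synonymous opportunity per
    class; classes without opportunity are pooled to the global mean rate.
    """
    obs = np.zeros(N_CONTEXT_CLASSES)
    opp = np.zeros(N_CONTEXT_CLASSES)
    var_keys = set(zip(variants["chrom"].astype(str), variants["pos"].astype(int),
                       variants["ref"], variants["alt"]))
    total_syn = 0
    for go in opportunities:
        syn = go.impact == SYN
        np.add.at(opp, go.context[syn], 1)
        for j in np.flatnonzero(syn):
            if (go.chrom, int(go.pos[j]), str(go.ref[j]), str(go.alt[j])) in var_keys:
                obs[go.context[j]] += 1
                total_syn += 1
    if total_syn == 0:
        raise ValueError("no synonymous variants: cannot estimate rates")
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(opp > 0, obs / np.maximum(opp, 1), np.nan)
    empty = ~np.isfinite(rates)
    if empty.any():
        log.info("estimate_rates: %d context classes without opportunity "
                 "pooled to the global rate", int(empty.sum()))
        rates[empty] = obs.sum() / opp.sum()
    return ContextRates(rates=rates, observed_syn=obs, opportunity_syn=opp)


@dataclass
class GeneDnDs:
    gene_id: str
    n_syn: int
    n_mis: int
    n_non: int
    e_syn: float
    e_mis: float
    omega: float
    p_pos: float
    p_neg: float


def _poisson_lrt_one_sided(n_s, n_m, e_s, e_m):
    """One-sided p-values for omega != 1 from the profile Poisson LRT.

    H1 is the saturated two-count model; H0 ties both counts to one rate.
    The one-sided convention halves the chi-squared tail on the side of the
    deviation, giving p = 0.5 exactly at the boundary.
    """
    def ll(n, mu):
        if mu <= 0:
            return 0.0 if n == 0 else -np.inf
        return n * np.log(mu) - mu

    t0 = (n_s + n_m) / (e_s + e_m)
    l0 = ll(n_s, t0 * e_s) + ll(n_m, t0 * e_m)
    l1 = ll(n_s, n_s) + ll(n_m, n_m)
    lam = max(0.0, 2 * (l1 - l0))
    tail = 0.5 * stats.chi2.sf(lam, 1)
    # direction: observed missense enrichment relative to expectation
    enriched = n_m * e_s > n_s * e_m
    depleted = n_m * e_s < n_s * e_m
    p_pos = tail if enriched else 1 - tail
    p_neg = tail if depleted else 1 - tail
    return p_pos, p_neg


def _poisson_exact_one_sided(n_s, n_m, e_s, e_m):
    """Exact Poisson tail p-values conditional on the synonymous rate."""
    t_hat = n_s / e_s if e_s > 0 else np.nan
    mu = t_hat * e_m
    if not np.isfinite(mu) or mu <= 0:
        return np.nan, np.nan
    p_pos = float(stats.poisson.sf(n_m - 1, mu))
    p_neg = float(stats.poisson.cdf(n_m, mu))
    return p_pos, p_neg


def gene_test(go: GeneOpportunities, variants: pd.DataFrame,
              rates: ContextRates, maf_min: float = 0.1,
              method: str = "lrt") -> GeneDnDs | None:
    """Per-gene dN/dS test at one frequency stratum.

    ``variants`` needs chrom, pos, ref, alt and a ``freq`` column (the
    target breed's alt frequency); only variants with freq >= maf_min are
    counted. Returns None (logged) for genes with zero missense
    expectation.
    """
    sel = variants[(variants["chrom"].astype(str) == go.chrom)
                   & (variants["freq"] >= maf_min)]
    keys = set(zip(sel["pos"].astype(int), sel["ref"], sel["alt"]))
    hit = np.fromiter(((int(p), str(r), str(a)) in keys
                       for p, r, a in zip(go.pos, go.ref, go.alt)),
                      dtype=bool, count=len(go.pos))
    n_syn = int(hit[go.impact == SYN].sum())
    n_mis = int(hit[go.impact == MIS].sum())
    n_non = int(hit[go.impact == NON].sum())
    e_syn = float(rates.rates[go.context[go.impact == SYN]].sum())
    e_mis = float(rates.rates[go.context[go.impact == MIS]].sum())
    if e_mis <= 0 or e_syn <= 0:
        log.info("gene %s excluded: zero expectation", go.gene_id)
        return None
    omega = ((n_mis / e_mis) / (n_syn / e_syn)) if n_syn > 0 else np.inf
    if n_syn == 0 and n_mis == 0:
        omega = np.nan
    if method == "lrt":
        p_pos, p_neg = _poisson_lrt_one_sided(n_syn, n_mis, e_syn, e_mis)
    elif method == "exact":
        p_pos, p_neg = _poisson_exact_one_sided(n_syn, n_mis, e_syn, e_mis)
    else:
        raise ValueError(f"unknown method: {method}")
    return GeneDnDs(go.gene_id, n_syn, n_mis, n_non, e_syn, e_mis,
                    float(omega), p_pos, p_neg)


def run_dnds(genes: list[GeneAnnotation], genome: dict[str, str],
             variants: pd.DataFrame, maf_min: float = 0.1,
             method: str = "lrt") -> pd.DataFrame:
    """Genome-wide dN/dS: rates from all synonymous variants, then per-gene
    tests at the requested frequency stratum, with per-direction BH q-values.
    """
    from statsmodels.stats.multitest import multipletests

    opps = [gene_opportunities(g, genome) for g in genes]
    rates = estimate_rates(variants, opps)
    rows = []
    for go in opps:
        r = gene_test(go, variants, rates, maf_min=maf_min, method=method)
        if r is not None:
            rows.append(r)
    df = pd.DataFrame([vars(r) for r in rows])
    if len(df):
        for side in ("p_pos", "p_neg"):
            ok = np.isfinite(df[side])
            q = np.full(len(df), np.nan)
            if ok.any():
                q[ok] = multipletests(df.loc[ok, side], method="fdr_bh")[1]
            df[side.replace("p_", "q_")] = q
    return df
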