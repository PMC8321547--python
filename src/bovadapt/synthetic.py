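"""Synthetic study generator.

Emulates the statistical structure the analysis stages assume, so the whole
pipeline is testable without the original resequencing data:

* hierarchical population allele frequencies drifting on a population tree
  (Balding–Nichols Beta model: child frequency ~ Beta(pi(1-F)/F,
  (1-pi)(1-F)/F) around the parent frequency pi, so that
  Var(p_child | pi) = F pi(1-pi));
* donor-ancestry tracts copied into a recipient population;
* selective sweeps (frequency outliers) for the FLK scan to flag;
* binary traits evolving on a phylogeny together with a residue covariate.

Genotypes are drawn independently per sample (no linkage disequilibrium);
the downstream stages are frequency-based, so LD realism is not required
for their contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import PanelConfig, SiteTable

DEFAULT_ANCESTRAL_RANGE = (0.05, 0.95)


@dataclass(frozen=True)
class SimTreeSpec:
    """Rooted population tree with per-branch drift.

    ``branches`` maps node name → (parent name | None for the root, branch
    drift F in (0,1); the root's drift is ignored). ``sample_sizes`` gives
    diploid sample counts for the leaf populations (the populations of the
    output table).
    """

    branches: dict[str, tuple[str | None, float]]
    sample_sizes: dict[str, int]
    ancestral_range: tuple[float, float] = DEFAULT_ANCESTRAL_RANGE
    seed: int = 0

    def __post_init__(self):
        roots = [n for n, (p, _) in self.branches.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {roots}")
        for n, (p, F) in self.branches.items():
            if p is not None and not 0 < F < 1:
                raise ValueError(f"branch {n}: drift F={F} outside (0,1)")
            if p is not None and p not in self.branches:
                raise ValueError(f"branch {n}: unknown parent {p}")
        for pop, n in self.sample_sizes.items():
            if pop not in self.branches:
                raise ValueError(f"sampled population {pop} not in tree")
            if n < 1:
                raise ValueError(f"population {pop}: sample size must be >= 1")
        # reachability from the root (connectedness)
        for n in self.branches:
            seen, cur = set(), n
            while cur is not None:
                if cur in seen:
                    raise ValueError("cycle in population tree")
                seen.add(cur)
                cur = self.branches[cur][0]

    @property
    def root(self) -> str:
        return next(n for n, (p, _) in self.branches.items() if p is None)

    @property
    def populations(self) -> list[str]:
        return sorted(self.sample_sizes)

    @classmethod
    def star(cls, pops: list[str], F: float = 0.02, n: int = 25,
             seed: int = 0) -> "SimTreeSpec":
        """Star tree: every population drifts independently from one root."""
        branches = {"root": (None, 0.0)}
        branches.update({p: ("root", F) for p in pops})
        return cls(branches, {p: n for p in pops}, seed=seed)

    def expected_kinship(self) -> tuple[list[str], np.ndarray]:
        """Drift covariance implied by the tree: F_ij = shared root-path drift.

        Branch drift composes as 1 - (1-F_total) = 1 - prod(1-F_b); the FLK
        drift scale is t = -ln(1-F), which is additive along a path, so the
        kinship entry for two populations is the summed t over their shared
        branches from the root.
        """
        pops = self.populations
        paths = {}
        for p in pops:
            path, cur = [], p
            while self.branches[cur][0] is not None:
                path.append(cur)
                cur = self.branches[cur][0]
            paths[p] = list(reversed(path))
        K = np.zeros((len(pops), len(pops)))
        for i, a in enumerate(pops):
            for j, b in enumerate(pops):
                shared = 0.0
                for x, y in zip(paths[a], paths[b]):
                    if x != y:
                        break
                    shared += -np.log1p(-self.branches[x][1])
                K[i, j] = shared
        return pops, K


def _topo_order(branches: dict[str, tuple[str | None, float]]) -> list[str]:
    order, placed = [], set()
    pending = sorted(branches)
    while pending:
        nxt = [n for n in pending if branches[n][0] is None or branches[n][0] in placed]
        order.extend(nxt)
        placed.update(nxt)
        pending = [n for n in pending if n not in placed]
    return order


def _bn_draw(rng: np.random.Generator, parent: np.ndarray, F: float) -> np.ndarray:
    """Balding–Nichols Beta draw around parent frequencies.

    Implemented through paired Gamma draws so that parent frequencies at the
    0/1 boundary propagate unchanged instead of producing 0/0.
    """
    a = parent * (1 - F) / F
    b = (1 - parent) * (1 - F) / F
    x = rng.gamma(np.maximum(a, 1e-300))
    y = rng.gamma(np.maximum(b, 1e-300))
    with np.errstate(invalid="ignore"):
        p = x / (x + y)
    fixed = (parent <= 0) | (parent >= 1) | ~np.isfinite(p)
    return np.where(fixed, parent, p)


def simulate_sites(spec: SimTreeSpec, n_sites: int, *,
                   genotypes: bool = True) -> SiteTable:
    """Simulate a SiteTable of unlinked biallelic SNPs.

    Ancestral frequencies are Uniform over ``spec.ancestral_range`` (keeps
    sites polymorphic); frequencies drift down the tree under the
    Balding–Nichols model; allele counts are Binomial(2N, p) per population.
    With ``genotypes=True`` a per-sample dosage matrix is also drawn
    (Binomial(2, p) per diploid sample, consistent with the counts).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_range
    pi = rng.uniform(lo, hi, size=n_sites)

    freqs = {spec.root: pi}
    for node in _topo_order(spec.branches):
        parent, F = spec.branches[node]
        if parent is None:
            continue
        freqs[node] = _bn_draw(rng, freqs[parent], F)

    pops = spec.populations
    latent = np.column_stack([freqs[p] for p in pops])

    positions = np.arange(1, n_sites + 1) * 1000  # 1 kb spacing on one contig
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
    sites = pd.DataFrame({
        "chrom": np.repeat("1", n_sites),
        "pos": positions,
        "ref": bases[ref_i],
        "alt": bases[alt_i],
    })

    table = SiteTable(
        sites=sites, populations=pops,
        alt_counts=np.zeros((n_sites, len(pops)), dtype=np.int64),
        called=np.zeros((n_sites, len(pops)), dtype=np.int64),
        latent_freq=latent,
        meta={"seed": spec.seed},
    )
    if genotypes:
        sizes = [spec.sample_sizes[p] for p in pops]
        table.samples = [f"{p}_{k}" for p, n in zip(pops, sizes) for k in range(n)]
        table.sample_pops = np.repeat(np.arange(len(pops)), sizes)
        cols = []
        for j, p in enumerate(pops):
            cols.append(rng.binomial(2, latent[:, [j]],
                                     size=(n_sites, sizes[j])).astype(np.int8))
        table.genotypes = np.concatenate(cols, axis=1)
        from .panel_io import recount_from_genotypes
        recount_from_genotypes(table)
    else:
        for j, p in enumerate(pops):
            two_n = 2 * spec.sample_sizes[p]
            table.alt_counts[:, j] = rng.binomial(two_n, latent[:, j])
            table.called[:, j] = two_n
    return table


def default_panel(spec: SimTreeSpec, groups: dict[str, set[str]] | None = None
                  ) -> PanelConfig:
    """PanelConfig for a simulated table (samples named ``<pop>_<k>``)."""
    if groups is None:
        groups = {p: {"target"} if i == 0 else {"other"}
                  for i, p in enumerate(spec.populations)}
    s2p = {f"{p}_{k}": p for p in spec.populations
           for k in range(spec.sample_sizes[p])}
    return PanelConfig(s2p, {p: frozenset(t) for p, t in groups.items()})


# ---------------------------------------------------------------------------
# Introgression tracts


@dataclass(frozen=True)
class TractSpec:
    """Donor→recipient introgression tracts (0-based half-open coordinates)."""

    donor: str
    recipient: str
    tracts: tuple[tuple[str, int, int], ...]
    carrier_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.carrier_fraction <= 1:
            raise ValueError("carrier fraction must be in (0, 1]")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in self.tracts:
            if e <= s:
                raise ValueError(f"tract {c}:{s}-{e}: end <= start")
            by_chrom.setdefault(c, []).append((s, e))
        for c, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping tracts on {c}")


def inject_introgression(table: SiteTable, spec: TractSpec
                         ) -> tuple[SiteTable, pd.DataFrame]:
    """Copy donor ancestry into the recipient within the given tracts.

    Within each tract a carrier-fraction share of recipient haplotypes is
    resampled from the donor's latent frequency. Returns the modified table
    plus the truth tracts for evaluator use.
    """
    if spec.donor not in table.populations or spec.recipient not in table.populations:
        raise ValueError("donor/recipient population not in table")
    if table.latent_freq is None:
        raise ValueError("introgression injection needs latent frequencies")
    rng = np.random.default_rng(spec.seed)
    out = table.subset(np.arange(table.n_sites))
    out.latent_freq = table.latent_freq.copy()
    jd, jr = table.pop_index(spec.donor), table.pop_index(spec.recipient)
    c = spec.carrier_fraction

    pos0 = table.pos0()
    chroms = table.sites["chrom"].astype(str).to_numpy()
    max_pos = {}
    for ch in np.unique(chroms):
        max_pos[ch] = pos0[chroms == ch].max()
    in_tract = np.zeros(table.n_sites, dtype=bool)
    for ch, s, e in spec.tracts:
        if ch not in max_pos or s > max_pos[ch]:
            raise ValueError(f"tract {ch}:{s}-{e} outside simulated coordinates")
        in_tract |= (chroms == ch) & (pos0 >= s) & (pos0 < e)

    idx = np.flatnonzero(in_tract)
    if idx.size:
        p_mix = c * table.latent_freq[idx, jd] + (1 - c) * table.latent_freq[idx, jr]
        out.latent_freq[idx, jr] = p_mix
        _redraw_population(out, jr, idx, rng)
    truth = pd.DataFrame(spec.tracts, columns=["chrom", "start", "end"])
    truth["label"] = spec.donor
    truth["carrier_frac"] = c
    return out, truth


def _redraw_population(table: SiteTable, j: int, idx: np.ndarray,
                       rng: np.random.Generator) -> None:
    """Redraw counts/genotypes for population j at sites idx from latent freq."""
    p = table.latent_freq[idx, j]
    if table.genotypes is not None:
        cols = np.flatnonzero(table.sample_pops == j)
        table.genotypes[np.ix_(idx, cols)] = rng.binomial(
            2, p[:, None], size=(idx.size, cols.size)).astype(np.int8)
        from .panel_io import recount_from_genotypes
        recount_from_genotypes(table)
    else:
        two_n = table.called[idx, j]
        table.alt_counts[idx, j] = rng.binomial(two_n, p)


def admix_population(table: SiteTable, target: str, parents: tuple[str, str],
                     weight: float = 0.5, seed: int = 0) -> SiteTable:
    """Rebuild one population as a two-way admixture of two parents.

    The target's latent frequency becomes ``weight * p_parent1 +
    (1-weight) * p_parent2`` genome-wide (a population whose haplotypes
    descend from both parents) and its counts/genotypes are redrawn.
    """
    if not 0 <= weight <= 1:
        raise ValueError("weight must be in [0, 1]")
    if table.latent_freq is None:
        raise ValueError("admixture injection needs latent frequencies")
    rng = np.random.default_rng(seed)
    out = table.subset(np.arange(table.n_sites))
    out.latent_freq = table.latent_freq.copy()
    j = table.pop_index(target)
    j1, j2 = (table.pop_index(p) for p in parents)
    out.latent_freq[:, j] = (weight * table.latent_freq[:, j1]
                             + (1 - weight) * table.latent_freq[:, j2])
    _redraw_population(out, j, np.arange(table.n_sites), rng)
    return out


# ---------------------------------------------------------------------------
# Selective sweeps


def inject_sweep(table: SiteTable, population: str, locus_index: int,
                 target_freq: float, *, shoulder: int = 2,
                 seed: int = 0) -> SiteTable:
    """Push one population's frequency toward ``target_freq`` at a locus.

    The locus and ``shoulder`` flanking markers on each side are set to the
    target frequency (a hard-sweep plateau); genotypes/counts are redrawn.
    """
    if not 0 <= target_freq <= 1:
        raise ValueError("target_freq must be in [0, 1]")
    if not 0 <= locus_index < table.n_sites:
        raise ValueError("locus index out of range")
    if table.latent_freq is None:
        raise ValueError("sweep injection needs latent frequencies")
    rng = np.random.default_rng(seed)
    out = table.subset(np.arange(table.n_sites))
    out.latent_freq = table.latent_freq.copy()
    j = table.pop_index(population)
    lo = max(0, locus_index - shoulder)
    hi = min(table.n_sites, locus_index + shoulder + 1)
    idx = np.arange(lo, hi)
    out.latent_freq[idx, j] = target_freq
    _redraw_population(out, j, idx, rng)
    return out


# ---------------------------------------------------------------------------
# Coding-sequence study for the dN/dS stage


def simulate_coding_study(n_genes: int = 200, n_codons: int = 200, *,
                          mut_prob: float = 0.02, omega: float = 1.0,
                          seed: int = 0):
    """Random genes plus variants drawn under a uniform mutation process.

    Each gene is a random open reading frame (internal stop codons are
    harmless: they only create nonsense opportunities). Every possible
    coding change occurs independently with probability ``mut_prob``,
    multiplied by ``omega`` for missense changes, so ``omega=1`` is the
    neutral null of the dN/dS test. Returns (genes, genome, variants):
    variants have columns chrom, pos, ref, alt, freq (freq drawn
    Uniform(0.6, 1) so both frequency strata keep them).
    """
    from .dnds import MIS, gene_opportunities
    from .panel_io import GeneAnnotation

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genes, genome = [], {}
    rows = []
    for g in range(n_genes):
        chrom = f"g{g}"
        L = 3 * n_codons
        seq = "".join(rng.choice(bases, size=L + 20))  # 10 bp flanks
        genome[chrom] = seq
        gene = GeneAnnotation(f"gene{g}", chrom, 10, 10 + L, "+",
                              ((10, 10 + L, 0),))
        genes.append(gene)
        go = gene_opportunities(gene, genome)
        prob = np.where(go.impact == MIS, mut_prob * omega, mut_prob)
        hit = rng.random(len(go.pos)) < prob
        # at most one alt per genomic position (biallelic SNPs)
        seen: set[int] = set()
        for j in np.flatnonzero(hit):
            p = int(go.pos[j])
            if p in seen:
                continue
            seen.add(p)
            rows.append((chrom, p, str(go.ref[j]), str(go.alt[j]),
                         float(rng.uniform(0.6, 1.0))))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "freq"])
    return genes, genome, variants


# ---------------------------------------------------------------------------
# Phylogeny + binary trait simulation


@dataclass(frozen=True)
class PhenotypeSimSpec:
    """Residue + binary phenotype evolving on a species tree.

    The residue state X is a symmetric 2-state Markov chain with the given
    transition rate. The phenotype Y is Bernoulli with marginal mean
    ``invlogit(b0 + b1 X)`` and phylogenetically correlated residuals: a
    Gaussian copula with tip correlation ``exp(-alpha * d_ij)`` (patristic
    distance d), so small ``alpha`` means strong phylogenetic signal and
    ``alpha -> inf`` recovers independent tips.
    """

    transition_rate: float = 0.02
    b0: float = -1.0
    b1: float = 2.0
    alpha: float = 0.05
    tree_depth: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.transition_rate <= 0:
            raise ValueError("transition rate must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class PhyloTraitData:
    """Species tree with per-tip residue state and binary phenotype."""

    tree: "object"  # skbio.TreeNode
    species: list[str]
    residue: np.ndarray  # X in {0,1}
    phenotype: np.ndarray  # Y in {0,1}

    def patristic(self) -> np.ndarray:
        dm = self.tree.tip_tip_distances(endpoints=self.species)
        order = [dm.ids.index(s) for s in self.species]
        return np.asarray(dm.data)[np.ix_(order, order)]

    def to_tsv(self, path) -> None:
        pd.DataFrame({"species": self.species, "residue": self.residue,
                      "phenotype": self.phenotype}).to_csv(path, sep="\t",
                                                           index=False)


def random_coalescent_tree(n_species: int, seed: int = 0,
                           depth: float | None = None):
    """Random binary tree with exponential coalescence times (skbio TreeNode).

    With ``depth`` set, branch lengths are rescaled so the root-to-tip
    height equals it (e.g. ~100 time units, the scale of a calibrated
    mammal phylogeny in millions of years).
    """
    from skbio import TreeNode

    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"sp{i}") for i in range(n_species)]
    heights = [0.0] * n_species
    t = 0.0
    k = n_species
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = t - heights[i]
        b.length = t - heights[j]
        parent.extend([a, b])
        nodes = [nodes[m] for m in range(k) if m not in (i, j)] + [parent]
        heights = [heights[m] for m in range(k) if m not in (i, j)] + [t]
        k -= 1
    root = nodes[0]
    root.length = None
    if depth is not None and t > 0:
        for node in root.traverse(include_self=False):
            node.length = node.length * depth / t
    return root


def simulate_phylo_trait(spec: PhenotypeSimSpec, n_species: int,
                         tree=None) -> PhyloTraitData:
    """Simulate residue states and a correlated binary phenotype on a tree."""
    from scipy.stats import norm

    if n_species < 4:
        raise ValueError("need at least 4 species")
    rng = np.random.default_rng(spec.seed)
    if tree is None:
        tree = random_coalescent_tree(n_species, seed=spec.seed,
                                      depth=spec.tree_depth)

    # residue: symmetric 2-state Markov chain down the tree
    states: dict[int, int] = {id(tree): int(rng.integers(0, 2))}
    for node in tree.preorder(include_self=False):
        t = node.length or 0.0
        p_switch = 0.5 * (1.0 - np.exp(-2.0 * spec.transition_rate * t))
        parent_state = states[id(node.parent)]
        flip = rng.random() < p_switch
        states[id(node)] = parent_state ^ int(flip)
    tips = list(tree.tips())
    species = [t.name for t in tips]
    x = np.array([states[id(t)] for t in tips], dtype=np.int64)

    # phenotype: Gaussian copula with phylogenetic correlation
    data = PhyloTraitData(tree, species, x, np.zeros(len(tips), dtype=np.int64))
    D = data.patristic()
    R = np.exp(-spec.alpha * D)
    np.fill_diagonal(R, 1.0)
    L = np.linalg.cholesky(R + 1e-9 * np.eye(len(tips)))
    z = L @ rng.standard_normal(len(tips))
    mu = 1.0 / (1.0 + np.exp(-(spec.b0 + spec.b1 * x)))
    data.phenotype = (z < norm.ppf(mu)).astype(np.int64)
    return data
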