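"""Input/output and site filtering.

Reads multi-sample VCFs into the internal :class:`SiteTable`, applies the
GATK-style hard filters and the sample-presence filter, and parses the
sample→population panel, BED tracts and BED12 gene annotations used by the
downstream stages.

Coordinate conventions: VCF positions are 1-based; every internal interval
type (tracts, genes, masks) is 0-based half-open, BED-style.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: closed vocabulary of population group tags
GROUP_TAGS = frozenset(
    {
        "target",
        "eu_taurine",
        "asian_taurine",
        "african_taurine",
        "chinese_taurine",
        "indicine",
        "bovinae_species",
        "other",
    }
)

HARD_FILTER_RULES = {
    # annotation -> (threshold, fail_if) ; GATK hard-filter defaults
    "QD": (2.0, "lt"),
    "MQ": (40.0, "lt"),
    "FS": (60.0, "gt"),
    "MQRankSum": (-12.5, "lt"),
    "ReadPosRankSum": (-8.0, "lt"),
}


class PanelError(ValueError):
    """Configuration problem in the sample→population panel."""


@dataclass(frozen=True)
class PanelConfig:
    """Sample→population map plus population group tags.

    Each sample belongs to exactly one population; each population carries a
    set of group tags from :data:`GROUP_TAGS` (e.g. ``{"target"}`` for the
    focal breed, ``{"eu_taurine"}`` for European taurine reference breeds).
    """

    sample_to_pop: dict[str, str]
    pop_groups: dict[str, frozenset[str]]

    def __post_init__(self):
        pops = set(self.sample_to_pop.values())
        missing = pops - set(self.pop_groups)
        if missing:
            raise PanelError(f"populations without group tags: {sorted(missing)}")
        bad = {t for tags in self.pop_groups.values() for t in tags} - GROUP_TAGS
        if bad:
            raise PanelError(f"unknown group tags: {sorted(bad)}")
        if not any("target" in tags for tags in self.pop_groups.values()):
            raise PanelError("no population tagged 'target'")

    @property
    def populations(self) -> list[str]:
        return sorted(self.pop_groups)

    def samples_for(self, pop: str) -> list[str]:
        return sorted(s for s, p in self.sample_to_pop.items() if p == pop)

    def pops_in_group(self, tag: str) -> list[str]:
        if tag not in GROUP_TAGS:
            raise PanelError(f"unknown group tag: {tag}")
        return sorted(p for p, tags in self.pop_groups.items() if tag in tags)

    @classmethod
    def from_tsv(cls, path) -> "PanelConfig":
        """Read a ``sample<TAB>population<TAB>group[,group...]`` panel file."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["sample", "population", "groups"], dtype=str)
        s2p: dict[str, str] = {}
        groups: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            if row.sample in s2p and s2p[row.sample] != row.population:
                raise PanelError(f"sample {row.sample} mapped to two populations")
            s2p[row.sample] = row.population
            tags = set(str(row.groups).split(","))
            groups.setdefault(row.population, set()).update(tags)
        return cls(s2p, {p: frozenset(t) for p, t in groups.items()})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s in sorted(self.sample_to_pop):
                pop = self.sample_to_pop[s]
                fh.write(f"{s}\t{pop}\t{','.join(sorted(self.pop_groups[pop]))}\n")


def _chrom_key(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))


@dataclass
class SiteTable:
    """Biallelic SNP sites with per-population allele counts.

    ``alt_counts[i, j]`` / ``called[i, j]`` are the alternative-allele count
    and the number of called alleles for site *i* in population *j*; the
    population frequency is their ratio, NaN where nothing was called.
    ``genotypes`` (optional) stores per-sample alt-allele dosage (0/1/2, −1
    for missing). ``latent_freq`` (optional) carries the generating
    population frequencies when the table came from the simulator.
    """

    sites: pd.DataFrame
    populations: list[str]
    alt_counts: np.ndarray
    called: np.ndarray
    samples: list[str] | None = None
    sample_pops: np.ndarray | None = None  # population index per sample
    genotypes: np.ndarray | None = None
    latent_freq: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def pop_index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"unknown population: {pop}") from None

    def freq(self, pop: str | None = None, source: str = "observed") -> np.ndarray:
        """Alt-allele frequency matrix (or one population's vector)."""
        if source == "latent":
            if self.latent_freq is None:
                raise ValueError("table carries no latent frequencies")
            f = self.latent_freq
        elif source == "observed":
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(self.called > 0,
                             self.alt_counts / np.maximum(self.called, 1), np.nan)
        else:
            raise ValueError(f"unknown frequency source: {source}")
        return f if pop is None else f[:, self.pop_index(pop)]

    def subset(self, mask) -> "SiteTable":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            alt_counts=self.alt_counts[idx],
            called=self.called[idx],
            genotypes=None if self.genotypes is None else self.genotypes[idx],
            latent_freq=None if self.latent_freq is None else self.latent_freq[idx],
            meta=dict(self.meta),
        )

    def sorted(self) -> "SiteTable":
        order = sorted(
            range(self.n_sites),
            key=lambda i: (_chrom_key(self.sites.iloc[i]["chrom"]),
                           int(self.sites.iloc[i]["pos"])),
        )
        return self.subset(np.asarray(order))

    def pos0(self) -> np.ndarray:
        """0-based positions (VCF pos − 1)."""
        return self.sites["pos"].to_numpy(dtype=np.int64) - 1


def _validate_table(t: SiteTable) -> None:
    if np.any(t.alt_counts > t.called):
        raise ValueError("alt_count exceeds called allele number")


# ---------------------------------------------------------------------------
# VCF input / output


def read_vcf(path, panel: PanelConfig) -> SiteTable:
    """Read biallelic SNP records from a VCF 4.x file into a SiteTable.

    Multi-allelic records and indels are dropped (counted in ``meta``).
    Samples absent from the panel are ignored with a warning; zero overlap
    between the VCF header and the panel is a configuration error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    header_samples = list(vcf.samples)
    known = [s for s in header_samples if s in panel.sample_to_pop]
    unknown = [s for s in header_samples if s not in panel.sample_to_pop]
    if unknown:
        log.warning("ignoring %d VCF samples absent from panel: %s...",
                    len(unknown), unknown[:5])
    if not known:
        raise PanelError("no VCF samples overlap the panel")
    keep_idx = np.array([header_samples.index(s) for s in known])

    pops = panel.populations
    pop_of = np.array([pops.index(panel.sample_to_pop[s]) for s in known])

    rows, dosages = [], []
    n_dropped = 0
    ann_fields = list(HARD_FILTER_RULES)
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=missing
        gt = np.asarray(v.gt_types)[keep_idx].astype(np.int8)
        gt[gt == 3] = -1
        row = {"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0]}
        for a in ann_fields:
            val = v.INFO.get(a)
            row[a] = float(val) if val is not None else np.nan
        rows.append(row)
        dosages.append(gt)
    if n_dropped:
        log.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"] + ann_fields)
    geno = (np.vstack(dosages) if dosages
            else np.zeros((0, len(known)), dtype=np.int8))
    table = SiteTable(
        sites=sites, populations=pops,
        alt_counts=np.zeros((len(sites), len(pops)), dtype=np.int64),
        called=np.zeros((len(sites), len(pops)), dtype=np.int64),
        samples=known, sample_pops=pop_of, genotypes=geno,
        meta={"dropped_non_snp": n_dropped},
    )
    recount_from_genotypes(table)
    _validate_table(table)
    return table.sorted()


def recount_from_genotypes(table: SiteTable) -> None:
    """Recompute per-population allele counts from the genotype matrix."""
    g = table.genotypes
    if g is None:
        raise ValueError("table has no genotype matrix")
    for j in range(len(table.populations)):
        cols = np.flatnonzero(table.sample_pops == j)
        sub = g[:, cols]
        called = (sub >= 0).sum(axis=1) * 2
        alt = np.where(sub > 0, sub, 0).sum(axis=1)
        table.called[:, j] = called
        table.alt_counts[:, j] = alt


def write_vcf(table: SiteTable, path) -> None:
    """Write a minimal deterministic VCF 4.2 with GT fields."""
    if table.genotypes is None:
        raise ValueError("write_vcf requires per-sample genotypes")
    opener = gzip.open if str(path).endswith(".gz") else open
    gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for a in HARD_FILTER_RULES:
            fh.write(f'##INFO=<ID={a},Number=1,Type=Float,Description="{a}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        has_ann = [a for a in HARD_FILTER_RULES if a in table.sites.columns]
        for i, row in enumerate(table.sites.itertuples(index=False)):
            info = ";".join(
                f"{a}={getattr(row, a):g}" for a in has_ann
                if np.isfinite(getattr(row, a))
            ) or "."
            gts = "\t".join(gt_str[int(d)] for d in table.genotypes[i])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                     f"{info}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Site filters


def hard_filter(table: SiteTable) -> tuple[SiteTable, dict[str, int]]:
    """Remove sites failing the GATK-style hard-filter thresholds.

    A missing annotation counts as a pass. A site failing several rules is
    attributed to every failed rule in the returned per-rule counts, but is
    removed only once.
    """
    n = table.n_sites
    fail_any = np.zeros(n, dtype=bool)
    counts: dict[str, int] = {}
    for ann, (thr, mode) in HARD_FILTER_RULES.items():
        if ann not in table.sites.columns:
            counts[ann] = 0
            continue
        vals = table.sites[ann].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            fails = (vals < thr) if mode == "lt" else (vals > thr)
        fails &= np.isfinite(vals)
        counts[ann] = int(fails.sum())
        fail_any |= fails
    counts["total_removed"] = int(fail_any.sum())
    return table.subset(~fail_any), counts


def presence_filter(table: SiteTable, min_fraction: float) -> SiteTable:
    """Keep sites genotyped in at least ``min_fraction`` of all samples.

    Boundary inclusive: a site called in exactly ``min_fraction`` of samples
    is retained.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if table.genotypes is not None:
        called_samples = (table.genotypes >= 0).sum(axis=1)
        total = table.genotypes.shape[1]
    else:
        called_samples = table.called.sum(axis=1) // 2
        if table.samples is not None:
            total = len(table.samples)
        elif table.n_sites:
            total = int(np.max(table.called.sum(axis=1)) // 2)
        else:
            total = 1
    frac = called_samples / max(total, 1)
    return table.subset(frac >= min_fraction)


def autosome_filter(table: SiteTable, autosomes) -> SiteTable:
    """Restrict to a configured autosome list (drops X/Y/unplaced contigs)."""
    allowed = {str(c) for c in autosomes}
    keep = table.sites["chrom"].astype(str).isin(allowed).to_numpy()
    return table.subset(keep)


# ---------------------------------------------------------------------------
# Gene annotation and tract BED files


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with ordered CDS segments (0-based half-open, with frame phase)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: tuple[tuple[int, int, int], ...] = ()  # (start, end, phase)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")
        last = -1
        for s, e, _ in self.cds:
            if s < last:
                raise ValueError(f"gene {self.gene_id}: CDS segments overlap/unsorted")
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: CDS outside gene span")
            last = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)


def read_genes_bed12(path) -> list[GeneAnnotation]:
    """Read gene models from BED12 (blocks interpreted as CDS segments)."""
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes",
            "blockStarts"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols,
                     dtype={"chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        cds, phase = [], 0
        for bs, sz in zip(starts, sizes):
            s = int(row.start) + bs
            cds.append((s, s + sz, phase))
            phase = (phase + sz) % 3
        genes.append(GeneAnnotation(str(row.name), str(row.chrom), int(row.start),
                                    int(row.end), str(row.strand), tuple(cds)))
    return genes


def write_genes_bed12(genes: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e, _ in g.cds)
            starts = ",".join(str(s - g.start) for s, e, _ in g.cds)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.cds)}\t{sizes},\t{starts},\n")


def read_tracts_bed(path) -> pd.DataFrame:
    """Read ancestry tracts: chrom, start, end, label, carrier_fraction."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "label", "carrier_frac"],
                     dtype={"chrom": str, "label": str})
    if df["carrier_frac"].isna().any():
        df["carrier_frac"] = df["carrier_frac"].fillna(1.0)
    return df


def write_tracts_bed(tracts: pd.DataFrame, path) -> None:
    tracts.to_csv(path, sep="\t", header=False, index=False,
                  columns=["chrom", "start", "end", "label", "carrier_frac"])
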