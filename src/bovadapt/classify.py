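"""High-frequency allele discovery and ancestral/introgressed classification.

Implements the breed-contrast discovery filter (alt-allele frequency >= 0.7
in the target breed, <= 0.1 in every contrast breed, autosomal) and the
decomposition of the discovered alleles into the categories that separate
ancestral-allele retention from introgression: target-specific, present at
low frequency in European taurines, absent from European taurines — and,
within the absent set, found in Bovinae species / African-Chinese taurines /
Hanwoo only / indicine only.

Throughout, "frequency" means the alternative (non-reference) allele
frequency relative to the reference assembly; the published filter calls
this MAF but uses thresholds above 0.5, which only makes sense for the
derived (alt) allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import percent
from .panel_io import PanelConfig, SiteTable, autosome_filter

log = logging.getLogger(__name__)

#: non-target groups used by the Table-2 style decomposition
NON_TARGET_GROUPS = ("eu_taurine", "indicine", "bovinae_species",
                     "african_taurine", "chinese_taurine", "asian_taurine")


@dataclass(frozen=True)
class HighFreqFilterSpec:
    """Discovery filter: high in the target, low in every contrast breed."""

    target: str
    contrasts: tuple[str, ...]
    target_min_freq: float = 0.7
    contrast_max_freq: float = 0.1
    autosomes: tuple[str, ...] | None = None

    def __post_init__(self):
        if not 0 <= self.contrast_max_freq < self.target_min_freq <= 1:
            raise ValueError(
                "need 0 <= contrast_max_freq < target_min_freq <= 1")


def discover_high_freq(table: SiteTable, spec: HighFreqFilterSpec) -> SiteTable:
    """Sites with target alt freq >= threshold and every contrast <= threshold.

    Both boundaries are inclusive. Sites with undefined frequency in any of
    the named populations are skipped (counted in the log).
    """
    if spec.autosomes is not None:
        table = autosome_filter(table, spec.autosomes)
    f_target = table.freq(spec.target)
    f_contrast = np.column_stack([table.freq(c) for c in spec.contrasts])
    defined = np.isfinite(f_target) & np.all(np.isfinite(f_contrast), axis=1)
    n_undef = int((~defined).sum())
    if n_undef:
        log.info("discover_high_freq: skipped %d sites with undefined "
                 "frequencies", n_undef)
    keep = defined.copy()
    keep[defined] = (f_target[defined] >= spec.target_min_freq) & np.all(
        f_contrast[defined] <= spec.contrast_max_freq, axis=1)
    return table.subset(keep)


@dataclass
class ClassifiedAllele:
    """Per-site group membership flags and the derived category."""

    site_index: int
    present_in: dict[str, bool]      # group -> alt allele observed
    determined: dict[str, bool]      # group -> enough called alleles to judge absence
    eu_class: str                    # absent | low | other
    category: str                    # target_specific | low_freq_eu | absent_eu | other_eu
    subcategory: str | None          # bovinae | afr_chn_taurine | hanwoo_only | indicine_only
    in_indicine: bool
    is_missense: bool = False

    @property
    def target_specific(self) -> bool:
        return self.category == "target_specific"


def _group_arrays(table: SiteTable, panel: PanelConfig, group: str):
    pops = [p for p in panel.pops_in_group(group) if p in table.populations]
    if not pops:
        return None
    idx = [table.pop_index(p) for p in pops]
    alt = table.alt_counts[:, idx]
    called = table.called[:, idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    return alt.sum(axis=1), called.sum(axis=1), freq


def classify(table: SiteTable, panel: PanelConfig,
             presence_threshold: float = 0.25) -> list[ClassifiedAllele]:
    """Classify each (already discovered) allele by group membership.

    An allele is *present* in a group iff its alt count is >= 1 in any
    population of the group; *absent* iff the alt count is 0 **and** at
    least ``presence_threshold`` of the group's alleles were called (absence
    is never declared from missingness alone); *low frequency* iff the
    maximum population frequency in the group is in (0, 0.1).
    """
    groups = [g for g in NON_TARGET_GROUPS if panel.pops_in_group(g)]
    arr = {g: _group_arrays(table, panel, g) for g in groups}
    arr = {g: a for g, a in arr.items() if a is not None}
    totals = {g: (a[1].max() if a[1].size else 0) for g, a in arr.items()}

    out: list[ClassifiedAllele] = []
    n_undetermined = 0
    for i in range(table.n_sites):
        present, determined, maxfreq = {}, {}, {}
        for g, (alt_g, called_g, freq_g) in arr.items():
            present[g] = bool(alt_g[i] >= 1)
            determined[g] = bool(totals[g] > 0
                                 and called_g[i] >= presence_threshold * totals[g])
            fg = freq_g[i]
            maxfreq[g] = float(np.nanmax(fg)) if np.any(np.isfinite(fg)) else np.nan
            if not determined[g] and not present[g]:
                n_undetermined += 1

        eu_f = maxfreq.get("eu_taurine", np.nan)
        if present.get("eu_taurine", False):
            eu_class = "low" if (0 < eu_f < 0.1) else "other"
        elif determined.get("eu_taurine", True):
            eu_class = "absent"
        else:
            eu_class = "undetermined"

        absent_everywhere = all(
            (not present[g]) and determined.get(g, False) for g in arr)
        if absent_everywhere:
            category, sub = "target_specific", None
        elif eu_class == "low":
            category, sub = "low_freq_eu", None
        elif eu_class == "absent":
            category = "absent_eu"
            if present.get("bovinae_species", False):
                sub = "bovinae"
            elif present.get("african_taurine", False) or present.get(
                    "chinese_taurine", False):
                sub = "afr_chn_taurine"
            elif present.get("asian_taurine", False):
                sub = "hanwoo_only"
            else:
                sub = "indicine_only"
        else:
            category, sub = "other_eu", None

        out.append(ClassifiedAllele(
            site_index=i, present_in=present, determined=determined,
            eu_class=eu_class, category=category, subcategory=sub,
            in_indicine=present.get("indicine", False)))
    if n_undetermined:
        log.info("classify: %d group-flags undetermined for lack of called "
                 "genotypes", n_undetermined)
    return out


@dataclass
class ClassificationReport:
    """Category counts plus the derived shares of the absent-from-EU set."""

    counts: dict[str, int]
    percentages: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self):
        if not self.percentages:
            den = self.counts.get("absent_eu", 0)
            for key in ("found_in_indicine", "found_in_bovinae",
                        "indicine_only", "afr_chn_taurine", "hanwoo_only"):
                self.percentages[f"{key}_pct"] = percent(
                    self.counts.get(key, 0), den)


def report(classified: list[ClassifiedAllele]) -> ClassificationReport:
    """Tally the category decomposition and derived percentages."""
    if not classified:
        raise ValueError("empty classification")
    counts = {
        "total": len(classified),
        "target_specific": sum(c.category == "target_specific" for c in classified),
        "low_freq_eu": sum(c.category == "low_freq_eu" for c in classified),
        "absent_eu": sum(c.category == "absent_eu" for c in classified),
        "found_in_indicine": sum(
            c.category == "absent_eu" and c.in_indicine for c in classified),
        "found_in_bovinae": sum(c.subcategory == "bovinae" for c in classified),
        "afr_chn_taurine": sum(
            c.subcategory == "afr_chn_taurine" for c in classified),
        "hanwoo_only": sum(c.subcategory == "hanwoo_only" for c in classified),
        "indicine_only": sum(c.subcategory == "indicine_only" for c in classified),
    }
    return ClassificationReport(counts)


def report_from_counts(counts: dict[str, int]) -> ClassificationReport:
    """Build the report arithmetic directly from category counts."""
    return ClassificationReport(dict(counts))


# ---------------------------------------------------------------------------
# Cross-species conservation scoring

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def conservation_score(column: dict[str, str], ref_residue: str,
                       alt_residue: str) -> float:
    """Signed alignment-column score for a missense change.

    ``(count of species carrying the alt residue - count carrying the ref
    residue) / column depth``: positive means the alternative amino acid is
    the more common state across species, negative that the reference is.
    """
    if not column:
        raise ValueError("empty alignment column")
    for aa in (ref_residue, alt_residue, *column.values()):
        if aa not in _AA:
            raise ValueError(f"unknown residue letter: {aa!r}")
    vals = list(column.values())
    n_alt = sum(v == alt_residue for v in vals)
    n_ref = sum(v == ref_residue for v in vals)
    return (n_alt - n_ref) / len(vals)
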