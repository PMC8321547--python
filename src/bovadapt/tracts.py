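"""Local-ancestry tract algebra.

Consumes BED-like tract calls (e.g. RFMix output summarised per population)
and provides: carrier-fraction-weighted genome shares, SNP-tract overlap,
the shared-allele tract filtering re-analysis, gene-to-segment assignment at
a total-length overlap threshold, and a length-preserving permutation test
for interval overlap.

All coordinates are 0-based half-open. A tract row is (chrom, start, end,
label, carrier_frac) where carrier_frac is the share of haplotypes in the
population assigned that ancestry within the tract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import percent

TRACT_COLUMNS = ["chrom", "start", "end", "label", "carrier_frac"]


@dataclass(frozen=True)
class GenomeMask:
    """Chromosome lengths with optional excluded regions."""

    chrom_lengths: dict[str, int]
    excluded: tuple[tuple[str, int, int], ...] = ()

    @property
    def total_length(self) -> int:
        total = sum(self.chrom_lengths.values())
        for c, s, e in merge_intervals(self.excluded):
            total -= min(e, self.chrom_lengths[c]) - s
        return total


def merge_intervals(intervals) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent (chrom, start, end) intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(str(c), []).append((int(s), int(e)))
    out = []
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((c, cur_s, cur_e))
    return out


def validate_tracts(tracts: pd.DataFrame, mask: GenomeMask | None = None) -> None:
    if (tracts["end"] <= tracts["start"]).any():
        raise ValueError("tract with end <= start")
    for label, sub in tracts.groupby("label"):
        for chrom, ch in sub.groupby("chrom"):
            ivs = ch.sort_values("start")[["start", "end"]].to_numpy()
            if np.any(ivs[1:, 0] < ivs[:-1, 1]):
                raise ValueError(
                    f"overlapping tracts for label {label} on {chrom}")
    if mask is not None:
        for row in tracts.itertuples(index=False):
            if str(row.chrom) not in mask.chrom_lengths:
                raise ValueError(f"tract chromosome {row.chrom} not in mask")
            if row.end > mask.chrom_lengths[str(row.chrom)]:
                raise ValueError(f"tract beyond chromosome end on {row.chrom}")


def genome_fraction(tracts: pd.DataFrame, mask: GenomeMask, label: str) -> float:
    """Carrier-fraction-weighted share of the unmasked genome with ``label``."""
    if label not in set(tracts["label"].astype(str)):
        if len(tracts) and label not in tracts["label"].values:
            raise KeyError(f"unknown ancestry label: {label}")
    validate_tracts(tracts, mask)
    sub = tracts[tracts["label"] == label]
    weighted = ((sub["end"] - sub["start"]) * sub["carrier_frac"]).sum()
    return float(weighted) / mask.total_length


def snp_tract_overlap(table, tracts: pd.DataFrame, label: str
                      ) -> tuple[np.ndarray, dict]:
    """Per-site flag for overlap with tracts of one ancestry label.

    A site at 0-based position p overlaps a tract iff start <= p < end
    (half-open, inclusive left). Returns the boolean vector plus a summary
    with the overlapping count and percentage (half-up, 2 decimals).
    """
    sub = tracts[tracts["label"] == label]
    pos0 = table.pos0()
    chroms = table.sites["chrom"].astype(str).to_numpy()
    flag = np.zeros(table.n_sites, dtype=bool)
    for chrom, ch in sub.groupby("chrom"):
        ivs = ch.sort_values("start")[["start", "end"]].to_numpy(dtype=np.int64)
        on = chroms == str(chrom)
        if not on.any() or not len(ivs):
            continue
        p = pos0[on]
        k = np.searchsorted(ivs[:, 0], p, side="right") - 1
        hit = (k >= 0) & (p < ivs[np.clip(k, 0, None), 1])
        flag[np.flatnonzero(on)] = hit
    summary = {
        "n_sites": int(table.n_sites),
        "n_overlapping": int(flag.sum()),
        "pct_overlapping": percent(int(flag.sum()), table.n_sites),
    }
    return flag, summary


def overlap_summary_from_counts(n_overlapping: int, n_sites: int) -> dict:
    """Summary arithmetic from plain counts (same rounding as the scan)."""
    return {"n_sites": n_sites, "n_overlapping": n_overlapping,
            "pct_overlapping": percent(n_overlapping, n_sites)}


def _sites_in_tract(allele_positions: dict[str, np.ndarray],
                    chrom: str, start: int, end: int) -> int:
    pos = allele_positions.get(str(chrom))
    if pos is None or not len(pos):
        return 0
    return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))


def _index_positions(sites_df: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for chrom, ch in sites_df.groupby("chrom"):
        out[str(chrom)] = np.sort(ch["pos0"].to_numpy(dtype=np.int64))
    return out


def filter_tracts(tracts: pd.DataFrame,
                  allele_sets: dict[str, pd.DataFrame]
                  ) -> tuple[pd.DataFrame, dict]:
    """Shared-allele filtering of putative donor tracts.

    ``allele_sets`` maps set names to site tables (DataFrames with columns
    ``chrom`` and ``pos0``); the key ``indicine_specific`` is the rescue
    set, every other key is a shared set. A tract intersecting at least one
    shared-set allele is removed unless it also contains at least one
    indicine-specific allele; tracts intersecting no classified allele are
    retained (no evidence against them).
    """
    shared_keys = [k for k in allele_sets if k != "indicine_specific"]
    shared_idx = {k: _index_positions(allele_sets[k]) for k in shared_keys}
    rescue_idx = (_index_positions(allele_sets["indicine_specific"])
                  if "indicine_specific" in allele_sets else {})

    keep = np.ones(len(tracts), dtype=bool)
    ledger = {"input": int(len(tracts)), "removed": 0, "retained": 0,
              "rescued": 0, "removed_by": {k: 0 for k in shared_keys}}
    for i, row in enumerate(tracts.itertuples(index=False)):
        hits = [k for k in shared_keys
                if _sites_in_tract(shared_idx[k], row.chrom, row.start, row.end)]
        if not hits:
            continue
        if _sites_in_tract(rescue_idx, row.chrom, row.start, row.end):
            ledger["rescued"] += 1
            continue
        keep[i] = False
        for k in hits:
            ledger["removed_by"][k] += 1
    ledger["removed"] = int((~keep).sum())
    ledger["retained"] = int(keep.sum())
    return tracts[keep].reset_index(drop=True), ledger


def assign_genes(genes, tracts: pd.DataFrame,
                 min_overlap_fraction: float = 0.6) -> dict[str, list[str]]:
    """Assign genes to ancestry classes by total-length overlap.

    A gene is assigned to a class iff the summed overlap of its span with
    that class's (merged) tracts is >= ``min_overlap_fraction`` x gene
    length (inclusive boundary). A gene can satisfy several classes; genes
    meeting no threshold are absent from the result.
    """
    merged = {label: merge_intervals(sub[["chrom", "start", "end"]].itertuples(
        index=False)) for label, sub in tracts.groupby("label")}
    result: dict[str, list[str]] = {}
    for g in genes:
        if g.length <= 0:
            raise ValueError(f"zero-length gene {g.gene_id}")
        classes = []
        for label, ivs in merged.items():
            ov = sum(max(0, min(e, g.end) - max(s, g.start))
                     for c, s, e in ivs if c == g.chrom)
            if ov >= min_overlap_fraction * g.length:
                classes.append(str(label))
        if classes:
            result[g.gene_id] = sorted(classes)
    return result


def overlap_permutation_test(query_intervals, annotation_intervals,
                             mask: GenomeMask, n_perm: int = 10000,
                             seed: int = 0) -> dict:
    """Length-preserving permutation test of interval overlap.

    Query intervals are placed uniformly at random within their own
    chromosome (lengths preserved); the statistic is total overlapping base
    pairs with the annotation. p uses the add-one estimator
    ``(1 + #{null >= observed}) / (n_perm + 1)``; fold is observed over the
    null mean.
    """
    rng = np.random.default_rng(seed)
    ann = merge_intervals(annotation_intervals)
    query = [(str(c), int(s), int(e)) for c, s, e in query_intervals]
    for c, s, e in query:
        if e - s > mask.chrom_lengths[c]:
            raise ValueError("query interval longer than its chromosome")

    # prefix sums of annotation coverage per chromosome
    cov: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in mask.chrom_lengths:
        ivs = np.array([(s, e) for cc, s, e in ann if cc == c],
                       dtype=np.int64).reshape(-1, 2)
        edges = np.concatenate([ivs[:, 0], ivs[:, 1]])
        order = np.argsort(edges, kind="stable")
        # cumulative covered bp up to each breakpoint
        pts = np.sort(edges)
        lens = np.concatenate([[0], np.cumsum(
            np.diff(pts) * _coverage_between(ivs, pts))]) if len(pts) else np.array([0])
        cov[c] = (pts, lens)

    def overlap_bp(c, s, e):
        pts, lens = cov[c]
        if not len(pts):
            return 0
        return _covered(pts, lens, e) - _covered(pts, lens, s)

    observed = sum(overlap_bp(c, s, e) for c, s, e in query)
    lengths = np.array([e - s for c, s, e in query])
    chroms = [c for c, s, e in query]
    null = np.empty(n_perm)
    for k in range(n_perm):
        tot = 0
        for (c, L) in zip(chroms, lengths):
            start = rng.integers(0, mask.chrom_lengths[c] - L + 1)
            tot += overlap_bp(c, start, start + L)
        null[k] = tot
    p = (1 + np.sum(null >= observed)) / (n_perm + 1)
    mean_null = float(null.mean())
    fold = observed / mean_null if mean_null > 0 else np.inf
    return {"observed": int(observed), "null_mean": mean_null,
            "fold": float(fold), "p": float(p), "n_perm": int(n_perm)}


def _coverage_between(ivs: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """0/1 coverage of each inter-breakpoint segment by merged intervals."""
    mids = (pts[:-1] + pts[1:]) / 2.0
    covered = np.zeros(len(mids), dtype=np.int64)
    for s, e in ivs:
        covered |= (mids >= s) & (mids < e)
    return covered


def _covered(pts: np.ndarray, lens: np.ndarray, x: int) -> int:
    """Covered bp in [0, x) given breakpoint prefix sums."""
    i = np.searchsorted(pts, x, "right") - 1
    if i < 0:
        return 0
    if i >= len(pts) - 1:
        return int(lens[-1])
    # x falls inside segment [pts[i], pts[i+1]); it is covered iff the
    # segment is covered, which the prefix-sum slope encodes
    seg = (lens[i + 1] - lens[i]) / (pts[i + 1] - pts[i])
    return int(lens[i] + seg * (x - pts[i]))
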