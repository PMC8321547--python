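import numpy as np
import pandas as pd
import pytest

from bovadapt.panel_io import PanelConfig, SiteTable


def make_table(freqs: dict[str, list[float]], two_n: int = 40,
               counts: dict[str, list[int]] | None = None,
               chrom: str = "1") -> SiteTable:
    """SiteTable with exact per-population frequencies (counts = freq*2N)."""
    pops = sorted(freqs)
    n_sites = len(next(iter(freqs.values())))
    if counts is None:
        counts = {p: [int(round(f * two_n)) for f in freqs[p]] for p in pops}
    alt = np.column_stack([counts[p] for p in pops]).astype(np.int64)
    called = np.full_like(alt, two_n)
    sites = pd.DataFrame({
        "chrom": [chrom] * n_sites,
        "pos": np.arange(1, n_sites + 1) * 100,
        "ref": ["A"] * n_sites,
        "alt": ["G"] * n_sites,
    })
    return SiteTable(sites=sites, populations=pops, alt_counts=alt,
                     called=called,
                     latent_freq=np.column_stack([freqs[p] for p in pops]))


@pytest.fixture
def six_group_panel() -> PanelConfig:
    """One population per reference group plus the target breed."""
    pops = {
        "yakut": {"target"},
        "holstein": {"eu_taurine"},
        "hanwoo": {"asian_taurine"},
        "ndama": {"african_taurine"},
        "luxi": {"chinese_taurine"},
        "brahman": {"indicine"},
        "yak": {"bovinae_species"},
    }
    s2p = {f"{p}_{i}": p for p in pops for i in range(2)}
    return PanelConfig(s2p, {p: frozenset(t) for p, t in pops.items()})
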