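import numpy as np
import pandas as pd
import pytest

from pfactor.simulate import GenotypePanel


def make_panel(dosages, bps=None, refs=None, alts=None, chrom=None) -> GenotypePanel:
    """Hand-built toy genotype panel for PRS tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    bps = list(bps) if bps is not None else [10_000 * (j + 1) for j in range(m)]
    refs = list(refs) if refs is not None else ["A"] * m
    alts = list(alts) if alts is not None else ["G"] * m
    chrom = list(chrom) if chrom is not None else [1] * m
    variants = pd.DataFrame(
        {
            "SNP": [f"s{j}" for j in range(m)],
            "CHR": chrom,
            "BP": bps,
            "REF": refs,
            "ALT": alts,
            "AAF": dosages.mean(axis=0) / 2.0,
            "block": [0] * m,
            "block_r": [np.nan] * m,
        }
    )
    return GenotypePanel(
        person_ids=np.array([f"P{i:04d}" for i in range(n)]),
        variants=variants,
        dosages=dosages,
    )


def make_sumstats(panel, beta, p, se=None, a1=None, a2=None) -> pd.DataFrame:
    """Summary statistics aligned to a toy panel (effect allele = ALT unless
    overridden)."""
    v = panel.variants
    return pd.DataFrame(
        {
            "SNP": v["SNP"],
            "CHR": v["CHR"],
            "BP": v["BP"],
            "A1": a1 if a1 is not None else v["ALT"],
            "A2": a2 if a2 is not None else v["REF"],
            "BETA": beta,
            "SE": se if se is not None else [0.01] * len(v),
            "P": p,
        }
    )


@pytest.fixture
def toy_ld_panel():
    """Three SNPs: B tags A (r2 ~ 0.5), C nearly independent of A."""
    rng = np.random.default_rng(5)
    a = rng.standard_normal(2000)
    b = np.sqrt(0.5) * a + np.sqrt(0.5) * rng.standard_normal(2000)
    c = np.sqrt(0.05) * a + np.sqrt(0.95) * rng.standard_normal(2000)
    dos = np.clip(np.column_stack([a, b, c]) + 1.0, 0.0, 2.0)
    return make_panel(dos, bps=[100_000, 110_000, 120_000])
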