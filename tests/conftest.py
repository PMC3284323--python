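import numpy as np
import pandas as pd
import pytest

from ccqtl import simulate
from ccqtl.core import DEFAULT_FOUNDERS, FounderPanel, QtlSpec


@pytest.fixture(scope="session")
def small_panel():
    """600-SNP single-chromosome founder panel (default divergence)."""
    return simulate.simulate_founders(
        600, chrom_lengths={"1": 50_000_000}, seed=11
    )


@pytest.fixture(scope="session")
def population(small_panel):
    """30 mosaic lines with a planted 3-founder QTL and exact dosages."""
    gmap = simulate.GeneticMap(chrom_lengths=dict(small_panel.chrom_lengths))
    mosaics = simulate.simulate_panel_lines(small_panel, 30, gmap, seed=12)
    qtl = QtlSpec(
        chrom="1",
        pos=25_000_000,
        functional_group=frozenset({"C57BL6J", "NODShiLtJ", "NZOHlLtJ"}),
        effect_size=8.0,
        dominance=0.5,
        h2_target=0.5,
    )
    phenos = simulate.assign_phenotypes(
        small_panel, mosaics, [qtl], seed=13, trait="MCV"
    )
    iset, X = simulate.true_dosages(small_panel, mosaics)
    return {
        "panel": small_panel,
        "mosaics": mosaics,
        "qtl": qtl,
        "phenos": phenos,
        "intervals": iset,
        "dosages": X,
        "line_ids": [m.line_id for m in mosaics],
    }


def make_panel(genotypes, spacing=1000, chrom="1", names=DEFAULT_FOUNDERS):
    """Hand-built panel from an (8, M) genotype array."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    m = genotypes.shape[1]
    pos = (np.arange(m) + 1) * spacing
    return FounderPanel(
        founder_names=list(names),
        chrom=np.array([chrom] * m, dtype=object),
        pos=pos,
        genotypes=genotypes,
        chrom_lengths={chrom: int(pos[-1])},
    )
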