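from pathlib import Path

import numpy as np
import pytest

from coresnp.containers import GenotypeMatrix
from coresnp.synthetic_data import PanelConfig, simulate_panel

DATA = Path(__file__).parent / "data"


def make_matrix(genotypes, chrom=None, pos=None, ref=None, alt=None, depth=None):
    """Small hand-built panel helper."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    return GenotypeMatrix(
        genotypes=g,
        chrom=np.array(chrom if chrom is not None else ["Chr01"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1) * 1000),
        ref=np.array(ref if ref is not None else ["A"] * m, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * m, dtype=object),
        depth=None if depth is None else np.asarray(depth),
    )


@pytest.fixture(scope="session")
def structured_panel():
    """Three-subpopulation panel with clear structure, no missing data."""
    matrix, truth = simulate_panel(PanelConfig(
        n_accessions=150, n_loci=1200, n_subpops=3, fst=0.3,
        missing_rate=0.0, maf_range=(0.1, 0.5), seed=13,
    ))
    return matrix, truth


@pytest.fixture(scope="session")
def clean_panel():
    """Unstructured panel without missing calls, for statistics checks."""
    matrix, truth = simulate_panel(PanelConfig(
        n_accessions=80, n_loci=400, n_subpops=1, fst=0.0,
        missing_rate=0.0, maf_range=(0.05, 0.5), seed=5,
    ))
    return matrix, truth
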