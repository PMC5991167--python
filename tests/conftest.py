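import numpy as np
import pandas as pd
import pytest

from rilmap.containers import SNP
from rilmap.observe import sample_marker_panel
from rilmap.simulate import GenomeModel, advance_ssd, truth_genotype_matrix


@pytest.fixture(scope="session")
def genome7():
    return GenomeModel.ryegrass_default()


@pytest.fixture(scope="session")
def cohort41(genome7):
    """The study-scale cohort: 41 single-seed-descent lines at F6."""
    return advance_ssd(41, 6, genome7, rng_seed=11)


@pytest.fixture(scope="session")
def panel_dense(genome7):
    """A dense SNP+PAV panel at the framework-map marker scale."""
    return sample_marker_panel(genome7, n_snp=350, n_pav=60, rng_seed=7)


@pytest.fixture(scope="session")
def truth41(cohort41, panel_dense):
    """Error-free genotype calls for the F6 cohort at the SNP panel."""
    return truth_genotype_matrix(cohort41.lines(6), panel_dense.subset(SNP))


def make_matrix(calls, chrom=None, pos=None, depths=None, individuals=None):
    """Small hand-built genotype matrices for rule-level tests."""
    from rilmap.containers import GenotypeMatrix

    calls = np.asarray(calls, dtype="<U1")
    n_ind, n_mark = calls.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(n_mark)],
            "chromosome": chrom if chrom is not None else ["c1"] * n_mark,
            "pos_cM": pos if pos is not None else np.arange(n_mark, dtype=float),
            "kind": SNP,
        }
    )
    return GenotypeMatrix(
        individuals=individuals or [f"i{k}" for k in range(n_ind)],
        markers=markers,
        calls=calls,
        depths=depths,
    )
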