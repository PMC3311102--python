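import numpy as np
import pytest

from haplomosaic.compatible_intervals import CompatibleInterval
from haplomosaic.genotype_model import (
    GenomicInterval,
    GenotypeMatrix,
    Marker,
)


def make_matrix(codes, positions=None, chrom="chr1", strains=None):
    """GenotypeMatrix from a (strains x markers) code array.

    Positions default to 100, 200, 300, ...; allele labels to (A, G).
    """
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    if positions is None:
        positions = [100 * (j + 1) for j in range(m)]
    if strains is None:
        strains = [f"s{i}" for i in range(n)]
    markers = [Marker(chrom=chrom, pos=int(p), index=j)
               for j, p in enumerate(positions)]
    return GenotypeMatrix(strains=list(strains), markers=markers, calls=codes,
                          allele_labels=[("A", "G")] * m)


def make_interval(matrix, start_idx, end_idx, ordinal=0):
    positions = matrix.positions()
    return CompatibleInterval(
        bounds=GenomicInterval(
            chrom=matrix.markers[0].chrom,
            start_pos=int(positions[start_idx]),
            end_pos=int(positions[end_idx]),
            start_idx=start_idx, end_idx=end_idx),
        ordinal=ordinal)


@pytest.fixture
def mk_matrix():
    return make_matrix


@pytest.fixture
def mk_interval():
    return make_interval


def random_matrix(rng, n_strains, n_markers, p_het=0.0, p_missing=0.0):
    codes = rng.integers(0, 2, size=(n_strains, n_markers)).astype(np.int8)
    if p_het:
        codes[rng.random(codes.shape) < p_het] = 2
    if p_missing:
        codes[rng.random(codes.shape) < p_missing] = -1
    return make_matrix(codes)
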