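import numpy as np
import pytest

from primir import Genome, GeneratorParams, TagCluster


STAGES6 = ("st01", "st02", "st03", "st04", "st05", "st06")


def make_tc(positions, pooled_tpm, strand="+", chrom="chr1",
            stages=("s1", "s2"), initiator=None, tc_id="TC000001",
            stage_matrix=None):
    """Build a TagCluster directly from member positions and tpm."""
    positions = np.asarray(positions, dtype=np.int64)
    order = np.argsort(positions)
    positions = positions[order]
    if stage_matrix is not None:
        mat = np.asarray(stage_matrix, dtype=float)[order]
    else:
        pooled = np.asarray(pooled_tpm, dtype=float)[order]
        mat = np.zeros((positions.size, len(stages)))
        mat[:, 0] = pooled
    return TagCluster(chrom, strand, positions, mat, tuple(stages),
                      initiator_class=initiator, tc_id=tc_id)


@pytest.fixture
def flat_genome():
    """Two small chromosomes of known sequence for initiator/motif tests."""
    return Genome({
        "chr1": "ACGT" * 250,           # 1 kb
        "chr2": "A" * 400 + "G" * 200 + "A" * 400,
    })


@pytest.fixture
def small_params():
    """Desk-scale generator conditions used across property tests."""
    return GeneratorParams(
        n_premirnas=6, n_unexpressed=0, frac_intragenic=0.0, n_stages=6,
        n_maternal_stages=2, promoter_dist_range=(200, 20_000),
        genome_size=600_000, n_chroms=2, n_filler=10,
        filler_mean_tags=500_000.0, frac_cgi=0.3,
        frac_transcript_support=1.0, frac_h3k4me3_only=0.0, frac_sharp=0.5,
    )
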