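import numpy as np
import pytest

from vsinorm import CountMatrix, McmcConfig, SyntheticConfig, simulate_pair


@pytest.fixture
def quick_mcmc():
    """Short MCMC protocol for unit tests: enough for point estimates."""
    return McmcConfig(draws=600, burn_in=200, seed=1)


@pytest.fixture
def reduced_mcmc():
    """The reduced protocol used for recovery checks."""
    return McmcConfig(draws=2000, burn_in=500, seed=1)


@pytest.fixture
def nb_pair():
    """A standard synthetic pair: 1000 regions, truth -1.5, dispersion 10."""
    return simulate_pair(
        SyntheticConfig(n_regions=1000, true_log2_factor=-1.5, dispersion=10, seed=7)
    )


@pytest.fixture
def identical_pair():
    """Two samples with literally identical counts (log-ratio forced to 0)."""
    base = simulate_pair(SyntheticConfig(n_regions=1000, dispersion=10, seed=3))
    row = base.matrix.row("query")
    return CountMatrix(["a", "b"], list(base.matrix.region_ids), np.vstack([row, row]))


def write_toy_gtf(path, genes):
    """Minimal GTF: one transcript + one exon per (gene_id, chrom, start, end, strand).

    Coordinates are given 0-based half-open and converted to GTF's 1-based
    inclusive on write.
    """
    with open(path, "w") as fh:
        for gid, chrom, start, end, strand in genes:
            attrs = f'gene_id "{gid}"; transcript_id "{gid}.1";'
            for feature in ("transcript", "exon"):
                fh.write(
                    f"{chrom}\ttoy\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
                )
    return path


def make_bam(path, reads, chrom_lengths):
    """Build a sorted, indexed BAM from (name, chrom, pos, is_reverse, length) tuples."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    }
    refs = list(chrom_lengths)
    unsorted = str(path) + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
        for name, chrom, pos, is_reverse, length in reads:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = "A" * length
            a.reference_id = refs.index(chrom)
            a.reference_start = pos
            a.cigarstring = f"{length}M"
            a.mapping_quality = 60
            a.flag = 16 if is_reverse else 0
            out.write(a)
    pysam.sort("-o", str(path), unsorted)
    pysam.index(str(path))
    return path
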