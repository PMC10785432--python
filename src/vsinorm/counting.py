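"""Read counting over invariant regions from coordinate-sorted BAM files.

Run-on assays localize the RNA polymerase position, so a read is assigned to
a region by its 5' end (a single genomic position): the alignment start for
forward-strand reads, the last aligned base for reverse-strand reads.  Each
read is counted at most once per region.  Full-overlap counting is available
behind a flag for non-run-on data.
"""

from __future__ import annotations

import logging

import numpy as np
import pysam

from .countmatrix import CountMatrix
from .regions import InvariantRegion

__all__ = ["count_reads_in_regions", "count_matrix_from_bams"]

logger = logging.getLogger(__name__)


def _five_prime(read: "pysam.AlignedSegment") -> int:
    if read.is_reverse:
        return read.reference_end - 1
    return read.reference_start


def _strand_ok(read: "pysam.AlignedSegment", region_strand: str, strandedness: str) -> bool:
    if strandedness == "unstranded":
        return True
    read_strand = "-" if read.is_reverse else "+"
    if strandedness == "same":
        return read_strand == region_strand
    if strandedness == "opposite":
        return read_strand != region_strand
    raise ValueError(f"strandedness must be same/opposite/unstranded, got {strandedness!r}")


def count_reads_in_regions(
    bam_path,
    regions: list[InvariantRegion],
    strandedness: str = "unstranded",
    full_overlap: bool = False,
) -> np.ndarray:
    """Per-region read counts from an indexed BAM.

    A read counts for a region when its 5' end lies in [start, end) (or,
    with ``full_overlap=True``, when the whole alignment does) and its
    strand is compatible under ``strandedness``.  Regions on chromosomes
    absent from the BAM get count 0 with a warning.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        valid = set(bam.references)
        for i, region in enumerate(regions):
            if region.chrom not in valid:
                logger.warning("chromosome %s not in BAM header; count set to 0", region.chrom)
                continue
            seen = set()
            for read in bam.fetch(region.chrom, max(region.start - 1000, 0), region.end + 1000):
                if read.is_unmapped or read.query_name in seen:
                    continue
                if not _strand_ok(read, region.strand, strandedness):
                    continue
                if full_overlap:
                    hit = read.reference_start >= region.start and read.reference_end <= region.end
                else:
                    hit = region.start <= _five_prime(read) < region.end
                if hit:
                    seen.add(read.query_name)
                    counts[i] += 1
    return counts


def count_matrix_from_bams(
    bam_paths: dict[str, str],
    regions: list[InvariantRegion],
    strandedness: str = "unstranded",
) -> CountMatrix:
    """Counts matrix over regions for several samples (sample_id -> BAM path)."""
    rows = [
        count_reads_in_regions(path, regions, strandedness)
        for path in bam_paths.values()
    ]
    return CountMatrix(
        sample_ids=list(bam_paths.keys()),
        region_ids=[r.gene_id for r in regions],
        counts=np.vstack(rows),
    )
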