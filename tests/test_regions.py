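import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsinorm import (
    GeneModel,
    length_threshold,
    select_invariant_regions,
    select_max_isoform,
    spike_in_coverage,
)
from vsinorm.regions import read_annotation_bed, read_annotation_gtf, write_regions_bed


@pytest.mark.parametrize(
    "rate,time,expected",
    [(3, 60, 180_000), (2, 10, 20_000), (3, 60.5, 181_500)],
)
def test_length_threshold(rate, time, expected):
    assert length_threshold(rate, time) == expected


@pytest.mark.parametrize("rate,time", [(0, 60), (3, 0), (-1, 60)])
def test_length_threshold_domain(rate, time):
    with pytest.raises(ValueError):
        length_threshold(rate, time)


def _tx(tid, count, length, gid="g1"):
    return GeneModel(gid, tid, "chr1", 1000, 1000 + length, "+", total_count=count)


class TestMaxIsoform:
    def test_highest_count_wins(self):
        best = select_max_isoform([_tx("t1", 10, 5000), _tx("t2", 50, 2000), _tx("t3", 3, 9000)])
        assert best.transcript_id == "t2"

    def test_count_tie_longer_wins(self):
        best = select_max_isoform([_tx("t1", 50, 2000), _tx("t2", 50, 5000)])
        assert best.transcript_id == "t2"

    def test_full_tie_lexicographic(self):
        best = select_max_isoform([_tx("tB", 50, 2000), _tx("tA", 50, 2000)])
        assert best.transcript_id == "tA"

    def test_single_transcript(self):
        only = _tx("t1", 0, 100)
        assert select_max_isoform([only]) is only

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_max_isoform([])

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValueError, match="multiple genes"):
            select_max_isoform([_tx("t1", 1, 100, "g1"), _tx("t2", 1, 100, "g2")])


class TestInvariantRegions:
    def test_plus_strand_arithmetic(self):
        gene = GeneModel("g", "t", "chr1", 0, 200_000, "+")
        (region,) = select_invariant_regions([gene], 180_000, 500, 1000)
        assert (region.start, region.end) == (180_000, 199_500)

    def test_minus_strand_mirror(self):
        gene = GeneModel("g", "t", "chr1", 0, 200_000, "-")
        (region,) = select_invariant_regions([gene], 180_000, 500, 1000)
        assert (region.start, region.end) == (500, 20_000)

    def test_short_gene_dropped(self):
        gene = GeneModel("g", "t", "chr1", 0, 180_400, "+")
        assert select_invariant_regions([gene], 180_000, 500, 1000) == []

    @settings(deadline=None, max_examples=100)
    @given(
        start=st.integers(min_value=0, max_value=10**6),
        length=st.integers(min_value=1000, max_value=10**6),
        threshold=st.integers(min_value=1, max_value=500_000),
        exclusion=st.integers(min_value=0, max_value=5000),
        strand=st.sampled_from("+-"),
    )
    def test_containment_and_strand_mirror(self, start, length, threshold, exclusion, strand):
        gene = GeneModel("g", "t", "chr1", start, start + length, strand)
        regions = select_invariant_regions([gene], threshold, exclusion, 1000)
        mirrored = GeneModel("g", "t", "chr1", start, start + length,
                             "-" if strand == "+" else "+")
        mirror_regions = select_invariant_regions([mirrored], threshold, exclusion, 1000)
        assert len(regions) == len(mirror_regions) <= 1
        for r in regions:
            assert gene.start <= r.start < r.end <= gene.end
            assert r.length >= 1000
        if regions:
            # reflecting about the gene midpoint maps the region onto its mirror
            (r,), (m,) = regions, mirror_regions
            assert gene.start + gene.end - r.end == m.start
            assert gene.start + gene.end - r.start == m.end

    def test_threshold_monotonicity(self):
        genes = [
            GeneModel(f"g{i}", f"t{i}", "chr1", 0, end, "+")
            for i, end in enumerate((50_000, 150_000, 250_000, 400_000))
        ]
        counts = [
            len(select_invariant_regions(genes, thr, 500, 1000))
            for thr in (10_000, 100_000, 200_000, 390_000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_output_sorted(self):
        genes = [
            GeneModel("g2", "t2", "chr2", 0, 300_000, "+"),
            GeneModel("g1", "t1", "chr1", 50_000, 350_000, "+"),
            GeneModel("g0", "t0", "chr1", 0, 300_000, "+"),
        ]
        regions = select_invariant_regions(genes, 180_000, 500, 1000)
        keys = [(r.chrom, r.start) for r in regions]
        assert keys == sorted(keys)


class TestSpikeInCoverage:
    def test_boundary_is_strict(self):
        depth = spike_in_coverage(300_000_000, 30_000_000)
        assert depth.coverage == 10.0
        assert not depth.passes_threshold

    def test_shallow_sample_fails(self):
        depth = spike_in_coverage(21_000_000, 30_000_000)
        assert depth.coverage == pytest.approx(0.7)
        assert not depth.passes_threshold

    def test_zero_bases(self):
        depth = spike_in_coverage(0)
        assert depth.coverage == 0.0 and not depth.passes_threshold

    def test_deep_sample_passes(self):
        assert spike_in_coverage(600_000_000, 30_000_000).passes_threshold

    def test_bad_length(self):
        with pytest.raises(ValueError):
            spike_in_coverage(100, 0)


def test_gtf_reader_converts_coordinates(tmp_path):
    from .conftest import write_toy_gtf

    path = write_toy_gtf(tmp_path / "toy.gtf", [("gA", "chr1", 100, 5000, "+")])
    (model,) = read_annotation_gtf(path)
    assert (model.start, model.end) == (100, 5000)
    assert model.gene_id == "gA" and model.transcript_id == "gA.1"


def test_bed_roundtrip(tmp_path):
    gene = GeneModel("g", "t", "chr1", 0, 200_000, "+")
    (region,) = select_invariant_regions([gene], 180_000, 500, 1000)
    bed = tmp_path / "regions.bed"
    write_regions_bed([region], bed)
    assert bed.read_text() == "chr1\t180000\t199500\tg\t0\t+\n"
    models = read_annotation_bed(bed)
    assert models[0].start == 180_000 and models[0].end == 199_500
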