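import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_gene, make_transcript
from isoapa.genome import (
    AnnotationParseError,
    GenomicInterval,
    extract_introns,
    extract_sequence,
    parse_annotation,
    read_bed12,
    read_end_sites,
    reverse_complement,
    write_bed12,
    write_gtf,
)

GTF_ONE_GENE = (
    'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
)


class TestGenomicInterval:
    def test_rejects_inverted(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_length(self):
        assert GenomicInterval("chr1", 5, 12).length == 7


class TestParseAnnotation:
    def test_one_based_conversion(self):
        genes = parse_annotation(GTF_ONE_GENE)
        assert len(genes) == 1
        t = genes[0].transcripts[0]
        assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]
        introns = extract_introns(t)
        assert [(i.start, i.end) for i in introns] == [(200, 300)]

    def test_two_transcripts_one_gene(self):
        text = GTF_ONE_GENE + (
            'chr1\tx\texon\t101\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t2";\n'
        )
        genes = parse_annotation(text)
        assert len(genes) == 1
        assert len(genes[0].transcripts) == 2
        assert (genes[0].span.start, genes[0].span.end) == (100, 500)

    def test_gff3(self):
        text = (
            "chr1\tx\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tx\texon\t101\t200\t.\t+\t.\tParent=t1\n"
            "chr1\tx\texon\t301\t400\t.\t+\t.\tParent=t1\n"
        )
        genes = parse_annotation(text)
        assert genes[0].gene_id == "g1"
        assert [(e.start, e.end) for e in genes[0].transcripts[0].exons] == [
            (100, 200), (300, 400),
        ]

    def test_malformed_line_names_line_number(self):
        text = GTF_ONE_GENE + "chr1\tbroken\n"
        with pytest.raises(AnnotationParseError) as err:
            parse_annotation(text)
        assert err.value.line_number == 3

    def test_exon_without_transcript_skipped(self, caplog):
        text = GTF_ONE_GENE + 'chr1\tx\texon\t900\t950\t.\t+\t.\tgene_id "g9";\n'
        with caplog.at_level("WARNING"):
            genes = parse_annotation(text)
        assert len(genes) == 1
        assert "without transcript" in caplog.text

    def test_round_trip(self, tmp_path):
        genes = parse_annotation(GTF_ONE_GENE)
        path = tmp_path / "out.gtf"
        write_gtf(genes, path)
        again = parse_annotation(path)
        assert len(again) == len(genes)
        for g1, g2 in zip(genes, again):
            assert g1.gene_id == g2.gene_id
            for t1, t2 in zip(g1.transcripts, g2.transcripts):
                assert t1.transcript_id == t2.transcript_id
                assert [(e.start, e.end, e.strand) for e in t1.exons] == [
                    (e.start, e.end, e.strand) for e in t2.exons
                ]


class TestExtractIntrons:
    def test_basic(self):
        t = make_transcript("t", [(0, 100), (200, 300), (500, 600)])
        assert [(i.start, i.end) for i in extract_introns(t)] == [(100, 200), (300, 500)]

    def test_single_exon(self):
        t = make_transcript("t", [(0, 100)])
        assert extract_introns(t) == ()

    @given(
        st.integers(1, 7),
        st.lists(st.integers(1, 50), min_size=14, max_size=14),
        st.sampled_from("+-"),
    )
    def test_count_property(self, n_exons, lengths, strand):
        # intron count always equals exon count - 1
        coords = []
        pos = 0
        for i in range(n_exons):
            start = pos
            pos += lengths[2 * i]
            coords.append((start, pos))
            pos += lengths[2 * i + 1]
        t = make_transcript("t", coords, strand)
        assert len(extract_introns(t)) == n_exons - 1
        assert sum(e.length for e in t.exons) == t.exonic_length


class TestBed12:
    def test_round_trip(self, tmp_path):
        reads = [
            make_transcript("r1", [(100, 200), (300, 400)], "+"),
            make_transcript("r2", [(50, 80)], "-"),
        ]
        path = tmp_path / "reads.bed12"
        assert write_bed12(reads, path) == 2
        again = list(read_bed12(path))
        assert [r.transcript_id for r in again] == ["r1", "r2"]
        assert [(e.start, e.end) for e in again[0].exons] == [(100, 200), (300, 400)]
        assert again[1].strand == "-"


class TestReadEndSites:
    def test_plus_strand_convention(self):
        gene = make_gene("g1", {"t1": [(900, 2100)]})
        reads = [make_transcript("r", [(1000, 2000)])]
        records, n_un = read_end_sites(reads, [gene])
        assert records[0].position == 1999
        assert records[0].gene_id == "g1"
        assert n_un == 0

    def test_minus_strand_convention(self):
        gene = make_gene("g1", {"t1": [(900, 2100)]}, strand="-")
        reads = [make_transcript("r", [(1000, 2000)], strand="-")]
        records, _ = read_end_sites(reads, [gene])
        assert records[0].position == 1000

    def test_unknown_chrom_unassigned(self):
        gene = make_gene("g1", {"t1": [(0, 100)]})
        reads = [make_transcript("r", [(10, 50)], chrom="chrX")]
        records, n_un = read_end_sites(reads, [gene])
        assert n_un == 1
        assert records[0].gene_id is None

    def test_simulated_assignment_oracle(self, rng):
        # gene spans separated along the chromosome; containment oracle
        genes = []
        spans = []
        pos = 0
        for i in range(2):
            start, end = pos + 500, pos + 2500
            genes.append(make_gene(f"g{i}", {f"t{i}": [(start, end)]}))
            spans.append((start, end, f"g{i}"))
            pos = end + 3000
        reads = []
        expected = []
        for k in range(100):
            start, end, gid = spans[int(rng.integers(0, 2))]
            terminus = int(rng.integers(start + 100, end - 1))
            reads.append(make_transcript(f"r{k}", [(terminus - 99, terminus + 1)]))
            expected.append(gid)
        records, n_un = read_end_sites(reads, genes)
        assert n_un == 0
        assert [r.gene_id for r in records] == expected

    def test_ambiguous_overlap_closest_three_prime_end(self):
        # overlapping genes: the closer annotated 3' end wins
        g1 = make_gene("g1", {"t1": [(0, 1000)]})
        g2 = make_gene("g2", {"t2": [(500, 3000)]})
        reads = [make_transcript("r", [(800, 990)])]
        records, _ = read_end_sites(reads, [g1, g2])
        assert records[0].gene_id == "g1"  # |989-999| < |989-2999|

    def test_strand_mirror(self, rng):
        # mirror of a plus-strand layout gives reflected positions
        gene = make_gene("g", {"t": [(100, 400), (600, 900)]})
        reads = [make_transcript(f"r{i}", [(150, 880 - i)]) for i in range(5)]
        fwd, _ = read_end_sites(reads, [gene])
        L = 1000
        gene_m = make_gene(
            "g", {"t": [(L - 900, L - 600), (L - 400, L - 100)]}, strand="-"
        )
        reads_m = [
            make_transcript(f"r{i}", [(L - (880 - i), L - 150)], strand="-")
            for i in range(5)
        ]
        rev, _ = read_end_sites(reads_m, [gene_m])
        for f, r in zip(fwd, rev):
            assert r.position == L - 1 - f.position


class TestExtractSequence:
    def test_forward(self):
        genome = {"c": "ACGT"}
        assert extract_sequence(genome, GenomicInterval("c", 0, 4, "+")) == "ACGT"

    def test_palindrome_minus(self):
        genome = {"c": "ACGT"}
        assert extract_sequence(genome, GenomicInterval("c", 0, 4, "-")) == "ACGT"

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            extract_sequence({"c": "ACGT"}, GenomicInterval("c", 2, 10, "+"))

    def test_uppercases_softmask(self):
        genome = {"c": "acgtn"}
        assert extract_sequence(genome, GenomicInterval("c", 0, 5, "+")) == "ACGTN"

    def test_random_against_slice_oracle(self, rng, random_genome):
        seq = random_genome["chr1"]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(50):
            start = int(rng.integers(0, len(seq) - 100))
            end = start + int(rng.integers(1, 100))
            strand = "+" if rng.random() < 0.5 else "-"
            got = extract_sequence(random_genome, GenomicInterval("chr1", start, end, strand))
            expected = seq[start:end]
            if strand == "-":
                expected = "".join(comp[b] for b in reversed(expected))
            assert got == expected

    def test_reverse_complement(self):
        assert reverse_complement("AACGTT") == "AACGTT"
        assert reverse_complement("AAGN") == "NCTT"
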