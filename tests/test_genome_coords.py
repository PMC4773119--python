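"""Genome projection, merging and interaction classification."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, strategies as st

import duplexscan as ds
from duplexscan.duplex_align import DuplexAlignment
from duplexscan.formats_io import GenomicInterval
from duplexscan.premrna import TranscriptModel


def model_with_exons(exon_spans, strand="+", cds=None, biotype="protein_coding"):
    exons = tuple(GenomicInterval("chr1", s, e, strand) for s, e in exon_spans)
    return TranscriptModel("tx", "g", "chr1", strand, exons, cds=cds, biotype=biotype)


def random_exon_model(rng, strand):
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, 50))
    spans = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 300))
        spans.append((pos, pos + length))
        pos += length + int(rng.integers(50, 500))
    return model_with_exons(spans, strand=strand, biotype="noncoding")


def mature_alignment(target_iv, length=10_000):
    return DuplexAlignment(
        lnc_id="l", target_id="tx", lnc_interval=(0, target_iv[1] - target_iv[0]),
        target_interval=target_iv, score=120, columns=(), lnc_length=600,
        target_length=length, mode="mRNA",
    )


def premrna_alignment(target_iv, length=10_000):
    return DuplexAlignment(
        lnc_id="l", target_id="tx", lnc_interval=(0, target_iv[1] - target_iv[0]),
        target_interval=target_iv, score=120, columns=(), lnc_length=600,
        target_length=length, mode="pre-mRNA",
    )


class TestProjection:
    def test_plus_strand_exon_split(self):
        model = model_with_exons([(100, 200), (300, 400)], biotype="noncoding")
        blocks = ds.project_to_genome((50, 150), model)
        assert [(b.start, b.end) for b in blocks] == [(150, 200), (300, 350)]

    def test_minus_strand_arithmetic(self):
        model = model_with_exons([(100, 200)], strand="-", biotype="noncoding")
        blocks = ds.project_to_genome((0, 10), model)
        assert [(b.start, b.end) for b in blocks] == [(190, 200)]

    def test_interval_beyond_transcript_rejected(self):
        model = model_with_exons([(100, 200)], biotype="noncoding")
        with pytest.raises(ValueError, match="exceeds"):
            ds.project_to_genome((50, 150), model)

    def test_round_trip_on_random_exon_structures(self):
        rng = np.random.default_rng(7)
        for k in range(300):
            model = random_exon_model(rng, "+" if k % 2 else "-")
            n = model.exonic_length
            s = int(rng.integers(0, n - 1))
            e = int(rng.integers(s + 1, n + 1))
            blocks = ds.project_to_genome((s, e), model)
            assert sum(len(b) for b in blocks) == e - s
            assert ds.project_to_transcript(blocks, model) == (s, e)


class TestMergeRegions:
    def test_overlapping_merge(self):
        out = ds.merge_regions(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 15)]
        )
        assert [(v.start, v.end) for v in out] == [(0, 15)]

    def test_disjoint_unchanged_and_sorted(self):
        out = ds.merge_regions(
            [GenomicInterval("chr1", 10, 15), GenomicInterval("chr1", 0, 5)]
        )
        assert [(v.start, v.end) for v in out] == [(0, 5), (10, 15)]

    def test_strands_kept_separate(self):
        out = ds.merge_regions(
            [GenomicInterval("chr1", 0, 10, "+"), GenomicInterval("chr1", 5, 15, "-")]
        )
        assert len(out) == 2

    @given(
        st.lists(
            st.tuples(st.integers(0, 400), st.integers(1, 60)),
            min_size=1, max_size=30,
        )
    )
    def test_idempotent_and_sorted(self, raw):
        ivs = [GenomicInterval("chr1", s, s + l) for s, l in raw]
        once = ds.merge_regions(ivs)
        assert ds.merge_regions(once) == once
        assert all(a.end < b.start for a, b in zip(once, once[1:]))
        assert sum(len(v) for v in once) <= sum(len(v) for v in ivs)

    def test_matches_bedtools_merge(self, tmp_path):
        """Independent oracle: bedtools merge on the same intervals."""
        rng = np.random.default_rng(8)
        ivs = sorted(
            (
                GenomicInterval(
                    f"chr{int(rng.integers(1, 4))}",
                    int(s := rng.integers(0, 5000)),
                    int(s + rng.integers(1, 400)),
                )
                for _ in range(200)
            ),
            key=lambda v: (v.chrom, v.start),
        )
        bed = tmp_path / "in.bed"
        bed.write_text("".join(f"{v.chrom}\t{v.start}\t{v.end}\n" for v in ivs))
        out = subprocess.run(
            ["bedtools", "merge", "-i", str(bed)],
            capture_output=True, text=True, check=True,
        ).stdout
        expected = [
            (f[0], int(f[1]), int(f[2]))
            for f in (line.split("\t") for line in out.strip().splitlines())
        ]
        ours = [(v.chrom, v.start, v.end) for v in ds.merge_regions(ivs)]
        assert ours == expected


class TestClassifyRegion:
    # mature transcript of 800 nt with CDS at [80, 450)
    def cds_model(self, strand="+"):
        if strand == "+":
            return model_with_exons([(0, 800)], cds=(80, 450))
        return model_with_exons([(0, 800)], strand="-", cds=(350, 720))

    @pytest.mark.parametrize(
        "iv,expected",
        [
            ((500, 560), "UTR3"),
            ((0, 50), "UTR5"),
            ((100, 200), "CDS"),
            ((70, 120), "CDS_UTR"),   # straddles CDS start
            ((430, 470), "CDS_UTR"),  # straddles CDS end
        ],
    )
    def test_mature_containment_rules(self, iv, expected):
        assert ds.classify_region(mature_alignment(iv), self.cds_model()) == expected

    def test_noncoding_biotype_takes_precedence(self):
        model = model_with_exons([(0, 800)], biotype="noncoding")
        assert ds.classify_region(mature_alignment((100, 200)), model) == "noncoding"

    def test_coding_model_without_cds_rejected(self):
        model = model_with_exons([(0, 800)])
        with pytest.raises(ValueError, match="CDS"):
            ds.classify_region(mature_alignment((0, 10)), model)

    def test_partition_is_total_on_random_intervals(self):
        rng = np.random.default_rng(9)
        model = self.cds_model()
        for _ in range(200):
            s = int(rng.integers(0, 799))
            e = int(rng.integers(s + 1, 801))
            cls = ds.classify_region(mature_alignment((s, e)), model)
            assert cls in ("CDS", "UTR5", "UTR3", "CDS_UTR")

    def test_premrna_exonic_pieces_classified(self):
        # exons [0,200)+[800,1000); CDS genomic [80, 950); pre-mRNA len 1000
        model = model_with_exons([(0, 200), (800, 1000)], cds=(80, 950))
        # spans the junction: exonic pieces [150,200) mature + [200,250) mature
        aln = premrna_alignment((150, 850))
        assert ds.classify_region(aln, model) == "CDS"
        # intron-only hit sits between mature 200|200 inside the CDS
        assert ds.classify_region(premrna_alignment((250, 300)), model) == "CDS"


class TestCisTrans:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 100, 500, "+"), ("chr1", 300, 700, "-"), "cis"),
            (("chr1", 100, 500, "+"), ("chr1", 300, 700, "+"), "trans"),
            (("chr1", 100, 500, "+"), ("chr2", 300, 700, "-"), "trans"),
            (("chr1", 100, 300, "+"), ("chr1", 300, 700, "-"), "trans"),  # abutting
            (("chr1", 100, 301, "+"), ("chr1", 300, 700, "-"), "cis"),  # 1 bp
        ],
    )
    def test_definition(self, a, b, expected):
        assert ds.classify_cis_trans(GenomicInterval(*a), GenomicInterval(*b)) == expected


class TestInteractionRecord:
    def test_fixture_interactions_conserve_block_lengths(self, mrna_results):
        for inter in mrna_results["interactions"]:
            a = inter.alignment
            n_t = sum(1 for _, tc in a.columns if tc != "-")
            n_l = sum(1 for qc, _ in a.columns if qc != "-")
            assert sum(len(b) for b in inter.target_genomic) == n_t
            assert sum(len(b) for b in inter.lnc_genomic) == n_l

    def test_noncoding_iff_noncoding_biotype(self, mrna_results, fixture_bundle):
        biotypes = {m.transcript_id: m.biotype for m in fixture_bundle.models}
        for inter in mrna_results["interactions"]:
            is_nc = biotypes[inter.alignment.target_id] != "protein_coding"
            assert (inter.region_class == "noncoding") == is_nc
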