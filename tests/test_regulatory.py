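"""Geometric rule filters for the four regulatory mechanisms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import duplexscan as ds
from duplexscan.duplex_align import DuplexAlignment
from duplexscan.formats_io import GenomicInterval
from duplexscan.genome_coords import InteractionRecord
from duplexscan.premrna import TranscriptModel


def make_interaction(region, target_id="tx", region_class="CDS", mode="mRNA"):
    """An interaction whose merged genomic region is ``region`` exactly."""
    aln = DuplexAlignment(
        lnc_id="l", target_id=target_id, lnc_interval=(0, len(region)),
        target_interval=(0, len(region)), score=200, columns=(),
        lnc_length=600, target_length=2000, mode=mode,
    )
    return InteractionRecord(
        alignment=aln,
        lnc_genomic=(GenomicInterval("chrL", 0, len(region), "+"),),
        target_genomic=(region,),
        region_class=region_class,
        locality="trans",
    )


def single_exon_coding_model(target_id="tx", strand="+"):
    # 1000-nt transcript on chr1 [0,1000); CDS [100, 600) leaves a 400-nt 3' UTR
    cds = (100, 600) if strand == "+" else (400, 900)
    return TranscriptModel(
        target_id, "g", "chr1", strand,
        (GenomicInterval("chr1", 0, 1000, strand),), cds=cds,
    )


REGION = GenomicInterval("chr1", 100, 200, "+")


class TestSpliceMask:
    def models(self):
        # two-exon gene so the interaction's span covers a splice boundary
        return [
            TranscriptModel(
                "tx", "g", "chr1", "+",
                (
                    GenomicInterval("chr1", 50, 150, "+"),
                    GenomicInterval("chr1", 400, 600, "+"),
                ),
                biotype="noncoding",
            )
        ]

    @pytest.mark.parametrize(
        "site,kept",
        [
            (GenomicInterval("chr1", 120, 140, "+"), True),
            (GenomicInterval("chr1", 90, 140, "+"), False),  # partial
            (GenomicInterval("chr1", 120, 140, "-"), False),  # strand
        ],
    )
    def test_containment_and_strand_rules(self, site, kept):
        inter = make_interaction(REGION, mode="pre-mRNA")
        out = ds.splice_mask_candidates([inter], [site], self.models())
        assert bool(out) == kept

    def test_strandless_clip_rejected(self):
        inter = make_interaction(REGION, mode="pre-mRNA")
        bad = GenomicInterval("chr1", 120, 140, "+")
        object.__setattr__(bad, "strand", ".")
        with pytest.raises(ValueError, match="strand"):
            ds.splice_mask_candidates([inter], [bad], self.models())

    def test_spanned_site_class_attached(self):
        inter = make_interaction(REGION, mode="pre-mRNA")
        out = ds.splice_mask_candidates(
            [inter], [GenomicInterval("chr1", 120, 140, "+")], self.models()
        )
        # the region [100,200) spans the exon1 end at 150, a constitutive site
        assert out[0].splice_site_class == "constitutive"


class TestClassifySpliceSite:
    def gene(self, skip_second_exon_in_b=True):
        exons_a = (
            GenomicInterval("chr1", 0, 100, "+"),
            GenomicInterval("chr1", 200, 300, "+"),
            GenomicInterval("chr1", 400, 500, "+"),
        )
        exons_b = (exons_a[0], exons_a[2]) if skip_second_exon_in_b else exons_a
        a = TranscriptModel("a", "g", "chr1", "+", exons_a, biotype="noncoding")
        b = TranscriptModel("b", "g", "chr1", "+", exons_b, biotype="noncoding")
        return [a, b]

    def test_boundary_used_by_all_covering_isoforms(self):
        assert ds.classify_splice_site(100, self.gene()) == "constitutive"
        assert ds.classify_splice_site(400, self.gene()) == "constitutive"

    def test_boundary_used_by_subset_is_alternative(self):
        assert ds.classify_splice_site(200, self.gene()) == "alternative"
        assert ds.classify_splice_site(300, self.gene()) == "alternative"

    def test_single_isoform_gene_all_constitutive(self):
        (a, _) = self.gene()
        for pos in a.internal_boundaries():
            assert ds.classify_splice_site(pos, [a]) == "constitutive"

    def test_non_boundary_position_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            ds.classify_splice_site(123, self.gene())

    def test_fixture_skipped_exon_is_alternative(self, fixture_bundle):
        models = [m for m in fixture_bundle.models if m.gene_id == "G01"]
        t01 = next(m for m in models if m.transcript_id == "T01")
        skipped = t01.exons[1]  # exon 2 is absent from T01B
        assert ds.classify_splice_site(skipped.start, models) == "alternative"
        assert ds.classify_splice_site(t01.exons[0].end, models) == "constitutive"


class TestIntersectSites:
    def test_basic_intersection(self):
        out = ds.intersect_site_sets(
            [GenomicInterval("chr1", 0, 10)], [GenomicInterval("chr1", 5, 20)]
        )
        assert [(v.start, v.end) for v in out] == [(5, 10)]

    def test_disjoint_sets_empty(self):
        assert (
            ds.intersect_site_sets(
                [GenomicInterval("chr1", 0, 10)], [GenomicInterval("chr1", 20, 30)]
            )
            == []
        )

    def test_strands_not_mixed(self):
        out = ds.intersect_site_sets(
            [GenomicInterval("chr1", 0, 10, "+")], [GenomicInterval("chr1", 5, 20, "-")]
        )
        assert out == []

    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 50)),
            min_size=1, max_size=20,
        )
    )
    def test_self_intersection_is_merge(self, raw):
        ivs = [GenomicInterval("chr1", s, s + l) for s, l in raw]
        assert ds.intersect_site_sets(ivs, ivs) == ds.merge_regions(ivs)


class TestMirnaMask:
    @pytest.mark.parametrize(
        "site,kept",
        [
            (GenomicInterval("chr1", 196, 204, "+"), True),   # len 8, overlap 4
            (GenomicInterval("chr1", 197, 205, "+"), False),  # len 8, overlap 3
            (GenomicInterval("chr1", 196, 203, "+"), True),   # len 7, overlap 4 (ceil)
            (GenomicInterval("chr1", 197, 204, "+"), False),  # len 7, overlap 3
            (GenomicInterval("chr1", 150, 158, "-"), False),  # inside, wrong strand
        ],
    )
    def test_half_overlap_rule(self, site, kept):
        inter = make_interaction(REGION)
        out = ds.mirna_mask_candidates([inter], [site])
        assert bool(out) == kept

    def test_overlap_counts_across_fragments(self):
        inter = InteractionRecord(
            alignment=make_interaction(REGION).alignment,
            lnc_genomic=(GenomicInterval("chrL", 0, 100, "+"),),
            target_genomic=(
                GenomicInterval("chr1", 100, 150, "+"),
                GenomicInterval("chr1", 160, 200, "+"),
            ),
            region_class="CDS",
            locality="trans",
        )
        # site [140,170): 10 in first fragment + 10 in second >= ceil(30/2)=15
        site = GenomicInterval("chr1", 140, 170, "+")
        assert ds.mirna_mask_candidates([inter], [site])


class TestSmd:
    def test_double_containment_required(self):
        model = single_exon_coding_model()
        inter = make_interaction(GenomicInterval("chr1", 550, 900, "+"), "tx", "CDS_UTR")
        inside_both = GenomicInterval("chr1", 650, 800, "+")
        outside_utr = GenomicInterval("chr1", 560, 620, "+")  # straddles CDS end 600
        assert ds.smd_candidates([inter], [inside_both], [model])
        assert not ds.smd_candidates([inter], [outside_utr], [model])

    def test_noncoding_target_never_kept(self):
        model = TranscriptModel(
            "tx", "g", "chr1", "+",
            (GenomicInterval("chr1", 0, 1000, "+"),), biotype="noncoding",
        )
        inter = make_interaction(GenomicInterval("chr1", 550, 900, "+"), "tx", "noncoding")
        assert not ds.smd_candidates(
            [inter], [GenomicInterval("chr1", 650, 800, "+")], [model]
        )


class TestEditing:
    @pytest.mark.parametrize(
        "pos,kept",
        [(150, True), (100, True), (199, True), (200, False), (99, False)],
    )
    def test_half_open_membership(self, pos, kept):
        inter = make_interaction(REGION)
        site = GenomicInterval("chr1", pos, pos + 1, "+")
        assert bool(ds.editing_candidates([inter], [site])) == kept

    def test_multibase_record_rejected(self):
        with pytest.raises(ValueError, match="single-base"):
            ds.editing_candidates(
                [make_interaction(REGION)], [GenomicInterval("chr1", 150, 152, "+")]
            )

    def test_empty_site_set_empty_output(self):
        assert ds.editing_candidates([make_interaction(REGION)], []) == []


class TestMonotonicity:
    def test_adding_features_and_interactions_never_removes(self):
        inter1 = make_interaction(REGION)
        inter2 = make_interaction(GenomicInterval("chr1", 300, 400, "+"))
        s1 = GenomicInterval("chr1", 150, 151, "+")
        s2 = GenomicInterval("chr1", 350, 351, "+")

        def keys(annotations):
            return {
                (a.interaction.interaction_id, a.evidence[0].start)
                for a in annotations
            }

        small = keys(ds.editing_candidates([inter1], [s1]))
        more_feats = keys(ds.editing_candidates([inter1], [s1, s2]))
        more_inter = keys(ds.editing_candidates([inter1, inter2], [s1, s2]))
        assert small <= more_feats <= more_inter

    def test_filters_commute_with_partitioning(self):
        inters = [
            make_interaction(GenomicInterval("chr1", 100, 200, "+")),
            make_interaction(GenomicInterval("chr2", 100, 200, "+")),
        ]
        sites = [
            GenomicInterval("chr1", 150, 151, "+"),
            GenomicInterval("chr2", 150, 151, "+"),
        ]
        joint = ds.editing_candidates(inters, sites)
        split = ds.editing_candidates([inters[0]], sites) + ds.editing_candidates(
            [inters[1]], sites
        )
        assert [(a.interaction.interaction_id, a.evidence) for a in joint] == [
            (a.interaction.interaction_id, a.evidence) for a in split
        ]
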