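"""Search against pre-mRNAs and keep junction-spanning interactions.

Intron interiors more than 250 nt from a splice site are masked with N, so
only splice-site-proximal sequence is searchable; interactions that span an
exon-intron border are candidate splice-signal maskers.
"""

import numpy as np

import duplexscan as ds
from duplexscan.formats_io import GenomicInterval
from duplexscan.premrna import TranscriptModel, build_premrna_query
from duplexscan.scoring import random_sequence

rng = np.random.default_rng(0)
genome = {"chr1": random_sequence(2000, rng)}

model = TranscriptModel(
    "tx1", "gene1", "chr1", "+",
    exons=(GenomicInterval("chr1", 100, 300, "+"), GenomicInterval("chr1", 1000, 1200, "+")),
    biotype="noncoding",
)
query, pmap = build_premrna_query(model, genome, flank=250)
print(f"pre-mRNA length {len(query.seq)} nt, {query.seq.count('N')} intron-interior nt masked")

# a lncRNA complementary to 60 nt straddling the first exon's 3' border
g0, g1 = 270, 330  # 30 exonic + 30 intronic genomic nt
segment = genome["chr1"][g0:g1]
lnc = ds.SequenceRecord("lnc1", random_sequence(200, rng) + ds.revcomp(segment) + random_sequence(200, rng))

hits = ds.search_transcriptome([lnc], [query], ds.default_matrix(), 60, mode="pre-mRNA")
for aln in hits:
    spans = ds.spans_junction(aln, model)
    print(f"hit score={aln.score} target[{aln.target_interval[0]}:{aln.target_interval[1]}) "
          f"spans a splice junction: {spans}")
# Junction-spanning pre-mRNA interactions are the ones that could block
# spliceosome assembly when the splice signal is base-paired by the lncRNA.
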