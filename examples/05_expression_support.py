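"""Expression support: unique-read RPKM, co-expression and balance.

Reads mapping to >10 positions or to more than one gene are discarded;
transcript-level RPKM uses reads hitting exactly one transcript. An
interaction is supported when both molecules are expressed in at least one
common library, and balanced when they differ by <10-fold or the lncRNA is
in excess.
"""

import warnings

import duplexscan as ds
from duplexscan.expression import compute_expression, read_mappings_tsv
import tempfile
from pathlib import Path

warnings.filterwarnings("ignore")

tmp = Path(tempfile.mkdtemp())
fixture = ds.make_fixture(seed=1, out_dir=tmp)

mappings = read_mappings_tsv(tmp / "mappings.tsv")
table = compute_expression(mappings, fixture.unit_lengths, fixture.gene_map)
print(f"libraries: {table.libraries}; transcripts expressed somewhere: "
      f"{len(table.expressed_units())}/{len(table.units)}")

for pair in [("LNC00", "T02"), ("LNC01", "T04"), ("LNC02", "T05"), ("LNC04", "T16")]:
    co = ds.coexpressed(pair, table)
    line = f"  {pair[0]} x {pair[1]}: co-expressed={co}"
    if co:
        lib = next(l for l in table.libraries
                   if table.rpkm(pair[0], l) > 0 and table.rpkm(pair[1], l) > 0)
        line += (f"  (in {lib}: rpkm {table.rpkm(pair[0], lib):.1f} vs "
                 f"{table.rpkm(pair[1], lib):.1f}, "
                 f"balanced={ds.expression_balanced(pair, table, lib)})")
    print(line)
# A predicted duplex can only exist in a cell where both molecules are present;
# the balance rule asks that the regulator is not vastly outnumbered.
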