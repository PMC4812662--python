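"""Origin of non-co-linear CNV genes.

CNV genes are tested for co-linearity with the outgroup (projection +
exonic alignment); for non-co-linear genes a genome-wide seed-and-extend
search finds the ancestral copy, and high-identity (>= 90%) pairs get an
origin call from the breakpoint context of the new copy: TE-flanked
capture, NAHR flanking homology, or NHEJ microhomology. Prints recovery
against the implanted duplications. Writes results/noncolinear.tsv.
"""

import pathlib
import sys
from collections import Counter

from cnvpol import io
from cnvpol.pipeline import stage_origin

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS, DATA = ROOT / "results", ROOT / "results" / "data"


def main() -> int:
    df = stage_origin(str(DATA), str(RESULTS))
    nc = df[~df["is_colinear"]]
    print(f"{len(df)} CNV genes tested; {len(nc)} non-co-linear")
    with_hit = nc[nc["ancestral_identity"] != ""]
    print(f"  {len(with_hit)} have a genomic homolog (ancestral copy)")
    print(f"  origin calls: {Counter(nc['origin_mechanism'].replace('', 'no_call'))}")

    truth = io.read_tsv(DATA / "truth.tsv")
    dup = truth[truth["origin"] != ""].dropna(subset=["origin"])
    by_gene = dict(zip(df["gene_id"], df["origin_mechanism"]))
    ok = tot = 0
    for r in dup.itertuples(index=False):
        if r.gene_id in by_gene:
            tot += 1
            ok += by_gene[r.gene_id] == r.origin
    if tot:
        print(f"  implanted duplication origins recovered: {ok}/{tot}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
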