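"""Annotate the catalog against gene models and the accession panel.

Gene impact categories (full gene / partial CDS / UTR-only / intron-only),
population sharing between cultivated and wild accessions and between the
indica/japonica subgroups, and hypergeometric term enrichment of the
CDS-disrupted genes with BH-FDR control. Writes results/gene_impact.tsv,
results/sharing.tsv, results/enrichment.tsv.
"""

import pathlib
import sys

from cnvpol import io
from cnvpol.impact import sharing_fractions
from cnvpol.pipeline import stage_impact

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS, DATA = ROOT / "results", ROOT / "results" / "data"


def main() -> int:
    out = stage_impact(str(DATA), str(RESULTS))
    summary = io.read_tsv(RESULTS / "gene_impact_summary.tsv").iloc[0]
    print(f"{summary.genes_affected} genes affected by "
          f"{summary.cnvs_hitting_genes} CNVs")
    print(f"  full {summary.full}, partial CDS {summary.partial_cds}, "
          f"UTR-only {summary.utr_only}, intron-only {summary.intron_only}; "
          f"CDS disrupted in {summary.cds_disrupted_genes} genes")
    for part, fracs in sharing_fractions(out["sharing"]).items():
        pretty = ", ".join(f"{k} {100 * v:.1f}%"
                           for k, v in sorted(fracs.items()))
        print(f"  sharing [{part}]: {pretty}")
    enr = out["enrichment"]
    if len(enr):
        sig = enr[enr["fdr"] < 0.05]
        print(f"  {len(sig)} of {len(enr)} terms enriched at FDR<0.05 "
              f"(top p={enr['p_value'].min():.3g})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
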