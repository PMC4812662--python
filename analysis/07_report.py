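"""Re-derive the catalog summary from the stage files and print it.

Every number is recomputed from results/*.tsv at report time; inconsistent
event ids across stages are an error. Writes results/report.json and
results/report.txt.
"""

import pathlib
import sys

from cnvpol.pipeline import write_report

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> int:
    write_report(str(RESULTS))
    print((RESULTS / "report.txt").read_text(), end="")
    return 0


if __name__ == "__main__":
    sys.exit(main())
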