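#!/usr/bin/env python
"""Transcript-protein fold-change concordance.

Matches the significant transcript and protein lists through the shared
gene symbols, then correlates their signed-log2 fold changes.  Because the
simulated proteome is drawn with effects copied from the transcript truth,
a strongly positive correlation is expected; the overlap is limited by the
detection power of each layer, as in real paired omic studies.
"""

import json
import shutil
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATASET, RESULTS, SCRATCH, ensure_dirs

from polyomic.cli import do_concord


def main() -> None:
    ensure_dirs()
    summary = do_concord(SCRATCH / "transcript_significant.tsv",
                         SCRATCH / "protein_significant.tsv",
                         DATASET / "symbol_map.tsv", SCRATCH / "concordance")
    print(f"significant features shared by both layers: {summary['n_overlap']}")
    if "pearson_r" in summary:
        print(f"fold-change concordance: r = {summary['pearson_r']:.4f}, "
              f"r^2 = {summary['r_squared']:.4f} over n = {summary['n']} pairs")
    for name in ("concordance_pairs.tsv", "concordance_summary.json"):
        shutil.copy(SCRATCH / name, RESULTS / name)
    print(f"pair table written to {RESULTS / 'concordance_pairs.tsv'}")


if __name__ == "__main__":
    main()
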