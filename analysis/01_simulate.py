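#!/usr/bin/env python
"""Generate the ground-truth multi-omic dataset for the analysis run.

Writes peptide-level iTRAQ reporter tables for two technical replicates,
transcript and metabolite matrices, gene sets with three planted enriched
sets, and all truth tables, under scratch/analysis/dataset/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATASET, ensure_dirs

from polyomic.cli import do_simulate, load_config


def main() -> None:
    ensure_dirs()
    cfg = load_config(None)
    cfg.update({k: v for k, v in CONFIG.items()})
    manifest = do_simulate(cfg, DATASET)
    print(f"dataset written to {DATASET}")
    print(f"  proteins:    {manifest['n_proteins']} (2 technical replicates, "
          f"7 KO + 7 WT samples)")
    print(f"  transcripts: {manifest['n_transcripts']} (5 KO + 5 WT samples)")
    print(f"  metabolites: {manifest['n_metabolites']} (9 KO + 9 WT samples)")
    planted = json.loads((DATASET / "planted_sets.json").read_text())
    print(f"  planted enriched gene sets: {planted}")


if __name__ == "__main__":
    main()
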