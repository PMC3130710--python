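"""Shared configuration for the numbered analysis drivers.

One seeded world at study scale: 34,273 transcripts (five samples per
group), 300 iTRAQ-quantified proteins (seven per group, two technical
replicates), 205 plasma metabolites (nine per group).  Bulk tables live
under scratch/ (regenerable); each driver writes its small summary tables
under results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
DATASET = SCRATCH / "dataset"
RESULTS = ROOT / "results"

CONFIG = {
    "seed": 2026,
    "fdr_threshold": 0.02,
    "sim": {
        "n_proteins": 300,
        "noise_cv": 0.2,
    },
    "enrich": {"n_sets": 50, "n_planted": 3, "set_size_range": [20, 120]},
}


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
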