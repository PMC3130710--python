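"""Gene-set over-representation against a declared background universe.

For a differential list of size n drawn from a universe of N features, a
set with K members in the universe and k in the list is scored by the
hypergeometric upper tail P(X >= k) — one-sided, enrichment only.  Reports
mirror the classic GO-tool layout: sample frequency k/n and background
frequency K/N as percentages, p, and a BH-adjusted p across the collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .errors import DataError

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named member sets plus the background universe (sampling frame)."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.universe) == 0:
            raise DataError("empty universe")
        # members outside the universe cannot participate in the sampling frame
        self.sets = {
            sid: (name, members & self.universe) for sid, (name, members) in self.sets.items()
        }

    @property
    def n_universe(self) -> int:
        return len(self.universe)


def annotate_frequencies(de_ids, members, universe) -> dict:
    """Counts and percentage frequencies for one set.

    Returns k (DE members of the set), n (DE list size), K (universe
    members of the set), N (universe size) and the derived percentages.
    DE ids outside the universe are dropped with a warning and counted.
    """
    de = set(de_ids)
    universe = set(universe)
    members = set(members) & universe
    outside = de - universe
    if outside:
        log.warning("%d DE ids outside the universe dropped", len(outside))
        de -= outside
    n = len(de)
    if n == 0:
        raise DataError("empty DE list after universe restriction")
    k = len(de & members)
    big_k, big_n = len(members), len(universe)
    return {
        "k": k,
        "n": n,
        "K": big_k,
        "N": big_n,
        "sample_freq_pct": round(100.0 * k / n, 1),
        "background_freq_pct": round(100.0 * big_k / big_n, 1),
        "n_dropped_outside_universe": len(outside),
    }


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise DataError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(de_ids, collection: GeneSetCollection) -> pd.DataFrame:
    """One record per set, BH-adjusted across the collection, sorted by adj_p."""
    rows = []
    for set_id, (name, members) in collection.sets.items():
        freq = annotate_frequencies(de_ids, members, collection.universe)
        p = hypergeom_pvalue(freq["k"], freq["n"], freq["K"], freq["N"])
        rows.append({
            "set_id": set_id,
            "name": name,
            "k": freq["k"],
            "n": freq["n"],
            "K": freq["K"],
            "N": freq["N"],
            "sample_freq_pct": freq["sample_freq_pct"],
            "background_freq_pct": freq["background_freq_pct"],
            "p_value": p,
        })
    table = pd.DataFrame(rows)
    if table.empty:
        raise DataError("empty gene-set collection")
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values(["adj_p", "p_value", "set_id"], kind="stable")
    return table.reset_index(drop=True)
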