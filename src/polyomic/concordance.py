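"""Cross-omic fold-change concordance.

Significant transcript and protein lists are matched by gene symbol
(case-insensitive, optionally through identifier->symbol maps) and the
agreement of their fold changes is quantified by the Pearson correlation of
the SIGNED-LOG2 transforms l = sign(fc) * log2(|fc|).  Signed fold changes
themselves have a jump discontinuity between +1 and -1 (there is no value
in (-1, 1)), which distorts a linear correlation; the signed-log2 transform
maps them back onto the continuous log-ratio scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

log = logging.getLogger(__name__)


def signed_log2(fc):
    """sign(fc) * log2(|fc|); inverse of the signed-fold-change display convention."""
    fc = np.asarray(fc, dtype=float)
    if (np.abs(fc) < 1.0).any():
        raise DataError("signed fold changes must have magnitude >= 1")
    out = np.sign(fc) * np.log2(np.abs(fc))
    return float(out) if out.ndim == 0 else out


def _to_symbols(df: pd.DataFrame, symbol_map: pd.Series | None) -> pd.Series:
    ids = df["feature_id"].astype(str)
    if symbol_map is not None:
        mapped = ids.map(lambda i: symbol_map.get(i, i))
    else:
        mapped = ids
    return mapped.str.upper()


def _best_per_symbol(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Resolve one-to-many symbol mappings by the largest |t| representative."""
    score = df["t_mod"].abs() if "t_mod" in df else df["signed_fc"].abs()
    df = df.assign(_score=score.to_numpy())
    n_multi = int((df.groupby("symbol").size() > 1).sum())
    best = df.sort_values(["_score"], ascending=False, kind="stable").drop_duplicates("symbol")
    return best.drop(columns="_score"), n_multi


def match_features(
    de_mrna: pd.DataFrame,
    de_protein: pd.DataFrame,
    mrna_symbol_map: pd.Series | None = None,
    protein_symbol_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Pair up genes present in both significant lists.

    Inputs are differential tables with at least ``feature_id`` and
    ``signed_fc`` columns (``t_mod`` used to break one-to-many symbol ties).
    Returns one row per shared symbol with both fold changes and their
    signed-log2 transforms.
    """
    if de_mrna.empty or de_protein.empty:
        return pd.DataFrame(
            columns=["gene_symbol", "fc_mrna", "fc_protein", "l_mrna", "l_protein"]
        )
    m = de_mrna.copy()
    p = de_protein.copy()
    m["symbol"] = _to_symbols(m, mrna_symbol_map)
    p["symbol"] = _to_symbols(p, protein_symbol_map)
    m, n_multi_m = _best_per_symbol(m)
    p, n_multi_p = _best_per_symbol(p)
    if n_multi_m or n_multi_p:
        log.info("one-to-many symbols resolved by max |t|: mRNA=%d, protein=%d",
                 n_multi_m, n_multi_p)
    merged = m.merge(p, on="symbol", suffixes=("_mrna", "_protein"))
    pairs = pd.DataFrame({
        "gene_symbol": merged["symbol"],
        "fc_mrna": merged["signed_fc_mrna"].astype(float),
        "fc_protein": merged["signed_fc_protein"].astype(float),
    })
    pairs["l_mrna"] = signed_log2(pairs["fc_mrna"].to_numpy())
    pairs["l_protein"] = signed_log2(pairs["fc_protein"].to_numpy())
    return pairs.sort_values("gene_symbol", kind="stable").reset_index(drop=True)


def fold_change_correlation(pairs: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson r (and r^2) between the signed-log2 fold changes of the layers."""
    n = len(pairs)
    if n < 3:
        raise DataError(f"need >=3 matched pairs for a correlation, got {n}")
    r = float(stats.pearsonr(pairs["l_mrna"], pairs["l_protein"]).statistic)
    return r, r * r, n
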