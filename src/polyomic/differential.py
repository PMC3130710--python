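"""Two-group differential analysis shared by the transcript, protein and
metabolite layers.

The model is the classic empirical-Bayes moderated t (Smyth 2004) for a
one-factor, two-level design (knockout vs wild-type):

* per feature g: pooled within-group variance ``s_g^2`` on ``d_g`` residual
  degrees of freedom;
* a scaled inverse-chi-square prior ``s_g^2 ~ s0^2 * d0 / chi2(d0)`` whose
  hyperparameters ``(d0, s0^2)`` are estimated across all features by
  matching the mean and variance of ``log s_g^2`` to their theoretical
  digamma/trigamma moments;
* posterior variance ``s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)`` and
  ``t_g = (mean_KO - mean_WT) / (s~_g * sqrt(1/n_KO + 1/n_WT))`` referred to
  a t distribution on ``d_g + d0`` degrees of freedom (normal when
  ``d0 = inf``).

All testing happens on the log2 scale; positive linear-scale inputs
(metabolite concentrations, protein ratios) are log2-transformed first with
a configurable floor.  Fold changes are reported in the signed convention
(``r`` if ``r >= 1`` else ``-1/r``), so -10.2 means 10.2-fold lower in the
knockout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigError, DataError

GROUP_KO = "KO"
GROUP_WT = "WT"


@dataclass
class ExpressionMatrix:
    """Features x samples numeric table with a two-group design.

    ``scale`` is ``"log2"`` (ready for testing) or ``"linear"`` (strictly
    positive concentrations/ratios, log2-transformed before testing).
    """

    values: pd.DataFrame
    groups: pd.Series
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ConfigError(f"unknown scale tag {self.scale!r}")
        if self.values.index.duplicated().any():
            raise DataError("duplicated feature ids")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise DataError(f"samples without group label: {missing}")
        unknown = set(self.groups.unique()) - {GROUP_KO, GROUP_WT}
        if unknown:
            raise DataError(f"unknown group labels {sorted(unknown)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def drop_samples(self, sample_ids) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if s not in set(sample_ids)]
        return ExpressionMatrix(self.values[keep], self.groups.loc[keep], self.scale)


def log2_transform(matrix: ExpressionMatrix, floor: float | None = None) -> ExpressionMatrix:
    """Log2-transform a linear-positive matrix.

    Zeros are floored at ``floor`` (default: half the smallest positive
    value in the matrix) so that sparse concentrations do not produce -inf.
    """
    if matrix.scale == "log2":
        return matrix
    vals = matrix.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise DataError("linear-scale matrix contains negative values")
    pos = vals[vals > 0]
    if pos.size == 0:
        raise DataError("linear-scale matrix is entirely zero")
    if floor is None:
        floor = pos.min() / 2.0
    out = np.log2(np.maximum(vals, floor))
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.groups,
        "log2",
    )


def group_stats(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature group means, pooled within-group variance and residual df.

    Equivalent to the cell-means one-way ANOVA with two levels:
    ``s^2`` is the pooled variance, ``df = n_KO + n_WT - 2``.
    """
    if matrix.scale != "log2":
        raise DataError("group_stats expects a log2-scale matrix; transform first")
    ko = matrix.samples_in(GROUP_KO)
    wt = matrix.samples_in(GROUP_WT)
    if len(ko) < 2 or len(wt) < 2:
        raise DataError(f"each group needs >=2 samples (got KO={len(ko)}, WT={len(wt)})")
    x_ko = matrix.values[ko].to_numpy(dtype=float)
    x_wt = matrix.values[wt].to_numpy(dtype=float)
    n_ko, n_wt = len(ko), len(wt)
    mean_ko = x_ko.mean(axis=1)
    mean_wt = x_wt.mean(axis=1)
    ss = x_ko.var(axis=1, ddof=0) * n_ko + x_wt.var(axis=1, ddof=0) * n_wt
    df = n_ko + n_wt - 2
    out = pd.DataFrame(
        {
            "mean_ko": mean_ko,
            "mean_wt": mean_wt,
            "s2": ss / df,
            "df": float(df),
            "n_ko": n_ko,
            "n_wt": n_wt,
        },
        index=matrix.values.index,
    )
    return out


@dataclass(frozen=True)
class EBPrior:
    """Variance prior: d0 degrees of freedom (may be inf) and scale s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ConfigError("prior d0 must be positive")
        if not (self.s0_sq > 0):
            raise ConfigError("prior s0_sq must be positive")


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on psi'(y) = x (monotone decreasing); the scheme and
    # its endpoints follow the standard method-of-moments treatment.
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-10:
            break
    return y


def estimate_eb_prior(s2: np.ndarray, df: float | np.ndarray, min_features: int = 50) -> EBPrior:
    """Method-of-moments fit of (d0, s0^2) from all per-feature variances.

    Matches the empirical mean and variance of ``log s^2`` to the
    digamma/trigamma moments implied by the scaled-F sampling model.  If the
    log-variances are underdispersed relative to pure chi-square sampling
    noise, the prior is degenerate: ``d0 = inf`` and ``s0^2 = mean(s^2)``.
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = s2 > 0
    if not ok.any():
        raise DataError("all variances are zero; cannot estimate a prior")
    if ok.sum() < min_features:
        raise DataError(
            f"need >={min_features} features with positive variance, got {int(ok.sum())}"
        )
    s2, df_arr = s2[ok], df_arr[ok]
    z = np.log(s2)
    e = z - special.digamma(df_arr / 2.0) + np.log(df_arr / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df_arr / 2.0).mean())
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = float(s2.mean())
    return EBPrior(d0=d0, s0_sq=s0_sq)


def moderated_t_test(stats_df: pd.DataFrame, prior: EBPrior) -> pd.DataFrame:
    """Moderated t, total df and two-sided p for each feature."""
    s2 = stats_df["s2"].to_numpy(dtype=float)
    df = stats_df["df"].to_numpy(dtype=float)
    n_ko = stats_df["n_ko"].to_numpy(dtype=float)
    n_wt = stats_df["n_wt"].to_numpy(dtype=float)
    diff = stats_df["mean_ko"].to_numpy(dtype=float) - stats_df["mean_wt"].to_numpy(dtype=float)
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0
    se = np.sqrt(s2_post * (1.0 / n_ko + 1.0 / n_wt))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), df_total),
    )
    out = stats_df.copy()
    out["t_mod"] = t
    out["df_total"] = df_total
    out["p_value"] = p
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Stable sort (ties keep input order), monotonicity enforced by a reverse
    cumulative minimum, clipped to [p, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = q
    return out


def signed_fold_change(mean_ko, mean_wt):
    """Signed fold change from log2 group means.

    ``r = 2**(mean_ko - mean_wt)``; reported as ``r`` when ``r >= 1`` and as
    ``-1/r`` otherwise, so the magnitude is always >= 1 and the sign tracks
    the direction of change in the knockout.
    """
    r = np.power(2.0, np.asarray(mean_ko, dtype=float) - np.asarray(mean_wt, dtype=float))
    out = np.where(r >= 1.0, r, -1.0 / r)
    if out.ndim == 0:
        return float(out)
    return out


def run_de(
    matrix: ExpressionMatrix,
    fdr_threshold: float = 0.02,
    prior: EBPrior | None = None,
    log2_floor: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full differential table plus the significant subset (adj_p < threshold)."""
    if matrix.values.shape[0] == 0:
        cols = [
            "feature_id", "mean_ko", "mean_wt", "signed_fc",
            "t_mod", "df_total", "p_value", "adj_p",
        ]
        empty = pd.DataFrame(columns=cols)
        return empty, empty.copy()
    mat = log2_transform(matrix, floor=log2_floor)
    st = group_stats(mat)
    if prior is None:
        prior = estimate_eb_prior(st["s2"].to_numpy(), float(st["df"].iloc[0]))
    st = moderated_t_test(st, prior)
    st["adj_p"] = bh_adjust(st["p_value"].to_numpy())
    st["signed_fc"] = signed_fold_change(st["mean_ko"].to_numpy(), st["mean_wt"].to_numpy())
    records = st.reset_index(names="feature_id")[
        ["feature_id", "mean_ko", "mean_wt", "signed_fc", "t_mod", "df_total", "p_value", "adj_p"]
    ]
    significant = records[records["adj_p"] < fdr_threshold].reset_index(drop=True)
    return records, significant


# -- QC screens ---------------------------------------------------------

def pca_outlier_flags(
    matrix: ExpressionMatrix, k_components: int = 2, z_threshold: float = 3.0
) -> pd.Series:
    """Flag samples with extreme scores on any of the first k components.

    Robust z per component: distance from the component median in units of
    1.4826*MAD, so the outlier itself does not inflate the yardstick.
    """
    n_samples = matrix.values.shape[1]
    if n_samples < k_components:
        raise DataError(f"{n_samples} samples but {k_components} components requested")
    x = matrix.values.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    x = x[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k_components] * s[:k_components]
    flags = np.zeros(n_samples, dtype=bool)
    for j in range(scores.shape[1]):
        col = scores[:, j]
        med = np.median(col)
        mad = np.median(np.abs(col - med))
        robust_sd = 1.4826 * mad
        if robust_sd == 0:
            continue
        flags |= np.abs(col - med) > z_threshold * robust_sd
    return pd.Series(flags, index=matrix.values.columns, name="pca_outlier")


def contamination_screen(
    matrix: ExpressionMatrix, marker_ids, z_threshold: float = 3.0
) -> pd.Series:
    """Flag samples whose mean marker abundance sits > z SDs above the cohort mean.

    Intended for blood-contamination markers (hemoglobin subunits) in tissue
    proteomes; markers missing from the matrix are skipped with a warning.
    """
    present = [m for m in marker_ids if m in matrix.values.index]
    skipped = [m for m in marker_ids if m not in matrix.values.index]
    if skipped:
        warnings.warn(f"contamination markers not in matrix, skipped: {skipped}")
    if not present:
        return pd.Series(False, index=matrix.values.columns, name="contaminated")
    marker_mean = matrix.values.loc[present].mean(axis=0)
    mu, sd = marker_mean.mean(), marker_mean.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        flags = pd.Series(False, index=matrix.values.columns)
    else:
        flags = (marker_mean - mu) / sd > z_threshold
    flags.name = "contaminated"
    return flags
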