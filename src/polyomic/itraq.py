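"""Regression-based iTRAQ protein quantification.

Each peptide spectrum contributes one (x, y) pair per sample channel, where
x is the internal-standard reporter intensity and y the sample reporter
intensity.  Least squares through the origin over a protein's pairs gives
the protein's sample/reference ratio as the slope ``sum(x*y)/sum(x^2)`` —
the zero intercept is forced by the physics (zero reference signal implies
zero sample signal for a shared peptide), and the quadratic weighting gives
high-intensity, high-precision pairs more influence.

The R^2 reported is the THROUGH-ORIGIN convention ``1 - SS_res / sum(y^2)``
(uncentered total sum of squares), clipped to [0, 1].  It is not comparable
to the centered R^2 of a fit with intercept; with no intercept the centered
definition can go negative and is the wrong yardstick.

Downstream stages: iterative standardized-residual outlier trimming, per
run/channel bias normalization so high-confidence protein ratios average to
fold change 1.0, QC filtering (R^2 > 0.70, >=2 unique peptides, >=4
observations), and compositing of the two technical replicates with a
mismatch filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import GROUP_KO, GROUP_WT, ExpressionMatrix
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

META_COLS = ("run_id", "protein_id", "peptide_key")


@dataclass
class RunDesign:
    """Channel layout of one multiplexed run."""

    run_id: str
    channel_to_sample: dict[str, str]  # sample channels only
    reference_channel: str
    replicate_id: str = "A"
    correction_matrix: np.ndarray | None = None  # column-stochastic, obs = C @ true

    def __post_init__(self) -> None:
        if self.reference_channel in self.channel_to_sample:
            raise ConfigError("reference channel cannot also carry a sample")
        if self.correction_matrix is not None:
            c = np.asarray(self.correction_matrix, dtype=float)
            n = len(self.channels)
            if c.shape != (n, n):
                raise ConfigError(
                    f"correction matrix is {c.shape}, expected ({n}, {n})"
                )

    @property
    def channels(self) -> list[str]:
        return [self.reference_channel, *self.channel_to_sample.keys()]


@dataclass(frozen=True)
class QuantParams:
    """Tunables of the quantifier; defaults are the published settings."""

    min_r2: float = 0.70            # strict >, per the published filter
    min_unique_peptides: int = 2
    min_observations: int = 4
    hc_r2: float = 0.9              # high-confidence cut for bias adjustment
    hc_min_peptides: int = 3
    outlier_z: float = 3.0
    outlier_max_rounds: int = 2
    mismatch_log2_threshold: float = 1.0
    bias_mean: str = "geometric"    # or "arithmetic"
    apply_bias: bool = True

    def __post_init__(self) -> None:
        if self.bias_mean not in ("geometric", "arithmetic"):
            raise ConfigError(f"bias_mean must be geometric|arithmetic, got {self.bias_mean!r}")


def apply_isotope_correction(rows: pd.DataFrame, design: RunDesign) -> pd.DataFrame:
    """Undo isotope-impurity spillover by solving the channel mixing system.

    With the column-stochastic convention observed = C @ true, the corrected
    intensities are the solution of the linear system (not a nominal-purity
    division); negative solutions are floored at 0.
    """
    if design.correction_matrix is None:
        return rows
    c = np.asarray(design.correction_matrix, dtype=float)
    if abs(np.linalg.det(c)) < 1e-12:
        raise ConfigError("correction matrix is singular")
    channels = design.channels
    observed = rows[channels].to_numpy(dtype=float)
    corrected = np.linalg.solve(c, observed.T).T
    corrected = np.maximum(corrected, 0.0)
    out = rows.copy()
    out[channels] = corrected
    return out


def build_ratio_pairs(
    rows: pd.DataFrame, design: RunDesign, protein_id: str, sample_id: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """(x, y) pairs for one protein and one sample within one run.

    Returns ``(pairs, peptide_keys, n_dropped)`` where ``pairs`` is (n, 2)
    with x = reference intensity, y = sample intensity; pairs with a zero on
    either axis are dropped and counted (a ratio against zero is undefined,
    and the pooled internal standard should never be truly zero).
    """
    if rows["run_id"].nunique() > 1:
        raise DataError("build_ratio_pairs expects rows from a single run")
    channel = None
    for ch, s in design.channel_to_sample.items():
        if s == sample_id:
            channel = ch
            break
    if channel is None:
        raise DataError(f"sample {sample_id!r} not in run {design.run_id!r}")
    sub = rows[rows["protein_id"] == protein_id]
    x = sub[design.reference_channel].to_numpy(dtype=float)
    y = sub[channel].to_numpy(dtype=float)
    keys = sub["peptide_key"].to_numpy()
    keep = (x > 0) & (y > 0)
    n_dropped = int((~keep).sum())
    return np.column_stack([x[keep], y[keep]]), keys[keep], n_dropped


def fit_protein_ratio(pairs: np.ndarray) -> tuple[float, float]:
    """Through-origin least squares: slope = sum(xy)/sum(x^2).

    r_squared uses the through-origin convention 1 - SS_res/sum(y^2),
    clipped to [0, 1].
    """
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if pairs.shape[0] == 0:
        raise DataError("no pairs to fit")
    x, y = pairs[:, 0], pairs[:, 1]
    sxx = float(np.dot(x, x))
    if sxx <= 0:
        raise DataError("all reference intensities are zero")
    slope = float(np.dot(x, y)) / sxx
    syy = float(np.dot(y, y))
    if syy <= 0:
        return slope, 0.0
    resid = y - slope * x
    r2 = 1.0 - float(np.dot(resid, resid)) / syy
    return slope, float(np.clip(r2, 0.0, 1.0))


def remove_regression_outliers(
    pairs: np.ndarray, max_rounds: int = 2, z: float = 3.0, min_keep: int = 3
) -> tuple[np.ndarray, int]:
    """Iteratively drop pairs with |standardized residual| > z and refit.

    Standardization is against the RMS residual of the current fit.  Only
    attempted with >= 4 pairs, at most ``max_rounds`` rounds, and never
    trimming below ``min_keep`` remaining pairs.  Returns a boolean keep
    mask aligned to the input plus the number removed.
    """
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    n = pairs.shape[0]
    keep = np.ones(n, dtype=bool)
    if n < 4:
        return keep, 0
    for _ in range(max_rounds):
        cur = pairs[keep]
        slope, _ = fit_protein_ratio(cur)
        resid = cur[:, 1] - slope * cur[:, 0]
        rms = float(np.sqrt(np.mean(resid ** 2)))
        if rms == 0:
            break
        bad_local = np.abs(resid) > z * rms
        if not bad_local.any():
            break
        # worst offenders first, stop at the floor
        order = np.argsort(-np.abs(resid))
        idx_global = np.flatnonzero(keep)
        budget = int(keep.sum()) - min_keep
        removed_this_round = 0
        for i in order:
            if budget <= 0:
                break
            if bad_local[i]:
                keep[idx_global[i]] = False
                budget -= 1
                removed_this_round += 1
        if removed_this_round == 0:
            break
    return keep, int(n - keep.sum())


def quantify_run(rows: pd.DataFrame, design: RunDesign, params: QuantParams = QuantParams()) -> pd.DataFrame:
    """Per-protein, per-sample regression estimates for one run.

    Returns one row per (protein, sample) with slope, through-origin R^2,
    unique-peptide and observation counts, max reporter intensity and the
    number of outlier pairs removed.
    """
    rows = apply_isotope_correction(rows, design)
    records = []
    for protein_id, sub in rows.groupby("protein_id", sort=True):
        x_ref = sub[design.reference_channel].to_numpy(dtype=float)
        keys = sub["peptide_key"].to_numpy()
        for channel, sample_id in design.channel_to_sample.items():
            y = sub[channel].to_numpy(dtype=float)
            keep0 = (x_ref > 0) & (y > 0)
            if not keep0.any():
                log.info("no usable pairs for %s / %s in %s", protein_id, sample_id, design.run_id)
                continue
            pairs = np.column_stack([x_ref[keep0], y[keep0]])
            pkeys = keys[keep0]
            keep, removed = remove_regression_outliers(
                pairs, max_rounds=params.outlier_max_rounds, z=params.outlier_z
            )
            pairs, pkeys = pairs[keep], pkeys[keep]
            slope, r2 = fit_protein_ratio(pairs)
            records.append({
                "protein_id": protein_id,
                "run_id": design.run_id,
                "replicate_id": design.replicate_id,
                "sample_id": sample_id,
                "channel": channel,
                "slope": slope,
                "r_squared": r2,
                "n_unique_peptides": int(pd.unique(pkeys).size),
                "n_observations": int(pairs.shape[0]),
                "max_intensity": float(pairs.max()) if pairs.size else 0.0,
                "outliers_removed": int(removed),
            })
    return pd.DataFrame(records, columns=[
        "protein_id", "run_id", "replicate_id", "sample_id", "channel", "slope",
        "r_squared", "n_unique_peptides", "n_observations", "max_intensity",
        "outliers_removed",
    ])


def _high_confidence(est: pd.DataFrame, params: QuantParams) -> pd.Series:
    return (est["r_squared"] > params.hc_r2) & (est["n_unique_peptides"] >= params.hc_min_peptides)


def adjust_channel_bias(
    estimates: pd.DataFrame, params: QuantParams = QuantParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize each run's channels so high-confidence ratios average to 1.0.

    Per (run, channel): the bias factor is the geometric (default) or
    arithmetic mean of the slopes of high-confidence proteins (R^2 > 0.9 and
    >= 3 unique peptides); all slopes in the channel are divided by it.  A
    channel with no high-confidence protein keeps factor 1.0 with a warning.
    The operation is idempotent.
    """
    est = estimates.copy()
    hc = _high_confidence(est, params)
    factors = []
    for (run_id, channel), idx in est.groupby(["run_id", "channel"], sort=True).groups.items():
        idx = pd.Index(idx)
        hc_idx = idx[hc.loc[idx]]
        if len(hc_idx) == 0:
            warnings.warn(f"run {run_id} channel {channel}: no high-confidence proteins; bias 1.0")
            factor = 1.0
        else:
            slopes = est.loc[hc_idx, "slope"].to_numpy(dtype=float)
            if params.bias_mean == "geometric":
                factor = float(np.exp(np.mean(np.log(slopes))))
            else:
                factor = float(np.mean(slopes))
        est.loc[idx, "slope"] = est.loc[idx, "slope"] / factor
        factors.append({
            "run_id": run_id,
            "channel": channel,
            "sample_id": est.loc[idx, "sample_id"].iloc[0],
            "bias_factor": factor,
            "n_high_confidence": int(len(hc_idx)),
        })
    return est, pd.DataFrame(factors)


def filter_estimates(estimates: pd.DataFrame, params: QuantParams = QuantParams()) -> pd.DataFrame:
    """Published QC gate: R^2 strictly > 0.70, >=2 unique peptides, >=4 observations."""
    keep = (
        (estimates["r_squared"] > params.min_r2)
        & (estimates["n_unique_peptides"] >= params.min_unique_peptides)
        & (estimates["n_observations"] >= params.min_observations)
    )
    return estimates[keep].reset_index(drop=True)


def composite_ratios(
    replicate_a: pd.DataFrame,
    replicate_b: pd.DataFrame,
    mismatch_log2_threshold: float = 1.0,
) -> pd.DataFrame:
    """Reconcile the two technical replicates into one ratio per (protein, sample).

    Both present: geometric mean of the two slopes, flagged (and excluded
    downstream) if they disagree by more than ``mismatch_log2_threshold`` in
    |log2|.  Exactly one present: that slope is used as-is.
    """
    for name, df in (("A", replicate_a), ("B", replicate_b)):
        if df.duplicated(subset=["protein_id", "sample_id"]).any():
            raise DataError(f"replicate {name} has duplicate (protein, sample) estimates")
    a = replicate_a[["protein_id", "sample_id", "slope"]].rename(columns={"slope": "slope_a"})
    b = replicate_b[["protein_id", "sample_id", "slope"]].rename(columns={"slope": "slope_b"})
    merged = a.merge(b, on=["protein_id", "sample_id"], how="outer")
    merged["slope_a"] = merged["slope_a"].astype(float)
    merged["slope_b"] = merged["slope_b"].astype(float)
    both = merged["slope_a"].notna() & merged["slope_b"].notna()
    ratio = np.where(
        both,
        np.sqrt(merged["slope_a"] * merged["slope_b"]),
        merged["slope_a"].fillna(merged["slope_b"]),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mismatch = both & (
            np.abs(np.log2(merged["slope_a"] / merged["slope_b"])) > mismatch_log2_threshold
        )
    out = pd.DataFrame({
        "protein_id": merged["protein_id"],
        "sample_id": merged["sample_id"],
        "ratio": ratio,
        "source": np.where(both, "both-replicates", "single-replicate"),
        "mismatch_flag": mismatch.to_numpy(dtype=bool),
    })
    return out


def replicate_concordance_slope(estimates: pd.DataFrame) -> tuple[float, int]:
    """Through-origin slope of replicate-B ratios regressed on replicate-A.

    The classic consistency check for a replicated design: after channel
    bias adjustment the two technical replicates of the same samples should
    fall on a line of slope 1 through the origin.  Returns (slope, n_pairs)
    over the (protein, sample) estimates present in both replicates.
    """
    reps = sorted(estimates["replicate_id"].unique())
    if len(reps) != 2:
        raise DataError(f"need exactly two replicates, got {reps}")
    a = estimates[estimates["replicate_id"] == reps[0]]
    b = estimates[estimates["replicate_id"] == reps[1]]
    merged = a[["protein_id", "sample_id", "slope"]].merge(
        b[["protein_id", "sample_id", "slope"]],
        on=["protein_id", "sample_id"], suffixes=("_a", "_b"),
    )
    if merged.empty:
        raise DataError("no shared (protein, sample) estimates between replicates")
    pairs = merged[["slope_a", "slope_b"]].to_numpy(dtype=float)
    slope, _ = fit_protein_ratio(pairs)
    return slope, len(merged)


def quantify_run_set(
    run_tables: list[tuple[pd.DataFrame, list[RunDesign]]],
    params: QuantParams = QuantParams(),
) -> tuple[ExpressionMatrix | None, pd.DataFrame, pd.DataFrame, dict]:
    """End-to-end quantification of a replicated experiment.

    ``run_tables`` holds one (peptide table, run designs) entry per technical
    replicate (1 or 2 supported).  Returns ``(matrix, composites, estimates,
    qc)`` where ``matrix`` is the log2 composite-ratio ExpressionMatrix
    (mismatched records excluded; samples grouped KO/WT by id prefix), and
    ``qc`` counts records surviving each stage.
    """
    if len(run_tables) == 0:
        warnings.warn("no peptide tables supplied; empty result")
        return None, pd.DataFrame(), pd.DataFrame(), {"n_spectra": 0}
    if len(run_tables) > 2:
        raise ConfigError("at most two technical replicates are supported")

    qc: dict[str, float | int] = {}
    all_estimates = []
    n_spectra = 0
    for table, designs in run_tables:
        n_spectra += len(table)
        for design in designs:
            sub = table[table["run_id"] == design.run_id]
            if sub.empty:
                continue
            all_estimates.append(quantify_run(sub, design, params))
    estimates = (
        pd.concat(all_estimates, ignore_index=True) if all_estimates else pd.DataFrame()
    )
    qc["n_spectra"] = n_spectra
    qc["n_estimates"] = len(estimates)
    if estimates.empty:
        warnings.warn("no protein estimates produced; empty result")
        return None, pd.DataFrame(), estimates, qc

    if params.apply_bias:
        estimates, bias_factors = adjust_channel_bias(estimates, params)
        qc["n_channels_adjusted"] = len(bias_factors)
    qc["n_high_confidence"] = int(_high_confidence(estimates, params).sum())
    qc["n_outlier_pairs_removed"] = int(estimates["outliers_removed"].sum())

    kept = filter_estimates(estimates, params)
    qc["n_pass_filter"] = len(kept)

    reps = sorted(kept["replicate_id"].unique())
    if len(reps) == 2:
        comp = composite_ratios(
            kept[kept["replicate_id"] == reps[0]],
            kept[kept["replicate_id"] == reps[1]],
            params.mismatch_log2_threshold,
        )
    else:
        comp = kept[["protein_id", "sample_id", "slope"]].rename(columns={"slope": "ratio"})
        comp["source"] = "single-replicate"
        comp["mismatch_flag"] = False
    qc["n_composite"] = len(comp)
    qc["n_mismatch_excluded"] = int(comp["mismatch_flag"].sum())

    usable = comp[~comp["mismatch_flag"]]
    if usable.empty:
        return None, comp, estimates, qc
    pivot = usable.pivot(index="protein_id", columns="sample_id", values="ratio")
    groups = pd.Series(
        [GROUP_KO if s.startswith("KO") else GROUP_WT for s in pivot.columns],
        index=pivot.columns,
    )
    matrix = ExpressionMatrix(np.log2(pivot), groups, scale="log2")
    qc["n_proteins_in_matrix"] = matrix.values.shape[0]
    return matrix, comp, estimates, qc
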