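"""Paired-allele pulldown quantification: from label-swapped replicate tables
to allele-specific interactor calls.

The stage order follows the screen's processing: combine label-swapped
replicates onto the Ref/Alt scale, remove batch effects with a parametric
empirical-Bayes location/scale adjustment, impute remaining missing values
from a down-shifted normal distribution, and flag ratio outliers with a
robust percentile z-test (globally, "mode A", or within intensity bins,
"mode B") whose two-sided p-value is ``erfc(z / sqrt(2))``.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .simulate import ALT_HEAVY, REF_HEAVY, PulldownPair
from ._util import stage_seed

logger = logging.getLogger(__name__)

#: Percentiles defining the robust z-score: the median and the one-sigma
#: quantiles of a standard normal (15.87 / 84.13).
_P_LO, _P_MID, _P_HI = 15.87, 50.0, 84.13


def combine_label_swap(pair: PulldownPair) -> pd.DataFrame:
    """Combine a pair of label-swapped replicates onto the Ref/Alt scale.

    The ALT_HEAVY replicate stores log2(Alt/Ref) (heavy over light), so its
    ratios are sign-inverted before averaging with the REF_HEAVY replicate.
    Proteins observed in only one replicate carry that single oriented value
    and are flagged ``single_replicate``.  Output rows are ordered by
    ``protein_id``.
    """
    if len(pair.replicates) != 2:
        raise ValueError(f"{pair.snp_id}: expected exactly two replicates")
    orientations = [str(rep["orientation"].iloc[0]) for rep in pair.replicates]
    for rep in pair.replicates:
        if rep["orientation"].nunique() != 1:
            raise ValueError(f"{pair.snp_id}: mixed orientations within one replicate")
    if set(orientations) != {REF_HEAVY, ALT_HEAVY}:
        raise ValueError(
            f"{pair.snp_id}: replicates must have opposite label orientations, "
            f"got {orientations} (bookkeeping fault)"
        )

    oriented = {}
    intens = {}
    for rep, orientation in zip(pair.replicates, orientations):
        sign = 1.0 if orientation == REF_HEAVY else -1.0
        r = rep.set_index("protein_id")
        oriented[orientation] = sign * r["log2_ratio"].astype(float)
        with np.errstate(divide="ignore"):
            intens[orientation] = np.log10(r["intensity"].astype(float)).replace(
                -np.inf, np.nan
            )

    fc = pd.DataFrame(
        {"ref_heavy": oriented[REF_HEAVY], "alt_heavy": oriented[ALT_HEAVY]}
    ).sort_index()
    li = pd.DataFrame(intens).sort_index()
    n_observed = fc.notna().sum(axis=1)
    out = pd.DataFrame(
        {
            "protein_id": fc.index,
            "log2fc_ref_over_alt": fc.mean(axis=1, skipna=True).to_numpy(),
            "oriented_ref_heavy": fc["ref_heavy"].to_numpy(),
            "oriented_alt_heavy": fc["alt_heavy"].to_numpy(),
            "mean_log10_intensity": li.mean(axis=1, skipna=True).to_numpy(),
            "n_observed": n_observed.to_numpy(),
            "single_replicate": (n_observed == 1).to_numpy(),
        }
    ).reset_index(drop=True)
    out.insert(0, "snp_id", pair.snp_id)
    return out


def _robust_pvalues(values: np.ndarray) -> np.ndarray:
    """Mode-A p-values for one set of log-ratios (NaNs excluded -> NaN p)."""
    p = np.full(values.shape, np.nan)
    obs = np.isfinite(values)
    v = values[obs]
    if v.size == 0:
        return p
    r0 = np.percentile(v, _P_MID)
    right = np.percentile(v, _P_HI) - r0
    left = r0 - np.percentile(v, _P_LO)
    if right <= 0 and np.any(v > r0):
        raise ValueError("degenerate right spread: all values identical above the median")
    if left <= 0 and np.any(v < r0):
        raise ValueError("degenerate left spread: all values identical below the median")
    right = right if right > 0 else 1.0
    left = left if left > 0 else 1.0
    z = np.where(v > r0, (v - r0) / right, (r0 - v) / left)
    p[obs] = erfc(z / np.sqrt(2.0))
    return p


def significance_outlier_test(
    log2fc: Sequence[float],
    log_intensity: Sequence[float] | None = None,
    mode: str = "B",
    min_bin_size: int = 300,
) -> np.ndarray:
    """Two-sided ratio-outlier p-values (robust percentile z-test).

    Mode A estimates the null spread from the 15.87/50/84.13 percentiles of
    the whole log-ratio distribution; the z-score uses the right spread for
    values above the median and the left spread below, and
    ``p = erfc(z / sqrt(2))`` (the two-sided tail of a standard normal).
    Mode B sorts proteins by ``log_intensity``, partitions them into
    equal-occupancy bins of at least ``min_bin_size`` and applies mode A
    within each bin; with fewer than ``min_bin_size`` observations it falls
    back to mode A (a single bin), which is logged.

    NaN ratios receive NaN p-values.  Percentiles use linear interpolation
    between order statistics; the intensity sort is stable, so ties are
    broken by input order.
    """
    x = np.asarray(log2fc, dtype=float)
    if mode not in ("A", "B"):
        raise ValueError(f"mode must be 'A' or 'B', got {mode!r}")
    if mode == "B" and log_intensity is None:
        raise ValueError("mode B requires log_intensity")
    obs_idx = np.flatnonzero(np.isfinite(x))
    p = np.full(x.shape, np.nan)
    if obs_idx.size == 0:
        return p
    if mode == "A" or obs_idx.size < 2 * int(min_bin_size):
        if mode == "B" and obs_idx.size < int(min_bin_size):
            logger.info(
                "mode B fallback to mode A: %d observed < min_bin_size=%d",
                obs_idx.size,
                min_bin_size,
            )
        if mode == "A":
            p = _robust_pvalues(x)
            return p
        bins = [obs_idx]
    else:
        li = np.asarray(log_intensity, dtype=float)[obs_idx]
        order = obs_idx[np.argsort(li, kind="stable")]
        n_bins = obs_idx.size // int(min_bin_size)
        bins = np.array_split(order, n_bins)
    for bin_idx in bins:
        p[bin_idx] = _robust_pvalues(x[bin_idx])
    return p


def _eb_batch_adjust(
    data: np.ndarray, batch_codes: np.ndarray, n_batches: int
) -> np.ndarray:
    """Parametric empirical-Bayes location/scale adjustment (NaN-aware).

    Standardizes each row with batch-design fitted means and pooled variance,
    estimates per-batch location/scale effects, shrinks them toward the batch
    prior (normal prior on locations, inverse-gamma on scales, hyperpriors by
    method of moments) with the standard iterative conditional solution, and
    back-transforms.
    """
    obs = np.isfinite(data)
    n_rows = data.shape[0]
    batch_means = np.full((n_rows, n_batches), np.nan)
    batch_n = np.zeros((n_rows, n_batches))
    for b in range(n_batches):
        cols = batch_codes == b
        block = data[:, cols]
        batch_n[:, b] = np.isfinite(block).sum(axis=1)
        with np.errstate(invalid="ignore"):
            batch_means[:, b] = np.nanmean(block, axis=1)
    n_total = batch_n.sum(axis=1)
    grand = (batch_n * batch_means).sum(axis=1) / n_total

    fitted = batch_means[:, batch_codes]
    resid = data - fitted
    var_pooled = np.nansum(resid**2, axis=1) / n_total
    sd_pooled = np.sqrt(var_pooled)
    sd_pooled[sd_pooled <= 0] = 1.0

    z = (data - grand[:, None]) / sd_pooled[:, None]

    adjusted = z.copy()
    for b in range(n_batches):
        cols = batch_codes == b
        zb = z[:, cols]
        n_b = np.isfinite(zb).sum(axis=1)
        gamma_hat = np.nanmean(zb, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            delta_hat = np.nansum((zb - gamma_hat[:, None]) ** 2, axis=1) / np.maximum(
                n_b - 1, 1
            )
        gamma_bar = float(np.mean(gamma_hat))
        tau2 = float(np.var(gamma_hat, ddof=1)) if n_rows > 1 else 0.0
        v_bar = float(np.mean(delta_hat))
        s2 = float(np.var(delta_hat, ddof=1)) if n_rows > 1 else 0.0

        if tau2 <= 1e-12 or s2 <= 1e-12:
            # Degenerate hyperpriors (e.g. noise-free offsets): no pooling.
            gamma_star = gamma_hat if tau2 > 1e-12 else np.full(n_rows, gamma_bar)
            delta_star = delta_hat.copy()
        else:
            a_prior = (2.0 * s2 + v_bar**2) / s2
            b_prior = (v_bar * s2 + v_bar**3) / s2
            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            for _ in range(200):
                g_new = (n_b * tau2 * gamma_hat + delta_star * gamma_bar) / (
                    n_b * tau2 + delta_star
                )
                ssq = np.nansum((zb - g_new[:, None]) ** 2, axis=1)
                d_new = (b_prior + 0.5 * ssq) / (n_b / 2.0 + a_prior - 1.0)
                change = max(
                    np.nanmax(np.abs(g_new - gamma_star)),
                    np.nanmax(np.abs(d_new - delta_star)),
                )
                gamma_star, delta_star = g_new, d_new
                if change < 1e-8:
                    break
        scale = np.sqrt(np.maximum(delta_star, 0.0))
        scale[scale <= 1e-10] = 1.0
        adjusted[:, cols] = (zb - gamma_star[:, None]) / scale[:, None]

    out = adjusted * sd_pooled[:, None] + grand[:, None]
    out[~obs] = np.nan
    return out


def correct_batch(
    matrix: pd.DataFrame, batches: Sequence
) -> tuple[pd.DataFrame, pd.Series]:
    """Remove per-batch location/scale effects from a log2fc matrix.

    ``matrix`` has proteins as rows and pulldowns as columns; ``batches``
    assigns a batch label to each column.  Single-batch input is returned
    unchanged.  Rows with fewer than two observed values in any batch are
    passed through unadjusted and flagged in the returned boolean series.
    """
    if len(batches) != matrix.shape[1]:
        raise ValueError(
            f"batch vector length {len(batches)} != number of pulldowns {matrix.shape[1]}"
        )
    if matrix.shape[1] < 2:
        raise ValueError("batch correction requires >= 2 pulldowns")
    labels = pd.Categorical([str(b) for b in batches])
    passthrough = pd.Series(False, index=matrix.index, name="batch_passthrough")
    if len(labels.categories) < 2:
        return matrix.copy(), passthrough

    data = matrix.to_numpy(dtype=float)
    codes = np.asarray(labels.codes)
    n_batches = len(labels.categories)
    obs_per_batch = np.stack(
        [np.isfinite(data[:, codes == b]).sum(axis=1) for b in range(n_batches)],
        axis=1,
    )
    eligible = (obs_per_batch >= 2).all(axis=1)
    passthrough[:] = ~eligible
    if passthrough.any():
        logger.info(
            "correct_batch: %d/%d rows passed through (fewer than 2 observed "
            "values in some batch)",
            int(passthrough.sum()),
            len(passthrough),
        )
    corrected = data.copy()
    if eligible.any():
        corrected[eligible] = _eb_batch_adjust(data[eligible], codes, n_batches)
    return pd.DataFrame(corrected, index=matrix.index, columns=matrix.columns), passthrough


def impute_missing(
    matrix: pd.DataFrame,
    width_factor: float = 0.3,
    downshift_factor: float = 1.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing values from a down-shifted normal distribution.

    Per column, missing entries are drawn from
    ``Normal(mean - downshift_factor * sd, (width_factor * sd)**2)`` of that
    column's observed values — the convention used for left-censored MS
    missingness, where unquantified ratios most plausibly sit in the
    low-abundance tail.  Returns the completed matrix and a boolean mask of
    imputed cells.  Deterministic under a fixed seed.
    """
    if not width_factor > 0:
        raise ValueError("width_factor must be > 0")
    rng = np.random.default_rng(stage_seed(seed, "impute"))
    filled = matrix.copy()
    mask = matrix.isna()
    for col in matrix.columns:
        values = matrix[col].astype(float)
        obs = values.dropna()
        n_missing = int(mask[col].sum())
        if n_missing == 0:
            continue
        if len(obs) < 3:
            raise ValueError(
                f"column {col!r} has {len(obs)} observed values; "
                "need >= 3 to estimate imputation moments"
            )
        m, s = float(obs.mean()), float(obs.std(ddof=1))
        draws = rng.normal(m - downshift_factor * s, width_factor * s, size=n_missing)
        filled.loc[mask[col], col] = draws
    return filled, mask


def call_interactors(
    combined: pd.DataFrame,
    alpha: float = 0.01,
    replicate_pvalues: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call allele-specific interactors from the combined table.

    ``combined`` needs columns ``snp_id``, ``protein_id``,
    ``log2fc_ref_over_alt`` and ``p_value`` (optionally ``imputed`` and
    ``single_replicate``).  Proteins with ``p < alpha`` are returned with the
    allele preference given by the sign of the fold change (REF iff
    positive).

    When ``replicate_pvalues`` is provided (long table with columns
    ``snp_id``, ``protein_id``, ``p_value``, one row per observed replicate
    measurement), a call additionally requires every observed replicate to be
    individually significant at ``alpha`` and at least one observed
    replicate — the label-swap support rule that keeps ratio outliers from a
    single orientation out of the call set.
    """
    required = {"snp_id", "protein_id", "log2fc_ref_over_alt", "p_value"}
    missing_cols = required - set(combined.columns)
    if missing_cols:
        raise ValueError(f"combined table lacks columns: {sorted(missing_cols)}")
    calls = combined[combined["p_value"] < alpha].copy()
    if replicate_pvalues is not None and len(calls):
        rep = replicate_pvalues.dropna(subset=["p_value"])
        support = rep.groupby(["snp_id", "protein_id"])["p_value"].agg(["max", "count"])
        keyed = calls.set_index(["snp_id", "protein_id"])
        sup = support.reindex(keyed.index)
        keep = (sup["count"] >= 1) & (sup["max"] < alpha)
        calls = keyed[keep.fillna(False).to_numpy()].reset_index()
    calls["allele_preference"] = np.where(
        calls["log2fc_ref_over_alt"] > 0, "REF", "ALT"
    )
    if "imputed" not in calls.columns:
        calls["imputed"] = False
    if "single_replicate" not in calls.columns:
        calls["single_replicate"] = False
    calls = calls.sort_values(
        ["snp_id", "p_value", "protein_id"], kind="stable"
    ).reset_index(drop=True)
    cols = [
        "snp_id",
        "protein_id",
        "log2fc_ref_over_alt",
        "p_value",
        "allele_preference",
        "imputed",
        "single_replicate",
    ]
    extra = [c for c in calls.columns if c not in cols]
    return calls[cols + extra]
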