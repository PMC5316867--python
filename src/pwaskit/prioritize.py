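"""Combined z-statistic ranking of SNP-TF interactions.

Interactions are ranked by two pooled z-scores: the z-scored per-locus mean
DNase I hypersensitivity (openness of the SNP's chromatin) and the z-scored
absolute log2 fold change from the pulldown screen (strength of the allelic
binding switch).  The two z-scores are averaged and the average converted to
a one-sided upper-tail normal p-value; large average z means an interaction
that is both strongly allele-specific and located in accessible chromatin.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _zscore(values: pd.Series, what: str) -> pd.Series:
    sd = float(values.std(ddof=1))
    if sd == 0:
        logger.info("%s: zero spread across entries; all z set to 0", what)
        return pd.Series(np.zeros(len(values)), index=values.index)
    return (values - float(values.mean())) / sd


def dhs_zscores(profiles: pd.DataFrame, normalize_depth: bool = False) -> pd.Series:
    """Per-locus accessibility z-scores from a loci x samples count table.

    Each locus is summarized by its mean read count across accessibility
    samples, then z-scored across loci (sd with n-1 denominator).  With
    ``normalize_depth`` the counts are first scaled to reads-per-million per
    sample column.  A zero spread yields all-zero z (logged).
    """
    if profiles.shape[0] < 2:
        raise ValueError("dhs_zscores requires >= 2 loci (z undefined for one)")
    if (profiles.to_numpy() < 0).any():
        raise ValueError("DHS counts must be non-negative")
    counts = profiles.astype(float)
    if normalize_depth:
        counts = counts / counts.sum(axis=0) * 1e6
    means = counts.mean(axis=1)
    z = _zscore(means, "dhs_zscores")
    z.name = "z_dhs"
    return z


def fc_zscores(abs_log2fc: pd.Series) -> pd.Series:
    """Pooled z-scores of absolute log2 fold changes across interactions.

    The absolute value is taken first, so the direction of the allele
    preference never affects the z-score; pooling is screen-wide.
    """
    if len(abs_log2fc) < 2:
        raise ValueError("fc_zscores requires >= 2 interactions")
    z = _zscore(abs_log2fc.abs().astype(float), "fc_zscores")
    z.name = "z_fc"
    return z


def combined_significance(z_dhs, z_fc):
    """Average two z-scores and convert to a one-sided upper-tail p-value.

    ``p = P(Z > (z_dhs + z_fc) / 2)`` under a standard normal; strictly
    decreasing in each argument.  Accepts scalars or aligned arrays and
    returns ``(z_avg, p)``.
    """
    zd = np.asarray(z_dhs, dtype=float)
    zf = np.asarray(z_fc, dtype=float)
    if not (np.all(np.isfinite(zd)) and np.all(np.isfinite(zf))):
        raise ValueError("combined_significance requires finite z-scores")
    z_avg = (zd + zf) / 2.0
    return z_avg, norm.sf(z_avg)


def prioritize_interactions(
    calls: pd.DataFrame,
    dhs: pd.DataFrame,
    threshold: float = 0.05,
    per_snp_fc: bool = False,
    normalize_depth: bool = False,
    add_bh: bool = False,
) -> pd.DataFrame:
    """Build the full prioritized table for a set of interactor calls.

    ``calls`` needs columns ``snp_id``, ``protein_id`` and
    ``log2fc_ref_over_alt``; ``dhs`` is the loci x samples count table
    covering every called locus.  Returns one row per interaction with
    ``abs_log2fc``, ``z_fc``, ``z_dhs``, ``z_avg``, ``p_combined``,
    ``selected`` (p below ``threshold``) and ``rank`` (ascending p, ties
    broken by descending ``abs_log2fc`` then ids).  ``per_snp_fc`` computes
    the fold-change z-scores within each SNP instead of pooled; ``add_bh``
    appends a Benjamini-Hochberg adjusted column (no correction is applied
    by default).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    out = calls.copy().reset_index(drop=True)
    missing = set(out["snp_id"]) - set(dhs.index)
    if missing:
        raise ValueError(f"loci absent from DHS table: {sorted(missing)[:5]}")
    z_dhs = dhs_zscores(dhs, normalize_depth=normalize_depth)
    out["abs_log2fc"] = out["log2fc_ref_over_alt"].abs()
    if per_snp_fc:
        out["z_fc"] = (
            out.groupby("snp_id")["abs_log2fc"]
            .transform(lambda s: _zscore(s, "fc_zscores(per-snp)"))
            .astype(float)
        )
    else:
        out["z_fc"] = fc_zscores(out["abs_log2fc"]).to_numpy()
    out["z_dhs"] = out["snp_id"].map(z_dhs).astype(float)
    out["z_avg"], out["p_combined"] = combined_significance(
        out["z_dhs"], out["z_fc"]
    )
    out["selected"] = out["p_combined"] < threshold
    if add_bh:
        out["p_combined_bh"] = multipletests(out["p_combined"], method="fdr_bh")[1]
    out = out.sort_values(
        ["p_combined", "abs_log2fc", "snp_id", "protein_id"],
        ascending=[True, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def select_events(prioritized: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Significant subset of a prioritized table, ranked ascending by p.

    Ties are broken by descending ``abs_log2fc``, then ``snp_id`` and
    ``protein_id``.
    """
    sel = prioritized[prioritized["p_combined"] < threshold].copy()
    sel = sel.sort_values(
        ["p_combined", "abs_log2fc", "snp_id", "protein_id"],
        ascending=[True, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    sel["rank"] = np.arange(1, len(sel) + 1)
    return sel


def filter_to_tfs(calls: pd.DataFrame, tf_annotation: Iterable[str]) -> pd.DataFrame:
    """Restrict calls to annotated transcription-factor protein ids."""
    tf_set = set(tf_annotation)
    if not tf_set:
        raise ValueError("TF annotation is empty")
    kept = calls[calls["protein_id"].isin(tf_set)].reset_index(drop=True)
    logger.info(
        "filter_to_tfs: kept %d / %d calls (%d dropped)",
        len(kept),
        len(calls),
        len(calls) - len(kept),
    )
    return kept
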