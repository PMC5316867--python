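"""Exact allelic-imbalance tests at heterozygous SNPs.

Ref/Alt read counts from an assay (ChIP, accessibility, transcription) are
compared against an expectation — a supplied background count pair (e.g.
input or genomic DNA) or, by default, a 50:50 split at matched depth — with
Fisher's exact test on the 2x2 table.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import pandas as pd
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)


class ImbalanceResult(NamedTuple):
    odds_ratio: float
    p_value: float
    haldane_corrected: bool


def fisher_imbalance(
    ref_count: int,
    alt_count: int,
    background_ref: int | None = None,
    background_alt: int | None = None,
) -> ImbalanceResult:
    """Fisher's exact test of assay Ref/Alt counts against an expectation.

    The two-sided p-value sums the probabilities of all 2x2 tables with the
    observed margins whose point probability does not exceed the observed
    table's (the standard exact two-sided convention).  When no background
    counts are given, a 50:50 expectation at matched depth is substituted
    (heterozygous genomic DNA; logged).  The odds ratio is the sample
    cross-product ratio, with the Haldane-Anscombe 0.5 correction applied
    (and flagged) whenever any cell is zero.
    """
    for name, v in (("ref_count", ref_count), ("alt_count", alt_count)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if ref_count + alt_count == 0:
        raise ValueError("site is not testable: ref_count + alt_count == 0")
    if (background_ref is None) != (background_alt is None):
        raise ValueError("provide both background counts or neither")
    if background_ref is None:
        depth = ref_count + alt_count
        background_ref = (depth + 1) // 2
        background_alt = depth // 2
        logger.info(
            "fisher_imbalance: no background supplied; using 50:50 expectation "
            "at matched depth (%d, %d)",
            background_ref,
            background_alt,
        )
    if background_ref < 0 or background_alt < 0:
        raise ValueError("background counts must be non-negative")
    table = [[ref_count, alt_count], [background_ref, background_alt]]
    if sum(table[0]) + sum(table[1]) == 0:
        raise ValueError("all-zero 2x2 table")
    p = float(min(fisher_exact(table, alternative="two-sided")[1], 1.0))
    cells = (ref_count, alt_count, background_ref, background_alt)
    corrected = any(c == 0 for c in cells)
    a, b, c, d = (x + 0.5 for x in cells) if corrected else cells
    odds_ratio = (a * d) / (b * c)
    return ImbalanceResult(float(odds_ratio), p, corrected)


def summarize_sites(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every (site, assay) row and tabulate odds ratios and p-values.

    ``counts`` columns: ``site_id``, ``assay``, ``ref_count``, ``alt_count``
    and optionally ``background_ref`` / ``background_alt`` (NA for the
    matched-depth 50:50 default).  Returns the result table (one row per
    testable input, ordered by site then assay, with allele ``preference``
    REF/ALT/NONE from the odds ratio) and a table of skipped sites with
    reasons.
    """
    rows, skipped = [], []
    for _, rec in counts.iterrows():
        site, assay = rec["site_id"], rec["assay"]
        try:
            ref = int(rec["ref_count"])
            alt = int(rec["alt_count"])
        except (TypeError, ValueError):
            skipped.append({"site_id": site, "assay": assay, "reason": "non-integer counts"})
            continue
        bg_ref = rec.get("background_ref")
        bg_alt = rec.get("background_alt")
        bg_ref = None if pd.isna(bg_ref) else int(bg_ref)
        bg_alt = None if pd.isna(bg_alt) else int(bg_alt)
        try:
            result = fisher_imbalance(ref, alt, bg_ref, bg_alt)
        except ValueError as exc:
            skipped.append({"site_id": site, "assay": assay, "reason": str(exc)})
            continue
        preference = (
            "REF" if result.odds_ratio > 1 else "ALT" if result.odds_ratio < 1 else "NONE"
        )
        rows.append(
            {
                "site_id": site,
                "assay": assay,
                "ref_count": ref,
                "alt_count": alt,
                "odds_ratio": result.odds_ratio,
                "p_value": result.p_value,
                "haldane_corrected": result.haldane_corrected,
                "preference": preference,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "assay",
            "ref_count",
            "alt_count",
            "odds_ratio",
            "p_value",
            "haldane_corrected",
            "preference",
        ],
    )
    if len(table):
        table = table.sort_values(["site_id", "assay"], kind="stable").reset_index(drop=True)
    skipped_df = pd.DataFrame(skipped, columns=["site_id", "assay", "reason"])
    return table, skipped_df
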