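"""4C-seq reduced-genome utilities.

In 4C-seq the alignment target is not the full genome but a "reduced
genome": the short sequences flanking every restriction site of the primary
enzyme.  This module performs the in-silico digestion (exact recognition-
site scan), extracts the 30-bp downstream flank on each strand, flags
uniquely mappable sites (exact-string uniqueness of the pooled flanks — a
stated proxy for an external-aligner mappability evaluation), and counts
reads in fixed-width windows with reads-per-million normalization and
between-condition log2 differences.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import revcomp

logger = logging.getLogger(__name__)

#: Standard recognition sequences of the enzymes used for the 4C digests.
ENZYMES = {"NlaIII": "CATG", "CviQI": "GTAC"}

DEFAULT_FLANK_LEN = 30
DEFAULT_WINDOW = 2500


def digest(
    contigs: Mapping[str, str], recognition: str, enzyme: str | None = None
) -> pd.DataFrame:
    """Scan contigs for exact occurrences of a recognition sequence.

    Palindromic recognition sequences (NlaIII's CATG, CviQI's GTAC) are
    scanned on the plus strand only and reported once per occurrence;
    non-palindromic sequences are additionally scanned as their reverse
    complement, with the hit marked on the minus strand.  Overlapping
    occurrences are all reported, in ascending position order per contig.

    Returns columns ``site_id``, ``contig``, ``position`` (0-based start of
    the recognition sequence), ``strand``, ``enzyme``, ``recognition``.
    """
    if not contigs:
        raise ValueError("empty contig set")
    recognition = recognition.upper()
    if len(recognition) < 4:
        raise ValueError("recognition sequence must be >= 4 bases")
    if set(recognition) - set("ACGT"):
        raise ValueError("recognition sequence must be IUPAC-unambiguous (ACGT only)")
    queries = [(recognition, "+")]
    rc = revcomp(recognition)
    if rc != recognition:
        queries.append((rc, "-"))
    rows = []
    for name in contigs:
        seq = str(contigs[name]).upper()
        for query, strand in queries:
            start = seq.find(query)
            while start != -1:
                rows.append((name, start, strand))
                start = seq.find(query, start + 1)
    rows.sort()
    out = pd.DataFrame(rows, columns=["contig", "position", "strand"])
    out.insert(0, "site_id", [f"{c}:{p}" for c, p in zip(out["contig"], out["position"])])
    out["enzyme"] = enzyme if enzyme is not None else ""
    out["recognition"] = recognition
    return out


def digest_enzyme(contigs: Mapping[str, str], enzyme: str) -> pd.DataFrame:
    """Digest with a named enzyme (NlaIII or CviQI)."""
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}; known: {sorted(ENZYMES)}")
    return digest(contigs, ENZYMES[enzyme], enzyme=enzyme)


def build_reduced_genome(
    contigs: Mapping[str, str],
    sites: pd.DataFrame,
    flank_len: int = DEFAULT_FLANK_LEN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract the two downstream flanks of each restriction site.

    The plus-strand flank is the ``flank_len`` bases immediately 3' of the
    recognition sequence on the plus strand; the minus-strand flank is the
    ``flank_len`` bases immediately 3' of the site on the minus strand, i.e.
    the reverse complement of the bases 5' of the site on the plus strand.
    Sites within ``flank_len`` of a contig edge are dropped (returned
    separately, and logged).  A site is flagged ``unique`` iff neither of
    its flank strings occurs more than once in the pooled multiset of all
    extracted flanks.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    entries, dropped = [], []
    for rec in sites.itertuples(index=False):
        seq = str(contigs[rec.contig]).upper()
        k = len(rec.recognition)
        pos = int(rec.position)
        if seq[pos : pos + k] != rec.recognition:
            raise ValueError(
                f"site {rec.site_id}: contig sequence does not match recognition"
            )
        if pos - flank_len < 0 or pos + k + flank_len > len(seq):
            dropped.append({"site_id": rec.site_id, "reason": "within flank_len of contig edge"})
            continue
        flank_plus = seq[pos + k : pos + k + flank_len]
        flank_minus = revcomp(seq[pos - flank_len : pos])
        entries.append(
            {
                "site_id": rec.site_id,
                "contig": rec.contig,
                "position": pos,
                "flank_plus": flank_plus,
                "flank_minus": flank_minus,
            }
        )
    if dropped:
        logger.info("build_reduced_genome: dropped %d edge site(s)", len(dropped))
    table = pd.DataFrame(
        entries, columns=["site_id", "contig", "position", "flank_plus", "flank_minus"]
    )
    pooled = Counter(table["flank_plus"]) + Counter(table["flank_minus"])
    table["unique"] = [
        pooled[fp] == 1 and pooled[fm] == 1
        for fp, fm in zip(table["flank_plus"], table["flank_minus"])
    ]
    dropped_df = pd.DataFrame(dropped, columns=["site_id", "reason"])
    return table, dropped_df


def window_interactions(
    reads: Mapping[str, pd.DataFrame],
    viewpoint: tuple[str, int, int] | None = None,
    window: int = DEFAULT_WINDOW,
    step: int | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Count mapped reads per fixed-width window and compare conditions.

    ``reads`` maps condition name to a BED-like frame (``contig``, ``start``,
    ``end``); a read is assigned to the window containing its start.  Windows
    of width ``window`` are tiled per contig every ``step`` bases (default:
    non-overlapping, ``step = window``).  Raw counts are normalized to
    reads-per-million of each condition's total mapped reads, with reads in
    viewpoint-overlapping windows excluded from that total; with exactly two
    conditions a ``log2_diff`` column is added, ``log2`` of the ratio of
    normalized counts with pseudocount 1 (first condition over second).
    """
    if not reads:
        raise ValueError("no read sets supplied")
    if step is None:
        step = window
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    conditions = list(reads)
    for cond, df in reads.items():
        if len(df) == 0:
            raise ValueError(f"zero total reads in condition {cond!r}")

    lengths: dict[str, int] = dict(contig_lengths or {})
    for df in reads.values():
        for contig, end in df.groupby("contig")["end"].max().items():
            lengths[contig] = max(lengths.get(contig, 0), int(end))

    frames = []
    for contig in sorted(lengths):
        starts = np.arange(0, max(lengths[contig], 1), step)
        frames.append(
            pd.DataFrame(
                {"contig": contig, "start": starts, "end": starts + window}
            )
        )
    windows = pd.concat(frames, ignore_index=True)
    windows["viewpoint"] = False
    if viewpoint is not None:
        v_contig, v_start, v_end = viewpoint
        windows["viewpoint"] = (
            (windows["contig"] == v_contig)
            & (windows["start"] < v_end)
            & (windows["end"] > v_start)
        )

    for cond in conditions:
        df = reads[cond]
        counts = np.zeros(len(windows), dtype=int)
        for contig, grp in df.groupby("contig"):
            sel = windows["contig"] == contig
            if not sel.any():
                continue
            pos = np.sort(grp["start"].to_numpy())
            w = windows[sel]
            counts[sel.to_numpy()] = np.searchsorted(pos, w["end"].to_numpy()) - np.searchsorted(
                pos, w["start"].to_numpy()
            )
        windows[f"count_{cond}"] = counts
        viewpoint_reads = int(counts[windows["viewpoint"].to_numpy()].sum())
        total = len(df) - viewpoint_reads
        if total <= 0:
            raise ValueError(
                f"condition {cond!r} has no reads outside the viewpoint window(s); "
                "cannot normalize"
            )
        windows[f"rpm_{cond}"] = counts / total * 1e6
    if len(conditions) == 2:
        a, b = conditions
        windows["log2_diff"] = np.log2(
            (windows[f"rpm_{a}"] + 1.0) / (windows[f"rpm_{b}"] + 1.0)
        )
    return windows
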