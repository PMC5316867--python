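"""End-to-end orchestration: synthesize -> quantify -> prioritize -> report.

The in-memory entry points (`quantify_screen`, `prioritize_screen`,
`run_screen_synthetic`) are what tests and scripts use; `run_screen` and
`run_4c` add file IO, a machine-readable manifest and a fallback log around
them for the command-line interface.  All randomness flows from one seed,
split deterministically per stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .fourc import DEFAULT_WINDOW, build_reduced_genome, digest_enzyme, window_interactions
from .prioritize import filter_to_tfs, prioritize_interactions, select_events
from .pulldown import (
    call_interactors,
    combine_label_swap,
    correct_batch,
    impute_missing,
    significance_outlier_test,
)
from .simulate import (
    ScreenSpec,
    generate_dhs_table,
    generate_pulldown_tables,
    generate_tf_annotation,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Working thresholds and parameters of one screen run.

    ``alpha_interactor`` is the interactor-call threshold on the ratio-
    outlier p-value; ``threshold_prioritize`` the selection threshold on the
    combined z p-value.
    """

    seed: int = 0
    alpha_interactor: float = 0.01
    threshold_prioritize: float = 0.05
    significance_mode: str = "B"
    min_bin_size: int = 300
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    batch_labels: tuple | None = None
    include_single_replicate: bool = False
    per_snp_fc: bool = False
    normalize_dhs_depth: bool = False
    window: int = DEFAULT_WINDOW
    step: int | None = None
    enzyme: str = "NlaIII"
    flank_len: int = 30

    def __post_init__(self) -> None:
        for name in ("alpha_interactor", "threshold_prioritize"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "batch_labels" in raw and raw["batch_labels"] is not None:
            raw["batch_labels"] = tuple(raw["batch_labels"])
        return cls(**raw)


def quantify_screen(
    pairs: Sequence,
    batches: Sequence | None = None,
    mode: str = "B",
    min_bin_size: int = 300,
    alpha: float = 0.01,
    impute_width: float = 0.3,
    impute_downshift: float = 1.8,
    seed: int = 0,
) -> dict:
    """Run the quantification stage over all pulldown pairs of a screen.

    Per locus the label-swapped replicates are combined onto the Ref/Alt
    scale; the combined log2fc matrix is batch-corrected (when more than one
    batch label is supplied) and imputed; the ratio-outlier test is run per
    locus on the combined values and, for label-swap support, on each
    replicate's observed oriented ratios.  Returns a dict with the long
    ``combined`` table (one row per locus x protein, with p-values), the
    ``calls`` table, the replicate p-value table and a log of fallbacks.
    """
    if not pairs:
        raise ValueError("no pulldown pairs supplied")
    fallbacks: list[str] = []
    combined_per_locus = {p.snp_id: combine_label_swap(p) for p in pairs}
    loci = [p.snp_id for p in pairs]

    fc = pd.DataFrame(
        {snp: df.set_index("protein_id")["log2fc_ref_over_alt"] for snp, df in combined_per_locus.items()}
    )
    if batches is not None and len(set(map(str, batches))) > 1:
        fc, passthrough = correct_batch(fc, batches)
        if passthrough.any():
            fallbacks.append(
                f"batch correction passed through {int(passthrough.sum())} rows"
            )
    filled, mask = impute_missing(
        fc, width_factor=impute_width, downshift_factor=impute_downshift, seed=seed
    )

    combined_rows = []
    rep_rows = []
    for pair in pairs:
        snp = pair.snp_id
        df = combined_per_locus[snp].copy()
        values = filled[snp].reindex(df["protein_id"]).to_numpy()
        df["log2fc_ref_over_alt"] = values
        df["imputed"] = mask[snp].reindex(df["protein_id"]).to_numpy()
        p = significance_outlier_test(
            values,
            df["mean_log10_intensity"].to_numpy(),
            mode=mode,
            min_bin_size=min_bin_size,
        )
        df["p_value"] = p
        combined_rows.append(df)
        for col in ("oriented_ref_heavy", "oriented_alt_heavy"):
            rep_vals = df[col].to_numpy()
            rep_p = significance_outlier_test(
                rep_vals,
                df["mean_log10_intensity"].to_numpy(),
                mode=mode,
                min_bin_size=min_bin_size,
            )
            obs = np.isfinite(rep_vals)
            rep_rows.append(
                pd.DataFrame(
                    {
                        "snp_id": snp,
                        "protein_id": df["protein_id"].to_numpy()[obs],
                        "replicate": col.removeprefix("oriented_"),
                        "p_value": rep_p[obs],
                    }
                )
            )
    combined = pd.concat(combined_rows, ignore_index=True)
    replicate_pvalues = pd.concat(rep_rows, ignore_index=True)
    calls = call_interactors(combined, alpha=alpha, replicate_pvalues=replicate_pvalues)
    if mode == "B":
        n_obs_min = min(int(np.isfinite(fc[snp].to_numpy()).sum()) for snp in loci)
        if n_obs_min < min_bin_size:
            fallbacks.append("mode B fell back to mode A on at least one locus")
    return {
        "combined": combined,
        "calls": calls,
        "replicate_pvalues": replicate_pvalues,
        "fallbacks": fallbacks,
    }


def prioritize_screen(
    interactions: pd.DataFrame,
    dhs: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    threshold: float = 0.05,
    tf_annotation: Iterable[str] | None = None,
    include_single_replicate: bool = False,
    per_snp_fc: bool = False,
    normalize_depth: bool = False,
) -> dict:
    """Rank a screen's interactions by the combined accessibility / fold-
    change z and select its significant allele-specific binding events.

    The fold-change z-scores pool the absolute log2 fold change of *every*
    quantified interaction passed in (the screen-wide distribution), so a
    strong allelic switch stands out against the bulk of inert protein-DNA
    pairs.  When a ``calls`` table is given, an event is ``selected`` only
    if its combined p is below ``threshold`` *and* it is a called
    interactor confirmed in both label-swapped replicates (single-replicate
    calls are excluded unless ``include_single_replicate``); without
    ``calls`` the selection is purely ``p < threshold``.  A TF annotation
    restricts the ranking to annotated proteins.
    """
    ranked_input = interactions
    n_calls_all = len(calls) if calls is not None else None
    n_calls_tf = None
    if tf_annotation is not None:
        ranked_input = filter_to_tfs(ranked_input, tf_annotation)
        if calls is not None:
            n_calls_tf = len(filter_to_tfs(calls, tf_annotation))
    if len(ranked_input) < 2:
        logger.info("prioritize_screen: fewer than 2 rankable interactions")
        prioritized = pd.DataFrame(
            columns=[
                "rank",
                "snp_id",
                "protein_id",
                "log2fc_ref_over_alt",
                "abs_log2fc",
                "z_fc",
                "z_dhs",
                "z_avg",
                "p_combined",
                "is_call",
                "selected",
            ]
        )
        selected = prioritized.copy()
    else:
        prioritized = prioritize_interactions(
            ranked_input,
            dhs,
            threshold=threshold,
            per_snp_fc=per_snp_fc,
            normalize_depth=normalize_depth,
        )
        if calls is not None:
            callable_calls = calls
            if not include_single_replicate and "single_replicate" in calls.columns:
                callable_calls = calls[~calls["single_replicate"].astype(bool)]
            call_keys = set(zip(callable_calls["snp_id"], callable_calls["protein_id"]))
            prioritized["is_call"] = [
                key in call_keys
                for key in zip(prioritized["snp_id"], prioritized["protein_id"])
            ]
            prioritized["selected"] &= prioritized["is_call"]
        else:
            prioritized["is_call"] = True
        selected = select_events(
            prioritized[prioritized["selected"]], threshold=threshold
        )
    return {
        "prioritized": prioritized,
        "selected": selected,
        "counts": {
            "n_calls": n_calls_all,
            "n_calls_tf_annotated": n_calls_tf,
            "n_ranked": len(prioritized),
            "n_selected": len(selected),
        },
    }


def run_screen_synthetic(
    spec: ScreenSpec,
    config: RunConfig | None = None,
    high_dhs_loci: Iterable[str] = (),
    dhs_enrichment: float = 10.0,
    tf_annotation: Iterable[str] | None = None,
) -> dict:
    """Synthesize a screen and run quantification + prioritization on it.

    Convenience wrapper used by tests and the acceptance script; returns the
    ground-truth ledger alongside every stage output.
    """
    config = config or RunConfig(seed=spec.seed)
    pairs, ledger = generate_pulldown_tables(spec)
    dhs, dhs_ledger = generate_dhs_table(
        spec, high_dhs_loci=high_dhs_loci, enrichment=dhs_enrichment
    )
    quant = quantify_screen(
        pairs,
        batches=spec.batch_labels,
        mode=config.significance_mode,
        min_bin_size=config.min_bin_size,
        alpha=config.alpha_interactor,
        impute_width=config.impute_width,
        impute_downshift=config.impute_downshift,
        seed=spec.seed,
    )
    pri = prioritize_screen(
        quant["combined"],
        dhs,
        calls=quant["calls"],
        threshold=config.threshold_prioritize,
        tf_annotation=tf_annotation,
        include_single_replicate=config.include_single_replicate,
        per_snp_fc=config.per_snp_fc,
        normalize_depth=config.normalize_dhs_depth,
    )
    return {
        "ledger": ledger,
        "dhs_ledger": dhs_ledger,
        "dhs": dhs,
        **quant,
        **pri,
    }


def _manifest(config: RunConfig, extra: Mapping) -> dict:
    manifest = {"pwaskit_version": __version__, "config": dataclasses.asdict(config)}
    if manifest["config"].get("batch_labels") is not None:
        manifest["config"]["batch_labels"] = list(manifest["config"]["batch_labels"])
    manifest.update(extra)
    return manifest


def simulate_to_dir(spec: ScreenSpec, outdir: str | Path, tf_fraction: float = 0.3) -> dict:
    """Write a full synthetic screen (pulldowns, DHS, TF list, ledger)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs, ledger = generate_pulldown_tables(spec)
    pulldown_dir = outdir / "pulldowns"
    for pair in pairs:
        pio.write_pulldown_pair(pair, pulldown_dir)
    dhs, dhs_ledger = generate_dhs_table(spec)
    pio.write_dhs_table(dhs, outdir / "dhs_counts.tsv")
    tfs = generate_tf_annotation(spec, ledger, tf_fraction=tf_fraction)
    pio.write_tf_annotation(tfs, outdir / "tf_annotation.txt")
    pio.write_json({**ledger, **dhs_ledger}, outdir / "ground_truth.json")
    pio.write_json(
        {"spec": {**dataclasses.asdict(spec), "batch_labels": list(spec.batch_labels or []) or None}},
        outdir / "screen_spec.json",
    )
    return {"pairs": pairs, "ledger": ledger, "dhs": dhs, "tfs": tfs}


def run_screen(
    pulldown_dir: str | Path,
    dhs_path: str | Path,
    outdir: str | Path,
    config: RunConfig,
    tf_path: str | Path | None = None,
) -> dict:
    """File-level screen run: quantify + prioritize + report bundle.

    Writes ``interactors.tsv``, ``combined.tsv``, ``prioritized.tsv``,
    ``selected.tsv``, ``counts.json`` and ``manifest.json``.  Identical
    inputs, config and seed reproduce the outputs byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = pio.read_pulldown_dir(pulldown_dir)
    dhs = pio.read_dhs_table(dhs_path)
    tfs = pio.read_tf_annotation(tf_path) if tf_path else None
    quant = quantify_screen(
        pairs,
        batches=config.batch_labels,
        mode=config.significance_mode,
        min_bin_size=config.min_bin_size,
        alpha=config.alpha_interactor,
        impute_width=config.impute_width,
        impute_downshift=config.impute_downshift,
        seed=config.seed,
    )
    pri = prioritize_screen(
        quant["combined"],
        dhs,
        calls=quant["calls"],
        threshold=config.threshold_prioritize,
        tf_annotation=tfs,
        include_single_replicate=config.include_single_replicate,
        per_snp_fc=config.per_snp_fc,
        normalize_depth=config.normalize_dhs_depth,
    )
    pio.write_table(quant["combined"], outdir / "combined.tsv")
    pio.write_table(quant["calls"], outdir / "interactors.tsv")
    pio.write_table(pri["prioritized"], outdir / "prioritized.tsv")
    pio.write_table(pri["selected"], outdir / "selected.tsv")
    pio.write_json(pri["counts"], outdir / "counts.json")
    pio.write_json(
        _manifest(
            config,
            {
                "stage": "screen",
                "inputs": {
                    "pulldown_dir": str(pulldown_dir),
                    "dhs": str(dhs_path),
                    "tf_annotation": str(tf_path) if tf_path else None,
                },
                "fallbacks": quant["fallbacks"],
                "counts": pri["counts"],
            },
        ),
        outdir / "manifest.json",
    )
    return {**quant, **pri}


def run_4c(
    fasta_path: str | Path,
    bed_paths: Mapping[str, str | Path],
    outdir: str | Path,
    config: RunConfig,
    viewpoint: tuple[str, int, int] | None = None,
) -> dict:
    """File-level 4C run: digest -> reduced genome -> window counts.

    Writes ``sites.bed``, ``reduced_genome.fasta``, ``reduced_genome.tsv``,
    ``windows.tsv`` and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = pio.read_fasta(fasta_path)
    sites = digest_enzyme(contigs, config.enzyme)
    entries, dropped = build_reduced_genome(contigs, sites, flank_len=config.flank_len)
    reads = {cond: pio.read_bed(p) for cond, p in bed_paths.items()}
    windows = window_interactions(
        reads,
        viewpoint=viewpoint,
        window=config.window,
        step=config.step,
        contig_lengths={name: len(seq) for name, seq in contigs.items()},
    )
    pio.write_sites_bed(sites, outdir / "sites.bed")
    pio.write_reduced_genome_fasta(entries, outdir / "reduced_genome.fasta")
    pio.write_table(entries, outdir / "reduced_genome.tsv")
    pio.write_table(windows, outdir / "windows.tsv")
    pio.write_json(
        _manifest(
            config,
            {
                "stage": "4c",
                "inputs": {
                    "fasta": str(fasta_path),
                    "beds": {c: str(p) for c, p in bed_paths.items()},
                },
                "counts": {
                    "n_sites": len(sites),
                    "n_reduced_entries": len(entries),
                    "n_edge_dropped": len(dropped),
                    "n_windows": len(windows),
                },
            },
        ),
        outdir / "manifest.json",
    )
    return {"sites": sites, "entries": entries, "dropped": dropped, "windows": windows}
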