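"""Synthetic inputs with known ground truth for the whole screen pipeline.

The generators emulate every input the pipeline consumes:

* paired-allele DNA-pulldown protein quantification tables (two label-swapped
  replicates per SNP locus, with spiked-in allele-specific binders, log-normal
  intensities, intensity-dependent missingness and per-batch offsets);
* a DNase I hypersensitivity read-count table (loci x accessibility samples);
* a transcription-factor annotation list;
* allele count tables at heterozygous sites;
* a toy genome (FASTA contigs) with planted restriction sites and mapped
  read positions for the 4C utilities.

Every generator is deterministic given the same spec and seed, and returns a
ground-truth ledger alongside the data so downstream stages can be scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import stage_seed

logger = logging.getLogger(__name__)

REF_HEAVY = "REF_HEAVY"
ALT_HEAVY = "ALT_HEAVY"

_BASES = np.array(list("ACGT"))

#: Fraction of the batch-offset scale, matching the location-shift component
#: the correction stage removes.
BATCH_OFFSET_SD = 0.5

#: Intensity model: log10 intensity ~ Normal(7, 1). Arbitrary but realistic
#: span for summed MS intensities; only relative binning matters downstream.
INTENSITY_LOG10_MEAN = 7.0
INTENSITY_LOG10_SD = 1.0


@dataclass(frozen=True)
class ScreenSpec:
    """Design of one synthetic paired-allele pulldown screen.

    Parameters
    ----------
    n_loci
        Number of SNP loci; each locus yields two label-swapped pulldowns.
    n_background_proteins
        Proteins quantified per pulldown (the shared protein universe).
    n_spiked_binders
        True allele-specific proteins spiked into the screen.
    spike_log2fc
        True log2 Ref/Alt effect size of each spike (sign drawn per binder).
    noise_sd
        Standard deviation of the per-replicate log-ratio noise.
    missing_rate_low_intensity
        Probability that a bottom-quartile-intensity ratio is missing (MNAR).
    n_dhs_samples
        Number of accessibility samples in the DHS table (the study design
        pools 15 fetal large intestine tissues and 12 CRC cell lines).
    batch_labels
        Optional batch label per locus pulldown pair; ``None`` means a single
        batch (no offsets applied).
    seed
        Master random seed for all generators.
    """

    n_loci: int = 116
    n_background_proteins: int = 1000
    n_spiked_binders: int = 20
    spike_log2fc: float = 4.0
    noise_sd: float = 0.3
    missing_rate_low_intensity: float = 0.1
    n_dhs_samples: int = 27
    batch_labels: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_loci", "n_background_proteins", "n_dhs_samples"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_spiked_binders < 0:
            raise ValueError("n_spiked_binders must be >= 0")
        if self.n_spiked_binders > self.n_background_proteins:
            raise ValueError(
                "spike count exceeds background protein count: "
                f"{self.n_spiked_binders} > {self.n_background_proteins}"
            )
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.missing_rate_low_intensity < 1:
            raise ValueError("missing_rate_low_intensity must be in [0, 1)")
        if self.batch_labels is not None and len(self.batch_labels) != self.n_loci:
            raise ValueError(
                "batch_labels must have one entry per locus pulldown pair"
            )

    @property
    def locus_ids(self) -> list[str]:
        return [f"snp_{i:04d}" for i in range(self.n_loci)]

    @property
    def protein_ids(self) -> list[str]:
        return [f"prot_{i:05d}" for i in range(self.n_background_proteins)]


@dataclass
class PulldownPair:
    """One SNP's Ref-vs-Alt pulldown experiment (two label-swapped replicates).

    Each replicate table has columns ``protein_id``, ``log2_ratio``
    (heavy over light channel; NaN when missing), ``intensity`` and
    ``orientation`` (``REF_HEAVY`` or ``ALT_HEAVY``).
    """

    snp_id: str
    ref_allele: str
    alt_allele: str
    replicates: tuple = field(default_factory=tuple)


def generate_pulldown_tables(spec: ScreenSpec) -> tuple[list[PulldownPair], dict]:
    """Simulate the paired-allele pulldown tables for a whole screen.

    Replicate 1 is Ref-heavy and replicate 2 Alt-heavy; the stored ratio is
    always heavy/light, so a true Ref-preferring binder shows a positive
    stored ratio in replicate 1 and a negative one in replicate 2.  Batch
    offsets (Normal(0, 0.5) per batch) are additive on the oriented Ref/Alt
    scale, so they survive label-swap combining and are removable by the
    batch-correction stage.  Missingness is injected preferentially at
    bottom-quartile intensities (missing-not-at-random).

    Returns the pulldown pairs and a ground-truth ledger listing every
    (locus, protein, true effect) spike, the batch offsets and the alleles.
    """
    rng = np.random.default_rng(stage_seed(spec.seed, "pulldown"))
    loci = spec.locus_ids
    proteins = np.array(spec.protein_ids)
    n = spec.n_background_proteins

    # Spikes: distinct proteins, each assigned to one locus, sign per binder.
    spike_proteins = rng.choice(n, size=spec.n_spiked_binders, replace=False)
    spike_loci = rng.integers(0, spec.n_loci, size=spec.n_spiked_binders)
    spike_signs = rng.choice([-1.0, 1.0], size=spec.n_spiked_binders)

    effects: dict[int, np.ndarray] = {}
    spikes_ledger = []
    for p_idx, l_idx, sign in zip(spike_proteins, spike_loci, spike_signs):
        effects.setdefault(int(l_idx), np.zeros(n))
        effects[int(l_idx)][int(p_idx)] = sign * spec.spike_log2fc
        spikes_ledger.append(
            {
                "snp_id": loci[int(l_idx)],
                "protein_id": str(proteins[int(p_idx)]),
                "true_log2fc": float(sign * spec.spike_log2fc),
            }
        )

    batch_labels = (
        list(spec.batch_labels) if spec.batch_labels is not None else ["batch0"] * spec.n_loci
    )
    offsets = {
        b: (float(rng.normal(0.0, BATCH_OFFSET_SD)) if spec.batch_labels is not None else 0.0)
        for b in sorted(set(map(str, batch_labels)))
    }

    pairs: list[PulldownPair] = []
    alleles_ledger = {}
    for l_idx, snp in enumerate(loci):
        ref, alt = rng.choice(4, size=2, replace=False)
        ref_allele, alt_allele = str(_BASES[ref]), str(_BASES[alt])
        alleles_ledger[snp] = {"ref": ref_allele, "alt": alt_allele}
        true = effects.get(l_idx, np.zeros(n))
        offset = offsets[str(batch_labels[l_idx])]
        reps = []
        for orientation, sign in ((REF_HEAVY, 1.0), (ALT_HEAVY, -1.0)):
            oriented = true + offset + rng.normal(0.0, spec.noise_sd, size=n)
            stored = sign * oriented
            intensity = 10.0 ** rng.normal(
                INTENSITY_LOG10_MEAN, INTENSITY_LOG10_SD, size=n
            )
            q25 = np.quantile(intensity, 0.25)
            missing = (intensity <= q25) & (
                rng.random(n) < spec.missing_rate_low_intensity
            )
            stored = stored.copy()
            stored[missing] = np.nan
            reps.append(
                pd.DataFrame(
                    {
                        "protein_id": proteins,
                        "log2_ratio": stored,
                        "intensity": intensity,
                        "orientation": orientation,
                    }
                )
            )
        pairs.append(PulldownPair(snp, ref_allele, alt_allele, tuple(reps)))

    ledger = {
        "loci": loci,
        "alleles": alleles_ledger,
        "spikes": spikes_ledger,
        "batch_labels": {snp: str(b) for snp, b in zip(loci, batch_labels)},
        "batch_offsets": offsets,
    }
    return pairs, ledger


def generate_dhs_table(
    spec: ScreenSpec,
    high_dhs_loci: Iterable[str] = (),
    base_mean: float = 20.0,
    enrichment: float = 10.0,
    dispersion: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a DNase I read-count table (loci x accessibility samples).

    Counts are negative-binomial with mean ``base_mean`` (variance
    ``mean + dispersion * mean**2``); loci in ``high_dhs_loci`` receive an
    ``enrichment``-fold elevated mean.  Returns the count table (rows indexed
    by locus id) and a ledger of per-locus expected counts.
    """
    loci = spec.locus_ids
    high = set(high_dhs_loci)
    unknown = high - set(loci)
    if unknown:
        raise ValueError(f"unknown locus id(s) in high_dhs_loci: {sorted(unknown)}")
    rng = np.random.default_rng(stage_seed(spec.seed, "dhs"))
    means = np.array(
        [base_mean * enrichment if snp in high else base_mean for snp in loci]
    )
    shape = (spec.n_loci, spec.n_dhs_samples)
    if dispersion <= 0:
        counts = rng.poisson(means[:, None], size=shape)
    else:
        r = 1.0 / dispersion
        p = r / (r + means)
        counts = rng.negative_binomial(r, p[:, None], size=shape)
    table = pd.DataFrame(
        counts,
        index=pd.Index(loci, name="locus_id"),
        columns=[f"sample_{j:02d}" for j in range(spec.n_dhs_samples)],
    )
    ledger = {"expected_counts": {snp: float(m) for snp, m in zip(loci, means)}}
    return table, ledger


def generate_tf_annotation(
    spec: ScreenSpec,
    ledger: Mapping | None = None,
    tf_fraction: float = 0.3,
) -> list[str]:
    """Simulate a TF annotation list (a subset of the protein universe).

    A random ``tf_fraction`` of background proteins is annotated; spiked
    binders listed in the pulldown ``ledger`` are always annotated, mirroring
    a screen whose true allele-specific binders are transcription factors.
    """
    rng = np.random.default_rng(stage_seed(spec.seed, "tf_annotation"))
    proteins = spec.protein_ids
    k = int(round(tf_fraction * len(proteins)))
    chosen = set(rng.choice(len(proteins), size=k, replace=False).tolist())
    tfs = {proteins[i] for i in chosen}
    if ledger is not None:
        tfs.update(s["protein_id"] for s in ledger.get("spikes", []))
    return sorted(tfs)


def generate_allele_counts(
    n_sites: int = 6,
    depth: int = 50,
    assays: Sequence[str] = ("chip",),
    ref_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate Ref/Alt read counts at heterozygous sites for exact testing.

    Each (site, assay) draws ``ref_count ~ Binomial(depth, f)`` with
    ``f = 0.5`` unless overridden in ``ref_fractions`` (site_id -> true Ref
    read fraction).  Background columns are left unset (the test substitutes
    a matched-depth 50:50 expectation).  Returns the long table and a ledger
    of true fractions.
    """
    if n_sites < 1 or depth < 1:
        raise ValueError("n_sites and depth must be >= 1")
    rng = np.random.default_rng(stage_seed(seed, "allele_counts"))
    sites = [f"site_{i:03d}" for i in range(n_sites)]
    fractions = {s: 0.5 for s in sites}
    if ref_fractions:
        unknown = set(ref_fractions) - set(sites)
        if unknown:
            raise ValueError(f"unknown site id(s): {sorted(unknown)}")
        fractions.update({s: float(f) for s, f in ref_fractions.items()})
    rows = []
    for site in sites:
        for assay in assays:
            ref = int(rng.binomial(depth, fractions[site]))
            rows.append(
                {
                    "site_id": site,
                    "assay": assay,
                    "ref_count": ref,
                    "alt_count": depth - ref,
                    "background_ref": pd.NA,
                    "background_alt": pd.NA,
                }
            )
    return pd.DataFrame(rows), {"true_ref_fraction": fractions}


def generate_toy_genome(
    n_contigs: int = 1,
    length: int = 10_000,
    site_density: float = 0.001,
    seed: int = 0,
    alphabet: str = "ACGT",
    site: str = "CATG",
) -> tuple[dict[str, str], list[tuple[str, int]], list[tuple[str, int]]]:
    """Random contigs with restriction sites planted at recorded positions.

    No accidental-site suppression is attempted: the returned ``sites`` list
    is recomputed by exhaustive substring scan over the final sequences, so
    it includes both planted and chance occurrences.  Restricting
    ``alphabet`` (e.g. to ``"ACT"``) prevents chance occurrences entirely.

    Returns ``(contigs, sites, planted)`` where ``sites`` and ``planted``
    are lists of ``(contig_id, 0-based position)``.
    """
    if length < 100:
        raise ValueError("length must be >= 100")
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if site_density < 0:
        raise ValueError("site_density must be >= 0")
    rng = np.random.default_rng(stage_seed(seed, "toy_genome"))
    letters = np.array(list(alphabet))
    contigs: dict[str, str] = {}
    planted: list[tuple[str, int]] = []
    k = len(site)
    for c in range(n_contigs):
        name = f"contig_{c:02d}"
        seq = letters[rng.integers(0, len(letters), size=length)]
        n_plant = int(round(length * site_density))
        taken: list[int] = []
        attempts = 0
        while len(taken) < n_plant and attempts < 50 * max(n_plant, 1):
            pos = int(rng.integers(0, length - k + 1))
            attempts += 1
            if all(abs(pos - t) >= k for t in taken):
                taken.append(pos)
        for pos in sorted(taken):
            seq[pos : pos + k] = list(site)
            planted.append((name, pos))
        contigs[name] = "".join(seq)
    sites = scan_sites(contigs, site)
    return contigs, sites, planted


def scan_sites(contigs: Mapping[str, str], site: str) -> list[tuple[str, int]]:
    """Exhaustive overlapping substring scan for ``site`` over all contigs."""
    out: list[tuple[str, int]] = []
    for name in contigs:
        seq = contigs[name].upper()
        start = seq.find(site)
        while start != -1:
            out.append((name, start))
            start = seq.find(site, start + 1)
    return out


def generate_4c_reads(
    contigs: Mapping[str, str],
    n_reads: int = 5000,
    conditions: Sequence[str] = ("cond_a", "cond_b"),
    enriched: tuple[str, int, int] | None = None,
    enriched_weight: float = 0.2,
    enrich_in: Sequence[str] = (),
    read_length: int = 30,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Simulate mapped 4C read positions (BED-like) per condition.

    Reads start uniformly over the genome; for conditions named in
    ``enrich_in`` a fraction ``enriched_weight`` of reads instead starts
    uniformly inside the ``enriched`` interval ``(contig, start, end)``,
    emulating a condition-specific contact gain.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(stage_seed(seed, "fourc_reads"))
    names = list(contigs)
    lengths = np.array([len(contigs[n]) for n in names])
    cum = np.cumsum(lengths)
    total = int(cum[-1])
    out: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        flat = rng.integers(0, total, size=n_reads)
        contig_idx = np.searchsorted(cum, flat, side="right")
        starts = flat - np.concatenate([[0], cum[:-1]])[contig_idx]
        read_contigs = np.array(names, dtype=object)[contig_idx]
        if enriched is not None and cond in set(enrich_in):
            e_contig, e_start, e_end = enriched
            take = rng.random(n_reads) < enriched_weight
            starts = starts.copy()
            starts[take] = rng.integers(e_start, e_end, size=int(take.sum()))
            read_contigs[take] = e_contig
        ends = np.minimum(
            starts + read_length,
            np.array([len(contigs[c]) for c in read_contigs]),
        )
        df = pd.DataFrame({"contig": read_contigs, "start": starts, "end": ends})
        out[cond] = df.sort_values(["contig", "start"], kind="stable").reset_index(
            drop=True
        )
    ledger = {
        "enriched": enriched,
        "enriched_weight": enriched_weight,
        "enrich_in": list(enrich_in),
    }
    return out, ledger
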