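"""Readers and writers for the pipeline's delimited-text interfaces.

Pulldown tables, DHS counts, interactor calls and window tables travel as
TSV; contigs and reduced genomes as FASTA (via Biopython); read positions as
three-column BED; ground-truth ledgers and run manifests as JSON.  Missing
log-ratios are encoded as ``NA``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import PulldownPair

_PULLDOWN_COLS = ["protein_id", "log2_ratio", "intensity", "orientation"]


def write_pulldown_pair(pair: PulldownPair, outdir: str | Path) -> list[Path]:
    """Write one pair as ``<snp>_rep{1,2}.tsv`` (NA for missing ratios)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rep in enumerate(pair.replicates, start=1):
        path = outdir / f"{pair.snp_id}_rep{i}.tsv"
        rep[_PULLDOWN_COLS].to_csv(path, sep="\t", index=False, na_rep="NA")
        paths.append(path)
    return paths


def read_pulldown_pair(
    snp_id: str, paths: Iterable[str | Path], ref_allele: str = "N", alt_allele: str = "N"
) -> PulldownPair:
    """Read the two replicate TSVs of one SNP back into a PulldownPair."""
    reps = tuple(
        pd.read_csv(p, sep="\t", na_values=["NA", ""], dtype={"protein_id": str})
        for p in paths
    )
    return PulldownPair(snp_id, ref_allele, alt_allele, reps)


def read_pulldown_dir(indir: str | Path) -> list[PulldownPair]:
    """Load every ``<snp>_rep{1,2}.tsv`` pair found in a directory."""
    indir = Path(indir)
    by_snp: dict[str, list[Path]] = {}
    for path in sorted(indir.glob("*_rep[12].tsv")):
        snp = path.name.rsplit("_rep", 1)[0]
        by_snp.setdefault(snp, []).append(path)
    pairs = []
    for snp, paths in sorted(by_snp.items()):
        if len(paths) != 2:
            raise ValueError(f"{snp}: expected 2 replicate files, found {len(paths)}")
        pairs.append(read_pulldown_pair(snp, paths))
    return pairs


def write_dhs_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="locus_id")


def read_dhs_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="locus_id")


def write_tf_annotation(tf_ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{tf}\n" for tf in tf_ids))


def read_tf_annotation(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA", ""])


def write_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_reduced_genome_fasta(entries: pd.DataFrame, path: str | Path) -> None:
    """One record per kept flank, id ``<site_id>/plus`` or ``<site_id>/minus``."""
    records = []
    for rec in entries.itertuples(index=False):
        records.append(SeqRecord(Seq(rec.flank_plus), id=f"{rec.site_id}/plus", description=""))
        records.append(SeqRecord(Seq(rec.flank_minus), id=f"{rec.site_id}/minus", description=""))
    SeqIO.write(records, str(path), "fasta")


def write_sites_bed(sites: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "contig": sites["contig"],
            "start": sites["position"],
            "end": sites["position"] + sites["recognition"].str.len(),
            "name": sites["site_id"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["contig", "start", "end"])
    df = df.iloc[:, :3]
    df.columns = ["contig", "start", "end"]
    return df


def write_bed(reads: pd.DataFrame, path: str | Path) -> None:
    reads[["contig", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
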