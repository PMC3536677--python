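"""Readers and writers for the on-disk formats.

Genome sequence goes to FASTA (via Biopython), gene models to GFF3 (1-based
inclusive on disk, 0-based half-open in memory), probe tracks to bedGraph
per factor/timepoint/replicate, peaks to BED6 with area and max enrichment
in extra columns, and tables to TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peaks import Peak, ProbeTrack
from .polii import Transcript


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(path, transcripts: list[Transcript]) -> None:
    """Write gene models as GFF3 gene/mRNA features (1-based inclusive)."""
    genes: dict[str, list[Transcript]] = {}
    for tx in transcripts:
        genes.setdefault(tx.gene_id or tx.transcript_id, []).append(tx)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, txs in genes.items():
            start = min(t.start for t in txs) + 1
            end = max(t.end for t in txs)
            strand = txs[0].strand
            fh.write(
                f"{txs[0].chrom}\tnotchpulse\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n"
            )
            for t in txs:
                fh.write(
                    f"{t.chrom}\tnotchpulse\tmRNA\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gid}\n"
                )


def read_gff3(path) -> list[Transcript]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "mRNA":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            out.append(
                Transcript(
                    transcript_id=attrs.get("ID", "?"),
                    chrom=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6],
                    gene_id=attrs.get("Parent"),
                )
            )
    return out


def write_bedgraph(path, track: ProbeTrack, time_index: int, rep_index: int) -> None:
    half = track.spacing / 2
    with open(path, "w") as fh:
        for pos, val in zip(track.positions, track.data[:, time_index, rep_index]):
            fh.write(f"{track.chrom}\t{int(pos - half)}\t{int(pos + half)}\t{val:.4f}\n")


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "value"], comment="t")


def write_peaks_bed(path, peaks: list[Peak]) -> None:
    """BED6 plus area and max-enrichment columns."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = int(min(1000, round(p.max_enrichment * 100)))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{p.time:g}min_{i}\t{score}\t.\t"
                f"{p.area:.1f}\t{p.max_enrichment:.3f}\n"
            )


def write_tsv(path, df: pd.DataFrame, index_label: str | None = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_m_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_JSONEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
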