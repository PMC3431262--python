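"""Readers and writers for the pipeline's file formats.

Sequence files go through Biopython. Small-RNA libraries are exchanged as
count-annotated FASTA (">id_xCOUNT", one record per distinct sequence);
tables are TSV with a commented header line naming units. All genomic
coordinates in emitted files are 1-based inclusive (GFF3 convention);
in-memory coordinates are 0-based half-open.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COUNT_RE = re.compile(r"_x(\d+)$")


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {id: sequence} with normalized alphabet."""
    return {rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_count_fasta(path: str | Path) -> dict[str, int]:
    """Read a collapsed library: headers end in '_xCOUNT'; returns {seq: count}.

    Records without the count suffix are taken as count 1. Counts for
    duplicate sequences are summed.
    """
    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COUNT_RE.search(rec.id)
        n = int(m.group(1)) if m else 1
        seq = normalize_seq(str(rec.seq))
        counts[seq] = counts.get(seq, 0) + n
    return counts


def write_count_fasta(counts: Mapping[str, int], path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, (seq, n) in enumerate(sorted(counts.items()), start=1):
            fh.write(f">{prefix}{i:06d}_x{n}\n{seq}\n")


def read_fastq_seqs(path: str | Path) -> list[str]:
    """Read raw reads from FASTQ (qualities ignored)."""
    return [normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_raw_fastq(counts: Mapping[str, int], adapter: str, path: str | Path) -> None:
    """Expand a collapsed library into raw FASTQ reads with 3' adapter appended."""
    with open(path, "w") as fh:
        i = 0
        for seq, n in sorted(counts.items()):
            raw = seq + adapter
            qual = "I" * len(raw)
            for _ in range(n):
                i += 1
                fh.write(f"@read{i:08d}\n{raw}\n+\n{qual}\n")


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_gff3(loci: Iterable, path: str | Path, source: str = "oryzamir") -> None:
    """Write accepted loci as miRNA_primary_transcript + miRNA features.

    Input items need attributes: name, chrom, start, end, strand (0-based
    half-open), mature_start, mature_end. Emitted coordinates are 1-based
    inclusive.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{source}\tmiRNA_primary_transcript\t{loc.start + 1}\t{loc.end}"
                f"\t.\t{loc.strand}\t.\tID={loc.name}\n"
            )
            fh.write(
                f"{loc.chrom}\t{source}\tmiRNA\t{loc.mature_start + 1}\t{loc.mature_end}"
                f"\t.\t{loc.strand}\t.\tID={loc.name}.mature;Derives_from={loc.name}\n"
            )


def read_gff3_intervals(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Read GFF3 features as (chrom, start0, end, strand, id) tuples."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            continue
        attr = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        out.append((f[0], int(f[3]) - 1, int(f[4]), f[6], attr.get("ID", "")))
    return out
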