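"""File-format layer: FASTA/FASTQ, GFF3 mature annotations, TSV tables.

Sequence formats go through Bio.SeqIO; tables through pandas. All readers
are gzip-transparent (a ``.gz`` suffix is detected by name).
"""
from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import CountMatrix, MatureArm, PrecursorRecord

GFF_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "frame",
    "attributes",
]


class FastqRead(NamedTuple):
    id: str
    sequence: str
    comment: str


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with _open_text(path, "wt") as handle:
        SeqIO.write(seqrecords, handle, "fasta")


def read_fastq(path) -> list[FastqRead]:
    """Read FASTQ into (id, sequence, comment) tuples.

    The comment is the free text after the first whitespace on the ``@``
    line; the synthetic-read generator stores per-read ground truth there.
    """
    reads = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            comment = rec.description[len(rec.id) :].strip()
            reads.append(FastqRead(rec.id, str(rec.seq), comment))
    return reads


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    """Write 4-line FASTQ records with constant 'I' quality."""
    with _open_text(path, "wt") as handle:
        for read in reads:
            header = f"@{read.id} {read.comment}".rstrip()
            handle.write(
                f"{header}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n"
            )


# ---------------------------------------------------------------------------
# Precursor reference: FASTA + GFF3-like mature annotation
# ---------------------------------------------------------------------------

def write_mature_gff(precursors: Sequence[PrecursorRecord], path) -> None:
    """Write mature-arm coordinates as GFF3 rows (1-based, inclusive)."""
    rows = []
    for pre in precursors:
        for arm in pre.mature_arms:
            rows.append(
                [
                    pre.id,
                    "mirgrad",
                    "miRNA",
                    arm.start + 1,  # GFF3 is 1-based inclusive
                    arm.end,
                    ".",
                    "+",
                    ".",
                    f"ID={arm.mature_id};arm={arm.arm}",
                ]
            )
    with _open_text(path, "wt") as handle:
        handle.write("##gff-version 3\n")
        pd.DataFrame(rows, columns=GFF_COLUMNS).to_csv(
            handle, sep="\t", header=False, index=False
        )


def _parse_gff_attributes(text: str) -> dict[str, str]:
    pairs = [item.split("=", 1) for item in text.strip().split(";") if "=" in item]
    return {k.strip(): v.strip() for k, v in pairs}


def read_precursors(fasta_path, gff_path) -> list[PrecursorRecord]:
    """Assemble PrecursorRecords from a FASTA plus a mature-arm GFF3."""
    sequences = read_fasta(fasta_path)
    table = pd.read_csv(
        gff_path, sep="\t", comment="#", header=None, names=GFF_COLUMNS
    )
    arms_by_seq: dict[str, list[MatureArm]] = {}
    for row in table.itertuples(index=False):
        if row.type != "miRNA":
            continue
        attrs = _parse_gff_attributes(row.attributes)
        arms_by_seq.setdefault(row.seqid, []).append(
            MatureArm(
                arm=attrs.get("arm", "5p"),
                start=int(row.start) - 1,  # to 0-based half-open
                end=int(row.end),
                mature_id=attrs["ID"],
            )
        )
    precursors = []
    for seqid, seq in sequences.items():
        arms = arms_by_seq.get(seqid)
        if arms:
            precursors.append(PrecursorRecord(seqid, seq, tuple(arms)))
    return precursors


# ---------------------------------------------------------------------------
# Count matrices and generic tables
# ---------------------------------------------------------------------------

def write_counts(matrix: CountMatrix, path) -> None:
    """Write a count matrix TSV; library sizes go on a '#library_size' line."""
    with _open_text(path, "wt") as handle:
        sizes = "\t".join(str(int(v)) for v in matrix.library_size)
        handle.write(f"#library_size\t{sizes}\n")
        matrix.counts.rename_axis("mirna_id").to_csv(handle, sep="\t")


def read_counts(path) -> CountMatrix:
    library_size = None
    with _open_text(path) as handle:
        first = handle.readline()
        if first.startswith("#library_size"):
            library_size = [int(v) for v in first.rstrip("\n").split("\t")[1:]]
            buffer = handle.read()
        else:
            buffer = first + handle.read()
    counts = pd.read_csv(_io.StringIO(buffer), sep="\t", index_col=0)
    if library_size is not None:
        library_size = pd.Series(library_size, index=counts.columns)
    return CountMatrix(counts, library_size)


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_gene_list(path) -> list[str]:
    """Read one gene id per line, ignoring blanks and '#' comments."""
    with _open_text(path) as handle:
        return [
            line.strip()
            for line in handle
            if line.strip() and not line.startswith("#")
        ]


def read_config(path) -> dict:
    """Load a flat key-value configuration file (YAML mapping)."""
    with _open_text(path) as handle:
        config = yaml.safe_load(handle) or {}
    if not isinstance(config, dict):
        raise ValueError("configuration must be a flat key-value mapping")
    return config
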