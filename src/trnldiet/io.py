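"""File formats: FASTA/FASTQ records, tab-separated tables, and the
bundle writers used by the pipeline.

Parsing goes through Biopython's SeqIO; sequences are uppercased on read
and CRLF line endings are tolerated.  All tabular outputs are
tab-separated with headers.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reads import MIDMap, RawRead
from .reference import ReferenceSequence
from .taxonomy import Taxonomy


class ParseError(ValueError):
    pass


# ----------------------------------------------------------------------
# FASTA / FASTQ
# ----------------------------------------------------------------------

def _check_fasta_header(path) -> None:
    with open(path, "r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(f"{path}: line {lineno}: expected FASTA header starting with '>'")
            return


def read_fasta(path) -> list[RawRead]:
    """Read a FASTA file into records (sequences uppercased)."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    _check_fasta_header(path)
    return [RawRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path) -> list[RawRead]:
    """Read a FASTQ file; qualities are kept (phred+33) but unused downstream."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            records.append(RawRead(rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return records


def read_sequences(path) -> list[RawRead]:
    """Read FASTA or FASTQ, dispatching on file extension."""
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: list[RawRead], path) -> None:
    recs = [SeqRecord(Seq(r.seq), id=r.read_id, description="") for r in records]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: list[RawRead], path) -> None:
    recs = []
    for r in records:
        rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
        qual = r.qual if r.qual is not None else "I" * len(r.seq)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


# ----------------------------------------------------------------------
# tabular inputs
# ----------------------------------------------------------------------

def read_reference_fasta(path) -> list[ReferenceSequence]:
    """Reference intron FASTA: record id = species_id."""
    return [ReferenceSequence(r.read_id, r.seq) for r in read_fasta(path)]


def read_taxonomy(path) -> Taxonomy:
    return Taxonomy.from_tsv(path)


def read_midmap(path) -> MIDMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mid_tag", "sample_id"} <= set(df.columns):
        raise ParseError(f"{path}: MID map needs columns mid_tag, sample_id")
    return MIDMap(dict(zip(df["mid_tag"], df["sample_id"])))


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: metadata needs a sample_id column")
    return df


def read_presence_table(path) -> pd.DataFrame:
    """Samples x labels presence table (e.g. microhistology results)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return (df > 0).astype(int)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_midmap(mids: MIDMap, path) -> None:
    rows = [{"mid_tag": t, "sample_id": s} for t, s in mids.items()]
    write_tsv(pd.DataFrame(rows), path)


def write_cluster_fasta(clusters, path) -> None:
    """Cluster centroids with sample and read count in the header."""
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(f">{cl.cluster_id} sample={cl.sample_id} count={cl.read_count}\n")
            fh.write(cl.centroid_seq + "\n")


def frame_to_string(df: pd.DataFrame) -> str:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
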