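"""Readers and writers for the plain-text artifacts of a run.

FASTQ uses Sanger Phred+33 qualities.  The sample sheet is a TSV with the
header ``sample_id  barcode  host_species  termite_species``.
"""

from __future__ import annotations

import hashlib
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .readprep import SampleSpec, TaggedRead

SHEET_COLUMNS = ["sample_id", "barcode", "host_species", "termite_species"]


def read_fastq(path: str | Path) -> list[TaggedRead]:
    reads = []
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            quals = np.frombuffer(qual.encode(), np.uint8).astype(np.int16) - 33
            reads.append(TaggedRead(id=title.split()[0], bases=seq, quals=quals))
    return reads


def write_fastq(reads: Iterable[TaggedRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in reads:
            qual = (np.asarray(r.quals, np.uint8) + 33).tobytes().decode()
            handle.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with open(path) as handle:
        return [(title.split()[0], seq) for title, seq in SimpleFastaParser(handle)]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n{seq}\n")


def read_sample_sheet(path: str | Path) -> list[SampleSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    return [SampleSpec(**row[SHEET_COLUMNS].to_dict()) for _, row in df.iterrows()]


def write_sample_sheet(samples: Sequence[SampleSpec], path: str | Path) -> None:
    pd.DataFrame(
        [[s.sample_id, s.barcode, s.host_species, s.termite_species] for s in samples],
        columns=SHEET_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "sample_id") -> None:
    df.to_csv(path, sep="\t", index=True, index_label=index_label)


def sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def phylotype_fasta_records(phylotypes) -> list[tuple[str, str]]:
    """Representative records with id and total abundance in the header."""
    return [
        (f"{p.phylotype_id};size={p.total_abundance}", p.representative)
        for p in phylotypes
    ]


def counts_frame(mapping: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    return pd.DataFrame(mapping).fillna(0).astype(int)
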