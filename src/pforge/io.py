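"""File-format helpers: FASTA, prophage tables, depth tracks, event CSVs.

Thin wrappers over Biopython and pandas that pin down the dialects the
package consumes and produces: FASTA for sequences, a tab-separated
prophage table (prophage, host, left, right, locus) with 1-based
inclusive printed-style coordinates, 3-column per-base depth TSVs
(replicon, position, depth), and flow-event CSVs with FSC-H/SSC-H/FL1-H
columns plus a sample sheet.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .attsite import AttSiteSet, ProphageRecord
from .errors import InputError
from .flow import CHANNELS


def read_fasta(path) -> dict[str, str]:
    """All records of a FASTA file as ``{id: uppercase sequence}``."""
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()),
        str(path),
        "fasta",
    )


PROPHAGE_TABLE_COLUMNS = ["prophage", "host", "left", "right", "locus"]


def read_prophage_table(path) -> list[ProphageRecord]:
    """TSV with columns prophage, host, left, right, locus (1-based incl.)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROPHAGE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"prophage table missing columns {missing}")
    return [
        ProphageRecord(
            host_id=str(row.host),
            left=int(row.left),
            right=int(row.right),
            locus_name=str(row.locus),
            name=str(row.prophage),
        )
        for row in df.itertuples()
    ]


def write_att_site_set(prefix, name: str, att: AttSiteSet) -> None:
    """Write one AttSiteSet as a sequence FASTA plus a summary TSV."""
    prefix = Path(prefix)
    write_fasta(
        prefix.with_suffix(".fasta"),
        {
            f"{name}_attL": att.attL,
            f"{name}_attR": att.attR,
            f"{name}_attB": att.attB,
            f"{name}_attP": att.attP,
        },
    )
    pd.DataFrame(
        [
            {
                "site_set": name,
                "crossover_start": att.crossover.start,
                "crossover_length": att.crossover.length,
                "crossover_sequence": att.crossover.sequence,
            }
        ]
    ).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)


def read_event_csv(path) -> pd.DataFrame:
    """Flow-cytometry event table with FSC-H, SSC-H, FL1-H columns."""
    df = pd.read_csv(path)
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise InputError(f"event table missing channels {missing}")
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    """TSV sample sheet: strain, strain_type, treatment, replicate, path."""
    df = pd.read_csv(path, sep="\t")
    needed = ["strain", "strain_type", "treatment", "replicate", "path"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InputError(f"sample sheet missing columns {missing}")
    return df


def write_termini_bed(path, replicon_id: str, termini: Iterable[tuple[int, float]]) -> None:
    """Coverage-step terminus calls as BED (0-based half-open) with scores."""
    rows = [
        {"chrom": replicon_id, "start": pos - 1, "end": pos, "name": f"terminus_{i+1}",
         "score": ratio}
        for i, (pos, ratio) in enumerate(termini)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
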