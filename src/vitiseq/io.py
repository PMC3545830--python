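"""Readers and writers for the pipeline's on-disk formats.

All tabular artifacts are tab-separated with a header row. Column layouts:

* catalog annotation: transcript_id, length, archetype, probeset_id,
  go_terms (';'-joined GO identifiers)
* reads: read_id, stage, length_after_trim, ambiguous_count
* alignment candidates: read_id, transcript_id, percent_identity,
  aligned_fraction
* probesets: probeset_id, suffix_class, transcript_id, evalue, EL31..EL38
* expression matrix: transcript_id + one RPKM column per stage, followed by
  one ``unique_<stage>`` column per stage

The catalog FASTA carries a random nucleotide sequence of each transcript's
declared length (sequence content is never analysed; only lengths matter).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .schema import TranscriptRecord


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_catalog_fasta(
    catalog: list[TranscriptRecord], path: str | Path, seed: int = 0
) -> Path:
    """Write one random-sequence FASTA record per transcript."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = (
        SeqRecord(
            Seq("".join(rng.choice(bases, size=r.length))),
            id=r.transcript_id,
            description=f"archetype={r.archetype} length={r.length}",
        )
        for r in catalog
    )
    SeqIO.write(records, str(path), "fasta")
    return path


def read_catalog_lengths(path: str | Path) -> pd.Series:
    """Transcript lengths from a catalog FASTA."""
    lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return pd.Series(lengths, name="length")


def annotation_go_map(annotation: pd.DataFrame) -> dict[str, frozenset[str]]:
    """transcript_id -> GO term set from a catalog annotation table."""
    out: dict[str, frozenset[str]] = {}
    for tid, cell in zip(annotation["transcript_id"], annotation["go_terms"]):
        if isinstance(cell, str) and cell:
            out[tid] = frozenset(cell.split(";"))
        else:
            out[tid] = frozenset()
    return out
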