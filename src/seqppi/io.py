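"""Plain-text I/O: FASTA sequence collections and pair-list TSVs.

Pair list format: three tab-separated columns ``idA  idB  label`` with
label 1 = binder, 0 = non-binder; lines starting with ``#`` are comments.
FASTA is written in a single-line-per-sequence dialect.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .curation import InteractionPair, SequenceRecord


def read_fasta(path: str | Path) -> dict[str, SequenceRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: dict[str, SequenceRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = SequenceRecord(id=rec.id, seq=str(rec.seq).upper())
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def write_fasta(
    records: Mapping[str, SequenceRecord] | Iterable[SequenceRecord], path: str | Path
) -> None:
    if isinstance(records, Mapping):
        records = records.values()
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_pairs_tsv(path: str | Path) -> list[InteractionPair]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pair list not found: {path}")
    pairs: list[InteractionPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            id_a, id_b, label = parts
            if label not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {label!r}")
            pairs.append(InteractionPair(id_a=id_a, id_b=id_b, label=int(label)))
    return pairs


def write_pairs_tsv(pairs: Sequence[InteractionPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# idA\tidB\tlabel\n")
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")
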