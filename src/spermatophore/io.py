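"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA goes through Biopython; tabular files are TSV with header rows
(counts, metadata, evidence, truth, GO map); hit tables use the
standard 12-column tabular dialect (see :mod:`spermatophore.orthology`);
semen-protein lists are one id per line with '#' comments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Set, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FLOAT_FORMAT = "%.6g"


def read_fasta(path) -> Dict[str, str]:
    """FASTA file -> ordered mapping id -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    records = [
        SeqRecord(Seq(seq), id=pid, description=descriptions.get(pid, ""))
        for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_counts(path) -> pd.DataFrame:
    """Counts TSV (first column gene id, one column per library)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_id_list(path) -> List[str]:
    """One id per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_id_list(ids: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def read_go_map(path) -> Dict[str, Set[str]]:
    """Two-column TSV (protein_id, class); repeated rows for multi-class."""
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, Set[str]] = {}
    for pid, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(pid, set()).add(label)
    return out


def write_go_map(go_map: Mapping[str, Set[str]], path) -> None:
    rows = [
        {"protein_id": pid, "go_class": label}
        for pid in go_map
        for label in sorted(go_map[pid])
    ]
    pd.DataFrame(rows, columns=["protein_id", "go_class"]).to_csv(
        path, sep="\t", index=False
    )


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
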