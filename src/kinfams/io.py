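"""Readers and writers for the package's plain-text formats.

FASTA goes through Biopython. Tabular formats are TSV with a header line and
``#`` comments:

* domain hits:     ``seq_id  family_id  start  stop  score``
* annotations:     ``seq_id  ec4  experimental`` (0/1 flag)
* drug records:    ``drug_id  target_seq_id  max_phase  assay_type  pchembl
  activity_nM  atc_code``
* family members:  ``funfam_id  seq_id  mda_key``

Merge trees serialise to Newick with quoted internal-node labels
``merge_order:merge_score``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence_domains import DomainHit, ProteinSequence

HIT_COLUMNS = ["seq_id", "family_id", "start", "stop", "score"]
ANNOTATION_COLUMNS = ["seq_id", "ec4", "experimental"]
DRUG_COLUMNS = [
    "drug_id",
    "target_seq_id",
    "max_phase",
    "assay_type",
    "pchembl",
    "activity_nM",
    "atc_code",
]


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def write_alignment_fasta(ids: list[str], rows: list[str], path: str | Path) -> None:
    records = [SeqRecord(Seq(r), id=i, description="") for i, r in zip(ids, rows)]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return ids, rows


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"seq_id": str, "family_id": str})
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing hit columns {sorted(missing)}")
    return [
        DomainHit(
            seq_id=row.seq_id,
            family_id=row.family_id,
            start=int(row.start),
            stop=int(row.stop),
            score=float(row.score),
        )
        for row in df.itertuples()
    ]


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [(h.seq_id, h.family_id, h.start, h.stop, h.score) for h in hits],
        columns=HIT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"seq_id": str, "ec4": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    df["experimental"] = df["experimental"].astype(int).astype(bool)
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["experimental"] = out["experimental"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_drug_records(path: str | Path):
    from .druggability import DrugRecord

    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"drug_id": str, "target_seq_id": str, "atc_code": str}
    )
    missing = set(DRUG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing drug columns {sorted(missing)}")
    return [
        DrugRecord(
            drug_id=row.drug_id,
            target_seq_id=row.target_seq_id,
            max_phase=int(row.max_phase),
            assay_type=str(row.assay_type),
            pchembl=float(row.pchembl),
            activity_nM=float(row.activity_nM),
            atc_code=str(row.atc_code),
        )
        for row in df.itertuples()
    ]


def write_drug_records(records, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                r.drug_id,
                r.target_seq_id,
                r.max_phase,
                r.assay_type,
                r.pchembl,
                r.activity_nM,
                r.atc_code,
            )
            for r in records
        ],
        columns=DRUG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_funfam_table(funfams, path: str | Path) -> None:
    rows = []
    for ff in funfams:
        mda = ";".join(sorted(str(m) for m in ff.mda_set))
        for member in ff.members:
            rows.append((ff.id, member, mda))
    pd.DataFrame(rows, columns=["funfam_id", "seq_id", "mda_key"]).to_csv(
        path, sep="\t", index=False
    )


def merge_tree_to_newick(tree) -> str:
    """Serialise a MergeTree: leaves labelled by cluster id, internal nodes
    by quoted ``merge_order:merge_score`` labels."""

    def render(node) -> str:
        if node.is_leaf:
            return _quote(node.cluster.id)
        label = f"{node.merge_order}:{node.merge_score:.4f}"
        return f"({render(node.left)},{render(node.right)}){_quote(label)}"

    return render(tree.root) + ";"


def _quote(label: str) -> str:
    return "'" + label.replace("'", "''") + "'"
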