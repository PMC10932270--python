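"""Sequence dataset I/O, class-ratio policy and stratified fold assignment.

Datasets are flat collections of labeled sequence windows, each assumed to be
centered (by default) on the candidate modified nucleotide. Sequences are read
from FASTA with a companion two-column label table (id, label); mixed T/U
alphabets are accepted verbatim and conversion is an explicit separate step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SequenceRecord",
    "Dataset",
    "FoldAssignment",
    "read_fasta_dataset",
    "write_fasta_dataset",
    "read_label_table",
    "rna_to_dna_alphabet",
    "dna_to_rna_alphabet",
    "apply_ratio_policy",
    "make_stratified_folds",
]

_RNA_DNA_OK = set("ACGUT")
_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled sequence window.

    ``site_index`` is the 0-based position of the candidate modified
    nucleotide; when ``None`` it defaults to the window center ``len(seq)//2``.
    """

    id: str
    sequence: str
    label: int
    site_index: int | None = None

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.site_index is not None and not (
            0 <= self.site_index < len(self.sequence)
        ):
            raise ValueError(
                f"site_index {self.site_index} out of range for record {self.id!r}"
            )

    @property
    def site(self) -> int:
        """Resolved candidate-site position (defaults to the window center)."""
        return self.site_index if self.site_index is not None else len(self.sequence) // 2


@dataclass
class Dataset:
    """Ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord]
    name: str = "dataset"

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_positive(self) -> int:
        return sum(r.label == 1 for r in self.records)

    @property
    def n_negative(self) -> int:
        return sum(r.label == 0 for r in self.records)

    @property
    def ratio(self) -> float:
        """Negative-to-positive count ratio."""
        if self.n_positive == 0:
            raise ValueError("ratio undefined: dataset has no positive records")
        return self.n_negative / self.n_positive

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def subset(self, ids, name: str | None = None) -> "Dataset":
        wanted = set(ids)
        return Dataset(
            [r for r in self.records if r.id in wanted],
            name=name or self.name,
        )


@dataclass
class FoldAssignment:
    """Stratified fold assignment: record id -> fold index in [0, n_folds)."""

    n_folds: int
    assignment: dict[str, int] = field(default_factory=dict)

    def fold_ids(self, fold: int) -> list[str]:
        return [rid for rid, f in self.assignment.items() if f == fold]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tfold\n")
            for rid, f in self.assignment.items():
                fh.write(f"{rid}\t{f}\n")


def read_label_table(path) -> dict[str, int]:
    """Read a two-column (id, label) table; delimiter and header are sniffed."""
    text = Path(path).read_text().strip()
    if not text:
        raise ValueError(f"empty label table: {path}")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows = list(csv.reader(text.splitlines(), delimiter=delimiter))
    labels: dict[str, int] = {}
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise ValueError(f"label table row {i} has fewer than 2 columns: {row}")
        rid, lab = row[0].strip(), row[1].strip()
        if i == 0 and not lab.lstrip("+-").isdigit():
            continue  # header row
        labels[rid] = int(lab)
    return labels


def read_fasta_dataset(fasta_path, label_table_path, name: str | None = None) -> Dataset:
    """Read FASTA + label table into a :class:`Dataset`.

    Input order is preserved and sequences are upper-cased; any FASTA id
    missing from the label table is a hard error.
    """
    labels = read_label_table(label_table_path)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in labels:
            raise KeyError(f"FASTA id {rec.id!r} missing from label table")
        records.append(
            SequenceRecord(id=rec.id, sequence=str(rec.seq).upper(), label=labels[rec.id])
        )
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return Dataset(records, name=name or Path(fasta_path).stem)


def write_fasta_dataset(dataset: Dataset, fasta_path, label_table_path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in dataset
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    with open(label_table_path, "w") as fh:
        fh.write("id\tlabel\n")
        for r in dataset:
            fh.write(f"{r.id}\t{r.label}\n")


def rna_to_dna_alphabet(sequence: str, permissive: bool = False) -> str:
    """Map an RNA sequence to the DNA alphabet: every U becomes T.

    Characters other than A/C/G/U/T are rejected; in ``permissive`` mode IUPAC
    ambiguity codes are mapped to ``N`` (which tokenizes to [UNK]).
    """
    out = []
    for ch in sequence.upper():
        if ch in _RNA_DNA_OK:
            out.append("T" if ch == "U" else ch)
        elif permissive and ch in _IUPAC_AMBIGUOUS:
            out.append("N")
        else:
            raise ValueError(f"invalid nucleotide {ch!r} in sequence")
    return "".join(out)


def dna_to_rna_alphabet(sequence: str) -> str:
    """Inverse alphabet map: every T becomes U."""
    return sequence.upper().replace("T", "U")


def apply_ratio_policy(
    dataset: Dataset,
    trigger_ratio: float = 10.0,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> Dataset:
    """Random under-sampling of negatives for heavily imbalanced training sets.

    If negatives/positives exceeds ``trigger_ratio``, negatives are sub-sampled
    (without replacement, seeded) down to ``target_ratio`` x positives;
    otherwise the dataset is returned unchanged. Positives are never touched.
    This policy is meant for training splits only — evaluation sets keep their
    natural imbalance.
    """
    if target_ratio < 1:
        raise ValueError("target_ratio must be >= 1")
    n_pos = dataset.n_positive
    if n_pos == 0:
        raise ValueError("ratio policy requires at least one positive record")
    if dataset.ratio <= trigger_ratio:
        return dataset
    negatives = [r for r in dataset.records if r.label == 0]
    n_keep = min(len(negatives), int(round(target_ratio * n_pos)))
    rng = np.random.default_rng(seed)
    keep_idx = set(rng.choice(len(negatives), size=n_keep, replace=False).tolist())
    kept_neg_ids = {negatives[i].id for i in keep_idx}
    records = [r for r in dataset.records if r.label == 1 or r.id in kept_neg_ids]
    return Dataset(records, name=dataset.name)


def make_stratified_folds(dataset: Dataset, n_folds: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold assignment; per-class fold sizes differ by at most 1."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = dataset.labels()
    for cls in (0, 1):
        if int((y == cls).sum()) < n_folds:
            raise ValueError(
                f"class {cls} has fewer than n_folds={n_folds} members"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    ids = [r.id for r in dataset.records]
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            assignment[ids[i]] = fold
    return FoldAssignment(n_folds=n_folds, assignment=assignment)
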