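"""Reading, validation and redundancy filtering of nucleotide sequence datasets.

The unit of all I/O is :class:`SequenceRecord` — one identified cDNA/DNA
sequence.  Labeled collections pair each record with a class name drawn from a
declared label set (e.g. ``{resistant, non-resistant}`` or the seven
herbicide-target enzyme classes).  FASTA input may be plain or gzipped; labels
come from a two-column TSV (id, label) or are assigned uniformly per file.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SequenceRecord",
    "LabeledDataset",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "load_labeled_dataset",
    "sanitize_sequence",
    "pairwise_identity",
    "greedy_redundancy_filter",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One identified nucleotide sequence.

    ``residues`` is kept uppercase over {A,C,G,T} plus IUPAC ambiguity codes;
    downstream encoders decide how to treat non-ACGT positions.
    """

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Parallel lists of records and class labels over a declared label set."""

    records: list[SequenceRecord]
    labels: list[str]
    label_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"records ({len(self.records)}) and labels ({len(self.labels)}) "
                "must have equal length"
            )
        if not self.label_set:
            self.label_set = frozenset(self.labels)
        bad = sorted(set(self.labels) - self.label_set)
        if bad:
            raise ValueError(f"labels outside the declared label set: {bad}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id in dataset: {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, label: str) -> list[SequenceRecord]:
        return [r for r, l in zip(self.records, self.labels) if l == label]


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into SequenceRecords.

    The header token before the first whitespace becomes the id, the remainder
    the description.  Errors on a malformed first line, empty sequences and
    duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    with _open_text(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first.startswith(">"):
            raise ValueError(f"{path}: not FASTA — first non-blank line lacks '>'")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for entry in SeqIO.parse(fh, "fasta"):
            residues = str(entry.seq)
            if not residues:
                raise ValueError(f"{path}: entry {entry.id!r} has an empty sequence")
            if entry.id in seen:
                raise ValueError(f"{path}: duplicate id {entry.id!r}")
            seen.add(entry.id)
            desc = entry.description
            desc = desc[len(entry.id):].strip() if desc.startswith(entry.id) else desc
            records.append(SequenceRecord(entry.id, desc, residues))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (60-column wrapped), preserving descriptions."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column delimited (tab or comma) id→label file."""
    path = Path(path)
    labels: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            labels[parts[0].strip()] = parts[1].strip()
    return labels


def load_labeled_dataset(
    fasta_path: str | Path,
    labels_path: str | Path | None = None,
    *,
    label: str | None = None,
    label_set: Iterable[str] | None = None,
) -> LabeledDataset:
    """Build a LabeledDataset from FASTA + per-id label file, or one uniform label.

    Ids present in the FASTA but missing from the label file are an error.
    """
    if (labels_path is None) == (label is None):
        raise ValueError("provide exactly one of labels_path or label")
    records = read_fasta(fasta_path)
    if label is not None:
        labels = [label] * len(records)
    else:
        table = read_labels(labels_path)
        missing = [r.id for r in records if r.id not in table]
        if missing:
            raise ValueError(f"ids without labels in {labels_path}: {missing[:10]}")
        labels = [table[r.id] for r in records]
    declared = frozenset(label_set) if label_set is not None else frozenset(labels)
    return LabeledDataset(records, labels, declared)


def sanitize_sequence(record: SequenceRecord) -> tuple[SequenceRecord, int]:
    """Normalize a record: uppercase, U→T; return it with a non-ACGT count.

    Ambiguity codes are retained (the encoder skips windows containing them);
    the caller decides whether to drop heavily ambiguous records.
    """
    residues = "".join(record.residues.split()).upper().replace("U", "T")
    if not residues:
        raise ValueError(f"record {record.id!r}: empty sequence after stripping")
    n_ambiguous = sum(1 for ch in residues if ch not in "ACGT")
    return replace(record, residues=residues), n_ambiguous


def _aligner(match: float, mismatch: float, gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    *,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = 0.0,
) -> float:
    """Global-alignment identity between two sequences, in [0, 1].

    Identity = identical aligned columns / length of the shorter sequence
    (the CD-HIT denominator convention).  With the default scoring
    (match +1, mismatch 0, gap 0) the number of identical columns in an
    optimal alignment is exactly the longest-common-subsequence length, so
    the value is parameter-tie-free; a negative ``gap`` gives a stricter,
    gap-averse alignment.
    """
    if not a.residues or not b.residues:
        raise ValueError("pairwise_identity requires non-empty sequences")
    aln = _aligner(match, mismatch, gap).align(a.residues, b.residues)[0]
    identities = aln.counts().identities
    return identities / min(len(a.residues), len(b.residues))


def greedy_redundancy_filter(
    records: Sequence[SequenceRecord],
    threshold: float,
    **identity_kwargs,
) -> list[SequenceRecord]:
    """Greedy longest-first redundancy removal at a pairwise-identity threshold.

    Records are visited by descending length (ties broken by id); each is
    retained iff its identity with every already-retained record is ≤
    ``threshold``.  A deterministic stand-in for CD-HIT clustering.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not records:
        raise ValueError("greedy_redundancy_filter requires at least one record")
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    retained: list[SequenceRecord] = []
    for rec in ordered:
        if all(
            pairwise_identity(rec, kept, **identity_kwargs) <= threshold
            for kept in retained
        ):
            retained.append(rec)
    original_order = {r.id: i for i, r in enumerate(records)}
    retained.sort(key=lambda r: original_order[r.id])
    return retained
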