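"""Reading, validating and labelling fixed-length DNA fragments.

The package works on datasets of equal-length DNA fragments (200 bp by
default) partitioned into labelled classes.  The three-class labelling
(strong enhancer / weak enhancer / non-enhancer) supports a two-layer view:

* layer I  — enhancers (strong + weak) versus non-enhancers;
* layer II — strong enhancers versus weak enhancers.

Generic binary tasks use the ``positive`` / ``negative`` labels instead.
Labels are never parsed out of FASTA headers; they are attached when a
per-class file is read, or taken from a two-column manifest TSV
(columns ``path`` and ``label``).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

STRONG_ENHANCER = "strong_enhancer"
WEAK_ENHANCER = "weak_enhancer"
NON_ENHANCER = "non_enhancer"
POSITIVE = "positive"
NEGATIVE = "negative"

KNOWN_LABELS = frozenset(
    {STRONG_ENHANCER, WEAK_ENHANCER, NON_ENHANCER, POSITIVE, NEGATIVE}
)

#: Labels counted as the positive class of the enhancer-vs-non-enhancer task.
LAYER1_POSITIVE = frozenset({STRONG_ENHANCER, WEAK_ENHANCER, POSITIVE})
LAYER1_NEGATIVE = frozenset({NON_ENHANCER, NEGATIVE})

VALID_BASES = frozenset("ACGT")
#: Single placeholder for any IUPAC ambiguity code under the "mask" policy.
MASK_CHAR = "N"


class FastaFormatError(ValueError):
    """Raised for files that cannot be parsed as FASTA."""


class SequenceValidationError(ValueError):
    """Raised when a record violates length or alphabet constraints."""


@dataclass(frozen=True)
class SequenceRecord:
    """One fixed-length DNA fragment with an identifier and a class label."""

    id: str
    seq: str
    label: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


def _clean_sequence(record_id: str, raw: str, ambiguous: str) -> str:
    """Uppercase a sequence and apply the ambiguity policy.

    ``ambiguous="reject"`` raises on any non-ACGT symbol; ``"mask"``
    replaces every such symbol with :data:`MASK_CHAR` so that downstream
    counting can skip it.
    """
    seq = raw.upper()
    if set(seq) <= VALID_BASES:
        return seq
    if ambiguous == "mask":
        return "".join(b if b in VALID_BASES else MASK_CHAR for b in seq)
    if ambiguous == "reject":
        bad = [(i + 1, b) for i, b in enumerate(seq) if b not in VALID_BASES]
        pos, sym = bad[0]
        raise SequenceValidationError(
            f"record '{record_id}': non-ACGT symbol '{sym}' at position {pos} "
            f"({len(bad)} offending position(s); use ambiguous='mask' to retain)"
        )
    raise ValueError(f"unknown ambiguity policy: {ambiguous!r}")


def read_fasta(
    path: str | Path,
    label: str,
    *,
    ambiguous: str = "reject",
    expected_length: int | None = None,
) -> list[SequenceRecord]:
    """Read one per-class FASTA file and attach ``label`` to every entry.

    Sequences are uppercased (soft-masked lowercase is treated as its
    uppercase base).  ``expected_length`` turns on strict-length mode:
    any entry of a different length raises, naming the entry.
    Gzipped files (``.gz`` suffix) are handled transparently.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        text_start = handle.read(1)
        if text_start == "":
            raise FastaFormatError(f"{path}: empty FASTA file")
        if text_start not in (">", ";"):
            raise FastaFormatError(
                f"{path}: line 1 does not start a FASTA entry (expected '>')"
            )
    records: list[SequenceRecord] = []
    with opener(path, "rt") as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            seq = _clean_sequence(entry.id, str(entry.seq), ambiguous)
            if not seq:
                raise FastaFormatError(f"{path}: entry '{entry.id}' has no sequence")
            if expected_length is not None and len(seq) != expected_length:
                raise SequenceValidationError(
                    f"record '{entry.id}': length {len(seq)} != expected "
                    f"{expected_length}"
                )
            records.append(SequenceRecord(id=entry.id, seq=seq, label=label))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving order and identifiers."""
    path = Path(path)
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        SeqIO.write(bio, handle, "fasta-2line")


@dataclass
class LayeredDataset:
    """Equal-length labelled fragments with two-layer class views."""

    records: list[SequenceRecord]
    n: int
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_counts:
            counts: dict[str, int] = {}
            for r in self.records:
                counts[r.label] = counts.get(r.label, 0) + 1
            self.class_counts = counts

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, labels: Iterable[str]) -> "LayeredDataset":
        wanted = set(labels)
        return LayeredDataset(
            [r for r in self.records if r.label in wanted], self.n
        )

    def binary_view(
        self, positive_labels: Iterable[str], negative_labels: Iterable[str]
    ) -> tuple[list[SequenceRecord], list[int]]:
        """Records of the two named groups, with +1/-1 class indicators.

        Record order is preserved; sequences outside both groups are
        dropped.
        """
        pos, neg = set(positive_labels), set(negative_labels)
        recs = [r for r in self.records if r.label in pos | neg]
        y = [1 if r.label in pos else -1 for r in recs]
        return recs, y

    def layer1(self) -> tuple[list[SequenceRecord], list[int]]:
        """Enhancer (strong + weak, +1) versus non-enhancer (-1)."""
        return self.binary_view(LAYER1_POSITIVE, LAYER1_NEGATIVE)

    def layer2(self) -> tuple[list[SequenceRecord], list[int]]:
        """Strong enhancer (+1) versus weak enhancer (-1); others excluded."""
        return self.binary_view({STRONG_ENHANCER}, {WEAK_ENHANCER})


def validate_dataset(
    records: Sequence[SequenceRecord],
    n: int | None = None,
    *,
    ambiguous: str = "reject",
) -> LayeredDataset:
    """Check length and alphabet constraints and build a dataset.

    All sequences must have length ``n`` (inferred from the first record
    when not given).  Under the default ``reject`` policy any non-ACGT
    symbol is an error naming the record and position; under ``mask``
    such symbols are replaced by :data:`MASK_CHAR` and excluded from all
    downstream counts.
    """
    if not records:
        raise SequenceValidationError("empty dataset")
    if n is None:
        n = len(records[0].seq)
    cleaned: list[SequenceRecord] = []
    for r in records:
        if len(r.seq) != n:
            raise SequenceValidationError(
                f"record '{r.id}': length {len(r.seq)} != dataset length {n}"
            )
        seq = _clean_sequence(r.id, r.seq, ambiguous)
        cleaned.append(r if seq == r.seq else SequenceRecord(r.id, seq, r.label))
    return LayeredDataset(cleaned, n)


def read_manifest(
    path: str | Path,
    *,
    ambiguous: str = "reject",
    n: int | None = None,
) -> LayeredDataset:
    """Load a dataset from a manifest TSV with columns ``path`` and ``label``.

    FASTA paths are resolved relative to the manifest's directory.
    """
    import pandas as pd

    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    for col in ("path", "label"):
        if col not in table.columns:
            raise ValueError(f"manifest {path} lacks required column '{col}'")
    records: list[SequenceRecord] = []
    for _, row in table.iterrows():
        fasta = Path(row["path"])
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        records.extend(read_fasta(fasta, str(row["label"]), ambiguous=ambiguous))
    return validate_dataset(records, n, ambiguous=ambiguous)
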