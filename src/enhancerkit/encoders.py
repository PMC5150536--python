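"""Sequence feature encoders: bi-profile Bayes, nucleotide and trinucleotide composition.

Three feature families turn a length-``n`` DNA fragment into numbers:

* **BPB** (bi-profile Bayes, ``2n`` features): position-specific empirical
  base frequencies estimated separately from the positive and the negative
  training class.  A sequence is encoded as the probability vector
  ``(p_1 … p_n, p_{n+1} … p_{2n})`` where ``p_i`` is the positive-class
  frequency of the observed base at position ``i`` and ``p_{n+i}`` the
  negative-class frequency.  For 200-bp fragments this yields 400 features.
* **NC** (nucleotide composition, 4 features): normalised single-base
  frequencies in the fixed order A, T, G, C.
* **PseNC** (pseudo-nucleotide composition, 64 features): overlapping
  trinucleotide (3-mer) frequencies, counts over the ``n - 2`` windows,
  in lexicographic order AAA … TTT.  This recovers local-order information
  that plain composition discards.

NC and PseNC depend only on the sequence itself; BPB requires a fitted
:class:`BPBModel` and is therefore the only training-dependent family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_io import MASK_CHAR, LayeredDataset, SequenceRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: Fixed NC feature order (A, T, G, C).
NC_ORDER = "ATGC"
#: The 64 trinucleotides in lexicographic order (AAA, AAC, ..., TTT).
TRINUCLEOTIDES = ["".join(t) for t in product(BASES, repeat=3)]
TRIMER_INDEX = {t: i for i, t in enumerate(TRINUCLEOTIDES)}

FAMILIES = ("BPB", "NC", "PseNC")

#: BPB lookup value at a masked (ambiguous) position: the uniform base
#: probability, so masked positions are uninformative rather than zero.
UNIFORM_BASE_PROB = 0.25


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a sequence to integer base indices (A=0, C=1, G=2, T=3; mask=-1)."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for i, b in enumerate(seq):
        if b != MASK_CHAR:
            out[i] = BASE_INDEX[b]
    return out


def indices_matrix(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Stack per-sequence base indices into an (m, n) integer matrix."""
    return np.stack([seq_to_indices(r.seq) for r in records])


@dataclass
class BPBModel:
    """Positional base-frequency profiles of the two training classes.

    ``pos_freq`` and ``neg_freq`` are 4 x n matrices (rows A, C, G, T);
    each column sums to 1 whenever at least one unmasked base contributed
    at that position.  ``alpha`` is an optional additive (Laplace)
    smoothing pseudocount, 0 by default: with realistic class sizes the
    raw frequency is the posterior-probability estimate, and smoothing is
    only needed to avoid exact zeros in tiny training sets.
    """

    n: int
    pos_freq: np.ndarray
    neg_freq: np.ndarray
    alpha: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pos_freq", "neg_freq"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != (4, self.n):
                raise ValueError(f"{name} must have shape (4, {self.n})")
            setattr(self, name, mat)

    def to_tsv(self, path: str | Path) -> None:
        """Serialise as two stacked 4 x n blocks for inspection."""
        rows = {}
        for block, mat in (("pos", self.pos_freq), ("neg", self.neg_freq)):
            for bi, base in enumerate(BASES):
                rows[f"{block}_{base}"] = mat[bi]
        frame = pd.DataFrame(rows).T
        frame.columns = [str(i + 1) for i in range(self.n)]
        frame.to_csv(path, sep="\t", index_label="profile")

    @classmethod
    def from_tsv(cls, path: str | Path, alpha: float = 0.0) -> "BPBModel":
        frame = pd.read_csv(path, sep="\t", index_col="profile")
        n = frame.shape[1]
        pos = np.stack([frame.loc[f"pos_{b}"].to_numpy(float) for b in BASES])
        neg = np.stack([frame.loc[f"neg_{b}"].to_numpy(float) for b in BASES])
        return cls(n=n, pos_freq=pos, neg_freq=neg, alpha=alpha)


def _profile_from_counts(
    counts: np.ndarray, contributing: np.ndarray, alpha: float
) -> np.ndarray:
    """Normalise per-position base counts to a frequency profile.

    ``contributing`` holds, per position, the number of sequences whose
    base there was unmasked.  Positions with no contribution fall back to
    the uniform profile.
    """
    denom = contributing + 4.0 * alpha
    safe = np.where(denom > 0, denom, 1.0)
    freq = (counts + alpha) / safe
    freq[:, denom == 0] = UNIFORM_BASE_PROB
    return freq


def position_counts(idx: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-position base counts (4 x n) and contributing-sequence counts."""
    counts = np.zeros((4, n), dtype=float)
    for b in range(4):
        counts[b] = (idx == b).sum(axis=0)
    contributing = counts.sum(axis=0)
    return counts, contributing


def fit_bpb(
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
    n: int | None = None,
    *,
    alpha: float = 0.0,
) -> BPBModel:
    """Estimate the positive and negative positional frequency profiles.

    ``pos_freq[b, i]`` is the fraction of positive training sequences
    carrying base ``b`` at position ``i`` (masked positions excluded from
    both numerator and denominator); ``neg_freq`` analogously.
    """
    if not positives or not negatives:
        raise ValueError("both the positive and the negative class must be non-empty")
    if n is None:
        n = len(positives[0].seq)
    for r in list(positives) + list(negatives):
        if len(r.seq) != n:
            raise ValueError(f"record '{r.id}': length {len(r.seq)} != {n}")
    pos_counts, pos_contrib = position_counts(indices_matrix(positives), n)
    neg_counts, neg_contrib = position_counts(indices_matrix(negatives), n)
    return BPBModel(
        n=n,
        pos_freq=_profile_from_counts(pos_counts, pos_contrib, alpha),
        neg_freq=_profile_from_counts(neg_counts, neg_contrib, alpha),
        alpha=alpha,
    )


def _bpb_lookup(freq: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Positional frequency of each observed base; masked -> uniform 0.25."""
    cols = np.arange(idx.shape[-1])
    vals = freq[np.clip(idx, 0, 3), cols]
    return np.where(idx >= 0, vals, UNIFORM_BASE_PROB)


def encode_bpb(model: BPBModel, record: SequenceRecord) -> np.ndarray:
    """Encode one sequence as its 2n-dimensional bi-profile Bayes vector."""
    if len(record.seq) != model.n:
        raise ValueError(
            f"record '{record.id}': length {len(record.seq)} != model n={model.n}"
        )
    idx = seq_to_indices(record.seq)
    return np.concatenate(
        [_bpb_lookup(model.pos_freq, idx), _bpb_lookup(model.neg_freq, idx)]
    )


def encode_bpb_many(model: BPBModel, idx: np.ndarray) -> np.ndarray:
    """Vectorised BPB encoding of an (m, n) base-index matrix -> (m, 2n)."""
    if idx.shape[1] != model.n:
        raise ValueError(
            f"sequence length {idx.shape[1]} != model length n={model.n}"
        )
    return np.hstack(
        [_bpb_lookup(model.pos_freq, idx), _bpb_lookup(model.neg_freq, idx)]
    )


def encode_nc(record: SequenceRecord | str) -> np.ndarray:
    """Normalised mononucleotide frequencies in the order A, T, G, C."""
    seq = record.seq if isinstance(record, SequenceRecord) else record
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    total = sum(1 for b in seq if b != MASK_CHAR)
    if total == 0:
        raise ValueError("sequence is fully masked; composition undefined")
    return np.array([seq.count(b) / total for b in NC_ORDER])


def encode_psenc(record: SequenceRecord | str) -> np.ndarray:
    """Overlapping trinucleotide frequencies (64 components, AAA ... TTT).

    Counts are taken over the ``n - 2`` sliding windows and divided by the
    number of fully unmasked windows, so the vector sums to 1 for every
    sequence with at least one clean window.
    """
    seq = record.seq if isinstance(record, SequenceRecord) else record
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 bp; trinucleotides undefined")
    counts = np.zeros(64)
    windows = 0
    for i in range(len(seq) - 2):
        tri = seq[i : i + 3]
        if MASK_CHAR in tri:
            continue
        counts[TRIMER_INDEX[tri]] += 1
        windows += 1
    if windows == 0:
        raise ValueError("no unmasked trinucleotide window in sequence")
    return counts / windows


@dataclass
class FeatureMatrix:
    """Samples x named-features table with family provenance in the names.

    Feature names follow the patterns ``BPB_pos_<i>`` / ``BPB_neg_<i>``
    (1-based position), ``NC_<base>``, and ``PseNC_<trimer>``, so every
    column maps back to exactly one (family, origin) pair.
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("values shape inconsistent with ids/names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {name: i for i, name in enumerate(self.feature_names)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as err:
            raise KeyError(f"unknown feature name: {err.args[0]!r}") from None

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = self.column_index(names)
        return FeatureMatrix(self.values[:, idx], list(names), list(self.sample_ids))

    def family_columns(self, family: str) -> list[str]:
        prefix = f"{family}_"
        return [n for n in self.feature_names if n.startswith(prefix)]

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "sample_id", self.sample_ids)
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t")
        ids = frame.pop("sample_id").astype(str).tolist()
        return cls(frame.to_numpy(float), list(frame.columns), ids)


def bpb_feature_names(n: int) -> list[str]:
    return [f"BPB_pos_{i + 1}" for i in range(n)] + [
        f"BPB_neg_{i + 1}" for i in range(n)
    ]


NC_FEATURE_NAMES = [f"NC_{b}" for b in NC_ORDER]
PSENC_FEATURE_NAMES = [f"PseNC_{t}" for t in TRINUCLEOTIDES]


def encode_dataset(
    data: LayeredDataset | Sequence[SequenceRecord],
    bpb: BPBModel | None = None,
    families: Sequence[str] = FAMILIES,
) -> FeatureMatrix:
    """Encode every record with the requested families, concatenated
    in the fixed order BPB, NC, PseNC with stable column names."""
    records = data.records if isinstance(data, LayeredDataset) else list(data)
    if not records:
        raise ValueError("no records to encode")
    families = tuple(families)
    if not families:
        raise ValueError("at least one feature family must be requested")
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown feature families: {sorted(unknown)}")

    blocks: list[np.ndarray] = []
    names: list[str] = []
    if "BPB" in families:
        if bpb is None:
            raise ValueError("BPB encoding requested without a fitted BPBModel")
        blocks.append(encode_bpb_many(bpb, indices_matrix(records)))
        names.extend(bpb_feature_names(bpb.n))
    if "NC" in families:
        blocks.append(np.stack([encode_nc(r) for r in records]))
        names.extend(NC_FEATURE_NAMES)
    if "PseNC" in families:
        blocks.append(np.stack([encode_psenc(r) for r in records]))
        names.extend(PSENC_FEATURE_NAMES)
    return FeatureMatrix(np.hstack(blocks), names, [r.id for r in records])
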