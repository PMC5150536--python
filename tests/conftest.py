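"""Shared fixtures and independent brute-force reference implementations.

The naive encoders and the naive F-score below are deliberately written
as plain character/loop code, independent of the package's vectorised
paths, so they can serve as oracles.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest

from enhancerkit.sequence_io import (
    NEGATIVE,
    NON_ENHANCER,
    POSITIVE,
    STRONG_ENHANCER,
    WEAK_ENHANCER,
    SequenceRecord,
)

BASES = "ACGT"


# --------------------------------------------------------------------------
# naive reference implementations (oracles)


def naive_nc(seq: str) -> list[float]:
    total = len(seq)
    return [seq.count(b) / total for b in "ATGC"]


def naive_psenc(seq: str) -> list[float]:
    trimers = ["".join(t) for t in product(BASES, repeat=3)]
    windows = [seq[i : i + 3] for i in range(len(seq) - 2)]
    return [sum(1 for w in windows if w == t) / len(windows) for t in trimers]


def naive_bpb_profiles(pos_seqs, neg_seqs):
    n = len(pos_seqs[0])
    pos = [[0.0] * n for _ in range(4)]
    neg = [[0.0] * n for _ in range(4)]
    for seqs, mat in ((pos_seqs, pos), (neg_seqs, neg)):
        for i in range(n):
            for b_idx, b in enumerate(BASES):
                mat[b_idx][i] = sum(1 for s in seqs if s[i] == b) / len(seqs)
    return pos, neg


def naive_bpb_encode(pos_profile, neg_profile, seq: str) -> list[float]:
    out = []
    for mat in (pos_profile, neg_profile):
        for i, b in enumerate(seq):
            out.append(mat[BASES.index(b)][i])
    return out


def naive_fscore(X, y) -> list[float]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    scores = []
    for j in range(X.shape[1]):
        pos = [X[i, j] for i in range(len(y)) if y[i] > 0]
        neg = [X[i, j] for i in range(len(y)) if y[i] < 0]
        allv = pos + neg
        mean_all = sum(allv) / len(allv)
        mean_pos = sum(pos) / len(pos)
        mean_neg = sum(neg) / len(neg)
        numer = (mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2
        denom = sum((v - mean_pos) ** 2 for v in pos) / (len(pos) - 1) + sum(
            (v - mean_neg) ** 2 for v in neg
        ) / (len(neg) - 1)
        if denom == 0:
            scores.append(math.inf if numer > 0 else 0.0)
        else:
            scores.append(numer / denom)
    return scores


def naive_mcc(tp, tn, fp, fn) -> float:
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / denom


# --------------------------------------------------------------------------
# fixtures


def random_records(rng, count, length, label):
    return [
        SequenceRecord(
            id=f"{label}_{i}",
            seq="".join(rng.choice(list(BASES), size=length)),
            label=label,
        )
        for i in range(count)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_bpb_records():
    """The 3+2 hand-countable training set used in the encoder examples."""
    pos = [
        SequenceRecord("p1", "ACG", POSITIVE),
        SequenceRecord("p2", "ACG", POSITIVE),
        SequenceRecord("p3", "ATG", POSITIVE),
    ]
    neg = [
        SequenceRecord("n1", "TTT", NEGATIVE),
        SequenceRecord("n2", "TTT", NEGATIVE),
    ]
    return pos, neg


@pytest.fixture
def three_class_records(rng):
    recs = []
    recs += random_records(rng, 6, 30, STRONG_ENHANCER)
    recs += random_records(rng, 5, 30, WEAK_ENHANCER)
    recs += random_records(rng, 11, 30, NON_ENHANCER)
    return recs
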