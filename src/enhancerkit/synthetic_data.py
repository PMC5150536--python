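"""Synthetic labelled DNA fragment generator with plantable class signal.

The original enhancer benchmark (742 strong enhancers, 742 weak
enhancers and 1484 non-enhancers of 200 bp, drawn from chromatin-state
calls in nine cell lines) is external data.  This module emulates its
*statistical structure* so that every pipeline stage is testable without
downloads.  Three kinds of class signal can be planted, matching the
three feature families:

* **positional signal** — a probability boost for one base at one
  position in a class (detectable by the bi-profile Bayes features);
* **composition shift** — a per-class deviation of the mononucleotide
  emission probabilities, e.g. C-enrichment in enhancer classes
  (detectable by nucleotide composition);
* **trinucleotide enrichment** — multiplicative over-representation of
  chosen 3-mers, planted by overwriting random windows so that the
  expected occurrence count is scaled by the multiplier (detectable by
  the trinucleotide composition).

A global ``effect_size`` in [0, 1] scales every planted signal; at 0 all
classes are exchangeable draws from the background (i.i.d. uniform over
A/C/G/T by default), which keeps null calibration analytic.  Every draw
flows from a single seeded generator, so output is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .encoders import BASES, BASE_INDEX, TRINUCLEOTIDES
from .sequence_io import (
    NEGATIVE,
    NON_ENHANCER,
    POSITIVE,
    STRONG_ENHANCER,
    WEAK_ENHANCER,
    LayeredDataset,
    SequenceRecord,
    write_fasta,
)


@dataclass(frozen=True)
class ClassSignal:
    """Planted signal of one class.

    ``positional``: (position, base, boost) triples; positions are
    1-based so they line up with the BPB feature names ``BPB_pos_<i>``.
    ``composition``: additive deviation of per-base emission probability.
    ``trimers``: multiplicative enrichment (1.0 = background) per 3-mer.
    """

    positional: tuple[tuple[int, str, float], ...] = ()
    composition: Mapping[str, float] = field(default_factory=dict)
    trimers: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic dataset.

    Defaults mirror the benchmark geometry: 200-bp fragments, class
    sizes 742 / 742 / 1484, uniform background composition.
    """

    n: int = 200
    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            STRONG_ENHANCER: 742,
            WEAK_ENHANCER: 742,
            NON_ENHANCER: 1484,
        }
    )
    signals: Mapping[str, ClassSignal] = field(default_factory=dict)
    effect_size: float = 1.0
    seed: int = 0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValueError("background must be a probability vector over ACGT")
        for label, sig in self.signals.items():
            for pos, base, boost in sig.positional:
                if not 1 <= pos <= self.n:
                    raise ValueError(
                        f"{label}: positional signal at {pos} outside 1..{self.n}"
                    )
                if base not in BASE_INDEX:
                    raise ValueError(f"{label}: unknown base {base!r}")
                if boost < 0:
                    raise ValueError("positional boosts must be non-negative")


def _emission_table(spec: GeneratorSpec, label: str) -> np.ndarray:
    """Per-position emission probabilities (4 x n) for one class.

    Background + composition shift + positional boosts, clipped at 0 and
    renormalised column-wise so every column stays a distribution.
    """
    sig = spec.signals.get(label, ClassSignal())
    base_probs = np.asarray(spec.background, dtype=float).copy()
    for b, delta in sig.composition.items():
        base_probs[BASE_INDEX[b]] += delta * spec.effect_size
    base_probs = np.clip(base_probs, 0.0, None)
    if base_probs.sum() <= 0:
        raise ValueError(f"{label}: composition shift removed all probability mass")
    base_probs /= base_probs.sum()
    table = np.tile(base_probs[:, None], (1, spec.n))
    for pos, b, boost in sig.positional:
        col = pos - 1
        table[BASE_INDEX[b], col] += boost * spec.effect_size
        table[:, col] = np.clip(table[:, col], 0.0, None)
        table[:, col] /= table[:, col].sum()
    return table


def _background_trimer_prob(table: np.ndarray, trimer: str) -> float:
    """Expected frequency of a 3-mer under the class's average emission."""
    mean_probs = table.mean(axis=1)
    p = 1.0
    for b in trimer:
        p *= mean_probs[BASE_INDEX[b]]
    return p


def _sample_class(
    spec: GeneratorSpec, label: str, size: int, rng: np.random.Generator
) -> list[SequenceRecord]:
    table = _emission_table(spec, label)
    cum = np.cumsum(table, axis=0)  # (4, n)
    u = rng.random((size, spec.n))
    idx = (u[:, :, None] > cum.T[None, :, :]).sum(axis=2)
    idx = np.minimum(idx, 3)
    # trinucleotide planting: overwrite random windows so the expected
    # count is scaled by the multiplier (expectation-level control)
    sig = spec.signals.get(label, ClassSignal())
    for trimer, mult in sorted(sig.trimers.items()):
        extra_rate = (mult - 1.0) * spec.effect_size
        if extra_rate <= 0:
            continue
        p_bg = _background_trimer_prob(table, trimer)
        lam = extra_rate * p_bg * (spec.n - 2)
        tri_idx = np.array([BASE_INDEX[b] for b in trimer])
        counts = rng.poisson(lam, size=size)
        for row in range(size):
            if counts[row] == 0:
                continue
            starts = rng.integers(0, spec.n - 2, size=counts[row])
            for s in starts:
                idx[row, s : s + 3] = tri_idx
    base_arr = np.array(list(BASES))
    records = []
    for row in range(size):
        seq = "".join(base_arr[idx[row]])
        records.append(SequenceRecord(id=f"{label}_{row:04d}", seq=seq, label=label))
    return records


def generate(spec: GeneratorSpec) -> LayeredDataset:
    """Draw the dataset described by ``spec``; reproducible per seed.

    Classes are generated in sorted-label order from one seeded
    generator, so the same spec always yields byte-identical sequences.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    for label in sorted(spec.class_sizes):
        size = spec.class_sizes[label]
        if size < 0:
            raise ValueError(f"negative class size for {label}")
        records.extend(_sample_class(spec, label, size, rng))
    return LayeredDataset(records, spec.n)


def truth_report(spec: GeneratorSpec) -> list[dict]:
    """Machine-readable manifest of planted signal per feature name.

    Positional boosts name both halves of the BPB pair they perturb
    (the positive- and negative-profile feature at that position);
    composition shifts name their NC feature directly and flag every
    3-mer containing the shifted base as an indirectly affected PseNC
    feature; trinucleotide enrichments name their PseNC feature directly.
    """
    entries: list[dict] = []
    seen: set[tuple[str, str]] = set()

    def add(family: str, feature: str, label: str, effect: float, direct: bool):
        key = (feature, label)
        if key in seen:
            return
        seen.add(key)
        entries.append(
            {
                "family": family,
                "feature": feature,
                "class": label,
                "effect": effect * spec.effect_size,
                "direct": direct,
            }
        )

    for label, sig in spec.signals.items():
        for pos, base, boost in sig.positional:
            if boost * spec.effect_size == 0:
                continue
            add("BPB", f"BPB_pos_{pos}", label, boost, True)
            add("BPB", f"BPB_neg_{pos}", label, boost, True)
        for base, delta in sig.composition.items():
            if delta * spec.effect_size == 0:
                continue
            add("NC", f"NC_{base}", label, delta, True)
            for trimer in TRINUCLEOTIDES:
                if base in trimer:
                    add("PseNC", f"PseNC_{trimer}", label, delta, False)
        for trimer, mult in sig.trimers.items():
            if (mult - 1.0) * spec.effect_size == 0:
                continue
            add("PseNC", f"PseNC_{trimer}", label, mult - 1.0, True)
    return entries


# ---------------------------------------------------------------------------
# canned study designs


def two_class_spec(
    n_per_class: int = 200,
    *,
    n: int = 200,
    n_positional: int = 10,
    boost: float = 0.3,
    c_shift: float = 0.05,
    trimer_mult: float = 2.0,
    effect_size: float = 1.0,
    seed: int = 0,
) -> GeneratorSpec:
    """A binary design: positives carry planted signal, negatives are background.

    ``n_positional`` evenly spaced positions get a +``boost`` probability
    on a fixed base rotation; positives are C-enriched by ``c_shift``
    (emulating the C-enrichment of real enhancers relative to
    non-enhancers) and carry 2-fold default enrichment of the 3-mers
    ATA, TAT and GGC, three of the 3-mers that are informative for
    enhancer identification.
    """
    positions = np.linspace(10, n - 10, n_positional).round().astype(int)
    rotation = "GCAT"
    positional = tuple(
        (int(p), rotation[i % 4], boost) for i, p in enumerate(positions)
    )
    signals = {
        POSITIVE: ClassSignal(
            positional=positional,
            composition={"C": c_shift},
            trimers={"ATA": trimer_mult, "TAT": trimer_mult, "GGC": trimer_mult},
        )
    }
    return GeneratorSpec(
        n=n,
        class_sizes={POSITIVE: n_per_class, NEGATIVE: n_per_class},
        signals=signals,
        effect_size=effect_size,
        seed=seed,
    )


def three_class_spec(
    strong: int = 742,
    weak: int = 742,
    non: int = 1484,
    *,
    n: int = 200,
    effect_size: float = 1.0,
    seed: int = 0,
) -> GeneratorSpec:
    """The benchmark-shaped design: three classes, two independent contrasts.

    Both enhancer classes share the layer-I signal (positional boosts,
    C-enrichment, 3-mer enrichment) that separates them from
    non-enhancers; strong enhancers additionally carry a layer-II
    positional contrast at different positions, mirroring the finding
    that enhancer identification and strength grading need different
    features.
    """
    layer1_positions = np.linspace(10, n - 10, 10).round().astype(int)
    rotation = "GCAT"
    layer1 = tuple(
        (int(p), rotation[i % 4], 0.3) for i, p in enumerate(layer1_positions)
    )
    layer2_positions = np.linspace(15, n - 15, 5).round().astype(int)
    layer2 = tuple(
        (int(p), rotation[(i + 2) % 4], 0.3) for i, p in enumerate(layer2_positions)
    )
    shared = {
        "composition": {"C": 0.05},
        "trimers": {"ATA": 2.0, "TAT": 2.0, "GGC": 2.0},
    }
    signals = {
        STRONG_ENHANCER: ClassSignal(positional=layer1 + layer2, **shared),
        WEAK_ENHANCER: ClassSignal(positional=layer1, **shared),
    }
    return GeneratorSpec(
        n=n,
        class_sizes={STRONG_ENHANCER: strong, WEAK_ENHANCER: weak, NON_ENHANCER: non},
        signals=signals,
        effect_size=effect_size,
        seed=seed,
    )


def write_dataset(
    dataset: LayeredDataset, spec: GeneratorSpec, outdir: str | Path
) -> dict[str, Path]:
    """Write per-class FASTA files, a manifest TSV and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    manifest_rows = []
    for label in sorted(dataset.class_counts):
        fasta = outdir / f"{label}.fasta"
        write_fasta([r for r in dataset.records if r.label == label], fasta)
        paths[label] = fasta
        manifest_rows.append(f"{fasta.name}\t{label}")
    manifest = outdir / "manifest.tsv"
    manifest.write_text("path\tlabel\n" + "\n".join(manifest_rows) + "\n")
    paths["manifest"] = manifest
    truth = outdir / "truth.json"
    truth.write_text(json.dumps(truth_report(spec), indent=2) + "\n")
    paths["truth"] = truth
    return paths
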