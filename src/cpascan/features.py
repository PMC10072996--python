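"""Tiled-window feature engineering.

Each fixed-length sequence window is broken into overlapping bins (baseline:
500 nt window, 30 nt bins, 10 nt step -> 48 bins; cryptic stage: 140/20/10
-> 13 bins).  For every registry representation and every bin, the feature
value is the maximum score over all motif placements lying fully inside the
bin (PWM scores in the linear odds domain, splice-site scores left in log
domain) or, for k-mer features, the total occurrence count within the bin.
With the 15-representation baseline registry this yields 15 x 48 = 720
features per 500 nt example.

Motif placements never straddle bin borders; a bin shorter than a motif
scores that representation's floor value (the pseudocount-only worst-path
odds for PWMs, the scorer's defined minimum otherwise).  The overlapping
bins (step < bin size) mitigate the boundary loss this implies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cpascan.motifs import (
    DEFAULT_PSEUDOCOUNT,
    KmerCountFeature,
    MotifRegistry,
    PWM,
    Representation,
    encode_sequence,
    pwm_odds_scores_encoded,
)


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class BinGrid:
    """Window/bin/step geometry defining the feature columns."""

    window_length: int
    bin_size: int
    step: int

    def __post_init__(self) -> None:
        if self.bin_size > self.window_length:
            raise FeatureError("bin size must not exceed window length")
        if self.step <= 0:
            raise FeatureError("step must be positive")
        if (self.window_length - self.bin_size) % self.step != 0:
            raise FeatureError(
                f"(window - bin) = {self.window_length - self.bin_size} not "
                f"divisible by step {self.step}"
            )

    @property
    def n_bins(self) -> int:
        return (self.window_length - self.bin_size) // self.step + 1

    def bin_interval(self, i: int) -> tuple[int, int]:
        """Half-open [start, end) of bin ``i`` within the window."""
        if not 0 <= i < self.n_bins:
            raise FeatureError(f"bin index {i} out of range 0..{self.n_bins - 1}")
        start = i * self.step
        return start, start + self.bin_size


def make_bin_grid(window_length: int, bin_size: int, step: int) -> BinGrid:
    return BinGrid(window_length, bin_size, step)


BASELINE_GRID = BinGrid(500, 30, 10)
CRYPTIC_GRID = BinGrid(140, 20, 10)

_FEATURE_NAME_RE = re.compile(r"^(?P<rep>.+)@bin(?P<bin>\d+)\[(?P<start>\d+)\.\.(?P<end>\d+)\)$")


def feature_name(rep_id: str, grid: BinGrid, bin_index: int) -> str:
    start, end = grid.bin_interval(bin_index)
    return f"{rep_id}@bin{bin_index:02d}[{start}..{end})"


def feature_names(registry: MotifRegistry, grid: BinGrid) -> list[str]:
    return [
        feature_name(rep_id, grid, i)
        for rep_id in registry.ids
        for i in range(grid.n_bins)
    ]


def parse_feature_name(name: str) -> tuple[str, int, int, int]:
    """Split ``repid@bin<k>[<start>..<end>)`` into (rep, bin, start, end)."""
    m = _FEATURE_NAME_RE.match(name)
    if m is None:
        raise FeatureError(f"unparseable feature name {name!r}")
    return (m["rep"], int(m["bin"]), int(m["start"]), int(m["end"]))


def pwm_floor(pwm: PWM, background=None, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Worst-path odds of a PWM: the score floor used for too-short bins."""
    lo = pwm.log_odds(background, pseudocount)
    return float(10.0 ** lo.min(axis=1).sum())


def rep_floor(rep: Representation, background=None,
              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    if isinstance(rep, PWM):
        return pwm_floor(rep, background, pseudocount)
    if isinstance(rep, KmerCountFeature):
        return 0.0
    return float(rep.floor)


def rep_offset_scores(
    rep: Representation,
    enc: np.ndarray,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[np.ndarray, int]:
    """Per-offset scores (N x n_offsets) and word length for a non-k-mer
    representation over a batch of encoded sequences."""
    if isinstance(rep, PWM):
        return pwm_odds_scores_encoded(enc, rep, background, pseudocount), len(rep)
    if isinstance(rep, KmerCountFeature):
        raise FeatureError("k-mer features have no single per-offset score array")
    return rep.per_offset_scores_encoded(enc), rep.word_length


def _kmer_occurrences(enc: np.ndarray, kmer: str) -> np.ndarray:
    """Boolean N x (W - k + 1) array marking start offsets of ``kmer``."""
    codes = encode_sequence(kmer)
    k = len(codes)
    n, w = enc.shape
    if w < k:
        return np.zeros((n, 0), dtype=bool)
    hits = np.ones((n, w - k + 1), dtype=bool)
    for j, c in enumerate(codes):
        hits &= enc[:, j : j + w - k + 1] == c
    return hits


def _bin_values(
    rep: Representation,
    enc: np.ndarray,
    grid: BinGrid,
    background,
    pseudocount: float,
) -> np.ndarray:
    """N x n_bins matrix of bin features for one representation."""
    n = enc.shape[0]
    out = np.empty((n, grid.n_bins))
    if isinstance(rep, KmerCountFeature):
        counts = np.zeros((n, grid.n_bins), dtype=np.int64)
        for kmer in sorted(rep.kmers):
            occ = _kmer_occurrences(enc, kmer).astype(np.int64)
            k = len(kmer)
            for i in range(grid.n_bins):
                lo, hi = grid.bin_interval(i)
                last = hi - k  # last start offset fully inside the bin
                if last >= lo and occ.shape[1] > 0:
                    counts[:, i] += occ[:, lo : min(last, occ.shape[1] - 1) + 1].sum(axis=1)
        return counts.astype(float)
    scores, word = rep_offset_scores(rep, enc, background, pseudocount)
    floor = rep_floor(rep, background, pseudocount)
    for i in range(grid.n_bins):
        lo, hi = grid.bin_interval(i)
        last = hi - word
        if last < lo or scores.shape[1] == 0:
            out[:, i] = floor
        else:
            out[:, i] = scores[:, lo : last + 1].max(axis=1)
    return out


def featurize_batch(
    sequences: Sequence[str],
    registry: MotifRegistry,
    grid: BinGrid,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    chunk_size: int = 2048,
) -> np.ndarray:
    """Feature matrix (N x n_representations * n_bins) for equal-length windows."""
    if len(sequences) == 0:
        return np.empty((0, len(registry) * grid.n_bins))
    lengths = {len(s) for s in sequences}
    if lengths != {grid.window_length}:
        raise FeatureError(
            f"window length(s) {sorted(lengths)} do not match grid window "
            f"{grid.window_length}"
        )
    blocks = []
    for start in range(0, len(sequences), chunk_size):
        chunk = sequences[start : start + chunk_size]
        enc = np.stack([encode_sequence(s) for s in chunk])
        cols = [
            _bin_values(rep, enc, grid, background, pseudocount) for rep in registry
        ]
        blocks.append(np.hstack(cols))
    return np.vstack(blocks)


def featurize(
    window,
    registry: MotifRegistry,
    grid: BinGrid,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Feature vector for a single window (a string or an object with a
    ``sequence`` attribute)."""
    seq = window if isinstance(window, str) else window.sequence
    return featurize_batch([seq], registry, grid, background, pseudocount)[0]


@dataclass
class FeatureMatrix:
    """Examples x (representation x bin) feature matrix with labels."""

    values: np.ndarray
    feature_names_: list[str]
    labels: np.ndarray
    example_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise FeatureError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names_):
            raise FeatureError("column count does not match feature names")
        if self.values.shape[0] != len(self.labels):
            raise FeatureError("row count does not match labels")
        if self.values.size and not np.isfinite(self.values).all():
            raise FeatureError("feature matrix contains non-finite values")
        if self.example_ids and len(self.example_ids) != self.values.shape[0]:
            raise FeatureError("example_ids length does not match rows")

    @property
    def n_examples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names_)
        df.insert(0, "label", self.labels)
        if self.example_ids:
            df.insert(0, "example_id", self.example_ids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        ids = [i for i, m in zip(self.example_ids, mask) if m] if self.example_ids else []
        return FeatureMatrix(self.values[mask], self.feature_names_, self.labels[mask], ids)


def assemble_matrix(
    windows: Iterable,
    registry: MotifRegistry,
    grid: BinGrid,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FeatureMatrix:
    """Featurize labelled windows into a FeatureMatrix, preserving row order.

    ``windows`` may be strings (labelled ``"unlabeled"``) or objects with
    ``sequence``, ``label`` and optionally ``gene_id`` attributes.
    """
    windows = list(windows)
    seqs, labels, ids = [], [], []
    for w in windows:
        if isinstance(w, str):
            seqs.append(w)
            labels.append("unlabeled")
            ids.append("")
        else:
            seqs.append(w.sequence)
            labels.append(w.label)
            ids.append(getattr(w, "gene_id", ""))
    values = featurize_batch(seqs, registry, grid, background, pseudocount)
    return FeatureMatrix(
        values=values,
        feature_names_=feature_names(registry, grid),
        labels=np.array(labels),
        example_ids=ids if any(ids) else [],
    )
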