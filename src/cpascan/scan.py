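"""Base-resolution scanning of pre-mRNAs with a trained baseline model.

Every possible window placement (starting at each base) of a pre-mRNA is
featurized and scored, yielding a per-base CPA probability track.  The
scanner slides the bin grid along the precomputed per-offset motif scores
instead of re-extracting each window, which is algebraically — and, by
contract, bit-for-bit — identical to naive window re-extraction while
costing O(gene length) per representation rather than O(length x window).

Track coordinates are window starts; the putative CPA base of placement
``s`` sits at ``s + flank`` (transcript coordinates, 5'->3').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from cpascan.features import (
    BASELINE_GRID,
    BinGrid,
    featurize_batch,
    rep_floor,
    rep_offset_scores,
)
from cpascan.motifs import (
    DEFAULT_PSEUDOCOUNT,
    KmerCountFeature,
    MotifRegistry,
    encode_sequence,
)
from cpascan.sequence_io import CPASite, GeneModel, reverse_complement

DEFAULT_THRESHOLD_D = 0.69
DEFAULT_TOP_TOLERANCE_NT = 50


class ScanError(ValueError):
    pass


@dataclass
class ScanTrack:
    """Per-placement CPA probabilities along one pre-mRNA.

    ``probabilities[s]`` scores the window starting at transcript offset
    ``s``; the corresponding putative CPA base is ``s + flank``.  When the
    gene model is attached, ``cpa_positions`` maps each entry onto genomic
    coordinates (strand-aware).
    """

    gene_id: str
    probabilities: np.ndarray
    flank: int
    gene: GeneModel | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ScanError("track probabilities must lie in [0, 1]")
        self.probabilities = p

    def __len__(self) -> int:
        return len(self.probabilities)

    @property
    def chrom(self) -> str:
        return self.gene.span.chrom if self.gene else self.gene_id

    @property
    def strand(self) -> str:
        return self.gene.span.strand if self.gene else "+"

    @property
    def cpa_positions(self) -> np.ndarray:
        """Genomic (or transcript, if no gene attached) coordinate of the
        putative CPA base for each track entry."""
        tx = np.arange(len(self.probabilities)) + self.flank
        if self.gene is None:
            return tx
        span = self.gene.span
        if span.strand == "+":
            return span.start + tx
        return span.end - 1 - tx

    def to_bedgraph(self, path) -> None:
        pos = self.cpa_positions
        order = np.argsort(pos)
        with open(path, "w", newline="\n") as fh:
            for i in order:
                p = int(pos[i])
                fh.write(f"{self.chrom}\t{p}\t{p + 1}\t{self.probabilities[i]:.6g}\n")


def scan_features(
    premrna: str,
    registry: MotifRegistry,
    grid: BinGrid = BASELINE_GRID,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Feature matrix for every window placement of ``premrna``.

    Row ``s`` holds the features of the window ``[s, s + W)``; there are
    ``len(premrna) - W + 1`` rows.  Computed incrementally from whole-gene
    per-offset scores; bit-identical to featurizing each extracted window.
    """
    W, b, step = grid.window_length, grid.bin_size, grid.step
    G = len(premrna)
    if G < W:
        raise ScanError(f"pre-mRNA ({G} nt) shorter than the window ({W} nt)")
    enc = encode_sequence(premrna)[None, :]
    n_place = G - W + 1
    bin_starts = np.arange(grid.n_bins) * step
    place_idx = np.arange(n_place)[:, None] + bin_starts[None, :]

    blocks = []
    for rep in registry:
        if isinstance(rep, KmerCountFeature):
            # windowed occurrence counts at every bin start
            counts_at = np.zeros(G - b + 1, dtype=np.int64)
            for kmer in sorted(rep.kmers):
                k = len(kmer)
                codes = encode_sequence(kmer)
                occ = np.ones(G - k + 1, dtype=np.int64)
                for j, c in enumerate(codes):
                    occ &= enc[0, j : j + G - k + 1] == c
                width = b - k + 1  # start offsets fully inside a bin
                if width < 1:
                    continue
                csum = np.concatenate([[0], np.cumsum(occ)])
                counts_at += csum[width : width + G - b + 1] - csum[: G - b + 1]
            blocks.append(counts_at[place_idx].astype(float))
            continue
        scores, word = rep_offset_scores(rep, enc, background, pseudocount)
        floor = rep_floor(rep, background, pseudocount)
        width = b - word + 1
        if width < 1 or scores.shape[1] == 0:
            binmax = np.full(G - b + 1, floor)
        else:
            binmax = np.lib.stride_tricks.sliding_window_view(
                scores[0], width
            ).max(axis=-1)
        blocks.append(binmax[place_idx])
    return np.concatenate(blocks, axis=1)


def scan_sequence(
    model,
    premrna: str,
    registry: MotifRegistry,
    grid: BinGrid = BASELINE_GRID,
    gene_id: str = "gene",
    gene: GeneModel | None = None,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    batch_rows: int = 200_000,
) -> ScanTrack:
    """Score every window placement of a pre-mRNA sequence."""
    X = scan_features(premrna, registry, grid, background, pseudocount)
    probs = np.concatenate(
        [
            model.predict_proba(X[i : i + batch_rows])
            for i in range(0, X.shape[0], batch_rows)
        ]
    )
    return ScanTrack(gene_id, probs, flank=grid.window_length // 2, gene=gene)


def scan_gene(
    model,
    gene: GeneModel,
    genome: Mapping[str, str],
    registry: MotifRegistry,
    grid: BinGrid = BASELINE_GRID,
    **kw,
) -> ScanTrack:
    """Scan a gene's pre-mRNA (read 5'->3' on the transcribed strand)."""
    span = gene.span
    seq = genome[span.chrom][span.start : span.end]
    if span.strand == "-":
        seq = reverse_complement(seq)
    if len(seq) < grid.window_length:
        raise ScanError(
            f"gene {gene.gene_id} ({len(seq)} nt) shorter than the scan "
            f"window ({grid.window_length} nt)"
        )
    return scan_sequence(model, seq, registry, grid, gene_id=gene.gene_id,
                         gene=gene, **kw)


def scan_sequence_naive(
    model,
    premrna: str,
    registry: MotifRegistry,
    grid: BinGrid = BASELINE_GRID,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Reference scanner that re-extracts and featurizes every window.

    Exists as the oracle for the incremental scanner's bit-identity
    contract; quadratic in gene length, use on short sequences only.
    """
    W = grid.window_length
    windows = [premrna[s : s + W] for s in range(len(premrna) - W + 1)]
    X = featurize_batch(windows, registry, grid, background, pseudocount)
    return model.predict_proba(X)


def gene_top_is_constitutive(
    track: ScanTrack,
    constitutive: CPASite,
    tolerance: int = DEFAULT_TOP_TOLERANCE_NT,
) -> bool:
    """Whether the track's argmax falls at the constitutive site.

    True iff some maximal-probability placement implies a CPA base within
    ``tolerance`` nt of the annotated cleavage base; probability ties are
    resolved in favour of the constitutive site.
    """
    probs = track.probabilities
    if probs.size == 0:
        return False
    top = probs.max()
    candidates = track.cpa_positions[probs == top]
    return bool(np.abs(candidates - constitutive.base).min() <= tolerance)


def fraction_top_constitutive(
    tracks: Iterable[ScanTrack],
    constitutive_sites: Mapping[str, CPASite],
    tolerance: int = DEFAULT_TOP_TOLERANCE_NT,
) -> float:
    """Fraction of genes whose track maximum coincides with the annotated
    constitutive site."""
    hits, total = 0, 0
    for track in tracks:
        site = constitutive_sites[track.gene_id]
        hits += gene_top_is_constitutive(track, site, tolerance)
        total += 1
    if total == 0:
        raise ScanError("no tracks supplied")
    return hits / total


def mutate_and_score(
    model,
    window_sequence: str,
    edits: Sequence[tuple[int, str]],
    registry: MotifRegistry,
    grid: BinGrid = BASELINE_GRID,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[float, float]:
    """Score a window before and after applying point edits.

    Returns ``(p_wild, p_mutant)`` from the same model; the edits are
    applied to a copy.  Offsets are 0-based within the window.
    """
    if len(window_sequence) != grid.window_length:
        raise ScanError("window length does not match the grid")
    mutant = list(window_sequence)
    for offset, base in edits:
        if not 0 <= offset < len(mutant):
            raise ScanError(f"edit offset {offset} outside the window")
        if base not in "ACGU":
            raise ScanError(f"invalid replacement base {base!r}")
        mutant[offset] = base
    X = featurize_batch(
        [window_sequence, "".join(mutant)], registry, grid, background, pseudocount
    )
    p = model.predict_proba(X)
    return float(p[0]), float(p[1])


def combine_probabilities(p_baseline: float, p_cryptic_model: float) -> float:
    """Two-stage combined score: the product of the stage probabilities."""
    for name, p in (("p_baseline", p_baseline), ("p_cryptic_model", p_cryptic_model)):
        if not 0.0 <= p <= 1.0:
            raise ScanError(f"{name} = {p} outside [0, 1]")
    return p_baseline * p_cryptic_model
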