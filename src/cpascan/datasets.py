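"""Construction of positive, negative and cryptic example sets.

Positives: one 'constitutive' CPA site per gene — the site with the highest
PSE x RPM usage score lying in (or at the end of) the 3'UTR of the gene's
longest isoform — represented by the 500 nt window centred on the cleavage
base.  Negatives: 500 nt windows tiled along the same genes at 100 nt steps,
discarding windows whose overlap with any known site's +/-250 nt region
exceeds 10% of the window (strict inequality at the boundary).  Training
negatives are subsampled to a 30:1 negative:positive ratio.  Genes on
chromosomes 1-14 form the training partition, 15-22 and X the test
partition; chrY and unplaced contigs are excluded.

Cryptic sites are contiguous runs of scanned bases whose predicted CPA
probability exceeds the mean constitutive-site probability (D > 0.69 by
default) and that overlap no known site region.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from cpascan.sequence_io import (
    CPASite,
    GeneModel,
    GenomicInterval,
    extract_window,
    reverse_complement,
)

DEFAULT_WINDOW = 500
DEFAULT_STEP = 100
DEFAULT_FLANK = 250
DEFAULT_MAX_OVERLAP_FRAC = 0.10
DEFAULT_NEGATIVE_RATIO = 30
DEFAULT_THRESHOLD_D = 0.69

TRAIN_CHROMS = tuple(f"chr{i}" for i in range(1, 15))
TEST_CHROMS = tuple(f"chr{i}" for i in range(15, 23)) + ("chrX",)

_CHROM_RE = re.compile(r"^chr([0-9]{1,2}|[XYM])$")


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledWindow:
    """A fixed-length example window with its class label.

    ``site_offset`` is the offset of the CPA base within the sequence
    (equal to the flank for site-centred windows); absent for negatives.
    ``score`` carries the calling model's probability for cryptic windows.
    """

    gene_id: str
    window: GenomicInterval
    sequence: str
    label: str
    site_offset: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative", "cryptic", "unlabeled"):
            raise DatasetError(f"unknown label {self.label!r}")
        if len(self.sequence) != len(self.window):
            raise DatasetError(
                f"sequence length {len(self.sequence)} != window span "
                f"{len(self.window)}"
            )

    @property
    def chrom(self) -> str:
        return self.window.chrom


def normalize_chrom(chrom: str) -> str:
    """Map chromosome name dialects onto the chr-prefixed form."""
    name = chrom if chrom.startswith("chr") else f"chr{chrom}"
    if _CHROM_RE.match(name) or "_" in name or name.startswith("chrUn"):
        return name
    raise DatasetError(
        f"unrecognised chromosome name {chrom!r}; expected names like "
        "'chr1'..'chr22', 'chrX' (or the same without the 'chr' prefix)"
    )


def site_region(site: CPASite, flank: int = DEFAULT_FLANK) -> GenomicInterval:
    """The +/-flank region around a site's cleavage base (clipped at 0)."""
    base = site.base
    return GenomicInterval(
        site.position.chrom,
        max(0, base - flank),
        base + flank,
        site.position.strand,
    )


def select_constitutive(
    sites: Iterable[CPASite],
    gene_models: Mapping[str, GeneModel],
) -> tuple[dict[str, CPASite], list[str]]:
    """Pick the constitutive CPA site of each gene.

    Per gene, among sites lying in (or at the end of) the 3'UTR, the one
    with maximal PSE x RPM wins; significance ties break toward the most
    3'-distal site.  Genes without a qualifying site are dropped and
    returned in the second element.
    """
    by_gene: dict[str, list[CPASite]] = defaultdict(list)
    for site in sites:
        by_gene[site.gene_id].append(site)

    chosen: dict[str, CPASite] = {}
    dropped: list[str] = []
    for gene_id, gene_sites in by_gene.items():
        model = gene_models.get(gene_id)
        if model is None:
            dropped.append(gene_id)
            continue
        region = model.three_prime_utr or model.span
        # inclusive right edge: a site at the UTR end still qualifies
        qualifying = [
            s for s in gene_sites if region.start <= s.base <= region.end
        ]
        if not qualifying:
            dropped.append(gene_id)
            continue
        strand = model.span.strand

        def rank(s: CPASite) -> tuple[float, int]:
            distal = s.base if strand == "+" else -s.base
            return (s.significance, distal)

        chosen[gene_id] = max(qualifying, key=rank)
    return chosen, dropped


def make_positive_windows(
    constitutive: Mapping[str, CPASite],
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
) -> list[LabeledWindow]:
    """Site-centred windows of length ``2 * flank`` for the positive class."""
    out = []
    for gene_id, site in constitutive.items():
        seq = extract_window(genome, site.position, flank)
        base = site.base
        if site.position.strand == "+":
            iv = GenomicInterval(site.position.chrom, base - flank, base + flank, "+")
        else:
            iv = GenomicInterval(
                site.position.chrom, base - flank + 1, base + flank + 1, "-"
            )
        out.append(
            LabeledWindow(gene_id, iv, seq, "positive", site_offset=flank)
        )
    return out


def tile_negatives(
    gene_models: Mapping[str, GeneModel] | Sequence[GeneModel],
    genome: Mapping[str, str],
    all_known_sites: Iterable[CPASite],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    max_overlap_frac: float = DEFAULT_MAX_OVERLAP_FRAC,
    flank: int = DEFAULT_FLANK,
) -> list[LabeledWindow]:
    """Tile genes into candidate negative windows and apply the overlap filter.

    A window is removed iff its overlap with any known site's +/-flank
    region exceeds ``max_overlap_frac * window`` bases (strictly greater);
    the filter considers all known sites, not only constitutive ones.
    Genes shorter than the window simply contribute no windows.
    """
    if window <= step:
        raise DatasetError("window must exceed step")
    if not 0.0 <= max_overlap_frac < 1.0:
        raise DatasetError("max_overlap_frac must be in [0, 1)")
    models = (
        list(gene_models.values())
        if isinstance(gene_models, Mapping)
        else list(gene_models)
    )
    regions_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for site in all_known_sites:
        r = site_region(site, flank)
        tmp[r.chrom].append((r.start, r.end))
    for chrom, pairs in tmp.items():
        regions_by_chrom[chrom] = np.array(pairs, dtype=np.int64)

    max_overlap = max_overlap_frac * window
    out: list[LabeledWindow] = []
    for gm in models:
        span = gm.span
        regions = regions_by_chrom.get(span.chrom)
        chrom_seq = genome[span.chrom]
        for start in range(span.start, span.end - window + 1, step):
            end = start + window
            if regions is not None and len(regions):
                overlap = np.maximum(
                    0,
                    np.minimum(end, regions[:, 1]) - np.maximum(start, regions[:, 0]),
                )
                if overlap.max() > max_overlap:
                    continue
            seq = chrom_seq[start:end]
            if span.strand == "-":
                seq = reverse_complement(seq)
            out.append(
                LabeledWindow(
                    gm.gene_id,
                    GenomicInterval(span.chrom, start, end, span.strand),
                    seq,
                    "negative",
                )
            )
    return out


def _example_chrom(example) -> str:
    if hasattr(example, "window"):
        return example.window.chrom
    if hasattr(example, "position"):
        return example.position.chrom
    raise DatasetError(f"example {example!r} carries no chromosome")


def split_by_chromosome(
    examples: Sequence,
    train_chroms: Sequence[str] = TRAIN_CHROMS,
    test_chroms: Sequence[str] = TEST_CHROMS,
) -> tuple[list, list, list]:
    """Partition examples into (train, test, excluded) by chromosome.

    Chromosome names are normalised to the chr-prefixed dialect.  Names in
    neither list (chrY, chrM, unplaced contigs) are excluded, not an error.
    """
    train_set = {normalize_chrom(c) for c in train_chroms}
    test_set = {normalize_chrom(c) for c in test_chroms}
    if train_set & test_set:
        raise DatasetError("train and test chromosome sets overlap")
    train, test, excluded = [], [], []
    for ex in examples:
        chrom = normalize_chrom(_example_chrom(ex))
        if chrom in train_set:
            train.append(ex)
        elif chrom in test_set:
            test.append(ex)
        else:
            excluded.append(ex)
    return train, test, excluded


def subsample_negatives(
    negatives: Sequence[LabeledWindow],
    n_positives: int,
    ratio: int = DEFAULT_NEGATIVE_RATIO,
    seed: int = 0,
) -> list[LabeledWindow]:
    """Uniform, seeded subsample to ``ratio * n_positives`` negatives."""
    need = ratio * n_positives
    if len(negatives) < need:
        raise DatasetError(
            f"insufficient negatives: need {need} for a {ratio}:1 ratio with "
            f"{n_positives} positives, have {len(negatives)} "
            f"(short by {need - len(negatives)})"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(negatives), size=need, replace=False))
    return [negatives[i] for i in idx]


def build_cryptic_set(
    tracks: Iterable,
    all_known_sites: Iterable[CPASite],
    genome: Mapping[str, str],
    threshold_d: float = DEFAULT_THRESHOLD_D,
    flank: int = DEFAULT_FLANK,
    half_window: int = DEFAULT_FLANK,
) -> list[LabeledWindow]:
    """Call cryptic CPA sites from per-gene probability tracks.

    Contiguous runs of track entries with probability strictly above
    ``threshold_d`` are merged into candidate sites; a run overlapping any
    known site's +/-flank region is discarded.  Each surviving run is
    represented by its peak-probability base, returned as a
    ``2 * half_window`` sequence window labelled ``cryptic``.
    """
    regions: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for site in all_known_sites:
        r = site_region(site, flank)
        regions[r.chrom].append((r.start, r.end))

    out: list[LabeledWindow] = []
    for track in tracks:
        probs = np.asarray(track.probabilities)
        positions = np.asarray(track.cpa_positions)
        chrom, strand = track.chrom, track.strand
        above = probs > threshold_d
        if not above.any():
            continue
        # maximal runs of consecutive True entries
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        starts = [0] if above[0] else []
        starts += [int(e) + 1 for e in edges if not above[e]]
        ends = [int(e) + 1 for e in edges if above[e]]
        if above[-1]:
            ends.append(len(above))
        for run_start, run_end in zip(starts, ends):
            run_pos = positions[run_start:run_end]
            lo, hi = int(run_pos.min()), int(run_pos.max()) + 1
            if any(
                min(hi, r_end) > max(lo, r_start)
                for r_start, r_end in regions.get(chrom, [])
            ):
                continue
            peak = run_start + int(np.argmax(probs[run_start:run_end]))
            peak_base = int(positions[peak])
            center = GenomicInterval(chrom, peak_base, peak_base + 1, strand)
            try:
                seq = extract_window(genome, center, half_window)
            except Exception:
                continue  # peak too close to a contig edge for a full window
            if strand == "+":
                iv = GenomicInterval(chrom, peak_base - half_window,
                                     peak_base + half_window, "+")
            else:
                iv = GenomicInterval(chrom, peak_base - half_window + 1,
                                     peak_base + half_window + 1, "-")
            out.append(
                LabeledWindow(
                    track.gene_id,
                    iv,
                    seq,
                    "cryptic",
                    site_offset=half_window,
                    score=float(probs[peak]),
                )
            )
    return out


def max_site_overlap(
    window: LabeledWindow,
    all_known_sites: Iterable[CPASite],
    flank: int = DEFAULT_FLANK,
) -> int:
    """Largest overlap (bases) between a window and any known site region."""
    best = 0
    for site in all_known_sites:
        best = max(best, window.window.overlap(site_region(site, flank)))
    return best
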