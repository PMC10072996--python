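"""Sequence-scoring representations of the core CPA elements.

Houses position probability matrices (PWMs), k-mer count features, the
weighted PAS hexamer PWM builder, U1 snRNP recognition scorers, and motif
shuffling for negative controls.

Scoring model
-------------
PWMs are scored as odds ratios against a background composition: for a
placement, the score is the product over motif positions of
``(p_i(base) + pseudocount, renormalised) / background(base)``.  This equals
``10 ** log10(odds)`` — the "linear domain" affinity-like score — computed
directly as the odds product.  A uniform PWM therefore scores exactly 1.0
everywhere.  5' splice-site scores are left in log10 domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

RNA_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}

#: 5' terminus of the U1 snRNA (5'->3', 9 nt) whose base pairing with the
#: pre-mRNA underlies 5' splice-site recognition and CPA suppression
#: ("telescripting").  Its perfect antiparallel complement on the target is
#: the donor-site consensus CAGGUAAGU.
U1_5PRIME = "ACUUACCUG"

DEFAULT_PSEUDOCOUNT = 1e-3
UNIFORM_BACKGROUND = np.full(4, 0.25)

#: Relative usage weights of the 13 PAS hexamer variants at human CPA sites
#: (rounded percentages; the canonical AAUAAA/AUUAAA dominate).
PAS_HEXAMER_WEIGHTS: dict[str, int] = {
    "AAUAAA": 53,
    "AUUAAA": 17,
    "UAUAAA": 3,
    "AGUAAA": 3,
    "AAGAAA": 2,
    "AAUAUA": 2,
    "AAUACA": 1,
    "CAUAAA": 1,
    "GAUAAA": 1,
    "AAUGAA": 1,
    "UUUAAA": 1,
    "ACUAAA": 1,
    "AAUAGA": 1,
}

#: k-mers whose summed occurrence count forms the "DSE k-mers" feature.
DSE_KMERS = frozenset({"G", "U", "GG", "GU", "UG", "UU"})


class MotifError(ValueError):
    pass


def encode_sequence(seq: str) -> np.ndarray:
    """Map an RNA string onto integer codes 0..3 (A, C, G, U)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[ord(base)] = idx
    enc = codes[arr]
    if (enc < 0).any():
        bad = seq[int(np.argmax(enc < 0))]
        raise MotifError(f"invalid base {bad!r} in sequence (alphabet ACGU)")
    return enc.astype(np.int64)


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over (A, C, G, U).

    ``matrix`` has one row per motif position; each row sums to 1.
    """

    name: str
    matrix: np.ndarray
    source_tag: str = "derived"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise MotifError(f"PWM {self.name!r}: matrix must be L x 4 with L >= 1")
        if (m < 0).any():
            raise MotifError(f"PWM {self.name!r}: negative probabilities")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise MotifError(f"PWM {self.name!r}: rows must each sum to 1")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(RNA_BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(
        self,
        background: np.ndarray | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> np.ndarray:
        """log10-odds matrix after per-cell pseudocount renormalisation."""
        bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise MotifError("background must sum to 1")
        probs = (self.matrix + pseudocount) / (1.0 + 4.0 * pseudocount)
        with np.errstate(divide="ignore"):  # pseudocount 0 -> -inf is wanted
            return np.log10(probs) - np.log10(bg)[None, :]


@dataclass(frozen=True)
class KmerCountFeature:
    """A feature whose value is the total (overlapping) count of a k-mer set."""

    name: str
    kmers: frozenset[str]

    def __post_init__(self) -> None:
        kmers = frozenset(self.kmers)
        if not kmers:
            raise MotifError(f"{self.name!r}: k-mer set must be non-empty")
        for k in kmers:
            if not k or any(b not in _BASE_INDEX for b in k):
                raise MotifError(f"{self.name!r}: invalid k-mer {k!r}")
        object.__setattr__(self, "kmers", kmers)


def pwm_from_consensus(
    name: str, consensus: str, strength: float = 0.9, source_tag: str = "derived"
) -> PWM:
    """PWM placing probability ``strength`` on each consensus base, the
    remainder spread over the three alternatives."""
    if not 0.25 <= strength <= 1.0:
        raise MotifError("strength must be in [0.25, 1]")
    rows = []
    for base in consensus:
        row = np.full(4, (1.0 - strength) / 3.0)
        row[_BASE_INDEX[base]] = strength
        rows.append(row)
    return PWM(name=name, matrix=np.array(rows), source_tag=source_tag)


def pwm_odds_scores(
    seq: str,
    pwm: PWM,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Per-offset linear-domain odds scores of ``pwm`` along ``seq``.

    Returns one strictly positive value per offset ``0 .. len(seq) - L``;
    an empty array when the sequence is shorter than the motif.
    """
    enc = encode_sequence(seq)
    return pwm_odds_scores_encoded(enc[None, :], pwm, background, pseudocount)[0]


def pwm_odds_scores_encoded(
    enc: np.ndarray,
    pwm: PWM,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Vectorised odds scoring of a batch of encoded sequences (N x W).

    Returns ``N x (W - L + 1)`` odds (empty second axis if W < L).
    """
    lo = pwm.log_odds(background, pseudocount)
    L = lo.shape[0]
    n, w = enc.shape
    if w < L:
        return np.empty((n, 0))
    windows = np.lib.stride_tricks.sliding_window_view(enc, L, axis=1)
    logs = lo[np.arange(L)[None, None, :], windows].sum(axis=-1)
    return 10.0 ** logs


def kmer_count_score(seq: str, feat: KmerCountFeature) -> int:
    """Total overlapping occurrence count of every k-mer in the set."""
    encode_sequence(seq)  # alphabet check
    total = 0
    for kmer in feat.kmers:
        start = 0
        while True:
            idx = seq.find(kmer, start)
            if idx < 0:
                break
            total += 1
            start = idx + 1  # overlaps counted
    return total


def build_weighted_pas_pwm(
    hexamer_counts: Mapping[str, float], name: str = "pas_hexamer"
) -> PWM:
    """Build the 'Hexamer' PAS PWM by count-weighting hexamer variants.

    Column ``j`` probability of base ``b`` is the count-weighted frequency of
    ``b`` at position ``j`` over all hexamers.
    """
    if not hexamer_counts:
        raise MotifError("hexamer_counts must be non-empty")
    matrix = np.zeros((6, 4))
    total = 0.0
    for hexamer, count in hexamer_counts.items():
        if len(hexamer) != 6:
            raise MotifError(f"PAS variant {hexamer!r} is not a hexamer")
        if count < 0:
            raise MotifError(f"negative count for {hexamer!r}")
        for j, base in enumerate(hexamer):
            matrix[j, _BASE_INDEX[base]] += count
        total += count
    if total <= 0:
        raise MotifError("all hexamer counts are zero")
    return PWM(name=name, matrix=matrix / total, source_tag="derived")


# ---------------------------------------------------------------------------
# U1 scorers


@dataclass(frozen=True)
class U1DuplexScorer:
    """Position-wise complementarity of a target window to the U1 5' end.

    Each window base is paired antiparallel with the U1 snRNA 5' terminus:
    a Watson-Crick pair scores ``match_weight``, a G:U wobble
    ``wobble_weight``, anything else 0.  The per-offset score is the sum over
    the 9 paired positions; a perfect complement (the donor consensus
    CAGGUAAGU) attains the maximum 9.0.  This is a deliberately simple
    hybridization proxy; precomputed per-base score tracks from a
    thermodynamic tool can be supplied instead wherever a scorer is accepted.
    """

    name: str = "u1_duplex"
    u1_sequence: str = U1_5PRIME
    match_weight: float = 1.0
    wobble_weight: float = 0.4
    log_domain: bool = True  # scores are already additive; no odds conversion

    @property
    def word_length(self) -> int:
        return len(self.u1_sequence)

    @property
    def max_score(self) -> float:
        return self.match_weight * self.word_length

    @property
    def floor(self) -> float:
        return 0.0

    def _pair_table(self) -> np.ndarray:
        """(position, target base) -> pairing weight, antiparallel geometry."""
        wc = {"A": "U", "U": "A", "G": "C", "C": "G"}
        wobble = {"G": "U", "U": "G"}
        k = self.word_length
        table = np.zeros((k, 4))
        for pos in range(k):
            u1_base = self.u1_sequence[k - 1 - pos]
            table[pos, _BASE_INDEX[wc[u1_base]]] = self.match_weight
            if u1_base in wobble:
                table[pos, _BASE_INDEX[wobble[u1_base]]] = self.wobble_weight
        return table

    def per_offset_scores_encoded(self, enc: np.ndarray) -> np.ndarray:
        table = self._pair_table()
        k = self.word_length
        n, w = enc.shape
        if w < k:
            return np.empty((n, 0))
        windows = np.lib.stride_tricks.sliding_window_view(enc, k, axis=1)
        return table[np.arange(k)[None, None, :], windows].sum(axis=-1)

    def per_offset_scores(self, seq: str) -> np.ndarray:
        return self.per_offset_scores_encoded(encode_sequence(seq)[None, :])[0]

    def score(self, seq: str) -> float:
        """Maximum duplex score over all placements in ``seq``."""
        scores = self.per_offset_scores(seq)
        if scores.size == 0:
            raise MotifError(
                f"sequence shorter than the U1 word ({self.word_length} nt)"
            )
        return float(scores.max())


#: Approximate human 5' splice-site (donor) base frequencies, positions -3..+6
#: relative to the exon/intron boundary, in A C G U order (percent).  Used as
#: the default likelihood table; an externally computed maximum-entropy table
#: can be loaded in its place.
_DONOR_FREQS_PERCENT = np.array(
    [
        [33, 37, 18, 12],  # -3
        [60, 13, 14, 13],  # -2
        [8, 4, 81, 7],  # -1
        [0, 0, 100, 0],  # +1 (G, invariant)
        [0, 0, 0, 100],  # +2 (U, invariant)
        [60, 3, 32, 5],  # +3
        [70, 8, 12, 10],  # +4
        [7, 6, 81, 6],  # +5
        [16, 17, 20, 47],  # +6
    ],
    dtype=float,
)


@dataclass(frozen=True)
class Splice5Scorer:
    """9-mer log-odds scorer for 5' splice-site (U1 recognition) likelihood.

    Scores stay in log10 domain.  The default table is built from donor-site
    position frequencies; ``from_table_file`` loads an external 9 x 4
    probability table (e.g. exported from a maximum-entropy model).
    """

    name: str = "splice5"
    frequencies: np.ndarray = field(
        default_factory=lambda: _DONOR_FREQS_PERCENT / 100.0
    )
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    log_domain: bool = True

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.shape != (9, 4):
            raise MotifError("5'SS table must be 9 x 4")
        object.__setattr__(self, "frequencies", f)

    @property
    def word_length(self) -> int:
        return 9

    def _log_odds(self) -> np.ndarray:
        probs = (self.frequencies + self.pseudocount) / (
            self.frequencies.sum(axis=1, keepdims=True) + 4 * self.pseudocount
        )
        return np.log10(probs) - np.log10(0.25)

    @property
    def floor(self) -> float:
        return float(self._log_odds().min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self._log_odds().max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(RNA_BASES[i] for i in self._log_odds().argmax(axis=1))

    @classmethod
    def from_table_file(cls, path: str | Path, name: str = "splice5") -> "Splice5Scorer":
        p = Path(path)
        if not p.exists():
            raise MotifError(f"5'SS score table not found: {p}")
        table = np.loadtxt(p)
        return cls(name=name, frequencies=table)

    def per_offset_scores_encoded(self, enc: np.ndarray) -> np.ndarray:
        lo = self._log_odds()
        k = self.word_length
        n, w = enc.shape
        if w < k:
            return np.empty((n, 0))
        windows = np.lib.stride_tricks.sliding_window_view(enc, k, axis=1)
        return lo[np.arange(k)[None, None, :], windows].sum(axis=-1)

    def per_offset_scores(self, seq: str) -> np.ndarray:
        return self.per_offset_scores_encoded(encode_sequence(seq)[None, :])[0]

    def score(self, seq: str) -> float:
        scores = self.per_offset_scores(seq)
        if scores.size == 0:
            raise MotifError("sequence shorter than the 9 nt splice-site word")
        return float(scores.max())


def u1_duplex_score(seq: str, scorer: U1DuplexScorer | None = None) -> float:
    """Maximum predicted U1 hybridization score within ``seq``."""
    return (scorer or U1DuplexScorer()).score(seq)


def splice5_score(seq: str, model: Splice5Scorer | None = None) -> float:
    """Maximum 5' splice-site log-odds score within ``seq`` (log10 domain)."""
    return (model or Splice5Scorer()).score(seq)


def shuffle_pwm(pwm: PWM, seed: int) -> PWM:
    """Permute the positions (columns) of a PWM, preserving their multiset.

    Deterministic for a given (pwm, seed); used to build shuffled-motif
    negative controls.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pwm))
    return PWM(
        name=f"{pwm.name}~shuf{seed}",
        matrix=pwm.matrix[perm],
        source_tag=pwm.source_tag,
    )


Representation = Union[PWM, KmerCountFeature, U1DuplexScorer, Splice5Scorer]


class MotifRegistry:
    """Ordered collection of scoring representations with unique ids."""

    def __init__(self, representations: Iterable[Representation]):
        self._reps: dict[str, Representation] = {}
        for rep in representations:
            if rep.name in self._reps:
                raise MotifError(f"duplicate representation id {rep.name!r}")
            self._reps[rep.name] = rep
        if not self._reps:
            raise MotifError("registry must contain at least one representation")

    @property
    def ids(self) -> list[str]:
        return list(self._reps)

    def __len__(self) -> int:
        return len(self._reps)

    def __iter__(self):
        return iter(self._reps.values())

    def __getitem__(self, rep_id: str) -> Representation:
        try:
            return self._reps[rep_id]
        except KeyError:
            raise MotifError(f"unknown representation id {rep_id!r}") from None

    def pwms(self) -> list[PWM]:
        return [r for r in self if isinstance(r, PWM)]


def default_baseline_registry() -> MotifRegistry:
    """The 15-representation default registry for the baseline CPA model.

    Covers the five core elements: the CFIm UGUA tetramer; two PAS models
    (the count-weighted hexamer PWM and a softer composite PAS PWM); the
    CA/UA cleavage dinucleotide; a U-rich element; four downstream-element
    (DSE) GU/U-rich PWMs plus the DSE k-mer count; and five RBP-style PWMs
    standing in for an externally supplied motif panel (synthetic stand-ins
    for database motifs, which arrive as PWM files in real runs).  The
    registry is data: any alternative set can be supplied per run.
    """
    reps: list[Representation] = [
        pwm_from_consensus("ugua", "UGUA", strength=0.97, source_tag="derived"),
        build_weighted_pas_pwm(PAS_HEXAMER_WEIGHTS, name="pas_hexamer"),
        pwm_from_consensus(
            "pas_composite", "AAUAAA", strength=0.70, source_tag="derived"
        ),
        PWM(
            name="cleavage_ca_ua",
            matrix=np.array([[0.0, 0.5, 0.0, 0.5], [1.0, 0.0, 0.0, 0.0]]),
            source_tag="derived",
        ),
        pwm_from_consensus("u_rich", "UUUUU", strength=0.85, source_tag="derived"),
        pwm_from_consensus("dse_gu8", "UGUGUGUG", strength=0.60, source_tag="derived"),
        pwm_from_consensus("dse_ug4", "UGUG", strength=0.75, source_tag="derived"),
        pwm_from_consensus("dse_u6", "UUUUUU", strength=0.65, source_tag="derived"),
        pwm_from_consensus("dse_g5", "GUGGU", strength=0.60, source_tag="derived"),
        KmerCountFeature(name="dse_kmers", kmers=DSE_KMERS),
        pwm_from_consensus("rbp_gcaug", "GCAUG", strength=0.85, source_tag="synthetic"),
        pwm_from_consensus("rbp_acac", "ACACA", strength=0.85, source_tag="synthetic"),
        pwm_from_consensus("rbp_are", "AUUUA", strength=0.85, source_tag="synthetic"),
        pwm_from_consensus("rbp_pyr", "UCUUC", strength=0.85, source_tag="synthetic"),
        pwm_from_consensus("rbp_agg", "AGGUA", strength=0.85, source_tag="synthetic"),
    ]
    return MotifRegistry(reps)


def synthetic_rbp_panel(n_pwms: int = 12, seed: int = 7) -> list[PWM]:
    """A synthetic RBP PWM panel for the constitutive-vs-cryptic stage.

    Contains one PAS-like motif (softened AAUAAA) plus randomly drawn
    consensus motifs of length 5-7; a desk-scale stand-in for a database
    panel of human RBP motifs supplied as files in real runs.
    """
    if n_pwms < 1:
        raise MotifError("panel must contain at least one PWM")
    rng = np.random.default_rng(seed)
    panel = [pwm_from_consensus("panel_pas_like", "AAUAAA", strength=0.8,
                                source_tag="synthetic")]
    for i in range(n_pwms - 1):
        length = int(rng.integers(5, 8))
        consensus = "".join(RNA_BASES[j] for j in rng.integers(0, 4, size=length))
        panel.append(
            pwm_from_consensus(
                f"panel_rbp{i:02d}_{consensus}", consensus,
                strength=float(rng.uniform(0.6, 0.9)), source_tag="synthetic",
            )
        )
    return panel


def load_registry(path: str | Path) -> MotifRegistry:
    """Load a registry from a YAML/JSON file.

    The file holds a list under ``representations``; each entry has an
    ``id``, a ``kind`` (``pwm`` | ``kmers`` | ``u1`` | ``splice5``) and
    either a ``file`` (pwm matrix or 5'SS table, resolved relative to the
    registry file) or inline parameters (``kmers`` list, ``consensus`` +
    ``strength`` for a consensus-built PWM).
    """
    import yaml

    path = Path(path)
    data = yaml.safe_load(path.read_text())
    entries = (data or {}).get("representations")
    if not entries:
        raise MotifError(f"{path}: no 'representations' listed")
    reps: list[Representation] = []
    for e in entries:
        kind = e.get("kind")
        rep_id = e.get("id")
        if not rep_id:
            raise MotifError(f"{path}: entry without an id: {e}")
        if kind == "pwm":
            if "file" in e:
                pwm = read_pwm_file(path.parent / e["file"], e.get("source_tag", "file"))
                reps.append(PWM(rep_id, pwm.matrix, pwm.source_tag))
            elif "consensus" in e:
                reps.append(
                    pwm_from_consensus(
                        rep_id, e["consensus"], e.get("strength", 0.9),
                        e.get("source_tag", "derived"),
                    )
                )
            else:
                raise MotifError(f"{path}: pwm entry {rep_id!r} needs file/consensus")
        elif kind == "kmers":
            reps.append(KmerCountFeature(rep_id, frozenset(e["kmers"])))
        elif kind == "u1":
            reps.append(U1DuplexScorer(name=rep_id))
        elif kind == "splice5":
            if "file" in e:
                reps.append(Splice5Scorer.from_table_file(path.parent / e["file"], rep_id))
            else:
                reps.append(Splice5Scorer(name=rep_id))
        else:
            raise MotifError(f"{path}: unknown representation kind {kind!r}")
    return MotifRegistry(reps)


# ---------------------------------------------------------------------------
# PWM file I/O: plain text, one matrix per file: ">name" then L rows of
# 4 whitespace-separated probabilities in A C G U order.


def read_pwm_file(path: str | Path, source_tag: str = "file") -> PWM:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise MotifError(f"{path}: expected a '>name' header line")
    name = lines[0][1:].strip()
    try:
        matrix = np.array([[float(x) for x in ln.split()] for ln in lines[1:]])
    except ValueError as exc:
        raise MotifError(f"{path}: malformed probability row: {exc}") from exc
    return PWM(name=name, matrix=matrix, source_tag=source_tag)


def write_pwm_file(pwm: PWM, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f">{pwm.name}\n")
        for row in pwm.matrix:
            fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
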