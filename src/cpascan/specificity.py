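"""Analytic specificity of the core CPA sequence elements in random sequence.

For an element with ``n`` equally weighted variants of word length ``k``
over an alphabet of size ``A``, searched within a window of ``W`` positions,
the expected-occurrence approximation of the probability of seeing the
element is ``n * W / A**k`` (using ``W`` placements, not ``W - k + 1``).
The five core elements and their search windows give, under uniform random
sequence:

===========================  =========================  ========
element                      n x W / A^k                 value
===========================  =========================  ========
UGUA (upstream)              1 x 100 / 4^4               0.39
PAS hexamer (13 variants)    13 x 20 / 4^6               0.063
U-rich (UUUU near site)      1 x 30 / 4^4                0.11
CA/UA cleavage dinucleotide  2 x 1 / 4^2                 0.13
GU-run DSE (8-mer, binary)   1 x 40 / 2^8                0.156
===========================  =========================  ========

The joint frequency of all five co-occurring around one base is the plain
product of the per-element probabilities, and its reciprocal (per kb) gives
the expected spacing of chance all-element sites.  With the PAS variants
weighted by their observed usage instead of equally, the PAS term drops to
0.022 and the expected spacing lengthens accordingly.

Two evaluation modes are provided: ``"printed"`` multiplies the values
rounded to the precision quoted above (the convention used for the headline
joint estimate), ``"exact"`` carries full precision.  No correction is made
for the A/U-rich composition of real genomes, which would make these
elements more frequent than the uniform model suggests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


class SpecificityError(ValueError):
    pass


@dataclass(frozen=True)
class ElementSpec:
    """Analytic description of one sequence element's chance occurrence."""

    name: str
    n_variants: int
    word_length: int
    alphabet_size: int
    window_positions: int
    weighted_probability: float | None = None  # overrides the analytic value
    printed_decimals: int = 2  # precision at which the value is quoted
    #: the conventionally quoted short value, when it is not the plain
    #: rounding of the analytic one (0.1171875 is quoted truncated as 0.11,
    #: 0.125 rounded up as 0.13)
    printed_value: float | None = None

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.word_length < 1:
            raise SpecificityError(f"{self.name}: variants and word length must be >= 1")
        if self.alphabet_size < 2:
            raise SpecificityError(f"{self.name}: alphabet size must be >= 2")
        if self.window_positions < 1:
            raise SpecificityError(f"{self.name}: window must have >= 1 position")


def element_probability(spec: ElementSpec, mode: str = "exact") -> float:
    """Expected-occurrence probability of one element in its search window.

    Returns ``weighted_probability`` when set, else
    ``n_variants * window_positions / alphabet_size ** word_length``.
    ``mode="printed"`` rounds to the element's quoted precision.
    """
    if spec.weighted_probability is not None:
        value = spec.weighted_probability
    else:
        value = (
            spec.n_variants
            * spec.window_positions
            / spec.alphabet_size**spec.word_length
        )
    if value > 1.0:
        raise SpecificityError(
            f"{spec.name}: expected occurrences {value:.3g} exceed 1; the "
            "occurrence-probability approximation breaks down"
        )
    if mode == "printed":
        if spec.printed_value is not None:
            return spec.printed_value
        return round(value, spec.printed_decimals)
    if mode != "exact":
        raise SpecificityError(f"unknown mode {mode!r} (use 'printed' or 'exact')")
    return value


def joint_frequency(probs: Sequence[float]) -> float:
    """Per-base frequency of all elements co-occurring: the plain product."""
    probs = list(probs)
    if not probs:
        raise SpecificityError("need at least one element probability")
    for p in probs:
        if not 0.0 < p <= 1.0:
            raise SpecificityError(f"probability {p} outside (0, 1]")
    return math.prod(probs)


def per_kb(frequency: float) -> float:
    """Convert a per-base frequency into 'one occurrence every N kb'."""
    if frequency <= 0:
        raise SpecificityError("frequency must be positive")
    return 1.0 / (frequency * 1000.0)


def _default_elements() -> tuple[ElementSpec, ...]:
    return (
        ElementSpec("UGUA", 1, 4, 4, 100, printed_decimals=2),
        ElementSpec("PAS", 13, 6, 4, 20, printed_decimals=3),
        ElementSpec("U-rich", 1, 4, 4, 30, printed_decimals=2, printed_value=0.11),
        ElementSpec("CA/UA", 2, 2, 4, 1, printed_decimals=2, printed_value=0.13),
        ElementSpec("DSE", 1, 8, 2, 40, printed_decimals=3),
    )


#: The five core elements with their default search-window geometry.
DEFAULT_ELEMENTS: tuple[ElementSpec, ...] = _default_elements()

#: PAS probability with hexamer variants weighted by observed usage at CPA
#: sites rather than equally; an input constant (the per-variant weights are
#: folded into it).
WEIGHTED_PAS_PROBABILITY = 0.022


def weighted_pas_element() -> ElementSpec:
    return ElementSpec(
        "PAS (usage-weighted)",
        13,
        6,
        4,
        20,
        weighted_probability=WEIGHTED_PAS_PROBABILITY,
        printed_decimals=3,
    )


def specificity_table(
    mode: str = "printed",
    elements: Iterable[ElementSpec] | None = None,
    pas_weighted: bool = False,
) -> pd.DataFrame:
    """Per-element probabilities plus the joint frequency and per-kb spacing.

    The returned frame has one row per element and a final ``joint`` row
    whose ``probability`` column holds the per-base joint frequency and
    whose ``every_kb`` column holds the expected spacing in kb.
    """
    elems = list(elements) if elements is not None else list(DEFAULT_ELEMENTS)
    if pas_weighted:
        elems = [weighted_pas_element() if e.name == "PAS" else e for e in elems]
    rows = [
        {"element": e.name, "probability": element_probability(e, mode), "every_kb": None}
        for e in elems
    ]
    joint = joint_frequency([r["probability"] for r in rows])
    rows.append({"element": "joint", "probability": joint, "every_kb": per_kb(joint)})
    return pd.DataFrame(rows)
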