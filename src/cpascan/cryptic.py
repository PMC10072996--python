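"""Second-stage discrimination of constitutive vs cryptic CPA sites.

Both classes pass the baseline model's bar; what separates them must lie in
signals beyond the core elements.  This stage therefore works on a tighter
-70..+70 window around the (annotated or called) CPA base, tiled into 20 nt
bins every 10 nt (13 bins), and scores each bin with two U1 snRNP
recognition proxies (a duplex-complementarity score and a 5' splice-site
log-odds score) plus a panel of RBP PWMs.  The classifier is the L1
logistic regression with the much stronger penalty C = 0.0018, chosen so
that only genuinely informative features survive; shuffled-PWM controls
(positions permuted per motif, seeded) probe whether performance depends on
the motifs' specific position order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from cpascan.datasets import LabeledWindow
from cpascan.evaluation import EvalResult, eval_from_scores
from cpascan.features import (
    CRYPTIC_GRID,
    BinGrid,
    FeatureMatrix,
    assemble_matrix,
    feature_names,
)
from cpascan.models import CRYPTIC_LR_C, ModelConfig, TrainedModel, train
from cpascan.motifs import (
    MotifRegistry,
    PWM,
    Splice5Scorer,
    U1DuplexScorer,
    shuffle_pwm,
)


class CrypticModelError(ValueError):
    pass


@dataclass
class CrypticStageConfig:
    """Configuration of the constitutive-vs-cryptic stage."""

    half_window: int = 70
    grid: BinGrid = field(default_factory=lambda: CRYPTIC_GRID)
    u1_scorers: tuple = field(
        default_factory=lambda: (U1DuplexScorer(), Splice5Scorer())
    )
    rbp_pwms: list[PWM] = field(default_factory=list)
    lr_strength: float = CRYPTIC_LR_C
    n_shuffles: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid.window_length != 2 * self.half_window:
            raise CrypticModelError(
                "grid window must equal 2 x half_window "
                f"({self.grid.window_length} != {2 * self.half_window})"
            )
        if self.n_shuffles < 1:
            raise CrypticModelError("n_shuffles must be >= 1")
        if len(self.u1_scorers) + len(self.rbp_pwms) == 0:
            raise CrypticModelError("at least one representation is required")

    def registry(self, pwms: Sequence[PWM] | None = None) -> MotifRegistry:
        return MotifRegistry(
            list(self.u1_scorers) + list(pwms if pwms is not None else self.rbp_pwms)
        )

    @property
    def n_columns(self) -> int:
        return (len(self.u1_scorers) + len(self.rbp_pwms)) * self.grid.n_bins

    def model_config(self) -> ModelConfig:
        return ModelConfig.linear(C=self.lr_strength, seed=self.seed)


def recenter_window(window: LabeledWindow, half_window: int = 70) -> LabeledWindow:
    """Slice a site-centred window down to +/-half_window around its site."""
    if window.site_offset is None:
        raise CrypticModelError(f"window for {window.gene_id} has no site offset")
    lo = window.site_offset - half_window
    hi = window.site_offset + half_window
    if lo < 0 or hi > len(window.sequence):
        raise CrypticModelError(
            f"cannot recenter {window.gene_id}: +/-{half_window} exceeds the "
            "stored window"
        )
    iv = window.window
    from cpascan.sequence_io import GenomicInterval

    if iv.strand == "+":
        new_iv = GenomicInterval(iv.chrom, iv.start + lo, iv.start + hi, "+")
    else:
        new_iv = GenomicInterval(iv.chrom, iv.end - hi, iv.end - lo, "-")
    return LabeledWindow(
        window.gene_id,
        new_iv,
        window.sequence[lo:hi],
        window.label,
        site_offset=half_window,
        score=window.score,
    )


def _as_windows(windows: Iterable, label: str) -> list:
    out = []
    for w in windows:
        if isinstance(w, str):
            out.append(
                type("W", (), {"sequence": w, "label": label, "gene_id": ""})()
            )
        else:
            out.append(
                type("W", (), {"sequence": w.sequence, "label": label,
                               "gene_id": getattr(w, "gene_id", "")})()
            )
    return out


def build_cryptic_matrix(
    constitutive_windows: Sequence,
    cryptic_windows: Sequence,
    config: CrypticStageConfig,
    pwms: Sequence[PWM] | None = None,
) -> FeatureMatrix:
    """Feature matrix for the constitutive-vs-cryptic task.

    Windows must be ``2 * half_window`` nt, site-centred.  Labels are
    ``constitutive`` (the positive class) and ``cryptic``.  Column count is
    ``(n_scorers + n_pwms) * n_bins``.
    """
    windows = _as_windows(constitutive_windows, "constitutive") + _as_windows(
        cryptic_windows, "cryptic"
    )
    registry = config.registry(pwms)
    matrix = assemble_matrix(windows, registry, config.grid)
    return matrix


def u1_positional_profile(
    windows: Sequence, scorer
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position median and standard deviation of a scorer's per-offset
    scores across equal-length windows."""
    seqs = [w if isinstance(w, str) else w.sequence for w in windows]
    if not seqs:
        raise CrypticModelError("empty window set")
    if len({len(s) for s in seqs}) != 1:
        raise CrypticModelError("windows must be equal length")
    scores = np.stack([scorer.per_offset_scores(s) for s in seqs])
    return np.median(scores, axis=0), scores.std(axis=0)


def train_cryptic_model(
    train_constitutive: Sequence,
    train_cryptic: Sequence,
    config: CrypticStageConfig,
    pwms: Sequence[PWM] | None = None,
) -> TrainedModel:
    matrix = build_cryptic_matrix(train_constitutive, train_cryptic, config, pwms)
    return train(config.model_config(), matrix, positive_label="constitutive")


def _evaluate_windows(
    model: TrainedModel,
    test_constitutive: Sequence,
    test_cryptic: Sequence,
    config: CrypticStageConfig,
    pwms: Sequence[PWM] | None,
) -> EvalResult:
    matrix = build_cryptic_matrix(test_constitutive, test_cryptic, config, pwms)
    scores = model.predict_proba(matrix.values)
    y = (matrix.labels == "constitutive").astype(int)
    return eval_from_scores(scores, y)


def shuffle_control(
    train_constitutive: Sequence,
    train_cryptic: Sequence,
    test_constitutive: Sequence,
    test_cryptic: Sequence,
    config: CrypticStageConfig,
) -> dict:
    """Train/evaluate the stage with the original PWMs and with
    position-shuffled PWM controls.

    Each of the ``n_shuffles`` controls permutes every PWM's positions
    independently (seeded from the config seed), rebuilds the features,
    retrains and re-evaluates.  Returns ``{"original": EvalResult,
    "shuffles": [EvalResult, ...]}``.
    """
    model = train_cryptic_model(train_constitutive, train_cryptic, config)
    original = _evaluate_windows(
        model, test_constitutive, test_cryptic, config, None
    )
    shuffles = []
    for j in range(config.n_shuffles):
        shuffled = [
            shuffle_pwm(pwm, seed=config.seed + 10_007 * (j + 1) + idx)
            for idx, pwm in enumerate(config.rbp_pwms)
        ]
        m = train_cryptic_model(
            train_constitutive, train_cryptic, config, pwms=shuffled
        )
        shuffles.append(
            _evaluate_windows(m, test_constitutive, test_cryptic, config, shuffled)
        )
    return {"original": original, "shuffles": shuffles}
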