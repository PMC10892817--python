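"""Weighted soft voting over the four member classifiers.

The ensemble fuses (CWT, inception), (CWT, residual), (GASF, residual) and
(GADF, residual).  Each member emits per-minute class probabilities; the
fused score of a class is the weight-convex combination of the members'
probabilities for that class, and the label is its argmax.  An exact tie is
broken toward ``A``: a missed apnea minute is the costlier error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

N_MEMBERS = 4

#: canonical (modality, architecture) pairing of the four members
MEMBER_KEYS = (
    ("CWT", "osa-inception"),
    ("CWT", "osa-residual"),
    ("GASF", "osa-residual"),
    ("GADF", "osa-residual"),
)


@dataclass
class EnsembleWeights:
    """Four nonnegative member weights, normalized to sum to 1."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.shape != (N_MEMBERS,):
            raise ValidationError(f"exactly {N_MEMBERS} weights required")
        if np.any(self.w < 0) or self.w.sum() <= 0:
            raise ValidationError("weights must be nonnegative with positive sum")
        self.w = self.w / self.w.sum()


@dataclass
class MemberPredictions:
    """Aligned per-segment probability rows from each member.

    ``probs`` has shape (n_members, n_segments, 2) with columns [p(N), p(A)];
    all members must refer to the same segments in the same order.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if (self.probs.ndim != 3 or self.probs.shape[0] != N_MEMBERS
                or self.probs.shape[2] != 2):
            raise ValidationError(
                f"member predictions must be ({N_MEMBERS}, n, 2), "
                f"got {self.probs.shape}"
            )
        if not np.allclose(self.probs.sum(axis=2), 1.0, atol=1e-6):
            raise ValidationError("member probability rows must sum to 1")


def soft_vote(preds: MemberPredictions,
              weights: EnsembleWeights) -> tuple[np.ndarray, np.ndarray]:
    """Fuse member probabilities; returns (labels, fused A-scores).

    ``labels`` are 0 (N) / 1 (A); the fused A-score is the ROC score.  An
    exact N/A tie resolves to A.
    """
    fused = np.tensordot(weights.w, preds.probs, axes=(0, 0))   # (n, 2)
    scores = fused[:, 1]
    labels = (scores >= fused[:, 0]).astype(int)                # tie -> A
    return labels, scores


def accuracy_weights(val_accuracies) -> EnsembleWeights:
    """Default weights: member validation accuracies, normalized to sum 1."""
    a = np.asarray(val_accuracies, dtype=np.float64)
    if a.shape != (N_MEMBERS,):
        raise ValidationError(f"exactly {N_MEMBERS} accuracies required")
    if np.any(a <= 0) or np.any(a > 1):
        raise ValidationError("accuracies must lie in (0, 1]")
    return EnsembleWeights(a / a.sum())
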