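"""Y-maze spontaneous alternation: visit extraction, triad scoring, nulls.

Spontaneous alternation is the fraction of overlapping triads — windows of
three consecutive arm visits — in which all three arms are distinct
(ABC, ACB, BCA, ...).  Re-entries into the previously visited arm count as
real visits, which puts the chance level for an unbiased visitor at
2/9 = 22.2%: of the nine equally likely (second, third) continuations of a
triad, two complete it with three distinct arms.  A permutation null that
shuffles the observed arm-label multiset gives a sequence-specific chance
level (close to 25% for near-equal arm counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import (
    ARMS,
    ArenaGeometry,
    ArmVisitSequence,
    Track,
    ValidationError,
)

__all__ = [
    "AlternationResult",
    "PermutationNull",
    "SESSION_S",
    "extract_arm_visits",
    "alternation_percentage",
    "correct_triad_count",
    "chance_level",
    "permutation_null",
    "total_arm_entries",
]

SESSION_S = 600.0  # 10-minute session, truncated from the first sample


@dataclass(frozen=True)
class AlternationResult:
    """Triad-based alternation score of one visit sequence.

    ``alternation_pct`` is ``100 * n_correct / n_triads`` and is None
    (undefined) when fewer than three visits were made.
    """

    subject_id: str
    n_visits: int
    n_triads: int
    n_correct: int
    alternation_pct: Optional[float]

    def __post_init__(self) -> None:
        if self.n_triads != max(0, self.n_visits - 2):
            raise ValidationError("n_triads must equal max(0, n_visits - 2)")
        if not (0 <= self.n_correct <= max(self.n_triads, 0)):
            raise ValidationError("n_correct out of range")
        if (self.alternation_pct is None) != (self.n_triads == 0):
            raise ValidationError("pct undefined exactly when no triads exist")


@dataclass(frozen=True)
class PermutationNull:
    """Null distribution of the alternation score under label shuffling."""

    n_perm: int
    seed: int
    mean_pct: float
    sd_pct: float
    per_perm: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# visit extraction from a track
# ---------------------------------------------------------------------------


def extract_arm_visits(track: Track, arena: Optional[ArenaGeometry] = None,
                       session_s: float = SESSION_S) -> ArmVisitSequence:
    """Derive the arm-visit sequence from a Y-maze track.

    A visit to arm X opens at the first sample where **both** the nose and
    the center of gravity are inside zone ``arm_X`` (which starts 3 cm into
    the arm) and closes at the first subsequent sample where either point
    has left that zone.  Because closure requires leaving the arm zone,
    consecutive same-arm visits are separated by at least one
    center/elsewhere sample; such re-entries are real visits.  The track is
    truncated ``session_s`` (600 s) after its first sample.
    """
    arena = arena if arena is not None else track.arena
    if arena.kind != "ymaze":
        raise ValidationError(f"expected a ymaze arena, got {arena.kind!r}")
    if len(track) < 2:
        raise ValidationError("track too short to extract visits")
    t = track.t
    keep = t < t[0] + session_s
    t = t[keep]
    nose = track.nose[keep]
    cog = track.cog[keep]
    ok = np.isfinite(nose).all(axis=1) & np.isfinite(cog).all(axis=1)

    both_in = {}
    for arm in ARMS:
        zone = f"arm_{arm}"
        with np.errstate(invalid="ignore"):
            n_in = arena.zone_contains(zone, nose[:, 0], nose[:, 1])
            c_in = arena.zone_contains(zone, cog[:, 0], cog[:, 1])
        both_in[arm] = np.where(ok, n_in & c_in, False)

    visits = []
    open_arm = None
    t_open = 0.0
    for i in range(len(t)):
        if open_arm is not None and not both_in[open_arm][i]:
            visits.append((open_arm, t_open, float(t[i])))
            open_arm = None
        if open_arm is None:
            for arm in ARMS:
                if both_in[arm][i]:
                    open_arm = arm
                    t_open = float(t[i])
                    break
    if open_arm is not None:
        # visit still open at session end: close at the last sample time + eps
        end = float(t[-1])
        visits.append((open_arm, t_open, end if end > t_open else t_open + 1e-9))
    return ArmVisitSequence(track.subject_id, visits)


# ---------------------------------------------------------------------------
# alternation statistic and nulls
# ---------------------------------------------------------------------------


def _triad_correct_mask(labels: np.ndarray) -> np.ndarray:
    a, b, c = labels[:-2], labels[1:-1], labels[2:]
    return (a != b) & (b != c) & (a != c)


def correct_triad_count(labels: Sequence[str]) -> Tuple[int, int]:
    """(number of correct triads, number of triads) for a label sequence."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < 3:
        return 0, 0
    mask = _triad_correct_mask(labels)
    return int(mask.sum()), n - 2


def alternation_percentage(seq: ArmVisitSequence) -> AlternationResult:
    """Spontaneous alternation over overlapping triads of consecutive visits.

    A correct triad is a window of three consecutive visits covering all
    three arms; windows slide by one visit, giving ``n_visits - 2`` triads.
    With fewer than three visits the percentage is undefined (None).
    """
    labels = seq.labels
    n_correct, n_triads = correct_triad_count(labels)
    pct = 100.0 * n_correct / n_triads if n_triads > 0 else None
    return AlternationResult(seq.subject_id, len(labels), n_triads, n_correct, pct)


def chance_level(model: str = "iid_uniform",
                 counts: Optional[Sequence[int]] = None) -> float:
    """Expected alternation percentage under a null visiting model.

    ``iid_uniform``: visits drawn independently and uniformly from the
    three arms; a triad is correct with probability 3!/3^2 relative to the
    free continuations, i.e. 2/9, so the chance level is 200/9 = 22.22%.

    ``permutation``: a uniform random shuffle of a fixed label multiset
    with per-arm counts ``(n_A, n_B, n_C)``; three consecutive positions
    are all distinct with probability
    ``6 n_A n_B n_C / (N (N-1) (N-2))``, N the total count.  For equal
    counts (10,10,10) this gives 24.63%, slightly above 2/9 because
    sampling without replacement favours label changes.
    """
    if model == "iid_uniform":
        return 200.0 / 9.0
    if model == "permutation":
        if counts is None or len(counts) != 3:
            raise ValidationError("permutation model needs three arm counts")
        na, nb, nc = (int(c) for c in counts)
        if min(na, nb, nc) < 0:
            raise ValidationError("arm counts must be non-negative")
        n = na + nb + nc
        if n < 3:
            raise ValidationError("need at least three visits in total")
        return 100.0 * 6.0 * na * nb * nc / (n * (n - 1) * (n - 2))
    raise ValidationError(f"unknown chance model {model!r}")


def permutation_null(seq: ArmVisitSequence, n_perm: int, seed: int,
                     keep_per_perm: bool = False) -> PermutationNull:
    """Null alternation distribution under uniform shuffles of the labels.

    Each permutation is a uniform random shuffle of the observed arm-label
    multiset (per-arm counts preserved exactly); the alternation percentage
    is computed per shuffle and summarised as mean and SD.  The mean
    converges to ``chance_level('permutation', counts)`` as ``n_perm``
    grows.  Fully reproducible from ``seed``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    labels = np.asarray(seq.labels)
    if len(labels) < 3:
        raise ValidationError("need at least three visits for a permutation null")
    rng = np.random.default_rng(seed)
    codes = np.searchsorted(np.array(ARMS), labels)
    mat = np.tile(codes, (n_perm, 1))
    mat = rng.permuted(mat, axis=1)
    a, b, c = mat[:, :-2], mat[:, 1:-1], mat[:, 2:]
    correct = (a != b) & (b != c) & (a != c)
    pcts = 100.0 * correct.mean(axis=1)
    return PermutationNull(
        n_perm=n_perm,
        seed=seed,
        mean_pct=float(pcts.mean()),
        sd_pct=float(pcts.std(ddof=1)) if n_perm > 1 else 0.0,
        per_perm=pcts if keep_per_perm else None,
    )


def total_arm_entries(seq: ArmVisitSequence) -> int:
    """Total number of arm visits made during the session."""
    return len(seq)
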