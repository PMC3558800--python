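"""Per-match-state information content and most-informative-model selection.

The information content of a match state is the Kullback-Leibler divergence
of its emission distribution from a background amino-acid composition,

    IC = sum_a p(a) * ln(p(a) / q(a))        [nats]

with the convention 0 * ln(0/q) = 0.  When a substitution falls inside
several significant domains, the model whose match state carries the most
information is the one interrogated for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import rel_entr

from .errors import HmmvarError, ValidationError
from .profile_hmm import (
    BackgroundComposition,
    ProfileHMM,
    SOURCE_PRIORITY,
    background_composition,
)


class NoCandidateModels(HmmvarError):
    """No model covers the substitution at a match state; no prediction is possible."""


@dataclass(frozen=True)
class InformationScore:
    """Information content of one candidate match state, in nats."""

    model_id: str
    state_index: int
    value: float


def information_content(
    emissions: np.ndarray | Sequence[float], background: BackgroundComposition
) -> float:
    """KL divergence (nats) of ``emissions`` from ``background``.

    Zero-probability emission terms contribute nothing; a zero in the
    background under a non-zero emission is a domain error.
    """
    p = np.asarray(emissions, dtype=float)
    if p.shape != (20,):
        raise ValidationError(f"emissions must be a 20-vector, got shape {p.shape}")
    if abs(p.sum() - 1.0) > 1e-4:  # matches profile row-sum tolerance (5-dp files)
        raise ValidationError(f"emissions sum to {p.sum():.8f}, not 1")
    q = background.probabilities
    if np.any((q <= 0) & (p > 0)):
        raise ValidationError(
            "background has zero mass where emissions are non-zero; KL undefined"
        )
    # rel_entr handles the p=0 convention and returns inf only where q=0 < p
    value = float(rel_entr(p, q).sum())
    return max(value, 0.0)  # clip the tiny negative round-off at p == q


def _window_indices(state: int, length: int, window: int) -> range:
    half = window // 2
    lo = max(1, state - half)
    hi = min(length, state + half)
    return range(lo, hi + 1)


def state_information(
    model: ProfileHMM,
    state_index: int,
    background: BackgroundComposition | None = None,
    window: int = 1,
) -> float:
    """Information content at a match state, optionally averaged over a
    symmetric window of ``window`` states (clipped at the model ends).

    Without an explicit ``background`` the model's own resolved composition
    (COMPO line, else uniform) is the reference.
    """
    if not 1 <= state_index <= model.length:
        raise ValidationError(
            f"state {state_index} outside model {model.model_id} of length {model.length}"
        )
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    bg = background if background is not None else background_composition(model)
    values = [
        information_content(model.match_emissions[s - 1], bg)
        for s in _window_indices(state_index, model.length, window)
    ]
    return float(np.mean(values))


def rank_candidates(
    candidates: Sequence[tuple[ProfileHMM, int]],
    background: BackgroundComposition | None = None,
    window: int = 1,
) -> list[InformationScore]:
    """Order candidate (model, state) pairs by decreasing information content.

    The head of the returned list is the selected model/state.  Each
    candidate is measured against ``background`` when supplied (for
    cross-model comparability), otherwise against its own model's resolved
    composition.  Ties break deterministically by library priority
    (superfamily > Pfam-A > Pfam-B > ab initio), then model_id.
    """
    scored = []
    for model, state in candidates:
        value = state_information(model, state, background=background, window=window)
        key = (-value, SOURCE_PRIORITY[model.source], model.model_id)
        scored.append((key, InformationScore(model.model_id, state, value)))
    scored.sort(key=lambda item: item[0])
    return [s for _, s in scored]


def select_model(
    candidates: Sequence[tuple[ProfileHMM, int]],
    background: BackgroundComposition | None = None,
    window: int = 1,
) -> tuple[ProfileHMM, int]:
    """The most informative candidate; raises :class:`NoCandidateModels` when empty."""
    if not candidates:
        raise NoCandidateModels("no model covers this substitution at a match state")
    best = rank_candidates(candidates, background=background, window=window)[0]
    for model, state in candidates:
        if model.model_id == best.model_id and state == best.state_index:
            return model, state
    raise AssertionError("ranked head not among candidates")  # pragma: no cover
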