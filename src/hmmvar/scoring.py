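"""Substitution scoring and the end-to-end prediction pipeline.

The score compares the match-state emission probability of the wild-type
residue (P_w) with that of the mutant (P_m) at the substitution's position
in the most informative covering model.  A score near zero means no
significant change in probability; scores below zero mark unfavourable
substitutions (the mutant is less likely than the wild type), scores above
zero favourable ones, and larger reductions in probability mean larger
predicted effects.

Two algebraic strategies satisfy that contract and are selectable:

* ``ratio`` (default):   S = ln(P_m / P_w)
  and its weighted form  S = ln((P_m * W_n) / (P_w * W_d));
* ``odds``:              S = ln[(P_m / (1 - P_m)) / (P_w / (1 - P_w))]
  and its weighted form  S = ln[((1 - P_w) * W_n) / ((1 - P_m) * W_d)].

For the default pair the weighted score is the unweighted score plus the
constant offset ln(W_n / W_d).  A raw score is compared against a prediction
threshold: substitutions scoring strictly below it are called damaging.
The default thresholds, -3.0 for unweighted and -1.5 for weighted scoring,
are the points where sensitivity and specificity were jointly maximised on
a large human disease/neutral benchmark; both are overridable.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .conservation import select_model
from .domains import (
    DEFAULT_E_THRESHOLD,
    DomainHit,
    Substitution,
    candidate_models,
    significant_hits,
)
from .errors import ValidationError
from .profile_hmm import BackgroundComposition, ModelSource, ProfileHMM, emission_probability
from .weights import WeightTable, weights_for

logger = logging.getLogger(__name__)

#: Probabilities below this are floored before taking logs ("*" cells occur
#: in real models; downstream ROC analysis needs finite scores).
DEFAULT_EPSILON = 1e-10

#: Default prediction thresholds per scoring method.
UNWEIGHTED_THRESHOLD = -3.0
WEIGHTED_THRESHOLD = -1.5


class Call(enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    NO_PREDICTION = "no_prediction"


class Method(enum.Enum):
    UNWEIGHTED = "unweighted"
    WEIGHTED = "weighted"


FORMULAS = ("ratio", "odds")


def _floor(p: float, epsilon: float, what: str) -> float:
    if p < epsilon:
        logger.warning("%s probability %.3g floored at epsilon %.1g", what, p, epsilon)
        return epsilon
    return p


def _check_formula(formula: str) -> None:
    if formula not in FORMULAS:
        raise ValidationError(f"formula must be one of {FORMULAS}, got {formula!r}")


def unweighted_score(
    p_wild: float,
    p_mutant: float,
    formula: str = "ratio",
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Species-independent effect score from the two emission probabilities.

    Zero at P_m = P_w, strictly increasing in P_m, strictly decreasing in
    P_w, for either strategy.  Zero probabilities are floored at ``epsilon``
    rather than producing infinities.
    """
    _check_formula(formula)
    pw = _floor(p_wild, epsilon, "wild-type")
    pm = _floor(p_mutant, epsilon, "mutant")
    if formula == "ratio":
        return math.log(pm / pw)
    pw = min(pw, 1.0 - epsilon)
    pm = min(pm, 1.0 - epsilon)
    return math.log((pm / (1.0 - pm)) / (pw / (1.0 - pw)))


def weighted_score(
    p_wild: float,
    p_mutant: float,
    w_d: float,
    w_n: float,
    formula: str = "ratio",
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Effect score modulated by the domain's pathogenicity weights.

    Strictly decreasing in W_d and increasing in W_n; reduces to the
    unweighted score when W_d = W_n.
    """
    _check_formula(formula)
    if w_d <= 0 or w_n <= 0:
        raise ValidationError(
            f"pathogenicity weights must be positive, got W_d={w_d}, W_n={w_n}"
        )
    pw = _floor(p_wild, epsilon, "wild-type")
    pm = _floor(p_mutant, epsilon, "mutant")
    if formula == "ratio":
        return math.log((pm * w_n) / (pw * w_d))
    pw = min(pw, 1.0 - epsilon)
    pm = min(pm, 1.0 - epsilon)
    return math.log(((1.0 - pw) * w_n) / ((1.0 - pm) * w_d))


def classify(score: float | None, threshold: float) -> Call:
    """Damaging iff ``score < threshold`` (strict); a tie is tolerated."""
    if score is None:
        return Call.NO_PREDICTION
    return Call.DAMAGING if score < threshold else Call.TOLERATED


@dataclass(frozen=True)
class PredictConfig:
    """Knobs of the prediction pipeline, all defaulting to the published setup."""

    e_threshold: float = DEFAULT_E_THRESHOLD
    formula: str = "ratio"
    threshold: float | None = None  # None -> method default
    epsilon: float = DEFAULT_EPSILON
    background: BackgroundComposition | None = None
    window: int = 1

    def resolved_threshold(self, method: Method) -> float:
        if self.threshold is not None:
            return self.threshold
        return WEIGHTED_THRESHOLD if method is Method.WEIGHTED else UNWEIGHTED_THRESHOLD


@dataclass(frozen=True)
class Prediction:
    """The scored consequence of one substitution."""

    substitution: Substitution
    method: Method
    call: Call
    threshold: float
    model_id: str | None = None
    state_index: int | None = None
    p_wild: float | None = None
    p_mutant: float | None = None
    score: float | None = None
    low_support: bool = False

    def __post_init__(self) -> None:
        if (self.score is None) != (self.call is Call.NO_PREDICTION):
            raise ValidationError("call is no_prediction iff the score is absent")
        if self.score is not None and self.call is not classify(self.score, self.threshold):
            raise ValidationError("call inconsistent with score and threshold")


def predict(
    sub: Substitution,
    hits: Sequence[DomainHit],
    library: Mapping[str, ProfileHMM],
    weights: WeightTable | None = None,
    config: PredictConfig = PredictConfig(),
) -> Prediction:
    """Score one substitution end to end.

    Pipeline: filter hits for significance, collect candidate (model, match
    state) pairs covering the position, pick the most informative one by KL
    information content, read P_w and P_m off its match state, score
    (weighted when a weight table is supplied) and classify.

    In weighted mode only domain-library models participate — weights exist
    only for curated domains, so whole-protein ab initio models never carry
    a weight and are excluded; a substitution outside all weighted domains
    gets no prediction.
    """
    method = Method.WEIGHTED if weights is not None else Method.UNWEIGHTED
    threshold = config.resolved_threshold(method)

    filtered = significant_hits(hits, config.e_threshold)
    candidates = candidate_models(sub, filtered, library)
    if method is Method.WEIGHTED:
        candidates = [
            (model, state)
            for model, state in candidates
            if model.source is not ModelSource.AB_INITIO
        ]
    if not candidates:
        return Prediction(sub, method, Call.NO_PREDICTION, threshold)

    model, state = select_model(
        candidates, background=config.background, window=config.window
    )
    p_wild = emission_probability(model, state, sub.wild_type)
    p_mutant = emission_probability(model, state, sub.mutant)
    low_support = p_wild < config.epsilon
    if low_support:
        logger.warning(
            "wild-type residue %s has probability %.3g at %s state %d; "
            "scoring with floored probability",
            sub, p_wild, model.model_id, state,
        )

    if method is Method.WEIGHTED:
        w_d, w_n = weights_for(model.model_id, weights)
        score = weighted_score(
            p_wild, p_mutant, w_d, w_n, formula=config.formula, epsilon=config.epsilon
        )
    else:
        score = unweighted_score(
            p_wild, p_mutant, formula=config.formula, epsilon=config.epsilon
        )

    return Prediction(
        substitution=sub,
        method=method,
        call=classify(score, threshold),
        threshold=threshold,
        model_id=model.model_id,
        state_index=state,
        p_wild=p_wild,
        p_mutant=p_mutant,
        score=score,
        low_support=low_support,
    )


def predict_all(
    subs: Sequence[Substitution],
    hits: Sequence[DomainHit],
    library: Mapping[str, ProfileHMM],
    weights: WeightTable | None = None,
    config: PredictConfig = PredictConfig(),
) -> list[Prediction]:
    """Vector convenience over :func:`predict`, preserving input order."""
    return [predict(s, hits, library, weights=weights, config=config) for s in subs]
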