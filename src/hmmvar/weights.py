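"""Domain-level pathogenicity weights.

Disease-associated and neutral substitutions from reference catalogues are
mapped onto the domain models covering them; the per-model tallies, with a
pseudo-count to keep every weight positive, yield the weights W_d and W_n
that modulate the weighted score.  A model never hit by either catalogue is
weight-neutral (W_d = W_n = pseudo-count).

Weights capture which protein domains tolerate missense change poorly; they
are not trained on the test substitutions themselves, and a leave-one-out
adjustment removes a substitution's own contribution before it is scored to
avoid circularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .domains import (
    DEFAULT_E_THRESHOLD,
    DomainHit,
    Substitution,
    candidate_models,
    significant_hits,
)
from .errors import ConsistencyError, FormatError, ValidationError
from .profile_hmm import ProfileHMM

DISEASE = "disease"
NEUTRAL = "neutral"
LABELS = (DISEASE, NEUTRAL)

#: Default pseudo-count added to both tallies, avoiding zero-divisible terms.
DEFAULT_PSEUDO_COUNT = 1.0

RecordKey = tuple[str, int, str, str, str]  # protein, position, wt, mut, label


def record_key(sub: Substitution, label: str) -> RecordKey:
    if label not in LABELS:
        raise ValidationError(f"label must be one of {LABELS}, got {label!r}")
    return (sub.protein_id, sub.position, sub.wild_type, sub.mutant, label)


@dataclass(frozen=True)
class WeightTable:
    """Per-model disease/neutral tallies and the derived weights.

    ``counts`` maps model_id -> (disease_count, neutral_count).
    ``memberships`` records, per distinct labelled substitution, the set of
    models it was counted into — the bookkeeping that makes leave-one-out
    exact.  ``normalized`` selects the relative-frequency weight variant
    (c + k) / (T + k) instead of the default c + k; the two differ only by a
    score offset constant across all substitutions.
    """

    counts: Mapping[str, tuple[int, int]]
    memberships: Mapping[RecordKey, frozenset[str]] = field(default_factory=dict)
    pseudo_count: float = DEFAULT_PSEUDO_COUNT
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.pseudo_count <= 0:
            raise ValidationError(f"pseudo-count must be > 0, got {self.pseudo_count}")
        for model_id, (c_d, c_n) in self.counts.items():
            if c_d < 0 or c_n < 0:
                raise ConsistencyError(
                    f"negative tally for model {model_id}: ({c_d}, {c_n})"
                )
        object.__setattr__(self, "counts", dict(self.counts))
        object.__setattr__(self, "memberships", dict(self.memberships))

    @property
    def total_disease(self) -> int:
        return sum(c for c, _ in self.counts.values())

    @property
    def total_neutral(self) -> int:
        return sum(c for _, c in self.counts.values())

    def __contains__(self, model_id: str) -> bool:
        return model_id in self.counts


def weights_for(model_id: str, table: WeightTable) -> tuple[float, float]:
    """The pathogenicity weights (W_d, W_n) for a model.

    Default form: count + pseudo-count, so an unmapped model is exactly
    weight-neutral.  With ``table.normalized`` the counts are additionally
    divided by the pseudo-counted dataset totals.
    """
    c_d, c_n = table.counts.get(model_id, (0, 0))
    k = table.pseudo_count
    w_d, w_n = c_d + k, c_n + k
    if table.normalized:
        w_d /= table.total_disease + k
        w_n /= table.total_neutral + k
    return w_d, w_n


def count_mappings(
    mutations: Iterable[tuple[Substitution, str]],
    hits: Sequence[DomainHit],
    library: Mapping[str, ProfileHMM],
    e_threshold: float = DEFAULT_E_THRESHOLD,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
    normalized: bool = False,
) -> WeightTable:
    """Tally labelled substitutions onto the significant models covering them.

    A substitution inside several overlapping domains increments every
    covering model's tally.  Substitutions outside all domains (or covered
    only at insert states) contribute nothing.  Duplicate records — same
    (protein, position, wild-type, mutant, label) — are counted once.
    """
    filtered = significant_hits(hits, e_threshold)
    counts: dict[str, list[int]] = {}
    memberships: dict[RecordKey, frozenset[str]] = {}
    for sub, label in mutations:
        key = record_key(sub, label)
        if key in memberships:
            continue
        models = frozenset(
            model.model_id for model, _ in candidate_models(sub, filtered, library)
        )
        if not models:
            continue
        memberships[key] = models
        column = 0 if label == DISEASE else 1
        for model_id in models:
            counts.setdefault(model_id, [0, 0])[column] += 1
    return WeightTable(
        counts={m: (c[0], c[1]) for m, c in counts.items()},
        memberships=memberships,
        pseudo_count=pseudo_count,
        normalized=normalized,
    )


def leave_one_out(table: WeightTable, sub: Substitution, label: str) -> WeightTable:
    """Remove ``sub``'s own contribution, if any, from the tallies.

    If the labelled substitution was counted into the table, every model it
    was counted into is decremented by one and a new table is returned;
    otherwise the table is returned unchanged.  The input is never mutated.
    """
    key = record_key(sub, label)
    models = table.memberships.get(key)
    if models is None:
        return table
    counts = {m: list(c) for m, c in table.counts.items()}
    column = 0 if label == DISEASE else 1
    for model_id in models:
        if model_id not in counts or counts[model_id][column] < 1:
            raise ConsistencyError(
                f"cannot decrement {label} tally of model {model_id} below zero"
            )
        counts[model_id][column] -= 1
    memberships = dict(table.memberships)
    del memberships[key]
    return WeightTable(
        counts={m: (c[0], c[1]) for m, c in counts.items()},
        memberships=memberships,
        pseudo_count=table.pseudo_count,
        normalized=table.normalized,
    )


def add_record(
    table: WeightTable, sub: Substitution, label: str, models: frozenset[str]
) -> WeightTable:
    """Inverse of :func:`leave_one_out`: count a labelled substitution back in."""
    key = record_key(sub, label)
    if key in table.memberships:
        raise ConsistencyError(f"record {key} already counted")
    if not models:
        raise ValidationError("a counted record must map onto at least one model")
    counts = {m: list(c) for m, c in table.counts.items()}
    column = 0 if label == DISEASE else 1
    for model_id in models:
        counts.setdefault(model_id, [0, 0])[column] += 1
    memberships = dict(table.memberships)
    memberships[key] = models
    return WeightTable(
        counts={m: (c[0], c[1]) for m, c in counts.items()},
        memberships=memberships,
        pseudo_count=table.pseudo_count,
        normalized=table.normalized,
    )


# ---------------------------------------------------------------------------
# Serialization


def read_labeled_mutations(path: str | Path) -> list[tuple[Substitution, str]]:
    """Read a labelled substitution table: protein_id, position, wt, mut, label."""
    records: list[tuple[Substitution, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(
                    f"expected 5 tab-separated columns, found {len(parts)}", lineno
                )
            protein_id, pos_txt, wt, mut, label = parts
            if label not in LABELS:
                raise FormatError(f"label must be one of {LABELS}, got {label!r}", lineno)
            try:
                sub = Substitution(protein_id, int(pos_txt), wt, mut)
            except (ValueError, ValidationError) as exc:
                raise FormatError(str(exc), lineno) from exc
            records.append((sub, label))
    return records


def write_labeled_mutations(
    records: Iterable[tuple[Substitution, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for sub, label in records:
            fh.write(
                f"{sub.protein_id}\t{sub.position}\t{sub.wild_type}\t{sub.mutant}\t{label}\n"
            )


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    """Serialize tallies as tab-separated ``model_id  disease_count  neutral_count``.

    Membership bookkeeping is not serialized; a table read back supports
    scoring but not leave-one-out (recompute from the catalogues for that).
    """
    with open(path, "w") as fh:
        for model_id in sorted(table.counts):
            c_d, c_n = table.counts[model_id]
            fh.write(f"{model_id}\t{c_d}\t{c_n}\n")


def read_weight_table(
    path: str | Path,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
    normalized: bool = False,
) -> WeightTable:
    counts: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"expected 3 tab-separated columns, found {len(parts)}", lineno
                )
            if parts[0] in counts:
                raise FormatError(f"duplicate model id {parts[0]!r}", lineno)
            try:
                counts[parts[0]] = (int(parts[1]), int(parts[2]))
            except ValueError:
                raise FormatError("tallies must be integers", lineno) from None
    return WeightTable(counts=counts, pseudo_count=pseudo_count, normalized=normalized)
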