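"""Domain hits on proteins and residue-to-match-state resolution.

A substitution can only be scored where a profile HMM covers it *at a match
state*.  This module represents significant domain assignments, expands
compact alignment maps into per-residue state lookups, filters hits by
e-value, and collects the candidate (model, match state) pairs for a
substitution.

Two hit-table layouts are accepted:

* the simplified tab-separated format
  ``protein_id  model_id  e_value  ali_from  ali_to  map_string``, where
  ``map_string`` is a run-length CIGAR-like string over the operations
  ``M`` (one residue aligned to one match state), ``I`` (inserted residue,
  no state) and ``D`` (deleted/skipped match state, no residue).  The state
  counter starts at match state 1, so an alignment beginning at model state
  *k* is written with a leading ``(k-1)D`` run;
* HMMER's ``hmmscan --domtblout`` table, paired with a companion map file of
  rows ``protein_id  model_id  ali_from  map_string`` (the domtblout format
  itself does not carry per-residue alignments).  Here the state counter
  starts at the row's ``hmm_from`` coordinate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import DuplicateHitError, FormatError, ValidationError
from .profile_hmm import AMINO_ALPHABET, ProfileHMM

logger = logging.getLogger(__name__)

#: Significance threshold on domain e-values; the boundary is inclusive.
DEFAULT_E_THRESHOLD = 0.01

#: Marker stored in a state map for an inserted residue (no match state).
INSERT = None

_CIGAR_TOKEN = re.compile(r"(\d*)([MID])")


@dataclass(frozen=True)
class Substitution:
    """One amino-acid substitution: ``wild_type`` at 1-based ``position`` -> ``mutant``."""

    protein_id: str
    position: int
    wild_type: str
    mutant: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        for role, letter in (("wild_type", self.wild_type), ("mutant", self.mutant)):
            if letter not in AMINO_ALPHABET:
                raise ValidationError(
                    f"{role} residue {letter!r} is not one of the 20 amino acids"
                )
        if self.wild_type == self.mutant:
            raise ValidationError(
                f"substitution {self.protein_id}:{self.position} has identical "
                f"wild-type and mutant residue {self.wild_type!r}"
            )

    def __str__(self) -> str:
        return f"{self.protein_id}:{self.wild_type}{self.position}{self.mutant}"


@dataclass(frozen=True)
class DomainHit:
    """One domain assignment on a protein.

    ``state_map`` maps every aligned protein position (1-based, within
    ``[ali_from, ali_to]``) to a 1-based match-state index, or to
    :data:`INSERT` for residues emitted by insert states.
    """

    protein_id: str
    model_id: str
    e_value: float
    ali_from: int
    ali_to: int
    state_map: Mapping[int, int | None]

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(f"e-value must be non-negative, got {self.e_value}")
        if self.ali_from > self.ali_to or self.ali_from < 1:
            raise ValidationError(
                f"invalid alignment envelope [{self.ali_from}, {self.ali_to}]"
            )
        positions = sorted(self.state_map)
        if positions and (
            positions[0] < self.ali_from or positions[-1] > self.ali_to
        ):
            raise ValidationError("state_map key outside the alignment envelope")
        last_state = 0
        for pos in positions:
            state = self.state_map[pos]
            if state is INSERT:
                continue
            if state <= last_state:
                raise ValidationError(
                    f"match-state indices must increase along the protein "
                    f"(state {state} at position {pos})"
                )
            last_state = state
        object.__setattr__(self, "state_map", dict(self.state_map))


def expand_map_string(
    map_string: str, ali_from: int, ali_to: int, start_state: int = 1
) -> dict[int, int | None]:
    """Expand a run-length M/I/D map into a per-position state lookup.

    ``M`` consumes one protein residue and one match state, ``I`` one residue
    only, ``D`` one match state only.  Exactly ``ali_to - ali_from + 1``
    residues must be consumed.
    """
    if not map_string:
        raise ValidationError("empty map string")
    consumed = sum(len(m.group(0)) for m in _CIGAR_TOKEN.finditer(map_string))
    if consumed != len(map_string):
        raise ValidationError(f"unparsable map string {map_string!r}")
    state_map: dict[int, int | None] = {}
    pos = ali_from
    state = start_state
    for m in _CIGAR_TOKEN.finditer(map_string):
        count = int(m.group(1) or 1)
        op = m.group(2)
        for _ in range(count):
            if op == "M":
                state_map[pos] = state
                pos += 1
                state += 1
            elif op == "I":
                state_map[pos] = INSERT
                pos += 1
            else:  # D
                state += 1
    if pos - 1 != ali_to:
        raise ValidationError(
            f"map string consumes residues up to {pos - 1}, envelope ends at {ali_to}"
        )
    return state_map


def read_domain_hits(
    path: str | Path, map_path: str | Path | None = None
) -> list[DomainHit]:
    """Read a hit table (simplified layout, or domtblout plus its map file)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = [
        (i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")
    ]
    if not body:
        return []
    first = body[0][1]
    if "\t" in first and len(first.split("\t")) == 6:
        if map_path is not None:
            raise ValidationError(
                "map file given but the hit table is in the simplified layout, "
                "which carries its own map strings"
            )
        return _read_simplified(body)
    return _read_domtblout(body, map_path)


def _check_duplicate(seen: set, key: tuple, lineno: int) -> None:
    if key in seen:
        raise DuplicateHitError(
            f"duplicate hit for (protein, model, envelope) {key}", lineno
        )
    seen.add(key)


def _read_simplified(body: list[tuple[int, str]]) -> list[DomainHit]:
    hits: list[DomainHit] = []
    seen: set[tuple] = set()
    for lineno, line in body:
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 6:
            raise FormatError(
                f"expected 6 tab-separated columns, found {len(parts)}", lineno
            )
        protein_id, model_id, e_txt, from_txt, to_txt, map_string = parts
        try:
            e_value = float(e_txt)
            ali_from = int(from_txt)
            ali_to = int(to_txt)
        except ValueError:
            raise FormatError(
                f"unparsable e-value/coordinates in {parts[2:5]}", lineno
            ) from None
        _check_duplicate(seen, (protein_id, model_id, ali_from, ali_to), lineno)
        try:
            state_map = expand_map_string(map_string, ali_from, ali_to)
            hits.append(
                DomainHit(protein_id, model_id, e_value, ali_from, ali_to, state_map)
            )
        except ValidationError as exc:
            raise FormatError(str(exc), lineno) from exc
    return hits


def _read_domtblout(
    body: list[tuple[int, str]], map_path: str | Path | None
) -> list[DomainHit]:
    if map_path is None:
        raise ValidationError(
            "domtblout tables carry no per-residue alignment; supply the companion "
            "map file (protein_id, model_id, ali_from, map_string) via map_path"
        )
    maps: dict[tuple[str, str, int], str] = {}
    with open(map_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"map file row needs 4 tab-separated columns, found {len(parts)}",
                    lineno,
                )
            maps[(parts[0], parts[1], int(parts[2]))] = parts[3]

    hits: list[DomainHit] = []
    seen: set[tuple] = set()
    for lineno, line in body:
        parts = line.split()
        if len(parts) < 23:
            raise FormatError(
                f"domtblout row has {len(parts)} fields, expected >= 23", lineno
            )
        model_id = parts[0]  # hmmscan: target = model, query = protein
        protein_id = parts[3]
        try:
            e_value = float(parts[12])  # per-domain independent e-value
            hmm_from = int(parts[15])
            ali_from = int(parts[17])
            ali_to = int(parts[18])
        except ValueError:
            raise FormatError("unparsable domtblout coordinates", lineno) from None
        _check_duplicate(seen, (protein_id, model_id, ali_from, ali_to), lineno)
        key = (protein_id, model_id, ali_from)
        if key not in maps:
            raise ValidationError(
                f"no alignment map for domtblout row {key}; add it to the map file"
            )
        try:
            state_map = expand_map_string(maps[key], ali_from, ali_to, start_state=hmm_from)
            hits.append(
                DomainHit(protein_id, model_id, e_value, ali_from, ali_to, state_map)
            )
        except ValidationError as exc:
            raise FormatError(str(exc), lineno) from exc
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Serialize hits in the simplified layout (for fixture bundles)."""
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(
                "\t".join(
                    [
                        hit.protein_id,
                        hit.model_id,
                        repr(hit.e_value),
                        str(hit.ali_from),
                        str(hit.ali_to),
                        compact_map_string(hit),
                    ]
                )
                + "\n"
            )


def compact_map_string(hit: DomainHit) -> str:
    """Re-encode a hit's state map as a run-length M/I/D string (state start 1)."""
    ops: list[str] = []
    state = 1
    for pos in range(hit.ali_from, hit.ali_to + 1):
        mapped = hit.state_map.get(pos, INSERT)
        if mapped is INSERT:
            ops.append("I")
        else:
            while state < mapped:
                ops.append("D")
                state += 1
            ops.append("M")
            state += 1
    out: list[str] = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        run = j - i
        out.append(f"{run}{ops[i]}" if run > 1 else ops[i])
        i = j
    return "".join(out)


def significant_hits(
    hits: Sequence[DomainHit], e_threshold: float = DEFAULT_E_THRESHOLD
) -> list[DomainHit]:
    """Keep hits with ``e_value <= e_threshold`` (inclusive), preserving order."""
    if e_threshold <= 0:
        raise ValidationError(f"e-value threshold must be positive, got {e_threshold}")
    return [h for h in hits if h.e_value <= e_threshold]


def resolve_match_state(hit: DomainHit, position: int) -> int | None:
    """Match-state index for ``position``, or ``None`` outside the envelope
    or at an insert state.  Absence is a value, not an error."""
    if not hit.ali_from <= position <= hit.ali_to:
        return None
    return hit.state_map.get(position, INSERT)


def candidate_models(
    sub: Substitution,
    hits: Sequence[DomainHit],
    library: Mapping[str, ProfileHMM],
) -> list[tuple[ProfileHMM, int]]:
    """All (model, match-state) pairs at which ``sub`` can be scored.

    ``hits`` should already be significance-filtered.  Hits whose model is
    missing from ``library`` are skipped with a logged warning.
    """
    candidates: list[tuple[ProfileHMM, int]] = []
    for hit in hits:
        if hit.protein_id != sub.protein_id:
            continue
        state = resolve_match_state(hit, sub.position)
        if state is None:
            continue
        model = library.get(hit.model_id)
        if model is None:
            logger.warning(
                "model %s (hit on %s) not in library; skipping", hit.model_id, hit.protein_id
            )
            continue
        if state > model.length:
            logger.warning(
                "hit on %s maps position %d to state %d beyond model %s length %d; skipping",
                hit.protein_id, sub.position, state, hit.model_id, model.length,
            )
            continue
        candidates.append((model, state))
    return candidates


def identity_hit(protein_id: str, model: ProfileHMM, e_value: float = 0.0) -> DomainHit:
    """A full-length hit with the identity residue->state map.

    Represents an ab initio model of the whole protein (query columns and
    match states coincide when the profile is built in hand mode), so the
    same candidate machinery scores both domain and whole-protein models.
    """
    return DomainHit(
        protein_id=protein_id,
        model_id=model.model_id,
        e_value=e_value,
        ali_from=1,
        ali_to=model.length,
        state_map={p: p for p in range(1, model.length + 1)},
    )
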