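"""Reading, writing and interrogating profile hidden Markov models.

A profile HMM models a family of related protein sequences as a chain of
match states, each emitting the 20 amino acids with position-specific
probabilities.  Variant scoring interrogates exactly these match-state
emission probabilities; insert emissions and state transitions are parsed
for format fidelity but never consumed downstream.

Files follow the HMMER3 ASCII convention: emission and transition values are
stored as negative natural logarithms of probabilities, and a literal ``*``
denotes probability zero.  The ``HMMER3/f`` dialect is the reference layout;
other HMMER3 minor dialects are accepted as long as the structural fields
(header, HMM alphabet line, per-node emission rows) parse.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

from .errors import EmissionLookupError, FormatError, ValidationError

#: Canonical amino-acid ordering used by HMMER for the amino alphabet.
AMINO_ALPHABET: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

# HMMER's own ASCII files store scores at 5 decimal places, so rows of a
# genuine hmmbuild profile sum to 1 only within ~2e-5; our writer is tighter.
_ROW_SUM_TOL = 1e-4


class ModelSource(enum.Enum):
    """Provenance of a profile, in tie-breaking priority order."""

    SUPERFAMILY = "superfamily"
    PFAM_A = "pfam_a"
    PFAM_B = "pfam_b"
    AB_INITIO = "ab_initio"


#: Lower value wins when information content ties.
SOURCE_PRIORITY = {
    ModelSource.SUPERFAMILY: 0,
    ModelSource.PFAM_A: 1,
    ModelSource.PFAM_B: 2,
    ModelSource.AB_INITIO: 3,
}


class BackgroundProvenance(enum.Enum):
    USER_FILE = "user_file"
    COMPO_LINE = "compo_line"
    UNIFORM = "uniform"


@dataclass(frozen=True)
class BackgroundComposition:
    """A background amino-acid composition used as the divergence reference.

    ``probabilities`` follows :data:`AMINO_ALPHABET` ordering and sums to 1;
    entries must be strictly positive wherever it serves as a KL denominator.
    """

    probabilities: np.ndarray
    provenance: BackgroundProvenance

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (20,):
            raise ValidationError(f"background composition must have 20 entries, got {p.shape}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"background composition sums to {p.sum():.12f}, not 1")
        object.__setattr__(self, "probabilities", p)


def uniform_background() -> BackgroundComposition:
    return BackgroundComposition(np.full(20, 0.05), BackgroundProvenance.UNIFORM)


@dataclass
class ProfileHMM:
    """A parsed profile HMM restricted to what variant scoring consumes.

    Parameters
    ----------
    model_id
        Accession if present in the source file, otherwise the model name.
    source
        Library of origin; drives tie-breaking when two models are equally
        informative.
    match_emissions
        ``(length, 20)`` matrix of probabilities, rows ordered by match-state
        index (1-based externally), columns by ``alphabet``.
    alphabet
        Amino-acid column ordering, as declared by the source file.
    compo
        Optional model-specific background composition (the ``COMPO`` line).
    map_annotation
        Optional per-node alignment-column index (the ``MAP`` field).
    name
        The ``NAME`` header, kept for round-tripping.
    """

    model_id: str
    source: ModelSource
    match_emissions: np.ndarray
    alphabet: tuple[str, ...] = AMINO_ALPHABET
    compo: np.ndarray | None = None
    map_annotation: tuple[int, ...] | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.match_emissions, dtype=float)
        if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] != 20:
            raise ValidationError(
                f"match_emissions must be (length >= 1, 20), got {m.shape}"
            )
        if (m < 0).any() or (m > 1).any():
            raise ValidationError("match emission probabilities must lie in [0, 1]")
        bad = np.abs(m.sum(axis=1) - 1.0) > _ROW_SUM_TOL
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"match state {k + 1} emissions sum to {m[k].sum():.8f}, not 1"
            )
        if len(self.alphabet) != 20 or sorted(self.alphabet) != sorted(AMINO_ALPHABET):
            raise ValidationError("alphabet must be a permutation of the 20 amino acids")
        if self.map_annotation is not None and len(self.map_annotation) != m.shape[0]:
            raise ValidationError("map_annotation length must equal model length")
        self.match_emissions = m
        self.alphabet = tuple(self.alphabet)
        if self.compo is not None:
            self.compo = np.asarray(self.compo, dtype=float)
        if self.name is None:
            self.name = self.model_id

    @property
    def length(self) -> int:
        """Number of match states."""
        return int(self.match_emissions.shape[0])

    def residue_index(self, residue: str) -> int:
        try:
            return self.alphabet.index(residue)
        except ValueError:
            raise EmissionLookupError(
                f"residue {residue!r} is not one of the 20 amino acids"
            ) from None


def emission_probability(model: ProfileHMM, state_index: int, residue: str) -> float:
    """Match-state emission probability of ``residue`` at 1-based ``state_index``.

    Ambiguity codes (``X``, ``B``, ``Z``) and gap/stop symbols are rejected:
    the score of a substitution is defined only for concrete residues.
    """
    if not 1 <= state_index <= model.length:
        raise EmissionLookupError(
            f"match-state index {state_index} outside [1, {model.length}]"
        )
    return float(model.match_emissions[state_index - 1, model.residue_index(residue)])


def background_composition(
    model: ProfileHMM | None = None,
    override: str | Path | None = None,
) -> BackgroundComposition:
    """Resolve the background composition for a model.

    Resolution order: a user-supplied composition file beats the model's
    ``COMPO`` line, which beats the uniform 1/20 fallback.  The returned
    vector follows :data:`AMINO_ALPHABET` ordering regardless of source.
    """
    if override is not None:
        return read_composition(override)
    if model is not None and model.compo is not None:
        p = np.empty(20)
        for i, letter in enumerate(AMINO_ALPHABET):
            p[i] = model.compo[model.alphabet.index(letter)]
        total = p.sum()
        if abs(total - 1.0) > 1e-4:
            raise ValidationError(f"COMPO line sums to {total:.6f}, not 1")
        return BackgroundComposition(p / total, BackgroundProvenance.COMPO_LINE)
    return uniform_background()


def read_composition(path: str | Path) -> BackgroundComposition:
    """Read a composition file of 20 whitespace-separated ``letter probability`` pairs."""
    seen: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError("expected 'letter probability' pair", lineno)
            letter, value = parts
            if letter not in AMINO_ALPHABET:
                raise FormatError(f"unknown amino acid {letter!r}", lineno)
            if letter in seen:
                raise FormatError(f"duplicate entry for {letter!r}", lineno)
            try:
                seen[letter] = float(value)
            except ValueError:
                raise FormatError(f"unparsable probability {value!r}", lineno) from None
    if len(seen) != 20:
        raise ValidationError(f"composition file lists {len(seen)} residues, need all 20")
    p = np.array([seen[a] for a in AMINO_ALPHABET])
    if (p < 0).any():
        raise ValidationError("composition probabilities must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-4:
        raise ValidationError(f"composition sums to {total:.6f}, not 1 (tolerance 1e-4)")
    return BackgroundComposition(p / total, BackgroundProvenance.USER_FILE)


# ---------------------------------------------------------------------------
# HMMER3 ASCII parsing


def _score_to_prob(token: str, lineno: int) -> float:
    if token == "*":
        return 0.0
    try:
        return math.exp(-float(token))
    except (ValueError, OverflowError):
        raise FormatError(f"unparsable numeric token {token!r}", lineno) from None


def _prob_to_score(p: float) -> str:
    # 10 decimal places keep the write/read round trip below 1e-9 in
    # probability space (HMMER's own 5 would not)
    if p == 0.0:
        return "*"
    return f"{-math.log(p):.10f}"


def read_profile(
    path: str | Path, source: ModelSource = ModelSource.AB_INITIO
) -> ProfileHMM:
    """Parse one HMMER3 ASCII profile from ``path``.

    Only the first model in a multi-model file is returned; use
    :func:`read_profiles` for libraries.  ``source`` tags the model's library
    of origin, which the file format itself does not record.
    """
    with open(path) as fh:
        models = list(_parse_stream(fh, source, str(path), first_only=True))
    if not models:
        raise FormatError(f"no profile found in {path}")
    return models[0]


def read_profiles(
    path: str | Path, source: ModelSource = ModelSource.AB_INITIO
) -> list[ProfileHMM]:
    """Parse every model in a (possibly concatenated) HMMER3 ASCII file."""
    with open(path) as fh:
        return list(_parse_stream(fh, source, str(path), first_only=False))


def _parse_stream(
    fh: TextIO, source: ModelSource, label: str, first_only: bool
) -> Iterable[ProfileHMM]:
    lines = fh.read().splitlines()
    pos = 0
    n_models = 0
    while pos < len(lines):
        # skip blank separation between concatenated models
        while pos < len(lines) and not lines[pos].strip():
            pos += 1
        if pos >= len(lines):
            break
        model, pos = _parse_one(lines, pos)
        model.source = source
        n_models += 1
        yield model
        if first_only:
            break
    if n_models == 0:
        raise FormatError(f"{label} contains no HMMER3 profile", 1)


def _parse_one(lines: list[str], start: int) -> tuple[ProfileHMM, int]:
    lineno = start + 1
    if not lines[start].startswith("HMMER3"):
        raise FormatError(
            f"not a HMMER3 file (first line {lines[start][:40]!r})", lineno
        )

    name: str | None = None
    acc: str | None = None
    leng: int | None = None
    alph: str | None = None
    has_map = False
    i = start + 1

    # header key/value section up to the HMM alphabet line
    while i < len(lines):
        line = lines[i]
        if line.startswith("HMM "):
            break
        parts = line.split(None, 1)
        if parts:
            key = parts[0]
            value = parts[1].strip() if len(parts) > 1 else ""
            if key == "NAME":
                name = value
            elif key == "ACC":
                acc = value
            elif key == "LENG":
                try:
                    leng = int(value)
                except ValueError:
                    raise FormatError(f"LENG value {value!r} is not an integer", i + 1) from None
            elif key == "ALPH":
                alph = value.lower()
            elif key == "MAP":
                has_map = value.lower() == "yes"
        i += 1
    else:
        raise FormatError("no HMM alphabet line found", len(lines))

    if name is None:
        raise FormatError("missing NAME header", start + 1)
    if leng is None:
        raise FormatError("missing LENG header", start + 1)
    if leng < 1:
        raise FormatError(f"LENG must be >= 1, got {leng}", start + 1)
    if alph != "amino":
        raise FormatError(f"alphabet {alph!r} is not 'amino'", start + 1)

    alphabet = tuple(lines[i].split()[1:])
    if len(alphabet) != 20 or sorted(alphabet) != sorted(AMINO_ALPHABET):
        raise FormatError("HMM line must list the 20 amino-acid letters", i + 1)
    i += 1  # transition-order header line
    if i >= len(lines):
        raise FormatError("truncated file after HMM line", i)
    i += 1

    compo: np.ndarray | None = None
    if i < len(lines) and lines[i].split()[:1] == ["COMPO"]:
        tokens = lines[i].split()[1:]
        if len(tokens) != 20:
            raise FormatError(f"COMPO line has {len(tokens)} values, expected 20", i + 1)
        compo = np.array([_score_to_prob(t, i + 1) for t in tokens])
        i += 1

    # node-0 insert emission line and transition line: structural, ignored
    for _ in range(2):
        if i >= len(lines) or lines[i].strip() in ("", "//"):
            raise FormatError("truncated node-0 block", i + 1)
        i += 1

    emissions = np.empty((leng, 20))
    map_annotation: list[int] = []
    for k in range(1, leng + 1):
        if i >= len(lines) or lines[i].strip() == "//":
            raise FormatError(
                f"found {k - 1} match-state rows but LENG is {leng}", i + 1
            )
        tokens = lines[i].split()
        if len(tokens) < 21:
            raise FormatError(
                f"match-state row has {len(tokens)} fields, expected node index + 20 emissions",
                i + 1,
            )
        try:
            node = int(tokens[0])
        except ValueError:
            raise FormatError(f"node index {tokens[0]!r} is not an integer", i + 1) from None
        if node != k:
            raise FormatError(f"expected node {k}, found {node}", i + 1)
        for j, tok in enumerate(tokens[1:21]):
            emissions[k - 1, j] = _score_to_prob(tok, i + 1)
        if has_map:
            if len(tokens) < 22:
                raise FormatError("MAP annotation promised but missing", i + 1)
            try:
                map_annotation.append(int(tokens[21]))
            except ValueError:
                raise FormatError(
                    f"MAP value {tokens[21]!r} is not an integer", i + 1
                ) from None
        i += 1
        # insert emission + transition lines for this node
        for _ in range(2):
            if i >= len(lines) or lines[i].strip() == "//":
                raise FormatError(f"truncated node {k} block", i + 1)
            i += 1

    if i >= len(lines) or lines[i].strip() != "//":
        extra = lines[i].split()[:1] if i < len(lines) else []
        if extra and extra[0].isdigit():
            raise FormatError(
                f"more match-state rows than LENG={leng}", i + 1
            )
        raise FormatError("missing '//' terminator", i + 1)
    i += 1

    model = ProfileHMM(
        model_id=acc or name,
        source=ModelSource.AB_INITIO,
        match_emissions=emissions,
        alphabet=alphabet,
        compo=compo,
        map_annotation=tuple(map_annotation) if has_map else None,
        name=name,
    )
    return model, i


# ---------------------------------------------------------------------------
# Writing

_UNIFORM_SCORE = f"{math.log(20):.5f}"
# transition scores for a plain profile: -ln p with p(m->m)=0.98, p(m->i)=p(m->d)=0.01,
# p(i->m)=p(i->i)=p(d->m)=p(d->d)=0.5
_TRANS_MID = ["0.02020", "4.60517", "4.60517", "0.69315", "0.69315", "0.69315", "0.69315"]
_TRANS_NODE0 = ["0.02020", "4.60517", "4.60517", "0.69315", "0.69315", "0.00000", "*"]
_TRANS_LAST = ["0.01005", "4.60517", "*", "0.69315", "0.69315", "0.00000", "*"]


def write_profile(model: ProfileHMM, path: str | Path) -> None:
    """Write ``model`` as a HMMER3/f ASCII file that :func:`read_profile` accepts.

    Insert emissions are written uniform and transitions as a fixed, properly
    normalised profile; scoring never reads them back.  Probability 0 is
    written as ``*`` per the format convention.
    """
    # fields are mutable; re-check invariants before committing to disk
    ProfileHMM(
        model_id=model.model_id,
        source=model.source,
        match_emissions=model.match_emissions,
        alphabet=model.alphabet,
        compo=model.compo,
        map_annotation=model.map_annotation,
        name=model.name,
    )
    m = model.match_emissions
    cons = [model.alphabet[int(np.argmax(row))] for row in m]
    with open(path, "w") as fh:
        fh.write("HMMER3/f [hmmvar]\n")
        fh.write(f"NAME  {model.name}\n")
        if model.model_id != model.name:
            fh.write(f"ACC   {model.model_id}\n")
        fh.write(f"LENG  {model.length}\n")
        fh.write("ALPH  amino\n")
        if model.map_annotation is not None:
            fh.write("MAP   yes\n")
        fh.write("HMM          " + "        ".join(model.alphabet) + "\n")
        fh.write(
            "            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n"
        )
        if model.compo is not None:
            fh.write("  COMPO   " + "  ".join(_prob_to_score(p) for p in model.compo) + "\n")
        fh.write("          " + "  ".join([_UNIFORM_SCORE] * 20) + "\n")
        fh.write("          " + "  ".join(_TRANS_NODE0) + "\n")
        for k in range(1, model.length + 1):
            row = "  ".join(_prob_to_score(p) for p in m[k - 1])
            map_col = str(model.map_annotation[k - 1]) if model.map_annotation else "-"
            fh.write(f"{k:7d}   {row} {map_col:>6} {cons[k - 1]} - - -\n")
            fh.write("          " + "  ".join([_UNIFORM_SCORE] * 20) + "\n")
            trans = _TRANS_LAST if k == model.length else _TRANS_MID
            fh.write("          " + "  ".join(trans) + "\n")
        fh.write("//\n")


def load_library(
    directory: str | Path,
    source: ModelSource = ModelSource.AB_INITIO,
    pattern: str = "*.hmm",
) -> dict[str, ProfileHMM]:
    """Read every profile under ``directory`` into a model_id -> model mapping."""
    library: dict[str, ProfileHMM] = {}
    for p in sorted(Path(directory).glob(pattern)):
        for model in read_profiles(p, source=source):
            library[model.model_id] = model
    return library
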