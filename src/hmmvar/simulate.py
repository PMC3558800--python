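"""Synthetic profiles, domain hits and labelled mutation sets.

Real inputs to this pipeline are curated HMM libraries, hmmscan hit tables
and disease/neutral mutation catalogues — none of which can ship with the
package.  This module generates structurally faithful synthetic stand-ins:
profiles whose match states mix a point mass on a consensus residue with a
uniform remainder, full-length domain hits, and mutation sets with a planted
effect (disease substitutions hit conserved states and improbable mutants;
neutral ones fall on weakly conserved states).  All generation is driven by
an integer seed and reproduces byte-identically.

What these fixtures deliberately do not emulate: realistic protein-family
emission structure (Dirichlet-mixture priors), insert/delete geometry of
real alignments, and database-scale class imbalance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .domains import DomainHit, Substitution, identity_hit, read_domain_hits, write_domain_hits
from .errors import ValidationError
from .profile_hmm import (
    AMINO_ALPHABET,
    ModelSource,
    ProfileHMM,
    load_library,
    write_profile,
)
from .scoring import unweighted_score
from .weights import DISEASE, NEUTRAL, read_labeled_mutations, write_labeled_mutations

#: Match states per synthetic model.
DEFAULT_MODEL_LENGTH = 40

#: Fraction of records planted on the "wrong" conservation stratum, emulating
#: annotation errors in curated mutation catalogues.
DEFAULT_LABEL_NOISE = 0.05


def synth_profile(
    length: int,
    conservation: float,
    seed: int,
    model_id: str = "SYN0001",
    source: ModelSource = ModelSource.PFAM_A,
) -> ProfileHMM:
    """A profile whose every match state has the same conservation level.

    Each state puts weight ``conservation`` on a seeded consensus residue and
    spreads the remainder uniformly, so state information content runs from
    0 (conservation 0) to ln 20 (conservation 1) against a uniform
    background.
    """
    if length < 1:
        raise ValidationError(f"length must be >= 1, got {length}")
    if not 0.0 <= conservation <= 1.0:
        raise ValidationError(f"conservation must be in [0, 1], got {conservation}")
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 20, size=length)
    emissions = np.full((length, 20), (1.0 - conservation) / 20.0)
    emissions[np.arange(length), consensus] += conservation
    return ProfileHMM(
        model_id=model_id,
        source=source,
        match_emissions=emissions,
        map_annotation=tuple(range(1, length + 1)),
    )


def _mixed_profile(
    length: int,
    conservation_high: float,
    conservation_low: float,
    rng: np.random.Generator,
    model_id: str,
    source: ModelSource,
) -> tuple[ProfileHMM, np.ndarray, np.ndarray]:
    """A profile with half its states conserved and half weakly conserved."""
    consensus = rng.integers(0, 20, size=length)
    high_states = np.zeros(length, dtype=bool)
    high_states[rng.permutation(length)[: length // 2]] = True
    emissions = np.empty((length, 20))
    for k in range(length):
        c = conservation_high if high_states[k] else conservation_low
        emissions[k] = (1.0 - c) / 20.0
        emissions[k, consensus[k]] += c
    model = ProfileHMM(
        model_id=model_id,
        source=source,
        match_emissions=emissions,
        map_annotation=tuple(range(1, length + 1)),
    )
    return model, consensus, high_states


@dataclass
class FixtureBundle:
    """A self-consistent synthetic benchmark: models, hits, labelled mutations."""

    models: dict[str, ProfileHMM]
    hits: list[DomainHit]
    mutations: list[tuple[Substitution, str]]
    planted_effect: float
    seed: int

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        hmm_dir = directory / "hmms"
        hmm_dir.mkdir(parents=True, exist_ok=True)
        for model_id in sorted(self.models):
            write_profile(self.models[model_id], hmm_dir / f"{model_id}.hmm")
        write_domain_hits(self.hits, directory / "hits.tsv")
        write_labeled_mutations(self.mutations, directory / "mutations.tsv")
        meta = {"seed": self.seed, "planted_effect": self.planted_effect}
        (directory / "bundle.json").write_text(json.dumps(meta, sort_keys=True) + "\n")

    @classmethod
    def read(cls, directory: str | Path) -> "FixtureBundle":
        directory = Path(directory)
        meta = json.loads((directory / "bundle.json").read_text())
        return cls(
            models=load_library(directory / "hmms", source=ModelSource.PFAM_A),
            hits=read_domain_hits(directory / "hits.tsv"),
            mutations=read_labeled_mutations(directory / "mutations.tsv"),
            planted_effect=meta["planted_effect"],
            seed=meta["seed"],
        )


def synth_benchmark(
    n_models: int,
    n_disease: int,
    n_neutral: int,
    conservation_high: float = 0.99,
    conservation_low: float = 0.1,
    seed: int = 0,
    model_length: int = DEFAULT_MODEL_LENGTH,
    label_noise: float = DEFAULT_LABEL_NOISE,
    source: ModelSource = ModelSource.PFAM_A,
) -> FixtureBundle:
    """Generate a benchmark with a planted disease/neutral score separation.

    One protein per model, covered end to end by an identity-mapped hit.
    Disease records substitute the consensus residue of a conserved state
    for an off-consensus residue (large probability drop); neutral records
    swap two off-consensus residues at a weakly conserved state (probability
    ratio 1, score ~0).  A ``label_noise`` fraction of records is planted on
    the opposite stratum while keeping its label, emulating annotation
    errors; set it to 0 for perfectly separable data.
    """
    if min(n_models, n_disease, n_neutral) < 1:
        raise ValidationError("n_models, n_disease and n_neutral must all be >= 1")
    if model_length < 2:
        raise ValidationError("model_length must be >= 2 to hold both strata")
    rng = np.random.default_rng(seed)

    models: dict[str, ProfileHMM] = {}
    consensus: dict[str, np.ndarray] = {}
    high_states: dict[str, np.ndarray] = {}
    hits: list[DomainHit] = []
    for i in range(n_models):
        model_id = f"SYN{i + 1:04d}"
        model, cons, high = _mixed_profile(
            model_length, conservation_high, conservation_low, rng, model_id, source
        )
        models[model_id] = model
        consensus[model_id] = cons
        high_states[model_id] = high
        hits.append(identity_hit(f"PROT{i + 1:04d}", model, e_value=1e-12))

    model_ids = sorted(models)
    mutations: list[tuple[Substitution, str]] = []
    seen: set[tuple] = set()
    score_sums = {DISEASE: 0.0, NEUTRAL: 0.0}

    def plant(label: str) -> None:
        for _ in range(10_000):  # retry loop for uniqueness
            model_id = model_ids[rng.integers(0, n_models)]
            protein_id = f"PROT{model_ids.index(model_id) + 1:04d}"
            damaging_stratum = label == DISEASE
            if rng.random() < label_noise:
                damaging_stratum = not damaging_stratum
            stratum = high_states[model_id] if damaging_stratum else ~high_states[model_id]
            states = np.flatnonzero(stratum)
            state = int(states[rng.integers(0, len(states))])
            cons_idx = int(consensus[model_id][state])
            others = [i for i in range(20) if i != cons_idx]
            if damaging_stratum:
                wt = AMINO_ALPHABET[cons_idx]
                mut = AMINO_ALPHABET[others[rng.integers(0, 19)]]
            else:
                wt_idx, mut_idx = rng.choice(others, size=2, replace=False)
                wt = AMINO_ALPHABET[int(wt_idx)]
                mut = AMINO_ALPHABET[int(mut_idx)]
            key = (protein_id, state + 1, wt, mut, label)
            if key in seen:
                continue
            seen.add(key)
            sub = Substitution(protein_id, state + 1, wt, mut)
            mutations.append((sub, label))
            row = models[model_id].match_emissions[state]
            p_w = float(row[AMINO_ALPHABET.index(wt)])
            p_m = float(row[AMINO_ALPHABET.index(mut)])
            score_sums[label] += unweighted_score(p_w, p_m)
            return
        raise ValidationError(
            "could not place a unique substitution; increase n_models or model_length"
        )

    for _ in range(n_disease):
        plant(DISEASE)
    for _ in range(n_neutral):
        plant(NEUTRAL)

    planted_effect = score_sums[NEUTRAL] / n_neutral - score_sums[DISEASE] / n_disease
    return FixtureBundle(
        models=models,
        hits=hits,
        mutations=mutations,
        planted_effect=planted_effect,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Simple MSA -> profile builder

_GAP_CHARS = set("-.")


def profile_from_msa(
    msa: Sequence[str],
    gap_rule: float = 0.5,
    pseudocount: float = 1.0,
    model_id: str = "MSA0001",
) -> ProfileHMM:
    """Build a whole-protein profile from an aligned set of sequences.

    Columns whose gap fraction is at most ``gap_rule`` become match states;
    emissions are pseudo-counted observed frequencies,
    (count + pseudocount) / (n_observed + 20 * pseudocount).
    ``map_annotation`` records each match state's 1-based source column.
    This is a plain frequency estimator — no Dirichlet-mixture priors — so
    profiles are flatter than curated-library models built from the same
    alignment.
    """
    if not msa:
        raise ValidationError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValidationError("ragged alignment: all rows must have equal length")
    if width == 0:
        raise ValidationError("zero-width alignment")
    if pseudocount < 0:
        raise ValidationError(f"pseudocount must be >= 0, got {pseudocount}")
    rows = [row.upper() for row in msa]
    for row in rows:
        for ch in row:
            if ch not in _GAP_CHARS and ch not in AMINO_ALPHABET:
                raise ValidationError(f"unexpected alignment character {ch!r}")

    emissions: list[np.ndarray] = []
    columns: list[int] = []
    for j in range(width):
        column = [row[j] for row in rows]
        residues = [ch for ch in column if ch not in _GAP_CHARS]
        gap_fraction = 1.0 - len(residues) / len(column)
        if gap_fraction > gap_rule:
            continue
        counts = np.zeros(20)
        for ch in residues:
            counts[AMINO_ALPHABET.index(ch)] += 1
        total = len(residues) + 20.0 * pseudocount
        if total == 0:
            raise ValidationError(
                f"column {j + 1} has no residues and pseudocount 0"
            )
        emissions.append((counts + pseudocount) / total)
        columns.append(j + 1)
    if not emissions:
        raise ValidationError("no column satisfied the gap rule; no match states")
    return ProfileHMM(
        model_id=model_id,
        source=ModelSource.AB_INITIO,
        match_emissions=np.array(emissions),
        map_annotation=tuple(columns),
    )
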