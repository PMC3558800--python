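"""Domain-centric ontology annotation of damaging predictions.

Protein function is largely carried by domains, so a damaging substitution
inside a domain can be annotated with the molecular-function and phenotype
ontology terms statistically associated with that domain model.  This module
consumes precomputed domain -> term mapping tables (dcGO-style); it does not
re-derive the associations.  Association scores, where present, are passed
through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import FormatError, ValidationError
from .scoring import Call, Prediction
import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Term:
    term_id: str
    term_name: str
    ontology_name: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.term_id or not self.ontology_name:
            raise ValidationError("term_id and ontology_name must be non-empty")


TermMapping = Mapping[str, frozenset[Term]]


def read_term_map(path: str | Path) -> dict[str, frozenset[Term]]:
    """Read a tab-separated mapping: model_id, term_id, term_name,
    ontology_name[, score].  Duplicate rows collapse; two rows giving the
    same (model, term) different scores are rejected."""
    staged: dict[str, dict[str, Term]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise FormatError(
                    f"expected 4 or 5 tab-separated columns, found {len(parts)}", lineno
                )
            if any(not p.strip() for p in parts[:4]):
                raise FormatError("empty field in mapping row", lineno)
            score = None
            if len(parts) == 5:
                try:
                    score = float(parts[4])
                except ValueError:
                    raise FormatError(f"unparsable score {parts[4]!r}", lineno) from None
            term = Term(parts[1], parts[2], parts[3], score)
            model_terms = staged.setdefault(parts[0], {})
            previous = model_terms.get(term.term_id)
            if previous is not None and previous != term:
                raise FormatError(
                    f"term {term.term_id} mapped to model {parts[0]} twice "
                    "with different annotations",
                    lineno,
                )
            model_terms[term.term_id] = term
    return {m: frozenset(t.values()) for m, t in staged.items()}


def annotate(
    pred: Prediction,
    mapping: TermMapping,
    only_damaging: bool = True,
    ontology_graph=None,
) -> frozenset[Term]:
    """Ontology terms for a prediction's selected domain model.

    By default only damaging calls are annotated (pathogenic consequences
    are what the terms describe); pass ``only_damaging=False`` to annotate
    every scored call.  With ``ontology_graph`` (an obonet-loaded OBO graph,
    edges child -> parent) each term is expanded to include its ancestors.
    """
    if pred.call is Call.NO_PREDICTION or pred.model_id is None:
        return frozenset()
    if only_damaging and pred.call is not Call.DAMAGING:
        return frozenset()
    terms = mapping.get(pred.model_id)
    if terms is None:
        logger.info("model %s has no ontology mapping", pred.model_id)
        return frozenset()
    if ontology_graph is None:
        return terms
    return terms | _ancestors(terms, ontology_graph)


def _ancestors(terms: frozenset[Term], graph) -> frozenset[Term]:
    import networkx as nx

    out: set[Term] = set()
    for term in terms:
        if term.term_id not in graph:
            continue
        for anc_id in nx.descendants(graph, term.term_id):
            data = graph.nodes[anc_id]
            out.add(
                Term(
                    term_id=anc_id,
                    term_name=data.get("name", anc_id),
                    ontology_name=term.ontology_name,
                    score=None,
                )
            )
    return frozenset(out)


def load_ontology(path: str | Path):
    """Load an OBO 1.2 ontology file into a graph for ancestor expansion."""
    import obonet

    return obonet.read_obo(path)
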