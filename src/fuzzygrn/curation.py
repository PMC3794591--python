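"""Evidence handling: confidence classes, fold-change discretization, and
transition-type inference.

A regulatory interaction can be supported by direct evidence (the TF binds
the target's promoter: ChIP, EMSA, footprinting, lacZ-fusion promoter
analysis) or indirect evidence (the target's expression changes when the TF
is perturbed: knockout or overexpression followed by northern blot,
real-time PCR or microarray).  Either class alone is not reliable per se —
fewer than 10% of known bindings come with an expression change and fewer
than 12% of expression effects with a binding — so an interaction is called
high confidence only when both classes are present.  Consensus-sequence
matches and author statements are kept as records but never lift confidence,
since their experimental basis cannot be traced.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import RegulatoryState, TransitionOutput

__all__ = [
    "EVIDENCE_CLASSES",
    "EvidenceRecord",
    "ConfidenceLabel",
    "classify_confidence",
    "discretize_fold_change",
    "infer_transition_type",
    "UnsupportedInteractionError",
]

EVIDENCE_CLASSES = ("binding", "expression", "consensus", "author_statement")


class UnsupportedInteractionError(ValueError):
    """Confidence asked for an interaction with no evidence records."""


@dataclass(frozen=True)
class EvidenceRecord:
    """One literature annotation supporting a transition."""

    transition_id: str
    article: str  # PubMed-style identifier
    eclass: str  # binding | expression | consensus | author_statement
    technique: str = ""  # e.g. ChIP, northern blot, lacZ-fusion, microarray
    quote: str = ""  # text anchor in the article, may be empty

    def __post_init__(self):
        if self.eclass not in EVIDENCE_CLASSES:
            raise ValueError(
                f"eclass must be one of {EVIDENCE_CLASSES}, got {self.eclass!r}"
            )
        if not self.article:
            raise ValueError("article identifier must be non-empty")


@dataclass(frozen=True)
class ConfidenceLabel:
    value: str  # "high" | "low"

    def __post_init__(self):
        if self.value not in ("high", "low"):
            raise ValueError(f"confidence must be high or low, got {self.value!r}")


def classify_confidence(records) -> ConfidenceLabel:
    """High iff both a binding-class and an expression-class record exist.

    Evidence is pooled across all articles and resources for the transition:
    an interaction with binding support in one study and an expression
    effect in another is high confidence.

    Raises ``UnsupportedInteractionError`` on an empty record list and
    ``ValueError`` if the records span multiple transitions.
    """
    records = list(records)
    if not records:
        raise UnsupportedInteractionError("unsupported interaction: no evidence records")
    tids = {r.transition_id for r in records}
    if len(tids) > 1:
        raise ValueError(f"records span multiple transitions: {sorted(tids)}")
    classes = {r.eclass for r in records}
    high = "binding" in classes and "expression" in classes
    return ConfidenceLabel("high" if high else "low")


def discretize_fold_change(fold: float) -> tuple[str, str]:
    """Map a reported expression fold change to (direction, magnitude).

    Weak is below 2-fold, medium between 2- and 5-fold (inclusive at both
    ends), strong above 5-fold.  Folds below 1 are repression reported the
    other way around: they are inverted to 1/fold and mapped to direction
    down.
    """
    if fold <= 0:
        raise ValueError(f"fold change must be positive, got {fold}")
    if fold == 1:
        raise ValueError("no change: fold change of exactly 1 cannot be discretized")
    direction = "up" if fold > 1 else "down"
    m = fold if fold > 1 else 1.0 / fold
    if m < 2:
        magnitude = "weak"
    elif m <= 5:
        magnitude = "medium"
    else:
        magnitude = "strong"
    return direction, magnitude


def infer_transition_type(
    tf_state: RegulatoryState, tg_effect: TransitionOutput
) -> tuple[str, str]:
    """Regulation type from the sign product of TF state and TG effect.

    Equal directions mean activation, opposite mean inhibition; the
    magnitude is the target's effect strength.  E.g. a TF knockout (down)
    with a weak upregulation of the target indicates a weak inhibition.
    Signals (present/absent) carry no regulation sign and are rejected.
    """
    if tf_state.direction not in ("up", "down"):
        raise ValueError(
            "cannot infer a regulation type from a present/absent state: "
            "signals carry no regulation sign"
        )
    rtype = "activation" if tf_state.direction == tg_effect.direction else "inhibition"
    return rtype, tg_effect.magnitude
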