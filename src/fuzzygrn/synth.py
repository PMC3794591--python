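"""Seeded generators of synthetic regulatory networks and simulated
literature-curation processes.

The defaults mirror the aggregate shape of a curated process-scale yeast
network: 100 target genes, 68 TFs, ~50 context signals in a two-level is-a
hierarchy, 322 multi-input context-gated transitions, and a curation record
of 410 articles carrying 1133 annotations (≈2.8 annotations per article,
≈3.5 per interaction).

Per-interaction literature attention is heterogeneous: each transition
draws an Exponential(1) attention weight and articles sample interactions
proportionally.  An exponential rate mixture makes the expected cumulative
discovery curve exactly first-order Hill, n(m) ∝ m/(k+m), which is the
saturation behaviour real curation projects exhibit; uniform attention
(``heterogeneous_attention=False``) gives the exponential-saturation
coupon-collector curve instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .curation import EvidenceRecord
from .model import (
    Entity,
    Network,
    RegulatoryState,
    Transition,
    TransitionInput,
    TransitionOutput,
)

__all__ = ["SynthConfig", "generate_network", "simulate_curation", "make_table1_fixture"]

_PROCESSES = (
    "gluconeogenesis",
    "fatty_acid_metabolism",
    "tca_cycle",
    "glyoxylate_cycle",
    "ethanol_metabolism",
    "glycerol_metabolism",
    "lactate_metabolism",
    "glucose_signaling",
    "tf_tf",
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic network and curation generators."""

    n_tgs: int = 100
    n_tfs: int = 68
    n_signals: int = 50
    n_transitions: int = 322
    inputs_per_transition: tuple[int, int] = (2, 4)
    p_high_evidence: float = 0.66
    articles: int = 410
    mean_annotations_per_article: float = 1133 / 410
    heterogeneous_attention: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_tgs", "n_tfs", "n_signals", "n_transitions", "articles"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.p_high_evidence <= 1:
            raise ValueError("p_high_evidence must lie in [0,1]")
        if self.mean_annotations_per_article <= 0:
            raise ValueError("mean_annotations_per_article must be positive")
        lo, hi = self.inputs_per_transition
        if lo < 1 or hi < lo:
            raise ValueError("inputs_per_transition must be a range with 1 <= lo <= hi")


def generate_network(config: SynthConfig = SynthConfig()) -> Network:
    """Random context-gated multi-input network, reproducible from the seed.

    Signals form a two-level ontology (each signal is-a one of a handful of
    signal classes); every transition has one TF input in a required
    up/down state plus 0+ signal inputs required present/absent, and one
    target-gene output with a uniform direction and magnitude.  The stored
    rtype is derived from the input/output states so generated networks are
    always validator-clean.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.inputs_per_transition
    if config.n_transitions > 0:
        if config.n_tfs < 1 or config.n_tgs < 1:
            raise ValueError("need at least one TF and one target gene for transitions")
        if hi - 1 > config.n_signals:
            raise ValueError(
                f"inputs_per_transition up to {hi} needs {hi - 1} signals, "
                f"only {config.n_signals} configured"
            )

    entities: list[Entity] = []
    n_classes = max(1, config.n_signals // 5) if config.n_signals else 0
    for c in range(n_classes):
        entities.append(
            Entity(id=f"sigclass{c:02d}", name=f"signal class {c}", etype="signal")
        )
    for s in range(config.n_signals):
        parent = f"sigclass{s % n_classes:02d}" if n_classes else None
        entities.append(
            Entity(
                id=f"sig{s:03d}",
                name=f"signal {s}",
                etype="signal",
                parents=(parent,) if parent else (),
            )
        )
    for t in range(config.n_tfs):
        entities.append(Entity(id=f"tf{t:03d}", name=f"TF {t}", etype="tf"))
    for g in range(config.n_tgs):
        entities.append(Entity(id=f"g{g:03d}", name=f"gene {g}", etype="gene"))

    from .model import derive_rtype

    transitions: list[Transition] = []
    for i in range(config.n_transitions):
        n_inputs = int(rng.integers(lo, hi + 1))
        tf = f"tf{rng.integers(config.n_tfs):03d}"
        tf_dir = "up" if rng.random() < 0.5 else "down"
        tf_mag = str(rng.choice(["weak", "medium", "strong", "na"]))
        inputs = [
            TransitionInput(
                entity_id=tf,
                role="tf",
                state=RegulatoryState(direction=tf_dir, magnitude=tf_mag),
            )
        ]
        sig_ids = rng.choice(config.n_signals, size=n_inputs - 1, replace=False)
        for s in sig_ids:
            inputs.append(
                TransitionInput(
                    entity_id=f"sig{s:03d}",
                    role="signal",
                    state=RegulatoryState(
                        direction="present" if rng.random() < 0.7 else "absent"
                    ),
                )
            )
        tg = f"g{rng.integers(config.n_tgs):03d}"
        out_dir = "up" if rng.random() < 0.5 else "down"
        out_mag = str(rng.choice(["weak", "medium", "strong"]))
        tr = Transition(
            id=f"T{i:04d}",
            process=_PROCESSES[int(rng.integers(len(_PROCESSES)))],
            inputs=tuple(inputs),
            outputs=(TransitionOutput(entity_id=tg, direction=out_dir, magnitude=out_mag),),
        )
        # store the derived rtype so files are auditable
        out = tr.outputs[0]
        tr = Transition(
            id=tr.id,
            process=tr.process,
            inputs=tr.inputs,
            outputs=(replace(out, rtype=derive_rtype(tr, out)),),
        )
        transitions.append(tr)

    return Network.from_lists(entities, transitions)


def simulate_curation(network: Network, config: SynthConfig) -> list[EvidenceRecord]:
    """Simulated literature record of the network, reproducible from seed.

    Each of ``config.articles`` articles contributes a Poisson-distributed
    number of annotations; each annotation cites one transition drawn
    according to the attention weights.  A fraction ``p_high_evidence`` of
    transitions is destined for high confidence: their annotations
    alternate binding and expression classes, while the rest draw from the
    classes that never combine to high confidence.
    """
    tids = sorted(network.transitions)
    if not tids:
        raise ValueError("network has no transitions to curate")
    rng = np.random.default_rng([config.seed, 1])
    n = len(tids)
    if config.heterogeneous_attention:
        w = rng.exponential(1.0, n)
        p = w / w.sum()
    else:
        p = np.full(n, 1.0 / n)
    destined_high = rng.random(n) < config.p_high_evidence
    low_classes = ("expression", "consensus", "author_statement")
    technique_of = {
        "binding": "ChIP",
        "expression": "microarray",
        "consensus": "PWM match",
        "author_statement": "review statement",
    }
    seen_count = {t: 0 for t in tids}
    records: list[EvidenceRecord] = []
    counts = rng.poisson(config.mean_annotations_per_article, config.articles)
    for a_idx in range(config.articles):
        article = f"PMID{10_000_000 + a_idx}"
        for _ in range(int(counts[a_idx])):
            ti = int(rng.choice(n, p=p))
            tid = tids[ti]
            if destined_high[ti]:
                eclass = "binding" if seen_count[tid] % 2 == 0 else "expression"
            else:
                eclass = str(low_classes[int(rng.integers(len(low_classes)))])
            seen_count[tid] += 1
            records.append(
                EvidenceRecord(
                    transition_id=tid,
                    article=article,
                    eclass=eclass,
                    technique=technique_of[eclass],
                    quote="",
                )
            )
    return records


def make_table1_fixture() -> Network:
    """Deterministic fixture matching the totals of a full curated network:
    100 target genes, 68 TFs, 322 interactions of which 212 carry combined
    binding+expression evidence, and 1133 annotations over 410 articles.

    Per-process structure is distributed arbitrarily but deterministically
    across nine subprocess labels; only the totals are contractual.
    """
    entities: list[Entity] = [
        Entity(id="carbon_source", name="carbon source", etype="signal"),
        Entity(
            id="fermentable_cs",
            name="fermentable carbon source",
            etype="signal",
            parents=("carbon_source",),
        ),
        Entity(
            id="non_fermentable_cs",
            name="non-fermentable carbon source",
            etype="signal",
            parents=("carbon_source",),
        ),
        Entity(id="glucose", name="glucose", etype="signal", parents=("fermentable_cs",)),
        Entity(id="ethanol", name="ethanol", etype="signal", parents=("non_fermentable_cs",)),
    ]
    for g in range(100):
        entities.append(Entity(id=f"G{g:03d}", name=f"gene {g}", etype="gene"))
    for t in range(68):
        entities.append(Entity(id=f"TF{t:02d}", name=f"TF {t}", etype="tf"))

    from .model import derive_rtype

    transitions: list[Transition] = []
    for i in range(322):
        tf_dir = "up" if i % 2 == 0 else "down"
        out_dir = "up" if i % 3 != 0 else "down"
        mag = ("weak", "medium", "strong")[i % 3]
        sig = "ethanol" if i % 2 == 0 else "glucose"
        sig_dir = "present" if i % 4 < 2 else "absent"
        inputs = (
            TransitionInput(
                entity_id=sig, role="signal", state=RegulatoryState(direction=sig_dir)
            ),
            TransitionInput(
                entity_id=f"TF{i % 68:02d}",
                role="tf",
                state=RegulatoryState(direction=tf_dir, magnitude="na"),
            ),
        )
        out = TransitionOutput(entity_id=f"G{i % 100:03d}", direction=out_dir, magnitude=mag)
        tr = Transition(
            id=f"T{i:03d}", process=_PROCESSES[i % len(_PROCESSES)], inputs=inputs, outputs=(out,)
        )
        tr = Transition(
            id=tr.id,
            process=tr.process,
            inputs=tr.inputs,
            outputs=(replace(out, rtype=derive_rtype(tr, out)),),
        )
        transitions.append(tr)

    # 1133 annotations: transitions 0..166 get 4 records, 167..321 get 3.
    # The first 212 transitions combine binding+expression (high), the
    # remaining 110 have expression-only support (low).
    records: list[EvidenceRecord] = []
    high_pattern = ("binding", "expression", "consensus", "author_statement")
    technique_of = {
        "binding": "ChIP",
        "expression": "northern blot",
        "consensus": "PWM match",
        "author_statement": "review statement",
    }
    rec_idx = 0
    for i in range(322):
        n_rec = 4 if i < 167 else 3
        for j in range(n_rec):
            eclass = high_pattern[j] if i < 212 else "expression"
            records.append(
                EvidenceRecord(
                    transition_id=f"T{i:03d}",
                    article=f"PMID{9_000_000 + rec_idx % 410}",
                    eclass=eclass,
                    technique=technique_of[eclass],
                    quote="",
                )
            )
            rec_idx += 1
    assert rec_idx == 1133

    return Network.from_lists(entities, transitions, records)
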