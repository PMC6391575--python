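"""The trained model: scheme + statistics + principle clusters.

Training runs the full induction pipeline — extract candidate principles
from gold mentions, summarize them with the greedy dominating-set cover,
estimate slot statistics, and compute each cluster's acceptance
threshold.  The result round-trips losslessly through a single JSON model
file; recognition needs only this file plus input text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__ as _pkg_version
from .corpus import AnnotatedDocument, Annotation
from .induction import (
    IDSCriteria,
    PrincipleCluster,
    build_domination_graph,
    extract_candidate_principles,
    greedy_dominating_set,
)
from .matching import Mention, recognize
from .normalize import (
    NormalizationEntry,
    SlotIndex,
    build_slot_index,
    normalize_mention,
    parse_family_file,
)
from .scheme import SlotScheme, dumps_slot_scheme, loads_slot_scheme
from .scoring import SlotStatistics, cluster_threshold, estimate_statistics
from .text import label_text

logger = logging.getLogger(__name__)


@dataclass
class Model:
    """A self-contained trained recognizer."""

    scheme: SlotScheme
    stats: SlotStatistics
    clusters: list[PrincipleCluster]
    window_limit: int = 30
    threshold_insertion_mode: str = "subtract"
    version: str = _pkg_version

    # -- persistence -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "mirslot-model",
            "version": self.version,
            "scheme": dumps_slot_scheme(self.scheme),
            "stats": self.stats.to_dict(),
            "clusters": [c.to_dict() for c in self.clusters],
            "window_limit": self.window_limit,
            "threshold_insertion_mode": self.threshold_insertion_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Model":
        return cls(
            scheme=loads_slot_scheme(d["scheme"], source="<model>"),
            stats=SlotStatistics.from_dict(d["stats"]),
            clusters=[PrincipleCluster.from_dict(c) for c in d["clusters"]],
            window_limit=d.get("window_limit", 30),
            threshold_insertion_mode=d.get("threshold_insertion_mode", "subtract"),
            version=d.get("version", "?"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    # -- annotation ------------------------------------------------------

    def recognize_text(self, text: str) -> list[Mention]:
        """All accepted mentions in a text, offsets into the text."""
        mentions: list[Mention] = []
        for seq in label_text(text, self.scheme):
            found = recognize(seq, self.clusters, self.stats, self.window_limit)
            for m in found:
                m.text = text[m.start : m.end]
            mentions.extend(found)
        return mentions

    def annotate_document(
        self, doc: AnnotatedDocument, normalizer: "Normalizer | None" = None
    ) -> AnnotatedDocument:
        """Predict annotations for one document (gold ones are ignored)."""
        anns = []
        for m in self.recognize_text(doc.text):
            accs: tuple[str, ...] = ()
            if normalizer is not None:
                accs = normalizer.best_accessions(m)
            anns.append(
                Annotation(
                    m.start,
                    m.end,
                    m.text,
                    accessions=accs,
                    score=m.score,
                    principle=str(m.alignment.principle),
                )
            )
        return AnnotatedDocument(doc.doc_id, doc.text, anns)

    def annotate_corpus(
        self, docs: Sequence[AnnotatedDocument], normalizer: "Normalizer | None" = None
    ) -> list[AnnotatedDocument]:
        return [self.annotate_document(d, normalizer) for d in docs]


def train(
    docs: Sequence[AnnotatedDocument],
    scheme: SlotScheme,
    criteria: IDSCriteria = IDSCriteria(),
    lambda_scale: float = 100.0,
    unseen_insertion: float = 30.0,
    pseudo_count: float = 0.0,
    threshold_insertion_mode: str = "subtract",
    window_limit: int = 30,
) -> Model:
    """Train a recognizer from a span-annotated corpus."""
    if not docs:
        raise ValueError("cannot train on an empty corpus")
    candidates = extract_candidate_principles(docs, scheme)
    if not candidates:
        raise ValueError("no usable gold mention produced a principle")
    graph = build_domination_graph([c.principle for c in candidates], criteria)
    clusters = greedy_dominating_set(graph, candidates)
    stats = estimate_statistics(
        docs,
        scheme,
        lambda_scale=lambda_scale,
        unseen_insertion=unseen_insertion,
        pseudo_count=pseudo_count,
    )
    for c in clusters:
        c.threshold = cluster_threshold(c, stats, threshold_insertion_mode)
    logger.info(
        "trained model: %d principles, %d clusters; thresholds %s",
        len(candidates),
        len(clusters),
        ", ".join(f"{str(c.dominant)}={c.threshold:.3f}" for c in clusters),
    )
    return Model(
        scheme=scheme,
        stats=stats,
        clusters=clusters,
        window_limit=window_limit,
        threshold_insertion_mode=threshold_insertion_mode,
    )


@dataclass
class Normalizer:
    """A compiled Rfam lexicon bound to a trained model."""

    entries: list[NormalizationEntry]
    index: SlotIndex
    scheme: SlotScheme = field(repr=False, default=None)  # type: ignore[assignment]
    stats: SlotStatistics = field(repr=False, default=None)  # type: ignore[assignment]

    @classmethod
    def from_family_file(cls, path: str | Path, model: Model) -> "Normalizer":
        entries = parse_family_file(path)
        index = build_slot_index(entries, model.scheme, model.clusters, model.stats)
        return cls(entries=entries, index=index, scheme=model.scheme, stats=model.stats)

    def normalize(self, mention: Mention) -> list[tuple[str, float]]:
        return normalize_mention(
            mention, self.index, self.entries, self.scheme, self.stats
        )

    def best_accessions(self, mention: Mention) -> tuple[str, ...]:
        """Top-scoring accession per sub-mention group, in mention order."""
        from .normalize import normalize_mention_groups

        out: list[str] = []
        for ranked in normalize_mention_groups(
            mention, self.index, self.entries, self.scheme, self.stats
        ):
            if ranked and ranked[0][0] not in out:
                out.append(ranked[0][0])
        return tuple(out)
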