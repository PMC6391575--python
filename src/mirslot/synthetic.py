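"""Synthetic annotated corpora with the statistical structure the
recognizer assumes.

The generator emulates sentence-level miRNA-mention corpora: each mention
is sampled from the slot grammar

    [Precursor]? [Species]? [indicator] [Order] ([Conj|,] [Order])* [Suffix]?

joined with ``-`` separators (conjunction lists use ``, -130a`` style
continuations, slash pairs use ``/``), embedded in filler sentences.  Gold
spans and gold Rfam accessions are recorded, and a matching toy family
file (real Rfam column layout) plus a manifest of expected counts are
emitted alongside.

Filler text draws from a fixed word list; with probability ``noise_rate``
a filler position is replaced by a slot-term or punctuation *decoy*, which
is what gives slots and symbols non-zero outside-mention frequencies.
Two structural invariants keep the emulation aligned with how such
corpora are annotated: distinct mentions are separated by at least one
plain filler word (adjacent lists would be a single gold mention), and a
mention never directly precedes sentence-final punctuation.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .corpus import AnnotatedDocument, Annotation, write_standoff

_FILLER = (
    "expression of the in was observed to regulate target genes during "
    "development while levels were measured by northern blot analysis "
    "suggesting that this pathway is required for normal cell growth "
    "we found significantly reduced compared with controls these data "
    "indicate a role downstream signaling upon induction tumor samples"
).split()

_DECOY_TERMS = ("hsa", "cel", "pre", "mir", "let", "3p", "5p", "-", ",", "(", ")")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    n_documents: int = 20
    sentences_per_doc: tuple[int, int] = (3, 8)
    mentions_per_sentence: dict[int, float] = field(
        default_factory=lambda: {0: 0.25, 1: 0.55, 2: 0.20}
    )
    p_precursor: float = 0.15
    p_species: float = 0.5
    p_suffix: float = 0.25
    p_let: float = 0.15
    p_slash: float = 0.10  # slash pair instead of comma list when length 2
    conj_len_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.72, 2: 0.12, 3: 0.08, 4: 0.05, 8: 0.03}
    )
    noise_rate: float = 0.05
    n_families: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_precursor, self.p_species, self.p_suffix, self.p_let,
                  self.p_slash, self.noise_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_documents <= 0:
            raise ValueError("n_documents must be positive")


@dataclass
class SyntheticCorpus:
    """Documents + matched toy family table + manifest of expected counts."""

    documents: list[AnnotatedDocument]
    family_file_text: str
    manifest: dict

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_standoff(self.documents, directory / "corpus")
        (directory / "family.txt").write_text(self.family_file_text, encoding="utf-8")
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True), encoding="utf-8"
        )


def _choice(rng: random.Random, dist: dict) -> object:
    r = rng.random() * sum(dist.values())
    acc = 0.0
    for k in sorted(dist):
        acc += dist[k]
        if r <= acc:
            return k
    return max(dist)


def _make_families(rng: random.Random, n: int) -> list[dict]:
    """A pool of toy Rfam families with ids like mir-146a / let-7c."""
    families = []
    used = set()
    n_let = max(1, n // 8)
    for i in range(n_let):
        order = "7" + "abcdefg"[i % 7]
        fam_id = f"let-{order}"
        if fam_id in used:
            continue
        used.add(fam_id)
        families.append({"order": order, "id": fam_id, "indicator": "let"})
    while len(families) < n:
        num = rng.randint(10, 499)
        order = str(num) + (rng.choice("abc") if rng.random() < 0.3 else "")
        fam_id = f"mir-{order}"
        if fam_id in used:
            continue
        used.add(fam_id)
        families.append({"order": order, "id": fam_id, "indicator": "mir"})
    for i, fam in enumerate(families):
        fam["accession"] = f"RF{10000 + i:05d}"
    return families


def _family_file_text(rng: random.Random, families: list[dict]) -> str:
    rows = []
    for fam in families:
        desc = f"{fam['id']} microRNA precursor family"
        prev = r"\N"
        if rng.random() < 0.2:
            prev = fam["id"].replace("-", "")
        rows.append(
            "\t".join(
                [
                    fam["accession"],
                    fam["id"],
                    str(rng.randint(1000, 3000)),
                    desc,
                    "Synthetic A",
                    "Synthetic; toy",
                    "50.00",
                    "50.10",
                    "49.90",
                    r"\N",
                    prev,
                    "0",
                    "1",
                    "0.59",
                    "seed",
                    "microRNA",
                ]
            )
        )
    return "\n".join(rows) + "\n"


def _sample_mention(rng: random.Random, cfg: GeneratorConfig, families: list[dict]
                    ) -> tuple[str, list[str]]:
    """One mention surface string plus its gold accession list."""
    let_pool = [f for f in families if f["indicator"] == "let"]
    mir_pool = [f for f in families if f["indicator"] == "mir"]
    if let_pool and rng.random() < cfg.p_let:
        fam = rng.choice(let_pool)
        indicator = "let"
        pool = let_pool
    else:
        fam = rng.choice(mir_pool)
        indicator = rng.choice(["miR", "miR", "miR", "mir", "microRNA"])
        pool = mir_pool
    k = int(_choice(rng, cfg.conj_len_dist))
    chosen = [fam]
    others = [f for f in pool if f is not fam]
    rng.shuffle(others)
    chosen.extend(others[: k - 1])
    parts = []
    if rng.random() < cfg.p_precursor:
        parts.append("pre-")
    if rng.random() < cfg.p_species:
        parts.append(rng.choice(["hsa", "cel"]) + "-")
    first = chosen[0]
    if len(chosen) == 2 and rng.random() < cfg.p_slash:
        body = f"{indicator}-{first['order']}/{chosen[1]['order']}"
    else:
        body = f"{indicator}-{first['order']}"
        rest = chosen[1:]
        for j, f in enumerate(rest):
            last = j == len(rest) - 1
            style = rng.choice([", -", ", "])
            if last and len(rest) > 1 and rng.random() < 0.5:
                body += f" and -{f['order']}"
            else:
                body += f"{style}{f['order']}"
    surface = "".join(parts) + body
    if rng.random() < cfg.p_suffix:
        surface += "-" + rng.choice(["5p", "3p"])
    return surface, [f["accession"] for f in chosen]


def _filler(rng: random.Random, cfg: GeneratorConfig, n: int) -> list[str]:
    words = []
    for _ in range(n):
        if rng.random() < cfg.noise_rate:
            words.append(rng.choice(_DECOY_TERMS))
        else:
            words.append(rng.choice(_FILLER))
    return words


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a seeded corpus, its toy family file, and a manifest."""
    rng = random.Random(config.seed)
    families = _make_families(rng, config.n_families)
    family_text = _family_file_text(rng, families)
    docs: list[AnnotatedDocument] = []
    n_mentions = 0
    used_accessions: set[str] = set()
    for di in range(config.n_documents):
        doc_id = f"doc{di:04d}"
        sentences: list[str] = []
        annotations: list[Annotation] = []
        pos = 0
        n_sents = rng.randint(*config.sentences_per_doc)
        for _ in range(n_sents):
            n_m = int(_choice(rng, config.mentions_per_sentence))
            pieces: list[str] = _filler(rng, config, rng.randint(2, 5))
            spans: list[tuple[int, str, list[str]]] = []
            for _m in range(n_m):
                surface, accs = _sample_mention(rng, config, families)
                spans.append((len(pieces), surface, accs))
                pieces.append(surface)
                # ≥1 plain filler word between/after mentions, none a decoy
                pieces.extend(rng.choice(_FILLER) for _ in range(rng.randint(1, 4)))
            pieces[-1] = pieces[-1] + "."
            # compute offsets
            sent_start = pos
            cursor = sent_start
            starts: dict[int, int] = {}
            for wi, w in enumerate(pieces):
                starts[wi] = cursor
                cursor += len(w) + 1
            sentence = " ".join(pieces)
            for wi, surface, accs in spans:
                s = starts[wi]
                annotations.append(Annotation(s, s + len(surface), surface, tuple(accs)))
                n_mentions += 1
                used_accessions.update(accs)
            sentences.append(sentence)
            pos = sent_start + len(sentence) + 1
        text = " ".join(sentences)
        for a in annotations:
            assert text[a.start : a.end] == a.text
        docs.append(AnnotatedDocument(doc_id, text, annotations))
    manifest = {
        "seed": config.seed,
        "n_documents": len(docs),
        "n_mentions": n_mentions,
        "n_families": len(families),
        "n_unique_ids_used": len(used_accessions),
        "noise_rate": config.noise_rate,
    }
    return SyntheticCorpus(docs, family_text, manifest)
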