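"""Annotated-corpus I/O and strict-span micro-averaged evaluation.

Two interchange formats are supported:

* **standoff** — a directory holding one ``<doc_id>.txt`` per document
  plus ``annotations.tsv`` with one line per annotation::

      doc_id <TAB> start <TAB> end <TAB> surface <TAB> accessions

  Offsets are 0-based half-open into the raw document text; the accession
  cell is ``;``-separated and may be empty (recognition-only corpora).

* **BioC XML** — a single collection file; each document holds one
  passage with the full text and ``annotation`` elements carrying
  ``type=miRNA`` and optional ``Rfam`` infons.

Evaluation is strict: a prediction is a true positive only if its
(start, end) span exactly equals a gold annotation's; in normalization
mode the predicted and gold accession sets must additionally intersect
(gold mentions may legitimately carry several IDs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree


@dataclass
class Annotation:
    """One gold or predicted mention within a document."""

    start: int
    end: int
    text: str = ""
    accessions: tuple[str, ...] = ()
    score: float | None = None
    principle: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad annotation offsets ({self.start}, {self.end})")
        self.accessions = tuple(self.accessions)


@dataclass
class AnnotatedDocument:
    """A document's raw text plus its (possibly empty) annotations."""

    doc_id: str
    text: str
    annotations: list[Annotation] = field(default_factory=list)


@dataclass
class EvalReport:
    """Micro-averaged strict-span precision/recall/F1."""

    tp: int
    fp: int
    fn: int
    per_document: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "F1": self.f1,
        }


# -- standoff ------------------------------------------------------------


def write_standoff(docs: list[AnnotatedDocument], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    for doc in docs:
        (directory / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        for a in sorted(doc.annotations, key=lambda a: (a.start, a.end)):
            acc = ";".join(a.accessions)
            lines.append(f"{doc.doc_id}\t{a.start}\t{a.end}\t{a.text}\t{acc}")
    (directory / "annotations.tsv").write_text("\n".join(lines) + ("\n" if lines else ""),
                                               encoding="utf-8")


def read_standoff(directory: str | Path) -> list[AnnotatedDocument]:
    directory = Path(directory)
    docs: dict[str, AnnotatedDocument] = {}
    for txt in sorted(directory.glob("*.txt")):
        doc_id = txt.stem
        docs[doc_id] = AnnotatedDocument(doc_id, txt.read_text(encoding="utf-8"))
    ann_path = directory / "annotations.tsv"
    if ann_path.exists():
        for lineno, line in enumerate(
            ann_path.read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                warnings.warn(f"{ann_path}:{lineno}: malformed line; skipped")
                continue
            doc_id, start, end, surface = parts[0], parts[1], parts[2], parts[3]
            accs = tuple(a for a in parts[4].split(";") if a) if len(parts) > 4 else ()
            doc = docs.get(doc_id)
            if doc is None:
                warnings.warn(f"{ann_path}:{lineno}: unknown document {doc_id!r}; skipped")
                continue
            try:
                s, e = int(start), int(end)
                ann = Annotation(s, e, surface, accs)
            except ValueError as err:
                warnings.warn(f"{ann_path}:{lineno}: {err}; skipped")
                continue
            if e > len(doc.text):
                warnings.warn(
                    f"{ann_path}:{lineno}: span {s}-{e} exceeds document length; dropped"
                )
                continue
            doc.annotations.append(ann)
    return list(docs.values())


# -- BioC ----------------------------------------------------------------


def write_bioc(docs: list[AnnotatedDocument], path: str | Path) -> None:
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = "mirslot"
    for doc in docs:
        d = etree.SubElement(root, "document")
        etree.SubElement(d, "id").text = doc.doc_id
        p = etree.SubElement(d, "passage")
        etree.SubElement(p, "offset").text = "0"
        etree.SubElement(p, "text").text = doc.text
        for k, a in enumerate(doc.annotations):
            ann = etree.SubElement(p, "annotation", id=f"{doc.doc_id}.{k}")
            infon = etree.SubElement(ann, "infon", key="type")
            infon.text = "miRNA"
            if a.accessions:
                rf = etree.SubElement(ann, "infon", key="Rfam")
                rf.text = ";".join(a.accessions)
            etree.SubElement(
                ann, "location", offset=str(a.start), length=str(a.end - a.start)
            )
            etree.SubElement(ann, "text").text = a.text
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def read_bioc(path: str | Path) -> list[AnnotatedDocument]:
    tree = etree.parse(str(path))
    docs = []
    for d in tree.findall(".//document"):
        doc_id = d.findtext("id") or f"doc{len(docs)}"
        text_parts = []
        annotations = []
        for p in d.findall("passage"):
            base = int(p.findtext("offset") or 0)
            ptext = p.findtext("text") or ""
            text_parts.append(ptext)
            for ann in p.findall("annotation"):
                loc = ann.find("location")
                if loc is None:
                    continue
                start = int(loc.get("offset"))
                length = int(loc.get("length"))
                accs = ()
                for infon in ann.findall("infon"):
                    if infon.get("key") == "Rfam" and infon.text:
                        accs = tuple(a for a in infon.text.split(";") if a)
                surface = ann.findtext("text") or ""
                try:
                    a = Annotation(start, start + length, surface, accs)
                except ValueError as err:
                    warnings.warn(f"{path}: bad annotation in {doc_id}: {err}; dropped")
                    continue
                annotations.append(a)
        text = "".join(text_parts)
        valid = []
        for a in annotations:
            if a.end > len(text):
                warnings.warn(
                    f"{path}: annotation {a.start}-{a.end} exceeds text in {doc_id}; dropped"
                )
                continue
            valid.append(a)
        docs.append(AnnotatedDocument(doc_id, text, valid))
    return docs


def read_corpus(path: str | Path, format: str = "standoff") -> list[AnnotatedDocument]:
    """Read a corpus in ``standoff`` (directory) or ``bioc`` (XML) format."""
    if format == "standoff":
        return read_standoff(path)
    if format == "bioc":
        return read_bioc(path)
    raise ValueError(f"unknown corpus format {format!r}")


def write_corpus(
    docs: list[AnnotatedDocument], path: str | Path, format: str = "standoff"
) -> None:
    if format == "standoff":
        write_standoff(docs, path)
    elif format == "bioc":
        write_bioc(docs, path)
    else:
        raise ValueError(f"unknown corpus format {format!r}")


# -- evaluation ----------------------------------------------------------


def evaluate(
    pred: list[AnnotatedDocument],
    gold: list[AnnotatedDocument],
    mode: str = "recognition",
) -> EvalReport:
    """Strict-span micro-averaged P/R/F over matching documents.

    ``mode="recognition"`` counts exact span matches; ``"normalization"``
    additionally requires a non-empty intersection of the predicted and
    gold accession sets.  Every predicted document id must exist in the
    gold corpus.
    """
    if mode not in ("recognition", "normalization"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    gold_by_id = {d.doc_id: d for d in gold}
    unknown = [d.doc_id for d in pred if d.doc_id not in gold_by_id]
    if unknown:
        raise ValueError(f"predicted documents missing from gold corpus: {unknown}")
    pred_by_id = {d.doc_id: d for d in pred}
    tp = fp = fn = 0
    per_doc: dict[str, tuple[int, int, int]] = {}
    for doc_id, gdoc in gold_by_id.items():
        pdoc = pred_by_id.get(doc_id)
        panns = list(pdoc.annotations) if pdoc else []
        ganns = list(gdoc.annotations)
        gmap = {(a.start, a.end): a for a in ganns}
        dtp = dfp = 0
        matched = set()
        for a in panns:
            g = gmap.get((a.start, a.end))
            ok = g is not None and (a.start, a.end) not in matched
            if ok and mode == "normalization":
                ok = bool(set(a.accessions) & set(g.accessions))
            if ok:
                dtp += 1
                matched.add((a.start, a.end))
            else:
                dfp += 1
        dfn = len(ganns) - dtp
        tp, fp, fn = tp + dtp, fp + dfp, fn + dfn
        per_doc[doc_id] = (dtp, dfp, dfn)
    return EvalReport(tp, fp, fn, per_doc)
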