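"""Hierarchical slot scheme: the lexical knowledge behind miRNA recognition.

A *slot* is a named lexical category — ``Species``, ``miRNA`` (the indicator
word), ``Order`` (the numbering string), ``Suffix`` and so on.  Closed-class
slots carry a term list ("hsa", "cel", ...); open-class slots carry a regular
expression (``Order`` matches strings like ``21``, ``181b``, ``16a1``).
Slots form a hierarchy: a token labeled with a child slot (``Hairpin``) is
also retrievable under its parent (``Suffix``), never the reverse.

The scheme is stored in a small plain-text format::

    SLOT Species
      hsa
      cel
    SLOT Order OPEN ^\\d{1,4}[a-z]{0,2}\\d?$
    SLOT Hairpin PARENT Suffix
      3p
      5p

All term matching is case-insensitive; terms are case-folded on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable


class SchemeError(ValueError):
    """Raised for structural problems in a slot scheme or its file."""


@dataclass
class SlotDef:
    """One slot: a name, an optional parent, and terms or a pattern."""

    name: str
    parent: str | None = None
    terms: set[str] = field(default_factory=set)
    pattern: str | None = None  # open-class recognizer regex, or None

    def __post_init__(self) -> None:
        self.terms = {t.casefold() for t in self.terms if t.strip()}
        if self.pattern is not None:
            self._compiled = re.compile(self.pattern)
        else:
            self._compiled = None

    @property
    def is_open_class(self) -> bool:
        return self.pattern is not None

    def matches(self, token: str) -> bool:
        """Case-insensitive single-token membership test."""
        tok = token.casefold()
        if tok in self.terms:
            return True
        if self._compiled is not None and self._compiled.fullmatch(tok):
            return True
        return False


@dataclass
class SlotScheme:
    """An ordered collection of slots with a validated hierarchy."""

    slots: list[SlotDef]
    version: str = "1"

    def __post_init__(self) -> None:
        self._by_name: dict[str, SlotDef] = {}
        for s in self.slots:
            if s.name in self._by_name:
                raise SchemeError(f"duplicate slot name: {s.name!r}")
            self._by_name[s.name] = s
        children: dict[str, list[str]] = {}
        for s in self.slots:
            if s.parent is not None:
                if s.parent not in self._by_name:
                    raise SchemeError(
                        f"slot {s.name!r} references unknown parent {s.parent!r}"
                    )
                children.setdefault(s.parent, []).append(s.name)
        self._children = children
        for s in self.slots:  # acyclicity
            seen = set()
            cur: str | None = s.name
            while cur is not None:
                if cur in seen:
                    raise SchemeError(f"slot hierarchy cycle through {cur!r}")
                seen.add(cur)
                cur = self._by_name[cur].parent
        for s in self.slots:
            if not s.is_open_class and not s.terms and s.name not in children:
                raise SchemeError(
                    f"closed-class slot {s.name!r} has no terms and no children"
                )
        # multi-word closed-class terms, per slot, longest first (greedy match)
        self._multi: list[tuple[tuple[str, ...], str]] = []
        for s in self.slots:
            for t in s.terms:
                if " " in t:
                    self._multi.append((tuple(t.split()), s.name))
        self._multi.sort(key=lambda p: -len(p[0]))

    # -- queries ---------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> SlotDef:
        return self._by_name[name]

    @property
    def slot_names(self) -> list[str]:
        return [s.name for s in self.slots]

    def ancestors(self, name: str) -> list[str]:
        """Parent chain of ``name``, nearest first (excludes ``name``)."""
        out = []
        cur = self._by_name[name].parent
        while cur is not None:
            out.append(cur)
            cur = self._by_name[cur].parent
        return out

    def descendants(self, name: str) -> set[str]:
        out: set[str] = set()
        stack = list(self._children.get(name, ()))
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(self._children.get(n, ()))
        return out

    def lookup_term(self, token_text: str) -> set[str]:
        """All slots matching the token, with parent generalization applied.

        A token matched by a child slot is also reported under every
        ancestor slot; an unknown token yields the empty set.
        """
        hits: set[str] = set()
        for s in self.slots:
            if s.matches(token_text):
                hits.add(s.name)
                hits.update(self.ancestors(s.name))
        return hits

    def multi_token_terms(self) -> list[tuple[tuple[str, ...], str]]:
        """Closed-class terms spanning several whitespace tokens."""
        return list(self._multi)

    def declaration_index(self, name: str) -> int:
        return self.slot_names.index(name)

    def most_specific(self, labels: Iterable[str]) -> str | None:
        """Pick one label deterministically from a token's label set.

        Ancestor labels are shadowed by their descendants, closed-class
        slots beat open-class pattern matches (a term list is the stronger
        evidence: ``5p`` is a Hairpin suffix even though it also fits the
        numbering pattern), and remaining ties go to scheme declaration
        order.  Returns None for an empty set.
        """
        labels = set(labels)
        if not labels:
            return None
        keep = [l for l in labels if not (self.descendants(l) & labels)]
        return min(
            keep,
            key=lambda l: (self._by_name[l].is_open_class, self.declaration_index(l)),
        )


# -- serialization -------------------------------------------------------

_SLOT_RE = re.compile(
    r"^SLOT\s+(?P<name>\S+)"
    r"(?:\s+PARENT\s+(?P<parent>\S+))?"
    r"(?:\s+OPEN\s+(?P<pattern>\S+))?\s*$"
)


def loads_slot_scheme(text: str, source: str = "<string>") -> SlotScheme:
    """Parse a scheme from its text form; errors carry line numbers."""
    slots: list[SlotDef] = []
    cur: dict | None = None

    def flush() -> None:
        nonlocal cur
        if cur is not None:
            slots.append(SlotDef(**cur))
            cur = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("VERSION"):
            continue
        if not line[0].isspace():
            m = _SLOT_RE.match(line)
            if not m:
                raise SchemeError(f"{source}:{lineno}: cannot parse {line!r}")
            flush()
            cur = {
                "name": m.group("name"),
                "parent": m.group("parent"),
                "pattern": m.group("pattern"),
                "terms": set(),
            }
        else:
            if cur is None:
                raise SchemeError(f"{source}:{lineno}: term before any SLOT header")
            cur["terms"].add(line.strip())
    flush()
    if not slots:
        raise SchemeError(f"{source}: no slots defined")
    version = "1"
    for raw in text.splitlines():
        if raw.startswith("VERSION"):
            version = raw.split(None, 1)[1].strip() if len(raw.split(None, 1)) > 1 else "1"
    return SlotScheme(slots=slots, version=version)


def load_slot_scheme(path: str | Path) -> SlotScheme:
    path = Path(path)
    return loads_slot_scheme(path.read_text(encoding="utf-8"), source=str(path))


def dumps_slot_scheme(scheme: SlotScheme) -> str:
    lines = [f"VERSION {scheme.version}"]
    for s in scheme.slots:
        head = f"SLOT {s.name}"
        if s.parent:
            head += f" PARENT {s.parent}"
        if s.pattern:
            head += f" OPEN {s.pattern}"
        lines.append(head)
        for t in sorted(s.terms):
            lines.append(f"  {t}")
    return "\n".join(lines) + "\n"


def save_slot_scheme(scheme: SlotScheme, path: str | Path) -> None:
    Path(path).write_text(dumps_slot_scheme(scheme), encoding="utf-8")


def default_scheme() -> SlotScheme:
    """The bundled scheme covering the published miRNA slot inventory."""
    text = (
        resources.files("mirslot.data").joinpath("default_scheme.txt").read_text("utf-8")
    )
    return loads_slot_scheme(text, source="mirslot.data/default_scheme.txt")
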