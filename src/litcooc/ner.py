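"""Dictionary-based named entity recognition.

Entities (genes/proteins, diseases, subcellular compartments, plus auxiliary
types loaded purely to absorb ambiguity) are recognised by exact dictionary
lookup: left-to-right, longest-match, non-overlapping, anchored at token
boundaries.  Matching is case-insensitive unless a name is flagged
case-sensitive.  A name listed in the stop-word file is never emitted.  A name
shared between dictionaries of different entity types is discarded as
ambiguous.  For ontology-backed types, every mention is propagated
("backtracked") to all ancestor terms so that associations accumulate at every
level of generality.

The matcher is contracted to produce exactly what a brute-force scan of every
dictionary name against every sentence position would; the token-anchored
hashed lookup used here is an internal acceleration.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Dictionary",
    "Mention",
    "DictionaryError",
    "load_dictionary",
    "tag_sentence",
    "tag_document",
    "resolve_ambiguity",
    "backtrack_ontology",
]


class DictionaryError(ValueError):
    """Malformed dictionary input (dangling reference, parent cycle, ...)."""


@dataclass(frozen=True)
class Mention:
    """One matched entity occurrence, localised within a sentence.

    ``serials`` holds every dictionary serial the matched name maps to (a
    name may map to several same-type serials, e.g. paralogous genes); after
    :func:`backtrack_ontology` it additionally holds all ancestor serials.
    ``entity_type`` is None while the serials span more than one type (such
    mentions are removed by :func:`resolve_ambiguity`).
    """

    doc_id: str
    paragraph_index: int
    sentence_index: int
    char_start: int
    char_end: int
    text: str
    serials: tuple[int, ...]
    entity_type: str | None


class Dictionary:
    """Typed entity lexicon with names, stop words and ontology parent edges."""

    def __init__(
        self,
        entries: Mapping[int, tuple[str, str]],
        names: Mapping[str, set[int]],
        stopwords: set[str],
        parents: Mapping[int, set[int]],
        case_sensitive_names: set[str] | None = None,
    ):
        self.entries: dict[int, tuple[str, str]] = dict(entries)
        self.stopwords = {s.lower() for s in stopwords}
        self.parents: dict[int, set[int]] = {k: set(v) for k, v in parents.items()}
        self.case_sensitive_names: set[str] = set(case_sensitive_names or ())
        # Split the name index by case policy; stop-worded names are
        # suppressed entirely at load time.
        self._names_cs: dict[str, frozenset[int]] = {}
        self._names_ci: dict[str, frozenset[int]] = {}
        for name, serials in names.items():
            if name.lower() in self.stopwords:
                continue
            if name in self.case_sensitive_names:
                self._names_cs[name] = frozenset(serials)
            else:
                key = name.lower()
                self._names_ci[key] = frozenset(serials) | self._names_ci.get(key, frozenset())
        self.name_lengths: tuple[int, ...] = tuple(
            sorted({len(n) for n in self._names_cs} | {len(n) for n in self._names_ci}, reverse=True)
        )
        self._ancestors: dict[int, frozenset[int]] = {}
        self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        for serials in list(self._names_cs.values()) + list(self._names_ci.values()):
            for s in serials:
                if s not in self.entries:
                    raise DictionaryError(f"name references unknown serial {s}")
        for child, ps in self.parents.items():
            if child not in self.entries:
                raise DictionaryError(f"parent edge references unknown serial {child}")
            for p in ps:
                if p not in self.entries:
                    raise DictionaryError(f"parent edge references unknown serial {p}")
        # Cycle detection by iterative DFS with colouring.
        color: dict[int, int] = {}
        for start in self.parents:
            if color.get(start):
                continue
            stack: list[tuple[int, Iterable[int]]] = [(start, iter(self.parents.get(start, ())))]
            color[start] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    c = color.get(nxt, 0)
                    if c == 1:
                        raise DictionaryError(f"cycle in parent relation at edge {node}->{nxt}")
                    if c == 0:
                        color[nxt] = 1
                        stack.append((nxt, iter(self.parents.get(nxt, ()))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = 2
                    stack.pop()

    # -- queries -------------------------------------------------------------

    def lookup(self, text: str) -> frozenset[int]:
        """Serials for an exact name candidate (both case policies)."""
        hits = self._names_cs.get(text, frozenset())
        hits |= self._names_ci.get(text.lower(), frozenset())
        return hits

    def all_names(self) -> Iterable[str]:
        yield from self._names_cs
        yield from self._names_ci

    def entity_type(self, serial: int) -> str:
        return self.entries[serial][1]

    def identifier(self, serial: int) -> str:
        return self.entries[serial][0]

    def serials_of_type(self, entity_type: str) -> list[int]:
        return sorted(s for s, (_, t) in self.entries.items() if t == entity_type)

    def ancestors(self, serial: int) -> frozenset[int]:
        """Transitive closure of the parent relation (serial excluded)."""
        cached = self._ancestors.get(serial)
        if cached is not None:
            return cached
        out: set[int] = set()
        stack = list(self.parents.get(serial, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents.get(p, ()))
        result = frozenset(out)
        self._ancestors[serial] = result
        return result

    def is_ancestor_pair(self, a: int, b: int) -> bool:
        return b in self.ancestors(a) or a in self.ancestors(b)


def _read_tsv(path: str, n_min_cols: int) -> list[list[str]]:
    rows: list[list[str]] = []
    if not os.path.exists(path):
        raise DictionaryError(f"missing dictionary file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < n_min_cols:
                raise DictionaryError(f"{path}:{lineno}: expected >= {n_min_cols} columns")
            rows.append([c.strip() for c in row])
    return rows


def load_dictionary(
    entities_path: str,
    names_path: str,
    groups_path: str | None = None,
    stopwords_path: str | None = None,
) -> Dictionary:
    """Load a dictionary from its four TSV files.

    * entities: ``serial TAB type TAB identifier``
    * names:    ``serial TAB name [TAB case_sensitive true/false]``
    * groups:   ``child_serial TAB parent_serial``
    * stopwords: ``name TAB true/false`` (true = suppress)

    Duplicate (name, serial) rows collapse; a dangling serial reference or a
    cycle in the parent relation raises :class:`DictionaryError`.
    """
    entries: dict[int, tuple[str, str]] = {}
    for serial_s, etype, identifier in (r[:3] for r in _read_tsv(entities_path, 3)):
        entries[int(serial_s)] = (identifier, etype)
    names: dict[str, set[int]] = {}
    case_sensitive: set[str] = set()
    for row in _read_tsv(names_path, 2):
        serial = int(row[0])
        name = row[1]
        names.setdefault(name, set()).add(serial)
        if len(row) >= 3 and row[2].lower() in ("1", "true", "t", "yes"):
            case_sensitive.add(name)
    parents: dict[int, set[int]] = {}
    if groups_path is not None and os.path.exists(groups_path):
        for child_s, parent_s in (r[:2] for r in _read_tsv(groups_path, 2)):
            parents.setdefault(int(child_s), set()).add(int(parent_s))
    stopwords: set[str] = set()
    if stopwords_path is not None and os.path.exists(stopwords_path):
        for row in _read_tsv(stopwords_path, 1):
            flag = row[1].lower() if len(row) >= 2 else "true"
            if flag in ("1", "true", "t", "yes"):
                stopwords.add(row[0])
    return Dictionary(entries, names, stopwords, parents, case_sensitive)


def _is_boundary(sentence: str, i: int) -> bool:
    """True when position i sits at a token edge (flanked by non-alnum)."""
    if i <= 0 or i >= len(sentence):
        return True
    return not sentence[i - 1].isalnum() or not sentence[i].isalnum()


def tag_sentence(
    sentence: str,
    dictionary: Dictionary,
    doc_id: str = "",
    paragraph_index: int = 0,
    sentence_index: int = 0,
) -> list[Mention]:
    """Left-to-right, longest-match, non-overlapping dictionary tagging.

    A match must start and end at token boundaries (flanked by non-alphanumeric
    characters or the string edges).  At each start position the longest
    matching name wins; matching then resumes after its end, so emitted
    mentions never overlap.
    """
    mentions: list[Mention] = []
    n = len(sentence)
    lengths = dictionary.name_lengths
    i = 0
    while i < n:
        if not sentence[i].isalnum() or not _is_boundary(sentence, i):
            i += 1
            continue
        hit: tuple[int, frozenset[int]] | None = None
        for L in lengths:
            j = i + L
            if j > n:
                continue
            if not _is_boundary(sentence, j):
                continue
            serials = dictionary.lookup(sentence[i:j])
            if serials:
                hit = (j, serials)
                break  # lengths are sorted descending: first hit is longest
        if hit is None:
            i += 1
            continue
        j, serials = hit
        types = {dictionary.entity_type(s) for s in serials}
        mentions.append(
            Mention(
                doc_id=doc_id,
                paragraph_index=paragraph_index,
                sentence_index=sentence_index,
                char_start=i,
                char_end=j,
                text=sentence[i:j],
                serials=tuple(sorted(serials)),
                entity_type=next(iter(types)) if len(types) == 1 else None,
            )
        )
        i = j
    return mentions


def tag_document(doc, dictionary: Dictionary) -> list[Mention]:
    """Tag every sentence of a :class:`litcooc.preprocess.Document`."""
    mentions: list[Mention] = []
    for p_idx, para in enumerate(doc.paragraphs):
        for s_idx, sentence in enumerate(para):
            mentions.extend(tag_sentence(sentence, dictionary, doc.doc_id, p_idx, s_idx))
    return mentions


def resolve_ambiguity(mentions: Sequence[Mention], dictionary: Dictionary) -> list[Mention]:
    """Drop mentions whose name maps to serials of more than one entity type.

    A term found in multiple dictionaries (e.g. a string naming both a gene
    and a compartment, or a scored type colliding with an auxiliary
    dictionary) is discarded as ambiguous.  Mentions mapping to several
    serials of the same type are kept with all their serials.
    """
    out: list[Mention] = []
    for m in mentions:
        types = {dictionary.entity_type(s) for s in m.serials}
        if len(types) == 1:
            if m.entity_type is None:
                m = replace(m, entity_type=next(iter(types)))
            out.append(m)
    return out


def backtrack_ontology(mentions: Sequence[Mention], dictionary: Dictionary) -> list[Mention]:
    """Propagate each mention to all ontology ancestors of its serials.

    A mention of "type 1 diabetes mellitus" also counts as a mention of
    "diabetes mellitus" and of every further ancestor, at the same location.
    Duplicate (location, serial) combinations collapse, so diamond-shaped
    parent paths contribute an ancestor only once.
    """
    out: list[Mention] = []
    for m in mentions:
        closed: set[int] = set(m.serials)
        for s in m.serials:
            closed |= dictionary.ancestors(s)
        if closed != set(m.serials):
            m = replace(m, serials=tuple(sorted(closed)))
        out.append(m)
    return out
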