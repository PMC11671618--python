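"""Annotation and localization catalogs.

An :class:`AnnotationCatalog` is a bidirectional protein<->term map: it
answers "which GO terms / KEGG pathways annotate this protein" and
"which proteins belong to this term" in O(1).  Subcellular localization
uses the same structure with compartments as terms.
"""

from __future__ import annotations

from collections.abc import Iterable

PLASMA_MEMBRANE = "plasma_membrane"
NUCLEUS = "nucleus"


class AnnotationCatalog:
    """Bidirectional map between proteins and annotation terms.

    Parameters
    ----------
    associations : iterable of (protein, term)
        One association per element; duplicates are silently collapsed.
    namespace : str
        Free-text tag ("GO", "KEGG", "localization") used in messages.
    term_names : mapping term -> human-readable name, optional
        Used for keyword matching (e.g. GO terms whose *name* contains
        "autophagy"); defaults to the term identifier itself.
    """

    def __init__(self, associations: Iterable[tuple[str, str]],
                 namespace: str = "GO",
                 term_names: dict[str, str] | None = None) -> None:
        self.namespace = namespace
        self._protein_terms: dict[str, set[str]] = {}
        self._term_members: dict[str, set[str]] = {}
        self._term_names: dict[str, str] = dict(term_names or {})
        for protein, term in associations:
            protein, term = str(protein).strip(), str(term).strip()
            if not protein or not term:
                raise ValueError(f"empty field in association ({protein!r}, {term!r})")
            self._protein_terms.setdefault(protein, set()).add(term)
            self._term_members.setdefault(term, set()).add(protein)

    # -- queries ---------------------------------------------------------
    def terms_of(self, protein: str) -> frozenset[str]:
        return frozenset(self._protein_terms.get(protein, ()))

    def members_of(self, term: str) -> frozenset[str]:
        return frozenset(self._term_members.get(term, ()))

    def term_size(self, term: str) -> int:
        return len(self._term_members.get(term, ()))

    def term_name(self, term: str) -> str:
        return self._term_names.get(term, term)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self._protein_terms)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._term_members)

    def n_associations(self) -> int:
        return sum(len(v) for v in self._protein_terms.values())

    def shared_terms(self, a: str, b: str) -> frozenset[str]:
        """Terms annotating both proteins."""
        return self.terms_of(a) & self.terms_of(b)

    def associations(self) -> list[tuple[str, str]]:
        """All (protein, term) pairs, sorted for reproducible output."""
        return sorted((p, t) for p, ts in self._protein_terms.items() for t in ts)

    def __len__(self) -> int:
        return len(self._term_members)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationCatalog):
            return NotImplemented
        return self._protein_terms == other._protein_terms

    def __repr__(self) -> str:
        return (f"AnnotationCatalog({self.namespace}: {len(self._protein_terms)} proteins, "
                f"{len(self._term_members)} terms, {self.n_associations()} associations)")


LocalizationCatalog = AnnotationCatalog
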