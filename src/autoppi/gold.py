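"""Gold-standard interaction sets.

Positives are the union of curated interaction sources after
canonicalization and de-duplication.  Negatives follow the
localization-incompatibility rule: a plasma-membrane protein and a
nuclear protein are assumed not to interact, so every membrane x nucleus
cross pair not already known to interact is a negative.  Proteins
annotated to *both* compartments are excluded from the rule — a
dual-localized protein breaks the incompatibility assumption.

Because realistic negative spaces run to millions of pairs, negatives
can be consumed lazily via :func:`iter_negative_pairs`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from collections.abc import Iterable, Iterator

import numpy as np

from .catalogs import AnnotationCatalog, NUCLEUS, PLASMA_MEMBRANE
from .pairs import Pair, canonical_pair

log = logging.getLogger("autoppi")


@dataclass
class GoldStandard:
    positives: set[Pair]
    negatives: set[Pair]
    provenance: dict[Pair, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"{len(overlap)} pairs appear as both positive and negative")


def merge_positive_sources(sources: list[Iterable[tuple[str, str]]],
                           names: list[str] | None = None
                           ) -> tuple[set[Pair], dict[Pair, set[str]]]:
    """Union of canonicalized pair sources, with per-pair provenance tags."""
    names = names or [f"source_{i}" for i in range(len(sources))]
    merged: set[Pair] = set()
    provenance: dict[Pair, set[str]] = {}
    for name, source in zip(names, sources):
        n_before = len(merged)
        pairs = {canonical_pair(a, b) for a, b in source}
        for p in pairs:
            provenance.setdefault(p, set()).add(name)
        merged |= pairs
        log.info("merge_positive_sources: %s contributed %d pairs (%d new)",
                 name, len(pairs), len(merged) - n_before)
    if not merged:
        raise ValueError("all positive sources are empty")
    log.info("merge_positive_sources: %d unique positive pairs after merge", len(merged))
    return merged, provenance


def _rule_compartments(localization: AnnotationCatalog) -> tuple[list[str], list[str]]:
    membrane = localization.members_of(PLASMA_MEMBRANE)
    nucleus = localization.members_of(NUCLEUS)
    if not membrane or not nucleus:
        raise ValueError("negative rule needs non-empty plasma_membrane and nucleus "
                         f"compartments (got {len(membrane)} / {len(nucleus)})")
    dual = membrane & nucleus
    if dual:
        log.info("build_negative_pairs: excluding %d dual-localized proteins", len(dual))
    return sorted(membrane - dual), sorted(nucleus - dual)


def iter_negative_pairs(localization: AnnotationCatalog,
                        positives: set[Pair]) -> Iterator[Pair]:
    """Lazily yield canonical membrane x nucleus pairs not known to interact."""
    membrane, nucleus = _rule_compartments(localization)
    for m in membrane:
        for n in nucleus:
            if m == n:
                continue
            pair = canonical_pair(m, n)
            if pair not in positives:
                yield pair


def build_negative_pairs(localization: AnnotationCatalog,
                         positives: set[Pair]) -> set[Pair]:
    """Materialized negative set (use the iterator at genome scale)."""
    negatives = set(iter_negative_pairs(localization, positives))
    log.info("build_negative_pairs: %d negative pairs", len(negatives))
    return negatives


def subsample_balanced(gold: GoldStandard, n_pos: int, n_neg: int,
                       seed: int) -> GoldStandard:
    """Uniform sample without replacement from each class, deterministic per seed."""
    if n_pos > len(gold.positives) or n_neg > len(gold.negatives):
        raise ValueError(f"requested {n_pos} positives / {n_neg} negatives but only "
                         f"{len(gold.positives)} / {len(gold.negatives)} available")
    rng = np.random.default_rng(seed)

    def draw(pairs: set[Pair], n: int) -> set[Pair]:
        ordered = sorted(pairs)
        idx = rng.choice(len(ordered), size=n, replace=False)
        return {ordered[i] for i in idx}

    sub_pos = draw(gold.positives, n_pos)
    sub_neg = draw(gold.negatives, n_neg)
    prov = {p: tags for p, tags in gold.provenance.items() if p in sub_pos or p in sub_neg}
    return GoldStandard(positives=sub_pos, negatives=sub_neg, provenance=prov)


def select_process_proteins(catalog: AnnotationCatalog, keyword: str,
                            extra: Iterable[str] = ()) -> set[str]:
    """Proteins annotated to any term whose *name* contains ``keyword``.

    Matching is case-insensitive substring.  ``extra`` unions in an
    externally curated protein list (e.g. a disease-database export).
    """
    key = keyword.lower()
    matching = [t for t in catalog.terms if key in catalog.term_name(t).lower()]
    if not matching:
        log.warning("select_process_proteins: no term name contains %r", keyword)
    selected: set[str] = set(extra)
    for term in matching:
        selected |= catalog.members_of(term)
    return selected


def enumerate_candidates(proteins: set[str], known: set[Pair], n: int,
                         seed: int) -> list[Pair]:
    """Draw ``n`` distinct random pairs over ``proteins``, excluding ``known``.

    If fewer than ``n`` pairs exist, all available pairs are returned
    with a warning.  At large scales (over ~2 million possible pairs)
    rejection sampling replaces full enumeration.
    """
    ordered = sorted(proteins)
    m = len(ordered)
    if m < 2:
        raise ValueError("need at least 2 proteins to form candidate pairs")
    rng = np.random.default_rng(seed)
    total = m * (m - 1) // 2
    if total <= 2_000_000:
        universe = [canonical_pair(a, b) for a, b in combinations(ordered, 2)]
        available = [p for p in universe if p not in known]
        if n >= len(available):
            if n > len(available):
                log.warning("enumerate_candidates: requested %d but only %d pairs "
                            "available; returning all", n, len(available))
            return sorted(available)
        idx = rng.choice(len(available), size=n, replace=False)
        return [available[i] for i in sorted(idx)]
    # rejection sampling for very large universes
    chosen: set[Pair] = set()
    attempts = 0
    while len(chosen) < n and attempts < 50 * n:
        i, j = rng.integers(m), rng.integers(m)
        attempts += 1
        if i == j:
            continue
        pair = canonical_pair(ordered[i], ordered[j])
        if pair not in known:
            chosen.add(pair)
    if len(chosen) < n:
        log.warning("enumerate_candidates: rejection sampling stalled at %d/%d",
                    len(chosen), n)
    return sorted(chosen)
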