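"""The four genomic-evidence features and their preprocessing.

Per protein pair:

* **co_expression** — Pearson correlation of the two genes' expression
  profiles over samples where both are measured; interacting proteins
  tend to be co-expressed.
* **minimal_go** — member count of the smallest GO term annotating both
  proteins: two proteins sharing a *specific* (small) term are far more
  likely to interact than two sharing only broad terms.
* **minimal_kegg** — same construction on KEGG pathways.
* **diversity** — total number of GO annotations over the two proteins,
  a promiscuity/functional-breadth signal.

Missingness (gene absent from the matrix, no shared term) is a value,
not an error: it is informative and receives a dedicated bin during
equal-frequency discretization.  Feature informativeness is scored with
a one-way ANOVA F statistic against the class label (a filter-strategy
score with a p-value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalogs import AnnotationCatalog
from .pairs import Pair

log = logging.getLogger("autoppi")

FEATURES = ("co_expression", "minimal_go", "minimal_kegg", "diversity")
BINNED_PREFIX = "bin_"


def co_expression_evidence(pair: Pair, expression: pd.DataFrame) -> float:
    """Pearson r of the two expression rows; NaN when undefined.

    Undefined when either protein is absent, fewer than 3 samples are
    jointly observed, or either row is constant on the shared samples.
    """
    a, b = sorted(pair)  # canonical order makes the value exactly swap-invariant
    if a not in expression.index or b not in expression.index:
        return np.nan
    xa = expression.loc[a].to_numpy(dtype=float)
    xb = expression.loc[b].to_numpy(dtype=float)
    ok = ~(np.isnan(xa) | np.isnan(xb))
    if ok.sum() < 3:
        return np.nan
    xa, xb = xa[ok], xb[ok]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return np.nan
    return float(np.corrcoef(xa, xb)[0, 1])


def minimal_shared_term_size(pair: Pair, catalog: AnnotationCatalog) -> float:
    """Member count of the smallest term shared by the pair; NaN if none."""
    shared = catalog.shared_terms(*pair)
    if not shared:
        return np.nan
    return float(min(catalog.term_size(t) for t in shared))


def diversity_of_functions(pair: Pair, catalog: AnnotationCatalog) -> int:
    """|terms(a)| + |terms(b)| over the GO catalog."""
    a, b = pair
    return len(catalog.terms_of(a)) + len(catalog.terms_of(b))


def compute_feature_table(pairs, go: AnnotationCatalog, kegg: AnnotationCatalog,
                          expression: pd.DataFrame,
                          labels: dict[Pair, int] | None = None) -> pd.DataFrame:
    """Assemble the raw feature table for an iterable of canonical pairs.

    Columns: protein_a, protein_b, the four features, and — when
    ``labels`` is given — a 0/1 ``label`` column.
    """
    rows = []
    for pair in pairs:
        row = {
            "protein_a": pair[0],
            "protein_b": pair[1],
            "co_expression": co_expression_evidence(pair, expression),
            "minimal_go": minimal_shared_term_size(pair, go),
            "minimal_kegg": minimal_shared_term_size(pair, kegg),
            "diversity": float(diversity_of_functions(pair, go)),
        }
        if labels is not None:
            row["label"] = labels[pair]
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# binning
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BinningScheme:
    """Equal-frequency cut points per feature with a reserved missing bin.

    For a feature with interior cut points ``c_1 < ... < c_{B-1}`` a
    present value maps to bin ``searchsorted(cuts, x)`` in ``0..B-1``
    (monotone in the raw value); missing maps to bin ``B``.
    """

    cuts: dict[str, tuple[float, ...]]

    def n_value_bins(self, feature: str) -> int:
        return len(self.cuts[feature]) + 1

    def missing_bin(self, feature: str) -> int:
        return self.n_value_bins(feature)

    def n_categories(self, feature: str) -> int:
        """Value bins plus the missing bin."""
        return self.n_value_bins(feature) + 1

    def transform_column(self, feature: str, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        cuts = np.asarray(self.cuts[feature])
        out = np.searchsorted(cuts, values, side="left")
        out[np.isnan(values)] = self.missing_bin(feature)
        return out.astype(int)

    def transform(self, table: pd.DataFrame,
                  features: tuple[str, ...] = FEATURES) -> pd.DataFrame:
        binned = table.copy()
        for f in features:
            binned[BINNED_PREFIX + f] = self.transform_column(f, table[f].to_numpy())
        return binned


def fit_binning(table: pd.DataFrame, n_bins: int,
                features: tuple[str, ...] = FEATURES) -> BinningScheme:
    """Fit equal-frequency cut points on the non-missing training values.

    Duplicate quantiles are merged, so a feature may end with fewer
    effective bins; an all-missing or constant feature collapses to a
    single value bin (with a warning).
    """
    if table.empty:
        raise ValueError("cannot fit binning on an empty table")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    cuts: dict[str, tuple[float, ...]] = {}
    for f in features:
        values = table[f].to_numpy(dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            log.warning("fit_binning: feature %r is all-missing; only the missing "
                        "bin will be populated", f)
            cuts[f] = ()
            continue
        qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
        merged = tuple(sorted(set(float(q) for q in qs)))
        # drop cut points outside the open value range (constant features)
        merged = tuple(q for q in merged if values.min() < q <= values.max())
        if len(merged) + 1 < n_bins:
            log.warning("fit_binning: feature %r has %d effective bins (requested %d)",
                        f, len(merged) + 1, n_bins)
        cuts[f] = merged
    return BinningScheme(cuts=cuts)


# ----------------------------------------------------------------------
# feature scoring (filter strategy)
# ----------------------------------------------------------------------

def score_features(table: pd.DataFrame,
                   features: tuple[str, ...] = FEATURES) -> pd.DataFrame:
    """One-way ANOVA F score of each raw feature against the class label.

    Missing values are excluded per feature.  Returns a DataFrame with
    columns (feature, score, p_value, rank), rank 1 = most informative.
    """
    if "label" not in table.columns:
        raise ValueError("score_features needs a labeled table")
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to score features")
    rows = []
    for f in features:
        x = table[f].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        pos, neg = x[ok & (y == 1)], x[ok & (y == 0)]
        if pos.size == 0 or neg.size == 0:
            raise ValueError(f"feature {f!r} has no observed values in one class")
        stat, p = stats.f_oneway(pos, neg)
        rows.append({"feature": f, "score": float(stat), "p_value": float(p)})
    out = pd.DataFrame(rows).sort_values("score", ascending=False, ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
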