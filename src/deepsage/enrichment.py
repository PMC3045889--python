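"""Gene Score Resampling (GSR) over-representation analysis.

GSR scores each gene category by an aggregate (here: the mean) of its member
genes' scores -- by default the absolute natural-log expression ratio
|R(ln)| -- and compares it against a null distribution obtained by
repeatedly drawing random gene sets of the same size from the scored
universe.  Unlike cutoff-based over-representation tests, no hit/no-hit
threshold is imposed on individual genes.

The resampling p-value uses add-one smoothing,
p = (1 + #{null aggregates >= observed}) / (B + 1), so it is never exactly
zero and the analysis is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_B = 10_000
DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 100


@dataclass(frozen=True)
class Category:
    """A gene category: a GO term or a user-defined (custom) accession set."""

    id: str
    accessions: frozenset[str]
    is_custom: bool = False

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError(f"category {self.id!r} has no accessions")


@dataclass
class EnrichmentResult:
    """Per-category GSR outcome."""

    category_id: str
    k: int  # analyzed size (members intersected with the scored universe)
    observed_aggregate: float
    p_value: float
    B: int
    seed: int
    is_custom: bool = False


def aggregate_scores(
    tag_to_accession: Mapping[str, str],
    rln_by_tag: Mapping[str, float],
    mode: str = "max_abs",
) -> dict[str, float]:
    """Collapse per-tag R(ln) values to one non-negative score per accession.

    ``mode`` is ``max_abs`` (best |R(ln)| over an accession's tags, the
    default replicate-handling rule) or ``mean_abs``.  Tags without an
    accession, and accessions without any scored tag, are excluded.
    """
    if mode not in ("max_abs", "mean_abs"):
        raise ValueError("mode must be 'max_abs' or 'mean_abs'")
    per_acc: dict[str, list[float]] = {}
    for tag, score in rln_by_tag.items():
        acc = tag_to_accession.get(tag)
        if acc is None:
            continue
        per_acc.setdefault(acc, []).append(abs(float(score)))
    if mode == "max_abs":
        return {acc: max(v) for acc, v in per_acc.items()}
    return {acc: float(np.mean(v)) for acc, v in per_acc.items()}


def gsr(
    categories: Sequence[Category],
    scores: Mapping[str, float],
    B: int = DEFAULT_B,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> list[EnrichmentResult]:
    """Run GSR over a set of categories against a scored gene universe.

    Each category is intersected with the scored universe; categories whose
    analyzed size falls outside ``[min_size, max_size]`` are skipped.  For
    an analyzed size k, the null is ``B`` mean aggregates of k accessions
    drawn without replacement from the universe; draws are shared across
    categories of equal k, so results are deterministic given the seed and
    independent of category order.
    """
    if not scores:
        raise ValueError("the scored gene universe is empty")
    universe = sorted(scores)
    values = np.array([float(scores[a]) for a in universe])
    if (values < 0).any():
        raise ValueError("gene scores must be non-negative")

    analyzed: list[tuple[Category, int, float]] = []
    for cat in categories:
        members = sorted(set(cat.accessions) & set(universe))
        k = len(members)
        if not min_size <= k <= max_size:
            continue
        obs = float(np.mean([scores[a] for a in members]))
        analyzed.append((cat, k, obs))

    # one null per distinct k, generated in sorted-k order for determinism
    rng = np.random.default_rng(seed)
    nulls: dict[int, np.ndarray] = {}
    for k in sorted({k for _, k, _ in analyzed}):
        draws = np.empty(B)
        n = len(values)
        for b in range(B):
            draws[b] = values[rng.choice(n, size=k, replace=False)].mean()
        nulls[k] = draws

    results = []
    for cat, k, obs in analyzed:
        exceed = int((nulls[k] >= obs - 1e-12).sum())
        p = (1 + exceed) / (B + 1)
        results.append(
            EnrichmentResult(cat.id, k, obs, p, B, seed, is_custom=cat.is_custom)
        )
    return results


class CategoryRegistry:
    """Category collection with duplicate-label protection."""

    def __init__(self, categories: Iterable[Category] = ()):
        self._by_id: dict[str, Category] = {}
        for cat in categories:
            self.add(cat)

    def add(self, category: Category) -> Category:
        if category.id in self._by_id:
            raise ValueError(f"duplicate category label: {category.id!r}")
        self._by_id[category.id] = category
        return category

    def add_custom_category(self, label: str, accessions: Iterable[str]) -> Category:
        """Register a user-defined category, analyzed identically to GO terms."""
        accs = frozenset(accessions)
        if not accs:
            raise ValueError("custom category needs a non-empty accession list")
        return self.add(Category(label, accs, is_custom=True))

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, label: str) -> bool:
        return label in self._by_id


def add_custom_category(
    registry: CategoryRegistry, label: str, accessions: Iterable[str]
) -> Category:
    """Functional wrapper over :meth:`CategoryRegistry.add_custom_category`."""
    return registry.add_custom_category(label, accessions)


def load_categories(path: str | Path, is_custom: bool = False) -> CategoryRegistry:
    """Load categories from a two-column TSV (term_id, accession)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    grouped: dict[str, set[str]] = {}
    for term, acc in frame.itertuples(index=False):
        grouped.setdefault(term, set()).add(acc)
    return CategoryRegistry(
        Category(term, frozenset(accs), is_custom=is_custom)
        for term, accs in grouped.items()
    )


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        (r.category_id, r.k, r.observed_aggregate, r.p_value, r.B, r.seed, r.is_custom)
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["term", "k", "aggregate", "p", "B", "seed", "is_custom"]
    )


def goslim_top_summary(
    dge_table: pd.DataFrame,
    tag_to_accession: Mapping[str, str],
    accession_go: Mapping[str, set[str]],
    slim_mapping: Mapping[str, str],
    top_n: int = 40,
) -> pd.DataFrame:
    """GO-slim term counts among the top-N most up-regulated tags.

    Tags are ranked by fold change (descending; ties at the cutoff broken
    by UniTag id, ascending, for determinism).  Each top tag maps to its
    accession, the accession's GO terms map to slim terms, and the summary
    counts distinct accessions per slim term.  Tags without an accession
    are tallied under ``unannotated``.
    """
    order = np.lexsort(
        (dge_table.index.to_numpy(), -dge_table["fold_change"].to_numpy())
    )
    top = dge_table.iloc[order].head(top_n)

    counts: dict[str, set[str]] = {}
    unannotated = 0
    for uid in top.index:
        acc = tag_to_accession.get(uid)
        if acc is None:
            unannotated += 1
            continue
        slims = {slim_mapping[g] for g in accession_go.get(acc, set()) if g in slim_mapping}
        for s in slims:
            counts.setdefault(s, set()).add(acc)
    rows = [(term, len(accs)) for term, accs in sorted(counts.items())]
    if unannotated:
        rows.append(("unannotated", unannotated))
    return pd.DataFrame(rows, columns=["slim_term", "n_accessions"])
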