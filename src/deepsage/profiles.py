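"""Normalized expression profiles and digital differential-expression tests.

Tag counts are normalized to copies x 100,000^-1 of the library depth.
Differential expression between two libraries is quantified by the fold
change of normalized abundances, its natural logarithm R(ln), and the
Audic-Claverie exact significance test for digital expression profiles.

The Audic-Claverie test conditions on the count x observed in the first
library: under the null hypothesis of equal relative abundance, the count y
in the second library (size ratio r = N2/N1) follows

    p(y | x) = r^y (x + y)! / (x! y! (1 + r)^(x + y + 1)),

which is the negative-binomial law NB(x + 1, N1/(N1 + N2)).  Tail sums are
therefore evaluated through the regularized incomplete beta function, which
is numerically stable for counts well beyond 10^5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Set

import numpy as np
import pandas as pd
from scipy import stats

from .tags import TagCountMatrix

#: abundance class labels on the copies x 100,000^-1 scale;
#: bins are [0, 10), [10, 100], (100, 500], (500, inf)
ABUNDANCE_CLASSES = ("<10", "10-100", "100-500", ">500")

#: fold-change thresholds used for the threshold/overlap summaries
DEFAULT_FOLD_THRESHOLDS = (3.0, 8.0, 20.0)

#: |R_ln| thresholds reported by the differential table summary:
#: the e-fold (2.7-fold) cut plus the 3-, 8- and 20-fold cuts
RLN_THRESHOLDS = (1.0, math.log(3.0), math.log(8.0), math.log(20.0))


def normalize(matrix: TagCountMatrix) -> pd.DataFrame:
    """Normalize counts to copies x 100,000^-1 per library.

    Returns a float DataFrame with the same shape as ``matrix.counts``.
    Column sums equal 100,000 exactly (up to floating-point rounding).
    """
    totals = np.array([matrix.library(c).total_tags for c in matrix.counts.columns], float)
    if (totals <= 0).any():
        raise ValueError("every library must have total_tags > 0")
    return matrix.counts * (100_000.0 / totals)


def abundance_class(copies_per_100k: float) -> str:
    """Abundance class of one normalized value (closed-boundary binning)."""
    if copies_per_100k < 10:
        return ABUNDANCE_CLASSES[0]
    if copies_per_100k <= 100:
        return ABUNDANCE_CLASSES[1]
    if copies_per_100k <= 500:
        return ABUNDANCE_CLASSES[2]
    return ABUNDANCE_CLASSES[3]


def abundance_classes(profile: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Per-library abundance-class histogram over detected tags.

    Only tags with a nonzero raw count in a library contribute to that
    library's histogram.  Returns a tidy frame (library, class, n_tags,
    percent); per library the class counts sum to the number of detected
    tags and the percentages to 100.
    """
    rows = []
    for lib_id in profile.columns:
        detected = profile.loc[counts[lib_id] > 0, lib_id]
        classes = detected.map(abundance_class)
        tally = classes.value_counts().reindex(ABUNDANCE_CLASSES, fill_value=0)
        total = max(len(detected), 1)
        for cls, n in tally.items():
            rows.append((lib_id, cls, int(n), 100.0 * n / total))
    return pd.DataFrame(rows, columns=["library", "class", "n_tags", "percent"])


def fold_and_ratio(
    count_ctrl: int,
    count_trt: int,
    n_ctrl: int,
    n_trt: int,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """Fold change (treatment/control, normalized scale) and R(ln).

    The pseudocount is added to *both* counts, but only when one of them is
    zero; with both counts positive the ratio of normalized abundances is
    used as-is.  R(ln) is the natural logarithm of the fold change, so
    R(ln) > 1.0 corresponds to the e-fold (~2.7-fold) threshold.
    """
    if n_ctrl <= 0 or n_trt <= 0:
        raise ValueError("library sizes must be positive")
    if count_ctrl < 0 or count_trt < 0:
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    x, y = float(count_ctrl), float(count_trt)
    if min(x, y) == 0:
        x += pseudocount
        y += pseudocount
        if x == 0 or y == 0:
            raise ValueError("both counts zero and pseudocount zero: fold undefined")
    fold = (y / n_trt) / (x / n_ctrl)
    return fold, math.log(fold)


def audic_claverie_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts (x, y) in libraries (N1, N2).

    Conditional on x, y follows NB(x + 1, N1/(N1 + N2)) under the null of
    equal relative abundance.  The two-sided p doubles the smaller of the
    inclusive lower tail P(Y <= y | x) and the strict upper tail
    P(Y > y | x), capped at 1.  Because the swapped comparison obeys the
    exact identity P(X <= x | y; N2, N1) = P(Y > y | x; N1, N2), this
    convention makes the p-value symmetric under exchanging the two
    libraries, (x, N1) <-> (y, N2).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p)
    upper = stats.nbinom.sf(y, x + 1, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def audic_claverie_pvalues(
    x: np.ndarray, y: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Vectorized :func:`audic_claverie_pvalue` over count arrays."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p)
    upper = stats.nbinom.sf(y, x + 1, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def _direction(fold: float) -> str:
    if fold > 1.0:
        return "up"
    if fold < 1.0:
        return "down"
    return "flat"


def differential_table(
    matrix: TagCountMatrix,
    control: str,
    treatment: str,
    pseudocount: float = 1.0,
    profile: pd.DataFrame | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-UniTag differential-expression table for one library pair.

    One row per UniTag with a nonzero count in at least one of the two
    libraries: raw counts, copies x 100,000^-1, fold change
    (treatment/control), R(ln), the Audic-Claverie two-sided p-value and the
    regulation direction.  ``table.attrs["summary"]`` holds the number of
    tags with |R(ln)| >= each of the 1.0 / ln3 / ln8 / ln20 thresholds.

    With ``bh_correction`` a Benjamini-Hochberg adjusted column ``p_bh`` is
    appended; raw p-values are always reported.
    """
    if control == treatment:
        raise ValueError("control and treatment must be different libraries")
    n_ctrl = matrix.library(control).total_tags
    n_trt = matrix.library(treatment).total_tags
    if profile is None:
        profile = normalize(matrix)

    counts = matrix.counts
    mask = (counts[control] > 0) | (counts[treatment] > 0)
    sub = counts.loc[mask]
    x = sub[control].to_numpy()
    y = sub[treatment].to_numpy()

    folds = np.empty(len(sub))
    rlns = np.empty(len(sub))
    for i, (xi, yi) in enumerate(zip(x, y)):
        folds[i], rlns[i] = fold_and_ratio(xi, yi, n_ctrl, n_trt, pseudocount)
    pvals = audic_claverie_pvalues(x, y, n_ctrl, n_trt)

    table = pd.DataFrame(
        {
            "unitag_id": sub.index,
            "sequence": matrix.sequences.loc[sub.index].to_numpy(),
            f"count_{control}": x,
            f"count_{treatment}": y,
            f"cp100k_{control}": profile.loc[sub.index, control].to_numpy(),
            f"cp100k_{treatment}": profile.loc[sub.index, treatment].to_numpy(),
            "fold_change": folds,
            "R_ln": rlns,
            "p_value": pvals,
            "direction": [_direction(f) for f in folds],
        }
    ).set_index("unitag_id")
    if bh_correction:
        table["p_bh"] = _benjamini_hochberg(pvals)
    table.attrs["summary"] = {
        round(t, 6): int((np.abs(rlns) >= t).sum()) for t in RLN_THRESHOLDS
    }
    table.attrs["libraries"] = (control, treatment)
    return table


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def regulated_set(
    table: pd.DataFrame, fold_threshold: float, direction: str = "up"
) -> set[str]:
    """UniTags at least ``fold_threshold``-fold regulated in one direction.

    ``direction`` is ``"up"`` (fold >= threshold) or ``"down"``
    (fold <= 1/threshold); the comparison is >= on the linear fold value.
    """
    if direction == "up":
        mask = table["fold_change"] >= fold_threshold
    elif direction == "down":
        mask = table["fold_change"] <= 1.0 / fold_threshold
    else:
        raise ValueError("direction must be 'up' or 'down'")
    return set(table.index[mask])


@dataclass
class OverlapReport:
    """Venn decomposition of 2-3 named UniTag sets at one fold threshold."""

    fold_threshold: float
    set_names: tuple[str, ...]
    regions: dict[tuple[str, ...], int]

    def union_size(self) -> int:
        return sum(self.regions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("&".join(k), v) for k, v in self.regions.items()]
        return pd.DataFrame(rows, columns=["region", "n_unitags"])


def venn_overlap(
    named_sets: Mapping[str, Set[str]], fold_threshold: float = 3.0
) -> OverlapReport:
    """Exclusive-region counts of the Venn decomposition of 2-3 tag sets."""
    if not named_sets:
        raise ValueError("at least one named set is required")
    names = tuple(named_sets)
    universe = set().union(*named_sets.values())
    regions: dict[tuple[str, ...], int] = {}
    from itertools import combinations

    for k in range(len(names), 0, -1):
        for combo in combinations(names, k):
            exact = set.intersection(*(set(named_sets[n]) for n in combo))
            for other in names:
                if other not in combo:
                    exact -= set(named_sets[other])
            regions[combo] = len(exact)
    assert sum(regions.values()) == len(universe)
    return OverlapReport(fold_threshold, names, regions)
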