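"""SNP-associated alternative tag (SAAT) families.

Tags that differ from another UniTag by one or a few substitutions are
interpreted as transcript isoforms or allelic variants of the same locus.
Because SuperSAGE tags are fixed-length and anchor-aligned, similarity is
measured as ungapped positional identity (26 minus the Hamming distance);
two tags are "similar" when they agree on at least 23 of 26 positions
(homology over more than 22 bp), and families are the single-linkage
connected components of that relation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tags import ANCHOR, TAG_LENGTH, validate_tag

DEFAULT_IDENTITY_THRESHOLD = 23


def tag_identity(a: str, b: str) -> int:
    """Number of identical positions between two 26 bp tags (0-26)."""
    validate_tag(a)
    validate_tag(b)
    return sum(1 for ca, cb in zip(a, b) if ca == cb)


@dataclass
class SAATFamily:
    """One family of near-identical UniTags.

    ``snp_positions`` are the 1-based tag positions (necessarily in 5-26,
    the anchor being invariant) where some member differs from the
    representative.  ``similar_hit_counts`` gives, per member, the number of
    other members within the similarity threshold of that member.
    """

    family_id: str
    members: list[str]
    representative: str
    snp_positions: list[int] = field(default_factory=list)
    similar_hit_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def find(self, a: str) -> str:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _similar_index_pairs(
    sequences: list[str], threshold: int
) -> set[tuple[int, int]]:
    """Index pairs of tags with >= ``threshold`` identical positions.

    Uses pigeonhole blocking over the 22 variable positions (the anchor is
    shared by every tag, so mismatches only occur there): with at most
    ``26 - threshold`` mismatches, partitioning the variable region into
    ``26 - threshold + 1`` blocks guarantees similar tags share one exact
    block.  Identities within a bucket are evaluated with a vectorized
    base-by-base comparison.  Falls back to one all-vs-all bucket for
    permissive thresholds where blocks would be too short to discriminate.
    """
    n = len(sequences)
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    arr = arr.reshape(n, TAG_LENGTH)
    max_mismatch = TAG_LENGTH - threshold
    n_blocks = max_mismatch + 1
    variable = TAG_LENGTH - len(ANCHOR)
    pairs: set[tuple[int, int]] = set()

    if n_blocks >= variable // 2:
        buckets: Iterable[list[int]] = [list(range(n))]
    else:
        bounds = [
            len(ANCHOR) + round(k * variable / n_blocks) for k in range(n_blocks + 1)
        ]
        grouped: dict[tuple[int, str], list[int]] = defaultdict(list)
        for i, seq in enumerate(sequences):
            for k in range(n_blocks):
                grouped[(k, seq[bounds[k]:bounds[k + 1]])].append(i)
        buckets = (b for b in grouped.values() if len(b) > 1)

    chunk = 512
    for bucket in buckets:
        idx = np.array(bucket)
        sub = arr[idx]
        for lo in range(0, len(idx), chunk):
            hi = min(lo + chunk, len(idx))
            ident = (sub[lo:hi, None, :] == sub[None, :, :]).sum(axis=2)
            rows, cols = np.nonzero(ident >= threshold)
            for r, c in zip(rows, cols):
                r_glob = lo + r
                if r_glob < c:
                    a, b = int(idx[r_glob]), int(idx[c])
                    pairs.add((a, b) if a < b else (b, a))
    return pairs


def build_families(
    tags: Mapping[str, str],
    threshold_identity: int = DEFAULT_IDENTITY_THRESHOLD,
    abundance: Mapping[str, float] | None = None,
    extra_links: Iterable[tuple[str, str]] = (),
) -> list[SAATFamily]:
    """Cluster UniTags into SAAT families by single linkage.

    Parameters
    ----------
    tags : mapping of UniTag id -> 26 bp sequence (unique ids).
    threshold_identity : minimum identical positions for a similarity link.
    abundance : optional UniTag id -> summed copies x 100,000^-1, used to
        pick each family's representative (ties broken by lexicographically
        smallest sequence).  Without it the tie-break alone decides.
    extra_links : additional similarity links (e.g. from imported aligner
        hits) merged into the built-in metric's links.

    Returns one :class:`SAATFamily` per connected component (singletons
    included), ordered and labelled deterministically by each family's
    smallest member id, so the partition does not depend on input order.
    """
    if not 1 <= threshold_identity <= TAG_LENGTH:
        raise ValueError("threshold must be in [1, 26]")
    seqs = dict(tags)
    for uid, seq in seqs.items():
        validate_tag(seq)

    uf = _UnionFind(seqs)
    hit_counts = {uid: 0 for uid in seqs}
    linked: set[tuple[str, str]] = set()
    ids = list(seqs)
    for i, j in _similar_index_pairs([seqs[u] for u in ids], threshold_identity):
        a, b = ids[i], ids[j]
        uf.union(a, b)
        linked.add((a, b) if a <= b else (b, a))
    for a, b in extra_links:
        if a in seqs and b in seqs and a != b:
            uf.union(a, b)
            linked.add((a, b) if a <= b else (b, a))
    for a, b in linked:
        hit_counts[a] += 1
        hit_counts[b] += 1

    components: dict[str, list[str]] = defaultdict(list)
    for uid in seqs:
        components[uf.find(uid)].append(uid)

    families = []
    # deterministic order: by smallest member id within each component
    for members in sorted(components.values(), key=lambda m: min(m)):
        members = sorted(members)
        rep = _pick_representative(members, seqs, abundance)
        snps = sorted(
            {
                i + 1
                for uid in members
                for i, (cm, cr) in enumerate(zip(seqs[uid], seqs[rep]))
                if cm != cr
            }
        )
        families.append(
            SAATFamily(
                family_id="",
                members=members,
                representative=rep,
                snp_positions=snps,
                similar_hit_counts={u: hit_counts[u] for u in members},
            )
        )
    for i, fam in enumerate(families, start=1):
        fam.family_id = f"SAAT-{i}"
    return families


def _pick_representative(
    members: list[str], seqs: Mapping[str, str], abundance: Mapping[str, float] | None
) -> str:
    if abundance is None:
        return min(members, key=lambda u: seqs[u])
    best = max(abundance.get(u, 0.0) for u in members)
    top = [u for u in members if abundance.get(u, 0.0) == best]
    return min(top, key=lambda u: seqs[u])


def similar_hit_histogram(families: list[SAATFamily]) -> pd.DataFrame:
    """Per-tag similar-hit histogram over the classes 0, 1, 2, >=3.

    Reproduces the semantics of a library self-comparison summary: the
    fraction of UniTags with no similar hit, one, two, or three and more.
    """
    counts = {"0": 0, "1": 0, "2": 0, ">=3": 0}
    total = 0
    for fam in families:
        for n in fam.similar_hit_counts.values():
            total += 1
            key = str(n) if n < 3 else ">=3"
            counts[key] += 1
    rows = [
        (cls, n, 100.0 * n / total if total else 0.0) for cls, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["similar_hits", "n_unitags", "percent"])


def family_profile(
    family: SAATFamily,
    profile: pd.DataFrame,
    dge_direction: Mapping[str, str] | None = None,
) -> dict:
    """Within-family expression summary.

    Returns per-member summed copies x 100,000^-1 across libraries, the
    representative's share of the family total, and (when per-tag DGE
    directions are supplied) whether member directions are discordant.
    """
    missing = [m for m in family.members if m not in profile.index]
    if missing:
        raise KeyError(f"family members absent from profile: {missing}")
    sums = {m: float(profile.loc[m].sum()) for m in family.members}
    total = sum(sums.values())
    rep_share = sums[family.representative] / total if total > 0 else 1.0 / len(family)
    summary = {
        "family_id": family.family_id,
        "member_sums": sums,
        "family_sum": total,
        "representative": family.representative,
        "representative_share": rep_share,
    }
    if dge_direction is not None:
        directions = {
            m: dge_direction[m] for m in family.members if m in dge_direction
        }
        active = {d for d in directions.values() if d != "flat"}
        summary["directions"] = directions
        summary["discordant"] = len(active) > 1
    return summary


def import_similarity_pairs(
    path: str | Path,
    min_matched_bases: float = DEFAULT_IDENTITY_THRESHOLD,
    max_errors: int = 10,
) -> set[tuple[str, str]]:
    """Read pairwise similarity links from a BLAST tabular (outfmt 6) file.

    A row's link is accepted when ``alignment_length * pct_identity / 100``
    reaches ``min_matched_bases`` equivalent matched bases.  Self-hits are
    discarded and links are symmetrized (stored with the ids sorted).
    Malformed rows raise after more than ``max_errors`` row-level errors.
    """
    links: set[tuple[str, str]] = set()
    errors: list[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                query, subject = fields[0], fields[1]
                pct_identity = float(fields[2])
                aln_length = int(fields[3])
            except (IndexError, ValueError) as exc:
                errors.append(f"line {lineno}: {exc}")
                if len(errors) > max_errors:
                    raise ValueError(
                        "too many malformed rows: " + "; ".join(errors)
                    ) from exc
                continue
            if query == subject:
                continue
            if aln_length * pct_identity / 100.0 >= min_matched_bases:
                links.add((query, subject) if query <= subject else (subject, query))
    return links


def families_to_frame(families: list[SAATFamily]) -> pd.DataFrame:
    """Flat table (family_id, unitag_id, is_representative, snp_positions)."""
    rows = []
    for fam in families:
        for m in fam.members:
            rows.append(
                (
                    fam.family_id,
                    m,
                    m == fam.representative,
                    ";".join(map(str, fam.snp_positions)),
                )
            )
    return pd.DataFrame(
        rows, columns=["family_id", "unitag_id", "is_representative", "snp_positions"]
    )
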