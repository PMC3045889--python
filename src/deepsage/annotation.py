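"""EST-bridged annotation of UniTags.

A 26 bp tag carries too little sequence to be annotated directly, so
function is transferred in two steps: (1) locate the tag on an EST from the
same species (anchored substring match on either strand), then (2) annotate
the EST against protein databases in taxonomic priority order
(chickpea/Fabaceae first, then Arabidopsis, then rice/maize), and let the
tag inherit the EST's best-tier record and GO terms.

The built-in tag-to-EST matcher is an anchored <=1-mismatch 26-mer scan;
matches are retained at >= 25/26 identical bases, a surrogate for the
original alignment e-value gate.  Pre-computed aligner hits in BLAST
tabular layout can be imported instead, in which case their printed
e-values gate retention directly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tags import ANCHOR, TAG_LENGTH, reverse_complement, validate_tag

#: retention gate of the built-in matcher: matched bases out of 26
RETENTION_MIN_MATCHED = 25
#: e-value gate for tier annotation tables
TIER_EVALUE_GATE = 1e-50
#: e-value gate for imported tag-to-EST hits
IMPORT_EVALUE_GATE = 1e-5

TIER_ORDER = ("Cicer/Fabaceae", "Arabidopsis", "rice/maize")

MULTIPLICITY_CLASSES = ("1", "2", "3", "4", "5", ">5")


@dataclass(frozen=True)
class ESTMatch:
    """One occurrence of a tag on an EST."""

    unitag_id: str
    est_id: str
    matched_bases: int
    offset: int  # 0-based start on the EST forward strand
    strand: str  # "+" or "-"


@dataclass
class AnnotationRecord:
    """Tiered protein annotation inherited by a UniTag from an EST."""

    unitag_id: str
    est_id: str
    protein_accession: str
    protein_name: str
    source_tier: str
    evalue: float
    go_terms: set[str] = field(default_factory=set)


@dataclass
class TierEntry:
    """One EST's hit inside a single-tier annotation table."""

    protein_accession: str
    protein_name: str
    evalue: float
    is_anonymous: bool = False
    is_weak_similarity: bool = False


def _half_index(tags: Mapping[str, str]) -> tuple[dict, dict, int]:
    half = TAG_LENGTH // 2
    first: dict[str, list[str]] = defaultdict(list)
    second: dict[str, list[str]] = defaultdict(list)
    for uid, seq in tags.items():
        validate_tag(seq)
        first[seq[:half]].append(uid)
        second[seq[half:]].append(uid)
    return first, second, half


def _scan_strand(
    seq: str,
    tags: Mapping[str, str],
    first: dict,
    second: dict,
    half: int,
    max_mismatches: int,
) -> Iterable[tuple[str, int, int]]:
    """Yield (unitag_id, offset_on_this_strand, mismatches).

    With <=1 mismatch allowed, one of the two tag halves must match the
    window exactly, so only tags indexed under either half of each window
    are verified base-by-base.  Mismatches inside the CATG anchor disqualify
    the occurrence.
    """
    n = len(seq)
    for i in range(n - TAG_LENGTH + 1):
        window = seq[i : i + TAG_LENGTH]
        candidates = set(first.get(window[:half], ()))
        candidates.update(second.get(window[half:], ()))
        for uid in candidates:
            tag = tags[uid]
            mism = [j for j in range(TAG_LENGTH) if tag[j] != window[j]]
            if len(mism) > max_mismatches:
                continue
            if any(j < len(ANCHOR) for j in mism):
                continue
            yield uid, i, len(mism)


def match_tags_to_ests(
    tags: Mapping[str, str],
    ests: Mapping[str, str],
    max_mismatches: int = 1,
) -> list[ESTMatch]:
    """Locate every tag occurrence on either strand of every EST.

    At most ``max_mismatches`` substitutions are tolerated (never inside the
    CATG anchor); ``matched_bases = 26 - mismatches``.  Minus-strand hits
    report the forward-strand 0-based offset of the occurrence.  ESTs
    shorter than 26 bases are skipped.  Only values 0 and 1 of
    ``max_mismatches`` are supported by the half-index scan.
    """
    if max_mismatches not in (0, 1):
        raise ValueError("the anchored scan supports at most 1 mismatch")
    first, second, half = _half_index(tags)
    matches: list[ESTMatch] = []
    for est_id, seq in ests.items():
        seq = seq.upper()
        if len(seq) < TAG_LENGTH:
            continue
        for uid, off, mism in _scan_strand(seq, tags, first, second, half, max_mismatches):
            matches.append(ESTMatch(uid, est_id, TAG_LENGTH - mism, off, "+"))
        rc = reverse_complement(seq)
        for uid, off, mism in _scan_strand(rc, tags, first, second, half, max_mismatches):
            fwd_off = len(seq) - off - TAG_LENGTH
            matches.append(ESTMatch(uid, est_id, TAG_LENGTH - mism, fwd_off, "-"))
    return matches


def match_tag_to_ests(
    tag: str, ests: Mapping[str, str], max_mismatches: int = 1
) -> list[ESTMatch]:
    """Single-tag convenience wrapper around :func:`match_tags_to_ests`."""
    return match_tags_to_ests({"tag": tag}, ests, max_mismatches)


def retain_matches(
    matches: Iterable[ESTMatch], min_matched_bases: int = RETENTION_MIN_MATCHED
) -> list[ESTMatch]:
    """Keep matches at or above the identity gate (default 25/26 bases)."""
    return [m for m in matches if m.matched_bases >= min_matched_bases]


def import_est_hits(
    path: str | Path, evalue_gate: float = IMPORT_EVALUE_GATE
) -> list[ESTMatch]:
    """Read tag-to-EST hits from a BLAST tabular (outfmt 6) file.

    Rows are retained when their printed e-value is below ``evalue_gate``.
    Columns used: query (UniTag id), subject (EST id), pct identity,
    alignment length, subject start, e-value (column 11).
    """
    matches: list[ESTMatch] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) == 1:
                f = line.split()
            uid, est_id = f[0], f[1]
            matched = round(int(f[3]) * float(f[2]) / 100.0)
            sstart, send = int(f[8]), int(f[9])
            strand = "+" if send >= sstart else "-"
            evalue = float(f[10])
            if evalue < evalue_gate:
                offset = min(sstart, send) - 1
                matches.append(ESTMatch(uid, est_id, matched, offset, strand))
    return matches


def load_tier_table(path: str | Path) -> dict[str, TierEntry]:
    """Load one tier's EST annotation table from TSV.

    Expected columns: est_id, protein_accession, protein_name, evalue,
    is_anonymous, is_weak_similarity (booleans as 0/1 or true/false).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    table: dict[str, TierEntry] = {}
    for row in frame.itertuples(index=False):
        table[row.est_id] = TierEntry(
            protein_accession=row.protein_accession,
            protein_name=row.protein_name,
            evalue=float(row.evalue),
            is_anonymous=str(row.is_anonymous).lower() in ("1", "true", "yes"),
            is_weak_similarity=str(row.is_weak_similarity).lower() in ("1", "true", "yes"),
        )
    return table


def transfer_annotation(
    matches: Iterable[ESTMatch],
    tier_tables: Sequence[tuple[str, Mapping[str, TierEntry]]],
    evalue_gate: float = TIER_EVALUE_GATE,
) -> tuple[list[AnnotationRecord], list[str]]:
    """Transfer tiered protein annotation from matched ESTs to their tags.

    ``tier_tables`` is a priority-ordered sequence of (tier name, table).
    For each retained (tag, EST) pair, the first tier whose entry passes --
    not anonymous, not weak-similarity, evalue <= gate -- supplies the
    record; priority beats e-value magnitude.  ESTs passing no tier are
    reported as anonymous (candidate novel transcripts).

    Returns ``(records, anonymous_est_ids)``.
    """
    records: list[AnnotationRecord] = []
    anonymous: set[str] = set()
    for match in matches:
        chosen: AnnotationRecord | None = None
        for tier_name, table in tier_tables:
            entry = table.get(match.est_id)
            if entry is None or entry.is_anonymous or entry.is_weak_similarity:
                continue
            if entry.evalue > evalue_gate:
                continue
            chosen = AnnotationRecord(
                unitag_id=match.unitag_id,
                est_id=match.est_id,
                protein_accession=entry.protein_accession,
                protein_name=entry.protein_name,
                source_tier=tier_name,
                evalue=entry.evalue,
            )
            break
        if chosen is None:
            anonymous.add(match.est_id)
        else:
            records.append(chosen)
    return records, sorted(anonymous)


def load_go_mapping(path: str | Path) -> dict[str, set[str]]:
    """Load an accession -> GO ids mapping from a two-column TSV."""
    mapping: dict[str, set[str]] = defaultdict(set)
    frame = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    for acc, go in frame.itertuples(index=False):
        mapping[acc].add(go)
    return dict(mapping)


def link_go(
    records: Iterable[AnnotationRecord], mapping: Mapping[str, set[str]]
) -> list[AnnotationRecord]:
    """Attach GO terms (deduplicated set) to each record's accession."""
    out = []
    for rec in records:
        rec.go_terms = set(mapping.get(rec.protein_accession, set()))
        out.append(rec)
    return out


def multiplicity_report(matches: Iterable[ESTMatch]) -> pd.DataFrame:
    """UniTags-per-EST multiplicity histogram.

    Counts, per matched EST, the number of distinct UniTags targeting it,
    and bins ESTs into the classes 1, 2, 3, 4, 5, >5 with percentages of
    all matched ESTs.  ``frame.attrs["per_est"]`` maps est_id to its
    multiplicity.
    """
    per_est: dict[str, set[str]] = defaultdict(set)
    for m in matches:
        per_est[m.est_id].add(m.unitag_id)
    mult = {est: len(tags) for est, tags in per_est.items()}
    tally = {cls: 0 for cls in MULTIPLICITY_CLASSES}
    for n in mult.values():
        tally[str(n) if n <= 5 else ">5"] += 1
    total = max(len(mult), 1)
    frame = pd.DataFrame(
        [(cls, n, 100.0 * n / total) for cls, n in tally.items()],
        columns=["n_unitags_per_est", "n_ests", "percent"],
    )
    frame.attrs["per_est"] = mult
    return frame


def multiplicity_vs_copies(
    matches: Iterable[ESTMatch], tag_copy_sums: Mapping[str, float]
) -> pd.DataFrame:
    """Per-EST table of targeting-UniTag count vs summed tag copies.

    Backs the correlation between how many UniTags target an EST and the
    cumulative normalized copies of those tags.
    """
    per_est: dict[str, set[str]] = defaultdict(set)
    for m in matches:
        per_est[m.est_id].add(m.unitag_id)
    rows = [
        (est, len(tags), sum(tag_copy_sums.get(t, 0.0) for t in tags))
        for est, tags in sorted(per_est.items())
    ]
    return pd.DataFrame(rows, columns=["est_id", "n_unitags", "summed_copies"])
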