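"""Ditag parsing, 26 bp tag extraction and tag counting.

SuperSAGE tags are 26 bp fragments anchored at the 3'-most NlaIII site of a
transcript: the first four bases are always the NlaIII recognition sequence
``CATG``, the remaining 22 bases are transcript-specific (released by
EcoP15I).  The sequenced unit is a *ditag*: two tags ligated tail-to-tail,
so a read carries one tag in sense orientation at its 5' end and the reverse
complement of a second tag at its 3' end.  Because ``CATG`` is its own
reverse complement, a well-formed ditag read both starts and ends with
``CATG``.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

TAG_LENGTH = 26
ANCHOR = "CATG"
#: accepted ditag read lengths (EcoP15I cut-length variation around 2x26)
MIN_DITAG_LENGTH = 50
MAX_DITAG_LENGTH = 54

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_IUPAC_DNA = set("ACGTRYSWKMBDHVN")
_STRICT_DNA = set("ACGT")

#: tag id prefix; ids are assigned sequentially in first-seen order
UNITAG_PREFIX = "STCa-"


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_valid_tag(seq: str) -> bool:
    """True iff *seq* is a well-formed 26 bp anchored tag.

    A valid tag is exactly 26 uppercase ``ACGT`` characters and starts with
    the ``CATG`` anchor.
    """
    return (
        len(seq) == TAG_LENGTH
        and seq.startswith(ANCHOR)
        and set(seq) <= _STRICT_DNA
    )


def validate_tag(seq: str) -> str:
    """Return *seq* if it is a valid tag, else raise ``ValueError``."""
    if not is_valid_tag(seq):
        raise ValueError(f"not a valid 26 bp CATG-anchored tag: {seq!r}")
    return seq


@dataclass(frozen=True)
class Library:
    """One SuperSAGE library: an organ under a condition.

    ``total_tags`` is the number of accepted tag observations attributed to
    the library and plays the role of the library size N in the digital
    expression statistic.
    """

    id: str
    organ: str
    condition: str
    total_tags: int = 0

    ORGANS = ("root", "nodule")
    CONDITIONS = ("control", "NaCl")

    def __post_init__(self) -> None:
        if self.total_tags < 0:
            raise ValueError("total_tags must be non-negative")


@dataclass
class ExtractionReport:
    """Per-run tally of accepted reads and rejection reasons."""

    reads_seen: int = 0
    reads_accepted: int = 0
    reads_rejected_by_reason: Counter = field(default_factory=Counter)
    #: tags lost from otherwise-accepted reads (e.g. one anchor missing)
    tags_rejected_by_reason: Counter = field(default_factory=Counter)
    rejected_read_ids: dict = field(default_factory=dict)

    REASONS = ("no_start_anchor", "no_end_anchor", "bad_length", "ambiguous_base")

    def record(self, reason: str, read_id: str | None = None) -> None:
        self.reads_rejected_by_reason[reason] += 1
        if read_id is not None:
            self.rejected_read_ids.setdefault(reason, []).append(read_id)

    @property
    def reads_rejected(self) -> int:
        return sum(self.reads_rejected_by_reason.values())

    def check(self) -> None:
        if self.reads_seen != self.reads_accepted + self.reads_rejected:
            raise AssertionError("report counters out of balance")

    def to_frame(self) -> pd.DataFrame:
        rows = [("reads_seen", self.reads_seen), ("reads_accepted", self.reads_accepted)]
        rows += [(f"rejected_{r}", self.reads_rejected_by_reason.get(r, 0)) for r in self.REASONS]
        return pd.DataFrame(rows, columns=["counter", "value"])


def extract_ditag_tags(read: str) -> tuple[list[str], list[str]]:
    """Extract up to two 26 bp tags from one ditag read.

    Tag 1 is the first 26 bases read in sense orientation; tag 2 is the
    reverse complement of the last 26 bases (so the read must *end* with
    ``CATG`` for tag 2 to carry its anchor).

    Returns ``(tags, reasons)`` where ``tags`` holds 0-2 accepted tag
    sequences and ``reasons`` the per-tag/per-read rejection reasons
    (``no_start_anchor``, ``no_end_anchor``, ``bad_length``,
    ``ambiguous_base``).  Reads outside 50-54 bp, or containing non-IUPAC
    characters, are rejected wholesale.
    """
    read = read.upper()
    if not set(read) <= _IUPAC_DNA:
        return [], ["ambiguous_base"]
    if not (MIN_DITAG_LENGTH <= len(read) <= MAX_DITAG_LENGTH):
        return [], ["bad_length"]

    tags: list[str] = []
    reasons: list[str] = []

    tag1 = read[:TAG_LENGTH]
    if not tag1.startswith(ANCHOR):
        reasons.append("no_start_anchor")
    elif not set(tag1) <= _STRICT_DNA:
        reasons.append("ambiguous_base")
    else:
        tags.append(tag1)

    tag2 = reverse_complement(read[-TAG_LENGTH:])
    if not tag2.startswith(ANCHOR):  # i.e. the read does not end with CATG
        reasons.append("no_end_anchor")
    elif not set(tag2) <= _STRICT_DNA:
        reasons.append("ambiguous_base")
    else:
        tags.append(tag2)

    return tags, reasons


@dataclass
class TagCountMatrix:
    """UniTag x library count matrix with library metadata.

    ``counts`` is an integer DataFrame indexed by UniTag id with one column
    per library id; ``sequences`` maps UniTag id to the 26-mer.  Library
    ``total_tags`` always equals the library's column sum.
    """

    counts: pd.DataFrame
    sequences: pd.Series
    libraries: list[Library]

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != [lib.id for lib in self.libraries]:
            raise ValueError("count columns must match declared libraries")
        if not self.counts.index.equals(self.sequences.index):
            raise ValueError("counts and sequences must share an index")
        if self.counts.index.has_duplicates:
            raise ValueError("UniTag ids must be unique")
        self._sync_totals()

    def _sync_totals(self) -> None:
        sums = self.counts.sum(axis=0)
        self.libraries = [
            Library(lib.id, lib.organ, lib.condition, int(sums[lib.id]))
            for lib in self.libraries
        ]

    # -- convenience -------------------------------------------------------
    @property
    def library_ids(self) -> list[str]:
        return [lib.id for lib in self.libraries]

    def library(self, lib_id: str) -> Library:
        for lib in self.libraries:
            if lib.id == lib_id:
                return lib
        raise KeyError(f"unknown library: {lib_id!r}")

    def organ_columns(self, organ: str) -> list[str]:
        return [lib.id for lib in self.libraries if lib.organ == organ]

    @property
    def organs(self) -> list[str]:
        seen: dict[str, None] = {}
        for lib in self.libraries:
            seen.setdefault(lib.organ, None)
        return list(seen)

    def n_tags(self) -> int:
        return len(self.counts)

    def copy(self) -> "TagCountMatrix":
        return TagCountMatrix(self.counts.copy(), self.sequences.copy(), list(self.libraries))


def count_tags(
    observations: Iterable[tuple[str, str]],
    libraries: Sequence[Library],
    report: ExtractionReport | None = None,
) -> TagCountMatrix:
    """Group a stream of ``(library_id, tag)`` observations into a matrix.

    Libraries must be declared up front; an observation naming an unknown
    library is a hard error.  UniTag ids (``STCa-1``, ``STCa-2``, ...) are
    assigned in first-seen order of the tag sequence.
    """
    lib_ids = [lib.id for lib in libraries]
    lib_index = {lib_id: j for j, lib_id in enumerate(lib_ids)}
    if len(lib_index) != len(lib_ids):
        raise ValueError("duplicate library ids")

    tag_index: dict[str, int] = {}
    rows: list[list[int]] = []
    for lib_id, tag in observations:
        if lib_id not in lib_index:
            raise KeyError(f"observation for undeclared library {lib_id!r}")
        validate_tag(tag)
        i = tag_index.setdefault(tag, len(tag_index))
        if i == len(rows):
            rows.append([0] * len(lib_ids))
        rows[i][lib_index[lib_id]] += 1

    ids = [f"{UNITAG_PREFIX}{i + 1}" for i in range(len(tag_index))]
    counts = pd.DataFrame(rows, index=ids, columns=lib_ids, dtype=np.int64)
    sequences = pd.Series(list(tag_index), index=ids, name="sequence")
    matrix = TagCountMatrix(counts, sequences, list(libraries))
    if report is not None:
        report.check()
    return matrix


def filter_singletons(matrix: TagCountMatrix) -> tuple[TagCountMatrix, pd.DataFrame]:
    """Drop organ-wise singleton UniTags.

    A tag whose summed count across all libraries of one organ equals 1 is
    excluded from that organ (its counts there are zeroed); tags with no
    counts left anywhere are removed.  Returns the filtered matrix and a
    report of the removals (unitag_id, organ).
    """
    counts = matrix.counts.copy()
    removed: list[tuple[str, str]] = []
    for organ in matrix.organs:
        cols = matrix.organ_columns(organ)
        organ_sum = counts[cols].sum(axis=1)
        singles = organ_sum[organ_sum == 1].index
        counts.loc[singles, cols] = 0
        removed += [(uid, organ) for uid in singles]
    keep = counts.sum(axis=1) > 0
    out = TagCountMatrix(counts.loc[keep], matrix.sequences.loc[keep], list(matrix.libraries))
    report = pd.DataFrame(removed, columns=["unitag_id", "organ"])
    return out, report


def is_low_complexity(
    seq: str,
    max_base_fraction: float = 0.8,
    min_repeat_span: int = 18,
) -> str | None:
    """Classify a tag as low-complexity, returning the triggering rule.

    Operates on the 22 variable positions (5-26); the CATG anchor is shared
    by every tag and carries no information.  Two rules:

    * ``mononucleotide``: one base occupies >= ``max_base_fraction`` of the
      variable positions;
    * ``tandem_repeat``: a 1-2 nt motif tandem-repeats across >=
      ``min_repeat_span`` consecutive variable positions.

    Returns ``None`` for complex tags.
    """
    body = seq[len(ANCHOR):]
    n = len(body)
    if max(Counter(body).values()) >= max_base_fraction * n:
        return "mononucleotide"
    for period in (1, 2):
        run = period
        best = period
        for i in range(period, n):
            run = run + 1 if body[i] == body[i - period] else period
            best = max(best, run)
        if best >= min_repeat_span:
            return "tandem_repeat"
    return None


def filter_low_complexity(
    matrix: TagCountMatrix,
    max_base_fraction: float = 0.8,
    min_repeat_span: int = 18,
) -> tuple[TagCountMatrix, pd.DataFrame]:
    """Remove low-complexity UniTags; report each removal with its rule."""
    removed = []
    for uid, seq in matrix.sequences.items():
        rule = is_low_complexity(seq, max_base_fraction, min_repeat_span)
        if rule is not None:
            removed.append((uid, seq, rule))
    removed_frame = pd.DataFrame(removed, columns=["unitag_id", "sequence", "rule"])
    keep = ~matrix.counts.index.isin(removed_frame["unitag_id"])
    out = TagCountMatrix(
        matrix.counts.loc[keep], matrix.sequences.loc[keep], list(matrix.libraries)
    )
    return out, removed_frame


# -- read-level driver -----------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def iter_reads(path: str | Path, fmt: str | None = None) -> Iterator[tuple[str, str]]:
    """Yield ``(record_id, sequence)`` from a FASTA/FASTQ file (plain or gzip)."""
    fmt = fmt or _sniff_format(path)
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, fmt):
            yield record.id, str(record.seq).upper()


def extract_reads(
    reads: Iterable[tuple[str, str]],
    library_id: str,
    report: ExtractionReport | None = None,
) -> tuple[list[tuple[str, str]], ExtractionReport]:
    """Run ditag extraction over a read stream for one library.

    Returns the accepted ``(library_id, tag)`` observations and the
    extraction report.  A read contributing at least one valid tag counts as
    accepted; rejection reasons are tallied per read.
    """
    report = report or ExtractionReport()
    observations: list[tuple[str, str]] = []
    for read_id, seq in reads:
        report.reads_seen += 1
        tags, reasons = extract_ditag_tags(seq)
        if tags:
            report.reads_accepted += 1
            observations += [(library_id, t) for t in tags]
            for reason in reasons:  # partially accepted reads: note the lost tag
                report.tags_rejected_by_reason[reason] += 1
        else:
            report.record(reasons[0] if reasons else "bad_length", read_id)
    return observations, report


def extract_libraries(
    read_files: Mapping[str, str | Path],
    libraries: Sequence[Library],
) -> tuple[TagCountMatrix, ExtractionReport]:
    """Extract and count tags for several libraries from FASTA/FASTQ files."""
    by_id = {lib.id: lib for lib in libraries}
    report = ExtractionReport()
    observations: list[tuple[str, str]] = []
    for lib_id, path in read_files.items():
        if lib_id not in by_id:
            raise KeyError(f"reads supplied for undeclared library {lib_id!r}")
        obs, report = extract_reads(iter_reads(path), lib_id, report)
        observations += obs
    matrix = count_tags(observations, list(libraries))
    report.check()
    return matrix, report
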