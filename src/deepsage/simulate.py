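"""Ground-truthed synthetic SuperSAGE data.

The generator emulates the structure of a two-organ (root, nodule), two
condition (control, NaCl) deepSuperSAGE experiment: a transcript pool with
a heavy-tailed abundance distribution (~90% of detected tags below 10
copies x 100,000^-1, under 1% above 500), SAAT isoform families (1-3
substitutions in the variable tag positions), spiked differential
expression with log-ratio effects drawn from +/-[1.0, 4.3], ditag reads at
the study's library depths, EST placements for every tag, tiered annotation
tables and GO-style categories with one spiked-enriched category.  Every
output is a pure function of (config, seed) and is accompanied by a truth
object sufficient to score recovery for every downstream module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .tags import ANCHOR, TAG_LENGTH, is_low_complexity, reverse_complement

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: pigeonhole blocks over the 22 variable positions used to keep unrelated
#: tags below the 23/26 family-link threshold: mismatches never fall in the
#: shared anchor, so <=3 of them leave at least one block exactly matched
_BLOCK_BOUNDS = (4, 10, 16, 21, 26)


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the profiled experiment: organ depths of 86,919 (root)
    and 57,281 (nodule) tag observations split evenly across control and
    NaCl libraries, a 40,000-transcript pool (matching the scale of the
    public EST collection; roughly 11-18,000 tags are detected per library
    at these depths), SAAT family-size classes covering 15% (one similar
    hit), 4% (two) and 2% (three or more) of tags with the remainder
    singletons, and differential-expression effects R(ln) drawn uniformly
    from +/-[1.0, 4.3].  Transcript abundances follow a Zipf (power-law)
    rank distribution with exponent ``abundance_exponent``; at the default
    exponent 1.0 and the default depths about 90% of detected tags fall
    below 10 copies x 100,000^-1, ~9% between 10 and 100, and fewer than
    1% above 500, the study-shaped class fractions recorded in
    ``abundance_class_targets``.
    """

    seed: int
    n_transcripts: int = 40_000
    organ_depths: dict = field(
        default_factory=lambda: {"root": 86_919, "nodule": 57_281}
    )
    frac_one_hit: float = 0.15
    frac_two_hits: float = 0.04
    frac_three_plus: float = 0.02
    de_fraction: float = 0.10
    rln_range: tuple[float, float] = (1.0, 4.3)
    abundance_exponent: float = 1.0
    abundance_class_targets: dict = field(
        default_factory=lambda: {"<10": 0.90, ">500": 0.01}
    )
    est_prefix_range: tuple[int, int] = (80, 150)
    est_suffix_length: int = 30
    n_categories: int = 40
    category_size_range: tuple[int, int] = (8, 40)
    spiked_category_size: int = 20
    error_rate: float = 0.0  # optional per-base read error, off by default

    def __post_init__(self) -> None:
        for f in (self.frac_one_hit, self.frac_two_hits, self.frac_three_plus,
                  self.de_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if any(d <= 0 for d in self.organ_depths.values()):
            raise ValueError("library depths must be positive")

    @property
    def library_depths(self) -> dict[str, int]:
        """Per-library depths: each organ's total split across conditions."""
        out = {}
        for organ, total in self.organ_depths.items():
            out[f"{organ}-control"] = (total + 1) // 2
            out[f"{organ}-NaCl"] = total // 2
        return out


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of the pipeline's estimates.

    Keys are tag *sequences* (UniTag ids are assigned downstream in
    first-seen order and are not known at generation time).
    """

    tags: list[str]
    families: list[list[str]]  # multi-member families only
    snp_positions: dict[str, list[int]]  # per family id -> 1-based positions
    placements: dict[str, tuple[str, int]]  # tag -> (est_id, offset)
    est_multiplicity: dict[str, int]  # ESTs x tags matching at <=1 mismatch
    abundance: dict[str, dict[str, float]]  # library -> tag -> probability
    de_tags: dict[str, float]  # tag -> realized R(ln) (NaCl vs control)
    accession_of: dict[str, str]  # tag -> protein accession
    categories: dict[str, list[str]]  # category id -> accessions
    spiked_category: str

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["placements"] = {k: list(v) for k, v in self.placements.items()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["placements"] = {
            k: (v[0], int(v[1])) for k, v in payload["placements"].items()
        }
        return cls(**payload)


@dataclass
class SyntheticTranscriptome:
    ests: dict[str, str]
    truth: SyntheticTruth
    config: SimulationConfig


class _TagPool:
    """Unique anchored tags kept pairwise below the family-link threshold."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.tags: list[str] = []
        self.family_of: dict[str, int] = {}
        self._blocks: list[dict[str, list[str]]] = [
            {} for _ in range(len(_BLOCK_BOUNDS) - 1)
        ]

    def _neighbours(self, tag: str) -> Iterable[str]:
        seen: set[str] = set()
        for b in range(len(_BLOCK_BOUNDS) - 1):
            key = tag[_BLOCK_BOUNDS[b]:_BLOCK_BOUNDS[b + 1]]
            for other in self._blocks[b].get(key, ()):
                if other not in seen:
                    seen.add(other)
                    yield other

    def _conflicts(self, tag: str, family: int) -> bool:
        if tag in self.family_of:
            return True
        for other in self._neighbours(tag):
            if self.family_of[other] == family:
                continue
            ident = sum(a == b for a, b in zip(tag, other))
            if ident >= 23:
                return True
        return False

    def admit(self, tag: str, family: int) -> bool:
        if "CATG" in tag[1:] or is_low_complexity(tag) or self._conflicts(tag, family):
            return False
        self.tags.append(tag)
        self.family_of[tag] = family
        for b in range(len(_BLOCK_BOUNDS) - 1):
            key = tag[_BLOCK_BOUNDS[b]:_BLOCK_BOUNDS[b + 1]]
            self._blocks[b].setdefault(key, []).append(tag)
        return True

    def random_tag(self, family: int, max_tries: int = 200) -> str:
        for _ in range(max_tries):
            body = "".join(self.rng.choice(list(_BASES), size=TAG_LENGTH - 4))
            tag = ANCHOR + body
            if self.admit(tag, family):
                return tag
        raise RuntimeError("could not draw a fresh unique tag")

    def mutate(self, parent: str, family: int, max_tries: int = 200) -> str:
        """A 1-3 substitution isoform of *parent* in positions 5-26."""
        for _ in range(max_tries):
            n_snp = int(self.rng.integers(1, 4))
            positions = self.rng.choice(
                np.arange(len(ANCHOR), TAG_LENGTH), size=n_snp, replace=False
            )
            chars = list(parent)
            for pos in positions:
                choices = [b for b in _BASES if b != parent[pos]]
                chars[pos] = choices[int(self.rng.integers(0, 3))]
            tag = "".join(chars)
            if self.admit(tag, family):
                return tag
        raise RuntimeError("could not derive a unique isoform tag")


def zipf_abundance(
    rng: np.random.Generator, n: int, exponent: float = 1.0
) -> np.ndarray:
    """Normalized Zipf rank abundances, randomly assigned to transcripts.

    Weight of the transcript at rank i is i^-exponent; ranks are shuffled
    so abundance is independent of generation order (and of family
    structure).  Returns a probability vector of length n.
    """
    ranks = rng.permutation(n) + 1
    w = ranks.astype(float) ** -exponent
    return w / w.sum()


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _catg_free(rng: np.random.Generator, length: int) -> str:
    while True:
        seq = _random_dna(rng, length)
        if "CATG" not in seq:
            return seq


def _build_est(rng: np.random.Generator, tag: str, config: SimulationConfig) -> str:
    """Embed *tag* in a random EST so its CATG is the 3'-most usable anchor."""
    lo, hi = config.est_prefix_range
    for _ in range(100):
        prefix = _random_dna(rng, int(rng.integers(lo, hi + 1)))
        suffix = _catg_free(rng, config.est_suffix_length)
        est = prefix + tag + suffix
        # the junction or tag body must not create a more-3' anchored site
        tail = est[len(prefix) + 1:]
        ok = True
        idx = tail.find("CATG")
        while idx != -1:
            if len(tail) - idx - 4 >= TAG_LENGTH - 4:
                ok = False
                break
            idx = tail.find("CATG", idx + 1)
        if ok:
            return est
    raise RuntimeError("could not embed tag in an EST")


def simulate_transcriptome(config: SimulationConfig) -> SyntheticTranscriptome:
    """Generate the transcript pool: tags, SAAT families, ESTs and truth.

    Tag sequences are unique, anchored, non-low-complexity, and unrelated
    tags stay below the 23/26 similarity threshold, so the generated family
    partition is exactly the single-linkage truth.  Each tag is embedded
    verbatim in its own EST (family isoforms in duplicated copies of the
    parent EST's layout), with the tag anchor as the 3'-most usable CATG.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts

    n2 = round(config.frac_one_hit * n / 2)
    n3 = round(config.frac_two_hits * n / 3)
    n4 = round(config.frac_three_plus * n / 4)
    n_family_members = 2 * n2 + 3 * n3 + 4 * n4
    if n_family_members > n:
        raise ValueError("family-size fractions request more members than transcripts")

    pool = _TagPool(rng)
    families: list[list[str]] = []
    fam_id = 0
    for size, count in ((2, n2), (3, n3), (4, n4)):
        for _ in range(count):
            parent = pool.random_tag(fam_id)
            members = [parent]
            for _ in range(size - 1):
                members.append(pool.mutate(parent, fam_id))
            families.append(members)
            fam_id += 1
    n_singletons = n - n_family_members
    for _ in range(n_singletons):
        pool.random_tag(fam_id)
        fam_id += 1
    tags = list(pool.tags)

    # ESTs: one per tag; isoforms reuse the parent's flanks (duplicated EST)
    ests: dict[str, str] = {}
    placements: dict[str, tuple[str, int]] = {}
    est_counter = 0
    parent_layout: dict[int, tuple[str, int, str]] = {}
    for tag in tags:
        fam = pool.family_of[tag]
        if fam in parent_layout:
            prefix, offset, suffix = parent_layout[fam]
            est = prefix + tag + suffix
        else:
            est = _build_est(rng, tag, config)
            offset = est.find(tag)
            parent_layout[fam] = (est[:offset], offset, est[offset + TAG_LENGTH:])
        est_counter += 1
        est_id = f"EST{est_counter:06d}"
        ests[est_id] = est
        placements[tag] = (est_id, offset)

    # truth multiplicity under the <=1-mismatch matcher: within a family,
    # tag t hits member u's EST iff Hamming(t, u) <= 1
    est_multiplicity = {est_id: 1 for est_id in ests}
    snp_positions: dict[str, list[int]] = {}
    for i, members in enumerate(families):
        rep = members[0]
        positions = {
            p + 1
            for m in members
            for p, (a, b) in enumerate(zip(m, rep))
            if a != b
        }
        snp_positions[f"family-{i + 1}"] = sorted(positions)
        for u in members:
            est_id = placements[u][0]
            extra = sum(
                1
                for t in members
                if t != u and sum(a != b for a, b in zip(t, u)) <= 1
            )
            est_multiplicity[est_id] = 1 + extra

    # abundances: Zipf rank weights, independently rank-shuffled per organ
    abundance: dict[str, dict[str, float]] = {}
    organ_base: dict[str, np.ndarray] = {}
    for organ in config.organ_depths:
        organ_base[organ] = zipf_abundance(rng, len(tags), config.abundance_exponent)

    # spiked differential expression, shared across organs
    n_de = round(config.de_fraction * len(tags))
    de_idx = rng.choice(len(tags), size=n_de, replace=False)
    lo, hi = config.rln_range
    effects = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
    log_effect = np.zeros(len(tags))
    log_effect[de_idx] = effects

    de_tags: dict[str, float] = {}
    for organ, base in organ_base.items():
        abundance[f"{organ}-control"] = {t: float(p) for t, p in zip(tags, base)}
        stressed = base * np.exp(log_effect)
        z = stressed.sum()
        stressed = stressed / z
        abundance[f"{organ}-NaCl"] = {t: float(p) for t, p in zip(tags, stressed)}
        if organ == next(iter(config.organ_depths)):
            # realized effects after renormalization (identical across organs)
            for i in de_idx:
                de_tags[tags[i]] = float(log_effect[i] - math.log(z))

    # annotation scene: one accession per family (isoforms share the gene),
    # one per singleton; categories over accessions with one spiked set
    accession_of: dict[str, str] = {}
    acc_counter = 0
    fam_accession: dict[int, str] = {}
    for tag in tags:
        fam = pool.family_of[tag]
        if fam not in fam_accession:
            acc_counter += 1
            fam_accession[fam] = f"ACC{acc_counter:05d}"
        accession_of[tag] = fam_accession[fam]

    all_accessions = sorted(set(accession_of.values()))
    categories: dict[str, list[str]] = {}
    size_lo, size_hi = config.category_size_range
    for c in range(config.n_categories):
        size = int(rng.integers(size_lo, size_hi + 1))
        members = rng.choice(all_accessions, size=min(size, len(all_accessions)),
                             replace=False)
        categories[f"CAT:{c + 1:04d}"] = sorted(members)
    # spiked category: accessions of the most abundant spiked tags, so the
    # score shift the category is defined by is actually expressed (and
    # observable) at the simulated depths
    first_base = organ_base[next(iter(config.organ_depths))]
    abundance_of = dict(zip(tags, first_base))
    spiked: list[str] = []
    seen_accs: set[str] = set()
    for t in sorted(de_tags, key=lambda t: -abundance_of[t]):
        acc = accession_of[t]
        if acc not in seen_accs:
            seen_accs.add(acc)
            spiked.append(acc)
        if len(spiked) >= config.spiked_category_size:
            break
    categories["CAT:SPIKED"] = sorted(spiked)

    truth = SyntheticTruth(
        tags=tags,
        families=[m for m in families],
        snp_positions=snp_positions,
        placements=placements,
        est_multiplicity=est_multiplicity,
        abundance=abundance,
        de_tags=de_tags,
        accession_of=accession_of,
        categories=categories,
        spiked_category="CAT:SPIKED",
    )
    return SyntheticTranscriptome(ests=ests, truth=truth, config=config)


def simulate_libraries(
    transcriptome: SyntheticTranscriptome,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[str]], dict[str, dict[str, int]]]:
    """Draw tag observations per library and assemble ditag reads.

    Per library, ``2 * ceil(depth / 2)`` tag observations are drawn
    multinomially from the library's abundance vector, shuffled, and paired
    uniformly at random into ditag reads ``tag1 + revcomp(tag2)`` (52 bp).
    Returns ``(reads_by_library, counts_by_library)`` where the count table
    is the exactly realized multiset -- the round-trip oracle for
    extraction and counting.
    """
    config = transcriptome.config
    truth = transcriptome.truth
    rng = rng or np.random.default_rng(config.seed + 1)
    reads_by_library: dict[str, list[str]] = {}
    counts_by_library: dict[str, dict[str, int]] = {}
    for lib_id, depth in config.library_depths.items():
        probs = truth.abundance[lib_id]
        tags = list(probs)
        p = np.array([probs[t] for t in tags])
        n_obs = 2 * ((depth + 1) // 2)
        counts = rng.multinomial(n_obs, p / p.sum())
        counts_by_library[lib_id] = {
            t: int(c) for t, c in zip(tags, counts) if c > 0
        }
        observations = np.repeat(np.arange(len(tags)), counts)
        rng.shuffle(observations)
        reads = []
        for i in range(0, len(observations), 2):
            t1 = tags[observations[i]]
            t2 = tags[observations[i + 1]]
            read = t1 + reverse_complement(t2)
            if config.error_rate > 0:
                read = _add_errors(rng, read, config.error_rate)
            reads.append(read)
        reads_by_library[lib_id] = reads
    return reads_by_library, counts_by_library


def _add_errors(rng: np.random.Generator, read: str, rate: float) -> str:
    chars = list(read)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = _BASES[int(rng.integers(0, 4))]
    return "".join(chars)


def design_mismatch_probes(tag: str) -> list[str]:
    """Three mismatch-probe variants of a 26 bp tag.

    Variant 1 differs at position 7 only; variant 2 at positions 7 and 13;
    variant 3 at positions 7, 13 and 20 (all 1-based).  Each substitution is
    the complement of the original base, so the anchor (positions 1-4) is
    never altered and variant i has Hamming distance i to the original.
    Used as hybridization background controls on tag microarrays.
    """
    if len(tag) != TAG_LENGTH:
        raise ValueError("probe design requires a 26 bp tag")
    variants = []
    for positions in ((7,), (7, 13), (7, 13, 20)):
        chars = list(tag)
        for pos in positions:
            chars[pos - 1] = _COMPLEMENT[tag[pos - 1]]
        variants.append("".join(chars))
    return variants


def family_pair_f1(
    predicted: Iterable[Iterable[str]], truth: Iterable[Iterable[str]]
) -> float:
    """Pairwise F1 of a predicted family partition against the truth.

    Both partitions are read as sets of co-clustered pairs (singletons
    contribute none).  Returns 1.0 when neither side has any pair.
    """

    def pairs(partition):
        out = set()
        for group in partition:
            group = sorted(group)
            for i, a in enumerate(group):
                for b in group[i + 1:]:
                    out.add((a, b))
        return out

    p, t = pairs(predicted), pairs(truth)
    if not p and not t:
        return 1.0
    if not p or not t:
        return 0.0
    tp = len(p & t)
    precision = tp / len(p)
    recall = tp / len(t)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# -- serialization helpers -------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write sequences to FASTA (60-column wrapping)."""
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")


def write_reads_fasta(reads: Iterable[str], library_id: str, path: str | Path) -> None:
    with open(path, "w") as handle:
        for i, read in enumerate(reads, start=1):
            handle.write(f">{library_id}:ditag{i:07d}\n{read}\n")
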