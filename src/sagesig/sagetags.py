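"""Serial-tag extraction and counting.

Concatemer reads carry ditags (two short expression tags ligated
tail-to-tail) separated by a fixed anchoring site (``CATG`` by default,
the NlaIII recognition sequence). This module extracts the ditags,
splits them into tags, counts tags into libraries and aggregates tag
counts to genes through a tag-to-gene mapping table.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.SeqIO.FastaIO import SimpleFastaParser

ANCHOR_SITE = "CATG"
DEFAULT_TAG_LEN = 10
DEFAULT_DITAG_BOUNDS = (20, 26)

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConcatemerRead:
    """A single concatemer sequencing read."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: illegal characters {sorted(bad)}"
            )


@dataclass
class TagLibrary:
    """Integer tag counts for one library.

    Invariants: every tag has length ``tag_len`` and contains no N; all
    stored counts are >= 1 (absent tags are implicitly zero).
    """

    library_id: str
    counts: Counter = field(default_factory=Counter)
    tag_len: int = DEFAULT_TAG_LEN
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tag, count in self.counts.items():
            if len(tag) != self.tag_len or "N" in tag:
                raise ValueError(f"invalid tag {tag!r} for tag_len {self.tag_len}")
            if count < 1:
                raise ValueError(f"tag {tag!r} has non-positive count {count}")

    @property
    def total_tags(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class TagToGeneMap:
    """Unambiguous tag-to-gene assignments plus the set of ambiguous tags.

    A tag appearing in the source table with more than one distinct gene
    is ambiguous and excluded from ``entries``.
    """

    entries: dict[str, str] = field(default_factory=dict)
    ambiguous_tags: set[str] = field(default_factory=set)
    # first gene listed for each ambiguous tag, for the keep_first policy
    first_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.entries) & self.ambiguous_tags
        if overlap:
            raise ValueError(f"tags both mapped and ambiguous: {sorted(overlap)[:5]}")
        if any(not g for g in self.entries.values()):
            raise ValueError("empty gene_id in mapping")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TagToGeneMap":
        seen: dict[str, list[str]] = {}
        for tag, gene in pairs:
            genes = seen.setdefault(tag, [])
            if gene not in genes:
                genes.append(gene)
        entries = {t: g[0] for t, g in seen.items() if len(g) == 1}
        ambiguous = {t for t, g in seen.items() if len(g) > 1}
        first = {t: seen[t][0] for t in ambiguous}
        return cls(entries=entries, ambiguous_tags=ambiguous, first_gene=first)


@dataclass
class GeneCounts:
    """Per-gene tag counts with the unmapped/ambiguous remainder."""

    library_id: str
    counts: dict[str, float]
    unmapped_total: int = 0
    ambiguous_total: int = 0


def extract_ditags(
    read: ConcatemerRead,
    min_len: int = DEFAULT_DITAG_BOUNDS[0],
    max_len: int = DEFAULT_DITAG_BOUNDS[1],
    site: str = ANCHOR_SITE,
) -> list[str]:
    """Extract ditags: maximal substrings strictly between consecutive
    anchoring sites whose length falls in ``[min_len, max_len]``.

    Out-of-bounds segments are discarded; order of appearance is kept.
    A read too short to contain a site yields an empty list.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    seq = read.sequence
    positions = []
    start = 0
    while True:
        i = seq.find(site, start)
        if i < 0:
            break
        positions.append(i)
        start = i + len(site)
    ditags = []
    for left, right in zip(positions, positions[1:]):
        segment = seq[left + len(site): right]
        if min_len <= len(segment) <= max_len:
            ditags.append(segment)
    return ditags


def split_ditag(ditag: str, tag_len: int = DEFAULT_TAG_LEN) -> tuple[str, str]:
    """Split a ditag into its two generating tags.

    The first tag is the leading ``tag_len`` bases; the second is the
    reverse complement of the trailing ``tag_len`` bases. Ditags between
    ``tag_len`` and ``2*tag_len`` long yield two overlapping tags.
    """
    if len(ditag) < tag_len:
        raise ValueError(f"ditag {ditag!r} shorter than tag_len {tag_len}")
    return ditag[:tag_len], reverse_complement(ditag[-tag_len:])


def count_tags(
    ditags: Iterable[str],
    tag_len: int = DEFAULT_TAG_LEN,
    dedupe: bool = True,
    linker_blacklist: frozenset[str] | set[str] = frozenset(),
    library_id: str = "library",
    metadata: dict | None = None,
) -> tuple[TagLibrary, dict]:
    """Count tags from a ditag stream into a :class:`TagLibrary`.

    With ``dedupe`` on, exact duplicate ditags are collapsed to one
    occurrence before splitting (PCR-duplicate control). Tags in
    ``linker_blacklist`` and N-containing tags are excluded; all
    exclusions are tallied in the returned stats dict.
    """
    ditags = list(ditags)
    stats = {
        "ditags_raw": len(ditags),
        "ditags_after_dedupe": len(ditags),
        "short_ditags_rejected": 0,
        "n_tags_discarded": 0,
        "blacklisted_tags": 0,
    }
    if dedupe:
        ditags = list(dict.fromkeys(ditags))
        stats["ditags_after_dedupe"] = len(ditags)
    counts: Counter = Counter()
    for ditag in ditags:
        if len(ditag) < tag_len:
            stats["short_ditags_rejected"] += 1
            continue
        for tag in split_ditag(ditag, tag_len):
            if "N" in tag:
                stats["n_tags_discarded"] += 1
            elif tag in linker_blacklist:
                stats["blacklisted_tags"] += 1
            else:
                counts[tag] += 1
    lib = TagLibrary(
        library_id=library_id,
        counts=counts,
        tag_len=tag_len,
        metadata=metadata or {},
    )
    return lib, stats


def aggregate_to_genes(
    lib: TagLibrary,
    mapping: TagToGeneMap,
    ambiguous_policy: str = "drop",
) -> GeneCounts:
    """Sum tag counts per gene through the mapping.

    Unmapped tags contribute to ``unmapped_total``; ambiguous tags are
    dropped (default) or, under ``keep_first``, counted toward the first
    gene listed for them in the source table.
    """
    if ambiguous_policy not in ("drop", "keep_first"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    gene_counts: dict[str, float] = {}
    unmapped = 0
    ambiguous = 0
    for tag, count in lib.counts.items():
        if tag in mapping.entries:
            gene = mapping.entries[tag]
            gene_counts[gene] = gene_counts.get(gene, 0) + count
        elif tag in mapping.ambiguous_tags:
            if ambiguous_policy == "keep_first":
                gene = mapping.first_gene[tag]
                gene_counts[gene] = gene_counts.get(gene, 0) + count
            else:
                ambiguous += count
        else:
            unmapped += count
    return GeneCounts(
        library_id=lib.library_id,
        counts=gene_counts,
        unmapped_total=unmapped,
        ambiguous_total=ambiguous,
    )


# ---------------------------------------------------------------------------
# I/O

def read_concatemer_fasta(path: str | Path) -> list[ConcatemerRead]:
    """Read concatemer reads from a (multi-record) FASTA file."""
    reads = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            reads.append(ConcatemerRead(title.split()[0], seq.upper()))
    return reads


def read_tag_table(path: str | Path, library_id: str | None = None,
                   tag_len: int = DEFAULT_TAG_LEN) -> TagLibrary:
    """Read a pre-counted ``tag<TAB>count`` table."""
    counts: Counter = Counter()
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tag, count = line.split("\t")
            if tag == "tag":  # header
                continue
            counts[tag] += int(count)
    return TagLibrary(
        library_id=library_id or Path(path).stem,
        counts=counts,
        tag_len=tag_len,
    )


def write_tag_table(lib: TagLibrary, path: str | Path,
                    sidecar_stats: Mapping | None = None) -> None:
    """Write a tag table sorted by descending count then tag, plus a JSON
    sidecar with totals."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("tag\tcount\n")
        for tag, count in sorted(lib.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            handle.write(f"{tag}\t{count}\n")
    sidecar = {
        "library_id": lib.library_id,
        "total_tags": lib.total_tags,
        "distinct_tags": len(lib),
        "tag_len": lib.tag_len,
        "metadata": dict(lib.metadata),
    }
    if sidecar_stats:
        sidecar.update(sidecar_stats)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_tag_gene_map(path: str | Path) -> TagToGeneMap:
    """Read a ``tag<TAB>gene_id`` mapping; repeated tag rows with distinct
    genes mark the tag as ambiguous."""
    pairs = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tag, gene = line.split("\t")
            if tag == "tag":
                continue
            pairs.append((tag, gene))
    return TagToGeneMap.from_pairs(pairs)


def read_gene_counts(path: str | Path, library_id: str | None = None) -> GeneCounts:
    """Read a ``gene_id<TAB>count`` table into :class:`GeneCounts`.

    The default library id is the file stem with a trailing ``.genes``
    marker (the writer's convention) removed.
    """
    if library_id is None:
        library_id = Path(path).stem
        if library_id.endswith(".genes"):
            library_id = library_id[: -len(".genes")]
    counts: dict[str, float] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, count = line.split("\t")
            if gene in ("gene", "gene_id"):
                continue
            value = float(count)
            counts[gene] = counts.get(gene, 0) + value
    return GeneCounts(library_id=library_id, counts=counts)


def write_gene_counts(counts: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tcount\n")
        for gene, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            handle.write(f"{gene}\t{count:g}\n")
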