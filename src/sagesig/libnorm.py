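"""Library normalization to a fixed tag total and virtual-library averaging.

Each library is rescaled so that its counts sum to a common target
(100,000 by default). A virtual reference library is built by per-key
averaging of two normalized libraries, treating absent keys as zero so
that totals are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

from sagesig.sagetags import GeneCounts, TagLibrary

DEFAULT_TARGET = 100_000.0


@dataclass
class NormalizedLibrary:
    """Real-valued counts rescaled to a fixed total.

    ``source_total`` keeps the pre-normalization tag total for use in
    count-based statistics. Virtual libraries record their construction
    in ``sources``; their total equals the mean of the source targets.
    """

    library_id: str
    counts: dict[str, float]
    target_size: float = DEFAULT_TARGET
    source_total: int | float = 0
    is_virtual: bool = False
    sources: tuple[str, ...] = field(default_factory=tuple)

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def get(self, key: str) -> float:
        return self.counts.get(key, 0.0)


def _as_counts(lib: Union[TagLibrary, GeneCounts, Mapping[str, float]]) -> tuple[str, dict]:
    if isinstance(lib, TagLibrary):
        return lib.library_id, dict(lib.counts)
    if isinstance(lib, GeneCounts):
        return lib.library_id, dict(lib.counts)
    return "library", dict(lib)


def normalize(
    lib: Union[TagLibrary, GeneCounts, Mapping[str, float]],
    target: float = DEFAULT_TARGET,
    library_id: str | None = None,
) -> NormalizedLibrary:
    """Rescale counts so they sum to ``target``; values are kept real."""
    inferred_id, counts = _as_counts(lib)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty library")
    factor = target / total
    return NormalizedLibrary(
        library_id=library_id or inferred_id,
        counts={k: v * factor for k, v in counts.items()},
        target_size=target,
        source_total=total,
    )


def make_virtual_library(
    a: NormalizedLibrary,
    b: NormalizedLibrary,
    library_id: str | None = None,
) -> NormalizedLibrary:
    """Average two normalized libraries key-wise into a virtual library.

    Keys present in only one library are averaged against zero (halved),
    which conserves the total: total(virtual) = (total(a) + total(b)) / 2.
    """
    if a.target_size != b.target_size:
        raise ValueError(
            f"mismatched targets: {a.target_size} vs {b.target_size}"
        )
    keys = set(a.counts) | set(b.counts)
    counts = {k: (a.get(k) + b.get(k)) / 2.0 for k in keys}
    return NormalizedLibrary(
        library_id=library_id or f"virtual({a.library_id},{b.library_id})",
        counts=counts,
        target_size=a.target_size,
        source_total=(a.source_total + b.source_total) / 2.0,
        is_virtual=True,
        sources=(a.library_id, b.library_id),
    )
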