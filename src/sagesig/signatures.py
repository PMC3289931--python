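"""Set algebra for expression signatures.

Builds the commonly-expressed gene core, the >=2-category
"multifunctional" grid, the metastatic and reference multifunctional
signatures with their unique/shared partition, and the differential
("biased") subset of the metastatic signature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from sagesig.diffexpr import ConsistentDESet, CountsLike, _counts_of
from sagesig.libnorm import NormalizedLibrary

DEFAULT_CATEGORY_NAMES = (
    "cell motility",
    "cell adhesion",
    "chemotaxis",
    "blood coagulation",
    "cell proliferation",
    "ECM remodeling",
    "angiogenesis",
    "antiapoptosis",
)


def format_percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100*num/den rounded half-up to ``decimals`` places.

    With ``decimals=0`` an integer-valued float is returned (36.0 for
    27/74), matching integer-rounded report figures.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class FunctionalCategories:
    """Named, possibly overlapping functional gene categories."""

    categories: dict[str, set[str]]

    def membership_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for genes in self.categories.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return counts

    @classmethod
    def from_table(cls, rows: Iterable[tuple[str, str]]) -> "FunctionalCategories":
        """Build from (gene_id, category) rows."""
        cats: dict[str, set[str]] = {}
        for gene, cat in rows:
            cats.setdefault(cat, set()).add(gene)
        return cls(categories=cats)


@dataclass
class SignatureReport:
    """Nested signature sets and their unique/shared partition.

    Identities maintained by construction:
    ``met_signature = grid & common_met``;
    ``nm_signature = grid & nm_expressed``;
    ``combined = met_signature | nm_signature``; ``unique_met``,
    ``unique_nm`` and ``shared`` partition ``combined``;
    ``biased_signature`` genes all lie in ``met_signature``.
    """

    common_met: set[str]
    nm_expressed: set[str]
    grid: set[str]
    met_signature: set[str]
    nm_signature: set[str]
    combined: set[str]
    unique_met: set[str]
    unique_nm: set[str]
    shared: set[str]
    biased_signature: list[tuple[str, str]]  # (gene, status)
    mean_expression: dict[str, float | None] = field(default_factory=dict)

    @property
    def biased_fraction_percent(self) -> float | None:
        """100*|biased|/|met_signature|, one decimal, half-up."""
        if not self.met_signature:
            return None
        return format_percentage(len(self.biased_signature), len(self.met_signature))

    def to_dict(self) -> dict:
        return {
            "counts": {
                "common_met": len(self.common_met),
                "nm_expressed": len(self.nm_expressed),
                "grid": len(self.grid),
                "met_signature": len(self.met_signature),
                "nm_signature": len(self.nm_signature),
                "combined": len(self.combined),
                "unique_met": len(self.unique_met),
                "unique_nm": len(self.unique_nm),
                "shared": len(self.shared),
                "biased_signature": len(self.biased_signature),
            },
            "biased_fraction_percent": self.biased_fraction_percent,
            "sets": {
                "met_signature": sorted(self.met_signature),
                "nm_signature": sorted(self.nm_signature),
                "unique_met": sorted(self.unique_met),
                "unique_nm": sorted(self.unique_nm),
                "shared": sorted(self.shared),
            },
            "biased_signature": [
                {"gene_id": g, "status": s} for g, s in self.biased_signature
            ],
            "mean_expression": self.mean_expression,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def expressed_genes(lib: CountsLike, min_count: float = 2) -> set[str]:
    """Genes with count >= ``min_count`` in the library."""
    return {g for g, c in _counts_of(lib).items() if c >= min_count}


def common_genes(libs: Sequence[CountsLike], min_count: float = 2) -> set[str]:
    """Genes expressed in every library (intersection of expressed sets)."""
    if len(libs) < 2:
        raise ValueError("need at least two libraries")
    core = expressed_genes(libs[0], min_count)
    for lib in libs[1:]:
        core &= expressed_genes(lib, min_count)
    return core


def build_grid(
    categories: Union[FunctionalCategories, Mapping[str, set]],
    min_categories: int = 2,
) -> set[str]:
    """Genes belonging to at least ``min_categories`` categories."""
    if not isinstance(categories, FunctionalCategories):
        categories = FunctionalCategories(dict(categories))
    return {
        g
        for g, n in categories.membership_counts().items()
        if n >= min_categories
    }


def _subset_mean(counts: Mapping[str, float], genes: set[str]) -> float | None:
    if not genes:
        return None
    return float(np.mean([counts.get(g, 0.0) for g in genes]))


def build_signature_report(
    met_libs: Sequence[CountsLike],
    nm_virtual: NormalizedLibrary,
    grid: set[str],
    consistent: ConsistentDESet,
    min_count: float = 2,
    nm_expressed_mode: str = "common",
    nm_component_libs: Sequence[CountsLike] | None = None,
) -> SignatureReport:
    """Assemble the full signature report.

    ``nm_expressed_mode`` selects the reference-side expressed set:
    ``common`` requires expression in both component libraries
    (``nm_component_libs``); ``virtual`` uses the averaged virtual
    library directly.
    """
    if nm_expressed_mode not in ("common", "virtual"):
        raise ValueError(f"unknown nm_expressed mode {nm_expressed_mode!r}")
    common_met = common_genes(list(met_libs), min_count) if len(met_libs) > 1 \
        else expressed_genes(met_libs[0], min_count)
    if nm_expressed_mode == "common":
        if nm_component_libs is None or len(nm_component_libs) < 2:
            raise ValueError("nm_expressed_mode='common' needs the two component libraries")
        nm_expressed = common_genes(list(nm_component_libs), min_count)
    else:
        nm_expressed = expressed_genes(nm_virtual, min_count)

    met_signature = grid & common_met
    nm_signature = grid & nm_expressed
    combined = met_signature | nm_signature
    shared = met_signature & nm_signature
    unique_met = met_signature - nm_signature
    unique_nm = nm_signature - met_signature

    de_genes = consistent.up_genes | consistent.down_genes
    biased: list[tuple[str, str]] = []
    for gene in sorted(met_signature & de_genes):
        if nm_virtual.get(gene) == 0:
            status = "unique_met"
        elif gene in consistent.up_genes:
            status = "up_differential"
        else:
            status = "down_differential"
        biased.append((gene, status))

    # mean normalized expression per subset, averaged across met libraries
    met_counts = [_counts_of(lib) for lib in met_libs]

    def met_mean(genes: set[str]) -> float | None:
        if not genes:
            return None
        per_lib = [_subset_mean(c, genes) for c in met_counts]
        return float(np.mean([m for m in per_lib if m is not None]))

    mean_expression = {
        "met_signature": met_mean(met_signature),
        "unique_met": met_mean(unique_met),
        "shared": met_mean(shared),
        "unique_nm": _subset_mean(nm_virtual.counts, unique_nm),
        "biased_signature": met_mean({g for g, _ in biased}),
    }

    return SignatureReport(
        common_met=common_met,
        nm_expressed=nm_expressed,
        grid=grid,
        met_signature=met_signature,
        nm_signature=nm_signature,
        combined=combined,
        unique_met=unique_met,
        unique_nm=unique_nm,
        shared=shared,
        biased_signature=biased,
        mean_expression=mean_expression,
    )


def annotate_subset(
    report: SignatureReport, gene_list: Iterable[str], label: str
) -> dict:
    """Overlap sizes between an external gene list and each report set."""
    genes = set(gene_list)
    overlaps = {
        name: len(genes & getattr(report, name))
        for name in (
            "common_met",
            "nm_expressed",
            "grid",
            "met_signature",
            "nm_signature",
            "unique_met",
            "unique_nm",
            "shared",
        )
    }
    overlaps["biased_signature"] = len(
        genes & {g for g, _ in report.biased_signature}
    )
    return {"label": label, "list_size": len(genes), "overlaps": overlaps}


# ---------------------------------------------------------------------------
# I/O helpers

def read_gene_list(path: str | Path) -> set[str]:
    """One gene per line; blank lines and # comments skipped."""
    genes = set()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.split("\t")[0])
    return genes


def read_categories(path: str | Path) -> FunctionalCategories:
    """TSV of ``gene_id<TAB>category`` rows."""
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, cat = line.split("\t")
            if gene == "gene_id":
                continue
            rows.append((gene, cat))
    return FunctionalCategories.from_table(rows)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


@dataclass
class PublishedSignatureEntry:
    gene_name: str
    gene_symbol: str
    direction: str  # up | down
    unique_met: bool


def load_published_biased_signature() -> list[PublishedSignatureEntry]:
    """The published biased-signature table bundled with the package."""
    from importlib import resources

    entries = []
    path = resources.files("sagesig").joinpath("data/biased_signature.tsv")
    for line in path.read_text().splitlines():
        if not line or line.startswith("gene_name"):
            continue
        name, symbol, direction, unique = line.split("\t")
        entries.append(
            PublishedSignatureEntry(
                gene_name=name,
                gene_symbol=symbol,
                direction=direction,
                unique_met=bool(int(unique)),
            )
        )
    return entries
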