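"""Synthetic data generation with a ground-truth ledger.

Generates every input the pipeline consumes — tag libraries (optionally
as concatemer FASTA), tag-to-gene maps, functional categories, curated
gene lists and qPCR tables — while recording enough truth to predict
every downstream set and statistic.

The default "study-shaped" scenario builds five metastatic and two
reference libraries at the published sequencing depths (87,957 / 108,331
/ 109,862 / 83,522 / 88,439 tags for the metastases; 77,757 / 77,019 for
the references), a ~4,200-gene universe with a shared expressed core,
150 planted fold-changes plus uniquely expressed genes, eight
overlapping functional categories yielding a 161-gene >=2-category grid,
and a planted "biased" signature inside it.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from sagesig.libnorm import make_virtual_library, normalize
from sagesig.sagetags import (
    ANCHOR_SITE,
    ConcatemerRead,
    GeneCounts,
    TagLibrary,
    TagToGeneMap,
    reverse_complement,
)
from sagesig.signatures import (
    DEFAULT_CATEGORY_NAMES,
    FunctionalCategories,
    common_genes,
    expressed_genes,
)

# Sequencing depths of the seven study libraries, metastatic then reference.
MET_DEPTHS = (87_957, 108_331, 109_862, 83_522, 88_439)
NM_DEPTHS = (77_757, 77_019)

# Category sizes of the eight metastasis-relevant functional processes.
DEFAULT_CATEGORY_SIZES = (126, 483, 125, 81, 302, 99, 66, 118)

DEFAULT_GRID_SIZE = 161


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_transcriptome(
    n_genes: int, mu: float = 0.0, sigma: float = 1.5, seed=0
) -> np.ndarray:
    """Strictly positive log-normal abundances normalized to sum 1.

    ``sigma=0`` degenerates to a uniform transcriptome.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed)
    if sigma == 0:
        return np.full(n_genes, 1.0 / n_genes)
    raw = rng.lognormal(mean=mu, sigma=sigma, size=n_genes)
    return raw / raw.sum()


@dataclass
class PlantedEffects:
    """Condition-specific abundances and the truth behind them."""

    met_abundance: np.ndarray
    nm_abundance: np.ndarray
    up_genes: list[int]  # indices, higher in met
    down_genes: list[int]  # indices, lower in met
    unique_genes: list[int]  # indices, zero in nm
    folds: dict[int, float] = field(default_factory=dict)


def plant_effects(
    base: np.ndarray,
    n_de: int = 150,
    fold: float = 8.0,
    n_unique: int = 10,
    seed=0,
    up_base_range: tuple[float, float] = (4e-5, 1e-4),
    down_base_range: tuple[float, float] = (1.5e-4, 3e-4),
) -> PlantedEffects:
    """Derive metastatic and reference abundance vectors from a base.

    Half the ``n_de`` genes (rounded up) are upregulated in the
    metastatic condition by roughly ``fold``, the rest downregulated; a
    further ``n_unique`` genes are zeroed in the reference. Planted genes
    are re-based into moderate abundance ranges so their counts clear the
    expression threshold at the study depths. The reference-side planted
    mass is then rescaled to exactly match the metastatic-side planted
    mass, so after normalization every unplanted gene has identical
    abundance in both conditions (no spurious global fold-change); the
    realized per-gene folds are recorded in ``folds``.
    """
    n_genes = base.size
    if n_de + n_unique > n_genes:
        raise ValueError("more planted genes than genes")
    rng = _rng(seed)
    chosen = rng.choice(n_genes, size=n_de + n_unique, replace=False)
    n_up = (n_de + 1) // 2
    up = sorted(int(i) for i in chosen[:n_up])
    down = sorted(int(i) for i in chosen[n_up:n_de])
    unique = sorted(int(i) for i in chosen[n_de:])

    met = base.astype(float).copy()
    nm = base.astype(float).copy()
    modified: list[int] = []

    if fold != 1.0:
        for idx in up:
            b = rng.uniform(*up_base_range)
            nm[idx] = b
            met[idx] = b * fold
            modified.append(idx)
        for idx in down:
            b = rng.uniform(*down_base_range)
            met[idx] = b
            nm[idx] = b * fold
            modified.append(idx)
    for idx in unique:
        b = rng.uniform(*up_base_range)
        met[idx] = b * fold
        nm[idx] = 0.0
        modified.append(idx)

    p_met = sum(met[i] for i in modified)
    p_nm = sum(nm[i] for i in modified)
    if p_nm > 0:
        scale = p_met / p_nm
        for idx in modified:
            nm[idx] *= scale
    met /= met.sum()
    nm /= nm.sum()
    folds = {
        idx: (met[idx] / nm[idx] if nm[idx] > 0 else np.inf)
        for idx in modified
    }
    return PlantedEffects(
        met_abundance=met,
        nm_abundance=nm,
        up_genes=up,
        down_genes=down,
        unique_genes=unique,
        folds=folds,
    )


def make_tag_map(
    n_genes: int, tag_len: int = 10, seed=0, site: str = ANCHOR_SITE
) -> list[str]:
    """One unique tag per gene, safe for exact concatemer round-trips.

    Tags contain neither N nor the anchoring site; tags ending in ``C``
    or ``CA`` are also rejected because a ditag junction (tag + reverse
    complement of the next tag) could otherwise spell out a spurious
    anchoring site across the boundary.
    """
    rng = _rng(seed)
    bases = np.array(list("ACGT"))
    tags: list[str] = []
    seen: set[str] = set()
    while len(tags) < n_genes:
        draw = rng.integers(0, 4, size=(n_genes, tag_len))
        for row in draw:
            tag = "".join(bases[row])
            if site in tag or tag in seen:
                continue
            if tag.endswith("C") or tag.endswith("CA"):
                continue
            seen.add(tag)
            tags.append(tag)
            if len(tags) == n_genes:
                break
    return tags


@dataclass
class SimulatedLibrary:
    """One sampled library plus its ground truth."""

    library_id: str
    depth: int
    gene_counts: GeneCounts
    tag_library: TagLibrary | None = None
    reads: list[ConcatemerRead] | None = None
    ditags: list[str] | None = None
    true_tag_counts: Counter | None = None  # pre-duplicate truth
    dedupe_tag_counts: Counter | None = None  # post-dedupe truth


def simulate_library(
    abundances: np.ndarray,
    depth: int,
    seed=0,
    library_id: str = "library",
    gene_ids: Sequence[str] | None = None,
    tag_map: Sequence[str] | None = None,
    emit_concatemers: bool = False,
    duplicate_rate: float = 0.0,
    ditags_per_read: int = 20,
    tag_len: int = 10,
    metadata: dict | None = None,
) -> SimulatedLibrary:
    """Multinomial draw of ``depth`` tags from a transcriptome.

    With ``emit_concatemers`` the sampled tag stream is paired into
    ditags (tag + reverse complement of the next tag), optionally
    duplicated at ``duplicate_rate`` to mimic PCR duplicates, and joined
    into concatemer reads separated by the anchoring site. For an odd
    ``depth`` the unpaired final tag is dropped from both the reads and
    the recorded truth.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(seed)
    n_genes = abundances.size
    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    if not emit_concatemers:
        counts = rng.multinomial(depth, abundances)
        gene_counts = {
            gene_ids[i]: int(c) for i, c in enumerate(counts) if c > 0
        }
        tag_lib = None
        if tag_map is not None:
            tag_lib = TagLibrary(
                library_id=library_id,
                counts=Counter(
                    {tag_map[i]: int(c) for i, c in enumerate(counts) if c > 0}
                ),
                tag_len=tag_len,
                metadata=metadata or {},
            )
        return SimulatedLibrary(
            library_id=library_id,
            depth=depth,
            gene_counts=GeneCounts(library_id=library_id, counts=gene_counts),
            tag_library=tag_lib,
        )

    if tag_map is None:
        raise ValueError("emit_concatemers requires a tag_map")
    stream = rng.choice(n_genes, size=depth, p=abundances)
    if depth % 2:
        stream = stream[:-1]
    tag_stream = [tag_map[i] for i in stream]
    ditags = [
        tag_stream[i] + reverse_complement(tag_stream[i + 1])
        for i in range(0, len(tag_stream), 2)
    ]
    if duplicate_rate > 0:
        dup_mask = rng.random(len(ditags)) < duplicate_rate
        with_dups: list[str] = []
        for d, dup in zip(ditags, dup_mask):
            with_dups.append(d)
            if dup:
                with_dups.append(d)
        ditags_out = with_dups
    else:
        ditags_out = list(ditags)

    true_counts: Counter = Counter(tag_stream)
    dedupe_counts: Counter = Counter()
    for ditag in dict.fromkeys(ditags_out):
        dedupe_counts[ditag[:tag_len]] += 1
        dedupe_counts[reverse_complement(ditag[-tag_len:])] += 1

    reads = []
    for start in range(0, len(ditags_out), ditags_per_read):
        chunk = ditags_out[start: start + ditags_per_read]
        seq = ANCHOR_SITE + ANCHOR_SITE.join(chunk) + ANCHOR_SITE
        reads.append(
            ConcatemerRead(f"{library_id}_read{start // ditags_per_read + 1}", seq)
        )

    gene_counts = {}
    tag_to_gene = {t: gene_ids[i] for i, t in enumerate(tag_map)}
    for tag, c in true_counts.items():
        gene = tag_to_gene[tag]
        gene_counts[gene] = gene_counts.get(gene, 0) + c
    tag_lib = TagLibrary(
        library_id=library_id,
        counts=Counter(true_counts),
        tag_len=tag_len,
        metadata=metadata or {},
    )
    return SimulatedLibrary(
        library_id=library_id,
        depth=depth,
        gene_counts=GeneCounts(library_id=library_id, counts=gene_counts),
        tag_library=tag_lib,
        reads=reads,
        ditags=ditags_out,
        true_tag_counts=true_counts,
        dedupe_tag_counts=dedupe_counts,
    )


def generate_categories(
    gene_ids: Sequence[str],
    sizes: Sequence[int] = DEFAULT_CATEGORY_SIZES,
    target_grid_size: int = DEFAULT_GRID_SIZE,
    seed=0,
    names: Sequence[str] = DEFAULT_CATEGORY_NAMES,
    grid_members: Sequence[str] | None = None,
) -> tuple[FunctionalCategories, set[str]]:
    """Random overlapping categories whose >=2-membership grid has exactly
    ``target_grid_size`` genes.

    Each grid gene receives exactly two category memberships; the
    remaining category capacity is filled with genes holding a single
    membership. ``grid_members`` forces the grid's identity (used by the
    scenario builder to align the grid with planted structure).
    """
    if len(names) != len(sizes):
        raise ValueError("names and sizes length mismatch")
    rng = _rng(seed)
    total_slots = sum(sizes)
    singles_needed = total_slots - 2 * target_grid_size
    if singles_needed < 0:
        raise ValueError("grid larger than category capacity allows")
    if target_grid_size + singles_needed > len(gene_ids):
        raise ValueError("not enough genes for the requested category sizes")

    gene_ids = list(gene_ids)
    if grid_members is None:
        grid = [gene_ids[i] for i in
                rng.choice(len(gene_ids), size=target_grid_size, replace=False)]
    else:
        grid = sorted(grid_members)
        if len(grid) != target_grid_size:
            raise ValueError("grid_members size does not match target_grid_size")
        rng.shuffle(grid)

    remaining = np.array(sizes, dtype=int)
    members: dict[str, set[str]] = {name: set() for name in names}
    for gene in grid:
        # always take the category with most remaining capacity, then a
        # second drawn proportionally to remaining capacity: never strands
        first = int(np.argmax(remaining))
        weights = remaining.astype(float).copy()
        weights[first] = 0.0
        if weights.sum() <= 0:
            raise ValueError("category sizes cannot host the grid")
        second = int(rng.choice(len(names), p=weights / weights.sum()))
        for c in (first, second):
            members[names[c]].add(gene)
            remaining[c] -= 1

    grid_set = set(grid)
    pool = [g for g in gene_ids if g not in grid_set]
    rng.shuffle(pool)
    if singles_needed > len(pool):
        raise ValueError("not enough non-grid genes for single memberships")
    cursor = 0
    for c, name in enumerate(names):
        for _ in range(int(remaining[c])):
            members[name].add(pool[cursor])
            cursor += 1
    categories = FunctionalCategories(categories=members)
    return categories, grid_set


@dataclass
class QpcrTruth:
    ratios: dict[str, float]  # gene -> planted sample/calibrator ratio
    efficiencies: dict[str, float]  # gene -> planted amplification efficiency
    reference_gene: str
    calibrator_id: str


def generate_qpcr(
    ratios: dict[str, float],
    efficiencies: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed=0,
    sample_id: str = "sample",
    calibrator_id: str = "calibrator",
    reference_gene: str = "REF",
    reference_efficiency: float = 2.0,
    base_ct: float = 24.0,
    n_replicates: int = 3,
    dilution_exponents: Sequence[int] = (0, -1, -2, -3, -4),
) -> tuple[list[tuple], list[tuple], QpcrTruth]:
    """Synthetic Ct tables and dilution series for planted expression ratios.

    Ct(sample) = Ct(calibrator) - log(ratio)/log(E); the reference gene
    is expressed equally everywhere. Returns (ct_rows, dilution_rows,
    truth) where ct_rows are (sample_id, gene_id, replicate, Ct) and
    dilution_rows are (gene_id, log10_dilution, Ct).
    """
    if any(r <= 0 for r in ratios.values()):
        raise ValueError("planted ratios must be positive")
    rng = _rng(seed)
    if efficiencies is None:
        efficiencies = {g: 2.0 for g in ratios}
    eff = dict(efficiencies)
    eff[reference_gene] = reference_efficiency

    ct_rows: list[tuple] = []
    dilution_rows: list[tuple] = []
    for gene, e in eff.items():
        slope = -1.0 / np.log10(e)  # negative: Ct rises as template dilutes
        for exp in dilution_exponents:
            ct = base_ct + slope * exp
            ct += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            dilution_rows.append((gene, float(exp), float(ct)))

    def emit(sample: str, gene: str, ct_true: float) -> None:
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            ct_rows.append((sample, gene, rep, float(ct_true + noise)))

    emit(calibrator_id, reference_gene, base_ct)
    emit(sample_id, reference_gene, base_ct)
    for gene, ratio in ratios.items():
        e = eff[gene]
        emit(calibrator_id, gene, base_ct)
        emit(sample_id, gene, base_ct - np.log(ratio) / np.log(e))

    truth = QpcrTruth(
        ratios=dict(ratios),
        efficiencies=eff,
        reference_gene=reference_gene,
        calibrator_id=calibrator_id,
    )
    return ct_rows, dilution_rows, truth


def planted_enriched_subset(
    universe: Sequence[str],
    de_list: set[str],
    size: int,
    hit_rate: float,
    seed=0,
) -> set[str]:
    """A subset of ``universe`` with a planted fraction of DE hits."""
    rng = _rng(seed)
    n_hits = int(round(size * hit_rate))
    de_pool = sorted(set(de_list))
    non_pool = sorted(set(universe) - set(de_list))
    if n_hits > len(de_pool) or size - n_hits > len(non_pool):
        raise ValueError("cannot realize the requested hit rate")
    hits = rng.choice(len(de_pool), size=n_hits, replace=False)
    miss = rng.choice(len(non_pool), size=size - n_hits, replace=False)
    return {de_pool[i] for i in hits} | {non_pool[i] for i in miss}


# ---------------------------------------------------------------------------
# The study-shaped end-to-end scenario


@dataclass
class Scenario:
    """All pipeline inputs for the study-shaped synthetic dataset plus the
    ground-truth ledger."""

    seed: int
    gene_ids: list[str]
    tag_map: list[str]
    met_libraries: list[SimulatedLibrary]
    nm_libraries: list[SimulatedLibrary]
    categories: FunctionalCategories
    grid: set[str]
    metastasis_list: set[str]
    qpcr_ct_rows: list[tuple]
    qpcr_dilution_rows: list[tuple]
    ledger: dict

    def write(self, outdir: str | Path) -> None:
        """Write all inputs as plain-text tables plus ledger.json."""
        from sagesig.sagetags import write_gene_counts

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib in self.met_libraries + self.nm_libraries:
            write_gene_counts(
                lib.gene_counts.counts, outdir / f"{lib.library_id}.genes.tsv"
            )
        with open(outdir / "tag_gene_map.tsv", "w") as fh:
            fh.write("tag\tgene_id\n")
            for tag, gene in zip(self.tag_map, self.gene_ids):
                fh.write(f"{tag}\t{gene}\n")
        with open(outdir / "categories.tsv", "w") as fh:
            fh.write("gene_id\tcategory\n")
            for name, genes in self.categories.categories.items():
                for g in sorted(genes):
                    fh.write(f"{g}\t{name}\n")
        with open(outdir / "metastasis_list.tsv", "w") as fh:
            for g in sorted(self.metastasis_list):
                fh.write(f"{g}\n")
        with open(outdir / "qpcr_ct.tsv", "w") as fh:
            fh.write("sample_id\tgene_id\treplicate\tct\n")
            for sample, gene, rep, ct in self.qpcr_ct_rows:
                fh.write(f"{sample}\t{gene}\t{rep}\t{ct:.6f}\n")
        with open(outdir / "qpcr_dilutions.tsv", "w") as fh:
            fh.write("gene_id\tlog10_dilution\tct\n")
            for gene, log_dil, ct in self.qpcr_dilution_rows:
                fh.write(f"{gene}\t{log_dil:g}\t{ct:.6f}\n")
        (outdir / "ledger.json").write_text(
            json.dumps(self.ledger, indent=2, sort_keys=True) + "\n"
        )


def paper_scenario(
    seed: int = 0,
    n_genes: int = 4200,
    n_de: int = 150,
    fold: float = 8.0,
    n_unique: int = 10,
    min_count: float = 2,
    sigma: float = 1.5,
    outlier_index: int = 1,
    outlier_sd: float = 0.8,
    grid_size: int = DEFAULT_GRID_SIZE,
    n_met_signature: int = 38,
    n_biased_differential: int = 7,
    n_nm_only_signature: int = 17,
) -> Scenario:
    """Build the full study-shaped synthetic dataset.

    Five metastatic libraries share one abundance vector (library
    ``outlier_index`` receives extra multiplicative noise on unplanted
    genes, making it the clustering outlier); two reference libraries
    share a second vector differing by the planted effects. The
    functional-category grid is constructed around the realized common
    core so that the metastatic multifunctional signature and its
    "biased" differential subset are known exactly.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    tag_map = make_tag_map(n_genes, seed=rng)

    base = generate_transcriptome(n_genes, sigma=sigma, seed=rng)
    effects = plant_effects(
        base, n_de=n_de, fold=fold, n_unique=n_unique, seed=rng
    )
    planted_idx = set(
        effects.up_genes + effects.down_genes + effects.unique_genes
    )

    met_libs: list[SimulatedLibrary] = []
    for i, depth in enumerate(MET_DEPTHS):
        abund = effects.met_abundance
        if i == outlier_index:
            jitter = np.exp(rng.normal(0.0, outlier_sd, size=n_genes))
            for idx in planted_idx:
                jitter[idx] = 1.0
            abund = abund * jitter
            abund = abund / abund.sum()
        met_libs.append(
            simulate_library(
                abund, depth, seed=rng, library_id=f"Met{i + 1}",
                gene_ids=gene_ids, tag_map=tag_map,
                metadata={"condition": "metastatic"},
            )
        )
    nm_libs = [
        simulate_library(
            effects.nm_abundance, depth, seed=rng, library_id=f"NM{i + 1}",
            gene_ids=gene_ids, tag_map=tag_map,
            metadata={"condition": "nonmetastatic"},
        )
        for i, depth in enumerate(NM_DEPTHS)
    ]

    # realized expressed structure
    met_counts = [lib.gene_counts for lib in met_libs]
    nm_counts = [lib.gene_counts for lib in nm_libs]
    common_met = common_genes(met_counts, min_count)
    nm_common = common_genes(nm_counts, min_count)
    virtual = make_virtual_library(
        normalize(nm_counts[0]), normalize(nm_counts[1]), library_id="NMvirtual"
    )
    met1_expressed = expressed_genes(met_counts[0], min_count)

    up_ids = [gene_ids[i] for i in effects.up_genes]
    down_ids = [gene_ids[i] for i in effects.down_genes]
    unique_ids = [gene_ids[i] for i in effects.unique_genes]

    # grid construction around the realized core: the metastatic
    # signature (grid & common core) contains the planted unique genes,
    # a chosen number of planted differential genes, and filler core
    # genes shared with the reference side
    unique_in_core = [g for g in unique_ids if g in common_met]
    # restrict the planted "biased differential" picks to genes whose
    # realized counts guarantee comfortable z-test power in every library
    diff_pool = [
        g for g in up_ids + down_ids
        if g in common_met
        and min(c.counts.get(g, 0) for c in met_counts) >= 15
    ]
    rng.shuffle(diff_pool)
    biased_diff = sorted(diff_pool[:n_biased_differential])
    planted_biased = sorted(unique_in_core + biased_diff)
    shared_pool = sorted(
        (common_met & nm_common)
        - set(up_ids) - set(down_ids) - set(unique_ids)
    )
    rng.shuffle(shared_pool)
    n_filler = n_met_signature - len(planted_biased)
    if n_filler < 0 or n_filler > len(shared_pool):
        raise ValueError("cannot realize the requested met-signature size")
    filler = shared_pool[:n_filler]
    met_signature = set(planted_biased) | set(filler)

    nm_only_pool = sorted(nm_common - common_met)
    rng.shuffle(nm_only_pool)
    nm_only = set(nm_only_pool[:n_nm_only_signature])
    outside_pool = sorted(
        set(gene_ids) - common_met - nm_common
    )
    rng.shuffle(outside_pool)
    n_outside = grid_size - len(met_signature) - len(nm_only)
    if n_outside < 0 or n_outside > len(outside_pool):
        raise ValueError("cannot realize the requested grid size")
    grid_members = met_signature | nm_only | set(outside_pool[:n_outside])
    categories, grid = generate_categories(
        gene_ids, target_grid_size=grid_size, seed=rng,
        grid_members=sorted(grid_members),
    )

    # curated "metastasis-associated" list: planted DE genes plus random
    # expressed genes, sized like the literature list
    assoc_pool = sorted(met1_expressed - set(up_ids) - set(down_ids))
    rng.shuffle(assoc_pool)
    metastasis_list = set(up_ids[:40]) | set(down_ids[:30]) | set(assoc_pool[:269])

    # qPCR validation of the planted biased signature
    qpcr_ratios = {}
    for g in planted_biased:
        idx = gene_ids.index(g)
        nm_a = effects.nm_abundance[idx]
        met_a = effects.met_abundance[idx]
        qpcr_ratios[g] = float(met_a / nm_a) if nm_a > 0 else float(fold)
    efficiencies = {
        g: float(rng.uniform(1.85, 2.0)) for g in qpcr_ratios
    }
    ct_rows, dilution_rows, qpcr_truth = generate_qpcr(
        qpcr_ratios, efficiencies, noise_sd=0.0, seed=rng,
        sample_id="Met_pool", calibrator_id="NM_pool",
    )

    ledger = {
        "seed": seed,
        "n_genes": n_genes,
        "depths": {"met": list(MET_DEPTHS), "nm": list(NM_DEPTHS)},
        "min_count": min_count,
        "planted_up": sorted(up_ids),
        "planted_down": sorted(down_ids),
        "planted_unique": sorted(unique_ids),
        "fold": fold,
        "outlier_library": met_libs[outlier_index].library_id,
        "common_met": sorted(common_met),
        "nm_common": sorted(nm_common),
        "met1_expressed": sorted(met1_expressed),
        "grid": sorted(grid),
        "met_signature": sorted(met_signature),
        "nm_signature": sorted(grid & nm_common),
        "planted_biased": planted_biased,
        "planted_biased_unique": sorted(unique_in_core),
        "planted_biased_differential": biased_diff,
        "metastasis_list_size": len(metastasis_list),
        "qpcr_ratios": {g: qpcr_ratios[g] for g in sorted(qpcr_ratios)},
        "qpcr_efficiencies": {
            g: efficiencies[g] for g in sorted(efficiencies)
        },
    }
    return Scenario(
        seed=seed,
        gene_ids=gene_ids,
        tag_map=tag_map,
        met_libraries=met_libs,
        nm_libraries=nm_libs,
        categories=categories,
        grid=grid,
        metastasis_list=metastasis_list,
        qpcr_ct_rows=ct_rows,
        qpcr_dilution_rows=dilution_rows,
        ledger=ledger,
    )
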