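"""End-to-end orchestration from a declarative YAML config.

Stage order: load -> normalize -> virtual reference -> pairwise DE ->
consistent DE -> signatures -> enrichment -> clustering -> qPCR.
Every stage writes its intermediates under the output directory and the
consolidated report records counts, percentages (recomputable from the
counts), seeds and parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from sagesig import __version__
from sagesig.clustering import (
    GeneExpressionTable,
    correlation_distance,
    farthest_pair,
    hierarchical_cluster,
    write_distance_matrix,
)
from sagesig.diffexpr import (
    cluster_size_bias,
    consistent_de,
    pairwise_de,
    write_de_table,
)
from sagesig.enrichment import run_enrichment
from sagesig.libnorm import make_virtual_library, normalize
from sagesig.qpcr import fit_standard_curve, pfaffl_ratio, summarize_replicates
from sagesig.sagetags import read_gene_counts
from sagesig.signatures import (
    annotate_subset,
    build_grid,
    build_signature_report,
    expressed_genes,
    format_percentage,
    read_categories,
    read_gene_list,
    write_gene_list,
)

logger = logging.getLogger("sagesig")

DEFAULT_PARAMS = {
    "min_count": 2,
    "alpha": 0.05,
    "normalization_target": 100000.0,
    # raw: z-tests on raw counts with true library totals (statistically
    # correct variance); normalized: counts and totals on the common scale
    "ztest_totals": "raw",
    "consistency": "per_library",
    "nm_expressed": "common",
    "min_categories": 2,
    "iterations": 100000,
    "seed": 0,
    "linkage": "average",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    return validate_config(config, base_dir=Path(path).parent)


def validate_config(config: dict, base_dir: Path | None = None) -> dict:
    inputs = dict(config.get("inputs", {}))
    params = {**DEFAULT_PARAMS, **(config.get("params") or {})}
    if base_dir is not None:
        for key, value in inputs.items():
            if isinstance(value, list):
                inputs[key] = [str((base_dir / v)) for v in value]
            elif isinstance(value, str):
                inputs[key] = str(base_dir / value)
    for key in ("met_libraries", "nm_libraries"):
        if key not in inputs or not inputs[key]:
            raise ValueError(f"config missing inputs.{key}")
    if len(inputs["nm_libraries"]) != 2:
        raise ValueError("exactly two reference libraries are required")
    for key, value in inputs.items():
        paths = value if isinstance(value, list) else [value]
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"inputs.{key}: missing file {p}")
    if not 0 <= params["alpha"] <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if params["min_count"] < 0 or params["iterations"] < 1:
        raise ValueError("invalid min_count or iterations")
    if params["ztest_totals"] not in ("raw", "normalized"):
        raise ValueError("ztest_totals must be raw or normalized")
    return {"inputs": inputs, "params": params}


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", stage, dt)
            else:
                logger.error("stage %s: failed after %.2fs", stage, dt)
            return False

    return _Timer()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute all stages; returns the consolidated report dict."""
    config = validate_config(config)
    inputs, params = config["inputs"], config["params"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    target = float(params["normalization_target"])
    min_count = params["min_count"]
    alpha = params["alpha"]
    report: dict = {
        "provenance": {
            "version": __version__,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True).encode()
            ).hexdigest(),
            "params": params,
        }
    }

    try:
        with _timed("load"):
            met = [read_gene_counts(p) for p in inputs["met_libraries"]]
            nm = [read_gene_counts(p) for p in inputs["nm_libraries"]]
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    try:
        with _timed("normalize"):
            met_norm = [normalize(lib, target) for lib in met]
            nm_norm = [normalize(lib, target) for lib in nm]
            virtual = make_virtual_library(*nm_norm, library_id="NMvirtual")
            report["normalize"] = {
                "target": target,
                "source_totals": {
                    lib.library_id: lib.source_total
                    for lib in met_norm + nm_norm
                },
                "virtual_total": virtual.total,
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("normalize", exc) from exc

    raw_mode = params["ztest_totals"] == "raw"
    met_for_test = met if raw_mode else met_norm
    ref = met_for_test[0]
    ref_id = met[0].library_id

    try:
        with _timed("pairwise_de"):
            de_lists: dict[str, set[str]] = {}
            pairwise_summary = {}
            for other, other_raw in zip(met_for_test[1:], met[1:]):
                other_id = other_raw.library_id
                results = pairwise_de(
                    ref, other, alpha=alpha, min_count=min_count
                )
                key = f"{ref_id}_vs_{other_id}"
                write_de_table(results, outdir / f"de_{key}.tsv")
                sig = {r.gene_id for r in results if r.significant}
                de_lists[key] = sig
                bias = cluster_size_bias(
                    met_norm[0].counts,
                    sig,
                    universe={r.gene_id for r in results},
                )
                pairwise_summary[key] = {
                    "tested": len(results),
                    "significant": len(sig),
                    "mean_count_de": bias.mean_de,
                    "mean_count_non_de": bias.mean_non_de,
                }
            report["pairwise_de"] = pairwise_summary
    except Exception as exc:  # noqa: BLE001
        raise StageError("pairwise_de", exc) from exc

    try:
        with _timed("consistent_de"):
            consistent = consistent_de(
                met_for_test,
                virtual,
                alpha=alpha,
                min_count=min_count,
                consistency=params["consistency"],
                met_ids=[lib.library_id for lib in met],
            )
            write_gene_list(consistent.up_genes, outdir / "consistent_up.tsv")
            write_gene_list(consistent.down_genes, outdir / "consistent_down.tsv")
            report["consistent_de"] = {
                "up": len(consistent.up_genes),
                "down": len(consistent.down_genes),
                "unique_up": len(consistent.unique_up),
                "total": len(consistent.up_genes) + len(consistent.down_genes),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("consistent_de", exc) from exc

    try:
        with _timed("signatures"):
            if "categories" not in inputs:
                raise ValueError("inputs.categories is required for signatures")
            categories = read_categories(inputs["categories"])
            grid = build_grid(categories, params["min_categories"])
            sig_report = build_signature_report(
                met_for_test,
                virtual,
                grid,
                consistent,
                min_count=min_count,
                nm_expressed_mode=params["nm_expressed"],
                nm_component_libs=nm if raw_mode else nm_norm,
            )
            sig_report.to_json(outdir / "signature_report.json")
            for name in ("met_signature", "nm_signature", "unique_met",
                         "unique_nm", "shared"):
                write_gene_list(getattr(sig_report, name), outdir / f"{name}.tsv")
            counts = sig_report.to_dict()["counts"]
            report["signatures"] = {
                "counts": counts,
                "percent_common_de": format_percentage(
                    report["consistent_de"]["total"], counts["common_met"]
                ) if counts["common_met"] else None,
                "percent_signature_biased": sig_report.biased_fraction_percent,
                "biased_signature": [
                    {"gene_id": g, "status": s}
                    for g, s in sig_report.biased_signature
                ],
            }
            if "metastasis_list" in inputs:
                assoc = read_gene_list(inputs["metastasis_list"])
                report["signatures"]["metastasis_list_overlap"] = annotate_subset(
                    sig_report, assoc, "metastasis_associated"
                )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("signatures", exc) from exc

    try:
        with _timed("enrichment"):
            universe = expressed_genes(ref, min_count)
            subsets = {"multifunctional": grid & universe}
            if "metastasis_list" in inputs:
                subsets["metastasis_associated"] = assoc & universe
            enrichment_report = {}
            seed = int(params["seed"])
            for sub_name, subset in subsets.items():
                if not subset:
                    continue
                per_comparison = {}
                for i, (key, de_list) in enumerate(sorted(de_lists.items())):
                    result = run_enrichment(
                        universe,
                        subset,
                        de_list & universe,
                        iterations=int(params["iterations"]),
                        seed=seed + i,
                    )
                    result.to_json(outdir / f"enrichment_{sub_name}_{key}.json")
                    per_comparison[key] = {
                        "observed_hits": result.observed_hits,
                        "observed_ratio": result.observed_ratio,
                        "baseline_ratio": result.simulated_baseline_ratio,
                        "p_binomial": result.p_binomial,
                    }
                enrichment_report[sub_name] = {
                    "subset_size": len(subset),
                    "comparisons": per_comparison,
                }
            report["enrichment"] = enrichment_report
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrichment", exc) from exc

    try:
        with _timed("clustering"):
            table = GeneExpressionTable.from_libraries(met_norm)
            dist = correlation_distance(table, min_count=min_count)
            dendro = hierarchical_cluster(
                dist, table.libraries, linkage=params["linkage"]
            )
            newick = dendro.to_newick()
            (outdir / "clustering.nwk").write_text(newick + "\n")
            write_distance_matrix(dist, table.libraries, outdir / "distances.tsv")
            pair = farthest_pair(dendro)
            report["clustering"] = {
                "linkage": params["linkage"],
                "newick": newick,
                "farthest_pair": list(pair),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("clustering", exc) from exc

    if "qpcr_ct" in inputs and "qpcr_dilutions" in inputs:
        try:
            with _timed("qpcr"):
                report["qpcr"] = run_qpcr_stage(
                    inputs["qpcr_ct"], inputs["qpcr_dilutions"], outdir
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError("qpcr", exc) from exc

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "report.txt").write_text(render_text_report(report))
    return report


def run_qpcr_stage(
    ct_path: str | Path,
    dilution_path: str | Path,
    outdir: Path,
    reference_gene: str = "REF",
    calibrator_id: str = "NM_pool",
) -> dict:
    """Fit standard curves and compute efficiency-corrected ratios for
    every (sample, gene) against the calibrator sample."""
    dilutions: dict[str, list[tuple[float, float]]] = {}
    with open(dilution_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("gene_id") or line.startswith("#"):
                continue
            gene, log_dil, ct = line.split("\t")
            dilutions.setdefault(gene, []).append((float(log_dil), float(ct)))
    curves = {
        gene: fit_standard_curve(points, gene_id=gene)
        for gene, points in dilutions.items()
    }

    cts: dict[tuple[str, str], list[float]] = {}
    with open(ct_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("sample_id") or line.startswith("#"):
                continue
            sample, gene, _rep, ct = line.split("\t")
            cts.setdefault((sample, gene), []).append(float(ct))
    means = {key: summarize_replicates(v).mean_ct for key, v in cts.items()}

    if reference_gene not in curves:
        raise ValueError(f"no dilution series for reference gene {reference_gene!r}")
    samples = sorted({s for s, _ in cts} - {calibrator_id})
    genes = sorted({g for _, g in cts} - {reference_gene})
    rows = []
    for sample in samples:
        for gene in genes:
            if (sample, gene) not in means or (calibrator_id, gene) not in means:
                continue
            result = pfaffl_ratio(
                curves[gene].efficiency,
                means[(calibrator_id, gene)],
                means[(sample, gene)],
                curves[reference_gene].efficiency,
                means[(calibrator_id, reference_gene)],
                means[(sample, reference_gene)],
                gene_id=gene,
                sample_id=sample,
                calibrator_id=calibrator_id,
            )
            rows.append(result)
    with open(outdir / "qpcr_ratios.tsv", "w") as fh:
        fh.write("sample_id\tgene_id\tratio\tdelta_ct_target\tdelta_ct_ref\n")
        for r in rows:
            fh.write(
                f"{r.sample_id}\t{r.gene_id}\t{r.ratio:.6g}\t"
                f"{r.delta_ct_target:.6g}\t{r.delta_ct_ref:.6g}\n"
            )
    return {
        "efficiencies": {g: c.efficiency for g, c in sorted(curves.items())},
        "ratios": {
            f"{r.sample_id}:{r.gene_id}": r.ratio for r in rows
        },
    }


def render_text_report(report: dict) -> str:
    lines = [f"sagesig pipeline report (v{report['provenance']['version']})", ""]
    if "normalize" in report:
        lines.append(f"normalization target: {report['normalize']['target']:g}")
    if "consistent_de" in report:
        de = report["consistent_de"]
        lines.append(
            f"consistently differential genes: {de['total']} "
            f"({de['up']} up, {de['down']} down, {de['unique_up']} unique)"
        )
    if "signatures" in report:
        sig = report["signatures"]
        counts = sig["counts"]
        lines.append(
            f"common core {counts['common_met']} genes; grid {counts['grid']}; "
            f"signature {counts['met_signature']}; biased {counts['biased_signature']}"
        )
        if sig.get("percent_common_de") is not None:
            lines.append(f"core differential: {sig['percent_common_de']}%")
        if sig.get("percent_signature_biased") is not None:
            lines.append(f"signature differential: {sig['percent_signature_biased']}%")
    if "clustering" in report:
        pair = report["clustering"]["farthest_pair"]
        lines.append(f"farthest libraries: {pair[0]} vs {pair[1]}")
    if "enrichment" in report:
        for name, entry in sorted(report["enrichment"].items()):
            for key, comp in sorted(entry["comparisons"].items()):
                lines.append(
                    f"enrichment {name} {key}: hits {comp['observed_hits']}"
                    f"/{entry['subset_size']} baseline {comp['baseline_ratio']:.4f}"
                    f" p={comp['p_binomial']:.3g}"
                )
    return "\n".join(lines) + "\n"
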