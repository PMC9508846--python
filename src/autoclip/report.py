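"""End-to-end orchestration: from an input bundle to a machine-readable report.

The pipeline mirrors the analysis order of the underlying study: call
interactions per dataset (method/peak-caller combination), rank each RBP's
own mRNA among its targets, evaluate autogenous enrichment under both null
frameworks, trace enrichment against stringency, summarize genomic-context
preference, and - when sequences and an affinity scale are available -
score mRNA-protein complementarity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats as sstats

from . import __version__
from .core_io import (
    InteractionMatrix,
    NullConfig,
    read_affinity_scale,
    read_curation,
    read_expression,
    read_peaks,
    read_residue_scale,
    read_sequences,
    read_transcript_models,
)
from .interactions import call_interactions, own_mrna_rank, support_index
from .context import cds_preference_test, context_profile
from .complementarity import (
    affinity_profile,
    density_profile,
    estat_scan,
    profile_scan,
    randomized_background,
)
from .null_models import autogenous_enrichment, enrichment_vs_stringency

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: input bundle, output directory, null settings."""

    input_dir: str | Path
    output_dir: str | Path
    exclude_overexpressed: bool = True
    null: NullConfig = field(default_factory=NullConfig)
    #: size of the cellular mRNA pool; None = number of annotated genes
    total_genes: int | None = None
    q_grid: tuple = tuple(range(0, 100, 10))
    rng_seed: int = 0
    profile_window: int = 63
    min_context_pairs: int = 10


def load_run_config(path: str | Path, input_dir=None, output_dir=None) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Recognized keys: input_dir, output_dir, exclude_overexpressed, seed,
    total_genes, q_grid, profile_window, min_context_pairs, and a
    ``null_model`` sub-mapping with NullConfig fields (a bare ``null`` key is
    accepted too, although YAML parses it as the null scalar).  Explicit
    ``input_dir``/``output_dir`` arguments override the file.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    null_fields = raw.pop("null_model", None)
    if null_fields is None:
        null_fields = raw.pop(None, None) or raw.pop("null", None) or {}
    null = NullConfig(**null_fields)
    seed = raw.pop("seed", 0)
    return RunConfig(
        input_dir=input_dir or raw.pop("input_dir"),
        output_dir=output_dir or raw.pop("output_dir"),
        null=null,
        rng_seed=seed,
        **raw,
    )


#: minimal structural schema of the report (section -> required keys)
REPORT_SCHEMA = {
    "meta": ["version", "seed", "input_checksums"],
    "datasets": ["incidence", "ranks", "enrichment", "stringency"],
}


def validate_report(report: dict) -> None:
    """Structural validation of a pipeline report against REPORT_SCHEMA."""
    for key in REPORT_SCHEMA["meta"]:
        if key not in report.get("meta", {}):
            raise ValueError(f"report.meta missing {key!r}")
    if "datasets" not in report:
        raise ValueError("report missing datasets section")
    for name, section in report["datasets"].items():
        if "error" in section or "excluded" in section:
            continue
        for key in REPORT_SCHEMA["datasets"]:
            if key not in section:
                raise ValueError(f"dataset {name} missing {key!r}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _summary_dict(summary) -> dict:
    return {
        "framework": summary.framework,
        "observed_k": summary.observed_k,
        "expected_k": summary.expected_k,
        "sd": summary.sd,
        "ratio": summary.ratio,
        "percentile_rank": summary.percentile_rank,
        "p_value": summary.p_value,
        "n_pairs": summary.n_pairs,
    }


def _dataset_section(
    matrix: InteractionMatrix,
    config: RunConfig,
    rng: np.random.Generator,
    models,
    peaks,
) -> dict:
    section: dict = {}
    cells = matrix.autogenous_cells()
    observed = matrix.observed_autogenous()
    section["incidence"] = {
        "n_rbps": len(matrix.rbp_ids),
        "n_genes_bound": int((matrix.row_margins > 0).sum()),
        "n_autogenous_eligible": len(cells),
        "observed_autogenous": observed,
        "autogenous_fraction": observed / len(cells) if cells else np.nan,
    }

    ranks = {}
    auto_rbps = [
        matrix.rbp_ids[j] for i, j in cells if matrix.incidence[i, j]
    ]
    for metric in ("density", "score"):
        rows = []
        for rbp in auto_rbps:
            result = own_mrna_rank(matrix, rbp, metric)
            if result.n_targets >= 2:
                rows.append(
                    {"rbp_id": rbp, "percentile_rank": result.percentile_rank,
                     "n_targets": result.n_targets}
                )
        ranks[metric] = {
            "per_rbp": rows,
            "median": float(np.median([r["percentile_rank"] for r in rows]))
            if rows
            else np.nan,
        }
    section["ranks"] = ranks

    section["enrichment"] = {
        fw: _summary_dict(autogenous_enrichment(matrix, fw, config.null, rng))
        for fw in ("protein_centric", "symmetric")
    }
    section["stringency"] = [
        {
            "q": point.q,
            "observed_k": point.observed_k,
            "expected_k": point.expected_k,
            "ratio": point.ratio,
        }
        for point in enrichment_vs_stringency(
            matrix, "density", "protein_centric", config.q_grid, config.null, rng
        )
    ]

    # genomic-context preference of autogenous binding
    auto_profiles, ref_profiles = [], []
    by_gene: dict[str, list] = {}
    for peak in peaks:
        by_gene.setdefault(peak.rbp_id, []).append(peak)
    for i, j in cells:
        if not matrix.incidence[i, j]:
            continue
        gene = matrix.gene_ids[i]
        model = models[gene]
        rbp = matrix.rbp_ids[j]
        gene_peaks = [p for p in peaks if p.interval.overlaps(model.span)]
        try:
            auto = context_profile(gene_peaks, model, rbp)
        except ValueError:
            continue
        others = []
        for other in {p.rbp_id for p in gene_peaks} - {rbp}:
            try:
                others.append(context_profile(gene_peaks, model, other).as_array())
            except ValueError:
                continue
        if not others:
            continue
        auto_profiles.append(auto.as_array())
        ref_profiles.append(np.mean(others, axis=0))
    ctx: dict = {"n_pairs": len(auto_profiles)}
    if auto_profiles:
        ctx["mean_autogenous"] = np.mean(auto_profiles, axis=0).tolist()
        ctx["mean_reference"] = np.mean(ref_profiles, axis=0).tolist()
    if len(auto_profiles) >= config.min_context_pairs:
        ctx["cds_preference"] = cds_preference_test(
            [p[1] for p in auto_profiles],
            [p[1] for p in ref_profiles],
            config.min_context_pairs,
        )
    section["context"] = ctx
    return section


def _complementarity_section(
    bundle: Path, matrices: dict, config: RunConfig, rng: np.random.Generator
) -> dict:
    scale_path = bundle / "scale.tsv"
    mrna_path = bundle / "mrna.fasta"
    protein_path = bundle / "protein.fasta"
    if not (scale_path.exists() and mrna_path.exists() and protein_path.exists()):
        return {"skipped": "sequences or affinity scale not provided"}
    scale = read_affinity_scale(scale_path)
    residue_path = bundle / "residue_scale.tsv"
    residue_scalar = read_residue_scale(residue_path) if residue_path.exists() else None
    mrnas = read_sequences(mrna_path)
    proteins = read_sequences(protein_path, rna=False)
    models = read_transcript_models(bundle / "models.tsv")

    rbp_genes = sorted(
        {r for m in matrices.values() for r in m.rbp_ids if r in proteins}
    )
    rows = []
    for gene in rbp_genes:
        if gene not in mrnas or gene not in models:
            continue
        protein, mrna = proteins[gene], mrnas[gene]
        model = models[gene]
        cds_offset = model.length("utr5")
        if model.length("cds") < 3 * len(protein):
            continue
        scan = estat_scan(protein, mrna, cds_offset, scale)
        bg = randomized_background(
            protein, scan.cds_value, None, 1000, scale, rng
        )
        row = {
            "gene_id": gene,
            "estat_cds": scan.cds_value,
            "estat_cds_rank": scan.cds_rank,
            "n_offsets": len(scan.offsets),
            "background_z": bg.z,
        }
        if residue_scalar is not None and len(mrna) > config.profile_window:
            mp = density_profile(mrna, ("C", "U"), config.profile_window)
            pp = affinity_profile(protein, residue_scalar, config.profile_window)
            if len(pp) < len(mp):
                pscan = profile_scan(mp, pp, cds_offset)
                row["profile_r_cds"] = pscan.cds_value
                row["profile_cds_rank"] = pscan.cds_rank
        rows.append(row)
    out: dict = {"per_rbp": rows, "n_rbps": len(rows)}
    if rows:
        out["median_cds_rank"] = float(np.median([r["estat_cds_rank"] for r in rows]))
        out["median_background_z"] = float(np.median([r["background_z"] for r in rows]))
        r_values = [r["profile_r_cds"] for r in rows if "profile_r_cds" in r]
        if r_values:
            out["mean_profile_r_cds"] = float(np.mean(r_values))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis on a bundle directory and write report.json.

    Any stage failure is captured in the report's error section; the report
    is still written and the exception re-raised by the CLI as a nonzero
    exit.  A fixed seed makes the report byte-identical across runs.
    """
    bundle = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.rng_seed)

    curation_path = bundle / "curation.tsv"
    curation = read_curation(curation_path) if curation_path.exists() else {}
    models = read_transcript_models(bundle / "models.tsv")
    config = replace(
        config,
        null=replace(
            config.null, total_genes=config.total_genes or len(models)
        ),
    )

    peak_files = sorted(bundle.glob("peaks_*.bed"))
    report: dict = {
        "meta": {
            "version": __version__,
            "seed": config.rng_seed,
            "exclude_overexpressed": config.exclude_overexpressed,
            "input_checksums": {f.name: _checksum(f) for f in sorted(bundle.iterdir()) if f.is_file()},
        },
        "datasets": {},
    }

    datasets = {}
    for path in peak_files:
        dataset_id = path.stem.removeprefix("peaks_")
        flagged = curation.get(dataset_id, False)
        if config.exclude_overexpressed and flagged:
            report["datasets"][dataset_id] = {
                "excluded": "overexpressed dataset excluded from analysis"
            }
            continue
        datasets[dataset_id] = read_peaks(path, dataset_id, flagged)
    if not datasets:
        logger.warning("no datasets left after overexpression filtering")

    matrices = {}
    child_seeds = ss.spawn(len(datasets) + 2)
    for (dataset_id, peaks), child in zip(sorted(datasets.items()), child_seeds):
        rng = np.random.default_rng(child)
        try:
            matrix = call_interactions(peaks, models)
            matrices[dataset_id] = matrix
            report["datasets"][dataset_id] = _dataset_section(
                matrix, config, rng, models, peaks
            )
        except Exception as err:  # capture stage failure, keep going
            logger.exception("dataset %s failed", dataset_id)
            report["datasets"][dataset_id] = {"error": str(err)}

    # interaction support index for autogenous pairs studied in >= 2 datasets
    if len(matrices) >= 2:
        isi_rows = []
        rbps = sorted({r for m in matrices.values() for r in m.rbp_ids})
        for rbp in rbps:
            studied = [m for m in matrices.values() if rbp in m.rbp_ids]
            if len(studied) < 2:
                continue
            gene = studied[0].rbp_gene.get(rbp, rbp)
            si = support_index(gene, rbp, matrices)
            isi_rows.append(
                {"rbp_id": rbp, "isi": si.isi, "n_methods": si.n_methods_studied}
            )
        supported = sum(r["isi"] > 0 for r in isi_rows)
        report["isi"] = {
            "per_rbp": isi_rows,
            "fraction_supported": supported / len(isi_rows) if isi_rows else np.nan,
        }

    try:
        report["complementarity"] = _complementarity_section(
            bundle, matrices, config, np.random.default_rng(child_seeds[-1])
        )
    except Exception as err:
        logger.exception("complementarity stage failed")
        report["complementarity"] = {"error": str(err)}

    # raw p-values are primary; Benjamini-Hochberg adjusted reported alongside
    names, pvals = [], []
    for name, section in report["datasets"].items():
        p = (
            section.get("enrichment", {})
            .get("protein_centric", {})
            .get("p_value")
        )
        if p is not None:
            names.append(name)
            pvals.append(p)
    if pvals:
        adjusted = sstats.false_discovery_control(pvals, method="bh")
        report["multiple_testing"] = {
            "method": "benjamini_hochberg",
            "adjusted_p": dict(zip(names, adjusted.tolist())),
        }

    validate_report(report)
    out_path = outdir / "report.json"
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
    logger.info("report written to %s", out_path)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
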