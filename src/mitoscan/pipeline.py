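"""End-to-end orchestration: inputs -> network -> scan -> reports.

The pipeline mirrors the analysis workflow for matrilineal cohort data:

1. read per-subject variant tables (resolving heteroplasmy by majority),
2. collapse subjects into distinct haplotypes,
3. impute haplotypes to ungenotyped matriline members via the pedigree,
4. compute familial-risk covariates,
5. build the haplotype network and its branch partitions,
6. permutation-scan all eligible branches (without and, optionally, with
   the familial-risk covariate) plus conditional follow-up rounds,
7. emit publication-shaped tables, the network, and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .network import build_network, enumerate_partitions, export_edge_tsv, export_graphml, loop_count
from .pedigree import Pedigree, familial_risk_table, matriline_of, impute_haplotypes, read_pedigree
from .reference import ReferenceSequence, load_packaged_reference, read_fasta, toy_reference
from .report import demographics_table, scan_table
from .simulate import SimParams, simulate_cohort
from .treescan import ScanConfig, ScanResult, permutation_scan, scan_rounds
from .variants import Haplotype, collapse_haplotypes, read_variant_table

logger = logging.getLogger("mitoscan")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def resolve_reference(spec: Union[str, int, None]) -> ReferenceSequence:
    """Reference from a config value: 'packaged', an int (toy length), or a FASTA path."""
    if spec is None or spec == "packaged":
        return load_packaged_reference()
    if isinstance(spec, int):
        return toy_reference(length=spec)
    return read_fasta(spec)


def assemble_subjects(
    subject_variants: dict,
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    conflict: str = "abort",
) -> tuple[pd.DataFrame, list[Haplotype], dict]:
    """Collapse, impute along matrilines, and attach covariates.

    Returns (subjects table, haplotypes with post-imputation carrier counts,
    info dict with counts and imputation log). The subjects table holds one
    row per phenotype-table subject with columns ``haplotype`` (NaN when
    unassigned), ``imputed``, ``matriline``, familial-risk columns, and the
    phenotype/covariate columns.
    """
    haps_genotyped, assignment = collapse_haplotypes(subject_variants)
    extended, imputed_flag, log = impute_haplotypes(assignment, pedigree, conflict=conflict)

    subjects = phenotypes.copy()
    subjects["subject_id"] = subjects["subject_id"].astype(str)
    subjects["haplotype"] = subjects["subject_id"].map(extended)
    subjects["imputed"] = subjects["subject_id"].map(
        lambda s: bool(imputed_flag.get(s, False))
    )
    subjects["matriline"] = [
        matriline_of(s, pedigree) if s in pedigree else None
        for s in subjects["subject_id"]
    ]

    fr = familial_risk_table(pedigree, subjects["subject_id"].tolist())
    subjects = subjects.merge(fr, on="subject_id", how="left")

    counts = subjects["haplotype"].value_counts()
    haplotypes = [
        Haplotype(h.id, h.variants, carrier_count=int(counts.get(h.id, h.carrier_count)))
        for h in haps_genotyped
    ]
    info = {
        "n_subjects": len(subjects),
        "n_genotyped": len(assignment),
        "n_imputed": int(subjects["imputed"].sum()),
        "n_unassigned": int(subjects["haplotype"].isna().sum()),
        "n_haplotypes": len(haplotypes),
        "imputation_log": log,
    }
    return subjects, haplotypes, info


def run_pipeline(
    config: dict,
    outdir: Union[str, Path],
    seed: Optional[int] = None,
) -> dict:
    """Run the full analysis described by a config mapping; return a summary.

    Config keys: ``simulate`` (SimParams fields; optional) or ``inputs``
    (variants, pedigree, flags, phenotypes, reference), ``scan`` (ScanConfig
    fields plus ``familial_risk``: none|both|only and ``rounds``: bool),
    ``max_steps``, ``conflict``. ``seed`` overrides both the simulation and
    scan seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    started = datetime.now(timezone.utc).isoformat()
    input_paths: dict[str, Path] = {}

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"] or {})
        if seed is not None:
            sim_kwargs["seed"] = seed
        if str(sim_kwargs.get("beta", "")).lower() in ("-inf", "-infinity"):
            sim_kwargs["beta"] = -np.inf
        if sim_kwargs.get("effect_clade") is not None:
            sim_kwargs["effect_clade"] = tuple(sim_kwargs["effect_clade"])
        params = SimParams(**sim_kwargs)
        cohort = simulate_cohort(params)
        input_paths = cohort.write(outdir / "inputs")
        reference = cohort.reference
        log(f"simulated cohort: {len(cohort.subjects)} subjects, "
            f"{cohort.truth['n_distinct_haplotypes']} haplotypes, "
            f"{cohort.truth['n_segregating_sites']} segregating sites")
    else:
        inputs = config["inputs"]
        for key in ("variants", "pedigree", "phenotypes"):
            if key not in inputs:
                raise KeyError(f"config inputs missing {key!r}")
            input_paths[key] = Path(inputs[key])
        if "flags" in inputs:
            input_paths["flags"] = Path(inputs["flags"])
        reference = resolve_reference(inputs.get("reference"))

    subject_variants = read_variant_table(
        input_paths["variants"], reference,
        exclude_windows=[tuple(w) for w in config.get("exclude_windows", [])],
    )
    pedigree = read_pedigree(input_paths["pedigree"], flags=input_paths.get("flags"))
    phenotypes = pd.read_csv(input_paths["phenotypes"], sep="\t",
                             dtype={"subject_id": str})

    subjects, haplotypes, info = assemble_subjects(
        subject_variants, pedigree, phenotypes, conflict=config.get("conflict", "abort")
    )
    log(f"assembled {info['n_subjects']} subjects: {info['n_genotyped']} genotyped, "
        f"{info['n_imputed']} imputed, {info['n_unassigned']} unassigned; "
        f"{info['n_haplotypes']} haplotypes")

    network = build_network(haplotypes, max_steps=config.get("max_steps"))
    partitions = enumerate_partitions(network)
    log(f"network: {network.graph.number_of_nodes()} nodes, "
        f"{network.graph.number_of_edges()} edges, {loop_count(network)} loops, "
        f"{len(partitions)} branch partitions")

    scan_cfg_raw = dict(config.get("scan", {}))
    familial_mode = scan_cfg_raw.pop("familial_risk", "both")
    do_rounds = scan_cfg_raw.pop("rounds", True)
    if seed is not None:
        scan_cfg_raw["seed"] = seed
    if "covariates" in scan_cfg_raw:
        scan_cfg_raw["covariates"] = tuple(scan_cfg_raw["covariates"])
    cfg = ScanConfig(**scan_cfg_raw)

    fr_covariates = tuple(cfg.covariates) + ("familial_risk", "familial_risk_missing")
    results: list[ScanResult] = []
    results_fr: list[ScanResult] = []
    if familial_mode in ("none", "both"):
        scan_fn = scan_rounds if do_rounds else permutation_scan
        results = list(scan_fn(network, subjects, cfg, partitions=partitions))
    if familial_mode in ("only", "both"):
        cfg_fr = ScanConfig(**{**scan_cfg_raw, "covariates": fr_covariates})
        results_fr = list(permutation_scan(network, subjects, cfg_fr, partitions=partitions))
    primary = results if results else results_fr

    eligible = [r for r in primary if not r.degenerate and r.round == 1]
    significant = [r for r in eligible if r.corrected_p < cfg.alpha]
    log(f"round 1: {len(eligible)} branches tested, {len(significant)} significant "
        f"at corrected p < {cfg.alpha}")

    fr_by_branch = {r.branch_id: r for r in results_fr if r.round == 1}
    table = scan_table([r for r in primary], with_familial=fr_by_branch if results_fr else None)
    table.to_csv(outdir / "scan_results.tsv", sep="\t", index=False)
    demo = demographics_table(subjects, significant, partitions)
    demo.to_csv(outdir / "demographics.tsv", sep="\t", index=False)
    subjects.to_csv(outdir / "subjects.tsv", sep="\t", index=False, float_format="%.6f")
    export_graphml(network, outdir / "network.graphml")
    export_edge_tsv(network, outdir / "network_edges.tsv")
    fr_table = subjects[["subject_id", "matriline", "familial_risk", "familial_risk_missing"]]
    fr_table.to_csv(outdir / "familial_risk.tsv", sep="\t", index=False, float_format="%.6f")

    manifest = {
        "config": _jsonable(config),
        "seed": seed,
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in input_paths.items()},
        "versions": {
            "mitoscan": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "outdir": outdir,
        "network": network,
        "partitions": partitions,
        "subjects": subjects,
        "results": primary,
        "results_familial": results_fr,
        "significant": significant,
        "info": info,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and np.isinf(obj):
        return "-inf" if obj < 0 else "inf"
    if isinstance(obj, Path):
        return str(obj)
    return obj
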