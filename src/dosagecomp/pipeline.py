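"""End-to-end pipeline driver with reproducible run manifests.

Orchestrates simulate -> integrate -> attenuate-strains ->
attenuate-genes -> trans (-> turnover when SILAC data is provided) as an
explicit two-pass design: the CN-mRNA mismatch filter triggers a
recomputation of the relative matrices, and protein-level reversion flags
feed back into the gene-level regressions.  Every run writes a JSON
manifest with the parameter snapshot, seed, stage timings and SHA-256
digests of all outputs; identical inputs and seed reproduce identical
digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genes as genes_mod
from . import integrate as integrate_mod
from . import strains as strains_mod
from . import trans as trans_mod
from . import turnover as turnover_mod
from .datatypes import Parameters
from .io import (
    read_annotation,
    read_expression_matrix,
    read_karyotypes,
    read_silac_table,
    write_annotation,
    write_expression_matrix,
    write_karyotypes,
    write_table,
)
from .simulate import CohortSpec, simulate_cohort

log = logging.getLogger("dosagecomp")

STAGES = ("simulate", "integrate", "attenuate-strains", "attenuate-genes",
          "trans", "turnover")


class StageError(RuntimeError):
    """Raised when a stage's required inputs are missing."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(out_dir, params: Parameters | None = None,
                 spec: CohortSpec | None = None,
                 stages=STAGES, seed: int | None = None,
                 inputs: dict | None = None) -> dict:
    """Run the selected stages in dependency order; return the manifest.

    With the ``simulate`` stage selected, a synthetic cohort is written to
    ``out_dir`` and used downstream; otherwise ``inputs`` must name the
    mRNA/protein/karyotype/annotation (and optionally SILAC) files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or Parameters()
    if seed is None:
        seed = params.rng_seed
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise StageError(f"unknown stages {sorted(unknown)}")
    inputs = dict(inputs or {})
    manifest: dict = {
        "seed": seed,
        "parameters": params.as_dict(),
        "stages": [],
        "outputs": {},
        "input_digests": {},
    }
    for key, path in inputs.items():
        manifest["input_digests"][key] = _sha256(Path(path))

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)

    def timed(stage: str, fn) -> None:
        t0 = time.perf_counter()
        fn()
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.perf_counter() - t0, 3)}
        )

    state: dict = {}

    def stage_simulate() -> None:
        cohort = simulate_cohort(spec or CohortSpec(seed=seed))
        state["cohort"] = cohort
        comments = [f"simulated cohort, seed {cohort.spec.seed}"]
        emit("annotation.tsv", lambda p: write_annotation(cohort.annotation, p, comments))
        emit("karyotypes.tsv", lambda p: write_karyotypes(cohort.karyotypes, p, comments))
        emit("mrna.tsv", lambda p: write_expression_matrix(cohort.mrna, p, comments))
        emit("protein.tsv", lambda p: write_expression_matrix(cohort.protein, p, comments))
        emit("truth_genes.tsv",
             lambda p: write_table(cohort.truth.genes, p, comments, index_label="gene_id"))
        emit("truth_strains.tsv",
             lambda p: write_table(cohort.truth.strains, p, comments))

    def load_inputs() -> None:
        if "cohort" in state:
            cohort = state["cohort"]
            state["annotation"] = cohort.annotation
            state["karyotypes"] = cohort.karyotypes
            state["mrna"] = cohort.mrna
            state["protein"] = cohort.protein
            return
        needed = {"mrna", "protein", "karyotypes", "annotation"}
        missing = needed - set(inputs)
        if missing:
            raise StageError(
                f"missing inputs {sorted(missing)}; run the simulate stage first "
                "or provide the files"
            )
        state["annotation"] = read_annotation(inputs["annotation"])
        state["karyotypes"] = read_karyotypes(inputs["karyotypes"])
        state["mrna"] = read_expression_matrix(inputs["mrna"], "mRNA")
        state["protein"] = read_expression_matrix(inputs["protein"], "protein")

    def stage_integrate() -> None:
        load_inputs()
        cohort = integrate_mod.build_integrated_cohort(
            {"mRNA": state["mrna"], "protein": state["protein"]},
            state["karyotypes"], state["annotation"], params=params,
        )
        state["integrated"] = cohort
        emit("relative_cn.tsv", lambda p: write_table(cohort.cn, p, params=params, seed=seed))
        for layer, rel in cohort.layers.items():
            emit(f"relative_{layer}.tsv",
                 lambda p, r=rel: write_table(r.values, p, params=params, seed=seed,
                                              index_label="gene_id"))
        emit("excluded_strains.tsv",
             lambda p: write_table(cohort.excluded, p, params=params, seed=seed,
                                   index=False))

    def require(key: str, stage: str) -> None:
        if key not in state:
            raise StageError(f"stage {stage!r} requires the integrate stage first")

    def stage_strains() -> None:
        require("integrated", "attenuate-strains")
        cohort = state["integrated"]
        tests = {}
        for layer, rel in cohort.layers.items():
            tests[layer] = strains_mod.strain_wilcoxon(
                rel, cohort.karyotypes, state["annotation"]
            )
            emit(f"strain_tests_{layer}.tsv",
                 lambda p, t=tests[layer]: write_table(t, p, params=params,
                                                       seed=seed, index=False))
        state["strain_tests"] = tests
        reverted = strains_mod.detect_reverted(
            tests.get("protein", pd.DataFrame(columns=["strain_id", "pseudomedian"])),
            cohort.karyotypes, band=params.reversion_band,
        )
        emit("reverted_strains.tsv",
             lambda p: write_table(pd.DataFrame({"strain_id": reverted}), p,
                                   params=params, seed=seed, index=False))
        for layer, rel in cohort.layers.items():
            summary = strains_mod.summarize_distributions(
                rel, cohort.cn, state["annotation"],
                gains_min_genes=params.gains_min_genes,
                losses_min_genes=params.losses_min_genes,
            )
            emit(f"distribution_summary_{layer}.tsv",
                 lambda p, s=summary: write_table(s, p, params=params, seed=seed,
                                                  index=False))
            if (summary["cn_class"] > 0).sum() >= 2:
                fit = strains_mod.fit_dosage_response(summary)
                emit(f"dosage_response_{layer}.tsv",
                     lambda p, f=fit: write_table(pd.DataFrame([f]), p,
                                                  params=params, seed=seed,
                                                  index=False))

    def stage_genes() -> None:
        require("integrated", "attenuate-genes")
        cohort = state["integrated"]
        slope_tables = {}
        for layer, rel in cohort.layers.items():
            slopes = genes_mod.fit_gene_slopes(
                rel, cohort.cn, cohort.karyotypes, state["annotation"],
                min_aneuploid_points=params.min_aneuploid_points,
                attenuation_threshold=params.attenuation_threshold,
            )
            slope_tables[layer] = slopes
            emit(f"gene_slopes_{layer}.tsv",
                 lambda p, s=slopes: write_table(s, p, params=params, seed=seed,
                                                 index_label="gene_id"))
            if len(slopes):
                grid = np.round(np.arange(0.05, 1.51, 0.05), 2)
                rt = genes_mod.rolling_threshold(slopes["slope"], grid)
                emit(f"rolling_threshold_{layer}.tsv",
                     lambda p, r=rt: write_table(r, p, params=params, seed=seed,
                                                 index=False))
        state["gene_slopes"] = slope_tables

    def stage_trans() -> None:
        require("integrated", "trans")
        cohort = state["integrated"]
        for layer, rel in cohort.layers.items():
            aneuploid = [k for k in cohort.karyotypes if not k.is_euploid]
            if not aneuploid:
                log.warning("trans stage: no aneuploid strains, skipped")
                return
            tm = trans_mod.trans_matrix(rel, cohort.karyotypes, state["annotation"])
            emit(f"trans_matrix_{layer}.tsv",
                 lambda p, t=tm: write_table(t, p, params=params, seed=seed,
                                             index_label="gene_id"))
            med = trans_mod.trans_medians(tm)
            emit(f"trans_medians_{layer}.tsv",
                 lambda p, m=med: write_table(m, p, params=params, seed=seed,
                                              index_label="gene_id"))
            tt = trans_mod.trans_ttests(tm)
            emit(f"trans_ttests_{layer}.tsv",
                 lambda p, t=tt: write_table(t, p, params=params, seed=seed,
                                             index_label="gene_id"))

    def stage_turnover() -> None:
        if "silac" not in inputs:
            log.warning("turnover stage: no SILAC input provided, skipped")
            return
        silac = read_silac_table(inputs["silac"])
        records = turnover_mod.fit_turnover(silac)
        emit("turnover_records.tsv",
             lambda p: write_table(records, p, params=params, seed=seed,
                                   index=False))
        matrix = turnover_mod.turnover_matrix(records)
        if matrix.shape[1] >= 5 and matrix.notna().to_numpy().any():
            complete = turnover_mod.filter_impute_turnover(
                matrix, presence_fraction=params.presence_fraction,
                k=params.knn_k,
            )
            qnorm = turnover_mod.quantile_normalize(complete)
            emit("turnover_qnorm.tsv",
                 lambda p: write_table(qnorm, p, params=params, seed=seed,
                                       index_label="protein_id"))

    runners = {
        "simulate": stage_simulate,
        "integrate": stage_integrate,
        "attenuate-strains": stage_strains,
        "attenuate-genes": stage_genes,
        "trans": stage_trans,
        "turnover": stage_turnover,
    }
    for stage in STAGES:
        if stage in stages:
            timed(stage, runners[stage])

    manifest_path = out / "manifest.json"
    manifest_for_digest = {k: v for k, v in manifest.items() if k != "stages"}
    manifest["digest"] = hashlib.sha256(
        json.dumps(manifest_for_digest, sort_keys=True).encode()
    ).hexdigest()
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
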