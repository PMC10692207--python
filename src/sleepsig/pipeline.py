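"""End-to-end reproduction driver.

Executes the full analysis chain on a synthetic cohort:

    simulate -> phenotypic partial correlations -> region decoding ->
    task / thickness association maps -> rest edges -> edge association maps
    -> signature correlations (full cohort + strata) -> global means / CPM

Every stage writes TSV outputs into the run directory, and a manifest records
the config hash and all derived stage seeds, so a manifest fully determines
the outputs (identical configs give identical files).  Task voxel data are
generated lazily inside the decoding stage and never materialised on disk by
the driver (use the ``simulate`` CLI verb to export them).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .associations import map_association
from .connectome import (cpm_fit_predict, global_mean_association_table,
                         network_block_means, task_global_connectivity)
from .errors import DependencyError, SleepsigError, StratificationError
from .io import (RunConfig, write_edge_table, write_matrix, write_table)
from .mvpa import decode_cohort, representational_connectivity_matrix
from .phenostats import pairwise_partial_correlations
from .restconn import edge_associations, edge_columns, edges_to_matrix
from .signatures import (PHQ2_SPLIT, SLEEP_SPLIT, signature_correlation_table,
                         stratified_signatures)
from .synthetic import (PHENOTYPES, default_coupling, default_task_design,
                        generate_atlas, generate_phenotypes,
                        generate_rest_data, generate_thickness)

log = logging.getLogger("sleepsig.pipeline")

_STAGE_DEPS = {
    "phenocorr": ("simulate",),
    "decode": ("simulate",),
    "associate_task": ("simulate", "decode"),
    "associate_anat": ("simulate",),
    "restconn": ("simulate",),
    "associate_rest": ("simulate", "restconn"),
    "signatures": ("associate_task", "associate_anat", "associate_rest"),
    "global_cpm": ("decode", "restconn"),
}


def _check_dependencies(config: RunConfig) -> None:
    for stage, deps in _STAGE_DEPS.items():
        if not config.stages.get(stage, True):
            continue
        for dep in deps:
            if not config.stages.get(dep, True):
                raise DependencyError(
                    f"stage {stage!r} requires disabled stage {dep!r}")


def _maps_frame(per_phenotype: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-phenotype association tables into units x phenotypes betas."""
    first = next(iter(per_phenotype.values()))
    out = pd.DataFrame(index=first["unit"].to_numpy())
    for phen, df in per_phenotype.items():
        out[phen] = df.set_index("unit")["beta"]
    return out


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run all enabled stages; returns the in-memory result bundle.

    On stage failure the exception is re-raised with the stage name, partial
    outputs are left in place and a ``FAILED`` marker file names the stage.
    """
    _check_dependencies(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}
    stage_times: Dict[str, float] = {}

    def run_stage(name: str, fn: Callable[[], None]) -> None:
        if not config.stages.get(name, True):
            log.info("stage %s disabled; skipping", name)
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            (out / "FAILED").write_text(f"{name}: {exc}\n")
            raise SleepsigError(f"stage {name!r} failed: {exc}") from exc
        stage_times[name] = time.perf_counter() - t0
        log.info("stage %s done in %.2fs", name, stage_times[name])

    # ---- simulate -------------------------------------------------------
    def simulate() -> None:
        seed = config.stage_seed("simulate")
        coupling = default_coupling()
        atlas = generate_atlas(config.n_regions, seed=seed)
        table = generate_phenotypes(config.n_subjects, coupling, seed=seed)
        thickness = generate_thickness(table, atlas, coupling, seed=seed)
        rest = generate_rest_data(table, atlas, coupling, seed=seed,
                                  n_ics=config.n_ics)
        results.update(atlas=atlas, table=table, thickness=thickness,
                       rest=rest, coupling=coupling,
                       design=default_task_design())
        write_table(atlas.to_frame(), out / "atlas.tsv")
        write_table(table, out / "phenotypes.tsv")
        write_table(thickness, out / "thickness.tsv")
        write_edge_table(rest.edges, rest.subject_id, rest.n_regions,
                         out / "edges.tsv")
        write_edge_table(rest.ic_edges, rest.subject_id, rest.n_ics,
                         out / "ic_edges.tsv")

    # ---- phenotypic correlations ---------------------------------------
    def phenocorr() -> None:
        pairs = pairwise_partial_correlations(results["table"])
        results["phenocorr"] = pairs
        write_table(pairs, out / "phenocorr.tsv")

    # ---- decoding -------------------------------------------------------
    def decode() -> None:
        seed = config.stage_seed("decode")
        task = decode_cohort(results["table"], results["atlas"],
                             results["design"], results["coupling"],
                             seed=seed, n_voxels=config.n_voxels,
                             backend=config.svm_backend, compute_rdms=True)
        results["task"] = task
        long = task.accuracy.reset_index().melt(
            id_vars="subject_id", var_name="region", value_name="accuracy")
        write_table(long, out / "decoding.tsv")
        longc = task.contrast.reset_index().melt(
            id_vars="subject_id", var_name="region", value_name="contrast")
        write_table(longc, out / "univariate.tsv")

    # ---- association maps ----------------------------------------------
    def associate_task() -> None:
        task = results["task"]
        acc = task.accuracy.to_numpy()
        per = {}
        for phen in PHENOTYPES:
            per[phen] = map_association(
                task.accuracy.reset_index(drop=True), results["table"],
                phen, modality="task", accuracy_by_unit=acc,
                n_samples=results["design"].n_samples)
        results["map_task"] = per
        write_table(pd.concat(per.values()), out / "map_task.tsv")

    def associate_anat() -> None:
        thick = results["thickness"].drop(columns="subject_id")
        per = {phen: map_association(thick.reset_index(drop=True),
                                     results["table"], phen, modality="anat")
               for phen in PHENOTYPES}
        results["map_anat"] = per
        write_table(pd.concat(per.values()), out / "map_anat.tsv")

    # ---- rest edges -----------------------------------------------------
    def restconn() -> None:
        # edge tables were written at simulate time; nothing stochastic here
        results["edge_cols"] = edge_columns(config.n_regions)

    def associate_rest() -> None:
        rest = results["rest"]
        per = {}
        for phen in PHENOTYPES:
            per[phen] = edge_associations(rest.edges, results["table"], phen,
                                          n_nodes=rest.n_regions)
        results["map_rest"] = per
        write_table(pd.concat(per.values()), out / "map_rest.tsv")
        per_ic = {}
        for phen in PHENOTYPES:
            per_ic[phen] = edge_associations(
                rest.ic_edges, results["table"], phen, n_nodes=rest.n_ics)
        results["map_ic"] = per_ic
        write_table(pd.concat(per_ic.values()), out / "map_ic.tsv")

    # ---- signature correlations ----------------------------------------
    def signatures() -> None:
        seed = config.stage_seed("signatures")
        atlas = results["atlas"]
        tables = []
        for cond, per, use_atlas in (
                ("task", results["map_task"], True),
                ("anat", results["map_anat"], True),
                ("rest", results["map_rest"], False)):
            t = signature_correlation_table(
                _maps_frame(per), atlas=atlas if use_atlas else None,
                n_perm=config.n_perm, seed=seed,
                alpha=config.alpha, n_phenotypes=config.n_phenotypes)
            t.insert(0, "condition", cond)
            tables.append(t)
        sig = pd.concat(tables, ignore_index=True)
        results["signatures"] = sig
        write_table(sig, out / "signatures.tsv")

        rest = results["rest"]
        table = results["table"]
        edges_df = pd.DataFrame(rest.edges, columns=results.get(
            "edge_cols", edge_columns(rest.n_regions)))

        def rest_maps(sub: pd.DataFrame) -> pd.DataFrame:
            idx = sub.index.to_numpy()
            per = {phen: edge_associations(
                rest.edges[idx], sub.reset_index(drop=True), phen,
                n_nodes=rest.n_regions) for phen in PHENOTYPES}
            return _maps_frame(per)

        strata_tables = []
        for spec in (PHQ2_SPLIT, SLEEP_SPLIT):
            try:
                per_stratum = stratified_signatures(
                    table, spec, rest_maps, atlas=None, seed=seed)
            except StratificationError as exc:
                # e.g. too few high-PHQ-2 subjects at small cohort sizes
                log.warning("skipping %s split: %s", spec.variable, exc)
                continue
            for label, t in per_stratum.items():
                t = t.copy()
                t.insert(0, "split", spec.variable)
                t.insert(1, "stratum", label)
                strata_tables.append(t)
        if strata_tables:
            strata = pd.concat(strata_tables, ignore_index=True)
        else:
            strata = pd.DataFrame(columns=[
                "split", "stratum", "phenotype_a", "phenotype_b", "r",
                "n_units", "p_beta", "p_spin", "significant"])
        results["signatures_strata"] = strata
        write_table(strata, out / "signatures_strata.tsv")

    # ---- global means and CPM ------------------------------------------
    def global_cpm() -> None:
        seed = config.stage_seed("global_cpm")
        rest = results["rest"]
        table = results["table"]
        task = results["task"]
        atlas = results["atlas"]
        rest_global = rest.edges.mean(axis=1)
        repconn = np.stack([representational_connectivity_matrix(t)
                            for t in task.rdm_triangles])
        task_global = task_global_connectivity(repconn)
        glob = pd.concat([
            global_mean_association_table(rest_global, table, "rest",
                                          config.alpha,
                                          config.n_phenotypes),
            global_mean_association_table(task_global, table, "task",
                                          config.alpha,
                                          config.n_phenotypes)],
            ignore_index=True)
        results["global"] = glob
        write_table(glob, out / "global.tsv")
        mean_repconn = repconn.mean(axis=0)
        blocks = network_block_means(mean_repconn, atlas)
        write_matrix(blocks.to_numpy(), out / "network_blocks_task.tsv",
                     labels=list(blocks.columns),
                     comment="# network-wise mean task representational "
                             "connectivity")
        from .associations import modality_design
        cpm_rows = []
        for phen in PHENOTYPES:
            cov = modality_design(table, "rest", phen).iloc[:, 1:]
            res = cpm_fit_predict(rest.edges, table[phen].to_numpy(float),
                                  covariates=cov, sel_p=config.sel_p,
                                  n_folds=config.cpm_folds, seed=seed)
            cpm_rows.append({
                "phenotype": phen, "performance_r": res.performance_r,
                "mean_selected": float(np.mean(res.n_selected)),
                "empty_folds": len(res.empty_folds)})
        cpm = pd.DataFrame(cpm_rows)
        results["cpm"] = cpm
        write_table(cpm, out / "cpm.tsv")

    run_stage("simulate", simulate)
    run_stage("phenocorr", phenocorr)
    run_stage("decode", decode)
    run_stage("associate_task", associate_task)
    run_stage("associate_anat", associate_anat)
    run_stage("restconn", restconn)
    run_stage("associate_rest", associate_rest)
    run_stage("signatures", signatures)
    run_stage("global_cpm", global_cpm)

    manifest = {
        "config": config.analysis_dict(),
        "config_hash": config.hash(),
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
        "version": __version__,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    return results
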