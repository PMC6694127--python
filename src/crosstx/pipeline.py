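"""End-to-end orchestration of the analysis stages.

``run_all`` executes, in order: per-dataset differential expression,
cross-dataset similarity (correlation, MDS, tissue test), separate
up/down enrichment, connectivity drug prediction with per-group
interested-drug overlap, and — when the dataset table declares two
groups (e.g. human vs animal cohorts) — the random-experiment
permutation stage for shared significant terms and shared interested
drugs.  Every run writes its resolved configuration, per-stage TSV/JSON
outputs and a manifest of output hashes, so identical inputs, config
and seed reproduce byte-identical results.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .connectivity import (
    SignatureError,
    overlap_candidates,
    score_catalogue,
    select_reversers,
    trim_signature,
)
from .diffexpr import DEResult, differential_expression, direction_matrix
from .enrichment import drugset_enrichment, enrich_dataset, records_to_frame, term_overlap
from .io import (
    read_drug_catalogue,
    read_drugset_gmt,
    read_expression_dataset,
    read_gmt,
)
from .permutation import DatasetNullSpec, permute_drug_overlap, permute_term_overlap
from .similarity import build_distance_model, tissue_distance_test

logger = logging.getLogger(__name__)

DATA_FILES = {"datasets": "datasets.tsv", "genesets": "genesets.gmt",
              "drugsets": "drugsets.gmt", "catalogue": "catalogue.tsv"}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    """Record of one run: resolved config, outputs, seeds, timings."""

    config: dict
    data_dir: str
    outdir: str
    stages: List[str] = field(default_factory=list)
    outputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: Dict[str, float] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def add_output(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _overlap_min(group: str, config: RunConfig) -> int:
    """Interested-drug recurrence threshold for a dataset group."""
    return config.animal_overlap_min if group == "animal" else config.human_overlap_min


def run_all(data_dir: str | Path, config: RunConfig, outdir: str | Path) -> RunManifest:
    """Run every stage on a simulation/analysis directory.

    The directory must contain ``datasets.tsv`` (dataset_id, tissue,
    organism, platform_id, scale, matrix, phenotype, group),
    ``genesets.gmt``, ``drugsets.gmt`` and ``catalogue.tsv``.
    """
    data_dir = Path(data_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, fname in DATA_FILES.items():
        if not (data_dir / fname).exists():
            raise FileNotFoundError(f"input '{key}' missing: expected {data_dir / fname}")

    manifest = RunManifest(config=config.to_dict(), data_dir=str(data_dir), outdir=str(outdir))
    config.to_yaml(outdir / "config.yaml")
    manifest.add_output(outdir / "config.yaml")

    table = pd.read_csv(data_dir / "datasets.tsv", sep="\t", dtype=str)
    datasets = []
    for _, row in table.iterrows():
        datasets.append(
            read_expression_dataset(
                data_dir / row["matrix"], data_dir / row["phenotype"], row.to_dict()
            )
        )
    groups = dict(zip(table["dataset_id"], table.get("group", pd.Series(["all"] * len(table)))))
    group_order = list(dict.fromkeys(groups.values()))
    genesets = read_gmt(data_dir / "genesets.gmt")
    drugsets = read_drugset_gmt(data_dir / "drugsets.gmt")
    catalogue = read_drug_catalogue(data_dir / "catalogue.tsv")

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            manifest.stages.append(name)
            manifest.timings[name] = round(time.perf_counter() - t0, 3)
            return out
        return wrap

    # ---- de ---------------------------------------------------------------
    def _de():
        d = outdir / "de"
        d.mkdir(exist_ok=True)
        results: List[DEResult] = []
        for ds in datasets:
            res = differential_expression(ds, config)
            results.append(res)
            res.records.to_csv(d / f"{ds.dataset_id}.de.tsv", sep="\t", index=False)
            manifest.add_output(d / f"{ds.dataset_id}.de.tsv")
            for direction in ("up", "down"):
                p = d / f"{ds.dataset_id}.{direction}.txt"
                p.write_text("\n".join(res.gene_list(direction)) + "\n")
                manifest.add_output(p)
        dm = direction_matrix(results, min_datasets=config.min_datasets)
        dm.to_csv(d / "direction_matrix.tsv", sep="\t")
        manifest.add_output(d / "direction_matrix.tsv")
        summary = {
            "n_datasets": len(results),
            "n_up": {r.dataset_id: len(r.up_genes) for r in results},
            "n_down": {r.dataset_id: len(r.down_genes) for r in results},
            "direction_matrix_genes": int(dm.shape[0]),
        }
        (d / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest.add_output(d / "summary.json")
        return results

    de_results = stage("de")(_de)

    # ---- similarity -------------------------------------------------------
    def _similarity():
        d = outdir / "similarity"
        d.mkdir(exist_ok=True)
        tissues = {ds.dataset_id: ds.tissue for ds in datasets}
        model = build_distance_model(de_results, tissues, config)
        ids = model.dataset_ids
        pd.DataFrame(model.corr, index=ids, columns=ids).to_csv(d / "corr.tsv", sep="\t")
        pd.DataFrame(model.dist, index=ids, columns=ids).to_csv(d / "dist.tsv", sep="\t")
        emb = pd.DataFrame(
            {
                "dataset_id": ids,
                "tissue": [model.tissue[i] for i in ids],
                "x": model.embedding[:, 0],
                "y": model.embedding[:, 1],
            }
        )
        emb.to_csv(d / "embedding.tsv", sep="\t", index=False)
        np.savetxt(d / "eigenvalues.tsv", model.eigenvalues, delimiter="\t")
        for f in ("corr.tsv", "dist.tsv", "embedding.tsv", "eigenvalues.tsv"):
            manifest.add_output(d / f)
        summary: dict = {"n_datasets": len(ids)}
        tissue_counts = pd.Series(list(model.tissue.values())).value_counts()
        if tissue_counts.size >= 2 and (tissue_counts >= 2).any():
            test = tissue_distance_test(model, config)
            summary["tissue_test"] = {
                "within_tissue_means": test.within_tissue_means,
                "observed_gap": test.observed,
                "n_permutations": test.n_permutations,
                "p": test.p,
                "distance_space": test.distance_space,
                "method": "tissue-label permutation of the within/between distance gap",
            }
        else:
            manifest.warnings.append("tissue test skipped: fewer than two multi-dataset tissues")
        (d / "tissue_test.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest.add_output(d / "tissue_test.json")
        return model

    stage("similarity")(_similarity)

    # ---- enrich -----------------------------------------------------------
    def _enrich():
        d = outdir / "enrich"
        d.mkdir(exist_ok=True)
        all_records = []
        for res in de_results:
            recs = enrich_dataset(res, genesets, config)
            all_records.extend(recs)
            records_to_frame(recs).to_csv(d / f"{res.dataset_id}.enrich.tsv", sep="\t", index=False)
            manifest.add_output(d / f"{res.dataset_id}.enrich.tsv")
        overlap = term_overlap(all_records, min_overlap=config.min_overlap)
        overlap.to_csv(d / "term_overlap.tsv", sep="\t")
        manifest.add_output(d / "term_overlap.tsv")
        summary = {
            "n_records": len(all_records),
            "n_overlap_rows": int(overlap.shape[0]),
            "overlap_convention": "per (term, direction); cells are signed -log10(p)",
        }
        (d / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest.add_output(d / "summary.json")
        return all_records

    enrich_records = stage("enrich")(_enrich)

    # ---- connect ----------------------------------------------------------
    def _connect():
        d = outdir / "connect"
        d.mkdir(exist_ok=True)
        candidate_lists: Dict[str, List[str]] = {}
        for res in de_results:
            try:
                sig = trim_signature(res, catalogue.gene_universe, config)
            except SignatureError as exc:
                manifest.warnings.append(str(exc))
                continue
            records = score_catalogue(sig, catalogue)
            frame = pd.DataFrame(
                {
                    "drug": [r.drug for r in records],
                    "es_up": [r.es_up for r in records],
                    "es_down": [r.es_down for r in records],
                    "score": [r.score for r in records],
                }
            )
            frame.to_csv(d / f"{res.dataset_id}.connectivity.tsv", sep="\t", index=False)
            manifest.add_output(d / f"{res.dataset_id}.connectivity.tsv")
            candidate_lists[res.dataset_id] = select_reversers(records, config)

        interested: Dict[str, List[str]] = {}
        counts: Dict[str, Dict[str, int]] = {}
        for group in group_order:
            lists = {i: l for i, l in candidate_lists.items() if groups[i] == group}
            if not lists:
                manifest.warnings.append(f"group '{group}': no connectivity query survived")
                continue
            try:
                drugs, cnt = overlap_candidates(lists, _overlap_min(group, config))
            except ValueError as exc:
                manifest.warnings.append(f"group '{group}': {exc}")
                continue
            interested[group] = drugs
            counts[group] = cnt
            rows = pd.DataFrame(
                {"drug": drugs, "n_datasets": [cnt[x] for x in drugs]}
            )
            rows.to_csv(d / f"interested_{group}.tsv", sep="\t", index=False)
            manifest.add_output(d / f"interested_{group}.tsv")
            if drugs:
                ds_records = drugset_enrichment(drugs, drugsets, catalogue.drugs, config)
                records_to_frame(ds_records).to_csv(
                    d / f"drugset_enrichment_{group}.tsv", sep="\t", index=False
                )
                manifest.add_output(d / f"drugset_enrichment_{group}.tsv")
        summary = {
            "candidate_list_sizes": {k: len(v) for k, v in candidate_lists.items()},
            "interested": interested,
        }
        (d / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest.add_output(d / "summary.json")
        return candidate_lists, interested

    candidate_lists, interested = stage("connect")(_connect)

    # ---- permtest (two-group comparison) ----------------------------------
    if len(group_order) >= 2:
        def _permtest():
            d = outdir / "permtest"
            d.mkdir(exist_ok=True)
            ga, gb = group_order[0], group_order[1]
            res_by_id = {r.dataset_id: r for r in de_results}

            def specs(group: str) -> List[DatasetNullSpec]:
                return [
                    DatasetNullSpec(
                        dataset_id=i,
                        universe=res_by_id[i].genes,
                        n_up=len(res_by_id[i].up_genes),
                        n_down=len(res_by_id[i].down_genes),
                    )
                    for i in res_by_id
                    if groups[i] == group
                ]

            def group_terms(group: str) -> set:
                support: Dict[str, set] = {}
                for r in enrich_records:
                    if groups[r.dataset_id] == group:
                        support.setdefault(r.term_id, set()).add(r.dataset_id)
                return {t for t, ds in support.items() if len(ds) >= config.min_overlap}

            obs_terms = len(group_terms(ga) & group_terms(gb))
            term_result = permute_term_overlap(
                specs(ga), specs(gb), genesets, config, observed=obs_terms
            )

            sizes_a = {i: len(l) for i, l in candidate_lists.items() if groups[i] == ga}
            sizes_b = {i: len(l) for i, l in candidate_lists.items() if groups[i] == gb}
            obs_drugs = len(set(interested.get(ga, [])) & set(interested.get(gb, [])))
            drug_result = permute_drug_overlap(
                sizes_a,
                sizes_b,
                len(catalogue),
                config,
                observed=obs_drugs,
                min_datasets_a=_overlap_min(ga, config),
                min_datasets_b=_overlap_min(gb, config),
            )

            for name, res in (("shared_terms", term_result), ("shared_drugs", drug_result)):
                payload = {
                    "statistic_name": res.statistic_name,
                    "observed": res.observed,
                    "n_permutations": res.n_permutations,
                    "null_counts": {str(k): v for k, v in sorted(res.null_counts.items())},
                    "n_ge": res.n_ge,
                    "p": res.p,
                    "seed": res.seed,
                    "groups": [ga, gb],
                }
                (d / f"{name}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
                manifest.add_output(d / f"{name}.json")
            return term_result, drug_result

        stage("permtest")(_permtest)

    manifest.write(outdir / "manifest.json")
    return manifest
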