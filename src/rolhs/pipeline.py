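"""End-to-end pipeline: generate -> validate/clean -> map -> store ->
search/similarity/evaluation -> export, with a reproducibility manifest."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from rolhs import __version__, etl_validation, onto_search, patient_similarity
from rolhs.dvh import compute_dvh, dvh_metrics
from rolhs.errors import RolhsError
from rolhs.rdf_graph import compile_mapping, export_graph, parse_turtle, serialize_turtle
from rolhs.resources import default_mapping_spec, fixture_ontology, write_fixture_ontology
from rolhs.synthetic_cohort import CohortTables, generate_cohort, inject_errors

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int = 0
    n_patients: int = 100
    group_weights: tuple[float, ...] = (1, 1, 1, 1, 1)
    error_rates: dict[str, float] = field(default_factory=dict)
    search_terms: tuple[str, ...] = ("fatigue",)
    child_levels: int = 1
    walks_per_patient: int = 5
    max_walk_length: int = 15
    embedding_kinds: tuple[str, ...] = ("word2vec",)
    dimension: int = 50
    epochs: int = 20
    include_dvh: bool = True
    out_dir: str = "rolhs_run"

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        cfg = cls(**doc)
        return cfg


def _dvh_table(tables: CohortTables) -> list[dict[str, str]]:
    rows = []
    course_of = {
        r["Patient ID Number"]: r["RT Course ID"]
        for r in tables["treatment_course"] if r.get("RT Course ID")
    }
    for pid, grid in sorted(tables.dose_grids.items()):
        course = course_of.get(pid)
        if course is None:
            continue
        for structure, mask in sorted(grid.masks.items()):
            curve = compute_dvh(grid.dose, mask, bin_width=50.0,
                                voxel_volume=grid.voxel_volume)
            metrics = dvh_metrics(curve, ["D95", "mean"])
            for metric, value in metrics.items():
                rows.append({
                    "Patient ID Number": pid,
                    "RT Course ID": course,
                    "Structure": structure,
                    "Metric": metric,
                    "Value": f"{value:.2f}",
                    "Unit": "cGy",
                })
    return rows


def run_pipeline(config: RunConfig, log=print) -> Path:
    """Run every stage into ``config.out_dir``; returns the run directory.

    Any stage failure aborts with a stage-named diagnostic; partial outputs
    are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    stage = "setup"
    try:
        t0 = time.perf_counter()

        def mark(name: str, **counts) -> None:
            nonlocal t0
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **counts}
            log(f"[{name}] {counts}")
            t0 = time.perf_counter()

        stage = "generate"
        tables = generate_cohort(config.n_patients, config.group_weights, config.seed)
        if config.error_rates:
            tables, ledger = inject_errors(tables, config.error_rates, config.seed)
        else:
            ledger = None
        tables.to_csv(out / "cohort")
        mark(stage, patients=config.n_patients,
             injected_errors=len(ledger) if ledger else 0)

        stage = "validate"
        rules = etl_validation.default_rules()
        etl_validation.dump_rules(rules, out / "rules.json")
        report = etl_validation.validate(tables, rules)
        report.to_json(out / "validation_report.json")
        cleaned = etl_validation.clean(tables, report)
        cleaned.to_csv(out / "cohort_clean")
        mark(stage, violations=len(report))

        stage = "map"
        ont = fixture_ontology()
        write_fixture_ontology(out / "ontology.json")
        if config.include_dvh:
            cleaned.tables["dvh_metrics"] = _dvh_table(cleaned)
        spec = default_mapping_spec(include_dvh=config.include_dvh)
        spec.dump(out / "mapping_spec.json")
        store = compile_mapping(spec, cleaned, ont)
        mlog = store.mapping_log
        completeness = etl_validation.mapping_completeness(
            mlog.n_source_elements, mlog.n_mapped_elements)
        serialize_turtle(store, out / "graph.ttl")
        reparsed = parse_turtle(out / "graph.ttl")
        manifest["triples"] = len(store)
        manifest["triples_reparsed"] = len(reparsed)
        manifest["mapping_completeness_pct"] = completeness
        mark(stage, triples=len(store), completeness=completeness)

        stage = "export"
        patients = sorted(s for s in store.subjects() if "/patient/" in s)
        if patients:
            from rolhs.rdf_graph import patient_subgraph
            sub = patient_subgraph(store, patients[0], 3)
            export_graph(sub, out / "patient0.dot", "dot", ont)
            export_graph(sub, out / "patient0.graphml", "graphml", ont)
        mark(stage, patients=len(patients))

        stage = "search"
        opts = onto_search.SearchOptions(child_levels=config.child_levels)
        result = onto_search.search(store, ont, list(config.search_terms), opts)
        result.to_json(out / "search_result.json")
        mark(stage, expanded=len(result.expanded_classes),
             hits=len(result.patient_uris()))

        stage = "similarity"
        corpus = patient_similarity.build_walk_corpus(
            store, patients, config.walks_per_patient, config.max_walk_length,
            config.seed)
        corpus.write_text(out / "walk_corpus.txt")
        training = corpus.extended(patient_similarity.ontology_corpus(ont))
        labels = {}
        for row in cleaned["diagnosis"]:
            pid, group = row.get("Patient ID Number"), row.get("Diagnosis Group")
            if pid and group:
                labels[f"{spec.base}/patient/{pid}"] = group
        eval_rows = []
        for kind in config.embedding_kinds:
            params = patient_similarity.EmbeddingParams(
                dimension=config.dimension, epochs=config.epochs, seed=config.seed)
            model = patient_similarity.train_embedding(training, kind, params)
            if model.vectors:
                model.write_word2vec_text(out / f"vectors_{kind}.txt")
            pvs = [patient_similarity.patient_vector(model, corpus, p)
                   for p in patients]
            rep = patient_similarity.evaluate_clusters(pvs, labels)
            rep.to_json(out / f"cluster_eval_{kind}.json")
            eval_rows.append(rep.to_tsv_row())
            manifest.setdefault("cluster_eval", {})[kind] = {
                "intra_cosine": rep.intra_cosine,
                "inter_cosine": rep.inter_cosine,
            }
        (out / "cluster_eval.tsv").write_text(
            "model\tintra_cosine\teuclidean\tmanhattan\tminkowski\n"
            + "\n".join(eval_rows) + "\n", encoding="utf-8")
        mark(stage, models=len(config.embedding_kinds))

        manifest["ok"] = True
    except RolhsError as exc:
        manifest["ok"] = False
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RolhsError(f"stage {stage!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                       encoding="utf-8")
    return out
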