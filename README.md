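# rolhs

Desk-scale toolkit for a radiation-oncology learning-health-system data
pipeline: validated ETL over relational-style clinical tables, ontology-driven
mapping to an RDF knowledge graph, hierarchy- and synonym-aware cohort search,
graph-walk embedding patient similarity, and dose-volume histogram computation
— all runnable end to end on a bundled synthetic cohort and fixture ontology.

## Components

| module | what it does |
|---|---|
| `rolhs.ontology` | load/validate a coded concept DAG (CURIE codes, labels, synonyms, multi-parent links); exact-match term lookup; leveled descendant/ancestor traversal |
| `rolhs.synthetic_cohort` | generate patient tables (demographics, diagnosis, staging, treatment course, toxicity, labs, dose grids) across 5 diagnosis groups with 18–25 categorical attributes per patient; inject seeded data-quality errors with a ground-truth ledger |
| `rolhs.etl_validation` | the five cleaning checks (type, cross-field, mandatory, range, format), cell-blanking drop policy, mapping-completeness metric |
| `rolhs.rdf_graph` | JSON mapping spec (ClassMap / PropertyBridge / class-map references) compiled to a triple store; Turtle serialization + parser; basic-graph-pattern queries with a minimal SPARQL SELECT front-end; DOT/GraphML export |
| `rolhs.onto_search` | q-term expansion (synonyms, k-level children, parents) and patient search over the compiled graph with provenance |
| `rolhs.patient_similarity` | breadth-first randomized walks per patient, four embedding kinds (word2vec SGNS, doc2vec PV-DBOW, GloVe-style factorization, fastText subwords — numpy implementations), similarity metrics, ranking, 5-group cluster evaluation |
| `rolhs.dvh` | cumulative DVH curves from dose grids + masks; Dx/Vx/mean metrics |
| `rolhs.cli` / `rolhs.pipeline` | `rolhs` command chaining generate → validate → map → search → similar → evaluate with a reproducibility manifest |

## CLI

```bash
rolhs generate -n 200 --seed 1 -o cohort
rolhs validate cohort --clean-to cohort_clean
rolhs map cohort_clean -o graph.ttl
rolhs search graph.ttl --terms "fatigue" --child-levels 1
rolhs similar graph.ttl --patient P0042 --model word2vec --metric cosine -k 10
rolhs query graph.ttl 'PREFIX roo: <http://www.cancerdata.org/roo/> SELECT ?p WHERE { ?p roo:hasTreatmentCourse ?c }'
rolhs run-all --config demo.json        # full pipeline into a run directory
```

`run-all` accepts a JSON config mirroring `rolhs.pipeline.RunConfig`
(seed, cohort size, group weights, error rates, search terms, walk and
embedding parameters, output directory). Reruns with the same config and
seed produce byte-identical Turtle and corpus outputs.

## File formats

* Ontology: JSON `{prefixes, classes:[{code,label,synonyms,definition,parents}]}`
  (`rolhs fixture-ontology` writes the bundled ROO/NCIT-style fixture).
* Mapping spec: JSON mirror of the D2RQ ClassMap / PropertyBridge triad
  (see `rolhs.resources.default_mapping_spec`).
* Graph: W3C Turtle (deterministic, one triple per line); exports as DOT and
  GraphML.
* Cohort: one CSV per table; validation rules and reports as JSON.
* Embeddings: word2vec text format; cluster evaluation as JSON + TSV.
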