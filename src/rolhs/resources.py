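"""Bundled fixture ontology and default mapping spec for the synthetic cohort.

The fixture ontology emulates ROO+NCIT fragments: coded classes with labels,
synonyms, definitions and parent links, arranged as a DAG.  Codes reuse
well-known NCIT identifiers where convenient (e.g. NCIT:C48720 for T1
staging) but the file is a self-contained fixture, not a claim about the
published thesauri.  CTCAE-style toxicity terms get grade-1..3 children so
that one-level child expansion of e.g. "fatigue" returns the term plus its
three grade classes.
"""

from __future__ import annotations

import json
from pathlib import Path

from rolhs.ontology import Ontology, ontology_from_dict
from rolhs.rdf_graph import ClassMap, MappingSpec, PropertyBridge

__all__ = [
    "PREFIXES",
    "BASE_URI",
    "fixture_ontology_dict",
    "fixture_ontology",
    "default_mapping_spec",
    "write_fixture_ontology",
]

PREFIXES = {
    "NCIT": "http://purl.obolibrary.org/obo/NCIT_",
    "CTCAE": "http://purl.obolibrary.org/obo/CTCAE_",
    "roo": "http://www.cancerdata.org/roo/",
}

BASE_URI = "http://rolhs.example.org"

# toxicity term -> fixture CTCAE code stem; grades 1..3 are children
CTCAE_TERMS = {
    "Fatigue": ("E10000", ("tiredness", "lack of energy")),
    "Urinary Frequency": ("E11000", ("pollakiuria",)),
    "Cystitis": ("E12000", ("bladder inflammation",)),
    "Esophagitis": ("E13000", ("esophageal inflammation",)),
    "Pneumonitis": ("E14000", ("lung inflammation",)),
    "Cough": ("E15000", ()),
    "Nausea": ("E16000", ()),
    "Radiation Dermatitis": ("E17000", ("dermatitis", "radiation skin injury")),
    "Lymphedema": ("E18000", ()),
    "Mucositis": ("E19000", ("oral mucositis",)),
    "Dysphagia": ("E20000", ("difficulty swallowing",)),
}

GROUP_CODES = {
    "Prostate Cancer": "NCIT:C4863",
    "Non-Small Cell Lung Cancer": "NCIT:C2926",
    "Small Cell Lung Cancer": "NCIT:C4917",
    "Breast Cancer": "NCIT:C4872",
    "Head and Neck Cancer": "NCIT:C4013",
}

T_STAGE_CODES = {
    "T1": "NCIT:C48720", "T1a": "NCIT:C48721", "T1b": "NCIT:C48722",
    "T1c": "NCIT:C48723", "T2": "NCIT:C48724", "T2a": "NCIT:C48725",
    "T2b": "NCIT:C48726", "T3": "NCIT:C48728", "T4": "NCIT:C48732",
}
N_STAGE_CODES = {"N0": "NCIT:C48705", "N1": "NCIT:C48706",
                 "N2": "NCIT:C48786", "N3": "NCIT:C48714"}
M_STAGE_CODES = {"M0": "NCIT:C48699", "M1": "NCIT:C48700"}
STAGE_GROUP_CODES = {"Stage I": "NCIT:C27966", "Stage II": "NCIT:C28054",
                     "Stage III": "NCIT:C27970", "Stage IV": "NCIT:C27971"}
HISTOLOGY_CODES = {
    "Adenocarcinoma": "NCIT:C2852",
    "Squamous Cell Carcinoma": "NCIT:C2929",
    "Small Cell Carcinoma": "NCIT:C4914",
    "Acinar Adenocarcinoma": "NCIT:C5651",
    "Ductal Carcinoma": "NCIT:C4017",
    "Lobular Carcinoma": "NCIT:C4018",
}
SMOKING_CODES = {"Never Smoker": "NCIT:C65108", "Former Smoker": "NCIT:C67148",
                 "Current Smoker": "NCIT:C67147"}
SEX_CODES = {"Male": "NCIT:C20197", "Female": "NCIT:C16576"}
RACE_CODES = {
    "White": "NCIT:C41261",
    "Black or African American": "NCIT:C16352",
    "Asian": "NCIT:C41260",
    "American Indian or Alaska Native": "NCIT:C41259",
    "Native Hawaiian or Other Pacific Islander": "NCIT:C41219",
}
MODALITY_CODES = {"Photon": "NCIT:C104914", "Electron": "NCIT:C15462",
                  "Proton": "NCIT:C66897"}
TECHNIQUE_CODES = {"IMRT": "NCIT:C16135", "VMAT": "NCIT:C116432",
                   "3D-CRT": "NCIT:C16035", "SBRT": "NCIT:C118286"}
GLEASON_CODES = {"6": "NCIT:C28089", "7": "NCIT:C28090",
                 "8": "NCIT:C28091", "9": "NCIT:C28092"}
PSA_CODES = {"Low": "roo:PSALow", "Intermediate": "roo:PSAIntermediate",
             "High": "roo:PSAHigh"}
LAB_CODES = {"PSA": "NCIT:C17634", "Creatinine": "NCIT:C64547",
             "Hemoglobin": "NCIT:C64848", "GFR": "NCIT:C90505"}
LATERALITY_CODES = {"Left": "NCIT:C25306", "Right": "NCIT:C25228"}
INTENT_CODES = {"Curative": "roo:CurativeIntent", "Palliative": "roo:PalliativeIntent"}


def _cls(code, label, parents=(), synonyms=(), definition=None):
    return {"code": code, "label": label, "parents": list(parents),
            "synonyms": list(synonyms), "definition": definition}


def fixture_ontology_dict() -> dict:
    classes = [
        _cls("NCIT:C2991", "Disease or Disorder"),
        _cls("NCIT:C3262", "Neoplasm", ["NCIT:C2991"], ["tumor", "tumour"]),
        _cls("NCIT:C27996", "Myocardial Infarction", ["NCIT:C2991"],
             ["heart attack", "acute coronary syndrome"]),
        _cls("NCIT:C4863", "Prostate Cancer", ["NCIT:C3262"],
             ["Prostate Carcinoma", "Carcinoma of the Prostate"],
             "A malignant neoplasm of the prostate gland."),
        _cls("NCIT:C4878", "Lung Cancer", ["NCIT:C3262"], ["Lung Carcinoma"]),
        _cls("NCIT:C2926", "Non-Small Cell Lung Cancer", ["NCIT:C4878"],
             ["NSCLC", "Non-Small Cell Lung Carcinoma"]),
        _cls("NCIT:C4917", "Small Cell Lung Cancer", ["NCIT:C4878"],
             ["SCLC", "Oat Cell Carcinoma"]),
        _cls("NCIT:C4872", "Breast Cancer", ["NCIT:C3262"], ["Breast Carcinoma"]),
        _cls("NCIT:C4013", "Head and Neck Cancer", ["NCIT:C3262"],
             ["Head and Neck Carcinoma"]),
        # TNM staging
        _cls("NCIT:C48885", "TNM Finding"),
        _cls("NCIT:C48881", "T Stage Finding", ["NCIT:C48885"], ["T Stage"]),
        _cls("NCIT:C48884", "N Stage Finding", ["NCIT:C48885"], ["N Stage"]),
        _cls("NCIT:C48883", "M Stage Finding", ["NCIT:C48885"], ["M Stage"]),
        _cls("NCIT:C48720", "T1 Stage", ["NCIT:C48881"], ["T1", "T1 Stage Finding"],
             "Primary tumor limited in size/extent (stage T1)."),
        _cls("NCIT:C48721", "T1a Stage", ["NCIT:C48720"], ["T1a"]),
        _cls("NCIT:C48722", "T1b Stage", ["NCIT:C48720"], ["T1b"]),
        _cls("NCIT:C48723", "T1c Stage", ["NCIT:C48720"], ["T1c"]),
        _cls("NCIT:C48724", "T2 Stage", ["NCIT:C48881"], ["T2"]),
        _cls("NCIT:C48725", "T2a Stage", ["NCIT:C48724"], ["T2a"]),
        _cls("NCIT:C48726", "T2b Stage", ["NCIT:C48724"], ["T2b"]),
        _cls("NCIT:C48728", "T3 Stage", ["NCIT:C48881"], ["T3"]),
        _cls("NCIT:C48732", "T4 Stage", ["NCIT:C48881"], ["T4"]),
        _cls("NCIT:C48705", "N0 Stage", ["NCIT:C48884"], ["N0"]),
        _cls("NCIT:C48706", "N1 Stage", ["NCIT:C48884"], ["N1"]),
        _cls("NCIT:C48786", "N2 Stage", ["NCIT:C48884"], ["N2"]),
        _cls("NCIT:C48714", "N3 Stage", ["NCIT:C48884"], ["N3"]),
        _cls("NCIT:C48699", "M0 Stage", ["NCIT:C48883"], ["M0"]),
        _cls("NCIT:C48700", "M1 Stage", ["NCIT:C48883"], ["M1"]),
        _cls("NCIT:C28108", "Stage Group"),
        _cls("NCIT:C27966", "Stage I", ["NCIT:C28108"]),
        _cls("NCIT:C28054", "Stage II", ["NCIT:C28108"]),
        _cls("NCIT:C27970", "Stage III", ["NCIT:C28108"]),
        _cls("NCIT:C27971", "Stage IV", ["NCIT:C28108"]),
        # histology
        _cls("NCIT:C16899", "Histologic Type", [], ["Histology"]),
        _cls("NCIT:C2852", "Adenocarcinoma", ["NCIT:C16899"]),
        _cls("NCIT:C5651", "Acinar Adenocarcinoma", ["NCIT:C2852"]),
        _cls("NCIT:C2929", "Squamous Cell Carcinoma", ["NCIT:C16899"]),
        _cls("NCIT:C4914", "Small Cell Carcinoma", ["NCIT:C16899"]),
        _cls("NCIT:C4017", "Ductal Carcinoma", ["NCIT:C16899"]),
        _cls("NCIT:C4018", "Lobular Carcinoma", ["NCIT:C16899"]),
        # demographics
        _cls("NCIT:C28421", "Sex"),
        _cls("NCIT:C20197", "Male", ["NCIT:C28421"]),
        _cls("NCIT:C16576", "Female", ["NCIT:C28421"]),
        _cls("NCIT:C17049", "Race"),
        *[_cls(code, label, ["NCIT:C17049"]) for label, code in RACE_CODES.items()],
        _cls("NCIT:C17934", "Smoking Status", [], ["Tobacco Use"]),
        _cls("NCIT:C65108", "Never Smoker", ["NCIT:C17934"], ["Non-Smoker"]),
        _cls("NCIT:C67148", "Former Smoker", ["NCIT:C17934"], ["Ex-Smoker"]),
        _cls("NCIT:C67147", "Current Smoker", ["NCIT:C17934"]),
        _cls("NCIT:C25229", "Laterality"),
        _cls("NCIT:C25306", "Left", ["NCIT:C25229"]),
        _cls("NCIT:C25228", "Right", ["NCIT:C25229"]),
        # treatment
        _cls("NCIT:C16960", "Patient"),
        _cls("roo:RadiotherapyCourse", "Radiotherapy Course", [],
             ["RT Course", "Radiation Treatment Course"]),
        _cls("roo:RadiationModality", "Radiation Treatment Modality"),
        _cls("NCIT:C104914", "Photon Beam Radiation Therapy",
             ["roo:RadiationModality"], ["Photon"]),
        _cls("NCIT:C15462", "Electron Beam Therapy", ["roo:RadiationModality"],
             ["Electron"]),
        _cls("NCIT:C66897", "Proton Beam Radiation Therapy",
             ["roo:RadiationModality"], ["Proton"]),
        _cls("roo:RadiationTechnique", "Radiation Treatment Technique"),
        _cls("NCIT:C16135", "Intensity-Modulated Radiation Therapy",
             ["roo:RadiationTechnique"], ["IMRT"]),
        _cls("NCIT:C116432", "Volumetric Modulated Arc Therapy",
             ["roo:RadiationTechnique"], ["VMAT"]),
        _cls("NCIT:C16035", "Three-Dimensional Conformal Radiation Therapy",
             ["roo:RadiationTechnique"], ["3D-CRT", "3DCRT"]),
        _cls("NCIT:C118286", "Stereotactic Body Radiation Therapy",
             ["roo:RadiationTechnique"], ["SBRT"]),
        _cls("roo:TreatmentIntent", "Treatment Intent"),
        _cls("roo:CurativeIntent", "Curative Intent", ["roo:TreatmentIntent"],
             ["Curative"]),
        _cls("roo:PalliativeIntent", "Palliative Intent", ["roo:TreatmentIntent"],
             ["Palliative"]),
        # prostate diagnostics
        _cls("NCIT:C18000", "Gleason Score", [], ["Gleason Grading"]),
        *[_cls(code, f"Gleason Score {value}", ["NCIT:C18000"])
          for value, code in GLEASON_CODES.items()],
        _cls("roo:PSACategory", "PSA Category"),
        _cls("roo:PSALow", "Low PSA", ["roo:PSACategory"]),
        _cls("roo:PSAIntermediate", "Intermediate PSA", ["roo:PSACategory"]),
        _cls("roo:PSAHigh", "High PSA", ["roo:PSACategory"]),
        # labs
        _cls("NCIT:C36292", "Laboratory Test", [], ["Lab Test"]),
        _cls("NCIT:C17634", "Prostate Specific Antigen Measurement",
             ["NCIT:C36292"], ["PSA", "PSA Test"]),
        _cls("NCIT:C64547", "Creatinine Measurement", ["NCIT:C36292"],
             ["Creatinine"]),
        _cls("NCIT:C64848", "Hemoglobin Measurement", ["NCIT:C36292"],
             ["Hemoglobin"]),
        _cls("NCIT:C90505", "Glomerular Filtration Rate", ["NCIT:C36292"],
             ["GFR"]),
        # dosimetry
        _cls("roo:DVHMetric", "DVH Metric", [], ["Dose Volume Histogram Metric"]),
        _cls("NCIT:C64783", "Centigray", [], ["cGy"]),
    ]
    # CTCAE terms with grade children
    classes.append(_cls("CTCAE:E00001", "Adverse Event", [], ["toxicity"]))
    for term, (stem, synonyms) in CTCAE_TERMS.items():
        classes.append(_cls(f"CTCAE:{stem}", term, ["CTCAE:E00001"], synonyms))
        for grade in (1, 2, 3):
            code = f"CTCAE:{stem[:-1]}{grade}"
            classes.append(_cls(code, f"{term} Grade {grade}", [f"CTCAE:{stem}"]))
    return {"prefixes": dict(PREFIXES), "classes": classes}


def fixture_ontology() -> Ontology:
    return ontology_from_dict(fixture_ontology_dict())


def write_fixture_ontology(path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(fixture_ontology_dict(), indent=1), encoding="utf-8")
    return path


def ctcae_term_codes() -> dict[str, str]:
    """Cell value 'Fatigue Grade 2' -> grade class code, for all combos."""
    out = {}
    for term, (stem, _) in CTCAE_TERMS.items():
        for grade in (1, 2, 3):
            out[f"{term} Grade {grade}"] = f"CTCAE:{stem[:-1]}{grade}"
    return out


def default_mapping_spec(include_dvh: bool = False) -> MappingSpec:
    """Mapping for the synthetic cohort schema onto the fixture ontology."""
    class_maps = [
        ClassMap("patient", "demographics", "Patient ID Number",
                 uri_template="patient/{Patient ID Number}", type_code="NCIT:C16960"),
        ClassMap("sex_class", "demographics", "Patient ID Number",
                 value_lookup={"column": "Sex", "map": SEX_CODES}),
        ClassMap("race_class", "demographics", "Patient ID Number",
                 value_lookup={"column": "Race", "map": RACE_CODES}),
        ClassMap("smoking_class", "demographics", "Patient ID Number",
                 value_lookup={"column": "Smoking Status", "map": SMOKING_CODES}),
        ClassMap("diagnosis", "diagnosis", "Patient ID Number",
                 uri_template="diagnosis/{Patient ID Number}",
                 type_lookup={"column": "Diagnosis Group", "map": GROUP_CODES}),
        ClassMap("histology_class", "diagnosis", "Patient ID Number",
                 value_lookup={"column": "Histology", "map": HISTOLOGY_CODES}),
        ClassMap("laterality_class", "diagnosis", "Patient ID Number",
                 value_lookup={"column": "Laterality", "map": LATERALITY_CODES}),
        ClassMap("t_stage", "staging", "Patient ID Number",
                 value_lookup={"column": "T Stage", "map": T_STAGE_CODES}),
        ClassMap("n_stage", "staging", "Patient ID Number",
                 value_lookup={"column": "N Stage", "map": N_STAGE_CODES}),
        ClassMap("m_stage", "staging", "Patient ID Number",
                 value_lookup={"column": "M Stage", "map": M_STAGE_CODES}),
        ClassMap("stage_group", "staging", "Patient ID Number",
                 value_lookup={"column": "Stage Group", "map": STAGE_GROUP_CODES}),
        ClassMap("gleason_class", "staging", "Patient ID Number",
                 value_lookup={"column": "Gleason Score", "map": GLEASON_CODES}),
        ClassMap("psa_class", "staging", "Patient ID Number",
                 value_lookup={"column": "PSA Category", "map": PSA_CODES}),
        ClassMap("course", "treatment_course", "Patient ID Number",
                 uri_template="course/{RT Course ID}",
                 type_code="roo:RadiotherapyCourse"),
        ClassMap("modality_class", "treatment_course", "Patient ID Number",
                 value_lookup={"column": "Modality", "map": MODALITY_CODES}),
        ClassMap("technique_class", "treatment_course", "Patient ID Number",
                 value_lookup={"column": "Technique", "map": TECHNIQUE_CODES}),
        ClassMap("intent_class", "treatment_course", "Patient ID Number",
                 value_lookup={"column": "Treatment Intent", "map": INTENT_CODES}),
        ClassMap("toxicity", "toxicity", "Patient ID Number",
                 uri_template="toxicity/{Patient ID Number}/{Toxicity}",
                 type_lookup={"column": "CTCAE Term", "map": ctcae_term_codes()}),
        ClassMap("lab", "labs", "Patient ID Number",
                 uri_template="lab/{Patient ID Number}/{Lab Name}",
                 type_lookup={"column": "Lab Name", "map": LAB_CODES}),
    ]
    bridges = [
        PropertyBridge("patient", "roo:hasDiagnosis", {"ref": "diagnosis"}),
        PropertyBridge("patient", "roo:hasSex", {"ref": "sex_class"}),
        PropertyBridge("patient", "roo:hasRace", {"ref": "race_class"}),
        PropertyBridge("patient", "roo:hasSmokingStatus", {"ref": "smoking_class"}),
        PropertyBridge("patient", "roo:hasMaritalStatus",
                       {"column": "Marital Status", "datatype": "integer"}),
        PropertyBridge("diagnosis", "roo:hasHistology", {"ref": "histology_class"}),
        PropertyBridge("diagnosis", "roo:hasLaterality", {"ref": "laterality_class"}),
        PropertyBridge("diagnosis", "roo:hasDiagnosisDate",
                       {"column": "Date of Diagnosis", "datatype": "date"}),
        PropertyBridge("diagnosis", "roo:hasTStage", {"ref": "t_stage"}),
        PropertyBridge("diagnosis", "roo:hasNStage", {"ref": "n_stage"}),
        PropertyBridge("diagnosis", "roo:hasMStage", {"ref": "m_stage"}),
        PropertyBridge("diagnosis", "roo:hasStageGroup", {"ref": "stage_group"}),
        PropertyBridge("diagnosis", "roo:hasGleasonScore", {"ref": "gleason_class"}),
        PropertyBridge("diagnosis", "roo:hasPSACategory", {"ref": "psa_class"}),
        PropertyBridge("diagnosis", "roo:hasToxicity", {"ref": "toxicity"}),
        PropertyBridge("toxicity", "roo:hasGrade",
                       {"column": "Grade", "datatype": "integer"}),
        PropertyBridge("patient", "roo:hasTreatmentCourse", {"ref": "course"}),
        PropertyBridge("course", "roo:hasModality", {"ref": "modality_class"}),
        PropertyBridge("course", "roo:hasTechnique", {"ref": "technique_class"}),
        PropertyBridge("course", "roo:hasTreatmentIntent", {"ref": "intent_class"}),
        PropertyBridge("course", "roo:hasPrescriptionDose",
                       {"column": "Prescription Dose", "datatype": "integer"}),
        PropertyBridge("course", "roo:hasFractionCount",
                       {"column": "Fraction Count", "datatype": "integer"}),
        PropertyBridge("course", "roo:hasStartDate",
                       {"column": "Radiotherapy Treatment Start Date",
                        "datatype": "date"}),
        PropertyBridge("course", "roo:hasPerformanceStatus",
                       {"column": "Performance Status Value", "datatype": "integer"}),
        PropertyBridge("patient", "roo:hasLabResult", {"ref": "lab"}),
        PropertyBridge("lab", "roo:hasLabValue",
                       {"column": "Lab Value", "datatype": "decimal"}),
    ]
    if include_dvh:
        class_maps.append(
            ClassMap("dvh_metric", "dvh_metrics", "Patient ID Number",
                     uri_template="dvh/{RT Course ID}/{Structure}/{Metric}",
                     type_code="roo:DVHMetric"))
        bridges += [
            PropertyBridge("course", "roo:hasDVHMetric", {"ref": "dvh_metric"}),
            PropertyBridge("dvh_metric", "roo:hasValue",
                           {"column": "Value", "datatype": "decimal"}),
        ]
    return MappingSpec(base=BASE_URI, class_maps=class_maps,
                       property_bridges=bridges)
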