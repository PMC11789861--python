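"""Bundled capmatinib example data for worked examples and tests.

Capmatinib (trade name Tabrecta) is a selective MET inhibitor approved in
2020 for NSCLC with MET exon 14 skipping mutations.  Two small datasets
support the package's worked examples:

* :func:`capmatinib_signal_pts` — 79 capmatinib adverse-event signal PTs
  across 18 system organ classes from FAERS-based surveillance, with
  report counts and whether each PT is listed in the product label
  (66 listed, 13 not).
* :func:`capmatinib_demographics_counts` — demographic composition counts
  for the 2,201 reports encompassed by those signals.
"""
from __future__ import annotations

import pandas as pd

# (SOC, PT, report count, listed in product label)
_SIGNAL_PTS = [
    ("blood and lymphatic system disorders", "lymphedema", 9, True),
    ("vascular disorders", "pulmonary thrombosis", 4, False),
    ("cardiac disorders", "peripheral swelling", 163, True),
    ("cardiac disorders", "pulmonary edema", 14, True),
    ("cardiac disorders", "hemoptysis", 7, False),
    ("cardiac disorders", "ascites", 5, True),
    ("gastrointestinal disorders", "dysphagia", 49, False),
    ("gastrointestinal disorders", "esophageal stenosis", 3, False),
    ("gastrointestinal disorders", "nausea", 176, True),
    ("gastrointestinal disorders", "retching", 6, True),
    ("reproductive system and breast disorders", "scrotal edema", 4, True),
    ("renal and urinary disorders", "fluid retention", 28, True),
    ("renal and urinary disorders", "renal impairment", 27, True),
    ("renal and urinary disorders", "chromaturia", 6, True),
    ("general disorders and administration site conditions", "edema", 86, True),
    ("general disorders and administration site conditions", "generalized edema", 21, True),
    ("general disorders and administration site conditions", "peripheral edema", 226, True),
    ("general disorders and administration site conditions", "increased energy", 5, False),
    ("general disorders and administration site conditions", "swelling", 43, True),
    ("general disorders and administration site conditions", "concomitant disease aggravation", 5, True),
    ("general disorders and administration site conditions", "death", 289, True),
    ("general disorders and administration site conditions", "fatigue", 191, True),
    ("general disorders and administration site conditions", "disease progression", 41, True),
    ("general disorders and administration site conditions", "asthenia", 74, True),
    ("skin and subcutaneous tissue disorders", "photosensitivity reaction", 6, True),
    ("endocrine disorders", "metastases to the adrenal glands", 3, True),
    ("immune system disorders", "swelling of eyelid", 3, True),
    ("neoplasms benign, malignant and unspecified (including cysts and polyps)", "metastases to the pleura", 3, True),
    ("neoplasms benign, malignant and unspecified (including cysts and polyps)", "malignant neoplasm progression", 97, True),
    ("neoplasms benign, malignant and unspecified (including cysts and polyps)", "metastases to central nervous system", 15, True),
    ("neoplasms benign, malignant and unspecified (including cysts and polyps)", "metastasis", 6, True),
    ("neoplasms benign, malignant and unspecified (including cysts and polyps)", "neoplasm", 5, True),
    ("neoplasms benign, malignant and unspecified (including cysts and polyps)", "brain neoplasm", 3, True),
    ("respiratory, thoracic and mediastinal disorders", "metastatic non-small cell lung cancer", 13, True),
    ("respiratory, thoracic and mediastinal disorders", "non-small cell lung cancer", 51, True),
    ("respiratory, thoracic and mediastinal disorders", "lung adenocarcinoma", 8, True),
    ("respiratory, thoracic and mediastinal disorders", "vocal cord paralysis", 5, True),
    ("respiratory, thoracic and mediastinal disorders", "pneumonitis", 16, True),
    ("respiratory, thoracic and mediastinal disorders", "pleural effusion", 24, True),
    ("respiratory, thoracic and mediastinal disorders", "malignant lung neoplasm", 25, True),
    ("respiratory, thoracic and mediastinal disorders", "lung carcinoma cell type unspecified stage iv", 5, True),
    ("respiratory, thoracic and mediastinal disorders", "choking", 5, False),
    ("respiratory, thoracic and mediastinal disorders", "pulmonary mass", 4, True),
    ("respiratory, thoracic and mediastinal disorders", "metastases to the lungs", 3, True),
    ("respiratory, thoracic and mediastinal disorders", "exertional dyspnea", 6, True),
    ("respiratory, thoracic and mediastinal disorders", "pulmonary fibrosis", 3, True),
    ("musculoskeletal and connective tissue disorders", "joint swelling", 75, True),
    ("musculoskeletal and connective tissue disorders", "metastases to the bones", 9, True),
    ("nervous system disorders", "central nervous system lesion", 5, True),
    ("nervous system disorders", "taste disorder", 8, False),
    ("investigations", "decreased creatinine renal clearance", 86, True),
    ("investigations", "decreased blood albumin", 3, True),
    ("investigations", "increased blood creatinine", 5, True),
    ("investigations", "increased amylase levels", 3, True),
    ("investigations", "increased liver function test", 11, True),
    ("investigations", "increased aspartate aminotransferase", 13, True),
    ("investigations", "increased gamma-glutamyl transferase", 6, True),
    ("investigations", "increased alanine aminotransferase", 15, True),
    ("investigations", "decreased blood sodium", 6, True),
    ("investigations", "increased blood bilirubin", 5, True),
    ("investigations", "decreased blood iron", 4, False),
    ("investigations", "decreased glomerular filtration rate", 3, True),
    ("investigations", "increased blood alkaline phosphatase", 3, True),
    ("investigations", "abnormal liver function test", 3, True),
    ("hepatobiliary disorders", "hepatotoxicity", 15, True),
    ("hepatobiliary disorders", "hepatic cytolysis", 11, True),
    ("hepatobiliary disorders", "hypoalbuminemia", 3, True),
    ("hepatobiliary disorders", "hyperbilirubinemia", 3, True),
    ("hepatobiliary disorders", "cholestasis", 4, True),
    ("hepatobiliary disorders", "hepatitis", 5, True),
    ("hepatobiliary disorders", "liver disorder", 8, True),
    ("ear and labyrinth disorders", "motion sickness", 3, True),
    ("ear and labyrinth disorders", "deafness", 12, False),
    ("ear and labyrinth disorders", "hypoacusis", 18, False),
    ("metabolism and nutrition disorders", "increased appetite", 8, False),
    ("metabolism and nutrition disorders", "decreased appetite", 68, True),
    ("metabolism and nutrition disorders", "dehydration", 22, False),
    ("metabolism and nutrition disorders", "hyponatremia", 8, True),
    ("metabolism and nutrition disorders", "eating disorder", 4, False),
]


def capmatinib_signal_pts() -> pd.DataFrame:
    """79 capmatinib signal PTs with SOC, report count and label status."""
    return pd.DataFrame(_SIGNAL_PTS, columns=["soc", "pt", "cases", "in_label"])


def capmatinib_label_pts() -> list[str]:
    """The 66 signal PTs listed in the capmatinib product label."""
    return [pt for _, pt, _, listed in _SIGNAL_PTS if listed]


def capmatinib_pt_soc_map() -> dict[str, str]:
    """PT -> SOC mapping covering the 79 example PTs."""
    return {pt: soc for soc, pt, _, _ in _SIGNAL_PTS}


def capmatinib_demographics_counts() -> dict[str, dict[str, int]]:
    """Demographic composition counts for the 2,201 capmatinib reports
    encompassed by the 79 signals (per dimension: gender, age group,
    country bucket)."""
    return {
        "gender": {"Male": 262, "Female": 285, "Unknown or missing": 1654},
        "age_group": {"18-49": 3, "50-69": 155, ">=70": 386, "Unknown or missing": 1657},
        "country": {"United States": 216, "Japan": 48, "Europe": 126, "Other": 1811},
    }
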