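"""Published reference data for the Dutch 2012-2015 shortage cohort study.

The underlying patient-level registry is confidential, but the study's
published summary statistics are public: the marginal composition of the
1844-shortage population (per start year, route of administration,
first-level ATC class and originator/generic status) and the table of
the 17 highest-impact shortages with their element ratings.  They serve
as generator defaults and as worked examples.
"""

from __future__ import annotations

import io

import pandas as pd

#: Size of the full Dutch 2012-2015 shortage population.
POPULATION_SIZE = 1844

#: Size of the randomly selected, rated sample.
SAMPLE_SIZE = 324

#: Marginal counts of the full population (n = 1844).
POPULATION_MARGINALS: dict[str, dict] = {
    "year": {2012: 387, 2013: 439, 2014: 470, 2015: 548},
    "route": {
        "oral": 1046, "parenteral": 554, "nasal_inhalation": 42,
        "cutaneous": 77, "rectal": 25, "ocular": 65, "other": 35,
    },
    "atc_class": {
        "A": 168, "B": 91, "C": 240, "D": 83, "G": 77, "H": 84, "J": 311,
        "L": 148, "M": 85, "N": 333, "P": 4, "R": 88, "S": 78, "V": 54,
    },
    "originator": {True: 1011, False: 833},
}

#: Marginal counts of the rated sample (n = 324).
SAMPLE_MARGINALS: dict[str, dict] = {
    "year": {2012: 58, 2013: 77, 2014: 77, 2015: 112},
    "route": {
        "oral": 168, "parenteral": 104, "nasal_inhalation": 8,
        "cutaneous": 13, "rectal": 8, "ocular": 16, "other": 7,
    },
    "atc_class": {
        "A": 27, "B": 17, "C": 38, "D": 15, "G": 13, "H": 11, "J": 59,
        "L": 26, "M": 15, "N": 56, "P": 3, "R": 12, "S": 17, "V": 15,
    },
    "originator": {True: 176, False: 148},
}

# Shortages with an overall patient-impact rating of 36 or higher, with
# the published per-element ratings (1 = low, 2 = moderate, 3 = high) and
# overall score.
_HIGH_IMPACT_CSV = """\
product_name,atc_class,route,originator,rating_alternative_product,rating_disease,rating_susceptibility,rating_costs,rating_n_patients,overall_published
BCG instillation,L,parenteral,true,2,3,3,2,2,72
Risperidone orodispersible tablet,N,oral,true,2,3,3,3,1,54
Epinephrine injection,C,parenteral,true,2,3,2,2,2,48
Methoxy polyethylene glycol-epoetin beta injection,B,parenteral,true,2,2,2,3,2,48
Bendamustine powder for infusion,L,parenteral,true,2,3,1,3,2,36
Bromperidol drops for oral use,N,oral,true,2,3,3,2,1,36
Dexamethasone tablet,H,oral,false,2,3,1,3,2,36
Disulfiram dispersible tablet,N,oral,true,2,3,2,3,1,36
Feneticilline capsule,J,oral,true,2,2,1,3,3,36
Flupentixol tablet,N,oral,true,2,3,3,2,1,36
Ibuprofen granules,M,oral,true,2,3,1,2,3,36
Isosorbide mononitrate sustained tablet,C,oral,true,2,3,1,3,2,36
Lamotrigine dispersible tablet,N,oral,false,2,3,2,3,1,36
Olanzapine orodispersible tablet,N,oral,false,2,3,3,2,1,36
Pergolide tablet,N,oral,false,2,3,2,3,1,36
Topiramate tablet,N,oral,false,2,3,2,3,1,36
Vincristine sulfate injection,L,parenteral,false,2,3,1,3,2,36
"""


def load_high_impact_examples() -> pd.DataFrame:
    """The 17 published highest-impact shortages with element ratings."""
    return pd.read_csv(io.StringIO(_HIGH_IMPACT_CSV),
                       dtype={"originator": bool})


def population_proportions(variable: str) -> dict:
    """Population marginal counts normalised to proportions."""
    counts = POPULATION_MARGINALS[variable]
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}
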