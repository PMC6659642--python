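"""gwascurate: machine curation of GWAS literature.

Extracts (publication, variant rsid, phenotype, p-value) associations from
full-text JATS/PMC-style XML using regex/dictionary candidate generation,
hand-written labeling functions, and a generative label model trained
without ground-truth labels.
"""

from importlib import resources

from .candgen import OntologyDictionary, normalize_pvalue
from .docmodel import parse_document
from .extractors import ModelConfig, extract_document, records_to_frame
from .labelmodel import LabelModelParams, fit, posterior, predict

__version__ = "0.1.0"

__all__ = [
    "parse_document",
    "normalize_pvalue",
    "OntologyDictionary",
    "ModelConfig",
    "extract_document",
    "records_to_frame",
    "LabelModelParams",
    "fit",
    "posterior",
    "predict",
    "load_builtin_dictionary",
]


def load_builtin_dictionary() -> OntologyDictionary:
    """The packaged mini phenotype dictionary (term, canonical, source TSV)."""
    path = resources.files("gwascurate").joinpath("data/phenotypes_mini.tsv")
    with resources.as_file(path) as p:
        return OntologyDictionary.from_tsv(p)
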