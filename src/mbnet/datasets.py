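"""Packaged reference fixtures.

Two small flat files ship with the package: the transcribed list of 46
metabolite biomarkers reported for schizophrenia and bipolar disorder
(47 rows; acetate is listed once per disease), and a hand-built partial
metabolic neighbourhood of L-glutamate whose enzyme labels exercise the
path-length-two extraction rule (twelve enzymes within reach, the
carbamoyl-phosphate synthase CPS1 beyond it).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from . import mapping


def _data_path(name: str) -> Path:
    return Path(resources.files("mbnet").joinpath("data", name))


def biomarker_fixture_path() -> Path:
    return _data_path("biomarkers_scz_bd.tsv")


def glutamate_graph_path() -> Path:
    return _data_path("glutamate_neighborhood.tsv")


def load_biomarker_fixture() -> list[mapping.Biomarker]:
    """The curated SCZ/BD biomarker list (46 unique metabolites)."""
    return mapping.load_biomarkers(biomarker_fixture_path())


def load_glutamate_graph() -> mapping.MetabolicGraph:
    """Partial L-glutamate metabolic neighbourhood with enzyme labels."""
    return mapping.MetabolicGraph.from_file(glutamate_graph_path())
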