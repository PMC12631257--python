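"""Bundled lookup tables.

The packaged PT→SOC table is a small toy dictionary covering the terms
used by the synthetic generator and examples; real analyses should plug
in a licensed MedDRA export with the same two-column (pt,soc) layout.
"""

from __future__ import annotations

from importlib import resources

from .io import MedDRADictionary, SynonymTable

__all__ = ["load_default_dictionary", "load_default_synonyms"]


def _data_path(name: str):
    return resources.files("pvsignal").joinpath("data", name)


def load_default_dictionary() -> MedDRADictionary:
    with resources.as_file(_data_path("pt_soc.csv")) as p:
        return MedDRADictionary.from_csv(p)


def load_default_synonyms() -> SynonymTable:
    with resources.as_file(_data_path("synonyms.csv")) as p:
        return SynonymTable.from_csv(p)
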