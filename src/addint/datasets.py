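"""Packaged example data."""

from __future__ import annotations

from importlib import resources

from .io import read_table
from .model_fit import ContingencyTable2x4

__all__ = ["load_oral_cancer", "oral_cancer_path"]


def oral_cancer_path():
    """Path-like handle to the packaged oral-cancer CSV fixture."""
    return resources.files("addint") / "data" / "oral_cancer.csv"


def load_oral_cancer() -> ContingencyTable2x4:
    """Oral cancer and smoking/alcohol case-control table.

    A classic 2x4 case-control table from a study of smoking (factor A) and
    alcohol use (factor B) in relation to oral cancer among male veterans
    under 60: cases (3, 8, 6, 225) and controls (20, 18, 12, 166) across
    (neither, smoking only, alcohol only, both).  The heavily depleted
    unexposed cells make it a stress test for interval procedures.
    """
    with resources.as_file(oral_cancer_path()) as p:
        return read_table(p)
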