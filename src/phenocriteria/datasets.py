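"""Access to the shipped miniature fixture files."""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def _data_path(name: str) -> Path:
    return Path(resources.files("phenocriteria") / "data" / name)


def mini_obo_path() -> Path:
    """Path to the ~40-term miniature ontology fixture."""
    return _data_path("mini_hp.obo")


def mini_annotations_path() -> Path:
    """Path to the 10-disease miniature annotation table fixture."""
    return _data_path("mini_annotations.tsv")
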