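"""Packaged data: the literature-curated multi-study variant catalogue.

The bundled TSV transcribes the published case reports for the 18 genes
in which pregnancy-loss variants were reported by two or more
independent studies (51 case records; compound-heterozygous pairs are
single records with two variant strings). Study identifiers are opaque
citation keys.
"""

from __future__ import annotations

from importlib import resources as importlib_resources
from pathlib import Path

from .catalogue import CatalogueRecord, load_catalogue

_FIXTURE_NAME = "multistudy_pl_catalogue.tsv"


def multistudy_catalogue_path() -> Path:
    """Filesystem path of the packaged catalogue TSV."""
    return Path(importlib_resources.files("plgenes") / "data" / _FIXTURE_NAME)


def load_multistudy_catalogue() -> list[CatalogueRecord]:
    """Load the packaged multi-study pregnancy-loss catalogue."""
    return load_catalogue(multistudy_catalogue_path())
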