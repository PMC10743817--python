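"""Gene-symbol normalization shared by every loader.

All cross-resource joins in this package are string joins on HGNC-style
symbols, so every reader funnels symbols through :func:`normalize_symbol`
with the same optional alias map. Alias resolution happens *after* case
normalization, so alias files may be written in any case.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping


def normalize_symbol(symbol: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Trim and uppercase a gene symbol, then apply the optional alias map.

    Raises ``ValueError`` for symbols that are empty after trimming.
    """
    sym = str(symbol).strip().upper()
    if not sym:
        raise ValueError("gene symbol is empty after normalization")
    if alias_map:
        sym = alias_map.get(sym, sym)
    return sym


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of ``legacy_symbol<TAB>current_symbol``.

    Both sides are case-normalized; the returned mapping is suitable for
    the ``alias_map`` argument of every loader in :mod:`plgenes.resources`.
    """
    aliases: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            aliases[row[0].strip().upper()] = row[1].strip().upper()
    return aliases
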