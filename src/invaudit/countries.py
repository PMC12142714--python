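"""Country-name normalization against the packaged alias table.

Repository metadata spells countries inconsistently ("USA", "United States of
America", "Viet Nam"); the audit normalizes every spelling to an ISO-3166-like
two-letter code plus one canonical display name. Unmatched names are passed
through flagged rather than dropped, so no record is silently lost.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = ["CountryMatch", "normalize_country", "known_countries"]


@dataclass(frozen=True)
class CountryMatch:
    code: str | None  # None when the name did not match the alias table
    name: str  # canonical name, or the verbatim input when unmatched

    @property
    def recognized(self) -> bool:
        return self.code is not None


@lru_cache(maxsize=1)
def _alias_table() -> dict[str, tuple[str, str]]:
    table: dict[str, tuple[str, str]] = {}
    path = resources.files("invaudit.data").joinpath("country_aliases.tsv")
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            table[row["alias"].casefold()] = (row["code"], row["canonical"])
    # codes resolve to themselves so normalized output re-ingests cleanly
    for code, canonical in list(table.values()):
        table.setdefault(code.casefold(), (code, canonical))
    return table


def normalize_country(name: str | None) -> CountryMatch:
    """Resolve a free-text country name; unmatched input is kept verbatim."""
    if name is None:
        return CountryMatch(None, "")
    text = name.strip()
    hit = _alias_table().get(text.casefold())
    if hit is None:
        return CountryMatch(None, text)
    code, canonical = hit
    return CountryMatch(code, canonical)


@lru_cache(maxsize=1)
def known_countries() -> dict[str, str]:
    """Code -> canonical name for every country in the alias table."""
    return {code: canonical for code, canonical in _alias_table().values()}
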