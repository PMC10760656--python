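"""Regional species checklist: loading, validation, and name reconciliation.

Sequence databases lag behind checklist taxonomy, so record names must be
mapped onto checklist names through canonicalization (binomial reduction,
case and diacritic normalization) and an explicit synonym table. Matching is
performed at species rank: subspecific epithets are dropped before lookup.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from refgap.errors import MalformedNameError, SchemaError, ValidationError

__all__ = [
    "IucnStatus", "Taxon", "SynonymMap", "Checklist", "MatchResult",
    "canonicalize_name", "resolve_name", "load_checklist", "load_synonyms",
    "THREATENED_STATUSES",
]


class IucnStatus(str, Enum):
    """IUCN Red List category codes."""

    CR = "CR"  # Critically Endangered
    EN = "EN"  # Endangered
    VU = "VU"  # Vulnerable
    NT = "NT"  # Near Threatened
    LC = "LC"  # Least Concern
    DD = "DD"  # Data Deficient
    NE = "NE"  # Not Evaluated


#: Categories counted as "threatened" (IUCN Red List threatened tier).
THREATENED_STATUSES = frozenset({IucnStatus.CR, IucnStatus.EN, IucnStatus.VU})

# tokens that flag hybrids or open nomenclature; such names are never matched
_UNIDENTIFIED_TOKENS = {"x", "sp", "sp.", "cf", "cf.", "aff", "aff."}

_ALPHA_WORD = re.compile(r"^[a-zA-Z-]+$")


def _strip_diacritics(text: str) -> str:
    return "".join(
        c for c in unicodedata.normalize("NFKD", text)
        if not unicodedata.combining(c)
    )


def canonicalize_name(raw: str) -> str:
    """Reduce a raw scientific name to a canonical two-word binomial.

    Whitespace is collapsed, diacritics stripped, the genus capitalized and
    the epithet lowercased. A third (subspecific) epithet is dropped, so
    trinomials collapse to the species binomial.

    Raises
    ------
    MalformedNameError
        If fewer than two alphabetic words remain after cleanup, or the name
        contains hybrid/open-nomenclature markers ("x", "sp.", "cf.").
    """
    if raw is None or not str(raw).strip():
        raise MalformedNameError("empty scientific name")
    words = _strip_diacritics(str(raw)).split()
    if any(w.lower() in _UNIDENTIFIED_TOKENS for w in words):
        raise MalformedNameError(
            f"hybrid or unidentified name marker in {raw!r}"
        )
    words = [w for w in words if _ALPHA_WORD.match(w)]
    if len(words) < 2:
        raise MalformedNameError(
            f"expected at least genus and epithet in {raw!r}"
        )
    genus, epithet = words[0].capitalize(), words[1].lower()
    return f"{genus} {epithet}"


@dataclass(frozen=True)
class Taxon:
    """One checklist species with its audit-relevant attributes."""

    scientific_name: str
    order: str
    family: str
    endemic: bool = False
    iucn_status: IucnStatus = IucnStatus.NE

    def __post_init__(self) -> None:
        if not self.order or not self.family:
            raise ValidationError(
                f"{self.scientific_name}: order and family must be non-empty"
            )

    @property
    def threatened(self) -> bool:
        return self.iucn_status in THREATENED_STATUSES


class SynonymMap:
    """Alias → accepted-name mapping, one level deep.

    No alias may map to two accepted names, and accepted names may not
    themselves appear as aliases, so resolution never chains or cycles.
    """

    def __init__(self, pairs: dict[str, str] | None = None):
        self._map: dict[str, str] = {}
        for alias, accepted in (pairs or {}).items():
            self.add(alias, accepted)

    def add(self, alias: str, accepted: str) -> None:
        alias_c = canonicalize_name(alias)
        accepted_c = canonicalize_name(accepted)
        if alias_c == accepted_c:
            raise ValidationError(f"alias {alias_c!r} maps to itself")
        existing = self._map.get(alias_c)
        if existing is not None and existing != accepted_c:
            raise ValidationError(
                f"alias {alias_c!r} maps to both {existing!r} and {accepted_c!r}"
            )
        if accepted_c in self._map:
            raise ValidationError(
                f"accepted name {accepted_c!r} is itself an alias"
            )
        if alias_c in set(self._map.values()):
            raise ValidationError(
                f"alias {alias_c!r} is already an accepted name in the map"
            )
        self._map[alias_c] = accepted_c

    def get(self, name: str) -> str | None:
        return self._map.get(name)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, name: str) -> bool:
        return name in self._map

    def items(self):
        return self._map.items()


@dataclass
class Checklist:
    """An ordered, validated collection of checklist taxa."""

    taxa: list[Taxon]
    name: str = "checklist"
    _by_name: dict[str, Taxon] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValidationError("checklist is empty")
        self._by_name = {}
        dupes = []
        for t in self.taxa:
            key = t.scientific_name.lower()
            if key in self._by_name:
                dupes.append(t.scientific_name)
            self._by_name[key] = t
        if dupes:
            raise ValidationError(f"duplicate checklist names: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.taxa)

    def __iter__(self):
        return iter(self.taxa)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._by_name

    def get(self, name: str) -> Taxon | None:
        return self._by_name.get(name.lower())

    @property
    def names(self) -> list[str]:
        return [t.scientific_name for t in self.taxa]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of resolving one record name against the checklist.

    ``status`` is one of ``direct``, ``synonym``, ``unmatched``;
    ``accepted_name`` is set for the first two. ``reason`` carries a machine
    code for unmatched names (``not-on-checklist``, ``dangling-synonym``,
    ``unidentified``).
    """

    query: str
    status: str
    accepted_name: str | None = None
    reason: str | None = None

    @property
    def matched(self) -> bool:
        return self.status in ("direct", "synonym")


def resolve_name(
    name: str, syn: SynonymMap, checklist: Checklist
) -> MatchResult:
    """Resolve a canonicalized name: direct hit, synonym hit, or unmatched.

    Dangling synonyms (alias whose accepted name is absent from the
    checklist) are reported as unmatched with reason ``dangling-synonym``.
    """
    try:
        canon = canonicalize_name(name)
    except MalformedNameError:
        return MatchResult(query=name, status="unmatched", reason="unidentified")
    if canon in checklist:
        hit = checklist.get(canon)
        return MatchResult(query=name, status="direct",
                           accepted_name=hit.scientific_name)
    target = syn.get(canon)
    if target is not None:
        if target in checklist:
            hit = checklist.get(target)
            return MatchResult(query=name, status="synonym",
                               accepted_name=hit.scientific_name)
        return MatchResult(query=name, status="unmatched",
                           reason="dangling-synonym")
    return MatchResult(query=name, status="unmatched", reason="not-on-checklist")


_TRUE_TOKENS = {"true", "1", "yes", "y", "t", "(e)", "e"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f", "", "nan"}


def _parse_endemic(value) -> bool:
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValidationError(f"unrecognized endemic flag: {value!r}")


_CHECKLIST_COLUMNS = ("scientific_name", "order", "family", "endemic",
                      "iucn_status")


def load_checklist(path: str | Path, name: str | None = None) -> Checklist:
    """Load and validate a checklist CSV.

    Expected columns: scientific_name, order, family, endemic, iucn_status.
    Names are canonicalized; an ``(E)`` mark appended to the name also sets
    the endemic flag, mirroring common checklist typography.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _CHECKLIST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    taxa: list[Taxon] = []
    for _, row in df.iterrows():
        raw_name = row["scientific_name"]
        endemic = _parse_endemic(row["endemic"])
        if "(E)" in raw_name or "(e)" in raw_name:
            endemic = True
            raw_name = raw_name.replace("(E)", "").replace("(e)", "")
        try:
            status = IucnStatus(str(row["iucn_status"]).strip().upper() or "NE")
        except ValueError:
            raise ValidationError(
                f"{raw_name!r}: unknown IUCN status {row['iucn_status']!r}"
            ) from None
        taxa.append(Taxon(
            scientific_name=canonicalize_name(raw_name),
            order=str(row["order"]).strip(),
            family=str(row["family"]).strip(),
            endemic=endemic,
            iucn_status=status,
        ))
    return Checklist(taxa=taxa, name=name or path.stem)


def load_synonyms(path: str | Path) -> SynonymMap:
    """Load a two-column synonym CSV with columns ``alias``, ``accepted``."""
    df = pd.read_csv(Path(path), dtype=str).fillna("")
    missing = [c for c in ("alias", "accepted") if c not in df.columns]
    if missing:
        raise SchemaError(f"synonym table missing columns {missing}")
    syn = SynonymMap()
    for _, row in df.iterrows():
        syn.add(row["alias"], row["accepted"])
    return syn
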