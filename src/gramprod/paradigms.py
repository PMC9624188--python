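"""Inflectional paradigms: agreement-slot inventories and allomorph maps.

A *paradigm* fixes the ceiling of per-lemma creativity: a lemma can at most be
attested in every agreement slot of the paradigm, so creativity values live in
``[1, K]`` with ``K = max_creativity`` (the number of slots). Surface markers
(affixes like ``-en`` or subject pronouns like ``she``) are normalized to slot
labels before counting, so allomorphic variants of one slot are never counted
as separate combinations: Spanish ``-as``/``-es`` are both second singular,
English ``she``/``he`` are both third singular. This slot-level granularity is
what makes the six-way ceiling hold for both built-in paradigms.

Two paradigms are built in:

``es-pres-ind``
    Spanish present indicative person/number suffixes (six slots, twelve
    affix allomorphs, diacritic-bearing plural forms preserved).
``en-prog``
    English present progressive "pronoun + be + V-ing" frames, keyed by the
    subject pronoun (six slots; *you* is slot-ambiguous on the surface and is
    expected to arrive disambiguated as ``you_sg``/``you_pl``).

Custom paradigms are loaded from small YAML files with keys ``name``,
``language``, ``slots`` (ordered list) and ``allomorphs`` (marker -> slot).
"""

from __future__ import annotations

import os
import unicodedata
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ParadigmConfigError, UnknownMarkerError, UnknownParadigmError

__all__ = ["Paradigm", "load_paradigm", "normalize_marker", "builtin_paradigm_names"]


def _key(marker: str) -> str:
    """Canonical lookup key for a surface marker.

    Unicode NFC so composed/decomposed diacritics compare equal, casefold so
    matching is case-insensitive, and one leading hyphen stripped so affixes
    may be written either ``-en`` or ``en``. Diacritics themselves are
    preserved (``áis`` is not ``ais``).
    """
    m = unicodedata.normalize("NFC", marker).casefold()
    if m.startswith("-"):
        m = m[1:]
    return m


@dataclass(frozen=True)
class Paradigm:
    """An agreement paradigm: ordered slots plus a surface-marker map."""

    name: str
    language: str
    slots: tuple[str, ...]
    allomorph_map: Mapping[str, str]
    _slot_lookup: dict[str, str] = field(init=False, repr=False, compare=False)
    _allo_lookup: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.slots:
            raise ParadigmConfigError(f"paradigm {self.name!r}: empty slot inventory")
        seen: dict[str, str] = {}
        for s in self.slots:
            if not s:
                raise ParadigmConfigError(f"paradigm {self.name!r}: blank slot label")
            k = _key(s)
            if k in seen:
                raise ParadigmConfigError(
                    f"paradigm {self.name!r}: duplicate slot {s!r} (clashes with {seen[k]!r})"
                )
            seen[k] = s
        allo: dict[str, str] = {}
        for marker, slot in self.allomorph_map.items():
            if _key(slot) not in seen:
                raise ParadigmConfigError(
                    f"paradigm {self.name!r}: allomorph {marker!r} maps to "
                    f"unknown slot {slot!r}"
                )
            mk = _key(marker)
            if mk in allo and allo[mk] != seen[_key(slot)]:
                raise ParadigmConfigError(
                    f"paradigm {self.name!r}: allomorph {marker!r} mapped to two slots"
                )
            allo[mk] = seen[_key(slot)]
        object.__setattr__(self, "_slot_lookup", seen)
        object.__setattr__(self, "_allo_lookup", allo)

    @property
    def max_creativity(self) -> int:
        """K: the number of agreement slots, the ceiling of per-lemma creativity."""
        return len(self.slots)


#: Table of built-in paradigms.  Both have six agreement slots.
_BUILTINS: dict[str, Paradigm] = {}


def _register(p: Paradigm) -> Paradigm:
    _BUILTINS[p.name] = p
    return p


_PERSON_NUMBER = ("1SG", "2SG", "3SG", "1PL", "2PL", "3PL")

ES_PRES_IND = _register(
    Paradigm(
        name="es-pres-ind",
        language="es",
        slots=_PERSON_NUMBER,
        allomorph_map={
            "-o": "1SG",
            "-as": "2SG",
            "-es": "2SG",
            "-a": "3SG",
            "-e": "3SG",
            "-amos": "1PL",
            "-emos": "1PL",
            "-áis": "2PL",
            "-éis": "2PL",
            "-ís": "2PL",
            "-an": "3PL",
            "-en": "3PL",
        },
    )
)

EN_PROG = _register(
    Paradigm(
        name="en-prog",
        language="en",
        slots=_PERSON_NUMBER,
        allomorph_map={
            "I": "1SG",
            "you_sg": "2SG",
            "she": "3SG",
            "he": "3SG",
            "it": "3SG",
            "we": "1PL",
            "you_pl": "2PL",
            "they": "3PL",
        },
    )
)


def builtin_paradigm_names() -> tuple[str, ...]:
    return tuple(sorted(_BUILTINS))


def load_paradigm(name_or_path: str | os.PathLike[str]) -> Paradigm:
    """Return a built-in paradigm by name, or load one from a YAML config.

    The config is a flat mapping with keys ``name``, ``language``, ``slots``
    (an ordered list of unique labels) and ``allomorphs`` (marker -> slot).
    Validation errors name the offending entry.
    """
    key = str(name_or_path)
    if key in _BUILTINS:
        return _BUILTINS[key]
    if not os.path.exists(key):
        raise UnknownParadigmError(
            f"unknown paradigm {key!r}; built-ins are {', '.join(builtin_paradigm_names())} "
            "and anything else must be a readable config file"
        )
    with open(key, encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParadigmConfigError(f"cannot parse paradigm config {key!r}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParadigmConfigError(f"paradigm config {key!r} is not a mapping")
    missing = {"name", "slots"} - raw.keys()
    if missing:
        raise ParadigmConfigError(f"paradigm config {key!r} missing fields: {sorted(missing)}")
    slots = raw["slots"]
    if not isinstance(slots, (list, tuple)):
        raise ParadigmConfigError(f"paradigm config {key!r}: 'slots' must be a list")
    allomorphs = raw.get("allomorphs") or {}
    if not isinstance(allomorphs, dict):
        raise ParadigmConfigError(f"paradigm config {key!r}: 'allomorphs' must be a mapping")
    return Paradigm(
        name=str(raw["name"]),
        language=str(raw.get("language", "und")),
        slots=tuple(str(s) for s in slots),
        allomorph_map={str(m): str(s) for m, s in allomorphs.items()},
    )


def normalize_marker(paradigm: Paradigm, marker: str, strict: bool = False) -> str:
    """Map a surface marker to its agreement-slot label.

    Slot labels pass through unchanged (normalization is idempotent); known
    allomorphs collapse to their slot.  An unmapped marker is returned in its
    canonical folded form when ``strict`` is off — pass-through mode for token
    lists that are already slot-coded in some private scheme — and raises
    :class:`UnknownMarkerError` when ``strict`` is on.
    """
    if not marker:
        raise UnknownMarkerError("empty marker")
    k = _key(marker)
    slot = paradigm._slot_lookup.get(k)
    if slot is not None:
        return slot
    slot = paradigm._allo_lookup.get(k)
    if slot is not None:
        return slot
    if strict:
        raise UnknownMarkerError(
            f"unknown marker {marker!r} for paradigm {paradigm.name!r}"
        )
    # pass-through: return the folded form so repeated normalization is stable
    return unicodedata.normalize("NFC", marker).casefold()
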