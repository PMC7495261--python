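"""Prefecture assignment from place names, postal codes and phone numbers.

Regional identifiers inside a tweet — proper-noun/region tokens, 7-digit
postal codes, and domestic phone numbers — are resolved to one of Japan's 47
prefectures through three offline lookup tables (gazetteer word, 3-digit
postal prefix, area-code prefix).  Foreign sites (Chernobyl, Three Mile
Island) and generic address words that cannot identify a prefecture
("…丁目", "…番地") fall into an OTHER bucket.  A tweet naming several
regions is assigned to all of them (multi-label); OTHER is used only when no
concrete prefecture matched at all.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .sentiment import REGION_POS, Token


class Prefecture(str, Enum):
    HOKKAIDO = "HOKKAIDO"; AOMORI = "AOMORI"; IWATE = "IWATE"; MIYAGI = "MIYAGI"
    AKITA = "AKITA"; YAMAGATA = "YAMAGATA"; FUKUSHIMA = "FUKUSHIMA"
    IBARAKI = "IBARAKI"; TOCHIGI = "TOCHIGI"; GUNMA = "GUNMA"
    SAITAMA = "SAITAMA"; CHIBA = "CHIBA"; TOKYO = "TOKYO"; KANAGAWA = "KANAGAWA"
    NIIGATA = "NIIGATA"; TOYAMA = "TOYAMA"; ISHIKAWA = "ISHIKAWA"; FUKUI = "FUKUI"
    YAMANASHI = "YAMANASHI"; NAGANO = "NAGANO"; GIFU = "GIFU"; SHIZUOKA = "SHIZUOKA"
    AICHI = "AICHI"; MIE = "MIE"; SHIGA = "SHIGA"; KYOTO = "KYOTO"; OSAKA = "OSAKA"
    HYOGO = "HYOGO"; NARA = "NARA"; WAKAYAMA = "WAKAYAMA"; TOTTORI = "TOTTORI"
    SHIMANE = "SHIMANE"; OKAYAMA = "OKAYAMA"; HIROSHIMA = "HIROSHIMA"
    YAMAGUCHI = "YAMAGUCHI"; TOKUSHIMA = "TOKUSHIMA"; KAGAWA = "KAGAWA"
    EHIME = "EHIME"; KOCHI = "KOCHI"; FUKUOKA = "FUKUOKA"; SAGA = "SAGA"
    NAGASAKI = "NAGASAKI"; KUMAMOTO = "KUMAMOTO"; OITA = "OITA"
    MIYAZAKI = "MIYAZAKI"; KAGOSHIMA = "KAGOSHIMA"; OKINAWA = "OKINAWA"
    OTHER = "OTHER"


CONCRETE_PREFECTURES = tuple(p for p in Prefecture if p is not Prefecture.OTHER)


@dataclass(frozen=True)
class Gazetteer:
    """Three lookup tables (place word, postal prefix, phone prefix) → prefecture."""

    place_names: Mapping[str, Prefecture]
    postal_prefixes: Mapping[str, Prefecture]
    phone_prefixes: Mapping[str, Prefecture]

    def __post_init__(self) -> None:
        for p in self.postal_prefixes:
            if not (len(p) == 3 and p.isdigit()):
                raise ValueError(f"postal prefix {p!r} is not 3 digits")
        for p in self.phone_prefixes:
            if not p.startswith("0"):
                raise ValueError(f"phone prefix {p!r} must start with 0")

    def vocabulary(self) -> frozenset[str]:
        """All place words, for seeding the builtin tokenizer."""
        return frozenset(self.place_names)

    @property
    def foreign_names(self) -> frozenset[str]:
        return frozenset(w for w, p in self.place_names.items() if p is Prefecture.OTHER)


def _read_tsv(path) -> list[tuple[str, str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if line:
                a, b = line.split("\t")
                rows.append((a, b))
    return rows


def load_gazetteer(
    place_path: str | Path, postal_path: str | Path, phone_path: str | Path
) -> Gazetteer:
    """Load the three TSV tables (word/prefix → prefecture name)."""
    places = {w: Prefecture(p) for w, p in _read_tsv(place_path)}
    postal = {w: Prefecture(p) for w, p in _read_tsv(postal_path)}
    phone = {w: Prefecture(p) for w, p in _read_tsv(phone_path)}
    return Gazetteer(places, postal, phone)


def default_gazetteer() -> Gazetteer:
    data = resources.files("radsent.data")
    with resources.as_file(data / "gazetteer.tsv") as g, resources.as_file(
        data / "postal_prefixes.tsv"
    ) as po, resources.as_file(data / "phone_prefixes.tsv") as ph:
        return load_gazetteer(g, po, ph)


def load_population(path: str | Path) -> dict[Prefecture, int]:
    table = {}
    for name, raw in _read_tsv(path):
        pref = Prefecture(name)
        pop = int(raw)
        if pop <= 0:
            raise ValueError(f"non-positive population for {name}")
        table[pref] = pop
    return table


def default_population() -> dict[Prefecture, int]:
    """Prefecture populations, reference date 2011-10-01."""
    with resources.as_file(resources.files("radsent.data") / "population_2011.tsv") as p:
        return load_population(p)


# --- identifier extraction --------------------------------------------------

# ASCII hyphen last so it stays literal inside regex character classes
_HYPHENS = "ー−‐–-"
_POSTAL = re.compile(rf"(?<!\d)〒?\s*(\d{{3}})[{_HYPHENS}]?(\d{{4}})(?!\d)")
# Domestic numbers: leading 0, hyphen-tolerant, 9–11 digits total.
_PHONE = re.compile(rf"(?<![\d{_HYPHENS}])(0[\d{_HYPHENS}]{{7,13}}\d)(?![\d{_HYPHENS}])")


def extract_region_tokens(tokens: Iterable[Token]) -> list[str]:
    """Surfaces of tokens tagged noun / proper noun / region, in order."""
    return [t.surface for t in tokens if (t.pos, t.pos_sub1, t.pos_sub2) == REGION_POS]


def extract_postal_codes(text: str) -> list[str]:
    """7-digit postal codes (〒 and full-width tolerant), digits only."""
    text = unicodedata.normalize("NFKC", text)
    return [a + b for a, b in _POSTAL.findall(text)]


def extract_phone_numbers(text: str) -> list[str]:
    """Candidate domestic phone numbers as digit strings (9–11 digits)."""
    text = unicodedata.normalize("NFKC", text)
    out = []
    for raw in _PHONE.findall(text):
        digits = re.sub(rf"[{_HYPHENS}]", "", raw)
        if 9 <= len(digits) <= 11:
            out.append(digits)
    return out


def _strip_phones(text: str) -> str:
    """Remove phone-number spans so their tails cannot masquerade as postal codes."""
    text = unicodedata.normalize("NFKC", text)

    def repl(m: re.Match) -> str:
        digits = re.sub(rf"[{_HYPHENS}]", "", m.group(1))
        return " " if 9 <= len(digits) <= 11 else m.group(1)

    return _PHONE.sub(repl, text)


def resolve_prefectures(text: str, tokens: Iterable[Token], gazetteer: Gazetteer) -> set[Prefecture]:
    """Union of place-name, postal-code and phone-number resolutions.

    Identifiers that exist but cannot name a concrete prefecture (foreign
    sites, unknown prefixes) yield OTHER — and OTHER is reported only when
    nothing concrete matched, so it never co-occurs with a real prefecture.
    An identifier-free tweet returns the empty set.
    """
    concrete: set[Prefecture] = set()
    saw_unresolvable = False

    for word in extract_region_tokens(tokens):
        pref = gazetteer.place_names.get(word)
        if pref is None or pref is Prefecture.OTHER:
            saw_unresolvable = True
        else:
            concrete.add(pref)

    for number in extract_phone_numbers(text):
        hit = None
        for length in range(min(5, len(number)), 1, -1):  # longest prefix wins
            hit = gazetteer.phone_prefixes.get(number[:length])
            if hit is not None:
                break
        if hit is None:
            saw_unresolvable = True
        else:
            concrete.add(hit)

    for code in extract_postal_codes(_strip_phones(text)):
        pref = gazetteer.postal_prefixes.get(code[:3])
        if pref is None:
            saw_unresolvable = True
        else:
            concrete.add(pref)

    if concrete:
        return concrete
    if saw_unresolvable:
        return {Prefecture.OTHER}
    return set()


def per_capita_rate(count: int, population: int) -> int:
    """Tweets per 1000 residents, rounded half away from zero to an integer."""
    if population <= 0:
        raise ValueError("population must be positive")
    x = count / population * 1000.0
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)
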