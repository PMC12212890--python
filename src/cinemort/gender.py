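"""Name-based gender labelling and the binary consolidation rules.

Raw labels come from a packaged first-name dictionary (six-valued
vocabulary); consolidation merges mostly_male into man and mostly_female
into woman, and excludes androgynous / unknown names from gender-stratified
statistics while keeping them in the overall cause counts.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

RAW_LABELS = ("male", "female", "mostly_male", "mostly_female", "androgynous", "unknown")
CONSOLIDATED_LABELS = ("man", "woman", "excluded")

_CONSOLIDATION = {
    "male": "man",
    "mostly_male": "man",
    "female": "woman",
    "mostly_female": "woman",
    "androgynous": "excluded",
    "unknown": "excluded",
}

_HONORIFICS = {
    "dr", "mr", "mrs", "ms", "miss", "sir", "dame", "lady", "lord",
    "prof", "professor", "rev", "fr", "st", "capt", "sgt", "col", "gen",
}

_PAREN_RE = re.compile(r"\([^)]*\)")


@dataclass
class NameDictionary:
    """Case-insensitive first-name -> raw gender label lookup."""

    entries: dict[str, str]
    source: str = ""

    def __post_init__(self) -> None:
        bad = set(self.entries.values()) - set(RAW_LABELS)
        if bad:
            raise ValueError(f"invalid labels in name dictionary: {sorted(bad)}")
        self.entries = {k.lower(): v for k, v in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def names_with_label(self, labels: str | Iterable[str]) -> list[str]:
        wanted = {labels} if isinstance(labels, str) else set(labels)
        return sorted(n for n, lab in self.entries.items() if lab in wanted)


def load_name_dictionary(source: str | Path | None = None) -> NameDictionary:
    """Load a two-column (name TAB label) dictionary; default is the packaged file."""
    if source is None:
        ref = resources.files("cinemort.data").joinpath("name_gender.tsv")
        text = ref.read_text(encoding="utf-8")
        source_id = "packaged:name_gender.tsv"
    else:
        text = Path(source).read_text(encoding="utf-8")
        source_id = str(source)
    entries: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{source_id}:{lineno}: expected 'name<TAB>label', got {line!r}")
        entries[parts[0]] = parts[1]
    return NameDictionary(entries=entries, source=source_id)


def extract_first_name(actor_name: str) -> str:
    """First whitespace token of an actor name, sans honorifics/parentheticals."""
    cleaned = _PAREN_RE.sub(" ", actor_name).replace('"', " ").strip()
    for token in cleaned.split():
        if token.rstrip(".").lower() in _HONORIFICS:
            continue
        return token.strip(",")
    return ""


def lookup_gender(first_name: str, name_dictionary: NameDictionary) -> str:
    """Dictionary label for a first name, ``unknown`` when absent.

    Hyphenated names try the full hyphenated form first, then the first
    component.
    """
    if not first_name:
        return "unknown"
    key = first_name.lower()
    if key in name_dictionary.entries:
        return name_dictionary.entries[key]
    if "-" in key:
        head = key.split("-", 1)[0]
        if head in name_dictionary.entries:
            logger.debug("hyphenated name %r resolved via component %r", first_name, head)
            return name_dictionary.entries[head]
    return "unknown"


def classify_actor(actor_name: str, name_dictionary: NameDictionary) -> str:
    return lookup_gender(extract_first_name(actor_name), name_dictionary)


def consolidate(raw_label: str) -> str:
    """male/mostly_male -> man; female/mostly_female -> woman; else excluded."""
    try:
        return _CONSOLIDATION[raw_label]
    except KeyError:
        raise ValueError(f"invalid raw gender label: {raw_label!r}") from None


@dataclass
class GenderTally:
    """Counts over the six raw labels and the three consolidated labels."""

    before: dict[str, int] = field(default_factory=dict)
    after: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.before.values())

    @property
    def excluded_fraction(self) -> float:
        return self.after["excluded"] / self.total if self.total else 0.0


def tally_genders(raw_labels: Sequence[str]) -> GenderTally:
    """Tally raw labels and apply the consolidation arithmetic."""
    before = Counter({lab: 0 for lab in RAW_LABELS})
    for lab in raw_labels:
        if lab not in _CONSOLIDATION:
            raise ValueError(f"invalid raw gender label: {lab!r}")
        before[lab] += 1
    after = Counter({lab: 0 for lab in CONSOLIDATED_LABELS})
    for lab, n in before.items():
        after[consolidate(lab)] += n
    return GenderTally(before=dict(before), after=dict(after))
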