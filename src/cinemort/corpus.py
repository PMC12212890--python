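"""Ingest crowd-sourced death entries from MediaWiki-style XML dumps or CSV.

Each wiki page is one actor; each wiki list item on the page is one death
entry ("*" bullets or "#" numbered items).  The film title and year are
pulled from the first parenthesised 4-digit year and the nearest preceding
italic/link span (falling back to the trailing run of capitalised tokens);
everything else is the free-text description handed to the classifiers.
"""

from __future__ import annotations

import csv
import html
import io
import logging
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

MEDIA_LABELS = ("film", "television", "video_game", "other_media", "unknown")

CSV_HEADER = ["actor_name", "film_title", "year", "medium", "description"]

_YEAR_RE = re.compile(r"\((1[89]\d{2}|20\d{2})\)")
_ITALIC_RE = re.compile(r"''+(.+?)''+")
_LINK_RE = re.compile(r"\[\[(?:[^|\]]*\|)?([^\]]+)\]\]")
_CATEGORY_RE = re.compile(r"\[\[\s*Category\s*:\s*([^\]|]+)(?:\|[^\]]*)?\]\]", re.IGNORECASE)
_LIST_ITEM_RE = re.compile(r"^\s*[*#]+\s*(.+)$")
# trailing run of capitalised tokens (incl. digits) right before the year paren
_TRAILING_TITLE_RE = re.compile(r"((?:[A-Z0-9][\w''&.-]*\s+)*[A-Z0-9][\w''&.-]*)\s*$")

_CURLY = {"‘": "'", "’": "'", "“": '"', "”": '"', "–": "-", "—": "-"}


@dataclass(frozen=True)
class DeathEntry:
    """One crowd-sourced death record (one actor, one on-screen death)."""

    actor_name: str
    film_title: str = ""
    year: int | None = None
    medium: str = "film"
    description: str = ""

    def __post_init__(self) -> None:
        if self.medium not in MEDIA_LABELS:
            raise ValueError(f"unknown medium label: {self.medium!r}")


@dataclass
class Corpus:
    """An ordered collection of death entries plus ingest provenance."""

    entries: list[DeathEntry] = field(default_factory=list)
    source_id: str = ""
    extraction_date: date | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def medium_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {m: 0 for m in MEDIA_LABELS}
        for e in self.entries:
            counts[e.medium] += 1
        return {m: n for m, n in counts.items() if n}


def _normalize_text(text: str) -> str:
    text = html.unescape(text)
    for curly, plain in _CURLY.items():
        text = text.replace(curly, plain)
    return text


def _strip_markup(text: str) -> str:
    text = _LINK_RE.sub(r"\1", text)
    text = text.replace("'''", "").replace("''", "")
    return re.sub(r"\s+", " ", text).strip()


def detect_medium(title: str, description: str, categories: Sequence[str] = ()) -> str:
    """Classify the medium of an entry.

    Page category tags win when present; otherwise a keyword scan of the
    film title and description.  Anything without a television / video-game
    signal is treated as film (the conservative default for this corpus).
    """
    for cat in categories:
        c = cat.lower()
        if "television" in c or re.search(r"\btv\b", c):
            return "television"
        if "video game" in c or "videogame" in c:
            return "video_game"
    blob = f"{title} {description}".lower()
    if "video game" in blob or "videogame" in blob:
        return "video_game"
    if re.search(r"\bepisode\b|\bseason\s+\d|\btv series\b|\btelevision\b", blob):
        return "television"
    return "film"


def parse_entry_text(raw_item: str, actor_name: str, categories: Sequence[str] = ()) -> DeathEntry | None:
    """Parse one wiki list item into a :class:`DeathEntry`.

    Returns ``None`` when no usable description remains.
    """
    text = _normalize_text(raw_item)

    year: int | None = None
    film_title = ""
    m = _YEAR_RE.search(text)
    if m:
        year = int(m.group(1))
        before = text[: m.start()]
        # nearest preceding italic or link span is the title...
        spans = list(_ITALIC_RE.finditer(before)) + list(_LINK_RE.finditer(before))
        spans = [s for s in spans if not _CATEGORY_RE.match(s.group(0))]
        if spans:
            best = max(spans, key=lambda s: s.end())
            film_title = _strip_markup(best.group(1))
            remainder = before[: best.start()] + before[best.end() :] + text[m.end() :]
        else:
            # ...else the trailing run of capitalised tokens before the "(year)"
            plain_before = _strip_markup(before)
            t = _TRAILING_TITLE_RE.search(plain_before)
            if t:
                film_title = t.group(1)
                remainder = plain_before[: t.start()] + " " + _strip_markup(text[m.end() :])
            else:
                remainder = before + text[m.end() :]
        description = _strip_markup(remainder)
        # drop dangling connectors left over from excising "Title (year)"
        description = re.sub(r"\s+(in|from|of|on|at)\s*$", "", description)
        description = description.strip(" :;,-—")
    else:
        description = _strip_markup(text).strip(" :;,-—")

    if not description:
        description = _strip_markup(text)
    if not description.strip():
        return None

    medium = detect_medium(film_title, description, categories)
    return DeathEntry(
        actor_name=actor_name,
        film_title=film_title,
        year=year,
        medium=medium,
        description=description,
    )


def _iter_pages(root: ET.Element):
    # MediaWiki exports carry a default namespace; synthetic fixtures may not.
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    for page in root.iter(f"{ns}page"):
        title_el = page.find(f"{ns}title")
        text_el = page.find(f".//{ns}text")
        title = (title_el.text or "").strip() if title_el is not None else ""
        text = text_el.text or "" if text_el is not None else ""
        yield title, text


def parse_dump(xml_source: str | Path | io.IOBase) -> Corpus:
    """Parse a MediaWiki-style XML export (or CSV) into a :class:`Corpus`.

    ``xml_source`` may be a path, an XML string, or a file-like object.
    Paths ending in ``.csv`` are routed to :func:`read_entries_csv`.
    Malformed XML raises :class:`xml.etree.ElementTree.ParseError` with the
    offending position; pages that yield no entries are logged, never
    silently dropped.
    """
    source_id = ""
    if isinstance(xml_source, (str, Path)) and not str(xml_source).lstrip().startswith("<"):
        path = Path(xml_source)
        if path.suffix.lower() == ".csv":
            return read_entries_csv(path)
        source_id = str(path)
        data = path.read_text(encoding="utf-8")
    elif isinstance(xml_source, (str, Path)):
        data = str(xml_source)
    else:
        data = xml_source.read()
        if isinstance(data, bytes):
            data = data.decode("utf-8")

    root = ET.fromstring(data)

    entries: list[DeathEntry] = []
    n_pages = 0
    for title, text in _iter_pages(root):
        n_pages += 1
        categories = _CATEGORY_RE.findall(text)
        page_entries = []
        for line in text.splitlines():
            m = _LIST_ITEM_RE.match(line)
            if not m:
                continue
            entry = parse_entry_text(m.group(1), actor_name=title, categories=categories)
            if entry is not None:
                page_entries.append(entry)
        if not page_entries and text.strip():
            logger.warning("page %r yielded no death entries; skipped", title)
        entries.extend(page_entries)

    logger.info("parsed %d pages -> %d entries", n_pages, len(entries))
    return Corpus(entries=entries, source_id=source_id, extraction_date=date.today())


def filter_medium(corpus: Corpus, allowed_media: Iterable[str]) -> Corpus:
    """Keep only entries whose medium is in ``allowed_media`` (order preserved)."""
    allowed = set(allowed_media)
    if not allowed:
        raise ValueError("allowed_media must be a non-empty set of medium labels")
    unknown = allowed - set(MEDIA_LABELS)
    if unknown:
        raise ValueError(f"unknown medium labels: {sorted(unknown)}")
    kept = [e for e in corpus.entries if e.medium in allowed]
    removed = len(corpus.entries) - len(kept)
    if removed:
        logger.info("filter_medium removed %d entries outside %s", removed, sorted(allowed))
    return replace(corpus, entries=kept)


def year_percentiles(
    corpus: Corpus, probs: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0)
) -> list[tuple[float, int]]:
    """Empirical year percentiles by the nearest-rank convention.

    prob 0 maps to the minimum, prob 1 to the maximum; otherwise the value
    at rank ``ceil(p * n)``.  Entries without a year are excluded (logged).
    """
    years = sorted(e.year for e in corpus.entries if e.year is not None)
    missing = len(corpus.entries) - len(years)
    if missing:
        logger.info("year_percentiles excluded %d entries without a year", missing)
    if not years:
        raise ValueError("no entries with a year")
    n = len(years)
    out = []
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"percentile prob out of range: {p}")
        if p == 0.0:
            out.append((p, years[0]))
        else:
            rank = math.ceil(p * n)
            out.append((p, years[min(rank, n) - 1]))
    return out


def write_entries_csv(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for e in corpus.entries:
            w.writerow([e.actor_name, e.film_title, e.year if e.year is not None else "", e.medium, e.description])


def read_entries_csv(source: str | Path | io.IOBase) -> Corpus:
    if isinstance(source, (str, Path)):
        fh = open(source, newline="", encoding="utf-8")
        source_id = str(source)
    else:
        fh = source
        source_id = ""
    try:
        r = csv.reader(fh)
        header = next(r, None)
        if header is None or [h.strip() for h in header] != CSV_HEADER:
            raise ValueError(f"entries CSV must have header {','.join(CSV_HEADER)}")
        entries = []
        for row in r:
            if not row:
                continue
            actor, title, year, medium, desc = row
            entries.append(
                DeathEntry(
                    actor_name=actor,
                    film_title=title,
                    year=int(year) if year else None,
                    medium=medium or "film",
                    description=desc,
                )
            )
    finally:
        if isinstance(source, (str, Path)):
            fh.close()
    return Corpus(entries=entries, source_id=source_id, extraction_date=date.today())
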