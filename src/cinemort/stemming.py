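"""Tokenisation and light suffix stemming for death-description matching.

The lexicon patterns are stemmed with the same function at load time, so the
only requirement on the stemmer is that it is deterministic and conflates
the common inflections (plural, past, progressive) onto one root.  A full
Porter stemmer is deliberately not used: the broad keyword matching here
only needs suffix conflation, and a small rule set is easier to audit.
"""

from __future__ import annotations

import re

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?")

_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")


def stem_token(token: str) -> str:
    """Stem one lowercase token: possessives, plural -s, -ed, -ing, final -e."""
    t = token
    if t.endswith("'s"):
        t = t[:-2]
    t = t.replace("'", "")
    if len(t) > 4 and t.endswith("sses"):
        t = t[:-2]
    elif len(t) > 4 and t.endswith("ies"):
        t = t[:-3] + "i"
    elif len(t) > 3 and t.endswith("s") and not t.endswith("ss") and not t.endswith("us"):
        t = t[:-1]
    stripped_inflection = False
    if len(t) > 5 and t.endswith("ing"):
        t = t[:-3]
        stripped_inflection = True
    elif len(t) > 4 and t.endswith("ed"):
        t = t[:-2]
        stripped_inflection = True
    if stripped_inflection and t.endswith(_DOUBLES):
        t = t[:-1]
    if len(t) > 3 and t.endswith("e"):
        t = t[:-1]
    return t


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumerics, keeping internal apostrophes."""
    return _TOKEN_RE.findall(text.lower())


def stem_text(description: str) -> list[str]:
    """Reduce a free-text description to an ordered list of word stems."""
    return [stem_token(tok) for tok in tokenize(description)]
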