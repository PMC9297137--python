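"""Canonical tokenizer shared by keyword matching and sentiment scoring.

One token stream for both stages keeps the sentiment-by-category flags
consistent with the food matches they are keyed to.
"""

from __future__ import annotations

import re

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)?")


def tokenize(text: str) -> list[str]:
    """Lowercase ``text`` and split it into word tokens.

    URLs and @-mentions are dropped; '#' is stripped from hashtags (the
    hashtag body survives as an ordinary token); the remainder is split on
    non-alphanumeric boundaries, so repeated whitespace and punctuation
    never affect the token stream.
    """
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    return _TOKEN_RE.findall(text.lower())


def normalize_phrase(phrase: str) -> str:
    """Lowercase a keyword phrase and collapse internal whitespace."""
    return " ".join(phrase.lower().split())
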