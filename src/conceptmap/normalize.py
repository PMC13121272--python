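"""Concept-name normalization.

Hospital feeds deliver concept names with arbitrary casing, underscores,
local punctuation and padding (``"Platelets_B_%"``).  Normalization maps
every name onto a canonical lower-case token string so that lexically
identical concepts embed identically.  The percent sign is the one special
character with clinical meaning (volume fractions, saturation) and is kept.
"""

from __future__ import annotations

import re

__all__ = ["normalize_name"]

# Anything outside lower-case ASCII letters, digits, '%' and space becomes a
# separator.  Replacement (rather than deletion) is deliberate: underscores
# act as token boundaries, so "Platelets_B_%" -> "platelets b %".
_NON_KEPT = re.compile(r"[^a-z0-9% ]")


def normalize_name(raw: str) -> str:
    """Normalize a raw concept name.

    Lower-cases, replaces every character that is not a letter, digit, ``%``
    or space with a space, collapses whitespace runs and strips the ends.
    Idempotent; the empty string maps to itself.

    >>> normalize_name("Platelets_B_%")
    'platelets b %'
    """
    lowered = raw.lower()
    spaced = _NON_KEPT.sub(" ", lowered)
    return " ".join(spaced.split())
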