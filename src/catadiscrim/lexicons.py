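"""Published CATA attribute lexicons for the three reference study designs.

The three consumer studies this package's diagnostics were developed
against used fixed attribute ballots: 38 terms for cricket-powder-enriched
oat biscuits, 34 for apple-pomace-enriched gluten-free biscuits and 16 for
strawberry varieties.  The ballots are reproduced here as plain
comma-separated strings together with a small parser, so synthetic panels
can be generated at the real studies' shapes.
"""

from __future__ import annotations

__all__ = [
    "CRICKET_BISCUIT_TERMS",
    "APPLE_POMACE_BISCUIT_TERMS",
    "STRAWBERRY_TERMS",
    "LEXICONS",
    "parse_lexicon",
]

CRICKET_BISCUIT_TERMS = (
    "too dark, too light, nice color, brown color, grainy, too strong odor, "
    "too weak odor, cheesy odor, bitter odor, seedy odor, earthy odor, "
    "sunflower-seedy odor, toasty odor, pleasant odor, fishy odor, friable, "
    "hard, soft, crumbly, fatty, crispy, granular, dry, too strong flavor, "
    "too weak flavor, cheesy flavor, seedy flavor, spicy flavor, salty taste, "
    "sunflower-seedy flavor, toasty flavor, tasty, sweet taste, sticky, "
    "piquant, fishy flavor, burnt flavor, long lasting taste"
)

APPLE_POMACE_BISCUIT_TERMS = (
    "light, dark, homogeneous, heterogenous, seedy, rustic, perfect size, "
    "small, fruity odor, citrus odor, apple odor, buttery odor, caramel odor, "
    "burnt odor, coconut odor, hard, flexible, chewy, crispy, solid, mealy, "
    "sunflower seedy, soft, sticky, friable, tasteless, vanilla flavor, "
    "fruity flavor, citrus flavor, apple flavor, caramel flavor, sweet bitter, "
    "sour, burnt"
)

STRAWBERRY_TERMS = (
    "sweet, sour, strawberry flavor, strawberry odor, flavorsome, tasteless, "
    "red color, irregular shape, regular shape, small, big, firm, hard, soft, "
    "juicy, dry"
)

#: Named ballots for the three reference designs.
LEXICONS: dict[str, str] = {
    "cricket_biscuit": CRICKET_BISCUIT_TERMS,
    "apple_pomace_biscuit": APPLE_POMACE_BISCUIT_TERMS,
    "strawberry": STRAWBERRY_TERMS,
}


def parse_lexicon(text: str, sep: str = ",") -> tuple[str, ...]:
    """Parse a separated attribute ballot into an ordered unique term tuple.

    Terms are stripped of surrounding whitespace; empty entries are
    dropped; duplicate terms (after trimming) are an error, since a CATA
    ballot lists each attribute once.
    """
    terms = [t.strip() for t in text.split(sep)]
    terms = [t for t in terms if t]
    if len(set(terms)) != len(terms):
        dupes = sorted({t for t in terms if terms.count(t) > 1})
        raise ValueError(f"duplicate attributes in lexicon: {dupes}")
    return tuple(terms)
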