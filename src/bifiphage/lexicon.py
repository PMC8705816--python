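"""Keyword lexicon mapping CDS product annotations to phage functional modules.

Temperate phages of *Bifidobacterium* (and lambdoid phages generally) organise
their genes into five functional modules: integration/excision, lysis, DNA
replication, head/tail morphogenesis and DNA packaging.  This module assigns a
CDS to a module from keywords in its free-text ``product`` annotation, which
is how prophage-aware annotation behaves when no curated viral HMM database is
available for the clade.
"""

from __future__ import annotations

from pathlib import Path

#: Canonical order of the five phage functional modules.
MODULES: tuple[str, ...] = (
    "integration_excision",
    "lysis",
    "dna_replication",
    "head_tail",
    "dna_packaging",
)

#: Keyword -> module lexicon.  Matching is case-insensitive substring search,
#: modules tried in ``MODULES`` order, first hit wins.  "terminase"/"portal"
#: are packaging, "capsid"/"head"/"tail" structural, "holin"/"lysin" lytic.
DEFAULT_LEXICON: dict[str, tuple[str, ...]] = {
    "integration_excision": ("integrase", "recombinase", "excisionase"),
    "lysis": ("holin", "endolysin", "lysozyme", "lysin"),
    "dna_replication": (
        "primase",
        "helicase",
        "polymerase",
        "replication",
        "single-stranded dna-binding",
    ),
    "head_tail": ("capsid", "head", "tail", "baseplate", "fiber"),
    "dna_packaging": ("terminase", "portal", "packaging"),
}


def product_module(product: str, lexicon: dict[str, tuple[str, ...]] | None = None) -> str | None:
    """Return the phage module a product annotation belongs to, or ``None``.

    Packaging keywords are tested before the structural ones so that e.g.
    "portal protein" is packaging even though portals cap the capsid.
    """
    if not product:
        return None
    lex = DEFAULT_LEXICON if lexicon is None else lexicon
    low = product.lower()
    # dna_packaging before head_tail: "terminase"/"portal" must not be
    # shadowed by broader structural words in custom lexica.
    order = ("integration_excision", "lysis", "dna_replication", "dna_packaging", "head_tail")
    for module in order:
        for keyword in lex.get(module, ()):
            if keyword in low:
                return module
    return None


def is_phage_product(product: str, lexicon: dict[str, tuple[str, ...]] | None = None) -> bool:
    """True when the product matches any module keyword."""
    return product_module(product, lexicon) is not None


def is_hypothetical_product(product: str) -> bool:
    """True for empty annotations or products declared hypothetical."""
    return (not product.strip()) or ("hypothetical" in product.lower())


def write_lexicon(lexicon: dict[str, tuple[str, ...]], path: str | Path) -> None:
    """Serialise a lexicon as editable two-column plain text."""
    lines = ["# module\tkeyword"]
    for module in MODULES:
        for keyword in lexicon.get(module, ()):
            lines.append(f"{module}\t{keyword}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lexicon(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a lexicon written by :func:`write_lexicon`."""
    lexicon: dict[str, list[str]] = {m: [] for m in MODULES}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        module, keyword = line.split("\t", 1)
        if module not in lexicon:
            raise ValueError(f"unknown phage module in lexicon file: {module!r}")
        lexicon[module].append(keyword)
    return {m: tuple(v) for m, v in lexicon.items()}
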