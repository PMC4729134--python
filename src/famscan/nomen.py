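"""Deterministic gene-symbol assignment following community nomenclature rules.

Rule precedence per locus: a conserved prior symbol (normalized from dot-number
to serial-letter style, e.g. ``VviSOC1.1`` -> ``VviSOC1a``), then the
Arabidopsis ortholog's symbol with the species prefix, then subfamily + serial
letter for MIKC^C loci, then subclass + clade digit + serial letter for MIKC*
(``MADSD``), M-alpha type I (``MADS1A``) and M-gamma type I (``MADS1G``) loci.
Serial letters run a..z then aa, ab, ... and are attributed in genomic order
(chromosome, then start), which replaces random attribution for
reproducibility.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

MIKC_C = "MIKC_C"
MIKC_STAR = "MIKC_STAR"
M_ALPHA = "M_ALPHA"
M_GAMMA = "M_GAMMA"
SUBCLASSES = (MIKC_C, MIKC_STAR, M_ALPHA, M_GAMMA)

SUBCLASS_PREFIX = {MIKC_STAR: "MADSD", M_ALPHA: "MADS1A", M_GAMMA: "MADS1G"}
_PREFIX_SUBCLASS = {v: k for k, v in SUBCLASS_PREFIX.items()}

RULES = ("kept_existing", "arabidopsis_ortholog", "subfamily_serial", "subclass_clade_serial")


class SymbolConflictError(ValueError):
    pass


@dataclass(frozen=True)
class CatalogLocus:
    """Input record for symbol assignment."""

    locus_id: str
    chromosome: str
    start: int
    subclass: str
    clade: int | None = None
    subfamily: str | None = None
    prior_symbol: str | None = None
    at_ortholog: str | None = None


@dataclass(frozen=True)
class SymbolAssignment:
    locus_id: str
    symbol: str
    rule_used: str
    subclass: str
    clade: int | None = None
    serial: str | None = None


def serial_letter(index: int) -> str:
    """0 -> a, 25 -> z, 26 -> aa, 27 -> ab, ..."""
    out = []
    index += 1
    while index > 0:
        index -= 1
        out.append(chr(ord("a") + index % 26))
        index //= 26
    return "".join(reversed(out))


_DOT_STYLE = re.compile(r"^(?P<base>.+?)\.(?P<num>\d+)$")


def normalize_prior_symbol(symbol: str) -> str:
    """Rewrite dot-number style to serial-letter style (X.1 -> Xa)."""
    m = _DOT_STYLE.match(symbol)
    if not m:
        return symbol
    return m.group("base") + serial_letter(int(m.group("num")) - 1)


def assign_symbols(catalog: list[CatalogLocus], species_prefix: str = "Vvi") -> list[SymbolAssignment]:
    """Assign a unique symbol to every locus (deterministic given the catalog)."""
    priors = [normalize_prior_symbol(l.prior_symbol) for l in catalog if l.prior_symbol]
    dupes = sorted({p for p in priors if priors.count(p) > 1})
    if dupes:
        loci = [l.locus_id for l in catalog if l.prior_symbol and normalize_prior_symbol(l.prior_symbol) in dupes]
        raise SymbolConflictError(f"duplicate prior symbols {dupes} on loci {loci}")

    ordered = sorted(catalog, key=lambda l: (l.chromosome, l.start, l.locus_id))
    used: set[str] = set()
    out: dict[str, SymbolAssignment] = {}

    def claim(symbol: str) -> str:
        if symbol in used:
            raise SymbolConflictError(f"symbol {symbol!r} assigned twice")
        used.add(symbol)
        return symbol

    # pass 1: conserved and ortholog-derived symbols
    for locus in ordered:
        if locus.prior_symbol:
            sym = normalize_prior_symbol(locus.prior_symbol)
            if not sym.startswith(species_prefix):
                sym = species_prefix + sym
            out[locus.locus_id] = SymbolAssignment(locus.locus_id, claim(sym), "kept_existing", locus.subclass, locus.clade)
    for locus in ordered:
        if locus.locus_id in out or not locus.at_ortholog:
            continue
        base = species_prefix + locus.at_ortholog
        sym, k = base, 0
        while sym in used:
            sym = base + serial_letter(k)
            k += 1
        out[locus.locus_id] = SymbolAssignment(locus.locus_id, claim(sym), "arabidopsis_ortholog", locus.subclass, locus.clade)

    # pass 2: serial symbols in genomic order
    counters: dict[tuple, int] = {}
    for locus in ordered:
        if locus.locus_id in out:
            continue
        if locus.subclass == MIKC_C:
            if not locus.subfamily:
                raise ValueError(f"{locus.locus_id}: MIKC^C locus without subfamily for serial naming")
            key = ("subfam", locus.subfamily)
            base = species_prefix + locus.subfamily
            rule = "subfamily_serial"
        else:
            if locus.clade is None:
                raise ValueError(f"{locus.locus_id}: subclass serial naming requires a clade index")
            key = ("subclass", locus.subclass, locus.clade)
            base = SUBCLASS_PREFIX[locus.subclass] + str(locus.clade)
            rule = "subclass_clade_serial"
        while True:
            n = counters.get(key, 0)
            counters[key] = n + 1
            serial = serial_letter(n)
            if base + serial not in used:
                break
        out[locus.locus_id] = SymbolAssignment(
            locus.locus_id, claim(base + serial), rule, locus.subclass, locus.clade, serial
        )
    return [out[l.locus_id] for l in catalog]


@dataclass(frozen=True)
class ParsedSymbol:
    kind: str  # subclass_clade | subfamily | unparsed
    subclass: str | None = None
    clade: int | None = None
    serial: str | None = None
    subfamily: str | None = None
    species_prefix: str | None = None


_SUBCLASS_RE = re.compile(r"^(?P<prefix>[A-Z][a-z]{2})?(?P<cls>MADSD|MADS1A|MADS1G)(?P<clade>\d+)(?P<serial>[a-z]+)$")
_SUBFAMILY_RE = re.compile(r"^(?P<prefix>[A-Z][a-z]{2})(?P<fam>[A-Z][A-Za-z0-9]*?\d*)(?P<serial>[a-z]+)?$")


def parse_symbol(symbol: str) -> ParsedSymbol:
    """Inverse of :func:`assign_symbols` on (subclass, clade, serial)."""
    if not symbol:
        raise ValueError("empty symbol")
    m = _SUBCLASS_RE.match(symbol)
    if m:
        return ParsedSymbol(
            kind="subclass_clade",
            subclass=_PREFIX_SUBCLASS[m.group("cls")],
            clade=int(m.group("clade")),
            serial=m.group("serial"),
            species_prefix=m.group("prefix"),
        )
    m = _SUBFAMILY_RE.match(symbol)
    if m:
        return ParsedSymbol(
            kind="subfamily",
            subclass=MIKC_C,
            subfamily=m.group("fam"),
            serial=m.group("serial"),
            species_prefix=m.group("prefix"),
        )
    return ParsedSymbol(kind="unparsed")
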