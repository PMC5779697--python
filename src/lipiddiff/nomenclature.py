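"""Shorthand lipid nomenclature: parsing, canonical formatting, chain matching.

Shotgun-lipidomics software reports species in a compact shorthand:
``CLASS C:D[;H]`` for a sum composition (total acyl carbons : total double
bonds, optional hydroxylation count) or ``CLASS C:D[;H]-C:D[;H]...`` when the
individual acyl/alkyl chains were resolved, e.g. ``PE 16:0-18:2``.  Ether
classes carry an ``O-`` suffix (``PC O-``, ``PE O-``) indicating an
alkyl/alkenyl linkage at sn-1.  Chain separators in the wild are a hyphen,
an en-dash, or a slash; whitespace between class token and composition is
optional.  This module parses those names into structured
:class:`LipidSpecies` objects, formats them canonically (hyphen separator,
single space after the class token, round-trip stable), and matches species
across classes by their multiset of chain compositions ("matched FAs") —
sn-position is deliberately ignored.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field


class LipidNameError(ValueError):
    """The name does not follow the shorthand grammar (e.g. unknown class)."""


class LipidStructureError(LipidNameError):
    """The name parses but is structurally inconsistent with its class."""


#: Number of acyl/alkyl chains each class carries when fully resolved.
CLASS_CHAIN_COUNTS: dict[str, int] = {
    "CL": 4,
    "TAG": 3,
    "DAG": 2,
    "PA": 2, "PC": 2, "PE": 2, "PG": 2, "PI": 2, "PS": 2,
    "PC O-": 2, "PE O-": 2,
    "Cer": 2, "HexCer": 2, "SM": 2,
    "LPA": 1, "LPC": 1, "LPE": 1, "LPG": 1, "LPI": 1, "LPS": 1,
    "LPC O-": 1, "LPE O-": 1,
    "SE": 1, "CE": 1,
    "Chol": 0, "ST": 0,
}

_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:;(\d+))?$")
_SEPARATOR_RE = re.compile(r"\s*[-–/]\s*")
# Class token: leading letters, optionally followed by an ether marker.
_NAME_RE = re.compile(
    r"^\s*([A-Za-z]+)\s?(O-?)?\s*(.*?)\s*$"
)


@dataclass(frozen=True)
class AcylChain:
    """One fatty acyl/alkyl chain: ``18:1;2`` = 18 carbons, 1 double bond,
    2 hydroxylations. ``ether_linked`` marks the sn-1 alkyl/alkenyl chain of
    O- classes."""

    carbons: int
    double_bonds: int
    hydroxylations: int = 0
    ether_linked: bool = False

    def __post_init__(self) -> None:
        if self.carbons <= 0:
            raise LipidStructureError(f"chain carbons must be positive, got {self.carbons}")
        if self.double_bonds < 0 or self.hydroxylations < 0:
            raise LipidStructureError("double bonds and hydroxylations must be non-negative")

    @property
    def composition(self) -> tuple[int, int, int]:
        return (self.carbons, self.double_bonds, self.hydroxylations)

    def __str__(self) -> str:
        base = f"{self.carbons}:{self.double_bonds}"
        return f"{base};{self.hydroxylations}" if self.hydroxylations else base


@dataclass(frozen=True)
class LipidSpecies:
    """Parsed identity of one lipid species.

    ``chains`` is empty when only the sum composition is known
    (``resolution == "sum_composition"``) and for chain-less classes
    (cholesterol/sterol, which are trivially chain-resolved).
    """

    class_code: str
    chains: tuple[AcylChain, ...] = ()
    sum_carbons: int = 0
    sum_double_bonds: int = 0
    sum_hydroxylations: int = 0
    resolution: str = "chain_resolved"  # or "sum_composition"
    canonical_name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.class_code not in CLASS_CHAIN_COUNTS:
            raise LipidNameError(f"unknown lipid class code: {self.class_code!r}")
        expected = CLASS_CHAIN_COUNTS[self.class_code]
        if self.resolution == "chain_resolved":
            if len(self.chains) != expected:
                raise LipidStructureError(
                    f"{self.class_code} requires {expected} chains, got {len(self.chains)}"
                )
            if self.chains:
                if sum(c.carbons for c in self.chains) != self.sum_carbons:
                    raise LipidStructureError("chain carbons do not sum to sum_carbons")
                if sum(c.double_bonds for c in self.chains) != self.sum_double_bonds:
                    raise LipidStructureError("chain double bonds do not sum to sum_double_bonds")
            n_ether = sum(c.ether_linked for c in self.chains)
            if self.is_ether and n_ether != 1:
                raise LipidStructureError(
                    f"{self.class_code} requires exactly one ether-linked chain"
                )
            if not self.is_ether and n_ether:
                raise LipidStructureError(
                    f"non-ether class {self.class_code} has an ether-linked chain"
                )
        if not self.canonical_name:
            object.__setattr__(self, "canonical_name", format_species_name(self))

    @property
    def is_ether(self) -> bool:
        return self.class_code.endswith("O-")

    def __str__(self) -> str:
        return self.canonical_name


def format_species_name(species: LipidSpecies) -> str:
    """Canonical shorthand: class token, one space, hyphen-joined chains
    (or the sum composition); chain-less classes are the bare class token."""
    if species.resolution == "chain_resolved" and species.chains:
        comp = "-".join(str(c) for c in species.chains)
    elif species.resolution == "chain_resolved":  # Chol / ST
        return species.class_code
    else:
        comp = f"{species.sum_carbons}:{species.sum_double_bonds}"
        if species.sum_hydroxylations:
            comp += f";{species.sum_hydroxylations}"
    return f"{species.class_code} {comp}"


def parse_species_name(name: str) -> LipidSpecies:
    """Parse a shorthand species name into a :class:`LipidSpecies`.

    Accepts hyphen ``-``, en-dash ``–`` and slash ``/`` chain separators and
    optional whitespace between the class token and the composition; parsing
    followed by canonical formatting round-trips.

    Raises
    ------
    LipidNameError
        Unknown class token or malformed composition.
    LipidStructureError
        Chain count inconsistent with the class.
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidNameError(f"empty or non-string lipid name: {name!r}")
    m = _NAME_RE.match(name)
    if m is None:  # pragma: no cover - regex matches any non-empty string
        raise LipidNameError(f"cannot parse lipid name: {name!r}")
    base, ether, rest = m.group(1), m.group(2), m.group(3)
    class_code = f"{base} O-" if ether else base
    if class_code not in CLASS_CHAIN_COUNTS:
        raise LipidNameError(f"unknown lipid class code: {class_code!r} in name {name!r}")
    expected = CLASS_CHAIN_COUNTS[class_code]

    if not rest:
        if expected != 0:
            raise LipidNameError(f"missing composition in lipid name: {name!r}")
        return LipidSpecies(class_code=class_code)
    if expected == 0:
        raise LipidStructureError(f"{class_code} carries no chains but name has composition: {name!r}")

    tokens = _SEPARATOR_RE.split(rest)
    parsed = []
    for tok in tokens:
        cm = _CHAIN_RE.match(tok)
        if cm is None:
            raise LipidNameError(f"malformed chain token {tok!r} in name {name!r}")
        parsed.append((int(cm.group(1)), int(cm.group(2)), int(cm.group(3) or 0)))

    if len(parsed) == 1 and expected != 1:
        # A single composition token on a multi-chain class is a sum composition.
        c, d, h = parsed[0]
        if c <= 0:
            raise LipidStructureError(f"sum carbons must be positive in {name!r}")
        return LipidSpecies(
            class_code=class_code,
            sum_carbons=c,
            sum_double_bonds=d,
            sum_hydroxylations=h,
            resolution="sum_composition",
        )
    if len(parsed) != expected:
        raise LipidStructureError(
            f"{class_code} requires {expected} chains, name {name!r} has {len(parsed)}"
        )
    chains = tuple(
        AcylChain(c, d, h, ether_linked=(i == 0 and bool(ether)))
        for i, (c, d, h) in enumerate(parsed)
    )
    return LipidSpecies(
        class_code=class_code,
        chains=chains,
        sum_carbons=sum(c.carbons for c in chains),
        sum_double_bonds=sum(c.double_bonds for c in chains),
        sum_hydroxylations=sum(c.hydroxylations for c in chains),
        resolution="chain_resolved",
    )


def chain_multiset(species: LipidSpecies) -> Counter:
    """Order-insensitive multiset of (carbons, double_bonds, hydroxylations).

    sn-position and ether linkage are discarded; sum-composition species raise
    ``LipidStructureError("chains unresolved")``.
    """
    if species.resolution != "chain_resolved":
        raise LipidStructureError(f"chains unresolved for {species.canonical_name}")
    return Counter(c.composition for c in species.chains)


def find_matched_pairs(
    class_a_species: list[LipidSpecies],
    class_b_species: list[LipidSpecies],
    include_ether: bool = False,
) -> list[tuple[LipidSpecies, LipidSpecies]]:
    """Pair species across two classes carrying identical chain multisets.

    Diacyl species are matched with diacyl species; ether (O-) species are
    excluded by default, or matched among themselves when ``include_ether``
    is true.  Each species appears in at most one pair: within each chain
    multiset the species of both classes are taken in lexicographic
    canonical-name order and zipped, which makes the result deterministic
    and symmetric (``find_matched_pairs(B, A)`` yields the mirrored pairs).
    """
    def eligible(spp):
        out = [s for s in spp if s.resolution == "chain_resolved" and s.chains]
        if not include_ether:
            out = [s for s in out if not s.is_ether]
        return sorted(out, key=lambda s: s.canonical_name)

    def by_key(spp):
        grouped: dict[tuple, list[LipidSpecies]] = {}
        for s in spp:
            key = (tuple(sorted(chain_multiset(s).items())), s.is_ether)
            grouped.setdefault(key, []).append(s)
        return grouped

    ga, gb = by_key(eligible(class_a_species)), by_key(eligible(class_b_species))
    pairs = [
        (a, b)
        for key in sorted(ga.keys() & gb.keys())
        for a, b in zip(ga[key], gb[key])
    ]
    pairs.sort(key=lambda ab: (ab[0].canonical_name, ab[1].canonical_name))
    return pairs


def species_catalog(species: list[LipidSpecies]):
    """Catalog table for export: one row per species (canonical name, class,
    sum composition, chains, ether flag, resolution)."""
    import pandas as pd

    rows = [
        {
            "canonical_name": s.canonical_name,
            "class_code": s.class_code,
            "sum_carbons": s.sum_carbons,
            "sum_double_bonds": s.sum_double_bonds,
            "sum_hydroxylations": s.sum_hydroxylations,
            "chains": "-".join(str(c) for c in s.chains),
            "ether": s.is_ether,
            "resolution": s.resolution,
        }
        for s in species
    ]
    return pd.DataFrame(rows)
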