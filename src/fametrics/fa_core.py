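"""Fatty-acid shorthand parsing and physical properties.

Fatty acids are written in the GC shorthand used throughout food and lipid
microbiology: ``C<chain>:<n_double_bonds>`` optionally followed by geometry
tokens with double-bond positions (``cis 9, 12``) and/or hydroxyl markers
(``3OH``).  All positions are counted from the carboxyl carbon (Δ
nomenclature).  Examples: ``C16:0`` (palmitic acid), ``C18:1 cis 9`` (oleic
acid), ``C18:3 cis 6, 9, 12`` (γ-linolenic acid, distinct from the
α-isomer ``C18:3 cis 9, 12, 15``), ``C18:0 3OH`` (3-hydroxystearic acid).

The module also ships a default table of pure-compound melting temperatures,
the physical ingredient of the weighted-average melting temperature (WAMT)
of a membrane's fatty-acid complement.  The table is overridable: melting
points differ between literature sources by up to a couple of degrees, so
downstream WAMT use is meant to be comparative (condition A vs. condition
B), not absolute.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "FattyAcid",
    "FattyAcidParseError",
    "MeltingPointTable",
    "parse_fatty_acid",
    "unsaturation_class",
    "melting_temperature",
    "default_melting_table",
]

MAX_DOUBLE_BONDS = 6


class FattyAcidParseError(ValueError):
    """Raised when a fatty-acid shorthand label cannot be interpreted."""


@dataclass(frozen=True)
class FattyAcid:
    """Parsed identity of a single fatty acid.

    Attributes
    ----------
    chain_length:
        Number of carbons in the acyl chain (≥ 2).
    double_bond_count:
        Number of C=C double bonds (0–6).
    double_bonds:
        Tuple of ``(position, geometry)`` pairs, strictly increasing in
        position, geometry ``"cis"`` or ``"trans"``.  ``None`` when the label
        declared unsaturation without stating positions (e.g. ``"C18:2"``).
    hydroxyl_positions:
        Positions of hydroxyl substituents, possibly empty.
    """

    chain_length: int
    double_bond_count: int
    double_bonds: tuple[tuple[int, str], ...] | None = ()
    hydroxyl_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.chain_length < 2:
            raise FattyAcidParseError(
                f"chain length must be >= 2, got {self.chain_length}"
            )
        if not (0 <= self.double_bond_count <= MAX_DOUBLE_BONDS):
            raise FattyAcidParseError(
                f"double-bond count must be in [0, {MAX_DOUBLE_BONDS}], "
                f"got {self.double_bond_count}"
            )
        if self.double_bonds is not None:
            if len(self.double_bonds) not in (0, self.double_bond_count):
                raise FattyAcidParseError(
                    f"{len(self.double_bonds)} double-bond positions given "
                    f"but {self.double_bond_count} bonds declared"
                )
            positions = [p for p, _ in self.double_bonds]
            if any(p < 1 or p >= self.chain_length for p in positions):
                raise FattyAcidParseError(
                    f"double-bond position out of range for C{self.chain_length}: "
                    f"{positions}"
                )
            if positions != sorted(set(positions)):
                raise FattyAcidParseError(
                    f"double-bond positions must be strictly increasing: {positions}"
                )
            if any(g not in ("cis", "trans") for _, g in self.double_bonds):
                raise FattyAcidParseError(
                    f"geometry must be cis or trans: {self.double_bonds}"
                )
            if self.double_bond_count > 0 and not self.double_bonds:
                # "C18:2" with no positions: normalize to positions-unknown
                object.__setattr__(self, "double_bonds", None)
        for p in self.hydroxyl_positions:
            if p < 1 or p > self.chain_length:
                raise FattyAcidParseError(
                    f"hydroxyl position {p} out of range for C{self.chain_length}"
                )

    @property
    def canonical_label(self) -> str:
        """Canonical shorthand; parsing it yields an equal ``FattyAcid``."""
        out = f"C{self.chain_length}:{self.double_bond_count}"
        if self.double_bonds:
            parts: list[str] = []
            current_geom: str | None = None
            for pos, geom in self.double_bonds:
                if geom != current_geom:
                    parts.append(geom)
                    current_geom = geom
                    parts.append(str(pos))
                else:
                    parts[-1] += f", {pos}"
            out += " " + " ".join(parts)
        for p in self.hydroxyl_positions:
            out += f" {p}OH"
        return out

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_label


_HEAD_RE = re.compile(r"^c\s*(\d+)\s*:\s*(\d+)", re.IGNORECASE)
_TOKEN_RE = re.compile(
    r"(?P<geom>cis|trans)|(?P<oh>\d+)\s*oh|(?P<pos>\d+)|(?P<sep>[,\s]+)",
    re.IGNORECASE,
)


def parse_fatty_acid(label: str) -> FattyAcid:
    """Parse a shorthand label like ``"C18:3 cis 9, 12, 15"``.

    Whitespace and comma spacing are flexible and matching is
    case-insensitive.  Geometry tokens apply to all following positions
    until the next geometry token; positions with no preceding geometry
    token default to *cis* (the overwhelmingly common configuration in
    biological membranes).

    Raises
    ------
    FattyAcidParseError
        If the label is empty, malformed, declares a position count that
        disagrees with the bond count, or places a bond at or beyond the
        chain length.
    """
    if not isinstance(label, str) or not label.strip():
        raise FattyAcidParseError("empty fatty-acid label")
    text = label.strip()
    head = _HEAD_RE.match(text)
    if head is None:
        raise FattyAcidParseError(
            f"label {label!r} does not start with 'C<chain>:<bonds>'"
        )
    chain = int(head.group(1))
    n_db = int(head.group(2))
    rest = text[head.end():]

    bonds: list[tuple[int, str]] = []
    hydroxyls: list[int] = []
    geometry = "cis"
    pos = 0
    while pos < len(rest):
        m = _TOKEN_RE.match(rest, pos)
        if m is None:
            raise FattyAcidParseError(
                f"unrecognized token {rest[pos:].split()[0]!r} in label {label!r}"
            )
        if m.lastgroup == "geom":
            geometry = m.group("geom").lower()
        elif m.lastgroup == "oh":
            hydroxyls.append(int(m.group("oh")))
        elif m.lastgroup == "pos":
            bonds.append((int(m.group("pos")), geometry))
        pos = m.end()

    if bonds and len(bonds) != n_db:
        raise FattyAcidParseError(
            f"label {label!r}: {len(bonds)} double-bond positions given "
            f"but {n_db} bonds declared"
        )
    return FattyAcid(
        chain_length=chain,
        double_bond_count=n_db,
        double_bonds=tuple(bonds) if bonds else (None if n_db else ()),
        hydroxyl_positions=tuple(sorted(hydroxyls)),
    )


def canonicalize(label: str) -> str:
    """Canonical form of a shorthand label (whitespace/case normalized)."""
    return parse_fatty_acid(label).canonical_label


_CLASS_NAMES = {0: "saturated", 1: "monoene", 2: "diene", 3: "triene"}


def unsaturation_class(fa: FattyAcid) -> str:
    """Classify by double-bond count: saturated / monoene / diene / triene
    / polyene_4plus.  Hydroxylation is ignored."""
    return _CLASS_NAMES.get(fa.double_bond_count, "polyene_4plus")


@dataclass
class MeltingPointTable:
    """Map from canonical fatty-acid identity to a pure-compound melting
    temperature in °C, with a free-text provenance note per entry.

    Lookup is by exact identity: positional isomers (γ- vs. α-linolenic)
    are distinct keys.  Absence of an entry is a value (``None``), not an
    error — callers decide how to renormalize over covered acids.
    """

    entries: dict[str, float] = field(default_factory=dict)
    source_notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canonical: dict[str, float] = {}
        notes: dict[str, str] = {}
        for label, temp in self.entries.items():
            key = canonicalize(label)
            if not (-60.0 <= temp <= 100.0):
                raise ValueError(
                    f"melting temperature {temp} °C for {key} outside "
                    "the plausible [-60, 100] °C range"
                )
            canonical[key] = float(temp)
            if label in self.source_notes:
                notes[key] = self.source_notes[label]
        self.entries = canonical
        self.source_notes = notes

    def get(self, fa: FattyAcid | str) -> float | None:
        key = fa.canonical_label if isinstance(fa, FattyAcid) else canonicalize(fa)
        return self.entries.get(key)

    def without_hydroxy_acids(self) -> "MeltingPointTable":
        """Copy excluding hydroxylated acids (their melting points are the
        least certain entries)."""
        keep = {
            k: v
            for k, v in self.entries.items()
            if not parse_fatty_acid(k).hydroxyl_positions
        }
        return MeltingPointTable(
            entries=keep,
            source_notes={k: n for k, n in self.source_notes.items() if k in keep},
        )

    def check_monotone(self) -> None:
        """Assert that within each chain length the temperature is
        non-increasing in double-bond count (saturated > monoene > diene >
        triene), the physical ordering a valid table must respect."""
        by_chain: dict[int, list[tuple[int, float]]] = {}
        for label, temp in self.entries.items():
            fa = parse_fatty_acid(label)
            by_chain.setdefault(fa.chain_length, []).append(
                (fa.double_bond_count, temp)
            )
        for chain, pairs in by_chain.items():
            pairs.sort()
            for (k1, t1), (k2, t2) in zip(pairs, pairs[1:]):
                if k2 > k1 and t2 >= t1:
                    raise ValueError(
                        f"C{chain}: melting point not decreasing with "
                        f"unsaturation ({k1} bonds: {t1} °C vs {k2} bonds: {t2} °C)"
                    )

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "MeltingPointTable":
        """Load from a two- or three-column TSV
        (canonical_label, melting_temp_C[, source_note])."""
        entries: dict[str, float] = {}
        notes: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"melting table line lacks a value: {line!r}")
                label, temp = fields[0], float(fields[1])
                entries[label] = temp
                if len(fields) >= 3 and fields[2].strip():
                    notes[label] = fields[2].strip()
        return cls(entries=entries, source_notes=notes)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# canonical_label\tmelting_temp_C\tsource_note\n")
            for label in sorted(self.entries):
                note = self.source_notes.get(label, "")
                fh.write(f"{label}\t{self.entries[label]:g}\t{note}\n")

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, float], notes: Mapping[str, str] | None = None
    ) -> "MeltingPointTable":
        return cls(entries=dict(mapping), source_notes=dict(notes or {}))


def melting_temperature(fa: FattyAcid, table: MeltingPointTable) -> float | None:
    """Exact-identity melting-point lookup; ``None`` when not covered."""
    return table.get(fa)


def default_melting_table() -> MeltingPointTable:
    """The packaged default melting-point table.

    Covers the ten acids routinely reported in fungal FAME profiles.
    Values are pure-compound melting points from standard
    physical-chemistry references; the 3-hydroxystearic entry is flagged
    low-confidence and can be dropped with
    :meth:`MeltingPointTable.without_hydroxy_acids`.
    """
    path = resources.files("fametrics").joinpath("data/melting_points_default.tsv")
    with resources.as_file(path) as p:
        return MeltingPointTable.from_tsv(p)


def sort_key(fa: FattyAcid | str) -> tuple:
    """Stable ordering for display: chain length, bond count, positions,
    hydroxylation."""
    if isinstance(fa, str):
        fa = parse_fatty_acid(fa)
    return (
        fa.chain_length,
        fa.double_bond_count,
        fa.double_bonds or (),
        fa.hydroxyl_positions,
    )
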