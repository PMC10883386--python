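"""Theoretical mass library for N-acyl-homoserine lactones (AHLs).

An AHL is a homoserine-lactone ring amide-linked to a fatty acyl chain of
``n`` carbons, optionally carrying a 3-oxo or 3-hydroxy substitution and one
or more C=C unsaturations.  The module enumerates the compound family over a
configurable chain-length range, computes nominal (integer atomic masses)
and monoisotopic [M+H]+ values, and annotates observed m/z values against
the library.

Nominal-mass arithmetic for the family is simple and worth stating: an
unmodified chain of ``n`` carbons has [M+H]+ = 14*n + 116; a 3-oxo group
adds 14 (+O, -2H); each unsaturation subtracts 2 (-2H); a 3-hydroxy group
adds 16 (+O).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "AcylDescriptor",
    "ElementalFormula",
    "AHLSpecies",
    "MassLibrary",
    "Annotation",
    "formula_of",
    "nominal_mh",
    "monoisotopic_mh",
    "build_library",
    "annotate_mz",
    "parse_name",
    "HSL_RING_FRAGMENT",
]

# Integer (nominal) atomic masses.
_NOMINAL = {"C": 12, "H": 1, "N": 14, "O": 16}
# Most-abundant-isotope exact masses.
_MONO = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221}
_PROTON = 1.00727646

#: Protonated homoserine-lactone ring fragment (C4H8NO2+), the
#: characteristic daughter ion of the AHL family at nominal m/z 102.
HSL_RING_FRAGMENT = {"C": 4, "H": 7, "N": 1, "O": 2}


@dataclass(frozen=True, order=True)
class AcylDescriptor:
    """Structural description of one acyl chain.

    Parameters
    ----------
    chain_length
        Number of carbons in the acyl chain (>= 2).
    oxo3
        3-oxo substitution on the chain.
    unsaturations
        Number of C=C double bonds; at most ``chain_length - 3``.
    hydroxy3
        3-hydroxy substitution; mutually exclusive with ``oxo3``.
    """

    chain_length: int
    oxo3: bool = False
    unsaturations: int = 0
    hydroxy3: bool = False

    def __post_init__(self) -> None:
        if self.chain_length < 2:
            raise ValueError(
                f"acyl chain needs >= 2 carbons, got {self.chain_length}"
            )
        if self.unsaturations < 0:
            raise ValueError("unsaturation count must be non-negative")
        cap = max(self.chain_length - 3, 0)
        if self.unsaturations > cap:
            raise ValueError(
                f"C{self.chain_length} chain supports at most {cap} "
                f"unsaturations, got {self.unsaturations}"
            )
        if self.oxo3 and self.hydroxy3:
            raise ValueError("3-oxo and 3-hydroxy are mutually exclusive")

    @property
    def name(self) -> str:
        """Canonical compound name, e.g. ``C8-HSL`` or ``Oxo-C14:1-HSL``."""
        core = f"C{self.chain_length}"
        if self.unsaturations:
            core += f":{self.unsaturations}"
        prefix = "Oxo-" if self.oxo3 else "3-OH-" if self.hydroxy3 else ""
        return f"{prefix}{core}-HSL"


_NAME_RE = re.compile(
    r"^(?P<prefix>Oxo-|3-OH-)?C(?P<n>\d+)(?::(?P<u>\d+))?-HSL$"
)


def parse_name(name: str) -> AcylDescriptor:
    """Parse a canonical AHL name back into its :class:`AcylDescriptor`."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"not a canonical AHL name: {name!r}")
    return AcylDescriptor(
        chain_length=int(m.group("n")),
        oxo3=m.group("prefix") == "Oxo-",
        unsaturations=int(m.group("u") or 0),
        hydroxy3=m.group("prefix") == "3-OH-",
    )


@dataclass(frozen=True)
class ElementalFormula:
    """CHNO elemental composition."""

    c: int
    h: int
    n: int
    o: int

    def __post_init__(self) -> None:
        if min(self.c, self.h, self.n, self.o) < 0:
            raise ValueError("element counts must be non-negative")

    def __str__(self) -> str:
        parts = []
        for sym, count in (("C", self.c), ("H", self.h), ("N", self.n), ("O", self.o)):
            if count == 1:
                parts.append(sym)
            elif count > 1:
                parts.append(f"{sym}{count}")
        return "".join(parts)


def formula_of(descriptor: AcylDescriptor) -> ElementalFormula:
    """Elemental formula of the neutral AHL for one acyl descriptor.

    A plain acyl-HSL with an ``n``-carbon chain is C(n+4) H(2n+5) N O3:
    the homoserine lactone contributes C4H7NO2 and the acyl amide the rest.
    3-oxo adds an oxygen and removes two hydrogens; 3-hydroxy adds only the
    oxygen; each double bond removes two hydrogens.
    """
    n = descriptor.chain_length
    c = n + 4
    h = 2 * n + 5
    o = 3
    if descriptor.oxo3:
        o += 1
        h -= 2
    if descriptor.hydroxy3:
        o += 1
    h -= 2 * descriptor.unsaturations
    return ElementalFormula(c=c, h=h, n=1, o=o)


def nominal_mh(formula: ElementalFormula) -> int:
    """Nominal [M+H]+ m/z: integer atomic masses plus 1 for the proton."""
    if formula.c < 1:
        raise ValueError("formula must contain at least one carbon")
    return (
        formula.c * _NOMINAL["C"]
        + formula.h * _NOMINAL["H"]
        + formula.n * _NOMINAL["N"]
        + formula.o * _NOMINAL["O"]
        + 1
    )


def monoisotopic_mh(formula: ElementalFormula) -> float:
    """Monoisotopic [M+H]+ m/z (Th)."""
    if formula.c < 1:
        raise ValueError("formula must contain at least one carbon")
    return (
        formula.c * _MONO["C"]
        + formula.h * _MONO["H"]
        + formula.n * _MONO["N"]
        + formula.o * _MONO["O"]
        + _PROTON
    )


@dataclass(frozen=True)
class AHLSpecies:
    """One theoretical compound: descriptor, formula and [M+H]+ masses."""

    descriptor: AcylDescriptor
    name: str
    formula: ElementalFormula
    nominal_mh: int
    monoisotopic_mh: float

    @classmethod
    def from_descriptor(cls, descriptor: AcylDescriptor) -> "AHLSpecies":
        f = formula_of(descriptor)
        return cls(
            descriptor=descriptor,
            name=descriptor.name,
            formula=f,
            nominal_mh=nominal_mh(f),
            monoisotopic_mh=monoisotopic_mh(f),
        )


@dataclass(frozen=True)
class MassLibrary:
    """Deterministically ordered collection of :class:`AHLSpecies`."""

    entries: tuple[AHLSpecies, ...]
    n_min: int
    n_max: int
    allow_oxo: bool
    max_unsat: int
    allow_hydroxy: bool = False

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_name(self, name: str) -> AHLSpecies:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    # -- export / import -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "n": [e.descriptor.chain_length for e in self.entries],
                "oxo": [e.descriptor.oxo3 for e in self.entries],
                "unsat": [e.descriptor.unsaturations for e in self.entries],
                "hydroxy": [e.descriptor.hydroxy3 for e in self.entries],
                "formula": [str(e.formula) for e in self.entries],
                "nominal_mh": [e.nominal_mh for e in self.entries],
                "monoisotopic_mh": [e.monoisotopic_mh for e in self.entries],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": {
                "n_min": self.n_min,
                "n_max": self.n_max,
                "allow_oxo": self.allow_oxo,
                "max_unsat": self.max_unsat,
                "allow_hydroxy": self.allow_hydroxy,
            },
            "entries": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MassLibrary":
        payload = json.loads(Path(path).read_text())
        return build_library(**payload["params"])


def build_library(
    n_min: int = 4,
    n_max: int = 18,
    allow_oxo: bool = True,
    max_unsat: int = 2,
    allow_hydroxy: bool = False,
) -> MassLibrary:
    """Enumerate the AHL family over a chain-length range.

    The default range (n = 4..18, 3-oxo allowed, up to two unsaturations)
    covers the nine reference standards used to establish the m/z 102
    daughter ion plus the longer-chain predictions such as Oxo-C14:1-HSL.
    Entries are sorted by nominal [M+H]+ (ties by structure) so that
    regeneration with equal parameters is bit-identical.
    """
    if not (2 <= n_min <= n_max <= 20):
        raise ValueError(f"need 2 <= n_min <= n_max <= 20, got {n_min}..{n_max}")
    if max_unsat < 0:
        raise ValueError("max_unsat must be non-negative")

    entries: list[AHLSpecies] = []
    for n in range(n_min, n_max + 1):
        for oxo, hydroxy in [(False, False)] + ([(True, False)] if allow_oxo else []) + (
            [(False, True)] if allow_hydroxy else []
        ):
            for u in range(0, min(max_unsat, max(n - 3, 0)) + 1):
                entries.append(
                    AHLSpecies.from_descriptor(
                        AcylDescriptor(n, oxo3=oxo, unsaturations=u, hydroxy3=hydroxy)
                    )
                )
    entries.sort(
        key=lambda e: (
            e.nominal_mh,
            e.descriptor.chain_length,
            e.descriptor.oxo3,
            e.descriptor.hydroxy3,
            e.descriptor.unsaturations,
        )
    )
    return MassLibrary(
        entries=tuple(entries),
        n_min=n_min,
        n_max=n_max,
        allow_oxo=allow_oxo,
        max_unsat=max_unsat,
        allow_hydroxy=allow_hydroxy,
    )


@dataclass(frozen=True)
class Annotation:
    """Ranked library matches for one observed m/z."""

    query_mz: float
    matches: tuple[tuple[AHLSpecies, float], ...]  # (species, signed mass error)
    tolerance: float
    mode: str = "nominal"

    @property
    def best(self) -> AHLSpecies | None:
        return self.matches[0][0] if self.matches else None


def annotate_mz(
    query_mz: float,
    library: MassLibrary,
    tolerance: float = 0.5,
    mode: Literal["nominal", "monoisotopic"] = "nominal",
) -> Annotation:
    """Match an observed m/z against the library.

    In ``nominal`` mode (unit-resolution triple-quadrupole data) the query
    is compared with integer nominal masses, default tolerance +-0.5;
    ``monoisotopic`` mode suits high-resolution inputs (typical tolerance
    +-0.01).  Matches are ranked by absolute mass error; an empty match
    list is a valid outcome (the mass may not be a simple acyl-HSL).

    Isomeric nominal masses (e.g. Oxo-C14:1-HSL vs C15:1-HSL, both 324)
    are reported as co-matches.  Exact ties are ordered preferring even
    acyl chains (fatty acyl chains grow by C2 units, so even-chain AHLs
    dominate in nature), then fewer unsaturations, then the unmodified
    chain, then the shorter one.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if mode not in ("nominal", "monoisotopic"):
        raise ValueError(f"unknown mode {mode!r}")

    scored: list[tuple[AHLSpecies, float]] = []
    for e in library:
        ref = e.nominal_mh if mode == "nominal" else e.monoisotopic_mh
        err = query_mz - ref
        if abs(err) <= tolerance:
            scored.append((e, err))
    scored.sort(
        key=lambda t: (
            abs(t[1]),
            t[0].descriptor.chain_length % 2,  # even chains first
            t[0].descriptor.unsaturations,
            t[0].descriptor.oxo3,
            t[0].descriptor.hydroxy3,
            t[0].descriptor.chain_length,
        )
    )
    return Annotation(
        query_mz=query_mz, matches=tuple(scored), tolerance=tolerance, mode=mode
    )
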