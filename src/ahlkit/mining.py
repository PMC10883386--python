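"""Post-processing of LuxI/LuxR homolog searches across genome assemblies.

Profile-HMM searches (hmmsearch ``--tblout`` tables, one per assembly) and
protein BLAST tables are treated as upstream inputs.  This module applies
the downstream bookkeeping: strict E-value significance filtering,
resolution of targets recognized by multiple models to the best model,
per-assembly copy counting for the synthase (LuxI) and receptor (LuxR)
families, deduplication of species represented by several assemblies
(keeping the assembly maximizing luxI_count x luxR_count), and distribution
summaries over the deduplicated species set.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "HmmHit",
    "BlastHit",
    "GenomeCopyNumbers",
    "CopySummary",
    "BlastFilterResult",
    "read_model_manifest",
    "read_assembly_manifest",
    "read_tblout",
    "filter_significant",
    "assign_best_model",
    "count_copies",
    "dedup_species",
    "summarize_copy_numbers",
    "read_blast",
    "filter_blast",
    "normalize_species",
]

FAMILIES = ("synthase", "receptor")

#: Default strain-suffix stripper: keeps the binomial ("Genus species"),
#: leaving sp.-style placeholder names untouched.
STRAIN_SUFFIX_RE = re.compile(r"^(\w+ (?:sp\. )?[\w.\-]+)\b.*$")


def normalize_species(name: str, pattern: re.Pattern | None = None) -> str:
    """Collapse a strain-level name to its species identity."""
    pattern = pattern or STRAIN_SUFFIX_RE
    m = pattern.match(name.strip())
    return m.group(1) if m else name.strip()


@dataclass(frozen=True)
class HmmHit:
    target_id: str
    assembly_id: str
    model_id: str
    family: str  # synthase | receptor
    evalue: float  # full-sequence E-value
    bit_score: float
    species_name: str = ""

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("E-value must be positive")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    species_name: str
    percent_identity: float
    query_coverage: float  # percent; NaN when query length unknown
    evalue: float
    bit_score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("identity must lie in [0, 100]")
        if not math.isnan(self.query_coverage) and not (
            0 <= self.query_coverage <= 100
        ):
            raise ValueError("coverage must lie in [0, 100]")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")


@dataclass(frozen=True)
class GenomeCopyNumbers:
    assembly_id: str
    species_name: str
    luxI_count: int
    luxR_count: int

    @property
    def product(self) -> int:
        return self.luxI_count * self.luxR_count


@dataclass(frozen=True)
class CopySummary:
    """Distribution statistics of one family's copy numbers over species."""

    family: str
    n_species: int
    median: float
    mean: float
    min: int
    max: int
    n_with_at_least_one: int
    n_with_exactly_one: int

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n_species": self.n_species,
            "median": self.median,
            "mean": self.mean,
            "min": self.min,
            "max": self.max,
            "n_with_at_least_one": self.n_with_at_least_one,
            "n_with_exactly_one": self.n_with_exactly_one,
        }


# ---------------------------------------------------------------------------
# manifests and readers


def read_model_manifest(path: str | Path) -> dict[str, str]:
    """TSV model_id -> family ('synthase' or 'receptor')."""
    manifest: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            model_id, family = row[0], row[1]
            if family not in FAMILIES:
                raise ValueError(
                    f"manifest family for {model_id!r} must be one of {FAMILIES}"
                )
            manifest[model_id] = family
    return manifest


def read_assembly_manifest(path: str | Path) -> dict[str, str]:
    """TSV assembly_id -> species_name (the assembly universe)."""
    universe: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            universe[row[0]] = row[1]
    return universe


def read_tblout(
    path: str | Path,
    model_manifest: Mapping[str, str],
    assembly_id: str | None = None,
) -> list[HmmHit]:
    """Parse a HMMER3 ``--tblout`` per-target table into hits.

    The assembly id defaults to the file stem (``<assembly_id>.tblout``
    naming convention).  The full-sequence E-value and score columns are
    used.  Unknown model ids and malformed rows raise immediately.
    """
    path = Path(path)
    if assembly_id is None:
        assembly_id = path.stem
    hits: list[HmmHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(maxsplit=18)
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: malformed tblout row")
            target_id, _acc, model_id = fields[0], fields[1], fields[2]
            if model_id not in model_manifest:
                raise KeyError(
                    f"{path}:{lineno}: model {model_id!r} not in manifest "
                    f"(known: {sorted(model_manifest)})"
                )
            try:
                evalue = float(fields[4])
                score = float(fields[5])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric E-value/score"
                ) from exc
            hits.append(
                HmmHit(
                    target_id=target_id,
                    assembly_id=assembly_id,
                    model_id=model_id,
                    family=model_manifest[model_id],
                    evalue=evalue,
                    bit_score=score,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# filtering pipeline


def filter_significant(
    hits: Iterable[HmmHit], threshold: float = 1e-5
) -> list[HmmHit]:
    """Keep hits with E-value strictly below the significance threshold.

    The inequality is strict, so a borderline hit at exactly the threshold
    (or, say, 9.7e-5 against 1e-5) is excluded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [h for h in hits if h.evalue < threshold]


def assign_best_model(hits: Iterable[HmmHit]) -> list[HmmHit]:
    """Resolve targets recognized by multiple models to one hit each.

    For every (assembly, target) the minimum-E-value hit survives; ties are
    broken by higher bit score, then lexicographically smallest model id.
    """
    best: dict[tuple[str, str], HmmHit] = {}
    for h in hits:
        key = (h.assembly_id, h.target_id)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bit_score, h.model_id) < (
            cur.evalue,
            -cur.bit_score,
            cur.model_id,
        ):
            best[key] = h
    return sorted(
        best.values(), key=lambda h: (h.assembly_id, h.target_id, h.model_id)
    )


def count_copies(
    hits: Iterable[HmmHit], assembly_universe: Mapping[str, str]
) -> list[GenomeCopyNumbers]:
    """Per-assembly counts of distinct surviving targets per family.

    Every assembly of the universe is reported, including zero-hit genomes.
    Hits referencing assemblies outside the universe are an error.
    """
    counts: dict[str, dict[str, set[str]]] = {
        a: {f: set() for f in FAMILIES} for a in assembly_universe
    }
    unknown: set[str] = set()
    for h in hits:
        if h.assembly_id not in counts:
            unknown.add(h.assembly_id)
            continue
        counts[h.assembly_id][h.family].add(h.target_id)
    if unknown:
        raise KeyError(
            f"hits reference assemblies missing from the universe: {sorted(unknown)}"
        )
    return [
        GenomeCopyNumbers(
            assembly_id=a,
            species_name=assembly_universe[a],
            luxI_count=len(counts[a]["synthase"]),
            luxR_count=len(counts[a]["receptor"]),
        )
        for a in sorted(assembly_universe)
    ]


def dedup_species(
    records: Iterable[GenomeCopyNumbers],
    species_pattern: re.Pattern | None = None,
) -> list[GenomeCopyNumbers]:
    """One record per species: keep the assembly with the largest
    luxI_count x luxR_count product.

    Ties go to the higher receptor count, then the lexicographically
    smallest assembly id.  Species identity is the strain-stripped name.
    """
    by_species: dict[str, GenomeCopyNumbers] = {}
    for r in sorted(records, key=lambda r: r.assembly_id):
        key = normalize_species(r.species_name, species_pattern)
        cur = by_species.get(key)
        if cur is None or (r.product, r.luxR_count, _neg_str(r.assembly_id)) > (
            cur.product,
            cur.luxR_count,
            _neg_str(cur.assembly_id),
        ):
            by_species[key] = r
    return sorted(by_species.values(), key=lambda r: r.species_name)


class _neg_str(str):
    """String whose ordering is reversed (for 'smallest id wins' in a max)."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def summarize_copy_numbers(
    records: Sequence[GenomeCopyNumbers],
) -> dict[str, CopySummary]:
    """Median/mean/min/max (and >=1 / ==1 counts) per family over species."""
    if not records:
        raise ValueError("no records to summarize")
    out: dict[str, CopySummary] = {}
    for family, attr in (("synthase", "luxI_count"), ("receptor", "luxR_count")):
        counts = np.array([getattr(r, attr) for r in records], dtype=float)
        out[family] = CopySummary(
            family=family,
            n_species=len(records),
            median=float(np.median(counts)),
            mean=float(np.mean(counts)),
            min=int(np.min(counts)),
            max=int(np.max(counts)),
            n_with_at_least_one=int(np.sum(counts >= 1)),
            n_with_exactly_one=int(np.sum(counts == 1)),
        )
    return out


# ---------------------------------------------------------------------------
# BLAST tables


def read_blast(
    path: str | Path,
    species_map: Mapping[str, str] | None = None,
    query_length: int | None = None,
) -> list[BlastHit]:
    """Read a BLAST tabular (``-outfmt 6``) file.

    Species names come from ``species_map`` (subject_id -> species).  Query
    coverage is computed as 100 * (qend - qstart + 1) / query_length when
    the query length is known, otherwise NaN.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected >= 12 columns")
            qstart, qend = int(f[6]), int(f[7])
            coverage = (
                100.0 * (qend - qstart + 1) / query_length
                if query_length
                else float("nan")
            )
            subject = f[1]
            species = species_map.get(subject, "") if species_map else ""
            hits.append(
                BlastHit(
                    query_id=f[0],
                    subject_id=subject,
                    species_name=species,
                    percent_identity=float(f[2]),
                    query_coverage=coverage,
                    evalue=float(f[10]),
                    bit_score=float(f[11]),
                )
            )
    return hits


@dataclass(frozen=True)
class BlastFilterResult:
    hits: tuple[BlastHit, ...]
    n_unique_species: int
    identity_range: tuple[float, float] | None
    coverage_range: tuple[float, float] | None


def filter_blast(
    hits: Iterable[BlastHit], evalue_threshold: float = 0.01
) -> BlastFilterResult:
    """Strict E-value filter plus unique-species and range bookkeeping."""
    if evalue_threshold <= 0:
        raise ValueError("threshold must be positive")
    kept = tuple(h for h in hits if h.evalue < evalue_threshold)
    species = {normalize_species(h.species_name) for h in kept if h.species_name}
    if kept:
        idents = [h.percent_identity for h in kept]
        covs = [h.query_coverage for h in kept if not math.isnan(h.query_coverage)]
        identity_range = (min(idents), max(idents))
        coverage_range = (min(covs), max(covs)) if covs else None
    else:
        identity_range = None
        coverage_range = None
    return BlastFilterResult(
        hits=kept,
        n_unique_species=len(species),
        identity_range=identity_range,
        coverage_range=coverage_range,
    )
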