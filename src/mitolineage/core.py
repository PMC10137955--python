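"""Shared data model for whole-mtGenome lineage analysis.

Coordinates are 1-based inclusive positions on the 16,569 bp circular
mitochondrial genome, numbered against the revised Cambridge Reference
Sequence (rCRS, NC_012920.1).  Variants are written in SWGDAM forensic
nomenclature: ``73G`` (substitution), ``315.1C`` (insertion), ``249DEL``
(deletion), ``152Y`` (point heteroplasmy, IUPAC mixed base), and lowercase
minor-length components such as ``309.1c`` for length heteroplasmy.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

MT_LENGTH = 16569

IUPAC_CODES = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
IUPAC_BASES = {code: bases for bases, code in IUPAC_CODES.items()}


class PositionError(ValueError):
    """Raised for positions outside 1..16569."""


def check_position(pos: int) -> int:
    if not 1 <= int(pos) <= MT_LENGTH:
        raise PositionError(f"position {pos} outside 1..{MT_LENGTH}")
    return int(pos)


def wrap_position(pos: int) -> int:
    """Circular position arithmetic: 16569 + 1 -> 1, 1 - 1 -> 16569."""
    return (int(pos) - 1) % MT_LENGTH + 1


# ---------------------------------------------------------------------------
# Gene regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRegion:
    """A named region on the circular genome, endpoints inclusive.

    Only the control region (CR, 16024–576) spans the origin.
    """

    name: str
    start: int
    end: int

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def __contains__(self, pos: int) -> bool:
        pos = check_position(pos)
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end

    def __len__(self) -> int:
        if self.wraps:
            return MT_LENGTH - self.start + 1 + self.end
        return self.end - self.start + 1


def _load_region_table() -> tuple[GeneRegion, ...]:
    with resources.files("mitolineage.data").joinpath("regions.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return tuple(
        GeneRegion(str(r.name), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    )


REGIONS: tuple[GeneRegion, ...] = _load_region_table()
N_REGIONS = len(REGIONS)  # 38: CR + 37 gene-coding regions

NON_CODING = "non-coding"


def annotate_region(pos: int) -> list[str]:
    """All regions containing ``pos`` in table order; ``["non-coding"]`` if none.

    Some gene regions overlap (ATP8/ATP6, ND4L/ND4, TI/TQ, ...); every
    containing region is returned and callers that need a single region use
    the first.
    """
    pos = check_position(pos)
    hits = [r.name for r in REGIONS if pos in r]
    return hits if hits else [NON_CODING]


def primary_region(pos: int) -> str:
    return annotate_region(pos)[0]


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

class VariantKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"
    POINT_HETEROPLASMY = "point_heteroplasmy"
    MINOR_LENGTH = "minor_length_component"


class VariantParseError(ValueError):
    pass


_LABEL_RE = re.compile(
    r"""^(?P<pos>\d+)
        (?:
            \.(?P<idx>\d+)(?P<insbase>[ACGTacgt])   # insertion / minor insertion
          | (?P<del>DEL)                            # deletion
          | (?P<base>[ACGTRYSWKMacgt])              # sub / PHP / minor base
        )$""",
    re.VERBOSE,
)


@dataclass(frozen=True, order=True)
class Variant:
    """A single rCRS-relative call, identified by its canonical label."""

    pos: int
    kind: VariantKind = field(compare=False)
    alt: str = ""          # base, IUPAC code, inserted base, or "" for DEL
    insert_index: int = 0  # 0 for non-insertions; >=1 for "309.1", "965.2"
    ref_allele: str | None = field(default=None, compare=False)

    def __post_init__(self):
        check_position(self.pos)
        if self.insert_index < 0:
            raise VariantParseError("insert_index must be >= 0")
        lower = self.alt.islower()
        if lower != (self.kind is VariantKind.MINOR_LENGTH):
            raise VariantParseError(
                f"lowercase alt is reserved for minor length components: "
                f"{self.pos}{self.alt!r}"
            )
        if (self.alt.upper() in IUPAC_BASES) != (
            self.kind is VariantKind.POINT_HETEROPLASMY
        ):
            raise VariantParseError(
                f"IUPAC mixed-base code requires point_heteroplasmy kind: "
                f"{self.label}"
            )

    @property
    def label(self) -> str:
        if self.kind is VariantKind.DELETION:
            return f"{self.pos}DEL"
        if self.insert_index:
            return f"{self.pos}.{self.insert_index}{self.alt}"
        return f"{self.pos}{self.alt}"

    def __str__(self) -> str:
        return self.label

    @property
    def is_minor_component(self) -> bool:
        return self.kind is VariantKind.MINOR_LENGTH

    def as_major(self) -> "Variant":
        """The uppercase (major molecule) counterpart of a minor component."""
        if not self.is_minor_component:
            return self
        alt = self.alt.upper()
        kind = VariantKind.INSERTION if self.insert_index else VariantKind.SUBSTITUTION
        return Variant(self.pos, kind, alt, self.insert_index, self.ref_allele)


def parse_variant_label(label: str) -> Variant:
    """Parse a SWGDAM-style label; ``format(parse(x)) == x`` for valid labels."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise VariantParseError(f"malformed variant label: {label!r}")
    pos = int(m.group("pos"))
    if m.group("del"):
        return Variant(pos, VariantKind.DELETION)
    if m.group("idx") is not None:
        idx = int(m.group("idx"))
        if idx == 0:
            raise VariantParseError(f"insertion index must be >= 1: {label!r}")
        base = m.group("insbase")
        kind = VariantKind.MINOR_LENGTH if base.islower() else VariantKind.INSERTION
        return Variant(pos, kind, base, idx)
    base = m.group("base")
    if base.islower():
        return Variant(pos, VariantKind.MINOR_LENGTH, base)
    if base in IUPAC_BASES:
        return Variant(pos, VariantKind.POINT_HETEROPLASMY, base)
    return Variant(pos, VariantKind.SUBSTITUTION, base)


def parse_variants(labels: Iterable[str]) -> frozenset[Variant]:
    return frozenset(parse_variant_label(s) for s in labels)


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Haplotype:
    """One sample's rCRS-relative call set.

    ``variant_freqs`` maps variant labels to read fractions in [0, 1]; for a
    point heteroplasmy it is the frequency of the non-reference allele, so the
    MAF is ``min(f, 1 - f)``.
    """

    sample_id: str
    individual_id: str
    tissue: str  # "blood" | "hair"
    variants: frozenset[Variant] = frozenset()
    no_call_positions: frozenset[int] = frozenset()
    variant_freqs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.tissue not in ("blood", "hair"):
            raise ValueError(f"tissue must be blood|hair, got {self.tissue!r}")
        overlap = self.no_call_positions & {v.pos for v in self.variants}
        if overlap:
            raise ValueError(f"no-call positions carry variants: {sorted(overlap)}")
        seen: dict[tuple[int, int], Variant] = {}
        for v in sorted(self.variants, key=lambda v: (v.pos, v.insert_index)):
            key = (v.pos, v.insert_index)
            if key in seen and not (v.is_minor_component or seen[key].is_minor_component):
                raise ValueError(f"duplicate call at {key}: {seen[key]} vs {v}")
            seen[key] = v

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(v.label for v in self.variants)

    def freq(self, variant: Variant | str) -> float | None:
        label = variant if isinstance(variant, str) else variant.label
        return self.variant_freqs.get(label)

    def phps(self) -> list[Variant]:
        return sorted(
            v for v in self.variants if v.kind is VariantKind.POINT_HETEROPLASMY
        )


# ---------------------------------------------------------------------------
# Pedigrees and maternal relationships
# ---------------------------------------------------------------------------

class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Maternal pedigree: individuals linked by mother_of edges.

    ``sex`` is used only to choose relationship labels (aunt vs uncle);
    unknown sex is recorded as "U".
    """

    mother_of: dict[str, str]          # child -> mother
    individuals: set[str] = field(default_factory=set)
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.individuals = set(self.individuals)
        self.individuals.update(self.mother_of)
        self.individuals.update(self.mother_of.values())
        for ind in self.individuals:
            self.sex.setdefault(ind, "U")
        # acyclicity + generation assignment
        self._generation: dict[str, int] = {}
        for ind in self.individuals:
            chain = set()
            cur = ind
            while cur in self.mother_of:
                if cur in chain:
                    raise PedigreeError(f"maternal cycle through {cur}")
                chain.add(cur)
                cur = self.mother_of[cur]
        for ind in sorted(self.individuals, key=lambda i: len(self.maternal_chain(i))):
            mother = self.mother_of.get(ind)
            self._generation[ind] = 1 if mother is None else self._generation[mother] + 1

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        mother_of = {}
        sex = {}
        inds = set()
        for r in df.itertuples(index=False):
            ind = str(r.individual_id)
            inds.add(ind)
            mid = getattr(r, "mother_id", None)
            if mid is not None and not pd.isna(mid) and str(mid):
                mother_of[ind] = str(mid)
            s = getattr(r, "sex", "U")
            sex[ind] = "U" if pd.isna(s) else str(s)
        return cls(mother_of=mother_of, individuals=inds, sex=sex)

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def generation(self, individual: str) -> int:
        self._require(individual)
        return self._generation[individual]

    def maternal_chain(self, individual: str) -> list[str]:
        """[individual, mother, grandmother, ...] up the maternal line."""
        chain = [individual]
        cur = individual
        while cur in self.mother_of:
            cur = self.mother_of[cur]
            chain.append(cur)
        return chain

    def _require(self, individual: str) -> None:
        if individual not in self.individuals:
            raise KeyError(f"unknown individual {individual!r}")

    def pairs(self) -> list[tuple[str, str]]:
        inds = sorted(self.individuals)
        return [(a, b) for i, a in enumerate(inds) for b in inds[i + 1 :]]


# The eleven maternal relationship types recognised for comparison
# stratification; keys are (steps-to-common-ancestor of the elder side,
# steps of the younger side).
RELATIONSHIP_NONE = ("none", 0)


def _relationship_label(da: int, db: int, elder_sex: str) -> tuple[str, int] | None:
    lo, hi = min(da, db), max(da, db)
    female = elder_sex == "F"
    table = {
        (0, 1): ("mother-offspring", 1),
        (1, 1): ("full siblings", 1),
        (0, 2): ("maternal grandmother and maternal grandson/granddaughter", 2),
        (1, 2): (
            "maternal aunt and maternal nephew/niece"
            if female
            else "maternal uncle and maternal nephew/niece",
            2,
        ),
        (2, 2): ("maternal first cousins", 3),
        (0, 3): ("maternal great grandmother and maternal great grandson", 3),
        (1, 3): (
            "maternal grandaunt and maternal grandnephew"
            if female
            else "maternal granduncle and maternal grandnephew",
            3,
        ),
        (2, 3): (
            "maternal cousin-aunt and maternal cousin-nephew"
            if female
            else "maternal cousin-uncle and maternal cousin-nephew",
            4,
        ),
    }
    return table.get((lo, hi))


def infer_maternal_relationship(
    a: str, b: str, ped: Pedigree
) -> tuple[str, int]:
    """Classify the maternal relationship between two individuals.

    Returns one of the eleven recognised (label, degree-of-kinship) types, or
    ("none", 0) for identical, unrelated, or more distant pairs.  The elder
    side (fewer steps to the common maternal ancestor) determines aunt/uncle
    style labels via its recorded sex.
    """
    ped._require(a)
    ped._require(b)
    if a == b:
        return RELATIONSHIP_NONE
    chain_a = ped.maternal_chain(a)
    chain_b = ped.maternal_chain(b)
    index_b = {ind: i for i, ind in enumerate(chain_b)}
    best = None
    for da, anc in enumerate(chain_a):
        if anc in index_b:
            best = (da, index_b[anc])
            break
    if best is None:
        return RELATIONSHIP_NONE
    da, db = best
    elder = a if da <= db else b
    rel = _relationship_label(da, db, ped.sex.get(elder, "U"))
    return rel if rel is not None else RELATIONSHIP_NONE
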