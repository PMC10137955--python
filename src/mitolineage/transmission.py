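"""Point-heteroplasmy transmission across mother–offspring pairs and lineages.

A PHP observed in both members of a pair is *inherited*; one observed only
in the offspring is *de novo*; one observed only in the mother is
*disappearing*.  The MAF change of an inherited PHP is the later
generation's MAF minus the former generation's.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import (
    Haplotype,
    IUPAC_BASES,
    Pedigree,
    Variant,
    VariantKind,
    primary_region,
)


class TransmissionClass(str, enum.Enum):
    INHERITED = "inherited"
    DE_NOVO = "de_novo"
    DISAPPEARING = "disappearing"


@dataclass(frozen=True)
class PHPRecord:
    pos: int
    sample_id: str
    individual_id: str
    tissue: str
    genotype: str               # e.g. "3386Y"
    major_allele: str
    major_freq: float
    minor_allele: str
    minor_freq: float
    region: str
    klass: TransmissionClass | None = None

    @property
    def maf(self) -> float:
        return min(self.major_freq, self.minor_freq)


@dataclass(frozen=True)
class TransmissionRecord:
    pos: int
    mother_sample: str
    offspring_sample: str
    klass: TransmissionClass
    genotype: str
    maf_change: float | None = None  # defined only for inherited


def maf_change(mother_maf: float, offspring_maf: float) -> float:
    """Offspring MAF minus mother MAF (later generation minus former)."""
    return offspring_maf - mother_maf


def php_maf(h: Haplotype, variant: Variant) -> float | None:
    f = h.freq(variant)
    if f is None:
        return None
    return min(f, 1.0 - f)


def _php_by_pos(h: Haplotype) -> dict[int, Variant]:
    return {
        v.pos: v
        for v in h.variants
        if v.kind is VariantKind.POINT_HETEROPLASMY
    }


def classify_transmission(
    mother: Haplotype, offspring: Haplotype
) -> list[TransmissionRecord]:
    """One record per PHP position in either sample; classes are exhaustive
    and mutually exclusive per genotype.

    A PHP at the same position but with a different mixed-base code in the
    two samples is treated as two events (a disappearing and a de novo PHP),
    not an inherited one.  Positions that are no-call in either sample are
    skipped.
    """
    skip = set(mother.no_call_positions) | set(offspring.no_call_positions)
    phps_m = _php_by_pos(mother)
    phps_o = _php_by_pos(offspring)
    records: list[TransmissionRecord] = []
    for pos in sorted(set(phps_m) | set(phps_o)):
        if pos in skip:
            continue
        vm, vo = phps_m.get(pos), phps_o.get(pos)
        if vm is not None and vo is not None and vm.alt == vo.alt:
            mm, mo = php_maf(mother, vm), php_maf(offspring, vo)
            change = None if mm is None or mo is None else maf_change(mm, mo)
            records.append(
                TransmissionRecord(
                    pos, mother.sample_id, offspring.sample_id,
                    TransmissionClass.INHERITED, vm.label, change,
                )
            )
            continue
        if vm is not None:
            records.append(
                TransmissionRecord(
                    pos, mother.sample_id, offspring.sample_id,
                    TransmissionClass.DISAPPEARING, vm.label,
                )
            )
        if vo is not None:
            records.append(
                TransmissionRecord(
                    pos, mother.sample_id, offspring.sample_id,
                    TransmissionClass.DE_NOVO, vo.label,
                )
            )
    return records


class LineageError(ValueError):
    pass


def lineage_trace(
    ped: Pedigree,
    samples: Sequence[Haplotype],
    pos: int,
) -> tuple[list[tuple[int, float | None]], bool]:
    """MAF series of the PHP at ``pos`` along a sampled maternal chain.

    ``samples`` must be ordered founder-first and form an unbroken maternal
    chain (each individual's mother is the previous one); a broken chain
    raises :class:`LineageError` naming the missing link.  Returns
    ``(series, persists)`` where ``series`` holds ``(generation, MAF)`` with
    ``None`` for samples lacking the PHP, and ``persists`` is True when the
    PHP is present in every sampled generation.
    """
    if len(samples) < 2:
        raise LineageError("a lineage needs at least two sampled generations")
    for prev, cur in zip(samples, samples[1:]):
        mother = ped.mother_of.get(cur.individual_id)
        if mother != prev.individual_id:
            raise LineageError(
                f"{cur.individual_id} is not recorded as a child of "
                f"{prev.individual_id}"
            )
    series: list[tuple[int, float | None]] = []
    present_all = True
    any_present = False
    for h in samples:
        v = _php_by_pos(h).get(pos)
        maf = None if v is None else php_maf(h, v)
        present = v is not None
        present_all &= present
        any_present |= present
        series.append((ped.generation(h.individual_id), maf))
    if not any_present:
        return [], False
    return series, present_all


def summarize_php(records: Iterable[PHPRecord]) -> dict:
    """Aggregate counts by tissue, IUPAC code, region, and transmission
    class, plus the MAF range; the by-tissue and by-code totals both equal
    the record count."""
    records = list(records)
    by_tissue: dict[str, int] = {}
    by_code: dict[str, int] = {}
    by_region: dict[str, int] = {}
    by_class: dict[str, int] = {}
    for r in records:
        by_tissue[r.tissue] = by_tissue.get(r.tissue, 0) + 1
        code = r.genotype[-1]
        by_code[code] = by_code.get(code, 0) + 1
        by_region[r.region] = by_region.get(r.region, 0) + 1
        if r.klass is not None:
            by_class[r.klass.value] = by_class.get(r.klass.value, 0) + 1
    mafs = [r.maf for r in records]
    return {
        "total": len(records),
        "by_tissue": by_tissue,
        "by_iupac": by_code,
        "by_region": by_region,
        "by_class": by_class,
        "maf_min": min(mafs) if mafs else None,
        "maf_max": max(mafs) if mafs else None,
    }


def php_records_from_haplotype(h: Haplotype) -> list[PHPRecord]:
    """Derive PHP records from a haplotype's calls and stored frequencies.

    The stored frequency of a PHP label is the non-reference (variant)
    allele fraction; the record's major/minor assignment follows from which
    side exceeds 50 %.
    """
    out = []
    for v in h.phps():
        f = h.freq(v)
        if f is None:
            continue
        bases = sorted(IUPAC_BASES[v.alt])
        ref = v.ref_allele
        alt = next((b for b in bases if b != ref), bases[0])
        ref_b = ref if ref in bases else next(b for b in bases if b != alt)
        ref_freq, alt_freq = 1.0 - f, f
        if alt_freq >= ref_freq:
            major, major_f, minor, minor_f = alt, alt_freq, ref_b, ref_freq
        else:
            major, major_f, minor, minor_f = ref_b, ref_freq, alt, alt_freq
        out.append(
            PHPRecord(
                pos=v.pos,
                sample_id=h.sample_id,
                individual_id=h.individual_id,
                tissue=h.tissue,
                genotype=v.label,
                major_allele=major,
                major_freq=major_f,
                minor_allele=minor,
                minor_freq=minor_f,
                region=primary_region(v.pos),
            )
        )
    return out
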