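"""Threshold-based variant calling from per-position read-count pileups.

The caller follows the forensic convention used by whole-mtGenome MPS kits:
an allele is reported when its read fraction meets the analytical and
interpretation thresholds (6 % by default), its read count reaches the
minimum (45), and its mean base quality reaches Q30.  Two passing bases at a
position yield a point heteroplasmy reported as an IUPAC mixed-base code
with MAF = the smaller of the two frequencies.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .core import (
    MT_LENGTH,
    Haplotype,
    IUPAC_CODES,
    Variant,
    VariantKind,
    check_position,
)
from .cstretch import (
    HOMOPOLYMER_REGIONS,
    HomopolymerRegion,
    region_of_position,
    report_cstretch,
)

BASES = ("A", "C", "G", "T")
DELETION = "-"


def round_percent(fraction: float, digits: int = 2) -> float:
    """Percentage rounded half-up, matching printed report conventions."""
    q = decimal.Decimal(10) ** -digits
    return float(
        decimal.Decimal(repr(fraction * 100)).quantize(
            q, rounding=decimal.ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class CallingThresholds:
    """Reporting gates.

    The analytical and interpretation thresholds play the same role in this
    pipeline (both 6 %); they are kept as separate fields for configuration
    fidelity.  The LHP thresholds gate competing molecule lengths in
    homopolymer regions and may be raised (0.20 insertions / 0.30 deletions)
    to suppress low-level length-heteroplasmy calls.
    """

    analytical_threshold: float = 0.06
    interpretation_threshold: float = 0.06
    min_q: float = 30.0
    min_reads: int = 45
    lhp_insertion_threshold: float = 0.06
    lhp_deletion_threshold: float = 0.06

    def __post_init__(self):
        for name in (
            "analytical_threshold",
            "interpretation_threshold",
            "lhp_insertion_threshold",
            "lhp_deletion_threshold",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "CallingThresholds":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        lhp = raw.pop("lhp_thresholds", {})
        if "insertion" in lhp:
            raw["lhp_insertion_threshold"] = lhp["insertion"]
        if "deletion" in lhp:
            raw["lhp_deletion_threshold"] = lhp["deletion"]
        return cls(**raw)


DEFAULT_THRESHOLDS = CallingThresholds()
# Stricter LHP gating recommended for length-variant calls.
STRICT_LHP_THRESHOLDS = replace(
    DEFAULT_THRESHOLDS, lhp_insertion_threshold=0.20, lhp_deletion_threshold=0.30
)


@dataclass
class PositionPileup:
    """Stranded read counts at one position.

    Insertion-supporting reads are anchored at this position; their counts
    are keyed by inserted sequence and are not part of the positional depth.
    """

    pos: int
    fwd: dict[str, int] = field(default_factory=dict)
    rev: dict[str, int] = field(default_factory=dict)
    ins: dict[str, int] = field(default_factory=dict)
    mean_q: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        check_position(self.pos)
        for counts in (self.fwd, self.rev, self.ins):
            if any(c < 0 for c in counts.values()):
                raise ValueError(f"negative read count at {self.pos}")

    def count(self, allele: str) -> int:
        return self.fwd.get(allele, 0) + self.rev.get(allele, 0)

    @property
    def depth(self) -> int:
        return sum(self.fwd.values()) + sum(self.rev.values())

    @property
    def fwd_depth(self) -> int:
        return sum(self.fwd.values())

    @property
    def rev_depth(self) -> int:
        return sum(self.rev.values())

    def quality(self, allele: str) -> float:
        return self.mean_q.get(allele, 40.0)


def allele_frequency(pileup: PositionPileup, allele: str) -> float | None:
    """Reads supporting ``allele`` divided by all reads at the position.

    Deletion-supporting reads are part of the denominator; insertion
    frequency is measured against the anchor position's depth.  Zero depth
    returns None (a no-call signal, not an error).
    """
    depth = pileup.depth
    if depth == 0:
        return None
    if allele in pileup.ins:
        return pileup.ins[allele] / depth
    return pileup.count(allele) / depth


def strand_bias(fwd_depth: int, rev_depth: int) -> float | None:
    """1 - min/max of the stranded depths: 0 = balanced, 1 = one strand only."""
    if fwd_depth < 0 or rev_depth < 0:
        raise ValueError("negative depth")
    if fwd_depth == 0 and rev_depth == 0:
        return None
    lo, hi = sorted((fwd_depth, rev_depth))
    return 1.0 - lo / hi


def coverage_fraction(n_no_call: int) -> float:
    """Genotyped fraction of the genome as a percentage (2 decimals)."""
    if not 0 <= n_no_call <= MT_LENGTH:
        raise ValueError(f"n_no_call outside 0..{MT_LENGTH}")
    return round_percent((MT_LENGTH - n_no_call) / MT_LENGTH)


def relative_read_depth(neg_depth: int, pos_depth: int) -> float:
    """Negative-control depth over positive-control depth (contamination gauge)."""
    if pos_depth <= 0:
        raise ValueError("positive-control depth must be > 0")
    return neg_depth / pos_depth


@dataclass(frozen=True)
class PositionCall:
    pos: int
    variants: tuple[Variant, ...]
    freqs: dict[str, float]
    no_call: bool = False


def call_position(
    pileup: PositionPileup,
    ref_allele: str,
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
) -> PositionCall:
    """Call one non-homopolymer position.

    Each allele is gated independently on frequency, read count, and mean
    quality; uniform scaling of all counts does not change the reported
    alleles once the read-count gate is satisfied.
    """
    th = thresholds
    depth = pileup.depth
    if depth == 0:
        return PositionCall(pileup.pos, (), {}, no_call=True)

    def passes(allele: str, count: int) -> bool:
        return (
            count / depth >= th.interpretation_threshold
            and count / depth >= th.analytical_threshold
            and count >= th.min_reads
            and pileup.quality(allele) >= th.min_q
        )

    passing_bases = [b for b in BASES if passes(b, pileup.count(b))]
    del_passes = passes(DELETION, pileup.count(DELETION))
    freqs = {
        b: pileup.count(b) / depth
        for b in (*BASES, DELETION)
        if pileup.count(b) > 0
    }
    variants: list[Variant] = []
    if not passing_bases and not del_passes:
        return PositionCall(pileup.pos, (), freqs, no_call=True)
    if len(passing_bases) >= 2:
        top = sorted(passing_bases, key=lambda b: freqs[b], reverse=True)[:2]
        code = IUPAC_CODES[frozenset(top)]
        variants.append(
            Variant(pileup.pos, VariantKind.POINT_HETEROPLASMY, code,
                    ref_allele=ref_allele)
        )
    elif passing_bases and passing_bases[0] != ref_allele:
        variants.append(
            Variant(pileup.pos, VariantKind.SUBSTITUTION, passing_bases[0],
                    ref_allele=ref_allele)
        )
    if del_passes:
        variants.append(
            Variant(pileup.pos, VariantKind.DELETION, ref_allele=ref_allele)
        )
    for seq, count in sorted(pileup.ins.items()):
        if passes(seq, count):
            freqs[f"ins:{seq}"] = count / depth
            for i, base in enumerate(seq, start=1):
                variants.append(
                    Variant(pileup.pos, VariantKind.INSERTION, base, i)
                )
    return PositionCall(pileup.pos, tuple(variants), freqs)


def php_maf(call: PositionCall, variant: Variant) -> float | None:
    """MAF of a point heteroplasmy: min of the two mixed-base frequencies."""
    if variant.kind is not VariantKind.POINT_HETEROPLASMY:
        return None
    from .core import IUPAC_BASES

    pair = sorted(IUPAC_BASES[variant.alt])
    f = [call.freqs.get(b, 0.0) for b in pair]
    return min(f)


@dataclass
class QCMetrics:
    strand_bias: dict[int, float | None] = field(default_factory=dict)
    coverage_fraction: float = 100.0
    total_depth: int = 0
    rrd: float | None = None


def call_sample(
    pileups: Mapping[int, PositionPileup],
    reference: Mapping[int, str],
    sample_id: str = "sample",
    individual_id: str = "ind",
    tissue: str = "blood",
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
    cstretch_fractions: Mapping[str, Mapping[str, float]] | None = None,
    cstretch_depths: Mapping[str, int] | None = None,
) -> tuple[Haplotype, QCMetrics]:
    """Call every supplied position and assemble the sample haplotype.

    Positions inside the seven homopolymer regions are not called from the
    positional pileups; their calls come from ``cstretch_fractions``
    (region name -> molecule profile -> read fraction), because molecule
    length can only be established from reads spanning the whole stretch.
    """
    variants: set[Variant] = set()
    no_call: set[int] = set()
    freqs: dict[str, float] = {}
    qc = QCMetrics()
    for pos in sorted(pileups):
        if region_of_position(pos) is not None:
            continue
        pileup = pileups[pos]
        qc.total_depth += pileup.depth
        qc.strand_bias[pos] = strand_bias(pileup.fwd_depth, pileup.rev_depth)
        result = call_position(pileup, reference.get(pos, "N"), thresholds)
        if result.no_call:
            no_call.add(pos)
            continue
        for v in result.variants:
            variants.add(v)
            if v.kind is VariantKind.POINT_HETEROPLASMY:
                freqs[v.label] = php_maf(result, v)
            elif v.kind is VariantKind.DELETION:
                freqs[v.label] = result.freqs.get(DELETION, 0.0)
            elif v.kind is VariantKind.SUBSTITUTION:
                freqs[v.label] = result.freqs.get(v.alt, 0.0)
    covered_regions = set()
    if cstretch_fractions:
        for name, fractions in cstretch_fractions.items():
            region = next(r for r in HOMOPOLYMER_REGIONS if r.name == name)
            depth = (cstretch_depths or {}).get(name)
            profile = report_cstretch(fractions, region, thresholds, depth)
            covered_regions.add(name)
            if profile.no_call:
                no_call.update(range(region.seg_start, region.seg_end + 1))
                continue
            variants.update(profile.reported_calls)
            for v in profile.reported_calls:
                mols = [
                    m
                    for m in fractions
                    if _molecule_has(region, m, v)
                ]
                if mols:
                    freqs[v.label] = sum(fractions[m] for m in mols)
    n_uncovered = MT_LENGTH - len(pileups) - sum(
        len(r.ref_segment) for r in HOMOPOLYMER_REGIONS if r.name in covered_regions
    )
    qc.coverage_fraction = coverage_fraction(len(no_call) + max(n_uncovered, 0))
    hap = Haplotype(
        sample_id=sample_id,
        individual_id=individual_id,
        tissue=tissue,
        variants=frozenset(variants),
        no_call_positions=frozenset(no_call),
        variant_freqs=freqs,
    )
    return hap, qc


def _molecule_has(region: HomopolymerRegion, profile: str, v: Variant) -> bool:
    from .cstretch import MoleculeDecodeError, molecule_calls

    try:
        calls = molecule_calls(region, profile)
    except MoleculeDecodeError:
        return False
    return v.label in calls or v.as_major().label in calls


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = [
    "pos", "ref",
    "A_fwd", "A_rev", "C_fwd", "C_rev", "G_fwd", "G_rev", "T_fwd", "T_rev",
    "del_fwd", "del_rev", "ins", "meanQ_A", "meanQ_C", "meanQ_G", "meanQ_T",
]


def pileups_to_frame(
    pileups: Mapping[int, PositionPileup], reference: Mapping[int, str]
) -> pd.DataFrame:
    rows = []
    for pos in sorted(pileups):
        p = pileups[pos]
        ins = ";".join(f"{seq}:{n}" for seq, n in sorted(p.ins.items()))
        rows.append(
            {
                "pos": pos,
                "ref": reference.get(pos, "N"),
                **{f"{b}_fwd": p.fwd.get(b, 0) for b in BASES},
                **{f"{b}_rev": p.rev.get(b, 0) for b in BASES},
                "del_fwd": p.fwd.get(DELETION, 0),
                "del_rev": p.rev.get(DELETION, 0),
                "ins": ins,
                **{f"meanQ_{b}": p.quality(b) for b in BASES},
            }
        )
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


def frame_to_pileups(
    df: pd.DataFrame,
) -> tuple[dict[int, PositionPileup], dict[int, str]]:
    pileups: dict[int, PositionPileup] = {}
    reference: dict[int, str] = {}
    for r in df.itertuples(index=False):
        pos = int(r.pos)
        reference[pos] = str(r.ref)
        ins = {}
        raw = getattr(r, "ins", "")
        if isinstance(raw, str) and raw:
            for part in raw.split(";"):
                seq, n = part.split(":")
                ins[seq] = int(n)
        pileups[pos] = PositionPileup(
            pos=pos,
            fwd={
                **{b: int(getattr(r, f"{b}_fwd")) for b in BASES},
                DELETION: int(getattr(r, "del_fwd", 0)),
            },
            rev={
                **{b: int(getattr(r, f"{b}_rev")) for b in BASES},
                DELETION: int(getattr(r, "del_rev", 0)),
            },
            ins=ins,
            mean_q={b: float(getattr(r, f"meanQ_{b}")) for b in BASES},
        )
    return pileups, reference


def write_vcf_like(haplotype: Haplotype, path) -> None:
    """Minimal VCF-style interchange: CHROM=chrM, POS, REF, ALT, AF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2-minimal\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tAF\n")
        for v in sorted(haplotype.variants):
            af = haplotype.freq(v)
            fh.write(
                f"chrM\t{v.pos}\t{v.label}\t{v.ref_allele or '.'}\t"
                f"{v.alt or '<DEL>'}\t{'' if af is None else round(af, 4)}\n"
            )
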