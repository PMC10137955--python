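"""Pairwise mtGenome haplotype comparison and SWGDAM verdicts.

Two haplotypes are compared at three evidence levels: homoplasmic variants
only; plus point heteroplasmies (PHPs); plus length-variant units (LHPs).
All calls inside one homopolymer region — including the driver substitution
such as 961C — form a single comparable unit that counts at most one
difference.  Forensic verdicts follow the SWGDAM control-region guidelines
extended to the whole molecule: two or more differing positions mean
exclusion, one means inconclusive, none means cannot exclude.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    Haplotype,
    N_REGIONS,
    NON_CODING,
    Pedigree,
    Variant,
    VariantKind,
    infer_maternal_relationship,
    primary_region,
)
from .cstretch import get_region, split_lhp_units


class ComparisonLevel(str, enum.Enum):
    HOMOPLASMIC_ONLY = "homo_only"
    WITH_PHP = "homo_php"
    FULL = "homo_php_lhp"


_LEVEL_ORDER = {
    ComparisonLevel.HOMOPLASMIC_ONLY: 0,
    ComparisonLevel.WITH_PHP: 1,
    ComparisonLevel.FULL: 2,
}
_KIND_LEVEL = {"homoplasmic": 0, "php": 1, "lhp": 2}


@dataclass(frozen=True)
class Difference:
    kind: str          # "homoplasmic" | "php" | "lhp"
    region: str        # gene region attribution (first listed for overlaps)
    detail_a: str      # variant label(s) in a, or "-"
    detail_b: str


@dataclass
class ComparisonResult:
    sample_a: str
    sample_b: str
    tissue_pattern: str
    level: ComparisonLevel
    n_diff_homoplasmic: int
    n_diff_php: int
    n_diff_lhp: int
    different_regions: list[str] = field(default_factory=list)
    details: list[tuple[str, str]] = field(default_factory=list)
    all_differences: list[Difference] = field(default_factory=list)

    @property
    def n_differences(self) -> int:
        """Differences counted at this comparison's level."""
        cut = _LEVEL_ORDER[self.level]
        return sum(
            1 for d in self.all_differences if _KIND_LEVEL[d.kind] <= cut
        )

    @property
    def n_consistent_regions(self) -> int:
        distinct = {r for r in self.different_regions if r != NON_CODING}
        return N_REGIONS - len(distinct)

    @property
    def identical(self) -> bool:
        return self.n_differences == 0


def _tissue_code(t: str) -> str:
    return {"blood": "B", "hair": "H"}[t]


def _unit_positions(region_name: str) -> range:
    r = get_region(region_name)
    return range(r.seg_start, r.seg_end + 1)


def compare(
    a: Haplotype, b: Haplotype, level: ComparisonLevel = ComparisonLevel.FULL
) -> ComparisonResult:
    """Compare two haplotypes, skipping positions that are no-call in either.

    Symmetric up to swapping the detail columns; a shared identical call
    never counts.  One differing homopolymer unit, one differing PHP
    position, or one differing homoplasmic position each contribute exactly
    one difference.
    """
    level = ComparisonLevel(level)
    skip = set(a.no_call_positions) | set(b.no_call_positions)

    units_a, rest_a = split_lhp_units(a.variants)
    units_b, rest_b = split_lhp_units(b.variants)
    diffs: list[Difference] = []

    # -- length-variant units -------------------------------------------------
    for name in sorted(set(units_a) | set(units_b)):
        if any(p in skip for p in _unit_positions(name)):
            continue
        set_a = units_a.get(name, frozenset())
        set_b = units_b.get(name, frozenset())
        if set_a != set_b:
            diffs.append(
                Difference(
                    "lhp",
                    get_region(name).gene_region,
                    _fmt_unit(set_a - set_b),
                    _fmt_unit(set_b - set_a),
                )
            )

    rest_a = {v for v in rest_a if v.pos not in skip}
    rest_b = {v for v in rest_b if v.pos not in skip}

    # -- point heteroplasmies -------------------------------------------------
    php_pos = {
        v.pos
        for v in rest_a | rest_b
        if v.kind is VariantKind.POINT_HETEROPLASMY
    }
    for pos in sorted(php_pos):
        at_a = {v.label for v in rest_a if v.pos == pos}
        at_b = {v.label for v in rest_b if v.pos == pos}
        if at_a != at_b:
            diffs.append(
                Difference(
                    "php",
                    primary_region(pos),
                    _fmt_unit_labels(at_a - at_b),
                    _fmt_unit_labels(at_b - at_a),
                )
            )

    # -- homoplasmic variants -------------------------------------------------
    keys = {
        (v.pos, v.insert_index)
        for v in rest_a | rest_b
        if v.pos not in php_pos
    }
    for pos, idx in sorted(keys):
        at_a = {v.label for v in rest_a if (v.pos, v.insert_index) == (pos, idx)}
        at_b = {v.label for v in rest_b if (v.pos, v.insert_index) == (pos, idx)}
        if at_a != at_b:
            diffs.append(
                Difference(
                    "homoplasmic",
                    primary_region(pos),
                    _fmt_unit_labels(at_a - at_b),
                    _fmt_unit_labels(at_b - at_a),
                )
            )

    cut = _LEVEL_ORDER[level]
    visible = [d for d in diffs if _KIND_LEVEL[d.kind] <= cut]
    return ComparisonResult(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        tissue_pattern=f"{_tissue_code(a.tissue)}-{_tissue_code(b.tissue)}",
        level=level,
        n_diff_homoplasmic=sum(d.kind == "homoplasmic" for d in diffs),
        n_diff_php=sum(d.kind == "php" for d in diffs),
        n_diff_lhp=sum(d.kind == "lhp" for d in diffs),
        different_regions=[d.region for d in visible],
        details=[(d.detail_a, d.detail_b) for d in visible],
        all_differences=diffs,
    )


def _fmt_unit(variants: Iterable[Variant]) -> str:
    return _fmt_unit_labels(v.label for v in variants)


def _fmt_unit_labels(labels: Iterable[str]) -> str:
    labels = sorted(labels)
    return " ".join(labels) if labels else "-"


# ---------------------------------------------------------------------------
# SWGDAM verdicts
# ---------------------------------------------------------------------------

class Verdict(str, enum.Enum):
    EXCLUSION = "exclusion"
    INCONCLUSIVE = "inconclusive"
    CANNOT_EXCLUDE = "cannot_exclude"


@dataclass(frozen=True)
class SwgdamVerdict:
    level: ComparisonLevel
    n_differences: int
    verdict: Verdict


def swgdam_verdict(
    result: ComparisonResult, level: ComparisonLevel | None = None
) -> SwgdamVerdict:
    """Verdict from the difference count at the requested evidence level.

    Length-heteroplasmy units are excluded from the count at the first two
    levels per the guidelines; at the full level they are deliberately
    included to quantify how length variants would inflate exclusions.
    """
    level = ComparisonLevel(level or result.level)
    cut = _LEVEL_ORDER[level]
    n = sum(1 for d in result.all_differences if _KIND_LEVEL[d.kind] <= cut)
    if n >= 2:
        verdict = Verdict.EXCLUSION
    elif n == 1:
        verdict = Verdict.INCONCLUSIVE
    else:
        verdict = Verdict.CANNOT_EXCLUDE
    return SwgdamVerdict(level, n, verdict)


# ---------------------------------------------------------------------------
# Tabulations
# ---------------------------------------------------------------------------

def tabulate_mother_offspring(
    pairs: Sequence[tuple[str, str]],
    haplotypes: Mapping[str, Haplotype],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One comparison row per (mother sample, offspring sample) pair.

    Headline counts: comparisons identical at the fullest level; consistent
    when heteroplasmic variants (PHP and LHP) are ignored; different when
    they are considered.
    """
    rows = []
    for m, o in pairs:
        res = compare(haplotypes[m], haplotypes[o])
        rows.append(
            {
                "mother": m,
                "offspring": o,
                "tissue_pattern": res.tissue_pattern,
                "n_consistent_regions": res.n_consistent_regions,
                "different_regions": "; ".join(res.different_regions),
                "n_diff_homoplasmic": res.n_diff_homoplasmic,
                "n_diff_php": res.n_diff_php,
                "n_diff_lhp": res.n_diff_lhp,
                "n_differences": res.n_differences,
                "details": "; ".join(f"{x}/{y}" for x, y in res.details),
            }
        )
    df = pd.DataFrame(rows)
    headline = {
        "n_comparisons": len(df),
        "identical": int((df["n_differences"] == 0).sum()),
        "consistent_ignoring_heteroplasmy": int(
            (df["n_diff_homoplasmic"] == 0).sum()
        ),
        "different_with_heteroplasmy": int((df["n_differences"] > 0).sum()),
    }
    return df, headline


def tabulate_by_relationship(
    ped: Pedigree,
    haplotypes: Mapping[str, Haplotype],
) -> pd.DataFrame:
    """Per maternal-relationship difference counts at the three levels.

    Every sample-pair combination (all tissue patterns) of every related
    individual pair is compared; per relationship the table reports the pair
    count, comparison count, and the differing-comparison count and
    percentage at each level.
    """
    by_ind: dict[str, list[Haplotype]] = {}
    for h in haplotypes.values():
        by_ind.setdefault(h.individual_id, []).append(h)
    records: dict[tuple[str, int], dict] = {}
    for a, b in ped.pairs():
        label, degree = infer_maternal_relationship(a, b, ped)
        if label == "none" or a not in by_ind or b not in by_ind:
            continue
        key = (label, degree)
        rec = records.setdefault(
            key,
            {
                "relationship": label,
                "degree": degree,
                "n_pairs": 0,
                "n_comparisons": 0,
                "diff_homo": 0,
                "diff_homo_php": 0,
                "diff_homo_php_lhp": 0,
            },
        )
        rec["n_pairs"] += 1
        for ha in by_ind[a]:
            for hb in by_ind[b]:
                res = compare(ha, hb)
                rec["n_comparisons"] += 1
                if res.n_diff_homoplasmic > 0:
                    rec["diff_homo"] += 1
                if res.n_diff_homoplasmic + res.n_diff_php > 0:
                    rec["diff_homo_php"] += 1
                if res.n_differences > 0:
                    rec["diff_homo_php_lhp"] += 1
    rows = sorted(records.values(), key=lambda r: (r["degree"], r["relationship"]))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    from .calling import round_percent

    for col in ("diff_homo", "diff_homo_php", "diff_homo_php_lhp"):
        df[f"{col}_pct"] = [
            round_percent(x / n) if n else 0.0
            for x, n in zip(df[col], df["n_comparisons"])
        ]
    return df


def empop_export(haplotypes: Iterable[Haplotype], path) -> None:
    """EMPOP-style haplotype listing: sample, range, variant labels."""
    with open(path, "w") as fh:
        for h in sorted(haplotypes, key=lambda h: h.sample_id):
            labels = " ".join(v.label for v in sorted(h.variants))
            fh.write(f"{h.sample_id}\t16024-16569;1-16023\t{labels}\n")
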