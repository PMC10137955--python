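"""Homopolymer (C-stretch) length-variant nomenclature.

Seven regions of the mtGenome are length-variable in practice.  Reads that
span such a region are grouped by molecule length into a run-length profile
(e.g. ``A-8C-T-6C-G`` for ACCCCCCCCTCCCCCCG), and the profile is resolved
into SWGDAM calls: insertions implied by the dominant molecule are reported
uppercase (``309.1C``); when a competing molecule length also passes the
reporting thresholds the region is a length heteroplasmy (LHP) and every
call not shared by all passing molecules is reported lowercase (``309.1c``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from .core import (
    Variant,
    VariantKind,
    parse_variant_label,
    primary_region,
)


class RunLengthError(ValueError):
    pass


class MoleculeDecodeError(ValueError):
    pass


class CorrectionError(ValueError):
    pass


def encode_runlength(segment: str) -> str:
    """Run-length encode a base string: ``ACCCCCCCTCCCCCCG -> A-7C-T-6C-G``.

    Runs of length >= 2 collapse to ``{n}{base}``; singletons are emitted
    bare.  Inverse of :func:`decode_runlength`.
    """
    if not segment:
        raise RunLengthError("empty segment")
    bad = set(segment) - set("ACGT")
    if bad:
        raise RunLengthError(f"non-ACGT characters: {sorted(bad)}")
    parts = []
    for base, group in itertools.groupby(segment):
        n = len(list(group))
        parts.append(f"{n}{base}" if n >= 2 else base)
    return "-".join(parts)


def decode_runlength(encoded: str) -> str:
    out = []
    for token in encoded.split("-"):
        token = token.strip()
        n = token[:-1]
        base = token[-1]
        if base not in "ACGT" or (n and not n.isdigit()):
            raise RunLengthError(f"bad run token {token!r} in {encoded!r}")
        out.append(base * (int(n) if n else 1))
    return "".join(out)


# ---------------------------------------------------------------------------
# Region definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomopolymerRegion:
    """One length-variable region.

    ``ref_segment`` is the rCRS sequence from ``seg_start``; ``drivers`` are
    the substitutions known to lengthen the stretch (e.g. 961C merges the two
    C runs around the reference 961T).  ``variation_kind`` states whether the
    common non-reference molecules carry insertions or deletions.
    """

    name: str
    seg_start: int
    ref_segment: str
    variation_kind: str  # "insertion" | "deletion"
    drivers: tuple[tuple[int, str], ...] = ()
    special: str | None = None  # custom reporting logic key

    @property
    def seg_end(self) -> int:
        return self.seg_start + len(self.ref_segment) - 1

    @property
    def rcrs_profile(self) -> str:
        return encode_runlength(self.ref_segment)

    def contains(self, pos: int) -> bool:
        return self.seg_start <= pos <= self.seg_end

    @property
    def gene_region(self) -> str:
        """Gene-region attribution for difference counting."""
        mid = (self.seg_start + self.seg_end) // 2
        return primary_region(mid)

    def mutable_runs(self) -> list[tuple[str, int, int]]:
        """Homopolymer runs (base, start, end) of length >= 2 in the reference."""
        runs = []
        pos = self.seg_start
        for base, group in itertools.groupby(self.ref_segment):
            n = len(list(group))
            if n >= 2:
                runs.append((base, pos, pos + n - 1))
            pos += n
        return runs


HOMOPOLYMER_REGIONS: tuple[HomopolymerRegion, ...] = (
    HomopolymerRegion("302-315", 302, "ACCCCCCCTCCCCCG", "insertion",
                      drivers=((310, "C"),)),
    HomopolymerRegion("955-966", 955, "ACCCCCTCCCCA", "insertion",
                      drivers=((961, "C"),)),
    HomopolymerRegion("12417-12426", 12417, "CAAAAAAAAC", "insertion"),
    HomopolymerRegion("16180-16194", 16180, "AAAACCCCCTCCCCA", "insertion",
                      drivers=((16182, "C"), (16183, "C"), (16189, "C"))),
    HomopolymerRegion("249", 249, "A", "deletion", special="249"),
    HomopolymerRegion("514-524", 514, "CACACACACAC", "deletion", special="ac-repeat"),
    HomopolymerRegion("8272-8280", 8272, "CCCCCTCTA", "deletion", special="9bp-del"),
)

_BY_NAME = {r.name: r for r in HOMOPOLYMER_REGIONS}


def get_region(name: str) -> HomopolymerRegion:
    return _BY_NAME[name]


def region_of_position(pos: int) -> HomopolymerRegion | None:
    for r in HOMOPOLYMER_REGIONS:
        if r.contains(pos):
            return r
    return None


# ---------------------------------------------------------------------------
# Molecule -> call-set decoding (insertion regions)
# ---------------------------------------------------------------------------

_MAX_INS_PER_RUN = 5


@lru_cache(maxsize=None)
def _candidate_table(region_name: str) -> dict[str, tuple[str, ...]]:
    """Map run-length profile -> canonical call labels for a region.

    Candidates enumerate driver-substitution subsets plus per-run insertion
    counts; ambiguous profiles (merged runs) resolve to the candidate with
    fewest substitutions and insertions placed in the rightmost run, which is
    the SWGDAM convention (insertions are named after the last position of
    the run).
    """
    region = get_region(region_name)
    runs = region.mutable_runs()
    table: dict[str, tuple[str, ...]] = {}
    driver_sets = sorted(
        (c for n in range(len(region.drivers) + 1)
         for c in itertools.combinations(region.drivers, n)),
        key=len,
    )
    for subs in driver_sets:
        sub_map = dict(subs)
        for ks in itertools.product(range(_MAX_INS_PER_RUN + 1), repeat=len(runs)):
            seq = []
            for pos, base in zip(
                range(region.seg_start, region.seg_end + 1), region.ref_segment
            ):
                seq.append(sub_map.get(pos, base))
                for run_i, (rbase, _, rend) in enumerate(runs):
                    if pos == rend:
                        seq.append(rbase * ks[run_i])
            profile = encode_runlength("".join(seq))
            if profile in table:
                continue
            calls = [f"{pos}{base}" for pos, base in subs]
            for run_i, (rbase, _, rend) in enumerate(runs):
                calls.extend(f"{rend}.{i}{rbase}" for i in range(1, ks[run_i] + 1))
            table[profile] = tuple(calls)
    return table


def molecule_calls(region: HomopolymerRegion, profile: str) -> frozenset[str]:
    """rCRS-relative call labels implied by one molecule's run-length profile."""
    if region.special is not None:
        return _special_molecule_calls(region, profile)
    table = _candidate_table(region.name)
    if profile not in table:
        raise MoleculeDecodeError(
            f"profile {profile!r} not interpretable in region {region.name}"
        )
    return frozenset(table[profile])


_REF_TOKENS = ("ref",)
_DEL_TOKENS = ("del", "DEL")


def _special_molecule_calls(region: HomopolymerRegion, profile: str) -> frozenset[str]:
    ref_like = profile in _REF_TOKENS or profile == region.rcrs_profile
    if region.special == "249":
        if ref_like or profile == "A":
            return frozenset()
        if profile in _DEL_TOKENS:
            return frozenset({"249DEL"})
    elif region.special == "ac-repeat":
        if ref_like or profile == "C(AC)5":
            return frozenset()
        if profile in _DEL_TOKENS or profile == "C(AC)4":
            return frozenset({"523DEL", "524DEL"})
    elif region.special == "9bp-del":
        if ref_like:
            return frozenset()
        if profile in _DEL_TOKENS:
            return frozenset(
                f"{p}DEL" for p in range(region.seg_start, region.seg_end + 1)
            )
    raise MoleculeDecodeError(
        f"profile {profile!r} not interpretable in region {region.name}"
    )


# ---------------------------------------------------------------------------
# Profile reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CStretchProfile:
    region: HomopolymerRegion
    length_fractions: Mapping[str, float]
    dominant: str | None
    reported_calls: frozenset[Variant] = frozenset()
    is_lhp: bool = False
    no_call: bool = False

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(v.label for v in self.reported_calls)


def _lowercase(label: str) -> str:
    return label[:-1] + label[-1].lower()


def report_cstretch(
    fractions: Mapping[str, float],
    region: HomopolymerRegion,
    thresholds,
    depth: int | None = None,
) -> CStretchProfile:
    """Resolve a molecule-length read profile into reported calls.

    ``fractions`` maps run-length profiles (from reads that fully span the
    region) to read fractions; ``depth`` enables the minimum-read-count gate.
    The dominant molecule's calls are always reported; competing molecule
    lengths whose fraction and read count pass the LHP thresholds make the
    region heteroplasmic and force calls not shared by every passing molecule
    to lowercase.
    """
    fractions = {k: float(v) for k, v in fractions.items() if v > 0}
    if not fractions:
        return CStretchProfile(region, {}, None, frozenset(), False, no_call=True)
    gate = (
        thresholds.lhp_insertion_threshold
        if region.variation_kind == "insertion"
        else thresholds.lhp_deletion_threshold
    )
    dominant = max(fractions, key=lambda k: (fractions[k], k))

    def passes(mol: str) -> bool:
        f = fractions[mol]
        if f < gate:
            return False
        if depth is not None and f * depth < thresholds.min_reads:
            return False
        return True

    passing = {m for m in fractions if passes(m)}
    passing.add(dominant)
    if depth is not None and fractions[dominant] * depth < thresholds.min_reads:
        return CStretchProfile(region, fractions, None, frozenset(), False, no_call=True)

    if region.special == "9bp-del" and len(passing) > 1:
        # With this amplicon design the base reads at 8272-8274 fall below the
        # read-count gate when the 9-bp deletion dominates, so those positions
        # report a clean deletion while 8275-8280 report base/deletion mixtures.
        labels = {"8272DEL", "8273DEL", "8274DEL"} | {
            _lowercase(f"{p}{b}")
            for p, b in zip(range(8275, 8281), "CCTCTA")
        }
        return _profile(region, fractions, dominant, labels, is_lhp=True)
    if region.special in ("ac-repeat", "249") and len(passing) > 1:
        # Deletion/reference mixtures report the residual reference base(s)
        # of the rightmost deleted unit as lowercase minor components.
        if region.special == "ac-repeat":
            labels = {"523a", "524c"}
        else:
            labels = {"249DEL", "249a"}
        return _profile(region, fractions, dominant, labels, is_lhp=True)

    call_sets = {m: molecule_calls(region, m) for m in passing}
    union = frozenset().union(*call_sets.values())
    shared = (
        frozenset.intersection(*call_sets.values()) if call_sets else frozenset()
    )
    labels = {c if c in shared else _lowercase(c) for c in union}
    is_lhp = any(lab[-1].islower() for lab in labels)
    return _profile(region, fractions, dominant, labels, is_lhp)


def _profile(region, fractions, dominant, labels, is_lhp) -> CStretchProfile:
    calls = frozenset(parse_variant_label(lab) for lab in labels)
    return CStretchProfile(region, dict(fractions), dominant, calls, is_lhp)


# ---------------------------------------------------------------------------
# Nomenclature corrections
# ---------------------------------------------------------------------------

def apply_nomenclature_corrections(
    calls: Sequence[Variant],
    insertion_distribution: Mapping[int, float] | None = None,
    thresholds=None,
) -> list[Variant]:
    """Rewrite the two calls that deviate from SWGDAM nomenclature.

    ``16189c`` is re-expressed as ``16189C`` plus ``16193.1c``; ``310Y``
    is re-expressed as 309.x insertion calls derived from the insertion-count
    read distribution of the 303-309 stretch (raises
    :class:`CorrectionError` when that distribution is not supplied).
    Idempotent: corrected output passes through unchanged.
    """
    gate = 0.06 if thresholds is None else thresholds.lhp_insertion_threshold
    out: list[Variant] = []
    for v in calls:
        if v.label == "16189c":
            out.append(parse_variant_label("16189C"))
            out.append(parse_variant_label("16193.1c"))
        elif v.label == "310Y":
            if not insertion_distribution:
                raise CorrectionError(
                    "310Y correction requires the insertion-count distribution"
                )
            passing = {k for k, f in insertion_distribution.items() if f >= gate}
            dom = max(insertion_distribution, key=insertion_distribution.get)
            passing.add(dom)
            top = max(passing)
            for i in range(1, top + 1):
                label = f"309.{i}C"
                if any(k < i for k in passing):
                    label = _lowercase(label)
                out.append(parse_variant_label(label))
        else:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# LHP unit grouping for comparisons
# ---------------------------------------------------------------------------

def split_lhp_units(
    variants: Iterable[Variant],
) -> tuple[dict[str, frozenset[Variant]], set[Variant]]:
    """Partition calls into per-homopolymer-region units and the remainder.

    Driver substitutions (961C, 16189C, ...) fall inside their region's span
    and are incorporated into the unit, so a 961C/961c difference and the
    surrounding 965.x components count once.
    """
    units: dict[str, set[Variant]] = {}
    rest: set[Variant] = set()
    for v in variants:
        region = region_of_position(v.pos)
        if region is not None:
            units.setdefault(region.name, set()).add(v)
        else:
            rest.add(v)
    return {k: frozenset(vs) for k, vs in units.items()}, rest


def merge_lhp_driver(calls: Iterable[Variant]) -> list[frozenset[Variant]]:
    """Group calls into comparable units: one per homopolymer region, one per
    other call."""
    units, rest = split_lhp_units(calls)
    groups = [unit for _, unit in sorted(units.items())]
    groups.extend(frozenset({v}) for v in sorted(rest))
    return groups
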