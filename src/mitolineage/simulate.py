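"""Simulated maternal pedigrees with heteroplasmy transmission.

The generative model: a founder haplotype carries random homoplasmic
substitutions and, at a configurable rate, point heteroplasmies with MAF
drawn from the reportable range (6–50 %).  Each transmission passes every
PHP through a single binomial germline bottleneck of effective size N —
resampling its frequency, with fixation at 0 converting it to a disappeared
allele and fixation at 1 to a homoplasmic substitution — and adds de novo
PHPs at a Poisson rate.  Blood and hair of the same individual diverge by
one extra within-tissue binomial resampling.  Homopolymer regions are
emitted as molecule-length read mixtures with N−1 stutter at 13.74 % of the
parental molecule, the rate observed for the 16189 stretch.

Pileups are the inverse of the caller: expected (deterministic) counts by
default so that calling a generated pileup recovers the source haplotype
exactly whenever every MAF clears the interpretation threshold with margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .calling import (
    CallingThresholds,
    DEFAULT_THRESHOLDS,
    PositionPileup,
    call_sample,
)
from .core import (
    Haplotype,
    IUPAC_CODES,
    MT_LENGTH,
    Pedigree,
    Variant,
    VariantKind,
)
from .cstretch import HOMOPOLYMER_REGIONS, get_region, region_of_position

_BASES = np.array(list("ACGT"))


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_generations: int = 3
    offspring_per_mother: int = 2
    bottleneck_size: int = 32          # effective germline bottleneck N
    n_founder_substitutions: int = 20
    php_init_rate: float = 1.0         # Poisson mean founder PHPs per genome
    php_init_maf_range: tuple[float, float] = (0.06, 0.5)
    de_novo_rate: float = 0.2          # Poisson mean new PHPs per transmission
    tissue_divergence: bool = True
    depth_mean: float = 4000.0         # lognormal location (reads)
    depth_sd: float = 0.3              # lognormal sigma (log-scale)
    strand_fraction: float = 0.5       # mean forward-read fraction
    stutter_rate: float = 0.1374       # N-1 molecule reads / parental reads
    cstretch_minor_fraction: float = 0.30
    exact_counts: bool = True

    def __post_init__(self):
        for name in ("stutter_rate", "strand_fraction",
                     "cstretch_minor_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationConfigError(f"{name} must be in [0,1], got {v}")
        for name in ("php_init_rate", "de_novo_rate"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        if self.bottleneck_size < 1:
            raise SimulationConfigError("bottleneck_size must be >= 1")
        lo, hi = self.php_init_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise SimulationConfigError(
                f"php_init_maf_range must satisfy 0 < lo <= hi <= 0.5, "
                f"got {self.php_init_maf_range}"
            )
        if self.n_generations < 1 or self.offspring_per_mother < 1:
            raise SimulationConfigError("pedigree dimensions must be >= 1")


@dataclass
class GroundTruth:
    haplotypes: dict[str, Haplotype] = field(default_factory=dict)
    php_mafs: pd.DataFrame | None = None        # sample, pos, genotype, maf
    transmissions: pd.DataFrame | None = None   # mother/offspring sample, pos, class


@dataclass
class SimulatedData:
    config: SimulationConfig
    pedigree: Pedigree
    reference: dict[int, str]
    pileups: dict[str, dict[int, PositionPileup]]
    cstretch_fractions: dict[str, dict[str, dict[str, float]]]
    cstretch_depths: dict[str, dict[str, int]]
    truth: GroundTruth


def synthetic_reference(seed: int) -> dict[int, str]:
    """A seeded random 16,569 bp genome with the real homopolymer segments
    planted at their true coordinates (the full reference is not required by
    any operation outside those segments)."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=MT_LENGTH)
    for region in HOMOPOLYMER_REGIONS:
        for offset, base in enumerate(region.ref_segment):
            seq[region.seg_start - 1 + offset] = base
    return {i + 1: str(b) for i, b in enumerate(seq)}


# ---------------------------------------------------------------------------
# Haplotype-level simulation
# ---------------------------------------------------------------------------

def _random_positions(rng, n, reference, forbidden):
    out = []
    while len(out) < n:
        pos = int(rng.integers(1, MT_LENGTH + 1))
        if pos in forbidden or region_of_position(pos) is not None:
            continue
        forbidden.add(pos)
        out.append(pos)
    return out


def _php_variant(pos: int, ref: str, alt: str) -> Variant:
    code = IUPAC_CODES[frozenset({ref, alt})]
    return Variant(pos, VariantKind.POINT_HETEROPLASMY, code, ref_allele=ref)


def _bottleneck(rng, maf: float, n: int) -> float:
    return float(rng.binomial(n, maf)) / n


def simulate_pedigree(
    config: SimulationConfig,
) -> tuple[SimulatedData, GroundTruth]:
    """Generate a pedigree, per-sample pileups, and the ground truth.

    The pedigree is a founder plus ``offspring_per_mother`` children per
    mother over ``n_generations`` generations; every individual contributes
    a blood sample and (when ``tissue_divergence``) a hair sample.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    reference = synthetic_reference(cfg.seed)

    # pedigree structure
    mother_of: dict[str, str] = {}
    gens: list[list[str]] = [["I1"]]
    counter = 1
    for g in range(1, cfg.n_generations):
        layer = []
        for mother in gens[g - 1]:
            for _ in range(cfg.offspring_per_mother):
                counter += 1
                child = f"I{counter}"
                mother_of[child] = mother
                layer.append(child)
        gens.append(layer)
    pedigree = Pedigree(mother_of=mother_of,
                        sex={i: "F" for layer in gens for i in layer})

    used: set[int] = set()
    founder_subs = {
        pos: _substitution(rng, pos, reference)
        for pos in _random_positions(rng, cfg.n_founder_substitutions,
                                     reference, used)
    }
    n_php = rng.poisson(cfg.php_init_rate)
    founder_phps = {}
    lo, hi = cfg.php_init_maf_range
    for pos in _random_positions(rng, n_php, reference, used):
        alt = _other_base(rng, reference[pos])
        founder_phps[pos] = (alt, float(rng.uniform(lo, hi)))

    # germline state per individual: {pos: (alt, maf)} plus fixed subs
    germline: dict[str, tuple[dict, dict]] = {
        "I1": (dict(founder_subs), dict(founder_phps))
    }
    transmission_rows = []
    for layer in gens[1:]:
        for child in layer:
            mother = mother_of[child]
            subs, phps = germline[mother]
            subs = dict(subs)
            new_phps: dict[int, tuple[str, float]] = {}
            for pos, (alt, maf) in phps.items():
                maf2 = _bottleneck(rng, maf, cfg.bottleneck_size)
                if maf2 <= 0.0:
                    continue
                if maf2 >= 1.0:
                    subs[pos] = alt
                    continue
                new_phps[pos] = (alt, maf2)
            for pos in _random_positions(
                rng, rng.poisson(cfg.de_novo_rate), reference, used
            ):
                alt = _other_base(rng, reference[pos])
                new_phps[pos] = (alt, float(rng.uniform(lo, hi)))
            germline[child] = (subs, new_phps)

    # tissue-level haplotypes
    truth = GroundTruth()
    php_rows = []
    tissues = ("blood", "hair") if cfg.tissue_divergence else ("blood",)
    for layer in gens:
        for ind in layer:
            subs, phps = germline[ind]
            for tissue in tissues:
                sid = f"{ind}-{'B' if tissue == 'blood' else 'H'}"
                t_phps = {}
                t_subs = dict(subs)
                for pos, (alt, maf) in phps.items():
                    m = (
                        _bottleneck(rng, maf, cfg.bottleneck_size)
                        if cfg.tissue_divergence
                        else maf
                    )
                    if m <= 0.0:
                        continue
                    if m >= 1.0:
                        t_subs[pos] = alt
                        continue
                    t_phps[pos] = (alt, m)
                variants = {
                    Variant(pos, VariantKind.SUBSTITUTION, alt,
                            ref_allele=reference[pos])
                    for pos, alt in t_subs.items()
                }
                freqs: dict[str, float] = {v.label: 1.0 for v in variants}
                for pos, (alt, maf) in t_phps.items():
                    v = _php_variant(pos, reference[pos], alt)
                    variants.add(v)
                    # stored frequency is the non-reference allele fraction
                    freqs[v.label] = maf
                    php_rows.append(
                        {"sample_id": sid, "pos": pos,
                         "genotype": v.label, "maf": maf}
                    )
                variants.update(_default_cstretch_calls())
                truth.haplotypes[sid] = Haplotype(
                    sample_id=sid, individual_id=ind, tissue=tissue,
                    variants=frozenset(variants), variant_freqs=freqs,
                )
    truth.php_mafs = pd.DataFrame(
        php_rows, columns=["sample_id", "pos", "genotype", "maf"]
    )

    for layer_i, layer in enumerate(gens[1:], start=1):
        for child in layer:
            mother = mother_of[child]
            for tissue in tissues:
                code = "B" if tissue == "blood" else "H"
                hm = truth.haplotypes[f"{mother}-{code}"]
                ho = truth.haplotypes[f"{child}-{code}"]
                from .transmission import classify_transmission

                for rec in classify_transmission(hm, ho):
                    transmission_rows.append(
                        {
                            "mother_sample": rec.mother_sample,
                            "offspring_sample": rec.offspring_sample,
                            "pos": rec.pos,
                            "class": rec.klass.value,
                        }
                    )
    truth.transmissions = pd.DataFrame(
        transmission_rows,
        columns=["mother_sample", "offspring_sample", "pos", "class"],
    )

    pileups = {}
    cs_fracs = {}
    cs_depths = {}
    for sid, hap in truth.haplotypes.items():
        p, f, d, _ = pileup_from_haplotype(hap, cfg, reference,
                                           rng=np.random.default_rng(
                                               rng.integers(2**31)))
        pileups[sid] = p
        cs_fracs[sid] = f
        cs_depths[sid] = d
    data = SimulatedData(
        config=cfg, pedigree=pedigree, reference=reference,
        pileups=pileups, cstretch_fractions=cs_fracs,
        cstretch_depths=cs_depths, truth=truth,
    )
    return data, truth


def _substitution(rng, pos, reference):
    return _other_base(rng, reference[pos])


def _other_base(rng, ref):
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, 3))]


def _default_cstretch_calls() -> set[Variant]:
    """Every simulated lineage carries the near-universal 315.1C molecule."""
    from .core import parse_variant_label

    return {parse_variant_label("315.1C")}


# ---------------------------------------------------------------------------
# Pileup synthesis (inverse of the caller)
# ---------------------------------------------------------------------------

def _ladder_molecules(region, call_labels: frozenset[str]) -> list[str]:
    """Minimal molecule set whose report reproduces ``call_labels``.

    The dominant molecule carries every call; each lowercase call adds the
    molecule lacking it (and the calls above it on the insertion ladder),
    which is exactly the N-1 stutter/reference ladder seen in real data.
    """
    from .cstretch import _candidate_table

    table = _candidate_table(region.name)
    by_set = {}
    for profile, calls in table.items():
        by_set.setdefault(frozenset(calls), profile)
    upper = {lab for lab in call_labels if not lab[-1].islower()}
    lower = sorted(
        (lab for lab in call_labels if lab[-1].islower()),
        key=_ladder_rank,
    )
    full = frozenset(lab[:-1] + lab[-1].upper() for lab in call_labels)
    if full not in by_set:
        raise ValueError(f"cannot realise calls {sorted(call_labels)}")
    molecules = [by_set[full]]
    remaining = set(full)
    for lab in reversed(lower):
        remaining = remaining - {lab[:-1] + lab[-1].upper()}
        shed = frozenset(remaining)
        if shed in by_set:
            molecules.append(by_set[shed])
    return molecules


def _ladder_rank(label: str) -> tuple[int, int]:
    from .core import parse_variant_label

    v = parse_variant_label(label)
    return (v.pos, v.insert_index)


def cstretch_fractions_from_calls(
    region_name: str,
    call_labels: frozenset[str],
    minor_fraction: float = 0.30,
    stutter_rate: float = 0.1374,
) -> dict[str, float]:
    """Molecule-length read fractions consistent with a reported call set."""
    region = get_region(region_name)
    if region.special == "249":
        if "249DEL" in call_labels:
            return {"DEL": 1.0}
        return {"ref": 1.0}
    if region.special == "ac-repeat":
        if {"523a", "524c"} <= set(call_labels):
            return {"C(AC)4": 1 - minor_fraction, "C(AC)5": minor_fraction}
        if "523DEL" in call_labels:
            return {"C(AC)4": 1.0}
        return {"ref": 1.0}
    if region.special == "9bp-del":
        if any(lab.endswith(("c", "t", "a")) for lab in call_labels):
            return {"DEL": 1 - minor_fraction, "ref": minor_fraction}
        if call_labels:
            return {"DEL": 1.0}
        return {"ref": 1.0}
    molecules = _ladder_molecules(region, call_labels)
    has_lower = any(lab[-1].islower() for lab in call_labels)
    if len(molecules) == 1 and not has_lower:
        if molecules[0] == region.rcrs_profile:
            return {molecules[0]: 1.0}
        # homoplasmic length variant: competitor stays below every gate
        return {molecules[0]: 1.0 - 0.02, region.rcrs_profile: 0.02}
    k = len(molecules) - 1
    per_minor = max(0.10, minor_fraction / k) if k else 0.0
    weights = np.array([1.0] + [per_minor] * k)
    weights = weights / weights.sum()
    fracs = {m: float(w) for m, w in zip(molecules, weights)}
    if has_lower and region.rcrs_profile not in fracs:
        # residual true-reference molecules below threshold (stutter floor)
        floor = min(0.02, stutter_rate / 10)
        fracs = {m: f * (1 - floor) for m, f in fracs.items()}
        fracs[region.rcrs_profile] = floor
    return fracs


def pileup_from_haplotype(
    haplotype: Haplotype,
    config: SimulationConfig = SimulationConfig(),
    reference: Mapping[int, str] | None = None,
    rng: np.random.Generator | None = None,
    positions: Mapping[int, bool] | None = None,
) -> tuple[
    dict[int, PositionPileup],
    dict[str, dict[str, float]],
    dict[str, int],
    dict[int, str],
]:
    """Emit per-position pileups, homopolymer molecule mixtures, and the
    effective reference used.

    A variant's recorded ``ref_allele`` overrides the supplied reference at
    its position (and a reference base colliding with a variant allele is
    repaired), so calling the output against the returned reference is a
    faithful inverse.  With ``config.exact_counts`` the counts are rounded
    expectations, so the caller recovers the haplotype exactly whenever
    every stored MAF is comfortably above the interpretation threshold and
    depth is >= 1000.
    """
    from .core import IUPAC_BASES

    if reference is None:
        reference = synthetic_reference(config.seed)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    variant_pos: dict[int, list[Variant]] = {}
    for v in haplotype.variants:
        variant_pos.setdefault(v.pos, []).append(v)

    wanted = (
        set(positions)
        if positions is not None
        else set(variant_pos) | {p for p in range(1, 201)}
    )

    def effective_ref(pos: int) -> str:
        base = reference.get(pos, "A")
        for v in variant_pos.get(pos, ()):
            if v.ref_allele:
                return v.ref_allele
            if v.kind is VariantKind.SUBSTITUTION and base == v.alt:
                return "A" if v.alt != "A" else "G"
            if v.kind is VariantKind.POINT_HETEROPLASMY:
                pair = IUPAC_BASES[v.alt]
                if base not in pair:
                    return sorted(pair)[0]
        return base

    ref_map: dict[int, str] = {}
    pileups: dict[int, PositionPileup] = {}
    for pos in sorted(wanted):
        if region_of_position(pos) is not None:
            continue
        if pos in haplotype.no_call_positions:
            continue
        depth = (
            int(round(config.depth_mean))
            if config.exact_counts
            else max(1, int(rng.lognormal(np.log(config.depth_mean),
                                          config.depth_sd)))
        )
        ref = effective_ref(pos)
        ref_map[pos] = ref
        allele_freqs: dict[str, float] = {ref: 1.0}
        ins: dict[str, int] = {}
        for v in variant_pos.get(pos, ()):  # noqa: B023
            if v.kind is VariantKind.SUBSTITUTION:
                allele_freqs = {v.alt: 1.0}
            elif v.kind is VariantKind.POINT_HETEROPLASMY:
                f = haplotype.freq(v)
                f = 0.5 if f is None else f
                pair = IUPAC_BASES[v.alt]
                alt = next(iter(pair - {ref}), sorted(pair)[0])
                allele_freqs = {ref: 1.0 - f, alt: f}
            elif v.kind is VariantKind.DELETION:
                allele_freqs = {"-": 1.0}
            elif v.kind is VariantKind.INSERTION and v.insert_index == 1:
                seq = "".join(
                    w.alt
                    for w in sorted(variant_pos[pos],
                                    key=lambda w: w.insert_index)
                    if w.kind is VariantKind.INSERTION
                )
                ins[seq] = None  # filled below once depth known
        counts = {}
        for allele, f in allele_freqs.items():
            n = f * depth
            counts[allele] = (
                int(round(n)) if config.exact_counts else int(rng.binomial(depth, f))
            )
        fwd = {}
        rev = {}
        for allele, n in counts.items():
            nf = (
                int(round(n * config.strand_fraction))
                if config.exact_counts
                else int(rng.binomial(n, config.strand_fraction))
            )
            fwd[allele] = nf
            rev[allele] = n - nf
        ins = {seq: int(round(0.98 * depth)) for seq in ins}
        pileups[pos] = PositionPileup(pos=pos, fwd=fwd, rev=rev, ins=ins)

    cs_fracs: dict[str, dict[str, float]] = {}
    cs_depths: dict[str, int] = {}
    for region in HOMOPOLYMER_REGIONS:
        labels = frozenset(
            v.label for v in haplotype.variants if region.contains(v.pos)
        )
        cs_fracs[region.name] = cstretch_fractions_from_calls(
            region.name, labels, config.cstretch_minor_fraction,
            config.stutter_rate,
        )
        cs_depths[region.name] = int(round(config.depth_mean))
    return pileups, cs_fracs, cs_depths, ref_map


def expected_stutter_reads(parent_reads: int, stutter_rate: float = 0.1374) -> int:
    """Expected N-1 stutter molecule read count for a parental molecule."""
    return int(round(parent_reads * stutter_rate))


def call_simulated_sample(
    data: SimulatedData,
    sample_id: str,
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
) -> Haplotype:
    truth_h = data.truth.haplotypes[sample_id]
    hap, _ = call_sample(
        data.pileups[sample_id],
        data.reference,
        sample_id=sample_id,
        individual_id=truth_h.individual_id,
        tissue=truth_h.tissue,
        thresholds=thresholds,
        cstretch_fractions=data.cstretch_fractions[sample_id],
        cstretch_depths=data.cstretch_depths[sample_id],
    )
    return hap
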