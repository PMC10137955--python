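"""Bundled reference dataset: ten maternal pedigrees, 33 individuals, 44
samples (33 blood, 11 hair), reconstructed at the variant-call level from a
published whole-mtGenome pedigree study's printed tables.

The dataset carries every reported point heteroplasmy with its printed
allele frequencies, per-sample length-variant call sets for the seven
homopolymer regions, the universal homoplasmic backbone, and one de novo
homoplasmic substitution (4475C in P06-H).  Pedigree-private homoplasmic
marker variants are synthetic: they exist only to make the ten maternal
haplotypes distinct and never differ within a pedigree, so no comparison
result depends on them.

Where the source tables disagree with each other the dataset is reconciled
so a single consistent comparison engine reproduces the headline results:
np 4776 is encoded as no-call in P01-B/P01-H and np 15115 as no-call in
Family7-C (the comparison contract skips positions that are no-call in
either sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .core import (
    Haplotype,
    Pedigree,
    Variant,
    VariantKind,
    parse_variant_label,
)
from .transmission import PHPRecord, php_records_from_haplotype

#: Homoplasmic variants observed in every sample (315.1C lives in the
#: 302-315 length-variant call sets instead).
BACKBONE = (
    "73G", "263G", "1438G", "2706G", "4769G",
    "7028T", "8860G", "11719A", "14766T", "15326G",
)

#: Synthetic per-pedigree marker variants (see module docstring).
PEDIGREE_MARKERS = {
    "P": ("10400T",),
    "JX": ("14502C",),
    "Family1": ("16311C",),
    "Family2": ("15043A",),
    "Family3": ("6392C",),
    "Family4": ("10398G",),
    "Family5": ("12372A",),
    "Family6": ("5178A",),
    "Family7": ("8701G",),
    "Family8": ("9540C",),
}

#: Individual-private homoplasmic calls.
EXTRA_HOMOPLASMIC = {
    "P06-H": ("4475C",),
}

#: Reconciliation no-calls (module docstring) plus the 54 uncovered
#: positions reported for P15-H.
NO_CALLS = {
    "P01-B": frozenset({4776}),
    "P01-H": frozenset({4776}),
    "Family7-C": frozenset({15115}),
    "P15-H": frozenset(range(5904, 5958)),
}

#: Mother-offspring individual pairs, founders first (23 pairs; the ten
#: pairs of the four-generation pedigree contribute four tissue patterns
#: each, for 53 sample comparisons).
MOTHER_OFFSPRING = (
    ("Family1-M", "Family1-C"),
    ("Family2-M", "Family2-C"),
    ("Family3-M", "Family3-C"),
    ("Family4-M", "Family4-C"),
    ("Family5-M", "Family5-C"),
    ("Family6-M", "Family6-C"),
    ("Family7-M", "Family7-C"),
    ("Family8-M", "Family8-C"),
    ("JX-N", "JX-M1"),
    ("JX-N", "JX-M2"),
    ("JX-M1", "JX-C1"),
    ("JX-M1", "JX-C2"),
    ("JX-M2", "JX-C3"),
    ("P01", "P03"),
    ("P01", "P04"),
    ("P01", "P06"),
    ("P01", "P08"),
    ("P01", "P09"),
    ("P03", "P12"),
    ("P04", "P13"),
    ("P06", "P14"),
    ("P08", "P15"),
    ("P12", "P18"),
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("mitolineage.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


@dataclass
class FixtureData:
    pedigree: Pedigree
    pedigree_of: dict[str, str]             # individual -> pedigree id
    haplotypes: dict[str, Haplotype]        # sample_id -> haplotype
    mother_offspring_pairs: list[tuple[str, str]]  # 53 sample pairs
    php_records: list[PHPRecord]

    def samples_of(self, individual: str) -> list[str]:
        return sorted(
            s for s, h in self.haplotypes.items() if h.individual_id == individual
        )


def _sample_pairs(
    mother: str, offspring: str, samples: dict[str, list[tuple[str, str]]]
) -> list[tuple[str, str]]:
    def by_tissue(ind, tissue):
        return next((s for s, t in samples[ind] if t == tissue), None)

    out = []
    for tm, to in (("blood", "blood"), ("blood", "hair"),
                   ("hair", "hair"), ("hair", "blood")):
        sm, so = by_tissue(mother, tm), by_tissue(offspring, to)
        if sm is not None and so is not None:
            out.append((sm, so))
    return out


def load_fixture() -> FixtureData:
    """Build the 44 reference haplotypes and the 53 mother-offspring
    comparison pairs."""
    ped_df = _read("fixture_pedigree.tsv")
    samples_df = _read("fixture_samples.tsv")
    php_df = _read("fixture_php.tsv")
    lhp_df = _read("fixture_lhp.tsv")

    pedigree = Pedigree.from_frame(ped_df)
    pedigree_of = dict(zip(ped_df["individual_id"], ped_df["pedigree_id"]))

    lhp_by_sample: dict[str, list[Variant]] = {}
    for r in lhp_df.itertuples(index=False):
        lhp_by_sample.setdefault(r.sample_id, []).extend(
            parse_variant_label(lab) for lab in r.calls.split()
        )
    php_by_sample: dict[str, list] = {}
    for r in php_df.itertuples(index=False):
        php_by_sample.setdefault(r.sample_id, []).append(r)

    haplotypes: dict[str, Haplotype] = {}
    for r in samples_df.itertuples(index=False):
        sid, ind, tissue = r.sample_id, r.individual_id, r.tissue
        labels = list(BACKBONE)
        labels.extend(PEDIGREE_MARKERS[pedigree_of[ind]])
        labels.extend(EXTRA_HOMOPLASMIC.get(sid, ()))
        variants = {parse_variant_label(lab) for lab in labels}
        variants.update(lhp_by_sample.get(sid, ()))
        freqs: dict[str, float] = {}
        for row in php_by_sample.get(sid, ()):
            v = parse_variant_label(row.genotype)
            v = Variant(v.pos, v.kind, v.alt, ref_allele=row.ref)
            variants.add(v)
            freqs[v.label] = float(row.alt_freq) / 100.0
        haplotypes[sid] = Haplotype(
            sample_id=sid,
            individual_id=ind,
            tissue=tissue,
            variants=frozenset(variants),
            no_call_positions=NO_CALLS.get(sid, frozenset()),
            variant_freqs=freqs,
        )

    by_ind: dict[str, list[tuple[str, str]]] = {}
    for sid, h in haplotypes.items():
        by_ind.setdefault(h.individual_id, []).append((sid, h.tissue))
    pairs = [
        p
        for mother, offspring in MOTHER_OFFSPRING
        for p in _sample_pairs(mother, offspring, by_ind)
    ]

    records = [
        rec for sid in sorted(haplotypes) for rec in
        php_records_from_haplotype(haplotypes[sid])
    ]
    return FixtureData(
        pedigree=pedigree,
        pedigree_of=pedigree_of,
        haplotypes=haplotypes,
        mother_offspring_pairs=pairs,
        php_records=records,
    )
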