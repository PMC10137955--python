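"""Shared data model: regions, variant nomenclature, pedigrees."""

import pytest

from mitolineage.core import (
    MT_LENGTH,
    N_REGIONS,
    PositionError,
    REGIONS,
    Pedigree,
    PedigreeError,
    VariantKind,
    VariantParseError,
    annotate_region,
    infer_maternal_relationship,
    parse_variant_label,
    wrap_position,
)


class TestRegions:
    def test_region_table_shape(self):
        assert N_REGIONS == 38
        wrapping = [r for r in REGIONS if r.wraps]
        assert [r.name for r in wrapping] == ["CR"]
        assert (REGIONS[0].start, REGIONS[0].end) == (16024, 576)

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (3386, ["ND1"]),
            (16154, ["CR"]),
            (8550, ["ATP8", "ATP6"]),   # overlapping genes: all reported
            (152, ["CR"]),
            (576, ["CR"]),
            (577, ["TF"]),
            (961, ["RNR1"]),
            (8280, ["non-coding"]),     # gap between CO2 and TK
            (5730, ["non-coding"]),
            (12361, ["ND5"]),
            (10762, ["ND4L", "ND4"]),
        ],
    )
    def test_annotation_examples(self, pos, expected):
        assert annotate_region(pos) == expected

    def test_annotation_matches_brute_force_scan(self):
        """Every position annotates identically to a direct interval scan."""
        for pos in range(1, MT_LENGTH + 1):
            hits = [
                r.name
                for r in REGIONS
                if (pos >= r.start or pos <= r.end)
                if r.wraps
            ] + [
                r.name
                for r in REGIONS
                if not r.wraps and r.start <= pos <= r.end
            ]
            # preserve table order
            ordered = [r.name for r in REGIONS if r.name in set(hits)]
            assert annotate_region(pos) == (ordered or ["non-coding"])

    def test_out_of_range_position(self):
        with pytest.raises(PositionError):
            annotate_region(0)
        with pytest.raises(PositionError):
            annotate_region(16570)

    def test_circular_arithmetic(self):
        assert wrap_position(MT_LENGTH + 1) == 1
        assert wrap_position(0) == MT_LENGTH


class TestVariantLabels:
    @pytest.mark.parametrize(
        "label,kind,pos,idx",
        [
            ("315.1C", VariantKind.INSERTION, 315, 1),
            ("249DEL", VariantKind.DELETION, 249, 0),
            ("152Y", VariantKind.POINT_HETEROPLASMY, 152, 0),
            ("73G", VariantKind.SUBSTITUTION, 73, 0),
            ("309.1c", VariantKind.MINOR_LENGTH, 309, 1),
            ("523a", VariantKind.MINOR_LENGTH, 523, 0),
            ("965.3c", VariantKind.MINOR_LENGTH, 965, 3),
            ("13683M", VariantKind.POINT_HETEROPLASMY, 13683, 0),
        ],
    )
    def test_parse_and_roundtrip(self, label, kind, pos, idx):
        v = parse_variant_label(label)
        assert (v.kind, v.pos, v.insert_index) == (kind, pos, idx)
        assert v.label == label

    def test_every_fixture_label_parses(self, fixture_data):
        labels = {
            v.label
            for h in fixture_data.haplotypes.values()
            for v in h.variants
        }
        assert len(labels) > 50
        for label in labels:
            assert parse_variant_label(label).label == label

    @pytest.mark.parametrize("bad", ["", "X73", "73", "309.C", "73g.1", "0A",
                                     "16570A", "309.0C"])
    def test_malformed_labels_rejected(self, bad):
        with pytest.raises((VariantParseError, PositionError)):
            parse_variant_label(bad)


class TestPedigree:
    def test_generations_and_acyclicity(self, fixture_data):
        ped = fixture_data.pedigree
        assert ped.generation("P01") == 1
        assert ped.generation("P12") == 3
        assert ped.generation("P18") == 4
        for child, mother in ped.mother_of.items():
            assert ped.generation(child) == ped.generation(mother) + 1

    def test_cycle_detection(self):
        with pytest.raises(PedigreeError):
            Pedigree(mother_of={"a": "b", "b": "a"})

    @pytest.mark.parametrize(
        "a,b,label,degree",
        [
            ("P01", "P03", "mother-offspring", 1),
            ("P03", "P04", "full siblings", 1),
            ("P01", "P12",
             "maternal grandmother and maternal grandson/granddaughter", 2),
            ("P04", "P12", "maternal aunt and maternal nephew/niece", 2),
            ("P09", "P12", "maternal uncle and maternal nephew/niece", 2),
            ("P12", "P13", "maternal first cousins", 3),
            ("P01", "P18",
             "maternal great grandmother and maternal great grandson", 3),
            ("P04", "P18", "maternal grandaunt and maternal grandnephew", 3),
            ("P09", "P18", "maternal granduncle and maternal grandnephew", 3),
            ("P13", "P18",
             "maternal cousin-aunt and maternal cousin-nephew", 4),
            ("P14", "P18",
             "maternal cousin-uncle and maternal cousin-nephew", 4),
            ("Family1-M", "P01", "none", 0),
        ],
    )
    def test_relationship_examples(self, fixture_data, a, b, label, degree):
        ped = fixture_data.pedigree
        assert infer_maternal_relationship(a, b, ped) == (label, degree)
        assert infer_maternal_relationship(b, a, ped) == (label, degree)

    def test_unknown_individual_raises(self, fixture_data):
        with pytest.raises(KeyError):
            infer_maternal_relationship("P01", "nobody", fixture_data.pedigree)

    def test_relationship_pair_counts(self, fixture_data):
        """Pair counts per relationship across the reconstructed pedigrees.

        All counts match the published stratification except full siblings,
        where the reconstructed pedigrees contain 12 pairs (the published
        count of 11 is inconsistent with its own 42 comparisons).
        """
        ped = fixture_data.pedigree
        counts = {}
        for a, b in ped.pairs():
            label, _ = infer_maternal_relationship(a, b, ped)
            counts[label] = counts.get(label, 0) + 1
        assert counts["mother-offspring"] == 23
        assert counts["full siblings"] == 12
        assert counts[
            "maternal grandmother and maternal grandson/granddaughter"] == 8
        assert counts["maternal aunt and maternal nephew/niece"] == 15
        assert counts["maternal uncle and maternal nephew/niece"] == 4
        assert counts["maternal first cousins"] == 8
        assert counts[
            "maternal great grandmother and maternal great grandson"] == 1
        assert counts["maternal grandaunt and maternal grandnephew"] == 3
        assert counts["maternal granduncle and maternal grandnephew"] == 1
        assert counts["maternal cousin-aunt and maternal cousin-nephew"] == 1
        assert counts["maternal cousin-uncle and maternal cousin-nephew"] == 2
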