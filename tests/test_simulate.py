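"""Simulator: determinism, caller round-trips, and transmission recovery."""

import numpy as np
import pytest

from mitolineage.calling import call_sample
from mitolineage.comparison import compare
from mitolineage.simulate import (
    SimulationConfig,
    SimulationConfigError,
    call_simulated_sample,
    cstretch_fractions_from_calls,
    expected_stutter_reads,
    pileup_from_haplotype,
    simulate_pedigree,
    synthetic_reference,
)
from mitolineage.transmission import TransmissionClass, classify_transmission


SMALL = SimulationConfig(seed=11, n_generations=3, offspring_per_mother=2,
                         php_init_rate=2.0, de_novo_rate=0.5)


@pytest.fixture(scope="module")
def small_sim():
    return simulate_pedigree(SMALL)


class TestConfig:
    def test_invalid_fields_are_named(self):
        with pytest.raises(SimulationConfigError, match="stutter_rate"):
            SimulationConfig(stutter_rate=1.5)
        with pytest.raises(SimulationConfigError, match="bottleneck_size"):
            SimulationConfig(bottleneck_size=0)
        with pytest.raises(SimulationConfigError, match="php_init_maf_range"):
            SimulationConfig(php_init_maf_range=(0.5, 0.06))

    def test_stutter_expectation(self):
        assert expected_stutter_reads(10000, 0.1374) == 1374


class TestDeterminism:
    def test_same_seed_same_output(self, small_sim):
        data, truth = small_sim
        data2, truth2 = simulate_pedigree(SMALL)
        assert set(truth.haplotypes) == set(truth2.haplotypes)
        for sid in truth.haplotypes:
            assert truth.haplotypes[sid].variants == truth2.haplotypes[sid].variants
        assert truth.php_mafs.equals(truth2.php_mafs)
        assert truth.transmissions.equals(truth2.transmissions)
        ref = synthetic_reference(SMALL.seed)
        assert ref == data2.reference == data.reference

    def test_different_seed_differs(self):
        t1 = simulate_pedigree(SMALL)[1]
        t2 = simulate_pedigree(
            SimulationConfig(seed=12, php_init_rate=2.0, de_novo_rate=0.5)
        )[1]
        assert any(
            t1.haplotypes[s].variants != t2.haplotypes[s].variants
            for s in t1.haplotypes
        )


class TestRoundTrip:
    def test_caller_recovers_simulated_haplotypes(self, small_sim):
        """Calling the emitted pileups recovers every planted variant whose
        MAF sits clear of the 6 % interpretation threshold, and plants no
        extras."""
        data, truth = small_sim
        for sid, want_h in truth.haplotypes.items():
            called = call_simulated_sample(data, sid)
            want = {v.label for v in want_h.variants}
            got = {v.label for v in called.variants}
            borderline = {
                v.label
                for v in want_h.phps()
                if min(want_h.freq(v), 1 - want_h.freq(v)) < 0.08
            }
            assert not (got - want), sid
            assert not ((want - got) - borderline), sid

    def test_random_haplotype_roundtrip(self):
        """100 random heteroplasmic haplotypes survive the pileup -> caller
        inverse exactly when MAFs are >= 8 % at depth >= 1000."""
        from mitolineage.core import (
            Haplotype,
            IUPAC_CODES,
            Variant,
            VariantKind,
        )

        rng = np.random.default_rng(7)
        cfg = SimulationConfig(seed=7, depth_mean=1500)
        ref = synthetic_reference(7)
        for trial in range(100):
            variants = set()
            freqs = {}
            positions = rng.choice(
                np.arange(600, 16000), size=6, replace=False
            )
            for i, pos in enumerate(map(int, positions)):
                from mitolineage.cstretch import region_of_position

                if region_of_position(pos) is not None:
                    continue
                base = ref[pos]
                alt = next(b for b in "ACGT" if b != base)
                if i % 2:
                    v = Variant(pos, VariantKind.SUBSTITUTION, alt,
                                ref_allele=base)
                    variants.add(v)
                    freqs[v.label] = 1.0
                else:
                    code = IUPAC_CODES[frozenset({base, alt})]
                    v = Variant(pos, VariantKind.POINT_HETEROPLASMY, code,
                                ref_allele=base)
                    variants.add(v)
                    freqs[v.label] = float(rng.uniform(0.08, 0.5))
            hap = Haplotype(
                sample_id=f"t{trial}", individual_id=f"t{trial}",
                tissue="blood", variants=frozenset(variants),
                variant_freqs=freqs,
            )
            pileups, fracs, depths, ref_map = pileup_from_haplotype(
                hap, cfg, ref
            )
            called, _ = call_sample(
                pileups, ref_map, sample_id=hap.sample_id,
                cstretch_fractions=fracs, cstretch_depths=depths,
            )
            assert {v.label for v in called.variants} == {
                v.label for v in hap.variants
            }

    def test_lhp_mixture_roundtrip(self, fixture_data):
        """Length-variant call sets of the reference samples survive the
        fraction-map inverse."""
        from mitolineage.cstretch import get_region, report_cstretch
        from mitolineage.calling import DEFAULT_THRESHOLDS

        seen = set()
        for h in fixture_data.haplotypes.values():
            for region_name in ("302-315", "955-966", "16180-16194"):
                region = get_region(region_name)
                labels = frozenset(
                    v.label for v in h.variants if region.contains(v.pos)
                )
                if labels in seen:
                    continue
                seen.add(labels)
                fracs = cstretch_fractions_from_calls(region_name, labels)
                profile = report_cstretch(
                    fracs, region, DEFAULT_THRESHOLDS, depth=4000
                )
                assert profile.labels == labels


class TestGenerativeProperties:
    def test_zero_rates_make_all_comparisons_identical(self):
        cfg = SimulationConfig(seed=5, php_init_rate=0.0, de_novo_rate=0.0)
        _, truth = simulate_pedigree(cfg)
        haps = list(truth.haplotypes.values())
        for other in haps[1:]:
            assert compare(haps[0], other).n_differences == 0

    def test_large_bottleneck_preserves_maf(self):
        cfg = SimulationConfig(
            seed=9, bottleneck_size=10**6, php_init_rate=3.0,
            de_novo_rate=0.0, n_generations=2, offspring_per_mother=3,
            tissue_divergence=False,
        )
        _, truth = simulate_pedigree(cfg)
        founder = truth.haplotypes["I1-B"]
        for v in founder.phps():
            f0 = founder.freq(v)
            for sid, h in truth.haplotypes.items():
                if sid == "I1-B":
                    continue
                f = h.freq(v)
                assert f is not None and abs(f - f0) < 0.01

    def test_transmission_class_recovery_away_from_threshold(self, small_sim):
        """Classes recovered from called haplotypes match ground truth for
        every PHP whose true MAF is 2 % clear of the 6 % threshold."""
        data, truth = small_sim
        called = {
            sid: call_simulated_sample(data, sid) for sid in truth.haplotypes
        }
        checked = 0
        for row in truth.transmissions.to_dict("records"):
            hm_t = truth.haplotypes[row["mother_sample"]]
            ho_t = truth.haplotypes[row["offspring_sample"]]

            def maf_of(h, pos):
                v = next((p for p in h.phps() if p.pos == pos), None)
                if v is None:
                    return 0.0
                f = h.freq(v)
                return min(f, 1 - f)

            if any(
                0 < maf_of(h, row["pos"]) < 0.08 for h in (hm_t, ho_t)
            ):
                continue  # truth PHP too close to the reporting threshold
            recs = classify_transmission(
                called[row["mother_sample"]], called[row["offspring_sample"]]
            )
            match = [r for r in recs if r.pos == row["pos"]]
            assert match, (row["pos"], row["mother_sample"])
            assert match[0].klass is TransmissionClass(row["class"])
            checked += 1
        assert checked > 0

    def test_maf_changes_centered_at_zero(self):
        """Selection-free binomial resampling leaves the mean MAF change
        within two standard errors of zero."""
        cfg = SimulationConfig(
            seed=21, n_generations=4, offspring_per_mother=3,
            php_init_rate=4.0, de_novo_rate=0.0, bottleneck_size=60,
            tissue_divergence=False,
        )
        _, truth = simulate_pedigree(cfg)
        haps = truth.haplotypes
        changes = []
        for row in truth.transmissions.to_dict("records"):
            if row["class"] != "inherited":
                continue
            hm = haps[row["mother_sample"]]
            ho = haps[row["offspring_sample"]]
            vm = next(p for p in hm.phps() if p.pos == row["pos"])
            vo = next(p for p in ho.phps() if p.pos == row["pos"])
            fm, fo = hm.freq(vm), ho.freq(vo)
            changes.append(fo - fm)
        changes = np.asarray(changes)
        assert len(changes) >= 10
        se = changes.std(ddof=1) / np.sqrt(len(changes))
        assert abs(changes.mean()) < 2 * se + 1e-9
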