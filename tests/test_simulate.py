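"""Cohort simulator: determinism, catalog structure, genotype model,
rendering moments, sex model, and truth-label conservation."""

import numpy as np
import pytest

from graftrace.simulate import (
    CloneSpec,
    CnvSpec,
    CohortConfig,
    ConfigError,
    MlpaSpec,
    RecipientSpec,
    SampleSpec,
    TumorTruth,
    default_config,
    read_cohort,
    render_observed_sample,
    simulate_catalog,
    simulate_cohort,
    simulate_germline,
    simulate_tumor_truth,
    write_cohort,
)
from graftrace.variants import VariantKey


def tiny_config(seed=0, **overrides):
    base = dict(
        seed=seed,
        n_common=800,
        n_rare_per_individual=40,
        recipients=[RecipientSpec(recipient_id="LR", sex="female")],
        clones=[
            CloneSpec(clone_id="truncal", fraction=1.0, private_mutation_count=60,
                      driver_mutations=[("BRAF", "7:140453136:A:T")]),
            CloneSpec(clone_id="sub", fraction=0.3, private_mutation_count=20,
                      driver_mutations=[("PIK3CA", "3:178936091:G:A")]),
        ],
        cnvs=[CnvSpec(chrom="9", start=21_948_801, end=22_163_300,
                      copy_state="homozygous_loss", clone_id="truncal")],
        samples=[
            SampleSpec(sample_id="donor_tf", role="donor_tumor",
                       individual="donor", purity=0.5),
            SampleSpec(sample_id="lr_blood", role="recipient_blood", individual="LR"),
            SampleSpec(sample_id="lr_om", role="recipient_metastasis",
                       individual="LR", purity=0.97, private_mutation_count=20),
        ],
    )
    base.update(overrides)
    return CohortConfig(**base)


def profile_fingerprint(profile):
    return [(str(ov.key), ov.depth, ov.alt_depth) for ov in profile]


class TestCatalog:
    def test_common_predicate_holds_for_every_entry(self):
        cfg = tiny_config(n_common=5000)
        catalog = simulate_catalog(cfg)
        for idx in catalog.common_indices:
            freqs = catalog.annots[idx].db_freqs
            assert sum(1 for f in freqs.values() if f >= 0.001) >= 2

    def test_rare_tier_below_threshold_everywhere(self):
        catalog = simulate_catalog(tiny_config())
        for idx in catalog.rare_indices:
            freqs = catalog.annots[idx].db_freqs
            assert all(f < 0.001 for f in freqs.values())

    def test_no_common_entries_when_configured(self):
        catalog = simulate_catalog(tiny_config(n_common=0))
        assert len(catalog.common_indices) == 0
        assert len(catalog.rare_indices) == 80     # 40 per individual x 2

    def test_deterministic_under_seed(self):
        c1 = simulate_catalog(tiny_config(seed=5))
        c2 = simulate_catalog(tiny_config(seed=5))
        assert c1.keys == c2.keys
        assert [a.db_freqs for a in c1.annots] == [a.db_freqs for a in c2.annots]


class TestGermline:
    def test_sex_model(self):
        cfg = tiny_config()
        rng = np.random.default_rng(0)
        catalog = simulate_catalog(cfg, rng)
        female = simulate_germline(catalog, "female", cfg, rng, "f")
        male = simulate_germline(catalog, "male", cfg, rng, "m")
        assert female.chry_count() == 0
        assert male.chry_count() == cfg.chry_variants_male == 20
        y_afs = [af for k, (_, af) in male.variants.items() if k.chrom == "Y"]
        assert all(af == 1.0 for af in y_afs)          # hemizygous

    def test_het_hom_allelic_fractions(self):
        cfg = tiny_config()
        rng = np.random.default_rng(1)
        catalog = simulate_catalog(cfg, rng)
        g = simulate_germline(catalog, "female", cfg, rng, "g")
        assert set(af for _, af in g.variants.values()) <= {0.5, 1.0}

    def test_sharing_rate_matches_catalog_frequencies(self):
        """Two germlines drawn from a 10,000-entry catalog share each entry
        with probability p^2, p = 1-(1-f)^2; the observed shared count must
        sit within 3 SE of sum(p^2)."""
        cfg = tiny_config(n_common=10_000, n_rare_per_individual=0,
                          chry_variants_male=0)
        rng = np.random.default_rng(42)
        catalog = simulate_catalog(cfg, rng)
        g1 = simulate_germline(catalog, "female", cfg, rng, "a")
        g2 = simulate_germline(catalog, "female", cfg, rng, "b")
        observed = len(set(g1.variants) & set(g2.variants))
        f = catalog.base_freq[catalog.common_indices]
        p = 1.0 - (1.0 - f) ** 2
        expected = float(np.sum(p**2))
        se = float(np.sqrt(np.sum(p**2 * (1 - p**2))))
        assert abs(observed - expected) <= 3 * se


class TestTumorTruth:
    def _setup(self, clones, cnvs):
        cfg = tiny_config()
        rng = np.random.default_rng(2)
        catalog = simulate_catalog(cfg, rng)
        germ = simulate_germline(catalog, "male", cfg, rng, "donor")
        return cfg, rng, germ, simulate_tumor_truth(germ, clones, cnvs, cfg, rng)

    def test_subclonal_af_below_truncal(self):
        clones = [CloneSpec(clone_id="t", fraction=1.0, private_mutation_count=50),
                  CloneSpec(clone_id="s", fraction=0.3, private_mutation_count=50)]
        _, _, _, truth = self._setup(clones, [])
        truncal = [sv.af_pure for sv in truth.somatic.values() if sv.clone_id == "t"]
        sub = [sv.af_pure for sv in truth.somatic.values() if sv.clone_id == "s"]
        assert truncal and sub
        assert max(sub) < min(truncal)
        assert all(af == 0.5 for af in truncal)
        assert all(af == pytest.approx(0.15) for af in sub)

    def test_homozygous_loss_removes_clone_somatic(self):
        clones = [CloneSpec(clone_id="t", fraction=1.0, private_mutation_count=400)]
        cnvs = [CnvSpec(chrom="1", start=1, end=120_000_000,
                        copy_state="homozygous_loss", clone_id="t")]
        _, _, _, truth = self._setup(clones, cnvs)
        for key in truth.somatic:
            assert not (key.chrom == "1" and key.pos <= 120_000_000)

    def test_driver_inside_own_loss_is_config_error(self):
        clones = [CloneSpec(clone_id="t", fraction=1.0,
                            driver_mutations=[("CDKN2A", "9:21970916:C:A")])]
        cnvs = [CnvSpec(chrom="9", start=21_948_801, end=22_163_300,
                        copy_state="homozygous_loss", clone_id="t")]
        with pytest.raises(ConfigError):
            self._setup(clones, cnvs)


class TestRendering:
    def test_purity_zero_emits_no_donor_variants(self):
        cfg = tiny_config()
        rng = np.random.default_rng(3)
        catalog = simulate_catalog(cfg, rng)
        donor = simulate_germline(catalog, "male", cfg, rng, "donor")
        host = simulate_germline(catalog, "female", cfg, rng, "LR")
        truth = simulate_tumor_truth(donor, cfg.clones, [], cfg, rng)
        profile, origins = render_observed_sample(
            truth, host, purity=0.0, mean_depth=200, rng=rng, sample_id="x"
        )
        assert set(profile.keys()) <= set(host.variants)
        # pure host variants are recipient_germline; polymorphisms carried by
        # both individuals keep a merged collision note
        assert all(
            v == "recipient_germline" or v.endswith("+host_germline")
            for v in origins.values()
        )

    def test_binomial_moments_at_half_purity(self):
        """1,000 truncal variants at purity 0.5, depth 200: the mean observed
        AF lies within 3 SE of 0.25."""
        cfg = tiny_config(n_common=0, n_rare_per_individual=0, chry_variants_male=0)
        rng = np.random.default_rng(4)
        catalog = simulate_catalog(cfg, rng)
        donor = simulate_germline(catalog, "male", cfg, rng, "donor")
        host = simulate_germline(catalog, "female", cfg, rng, "LR")
        clones = [CloneSpec(clone_id="t", fraction=1.0, private_mutation_count=1000)]
        truth = simulate_tumor_truth(donor, clones, [], cfg, rng)
        profile, _ = render_observed_sample(
            truth, host, purity=0.5, mean_depth=200, rng=rng, sample_id="x"
        )
        afs = np.array([ov.af for ov in profile])
        se = np.sqrt(0.25 * 0.75 / 200 / len(afs))
        assert abs(afs.mean() - 0.25) <= 3 * se

    def test_truncal_driver_af_tracks_purity(self):
        """Across renders at purity 0.78 the driver AF averages 0.39."""
        cfg = tiny_config(n_common=0, n_rare_per_individual=0, chry_variants_male=0)
        rng = np.random.default_rng(5)
        catalog = simulate_catalog(cfg, rng)
        donor = simulate_germline(catalog, "male", cfg, rng, "donor")
        host = simulate_germline(catalog, "female", cfg, rng, "LR")
        truth = simulate_tumor_truth(donor, cfg.clones, [], cfg, rng)
        key = VariantKey("7", 140453136, "A", "T")
        afs = []
        for _ in range(60):
            profile, _ = render_observed_sample(
                truth, host, purity=0.78, mean_depth=200, rng=rng, sample_id="x"
            )
            afs.append(profile.get(key).af)
        se = np.sqrt(0.39 * 0.61 / 200 / len(afs))
        assert np.mean(afs) == pytest.approx(0.39, abs=3 * se)

    def test_female_host_chry_is_entirely_donor_origin(self):
        cohort = simulate_cohort(tiny_config())
        profile = cohort.samples["lr_om"]
        origins = cohort.truth.sample_origins["lr_om"]
        y_keys = [k for k in profile.keys() if k.chrom == "Y"]
        assert y_keys
        for k in y_keys:
            assert origins[str(k)].startswith("donor_germline")
        assert cohort.samples["lr_blood"].chrom_count("Y") == 0

    def test_every_emitted_variant_has_one_origin_label(self):
        cohort = simulate_cohort(tiny_config())
        for sid, profile in cohort.samples.items():
            origins = cohort.truth.sample_origins[sid]
            assert {str(k) for k in profile.keys()} == set(origins)


class TestCohortDeterminismAndIO:
    def test_simulate_twice_identical(self):
        c1 = simulate_cohort(tiny_config(seed=9))
        c2 = simulate_cohort(tiny_config(seed=9))
        for sid in c1.samples:
            assert profile_fingerprint(c1.samples[sid]) == profile_fingerprint(c2.samples[sid])
        assert c1.truth.origins == c2.truth.origins

    def test_seed_changes_variants_not_structure(self):
        c1 = simulate_cohort(tiny_config(seed=1))
        c2 = simulate_cohort(tiny_config(seed=2))
        assert set(c1.samples) == set(c2.samples)
        assert profile_fingerprint(c1.samples["donor_tf"]) != profile_fingerprint(c2.samples["donor_tf"])

    def test_write_byte_identical_and_round_trip(self, tmp_path):
        cfg = tiny_config(seed=13)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        c1 = write_cohort(cfg, d1)
        write_cohort(cfg, d2)
        for path in sorted(d1.iterdir()):
            assert path.read_bytes() == (d2 / path.name).read_bytes()

        back = read_cohort(d1)
        for sid in c1.samples:
            assert profile_fingerprint(back.samples[sid]) == profile_fingerprint(c1.samples[sid])
        assert back.truth.sample_purity == c1.truth.sample_purity
        assert set(back.mlpa_samples) == set(c1.mlpa_samples)

    def test_default_config_shape(self):
        cfg = default_config()
        assert [s.role for s in cfg.samples].count("recipient_blood") == 1
        purities = sorted(s.purity for s in cfg.samples
                          if s.role in ("recipient_tumor", "recipient_metastasis"))
        assert purities == [0.78, 0.78, 0.97]
        assert cfg.cnvs[0].start == 21_948_801 and cfg.cnvs[0].end == 22_163_300


class TestConfigValidation:
    def test_truncal_clone_required(self):
        with pytest.raises(ValueError, match="truncal"):
            tiny_config(clones=[CloneSpec(clone_id="s", fraction=0.4)])

    def test_unknown_cnv_clone_rejected(self):
        with pytest.raises(ValueError, match="carrier clone"):
            tiny_config(cnvs=[CnvSpec(chrom="9", start=1, end=2,
                                      copy_state="gain", clone_id="ghost")])

    def test_class_probs_must_sum_to_one(self):
        probs = {c: 0.0 for c in
                 ("utr_or_unspecified_exonic", "indel", "nonsynonymous",
                  "nonsense", "synonymous", "splice_site", "non_exonic_or_ncRNA")}
        probs["indel"] = 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            tiny_config(class_probs=probs)
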