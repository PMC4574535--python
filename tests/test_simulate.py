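"""Titration simulator: VAF dilution, truth rules, sampling, virtual callers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somatic_ensemble.simulate import (
    HET,
    HOM_ALT,
    HOM_REF,
    OTHER,
    CallerProfile,
    GenotypeSite,
    MixtureConfig,
    build_truth,
    default_caller_profiles,
    cross_contaminated_pair_config,
    enforce_prior_rate,
    expected_vaf,
    generate_dataset,
    prior_mutation_rate,
    sample_evidence,
    simulate_caller_votes,
)
from somatic_ensemble.features import SampleEvidence


class TestExpectedVaf:
    @pytest.mark.parametrize(
        "pure,fraction,expected",
        [
            (0.50, 0.70, 0.35),   # het tumor variant in 30%-contaminated tumor
            (0.50, 0.30, 0.15),   # 70:30 normal:tumor virtual tumor
            (0.50, 0.05, 0.025),  # 5% tumor contamination in the normal
            (0.50, 1.00, 0.50),
            (0.33, 0.70, 0.231),
        ],
    )
    def test_dilution_is_product(self, pure, fraction, expected):
        assert expected_vaf(pure, fraction) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_bilinear_and_bounded(self, v, f):
        out = expected_vaf(v, f)
        assert 0.0 <= out <= 1.0
        assert out == pytest.approx(v * f)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_vaf(1.2, 0.5)


class TestBuildTruth:
    def _site(self, pos, gn, gt):
        return GenotypeSite("chr1", pos, "G", "A", gn, gt)

    def test_genotype_partition_rules(self):
        sites = [
            self._site(1, HOM_REF, HET),       # somatic
            self._site(2, HOM_REF, HOM_REF),   # reference
            self._site(3, HET, HET),           # ambiguous
            self._site(4, HET, HOM_REF),       # ambiguous
            self._site(5, HOM_ALT, HOM_ALT),   # ambiguous
            self._site(6, HOM_REF, HOM_ALT),   # ambiguous
            self._site(7, OTHER, HET),         # ambiguous
        ]
        truth = build_truth(sites)
        assert truth.somatic == {sites[0].key}
        assert truth.reference == {sites[1].key}
        assert truth.ambiguous == {s.key for s in sites[2:]}

    def test_partition_is_exhaustive_within_callable_mask(self, rng):
        genotypes = [HOM_REF, HET, HOM_ALT, OTHER]
        sites = [
            self._site(i, genotypes[rng.integers(4)], genotypes[rng.integers(4)])
            for i in range(1, 200)
        ]
        mask = {s.key for s in sites[::2]}
        truth = build_truth(sites, callable_mask=mask)
        assert len(truth) == len(mask)
        assert (truth.somatic | truth.reference | truth.ambiguous) <= mask

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError):
            GenotypeSite("chr1", 1, "G", "A", "weird", HET)


class TestPriorRate:
    def _truth(self, n_somatic=500):
        sites = [GenotypeSite("chr1", i, "G", "A", HOM_REF, HET)
                 for i in range(1, n_somatic + 1)]
        sites += [GenotypeSite("chr2", i, "G", "A", HOM_REF, HOM_REF)
                  for i in range(1, 101)]
        return build_truth(sites)

    def test_kept_subset_has_rounded_target_size(self):
        truth = self._truth()
        masked = enforce_prior_rate(truth, interrogated_sites=10_000_000,
                                    rate=1e-5, seed=1)
        assert len(masked.somatic) == 100
        assert masked.somatic <= truth.somatic
        # the remainder is excluded from scoring, not relabelled reference
        assert masked.ambiguous == truth.somatic - masked.somatic
        assert masked.reference == truth.reference

    def test_noop_when_target_equals_somatic_count(self):
        truth = self._truth()
        out = enforce_prior_rate(truth, interrogated_sites=500, rate=1.0, seed=0)
        assert out.somatic == truth.somatic

    def test_target_exceeding_somatic_warns_and_keeps_all(self):
        truth = self._truth(n_somatic=10)
        with pytest.warns(UserWarning, match="keeping all"):
            out = enforce_prior_rate(truth, interrogated_sites=1_000_000,
                                     rate=1e-3, seed=0)
        assert out.somatic == truth.somatic

    def test_sub_single_mutation_rate_rejected(self):
        with pytest.raises(ValueError):
            enforce_prior_rate(self._truth(), interrogated_sites=1000,
                               rate=1e-6)

    def test_deterministic_given_seed(self):
        truth = self._truth()
        a = enforce_prior_rate(truth, 1_000_000, 1e-4, seed=9)
        b = enforce_prior_rate(truth, 1_000_000, 1e-4, seed=9)
        assert a.somatic == b.somatic

    def test_prior_rate_arithmetic(self):
        assert prior_mutation_rate(810_679, 2_200_000_000) == pytest.approx(
            810_679 / 2.2e9
        )


class TestSampleEvidence:
    CFG = MixtureConfig(fixed_depth=True)

    def test_zero_vaf_zero_error_never_yields_alt_reads(self):
        cfg = MixtureConfig(base_error_rate=0.0, fixed_depth=True)
        rng = np.random.default_rng(0)
        for _ in range(50):
            ev = sample_evidence("reference", cfg, "tumor", rng,
                                 artifact_vaf=0.0)
            assert ev.alt_count == 0

    def test_mean_alt_fraction_matches_effective_vaf(self):
        # law of large numbers: mean alt count -> depth x effective VAF
        cfg = MixtureConfig(subclone_vafs=(0.2,), base_error_rate=0.0,
                            fixed_depth=True)
        rng = np.random.default_rng(1)
        n = 4000
        alts = np.array([
            sample_evidence("somatic", cfg, "tumor", rng,
                            subclone_vaf=0.2).alt_count
            for _ in range(n)
        ])
        target = 30 * 0.2  # pure tumor: effective VAF = subclone VAF
        stderr = np.sqrt(30 * 0.2 * 0.8 / n)
        assert alts.mean() == pytest.approx(target, abs=3 * stderr)

    def test_low_vaf_depth_grid_scales_alt_counts(self):
        # a VAF x depth grid at count level: mean alt tracks depth x VAF
        rng = np.random.default_rng(8)
        for depth in (10, 50):
            for vaf in (0.05, 0.4):
                cfg = MixtureConfig(subclone_vafs=(vaf,), depth_tumor=depth,
                                    base_error_rate=0.0, fixed_depth=True)
                alts = np.array([
                    sample_evidence("somatic", cfg, "tumor", rng,
                                    subclone_vaf=vaf).alt_count
                    for _ in range(1500)
                ])
                stderr = np.sqrt(depth * vaf * (1 - vaf) / 1500)
                assert alts.mean() == pytest.approx(depth * vaf,
                                                    abs=4 * stderr)

    def test_contaminated_normal_carries_diluted_signal(self):
        cfg = cross_contaminated_pair_config()
        rng = np.random.default_rng(2)
        alts = [
            sample_evidence("somatic", cfg, "normal", rng,
                            subclone_vaf=0.5).alt_count
            for _ in range(2000)
        ]
        # expected VAF 0.5 * 0.05 = 2.5% at 30x -> mean alt ~0.75
        assert np.mean(alts) == pytest.approx(0.75, abs=0.15)

    def test_counts_never_exceed_depth(self, rng):
        cfg = MixtureConfig()
        for _ in range(200):
            ev = sample_evidence("somatic", cfg, "tumor", rng,
                                 subclone_vaf=0.5)
            assert ev.ref_count + ev.alt_count <= ev.depth

    def test_artifact_sites_have_degraded_qualities_and_strand_bias(self):
        rng = np.random.default_rng(3)
        clean, artifact = [], []
        for _ in range(300):
            clean.append(sample_evidence("reference", self.CFG, "tumor", rng,
                                         artifact_vaf=0.0))
            artifact.append(sample_evidence("reference", self.CFG, "tumor",
                                            rng, artifact_vaf=0.15))
        mq_clean = np.mean([np.mean(e.mapq_values) for e in clean])
        mq_art = np.mean([np.mean(e.mapq_values) for e in artifact])
        assert mq_art < mq_clean - 10
        fwd = sum(e.alt_fwd for e in artifact)
        rev = sum(e.alt_rev for e in artifact)
        assert fwd > 2 * rev  # configured forward-strand bias

    def test_unknown_role_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_evidence("somatic", self.CFG, "plasma", rng)


class TestCallerVotes:
    def _evidence(self, alt=10, depth=30, normal_alt=0):
        tumor = SampleEvidence(depth=depth, ref_fwd=(depth - alt) // 2,
                               ref_rev=depth - alt - (depth - alt) // 2,
                               alt_fwd=alt // 2, alt_rev=alt - alt // 2)
        normal = SampleEvidence(depth=30, ref_fwd=15 - normal_alt, ref_rev=15,
                                alt_fwd=normal_alt)
        return tumor, normal

    def test_oracle_caller_reproduces_truth(self, rng):
        oracle = CallerProfile("oracle", sensitivity=1.0, min_alt_reads=0,
                               fp_rate_artifact=0.0, fp_rate_clean=0.0)
        tumor, normal = self._evidence()
        for truth_class, expected in [("somatic", 1), ("reference", 0)]:
            votes = simulate_caller_votes(tumor, normal, truth_class,
                                          [oracle], rng)
            assert votes[0].called == expected

    def test_false_positive_rate_within_binomial_envelope(self):
        rng = np.random.default_rng(4)
        fp = CallerProfile("fp", fp_rate_artifact=0.5, min_alt_reads=2)
        tumor, normal = self._evidence(alt=4)
        n = 1000
        called = sum(
            simulate_caller_votes(tumor, normal, "reference", [fp], rng,
                                  artifact=True)[0].called
            for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert called / n == pytest.approx(0.5, abs=4 * se)

    def test_contamination_intolerant_caller_drops_to_floor(self, rng):
        strict = CallerProfile("strict", sensitivity=0.99,
                               normal_alt_tolerance=1,
                               contaminated_floor=0.0)
        tumor, normal_dirty = self._evidence(alt=10, normal_alt=3)
        votes = [simulate_caller_votes(tumor, normal_dirty, "somatic",
                                       [strict], rng)[0].called
                 for _ in range(50)]
        assert sum(votes) == 0

    def test_score_kinds(self, rng):
        tumor, normal = self._evidence(alt=12)
        profiles = [
            CallerProfile("binary", sensitivity=1.0, score_kind="none"),
            CallerProfile("phred", sensitivity=1.0, score_kind="phred"),
            CallerProfile("fet", sensitivity=1.0, score_kind="fet_p"),
        ]
        votes = simulate_caller_votes(tumor, normal, "somatic", profiles, rng)
        assert votes[0].score is None
        assert votes[1].score >= 0
        assert 0 <= votes[2].score <= 1

    def test_empty_profiles_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_caller_votes(*self._evidence(), "somatic", [], rng)


class TestGenerateDataset:
    def test_feature_matrix_is_total_and_labelled(self):
        ds = generate_dataset(n_somatic=50, n_reference=200, seed=0)
        assert len(ds.features) == 250
        assert not ds.features.isna().any().any()
        assert ds.labels.sum() == 50
        assert (ds.features.index == ds.labels.index).all()
        assert len(ds.truth.somatic) == 50
        assert len(ds.truth.reference) == 200

    def test_all_somatic_free_dataset_contains_only_false_candidates(self):
        ds = generate_dataset(n_somatic=0, n_reference=100, seed=1)
        assert ds.labels.sum() == 0
        assert len(ds.truth.somatic) == 0

    def test_deterministic_given_seed(self):
        a = generate_dataset(n_somatic=30, n_reference=100, seed=7)
        b = generate_dataset(n_somatic=30, n_reference=100, seed=7)
        assert a.features.equals(b.features)

    def test_dbsnp_column_only_when_enabled(self):
        with_db = generate_dataset(n_somatic=20, n_reference=50, seed=2,
                                   include_dbsnp=True)
        without = generate_dataset(n_somatic=20, n_reference=50, seed=2)
        assert "dbsnp" in with_db.features.columns
        assert "dbsnp" not in without.features.columns

    def test_frozen_reference_sites_reused_across_configs(self):
        clean = generate_dataset(n_somatic=20, n_reference=80, seed=3)
        contaminated = generate_dataset(
            cross_contaminated_pair_config(), n_somatic=20, n_reference=80,
            seed=3, reference_specs=clean.reference_specs,
        )
        assert contaminated.truth.reference == clean.truth.reference

    def test_union_callset_round_trip(self):
        ds = generate_dataset(n_somatic=20, n_reference=80, seed=4)
        union = ds.union_callset()
        union_keys = {c.key for c in union.candidates}
        voted = {k for k, votes in ds.votes.items()
                 if any(v.called for v in votes)}
        assert union_keys == voted

    def test_file_emission(self, tmp_path):
        ds = generate_dataset(n_somatic=10, n_reference=30, seed=5)
        ds.write_truth_vcf(tmp_path / "truth.vcf")
        ds.write_caller_vcfs(tmp_path / "callers")
        ds.write_pileup_tsv(tmp_path / "pileup.tsv")
        ds.write_feature_tsv(tmp_path / "features.tsv")
        from somatic_ensemble.features import read_pileup_tsv
        from somatic_ensemble.variants import read_caller_vcf

        truth_calls = read_caller_vcf(tmp_path / "truth.vcf", "truth")
        assert {c.key for c, _ in truth_calls} == ds.truth.somatic
        pileup = read_pileup_tsv(tmp_path / "pileup.tsv")
        assert len(pileup) == 40
        assert len(list((tmp_path / "callers").glob("*.vcf"))) == 5

    def test_five_default_profiles_have_distinct_characters(self):
        profiles = default_caller_profiles()
        assert len({p.caller_id for p in profiles}) == 5
        assert any(p.normal_alt_tolerance is not None for p in profiles)
        assert any(p.min_vaf > 0 for p in profiles)
        assert len({p.score_kind for p in profiles}) == 3


class TestPipelineRecovery:
    def test_classifier_separates_well_separated_classes(self):
        from somatic_ensemble.boosting import StochasticAdaBoostClassifier

        ds = generate_dataset(n_somatic=150, n_reference=600, seed=6)
        model = StochasticAdaBoostClassifier(
            n_iterations=30, max_depth=2, subsample_fraction=1.0,
            random_state=0,
        ).fit(ds.features, ds.labels.to_numpy())
        P = model.somatic_probability(ds.features)
        labels = ds.labels.to_numpy()
        assert (P[labels == 1] > 0.5).mean() > 0.97
        assert (P[labels == 0] < 0.5).mean() > 0.97
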