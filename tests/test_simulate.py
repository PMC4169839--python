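"""Synthetic populations, trait simulation and the power experiment."""

import numpy as np
import pytest

from introscan.segments import build_design_matrix, build_segments, rank_status
from introscan.simulate import (
    GenomeSpec,
    TraitArchitecture,
    classify_detections,
    make_ideal_population,
    make_overlapping_population,
    run_power_experiment,
    simulate_trait,
)
from introscan.simulate import _genetic_values
from introscan.significance import PermutationConfig, SegmentTestResult


class TestIdealPopulation:
    def test_defaults_tile_genome_without_overlap(self, pop1):
        # 9 x 40 cM blocks, 100% marker coverage, zero pairwise overlap
        carriers = np.count_nonzero(pop1.dosage > 0, axis=0)
        assert np.all(carriers == 1)
        assert np.all(np.isin(pop1.dosage, (0, 2)))
        per_line = np.count_nonzero(pop1.dosage > 0, axis=1)
        assert np.all(per_line == 4)  # 40 cM at 10 cM spacing

    def test_pipeline_yields_identity_design(self, design1):
        assert np.array_equal(design1.Z, 2.0 * np.eye(9))

    def test_single_line_with_recipient_is_all_donor(self):
        spec = GenomeSpec(n_chromosomes=1, chromosome_length_cM=40.0)
        geno = make_ideal_population(
            spec, n_lines=1, segment_length_cM=40.0, include_recipient=True
        )
        assert np.all(geno.dosage[0] == 2)
        assert np.all(geno.dosage[1] == 0)

    def test_non_tiling_layout_rejected_unless_flagged(self):
        with pytest.raises(ValueError, match="tile"):
            make_ideal_population(n_lines=7)
        geno = make_ideal_population(n_lines=7, allow_partial=True)
        covered = geno.dosage.any(axis=0)
        assert covered.sum() == 7 * 4  # trailing markers stay recipient-only


class TestOverlappingPopulation:
    def test_default_seed_gives_rank_deficient_design(self, pop2, design2):
        assert rank_status(design2).status == "rank_deficient"

    @pytest.mark.parametrize("seed", range(40))
    def test_accepted_populations_meet_all_constraints(self, seed):
        # independent re-measurement of the generator's acceptance rules
        geno = make_overlapping_population(seed=seed)
        dosage = geno.dosage
        coverage = np.count_nonzero(dosage.any(axis=0)) / dosage.shape[1]
        assert coverage >= 0.95
        assert (np.count_nonzero(dosage > 0, axis=0) >= 2).any()
        assert build_segments(geno).n_segments > dosage.shape[0]

    def test_degenerate_full_length_segments(self):
        spec = GenomeSpec(n_chromosomes=1)
        geno = make_overlapping_population(
            spec,
            n_lines=2,
            seg_per_line_range=(1, 1),
            length_range_cM=(120.0, 120.0),
            seed=0,
            min_coverage=0.0,
            require_excess_segments=False,
            max_tries=50,
        )
        # both lines all-donor; collapse yields a single shared segment
        assert np.all(geno.dosage == 2)
        assert build_segments(geno).n_segments == 1

    def test_unattainable_constraints_report_failure(self):
        with pytest.raises(RuntimeError, match="last failed constraint"):
            make_overlapping_population(
                n_lines=2,
                seg_per_line_range=(1, 1),
                length_range_cM=(20.0, 20.0),
                min_coverage=0.999,
                max_tries=25,
            )


class TestSimulateTrait:
    def test_allele_effects_follow_donor_advantage_rule(self, pop1):
        for n_loci, a_expected in ((2, 25.0), (4, 12.5), (6, 100.0 / 12)):
            _, arch = simulate_trait(pop1, n_loci=n_loci, h2=0.5, seed=1)
            effects = [a for _, _, a in arch.loci]
            assert effects == pytest.approx([a_expected] * n_loci)
            # full donor minus full recipient genotype difference = 100
            assert sum(2 * a for a in effects) == pytest.approx(100.0)

    def test_high_heritability_limit_is_nearly_noise_free(self, pop1):
        y, arch = simulate_trait(pop1, n_loci=2, h2=0.9999, seed=2)
        g = _genetic_values(pop1, arch)
        assert np.var(y.values - g) / np.var(g) < 1e-2

    def test_variance_decomposition_at_half_heritability(self, pop1):
        arch = TraitArchitecture([("chr1", 60.0, 25.0)], heritability=0.5)
        g = _genetic_values(pop1, arch)
        vg = np.var(g)
        rng = np.random.default_rng(3)
        noise = []
        for _ in range(2000):
            y, _ = simulate_trait(pop1, architecture=arch, h2=0.5, rng=rng)
            noise.append(y.values - g)
        observed = np.var(np.concatenate(noise))
        assert observed == pytest.approx(vg, rel=0.05)

    def test_replicated_plots_keep_line_mean_heritability(self, pop1):
        arch = TraitArchitecture([("chr1", 60.0, 25.0)], heritability=0.5)
        g = _genetic_values(pop1, arch)
        rng = np.random.default_rng(4)
        means = []
        for _ in range(1500):
            y, _ = simulate_trait(
                pop1, architecture=arch, h2=0.5, rng=rng, n_reps=4
            )
            means.append(y.values.reshape(9, 4).mean(axis=1) - g)
        assert np.var(np.concatenate(means)) == pytest.approx(np.var(g), rel=0.05)

    def test_zero_effect_architecture_uses_unit_noise(self, pop1):
        null = TraitArchitecture([], heritability=0.5)
        rng = np.random.default_rng(5)
        draws = [
            simulate_trait(pop1, architecture=null, rng=rng)[0].values
            for _ in range(500)
        ]
        assert np.var(np.concatenate(draws)) == pytest.approx(1.0, rel=0.1)

    def test_heritability_out_of_range_rejected(self, pop1):
        with pytest.raises(ValueError, match="heritability"):
            simulate_trait(pop1, h2=1.0)

    def test_loci_snap_to_marker_grid(self, pop1):
        _, arch = simulate_trait(pop1, n_loci=6, h2=0.5, seed=6)
        grid = set(GenomeSpec().marker_positions())
        for _, pos, _ in arch.loci:
            assert pos in grid


def _result(sid, significant):
    return SegmentTestResult(
        segment_id=sid, effect=1.0, p_raw=0.5, p_adjusted=0.5,
        significant=significant,
    )


class TestClassifyDetections:
    def test_no_significant_segments(self, smap1):
        arch = TraitArchitecture([("chr1", 60.0, 25.0)], heritability=0.5)
        results = [_result(s, False) for s in smap1.segment_ids]
        assert classify_detections(results, smap1, arch) == (0, 0)

    def test_one_segment_covering_two_loci_counts_both(self, smap1):
        arch = TraitArchitecture(
            [("chr1", 50.0, 25.0), ("chr1", 70.0, 25.0)], heritability=0.5
        )
        results = [_result(s, s == "chr1:45-75") for s in smap1.segment_ids]
        assert classify_detections(results, smap1, arch) == (2, 0)

    def test_significant_segment_without_locus_is_false_positive(self, smap1):
        arch = TraitArchitecture([("chr1", 60.0, 25.0)], heritability=0.5)
        results = [
            _result(s, s in ("chr1:45-75", "chr3:5-35"))
            for s in smap1.segment_ids
        ]
        assert classify_detections(results, smap1, arch) == (1, 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_containment_oracle(self, smap2, seed):
        rng = np.random.default_rng(seed)
        arch_loci = []
        for _ in range(3):
            seg = smap2.segments[rng.integers(smap2.n_segments)]
            pos = float(rng.uniform(0, 120))
            arch_loci.append((seg.chromosome, pos, 10.0))
        arch = TraitArchitecture(arch_loci, heritability=0.5)
        flags = rng.random(smap2.n_segments) < 0.3
        results = [
            _result(s, bool(f)) for s, f in zip(smap2.segment_ids, flags)
        ]
        got = classify_detections(results, smap2, arch)
        # brute force: double loop over loci and significant segments
        sig = [s for s, f in zip(smap2.segments, flags) if f]
        correct = sum(
            any(
                s.chromosome == c and s.start_cM <= p <= s.end_cM for s in sig
            )
            for c, p, _ in arch_loci
        )
        false = sum(
            not any(
                s.chromosome == c and s.start_cM <= p <= s.end_cM
                for c, p, _ in arch_loci
            )
            for s in sig
        )
        assert got == (correct, false)


class TestPowerExperiment:
    def test_reproducible_for_identical_seeds(self):
        kwargs = dict(
            population="ideal", methods=("BLUP",), n_loci=2, h2=0.7,
            n_runs=5, perm_cfg=PermutationConfig(r=49, alpha=0.05, seed=0),
            seed=123,
        )
        a = run_power_experiment(**kwargs)["BLUP"]
        b = run_power_experiment(**kwargs)["BLUP"]
        assert a.per_run == b.per_run

    def test_lsq_rejected_on_overlapping_population(self):
        with pytest.raises(ValueError, match="rank deficient"):
            run_power_experiment(
                population="overlapping", methods=("LSQ",), n_runs=2
            )

    def test_null_trait_calibration_and_zero_power(self):
        null = TraitArchitecture([], heritability=0.5)
        res = run_power_experiment(
            population="ideal", methods=("LSQ",), h2=0.5, n_runs=300,
            seed=7, architecture=null, adjust="none",
        )["LSQ"]
        assert res.correct_rate == 0.0
        alpha = 0.01
        se = np.sqrt(alpha * (1 - alpha) / res.n_noncausal_total)
        assert abs(res.fp_rate - alpha) < 3 * se

    def test_high_heritability_power_exceeds_ninety_percent(self):
        res = run_power_experiment(
            population="ideal", methods=("LSQ", "RMLV"), n_loci=2, h2=0.99,
            n_runs=200, seed=3,
        )
        assert res["LSQ"].correct_rate > 0.9
        assert res["RMLV"].correct_rate > 0.9

    def test_power_increases_with_heritability(self):
        rates = [
            run_power_experiment(
                population="ideal", methods=("LSQ",), n_loci=2, h2=h2,
                n_runs=120, seed=8,
            )["LSQ"].correct_rate
            for h2 in (0.5, 0.7, 0.9)
        ]
        assert rates[0] < rates[1] < rates[2]
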