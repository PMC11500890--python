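"""The synthetic paired-cohort generator."""

import dataclasses

import numpy as np
import pytest

from dentmatch.dentition import (
    FDI_POSITIONS,
    Dentition,
    ToothState,
    TransitionGraph,
    default_transition_graph,
)
from dentmatch.io import cohort_frame
from dentmatch.simulate import (
    CohortConfig,
    NoiseParams,
    drift_free,
    forward_simulate,
    generate_cohort,
    inject_detection_noise,
    make_step_dataset,
    sample_am_dentition,
    sample_interval_days,
)

N, P, RC, M, PO, I = ToothState


def single_hazard_config(edge, h, **kwargs):
    priors = kwargs.pop("priors", {N: 1.0})
    return CohortConfig(
        baseline_priors=priors, transition_hazards={edge: h}, **kwargs
    )


class TestConfigValidation:
    def test_priors_must_sum_to_one(self):
        with pytest.raises(ValueError, match="priors"):
            CohortConfig(baseline_priors={N: 0.5, P: 0.4})

    def test_hazard_on_non_edge_rejected(self):
        cfg = single_hazard_config((I, N), 0.01)
        with pytest.raises(ValueError, match="non-edge"):
            generate_cohort(cfg)

    def test_hazard_probability_bounds(self):
        with pytest.raises(ValueError, match="hazard"):
            single_hazard_config((N, P), 1.5)

    def test_interval_bounds(self):
        with pytest.raises(ValueError):
            CohortConfig(interval_min=0)


class TestSampleAmDentition:
    def test_pure_natural_priors(self, rng):
        cfg = CohortConfig(baseline_priors={N: 1.0})
        assert sample_am_dentition(cfg, rng) == Dentition.uniform(N)

    def test_fixed_seed_reproduces_dentition(self):
        cfg = CohortConfig()
        d1 = sample_am_dentition(cfg, np.random.default_rng(9))
        d2 = sample_am_dentition(cfg, np.random.default_rng(9))
        assert d1 == d2

    def test_binomial_prior_recovery(self):
        cfg = CohortConfig(baseline_priors={N: 0.8, P: 0.2})
        rng = np.random.default_rng(0)
        n_dent = 313  # ~10,000 positions
        states = [
            s for _ in range(n_dent) for s in sample_am_dentition(cfg, rng).codes()
        ]
        frac = sum(s is P for s in states) / len(states)
        assert frac == pytest.approx(0.2, abs=0.01)


class TestIntervalSampling:
    def test_support_and_moment_matching(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(7)
        days = sample_interval_days(cfg, rng, size=20000)
        assert days.min() >= 1 and days.max() <= 7732
        # the sampling law is solved to reproduce the configured moments
        assert days.mean() == pytest.approx(2197.5, abs=50)
        assert days.std() == pytest.approx(1934.7, abs=60)

    def test_low_dispersion_config_uses_bell_shaped_law(self):
        cfg = CohortConfig(
            interval_mean=75.0, interval_sd=10.0, interval_min=50, interval_max=99
        )
        rng = np.random.default_rng(8)
        days = sample_interval_days(cfg, rng, size=20000)
        assert days.min() >= 50 and days.max() <= 99
        assert days.mean() == pytest.approx(75.0, abs=1.0)
        assert days.std() == pytest.approx(10.0, abs=1.0)


class TestForwardSimulate:
    def test_zero_hazards_freeze_the_dentition(self, rng):
        cfg = drift_free(CohortConfig())
        am = sample_am_dentition(cfg, rng)
        assert forward_simulate(am, 5000, cfg, rng) == am

    def test_short_interval_applies_exactly_one_step(self, rng):
        # N -> M is certain per step, M -> I certain next: step count is visible
        cfg = CohortConfig(
            baseline_priors={N: 1.0},
            transition_hazards={(N, M): 1.0, (M, I): 1.0},
        )
        am = Dentition.uniform(N)
        assert forward_simulate(am, 50, cfg, rng) == Dentition.uniform(M)
        assert forward_simulate(am, 150, cfg, rng) == Dentition.uniform(I)

    def test_geometric_survival_closed_form(self):
        # single hazard 0.01/100d over 7,700 days: P(loss) = 1 - 0.99^77
        cfg = single_hazard_config((N, M), 0.01)
        rng = np.random.default_rng(77)
        n_dent = 313
        hits = total = 0
        am = Dentition.uniform(N)
        for _ in range(n_dent):
            pm = forward_simulate(am, 7700, cfg, rng)
            hits += sum(s is M for s in pm.codes())
            total += 32
        expected = 1.0 - 0.99**77
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(hits / total - expected) < 3 * se

    def test_output_always_reachable_from_input(self, graph, rng):
        cfg = CohortConfig(seed=5)
        for _ in range(10):
            am = sample_am_dentition(cfg, rng)
            pm = forward_simulate(am, int(rng.integers(1, 7732)), cfg, rng)
            for pos in FDI_POSITIONS:
                assert graph.is_reachable(am[pos], pm[pos])

    def test_respects_injected_graph(self, rng):
        sparse = TransitionGraph([(N, M)])
        cfg = single_hazard_config((N, P), 0.5)
        with pytest.raises(ValueError, match="non-edge"):
            forward_simulate(Dentition.uniform(N), 100, cfg, rng, graph=sparse)


class TestDetectionNoise:
    def test_perfect_recall_is_identity(self, rng):
        noise = NoiseParams(recall={s: 1.0 for s in ToothState})
        d = Dentition.uniform(P)
        assert inject_detection_noise(d, noise, rng) == d

    def test_zero_recall_corrupts_every_prosthesis(self, rng):
        noise = NoiseParams(recall={**dict(NoiseParams().recall), P: 0.0})
        d = Dentition.uniform(P)
        noisy = inject_detection_noise(d, noise, rng)
        assert all(s is N for s in noisy.codes())

    def test_corruption_rate_matches_recall(self):
        noise = NoiseParams()  # prosthesis recall 0.843
        rng = np.random.default_rng(55)
        d = Dentition.uniform(P)
        corrupted = total = 0
        for _ in range(313):  # ~10,000 prosthesis positions
            noisy = inject_detection_noise(d, noise, rng)
            corrupted += sum(s is not P for s in noisy.codes())
            total += 32
        expected = 1.0 - 0.843
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(corrupted / total - expected) < 3 * se

    def test_states_without_confusions_never_corrupted(self, rng):
        noise = NoiseParams(recall={s: 0.0 for s in ToothState})
        d = Dentition.uniform(M)
        assert inject_detection_noise(d, noise, rng) == d


class TestGenerateCohort:
    def test_paired_bookkeeping(self):
        records, manifest = generate_cohort(CohortConfig(n_individuals=50, seed=1))
        assert len(records) == 100
        ids = {r.individual_id for r in records}
        assert len(ids) == 50
        roles = {(r.individual_id, r.role) for r in records}
        assert len(roles) == 100
        assert len(manifest["pairs"]) == 50

    def test_pm_date_follows_am_date_by_the_true_interval(self):
        records, manifest = generate_cohort(CohortConfig(n_individuals=30, seed=2))
        by_id = {}
        for r in records:
            by_id.setdefault(r.individual_id, {})[r.role] = r
        for pair in manifest["pairs"]:
            am = by_id[pair["individual_id"]]["AM"]
            pm = by_id[pair["individual_id"]]["PM"]
            assert (pm.imaging_date - am.imaging_date).days == pair["interval_days"]
            assert 1 <= pair["interval_days"] <= 7732

    def test_sex_ratio(self):
        records, _ = generate_cohort(CohortConfig(n_individuals=1029, seed=3))
        n_female = sum(r.sex == "F" for r in records) / 2
        se = np.sqrt(1029 * 0.548 * 0.452)
        assert abs(n_female - 564) < 3 * se

    def test_same_seed_gives_byte_identical_csv(self):
        cfg = CohortConfig(n_individuals=40, seed=4, noise=NoiseParams())
        csv1 = cohort_frame(generate_cohort(cfg)[0]).to_csv(index=False)
        csv2 = cohort_frame(generate_cohort(cfg)[0]).to_csv(index=False)
        assert csv1 == csv2

    def test_different_seeds_differ(self):
        r1, _ = generate_cohort(CohortConfig(n_individuals=40, seed=4))
        r2, _ = generate_cohort(CohortConfig(n_individuals=40, seed=5))
        assert cohort_frame(r1).to_csv() != cohort_frame(r2).to_csv()

    def test_true_pairs_never_discrepant_without_noise(self, graph, params):
        from dentmatch.similarity import similarity_score

        records, _ = generate_cohort(CohortConfig(n_individuals=30, seed=6))
        by_id = {}
        for r in records:
            by_id.setdefault(r.individual_id, {})[r.role] = r
        for roles in by_id.values():
            am, pm = roles["AM"].dentition, roles["PM"].dentition
            assert all(
                graph.is_reachable(am[pos], pm[pos]) for pos in FDI_POSITIONS
            )
            s = similarity_score(graph, params, pm, am)
            # every per-position score comes from the reachable branch
            changed = [
                s.per_position_scores[pos]
                for pos in FDI_POSITIONS
                if am[pos] != pm[pos]
            ]
            assert all(
                pts == min(
                    params.unit_step_score * graph.distance(am[pos], pm[pos]),
                    params.max_position_score,
                )
                for pos, pts in s.per_position_scores.items()
                if am[pos] != pm[pos]
            ), changed

    def test_transition_frequency_recovers_configured_hazard(self):
        # one step (interval <= 100 d), single edge: frequency ~ hazard
        cfg = single_hazard_config(
            (N, P), 0.02, n_individuals=160, interval_mean=75.0,
            interval_sd=10.0, interval_min=50, interval_max=99,
            female_hazard_multiplier=1.0, seed=8,
        )
        records, manifest = generate_cohort(cfg)
        n_positions = 160 * 32
        freq = manifest["true_transition_counts"].get("NATURAL->PROSTHESIS", 0) / n_positions
        se = np.sqrt(0.02 * 0.98 / n_positions)
        assert abs(freq - 0.02) < 3 * se


class TestStepDataset:
    def test_means_and_support(self, rng):
        ds = make_step_dataset(5000, 3000, 0.05, 0.0, rng)
        assert ds.interval_days.min() >= 2850
        assert ds.interval_days.max() < 3450
        low = ds.similarity[ds.interval_days < 3000]
        high = ds.similarity[ds.interval_days >= 3000]
        assert low.mean() == pytest.approx(0.95)
        assert high.mean() == pytest.approx(0.90)

    def test_step_must_align_with_unit(self, rng):
        with pytest.raises(ValueError, match="multiple"):
            make_step_dataset(100, 3050, 0.05, 0.05, rng)
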