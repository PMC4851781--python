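"""Search strategies: oracle equivalence, pruning soundness, budgets."""

import random

import pytest

from anonlattice import (
    Evaluator,
    PrivacyConfig,
    SearchConfig,
    lattice_spec_for,
    report_stats,
    search_bfs,
    search_exhaustive,
    search_optimal,
    strict_precedes,
)
from anonlattice.lattice import enumerate_rank_order
from anonlattice.synthetic import SyntheticSpec, figure2_fixture, generate_dataset

from conftest import random_instance


def _cfg(privacy, **kw):
    return SearchConfig(privacy=privacy, **kw)


def test_exhaustive_checks_whole_lattice():
    dataset, hierarchies, _ = figure2_fixture()
    privacy = PrivacyConfig(k=2, suppression_limit=0.25)
    res = search_exhaustive(dataset, hierarchies, _cfg(privacy, algorithm="exhaustive"))
    assert res.stats.checked == 6
    assert res.optimal_guarantee
    assert report_stats(res)["checked_pct"] == 100.0


def test_k1_yields_bottom_with_full_quality():
    dataset, hierarchies, _ = figure2_fixture()
    privacy = PrivacyConfig(k=1, suppression_limit=0.0)
    for fn, alg in [
        (search_exhaustive, "exhaustive"),
        (search_optimal, "optimal"),
        (search_bfs, "bfs"),
    ]:
        res = fn(dataset, hierarchies, _cfg(privacy, algorithm=alg))
        policy, ev = res.solution
        assert policy == (0, 0)
        assert ev.quality == 1.0 and ev.suppressed_count == 0


def test_unsolvable_when_k_exceeds_n():
    dataset, hierarchies, _ = figure2_fixture()
    privacy = PrivacyConfig(k=dataset.n + 1, suppression_limit=0.0)
    for fn, alg in [
        (search_exhaustive, "exhaustive"),
        (search_optimal, "optimal"),
        (search_bfs, "bfs"),
    ]:
        res = fn(dataset, hierarchies, _cfg(privacy, algorithm=alg))
        assert res.solution is None


def test_exhaustive_refuses_oversized_lattices():
    spec = SyntheticSpec(n=5, domain_sizes=(8,) * 3, seed=1)
    dataset, hierarchies = generate_dataset(spec)
    cfg = _cfg(PrivacyConfig(), algorithm="exhaustive", oracle_cap=10)
    with pytest.raises(ValueError, match="bfs"):
        search_exhaustive(dataset, hierarchies, cfg)


def test_all_strategies_agree_on_random_instances():
    """On >= 50 random solvable-or-not instances the optimal sweep and the
    run-to-completion best-first search return the exhaustive oracle's
    solution quality (or agree no solution exists)."""
    rng = random.Random(2024)
    solvable = 0
    for trial in range(50):
        dataset, hierarchies, privacy = random_instance(rng)
        ex = search_exhaustive(dataset, hierarchies, _cfg(privacy, algorithm="exhaustive"))
        op = search_optimal(dataset, hierarchies, _cfg(privacy, algorithm="optimal"))
        bf = search_bfs(dataset, hierarchies, _cfg(privacy, algorithm="bfs"))
        assert bf.optimal_guarantee and op.optimal_guarantee
        if ex.solution is None:
            assert op.solution is None and bf.solution is None, trial
        else:
            solvable += 1
            assert op.solution is not None and bf.solution is not None, trial
            assert abs(op.quality - ex.quality) < 1e-12, trial
            assert abs(bf.quality - ex.quality) < 1e-12, trial
    assert solvable >= 10  # the instance mix must exercise real searches


def test_prediction_skips_are_sound():
    """No policy skipped through the protection store is anonymous; no
    policy skipped through the quality store beats the returned optimum."""
    rng = random.Random(77)
    for _ in range(10):
        dataset, hierarchies, privacy = random_instance(rng, max_m=3, max_domain=4, max_n=40)
        spec = lattice_spec_for(hierarchies)
        op = search_optimal(dataset, hierarchies, _cfg(privacy, algorithm="optimal"))
        evaluator = Evaluator(dataset, hierarchies, privacy)
        best = op.quality if op.solution is not None else float("-inf")
        checked = op.stats.checked
        assert checked <= spec.size
        for x in enumerate_rank_order(spec):
            res = evaluator.evaluate(x)
            if res.anonymous:
                assert res.quality <= best + 1e-12


def test_prediction_reduces_checked_counts():
    rng = random.Random(5150)
    for _ in range(8):
        dataset, hierarchies, privacy = random_instance(rng, max_m=3)
        for fn, alg in [(search_optimal, "optimal"), (search_bfs, "bfs")]:
            with_pred = fn(dataset, hierarchies, _cfg(privacy, algorithm=alg))
            without = fn(dataset, hierarchies,
                         _cfg(privacy, algorithm=alg, use_prediction=False))
            assert with_pred.stats.checked <= without.stats.checked
            if with_pred.solution is None:
                assert without.solution is None
            else:
                assert abs(with_pred.quality - without.quality) < 1e-12
            assert without.stats.checked == lattice_spec_for(hierarchies).size


def test_anonymous_bottom_prunes_almost_everything():
    """When the untransformed data already satisfies the privacy model the
    incumbent quality of 1 bound-prunes every proper generalization."""
    spec = SyntheticSpec(n=40, domain_sizes=(4, 4, 4), seed=9, outlier_fraction=0.0)
    dataset, hierarchies = generate_dataset(spec)
    privacy = PrivacyConfig(k=1, suppression_limit=0.0)
    lattice = lattice_spec_for(hierarchies)
    op = search_optimal(dataset, hierarchies, _cfg(privacy, algorithm="optimal"))
    bf = search_bfs(dataset, hierarchies, _cfg(privacy, algorithm="bfs"))
    assert op.quality == 1.0 and bf.quality == 1.0
    assert op.stats.checked < lattice.size
    assert bf.stats.checked < lattice.size


def test_bfs_budget_of_one_returns_bottom_iff_anonymous():
    dataset, hierarchies, _ = figure2_fixture()
    solvable = PrivacyConfig(k=1, suppression_limit=0.0)
    res = search_bfs(dataset, hierarchies,
                     _cfg(solvable, algorithm="bfs", evaluation_budget=1))
    assert res.stats.checked == 1
    assert res.solution is not None and res.solution[0] == (0, 0)
    assert not res.optimal_guarantee

    strict = PrivacyConfig(k=2, suppression_limit=0.0)
    res = search_bfs(dataset, hierarchies,
                     _cfg(strict, algorithm="bfs", evaluation_budget=1))
    assert res.stats.checked == 1
    assert res.solution is None


def test_bfs_budget_respected_and_trajectory_monotone():
    rng = random.Random(31)
    for _ in range(10):
        dataset, hierarchies, privacy = random_instance(rng)
        budget = rng.randint(1, 30)
        res = search_bfs(dataset, hierarchies,
                         _cfg(privacy, algorithm="bfs", evaluation_budget=budget))
        assert res.stats.checked <= budget
        qualities = [q for _, q in res.stats.trajectory]
        assert qualities == sorted(qualities)
        evals = [e for e, _ in res.stats.trajectory]
        assert evals == sorted(evals)


def test_stats_report_shape():
    dataset, hierarchies, _ = figure2_fixture()
    privacy = PrivacyConfig(k=2, suppression_limit=0.25)
    res = search_optimal(dataset, hierarchies, _cfg(privacy, algorithm="optimal"))
    report = report_stats(res)
    assert set(report["properties"]) == {"insufficient_quality", "insufficient_protection"}
    for stats in report["properties"].values():
        assert stats["max_antichain"] <= max(stats["inserts"], 1)
        assert 0.0 <= stats["hit_rate_pct"] <= 100.0
    assert report["solution"]["policy"] == [1, 0]

    off = search_optimal(dataset, hierarchies,
                         _cfg(privacy, algorithm="optimal", use_prediction=False))
    off_report = report_stats(off)
    for stats in off_report["properties"].values():
        assert stats["hits"] == 0  # prediction disabled


def test_budgets_only_valid_for_bfs():
    with pytest.raises(ValueError):
        SearchConfig(algorithm="optimal", evaluation_budget=5)
    with pytest.raises(ValueError):
        SearchConfig(algorithm="unknown")
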