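"""Start-threshold estimation and the iterative rater loop."""

from __future__ import annotations

import numpy as np
import pytest

from autofoci import thresholding as th
from autofoci.core import OEPRecord
from autofoci.synthetic import generate_oep_mixture


def _records(oeps):
    recs = [OEPRecord("c", i, 1.0, 1.0, 1.0, float(v)) for i, v in enumerate(oeps)]
    from autofoci.oep import attach_log_scores

    attach_log_scores(recs)
    return recs


def test_count_foci_bruteforce_and_monotone():
    rng = np.random.default_rng(0)
    recs = _records(10.0 ** rng.normal(0, 2, size=200))
    for t in (-2.0, -0.5, 0.0, 1.0, 3.0):
        expected = sum(1 for r in recs if r.log_oep >= t) / 40
        assert th.count_foci(recs, t, 40) == pytest.approx(expected)
    thresholds = np.linspace(-5, 5, 41)
    counts = [th.count_foci(recs, t, 40) for t in thresholds]
    assert all(a >= b for a, b in zip(counts, counts[1:]))  # non-increasing
    with pytest.raises(ValueError):
        th.count_foci(recs, 0.0, 0)


def test_oep_histogram_modes():
    vals, _ = generate_oep_mixture(500, 200, seed=1)
    counts, edges = th.oep_histogram(vals, mode="log", bins=60)
    assert counts.sum() == 700
    inv_counts, _ = th.oep_histogram(vals, mode="inverse_log")
    assert inv_counts.sum() == np.sum(vals > 1.0)
    with pytest.raises(ValueError):
        th.oep_histogram(vals, mode="bogus")
    with pytest.raises(th.NoThresholdError):
        th.oep_histogram([0.0, -1.0])


def test_start_threshold_sits_between_the_modes():
    for seed in range(10):
        vals, labels = generate_oep_mixture(2000, 400, seed=seed)
        t = th.estimate_start_threshold(vals)
        assert -1.0 < t < 2.0  # strictly between the component log-means


def test_start_threshold_misclassification_under_5pct():
    """With modes 3 log-sds apart the estimated threshold misclassifies
    fewer than 5% of the pooled sample."""
    for seed in range(5):
        vals, labels = generate_oep_mixture(
            2000, 400, bg_logmean=-1.0, foci_logmean=2.0, seed=seed
        )
        t = th.estimate_start_threshold(vals)
        logs = np.log10(vals)
        wrong = np.sum((logs >= t) & (labels == 0)) + np.sum((logs < t) & (labels == 1))
        assert wrong / len(vals) < 0.05


def test_start_threshold_failure_modes():
    with pytest.raises(th.NoThresholdError):
        th.estimate_start_threshold([])
    with pytest.raises(th.NoThresholdError):
        # unimodal sample: no transition exists
        rng = np.random.default_rng(0)
        th.estimate_start_threshold(10.0 ** rng.normal(0, 0.3, size=500))


def test_start_threshold_reports_estimator_parts():
    vals, _ = generate_oep_mixture(2000, 400, seed=2)
    t, parts = th.estimate_start_threshold(vals, return_parts=True)
    assert parts  # at least one estimator survived
    assert set(parts) <= {"kde_valley", "gmm", "otsu"}
    assert t == pytest.approx(np.mean(list(parts.values())))


def test_boundary_oracle_drives_threshold_to_its_boundary():
    vals, _ = generate_oep_mixture(1500, 300, seed=4)
    recs = _records(vals)
    start = th.estimate_start_threshold(vals)
    target = 0.9  # within the sparse transition region
    sess = th.ThresholdSession(records=recs, n_cells=100, threshold=start)
    sess = th.adjust_threshold(sess, th.BoundaryOracle(target))
    assert sess.converged
    expected = sum(1 for r in recs if r.log_oep >= target) / 100
    assert sess.final_foci_per_cell == pytest.approx(expected, rel=0.10)


def test_convergence_invariant_sd_of_last_six():
    for seed in (0, 5, 9):
        vals, _ = generate_oep_mixture(1200, 250, seed=seed)
        recs = _records(vals)
        sess = th.ThresholdSession(
            records=recs, n_cells=80, threshold=th.estimate_start_threshold(vals)
        )
        sess = th.adjust_threshold(sess, th.BoundaryOracle(0.5))
        assert sess.iterations >= 6
        last = np.asarray(sess.foci_per_cell_history[-6:])
        if sess.converged:
            assert last.std() < 0.05 * last.mean()
        assert sess.final_foci_per_cell == pytest.approx(last.mean())


def test_all_focus_oracle_pushes_threshold_down():
    vals, _ = generate_oep_mixture(800, 200, seed=6)
    recs = _records(vals)
    start = th.estimate_start_threshold(vals)

    def always_focus(shown):
        return [True] * len(shown)

    sess = th.ThresholdSession(records=recs, n_cells=50, threshold=start)
    sess = th.adjust_threshold(sess, always_focus, max_iter=20)
    hist = sess.threshold_history
    assert all(a > b for a, b in zip(hist, hist[1:]))  # strictly decreasing
    assert sess.threshold < start


def test_label_oracle_answers_from_table():
    recs = _records([10.0, 0.1])
    oracle = th.LabelOracle({("c", 0): True, ("c", 1): False})
    assert oracle(recs) == [True, False]


def test_adjust_threshold_requires_scored_objects():
    recs = [OEPRecord("c", 0, 1.0, 1.0, 1.0, 1.0)]  # log_oep never attached
    sess = th.ThresholdSession(records=recs, n_cells=1, threshold=0.0)
    with pytest.raises(th.NoThresholdError):
        th.adjust_threshold(sess, lambda shown: [True] * len(shown))
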