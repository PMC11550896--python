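"""Uniformity testing, nearest-neighbour machinery, Clark-Evans index.

Hand oracles: the A^2 value for {0.25, 0.5, 0.75} evaluated term by term
with the raw formula, and the Clark-Evans R for four corners of a square.
Monte-Carlo oracles calibrate the null behaviour of both tests.
"""

import math

import numpy as np
import pytest

from thermospot.spatial_stats import (
    InsufficientSampleError,
    PointPattern,
    ad_statistic,
    ad_uniform,
    clark_evans,
    nn_distances,
    segment_counts,
    segment_totals,
)
from thermospot.spot_model import SpotRecord, SpotTable, StudyRegion

UNIT = StudyRegion(length_px=1.0, width_px=1.0, px_to_mm=1.0, n_segments=1)


def brute_force_a2(xs, lower, upper):
    """Direct term-by-term evaluation of the A^2 formula."""
    u = sorted((x - lower) / (upper - lower) for x in xs)
    n = len(u)
    total = 0.0
    for i in range(1, n + 1):
        total += (2 * i - 1) * (math.log(u[i - 1]) + math.log(1 - u[n - i]))
    return -n - total / n


def test_a2_matches_hand_evaluation():
    expected = brute_force_a2([0.25, 0.5, 0.75], 0.0, 1.0)
    assert expected == pytest.approx(0.26943084337, abs=1e-9)
    assert ad_statistic([0.25, 0.5, 0.75], 0.0, 1.0) == pytest.approx(
        expected, abs=1e-9
    )


def test_a2_affine_invariance():
    a_unit = ad_statistic([0.25, 0.5, 0.75], 0.0, 1.0)
    a_px = ad_statistic([300.0, 600.0, 900.0], 0.0, 1200.0)
    assert a_px == pytest.approx(a_unit, abs=1e-12)


def test_a2_agrees_with_brute_force_on_random_samples():
    rng = np.random.default_rng(5)
    for n in (3, 10, 57):
        xs = rng.uniform(2.0, 9.0, size=n)
        assert ad_statistic(xs, 2.0, 9.0) == pytest.approx(
            brute_force_a2(xs, 2.0, 9.0), rel=1e-12
        )


def test_ad_uniform_rejects_power_law_sample():
    """~x^4 density on [0, 1200] is grossly nonuniform: p < 0.01."""
    rng = np.random.default_rng(11)
    xs = 1200.0 * rng.random(200) ** (1.0 / 5.0)
    res = ad_uniform(xs, 0.0, 1200.0, rng=12)
    assert res.p_value < 0.01


def test_ad_uniform_requires_three_points():
    with pytest.raises(InsufficientSampleError):
        ad_uniform([0.2, 0.4], 0.0, 1.0)


def test_ad_uniform_clamps_boundary_values_with_warning():
    with pytest.warns(UserWarning, match="clamped"):
        res = ad_uniform([0.0, 0.5, 1.0], 0.0, 1.0, rng=0)
    assert np.isfinite(res.a2)


def test_ad_null_p_values_uniform():
    """Monte-Carlo p-values are uniform under the null (KS < 0.05)."""
    from scipy.stats import kstest

    from thermospot.spatial_stats import _a2_rows

    rng = np.random.default_rng(2024)
    n, reps, b = 25, 2000, 10_000
    observed = _a2_rows(np.sort(rng.random((reps, n)), axis=1))
    null = np.sort(_a2_rows(np.sort(rng.random((b, n)), axis=1)))
    # p_i against a shared null reference sample
    p = (1.0 + (b - np.searchsorted(null, observed, side="left"))) / (b + 1.0)
    assert kstest(p, "uniform").statistic < 0.05


def test_ad_asymptotic_agrees_with_monte_carlo():
    rng = np.random.default_rng(3)
    for n in (20, 100):
        xs = rng.random(n)
        p_mc = ad_uniform(xs, 0.0, 1.0, rng=4, n_mc=20_000).p_value
        p_as = ad_uniform(xs, 0.0, 1.0, p_method="asymptotic").p_value
        assert p_as == pytest.approx(p_mc, abs=0.02)


# --- nearest neighbours -----------------------------------------------------

def test_nn_single_pair():
    d = nn_distances(PointPattern([(0, 0), (3, 4)], StudyRegion(10, 10)))
    assert list(d) == [5.0, 5.0]


def test_nn_square_corners():
    reg = StudyRegion(10, 10)
    d = nn_distances(PointPattern([(0, 0), (10, 0), (0, 10), (10, 10)], reg))
    assert list(d) == [10.0] * 4


def test_nn_duplicates_give_zero():
    d = nn_distances(PointPattern([(1, 1), (1, 1), (5, 5)], StudyRegion(10, 10)))
    assert sorted(d)[:2] == [0.0, 0.0]


def test_nn_requires_two_points():
    with pytest.raises(InsufficientSampleError):
        nn_distances(PointPattern([(1, 1)], StudyRegion(10, 10)))


def test_nn_agrees_with_all_pairs_brute_force():
    rng = np.random.default_rng(8)
    for n in (5, 50, 200):
        pts = rng.random((n, 2))
        pat = PointPattern(pts, UNIT)
        diffs = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt((diffs**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        assert np.allclose(nn_distances(pat), dist.min(axis=1))


# --- Clark-Evans ------------------------------------------------------------

def test_clark_evans_corner_oracle():
    """4 corners of a 10x10: r_obs=10, lambda=0.04, r_exp=2.5, R=4."""
    reg = StudyRegion(10, 10)
    res = clark_evans(
        PointPattern([(0, 0), (10, 0), (0, 10), (10, 10)], reg), "none"
    )
    assert res.R == pytest.approx(4.0)
    assert res.r_exp == pytest.approx(2.5)


def test_clark_evans_coincident_points():
    res = clark_evans(PointPattern([(2, 2)] * 5, StudyRegion(10, 10)), "donnelly")
    assert res.R == 0.0


def test_clark_evans_requires_two_points():
    with pytest.raises(InsufficientSampleError):
        clark_evans(PointPattern([(1, 1)], StudyRegion(10, 10)))


def test_clark_evans_csr_expectation_approaches_one():
    """Uncorrected R on CSR drifts toward 1 from below as n grows."""
    rng = np.random.default_rng(17)
    means = {}
    for n in (25, 400):
        means[n] = np.mean(
            [
                clark_evans(PointPattern(rng.random((n, 2)), UNIT), "none").R
                for _ in range(300)
            ]
        )
    # edge effects inflate the uncorrected R above 1; the bias shrinks with n
    assert means[25] > means[400] > 1.0
    assert means[400] == pytest.approx(1.0, abs=0.03)


def test_clark_evans_hexagonal_lattice_regular():
    """A large hexagonal lattice approaches the regular maximum ~2.1491."""
    s = 0.05
    pts = []
    for row in range(int(1.0 / (s * math.sqrt(3) / 2))):
        y = row * s * math.sqrt(3) / 2
        offset = 0.0 if row % 2 == 0 else s / 2
        x = offset
        while x <= 1.0:
            pts.append((x, y))
            x += s
    res = clark_evans(PointPattern(pts, UNIT), "none")
    assert res.R > 2.0
    assert res.R < 2.1491 * 1.05


def test_clark_evans_thomas_cluster_detected():
    """A tight Thomas pattern gives R < 1 with p < 0.01."""
    rng = np.random.default_rng(23)
    region = StudyRegion(1200, 300)
    parents = np.column_stack(
        [rng.uniform(0, 1200, 12), rng.uniform(0, 300, 12)]
    )
    pts = []
    for p in parents:
        off = p + rng.normal(scale=2.0, size=(8, 2))
        off = off[(off[:, 0] >= 0) & (off[:, 0] <= 1200)
                  & (off[:, 1] >= 0) & (off[:, 1] <= 300)]
        pts.append(off)
    pat = PointPattern(np.vstack(pts), region)
    res = clark_evans(pat, "donnelly")
    assert res.R < 1.0 and res.p_value < 0.01


def test_donnelly_calibrated_uncorrected_anticonservative():
    """Edge-corrected z test holds its size under CSR; uncorrected does not."""
    rng = np.random.default_rng(31)
    reps, n = 600, 100
    rej = {"donnelly": 0, "none": 0}
    for _ in range(reps):
        pat = PointPattern(rng.random((n, 2)), UNIT)
        for corr in rej:
            if clark_evans(pat, corr).p_value < 0.05:
                rej[corr] += 1
    assert abs(rej["donnelly"] / reps - 0.05) < 0.02
    assert rej["none"] / reps > 0.10


# --- segment counts ---------------------------------------------------------

def _table(xs_by_pid):
    region = StudyRegion()
    records = []
    i = 0
    for pid, xs in xs_by_pid.items():
        for x in xs:
            records.append(
                SpotRecord(pid, 1, float(x), float(i % 250), frozenset(["cold"]),
                           2.0, "cold", f"L{i}")
            )
            i += 1
    return SpotTable(records, region)


def test_segment_counts_and_totals():
    table = _table({"a": [0.0, 150.0, 450.0], "b": [1000.0]})
    counts = segment_counts(table)
    assert counts[("a", 1)] == 2 and counts[("a", 2)] == 1
    assert counts[("a", 3)] == 0 and counts[("b", 4)] == 1
    assert segment_totals(counts) == {1: 2, 2: 1, 3: 0, 4: 1}


def test_segment_counts_empty_table():
    assert segment_counts(SpotTable([], StudyRegion())) == {}


def test_segment_counts_all_at_wrist():
    counts = segment_counts(_table({"a": [0.0, 1.0, 2.0]}))
    assert segment_totals(counts) == {1: 3, 2: 0, 3: 0, 4: 0}


def test_segment_occupancy_sums_to_table_size(ref_classified):
    confirmed = ref_classified.confirmed()
    counts = segment_counts(confirmed)
    assert sum(counts.values()) == len(confirmed)
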