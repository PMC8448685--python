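"""Group assembly: inclusion rules, ROI exclusion, delay aggregation."""

import numpy as np
import pytest

from delaynet.errors import EmptyNetworkError, ValidationError
from delaynet.network import (
    exclude_rois,
    filter_small_diameter,
    group_average,
    subject_delays,
    to_delay_network,
)
from delaynet.synthetic import SynthConfig, generate_connectome

from conftest import edge_stack


def chained_delay(length=0.1, diameter=3.0, mtv=0.31896484, fr=0.5, fcsf=0.1):
    """Independent composition of the formula chain for one edge."""
    avf = (1 - mtv) * (1 - fcsf) * fr
    g = np.sqrt(1 / (1 + mtv / avf))
    v = 7e6 * diameter * 1e-6 * np.sqrt(-np.log(g))
    return length / v, g, v


def test_subject_delay_matches_formula_chain():
    # mtv chosen so the composed g-ratio is ~0.7 and v ~12.5 m/s
    stack = edge_stack([10] * 14)
    delays = subject_delays(stack)
    expected, g, v = chained_delay()
    assert 0.69 < g < 0.71
    assert delays[0, 0, 1] == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(7.97e-3, rel=1e-2)  # ~8 ms for 0.1 m


def test_absent_edge_has_no_delay():
    stack = edge_stack([0, 10, 10, 10, 10, 10, 10, 10, 10, 10])
    delays = subject_delays(stack)
    assert delays[0, 0, 1] == 0.0
    assert np.all(delays[1:, 0, 1] > 0)


def test_unmyelinated_edge_dropped_with_warning():
    stack = edge_stack([10] * 10, mtv=0.0)  # g = 1 -> v = 0
    with pytest.warns(UserWarning, match="zero velocity"):
        delays = subject_delays(stack)
    assert np.all(delays == 0)


@pytest.mark.parametrize("counts,retained", [
    ([5] * 9 + [0] * 5, True),     # > 4 streamlines in exactly 9 subjects
    ([4] * 14, False),             # 4 is not "more than 4"
    ([100] * 8 + [0] * 6, False),  # subject criterion fails
    ([5] * 8 + [4] * 6, False),    # only 8 subjects above the cut
])
def test_group_retention_rule(counts, retained):
    stack = edge_stack(counts)
    if retained:
        net = group_average(stack)
        assert net.adjacency[0, 1]
        assert net.n_contrib[0, 1] == sum(c > 4 for c in counts)
    else:
        with pytest.raises(EmptyNetworkError):
            group_average(stack)


def test_min_subjects_exceeding_stack_errors():
    stack = edge_stack([5] * 5)
    with pytest.raises(ValidationError):
        group_average(stack, min_subjects=9)


def test_contributors_only_enter_means():
    """Subjects failing the count criterion contribute nothing (no
    zero-imputation), and the group delay lies inside the contributor
    range."""
    counts = [10] * 9 + [2] * 5
    stack = edge_stack(counts)
    # give non-contributors a wildly different length
    for i in range(9, 14):
        stack.weights["length"][i, 0, 1] = stack.weights["length"][i, 1, 0] = 10.0
    net = group_average(stack)
    assert net.length[0, 1] == pytest.approx(0.1)
    delays = subject_delays(stack)
    contrib = delays[:9, 0, 1]
    assert contrib.min() <= net.delay[0, 1] <= contrib.max()


def test_delay_aggregation_modes():
    stack, _ = generate_connectome(SynthConfig(n_rois=20, seed=4))
    a = group_average(stack, delay_aggregation="subject_mean")
    b = group_average(stack, delay_aggregation="ratio_of_means")
    sel = a.adjacency
    # same edges, slightly different delays, same order of magnitude
    np.testing.assert_array_equal(a.adjacency, b.adjacency)
    assert not np.allclose(a.delay[sel], b.delay[sel], rtol=1e-12)
    np.testing.assert_allclose(a.delay[sel], b.delay[sel], rtol=0.2)


def test_group_delay_bracketed_by_contributors(rng):
    for seed in range(5):
        stack, _ = generate_connectome(SynthConfig(n_rois=16, seed=seed))
        net = group_average(stack)
        delays = subject_delays(stack)
        contrib = (stack.weights["count"] > 4) & (delays > 0)
        i, j = np.where(np.triu(net.adjacency, 1))
        for a, b in zip(i, j):
            vals = delays[contrib[:, a, b], a, b]
            assert vals.min() - 1e-15 <= net.delay[a, b] <= vals.max() + 1e-15


def test_retention_monotonicity():
    """Raising either threshold never adds edges."""
    for seed in range(10):
        stack, _ = generate_connectome(
            SynthConfig(n_rois=14, seed=seed, nos_mean=8.0))
        def edges(mc, ms):
            try:
                return group_average(stack, mc, ms).adjacency
            except EmptyNetworkError:
                return np.zeros((14, 14), dtype=bool)
        base = edges(4, 9)
        assert not np.any(edges(6, 9) & ~base)
        assert not np.any(edges(4, 11) & ~base)


def test_exclude_rois_semantics():
    stack, _ = generate_connectome(SynthConfig(n_rois=20, seed=4))
    names = list(stack.rois["name"])
    out = exclude_rois(stack, [names[0], names[3], names[0]])  # dup deduped
    assert out.n_rois == 18
    assert names[0] not in list(out.rois["name"])
    same = exclude_rois(stack, [])
    assert same.n_rois == 20
    with pytest.raises(ValidationError, match="nosuch"):
        exclude_rois(stack, ["nosuch"])


def test_exclude_commutes_with_group_average():
    stack, _ = generate_connectome(SynthConfig(n_rois=20, seed=9))
    labels = list(stack.rois["name"])[:4]
    a = group_average(exclude_rois(stack, labels))
    b = exclude_rois(group_average(stack), labels)
    np.testing.assert_array_equal(a.adjacency, b.adjacency)
    np.testing.assert_allclose(a.delay, b.delay, rtol=1e-12)


def test_filter_small_diameter_boundaries():
    stack, _ = generate_connectome(SynthConfig(n_rois=20, seed=4))
    net = group_average(stack)
    i, j = np.where(np.triu(net.adjacency, 1))
    # force one edge just below and one exactly at the threshold
    net.diameter[i[0], j[0]] = net.diameter[j[0], i[0]] = 0.9
    net.diameter[i[1], j[1]] = net.diameter[j[1], i[1]] = 1.0
    out = filter_small_diameter(net, 1.0)
    assert not out.adjacency[i[0], j[0]]   # 0.9 um removed
    assert out.adjacency[i[1], j[1]]       # exactly 1.0 um kept (strict <)
    unchanged = filter_small_diameter(net, 0.0)
    np.testing.assert_array_equal(unchanged.adjacency, net.adjacency)


def test_to_delay_network():
    stack = edge_stack([10] * 10)
    net = group_average(stack)
    dn = to_delay_network(net)
    np.testing.assert_array_equal(dn.coupling, net.adjacency)
    assert dn.tau[0, 1] == dn.tau[1, 0] == net.delay[0, 1]
    expected, _, _ = chained_delay()
    assert dn.tau[0, 1] == pytest.approx(expected, rel=1e-12)
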