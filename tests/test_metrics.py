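"""Length, branch-point, area and thickness metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tubequant.metrics import (
    DIAGONAL_WEIGHT,
    average_thickness,
    consolidate_nodes,
    find_branch_pixels,
    included_area_mask,
    measure_area,
    measure_length,
    relative_percent_difference,
)


def brute_force_length(mask, scale=1.0):
    """Independent oracle: enumerate every 8-adjacent foreground pair."""
    pts = {tuple(p) for p in np.argwhere(np.asarray(mask, dtype=bool))}
    total = 0.0
    for (r, c) in pts:
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):  # each pair once
            q = (r + dr, c + dc)
            if q not in pts:
                continue
            if dr and dc:
                # skip diagonals redundant through a shared orthogonal neighbor
                if (r, c + dc) in pts or (r + dr, c) in pts:
                    continue
                total += DIAGONAL_WEIGHT
            else:
                total += 1.0
    return total * scale


# --- length ----------------------------------------------------------------


def test_horizontal_line_length():
    m = np.zeros((3, 13), dtype=bool)
    m[1, 1:12] = True  # 11 pixels
    assert measure_length(m, 1.0) == pytest.approx(10.0)


def test_diagonal_line_uses_1414_weight():
    m = np.eye(11, dtype=bool)
    assert measure_length(m, 1.0) == pytest.approx(10 * 1.414)


def test_l_shaped_path_with_scale():
    m = np.zeros((8, 8), dtype=bool)
    m[1, 1:7] = True  # 6-px horizontal
    m[1:7, 6] = True  # 6-px vertical sharing the corner (1, 6)
    assert measure_length(m, 2.0) == pytest.approx(20.0)


def test_empty_skeleton_has_zero_length():
    assert measure_length(np.zeros((4, 4), dtype=bool), 1.0) == 0.0


def test_length_matches_brute_force_enumeration_on_random_masks():
    rng = np.random.default_rng(21)
    for _ in range(20):
        m = rng.random((12, 12)) < 0.35
        assert measure_length(m, 1.0) == pytest.approx(brute_force_length(m))


def test_length_invariant_under_transpose_and_rotation():
    rng = np.random.default_rng(22)
    m = rng.random((15, 10)) < 0.3
    base = measure_length(m, 1.0)
    assert measure_length(m.T, 1.0) == pytest.approx(base)
    assert measure_length(np.rot90(m), 1.0) == pytest.approx(base)


def test_length_scales_linearly_and_area_quadratically():
    m = np.zeros((6, 20), dtype=bool)
    m[2, 2:18] = True
    em = np.zeros((6, 20), dtype=bool)
    em[1:4, 2:18] = True
    assert measure_length(m, 3.0) == pytest.approx(3 * measure_length(m, 1.0))
    assert measure_area(em, m, 1, 3.0) == pytest.approx(9 * measure_area(em, m, 1, 1.0))


# --- branch pixels ---------------------------------------------------------


def test_straight_line_has_no_branch_pixels():
    m = np.zeros((3, 10), dtype=bool)
    m[1, 1:9] = True
    assert not find_branch_pixels(m).any()


def test_plus_center_is_a_branch_pixel():
    m = np.zeros((7, 7), dtype=bool)
    m[3, 1:6] = True
    m[1:6, 3] = True
    nodes = find_branch_pixels(m)
    assert nodes[3, 3]  # center has 4 neighbors
    # arm pixels touching the center also see >= 3 neighbors via diagonals;
    # all flagged pixels sit within one step of the true junction and
    # consolidate to a single branch point
    rows, cols = np.nonzero(nodes)
    assert (np.hypot(rows - 3.0, cols - 3.0) <= 1.5).all()
    assert len(consolidate_nodes(nodes, radius=5)) == 1


def test_y_junction_branch_pixels_near_true_junction():
    m = np.zeros((16, 16), dtype=bool)
    m[8, 1:9] = True  # stem to (8, 8)
    for i in range(1, 8):
        m[8 - i, 8 + i] = True  # up-right arm
        m[8 + i, 8 + i] = True  # down-right arm
    nodes = find_branch_pixels(m)
    assert nodes.sum() >= 1
    rows, cols = np.nonzero(nodes)
    assert (np.hypot(rows - 8.0, cols - 8.0) <= 2).all()


# --- node consolidation ----------------------------------------------------


def test_two_nearby_nodes_average_to_one():
    m = np.zeros((5, 10), dtype=bool)
    m[0, 0] = m[0, 4] = True
    pts = consolidate_nodes(m, radius=30)
    assert len(pts) == 1
    assert (pts[0].row, pts[0].col, pts[0].support) == (0.0, 2.0, 2)


def test_distant_nodes_stay_separate():
    m = np.zeros((10, 250), dtype=bool)
    m[5, 10] = m[5, 210] = True  # 200 px apart
    assert len(consolidate_nodes(m, radius=30)) == 2


def test_salt_and_pepper_node_cluster_collapses_to_one():
    # 7 scattered node pixels inside a 10-px disc: one consolidated point
    rng = np.random.default_rng(31)
    m = np.zeros((64, 64), dtype=bool)
    n = 0
    while n < 7:
        r, c = rng.integers(22, 43, 2)
        if math.hypot(r - 32, c - 32) <= 10 and not m[r, c]:
            m[r, c] = True
            n += 1
    pts = consolidate_nodes(m, radius=30)
    assert len(pts) == 1 and pts[0].support == 7


def brute_single_linkage_count(points, radius):
    """Independent oracle: transitive closure of the within-radius relation."""
    groups = [{i} for i in range(len(points))]
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    math.dist(points[a], points[b]) <= radius
                    for a in groups[i]
                    for b in groups[j]
                ):
                    groups[i] |= groups[j]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
    return len(groups)


def test_consolidation_matches_single_linkage_oracle():
    rng = np.random.default_rng(32)
    for _ in range(10):
        m = np.zeros((60, 60), dtype=bool)
        pts = rng.integers(0, 60, (12, 2))
        m[pts[:, 0], pts[:, 1]] = True
        coords = [tuple(p) for p in np.argwhere(m)]
        for radius in (3, 8, 15):
            assert len(consolidate_nodes(m, radius)) == brute_single_linkage_count(
                coords, radius
            )


def test_consolidated_count_non_increasing_in_radius():
    rng = np.random.default_rng(33)
    m = rng.random((50, 50)) < 0.02
    counts = [len(consolidate_nodes(m, r)) for r in (0, 2, 5, 10, 25, 60)]
    assert counts == sorted(counts, reverse=True)


# --- area ------------------------------------------------------------------


def _area_fixture():
    """Four components whose skeleton intersections are 0, 9, 10, 80 px."""
    em = np.zeros((40, 460), dtype=bool)
    sk = np.zeros((40, 460), dtype=bool)
    col = 5
    comps = []
    for inter in (0, 9, 10, 80):
        w = max(inter + 10, 30)
        em[5:15, col : col + w] = True
        if inter:
            sk[10, col + 2 : col + 2 + inter] = True
        comps.append((inter, 10 * w))
        col += w + 10
    return em, sk, comps


def test_components_without_skeleton_support_excluded():
    em, sk, comps = _area_fixture()
    kept = included_area_mask(em, sk, overlap=10)
    expected_px = sum(area for inter, area in comps if inter >= 10)
    assert kept.sum() == expected_px
    assert measure_area(em, sk, 10, 1.0) == pytest.approx(expected_px)


def test_supported_component_contributes_full_area_scaled():
    em = np.zeros((30, 60), dtype=bool)
    em[5:15, 5:55] = True  # 500-px component
    sk = np.zeros((30, 60), dtype=bool)
    sk[10, 8:48] = True  # 40-px skeleton run
    assert measure_area(em, sk, overlap=10, scale=2.0) == pytest.approx(500 * 4.0)


# --- thickness and percent difference --------------------------------------


def test_thickness_is_area_over_length():
    assert average_thickness(200.0, 50.0) == pytest.approx(4.0)


def test_thickness_empty_image_convention():
    assert average_thickness(0.0, 0.0) == 0.0


def test_thickness_undefined_flagged_as_missing():
    assert math.isnan(average_thickness(10.0, 0.0))


@pytest.mark.parametrize("pair,expected", [((100, 100), 0.0), ((150, 100), 50.0)])
def test_relative_percent_difference_values(pair, expected):
    assert relative_percent_difference(*pair) == pytest.approx(expected)


def test_relative_percent_difference_both_zero_undefined():
    assert math.isnan(relative_percent_difference(0.0, 0.0))


@settings(derandomize=True, max_examples=50)
@given(
    a=st.floats(min_value=0.1, max_value=1e6),
    b=st.floats(min_value=0.1, max_value=1e6),
)
def test_relative_percent_difference_symmetric(a, b):
    assert relative_percent_difference(a, b) == relative_percent_difference(b, a)
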