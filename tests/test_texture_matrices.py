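"""Texture-matrix builders checked against brute-force enumeration on small
hand grids, plus the symmetry/invariance properties the matrices must obey."""

import itertools

import numpy as np
import pytest

from radstage.images import ImageVolume, TumorMask
from radstage.radiomics import (
    GLCM_FEATURES,
    discretize,
    glcm_features,
    glcm_matrix,
    gldm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    minmax_normalize,
    ngtdm_features,
    ngtdm_table,
)
from radstage.radiomics.gldm import dependence_counts

from conftest import make_disc

ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(disc, distance, angle):
    """Enumerate every in-mask voxel pair at the offset, both orders."""
    dr, dc = (distance * s for s in ANGLE_STEPS[angle])
    n = disc.n_levels
    counts = np.zeros((n, n))
    ns, nr, nc = disc.levels.shape
    for s, r, c in itertools.product(range(ns), range(nr), range(nc)):
        r2, c2 = r + dr, c + dc
        if not (0 <= r2 < nr and 0 <= c2 < nc):
            continue
        if disc.mask[s, r, c] and disc.mask[s, r2, c2]:
            i, j = disc.levels[s, r, c] - 1, disc.levels[s, r2, c2] - 1
            counts[i, j] += 1
            counts[j, i] += 1
    return counts / counts.sum() if counts.sum() else None


def brute_runs(disc, angle):
    """Enumerate maximal equal-level runs along the direction per slice."""
    dr, dc = ANGLE_STEPS[angle]
    n = disc.n_levels
    ns, nr, nc = disc.levels.shape
    max_len = max(nr, nc)
    mat = np.zeros((n, max_len))
    for s in range(ns):
        seen = set()
        for r, c in itertools.product(range(nr), range(nc)):
            if not disc.mask[s, r, c] or (r, c) in seen:
                continue
            pr, pc = r - dr, c - dc
            if (
                0 <= pr < nr
                and 0 <= pc < nc
                and disc.mask[s, pr, pc]
                and disc.levels[s, pr, pc] == disc.levels[s, r, c]
            ):
                continue  # not a run start
            length = 0
            rr, cc = r, c
            while (
                0 <= rr < nr
                and 0 <= cc < nc
                and disc.mask[s, rr, cc]
                and disc.levels[s, rr, cc] == disc.levels[s, r, c]
            ):
                seen.add((rr, cc))
                length += 1
                rr, cc = rr + dr, cc + dc
            mat[disc.levels[s, r, c] - 1, length - 1] += 1
    return mat


def brute_zones(disc):
    """Flood-fill 26-connected equal-level zones."""
    ns, nr, nc = disc.levels.shape
    visited = np.zeros_like(disc.mask)
    zones = []
    offs = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    for start in itertools.product(range(ns), range(nr), range(nc)):
        if not disc.mask[start] or visited[start]:
            continue
        lvl = disc.levels[start]
        stack, size = [start], 0
        visited[start] = True
        while stack:
            v = stack.pop()
            size += 1
            for o in offs:
                w = tuple(a + b for a, b in zip(v, o))
                if all(0 <= w[i] < disc.levels.shape[i] for i in range(3)):
                    if disc.mask[w] and not visited[w] and disc.levels[w] == lvl:
                        visited[w] = True
                        stack.append(w)
        zones.append((int(lvl), size))
    n = disc.n_levels
    mat = np.zeros((n, max(s for _, s in zones)))
    for lvl, size in zones:
        mat[lvl - 1, size - 1] += 1
    return mat


def brute_dependence(disc, kernel):
    ns, nr, nc = disc.levels.shape
    dep = np.zeros_like(disc.levels)
    rng = range(-kernel, kernel + 1)
    for v in itertools.product(range(ns), range(nr), range(nc)):
        if not disc.mask[v]:
            continue
        count = 0
        for o in itertools.product(rng, rng, rng):
            if o == (0, 0, 0):
                continue
            w = tuple(a + b for a, b in zip(v, o))
            if all(0 <= w[i] < disc.levels.shape[i] for i in range(3)):
                if disc.mask[w] and disc.levels[w] == disc.levels[v]:
                    count += 1
        dep[v] = count
    return dep


def brute_ngtdm(disc, kernel):
    ns, nr, nc = disc.levels.shape
    n_i = np.zeros(disc.n_levels)
    s_i = np.zeros(disc.n_levels)
    rng = range(-kernel, kernel + 1)
    for v in itertools.product(range(ns), range(nr), range(nc)):
        if not disc.mask[v]:
            continue
        nb = []
        for o in itertools.product(rng, rng, rng):
            if o == (0, 0, 0):
                continue
            w = tuple(a + b for a, b in zip(v, o))
            if all(0 <= w[i] < disc.levels.shape[i] for i in range(3)):
                if disc.mask[w]:
                    nb.append(disc.levels[w])
        if nb:
            i = disc.levels[v] - 1
            n_i[i] += 1
            s_i[i] += abs(disc.levels[v] - np.mean(nb))
    return n_i, s_i


@pytest.fixture
def hand_grid(rng):
    """5x5x2 random levels with an irregular mask: the oracle battleground."""
    levels = rng.integers(1, 5, size=(2, 5, 5)).astype(np.int32)
    mask = rng.random((2, 5, 5)) > 0.25
    mask[0, 0, 0] = True  # never fully empty
    levels[~mask] = 0
    return make_disc(levels, n_levels=4, mask=mask)


class TestGLCM:
    def test_hand_example_rows(self):
        disc = make_disc(np.tile([1, 1, 2, 2], (4, 1)))
        p = glcm_matrix(disc, distance=1, angle=0)
        assert p[0, 0] == pytest.approx(1 / 3)
        assert p[1, 1] == pytest.approx(1 / 3)
        assert p[0, 1] == pytest.approx(1 / 6)
        assert glcm_features(p)["Contrast"] == pytest.approx(1 / 3)

    def test_constant_roi(self):
        disc = make_disc(np.ones((3, 3), int))
        p = glcm_matrix(disc, 1, 0)
        assert p[0, 0] == 1.0
        f = glcm_features(p)
        assert f["Contrast"] == 0.0
        assert f["MaximumProbability"] == 1.0
        assert f["Correlation"] is None  # degenerate marginal

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("distance", [1, 2])
    def test_matches_brute_force(self, hand_grid, angle, distance):
        ours = glcm_matrix(hand_grid, distance, angle)
        brute = brute_glcm(hand_grid, distance, angle)
        assert ours is not None and brute is not None
        assert np.allclose(ours, brute)

    def test_normalized_and_symmetric(self, hand_grid):
        p = glcm_matrix(hand_grid, 1, 45)
        assert p.sum() == pytest.approx(1.0)
        assert np.allclose(p, p.T)

    def test_transpose_invariance_of_features(self, hand_grid):
        p = glcm_matrix(hand_grid, 1, 135)
        f1, f2 = glcm_features(p), glcm_features(p.T)
        for name in GLCM_FEATURES:
            if f1[name] is not None:
                assert f1[name] == pytest.approx(f2[name])

    def test_exactly_twenty_features(self, hand_grid):
        assert len(glcm_features(glcm_matrix(hand_grid, 1, 0))) == 20


class TestGLRLM:
    def test_hand_run_example(self):
        disc = make_disc(np.array([[1, 1, 1, 2, 2]]))
        f = glrlm_features(disc, angle=0)
        assert f["RunPercentage"] == pytest.approx(2 / 5)

    def test_single_long_run(self):
        disc = make_disc(np.ones((1, 7), int))
        assert glrlm_features(disc, 0)["LongRunEmphasis"] == pytest.approx(49.0)

    def test_checkerboard_all_unit_runs(self):
        board = (np.indices((4, 4)).sum(axis=0) % 2) + 1
        disc = make_disc(board)
        assert glrlm_features(disc, 0)["RunPercentage"] == 1.0

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_matches_brute_force(self, hand_grid, angle):
        ours = glrlm_matrix(hand_grid, angle)
        brute = brute_runs(hand_grid, angle)
        # trim both to the same occupied width
        w = max(ours.shape[1], brute.shape[1])
        o = np.zeros((ours.shape[0], w)); o[:, : ours.shape[1]] = ours
        b = np.zeros((brute.shape[0], w)); b[:, : brute.shape[1]] = brute
        assert np.array_equal(o, b)

    def test_exactly_fifteen_features(self, hand_grid):
        assert len(glrlm_features(hand_grid, 0)) == 15


class TestGLSZM:
    def test_two_blob_zone_percentage(self):
        lv = np.zeros((1, 3, 8), int)
        lv[0, 0, :3] = 1  # zone of 3
        lv[0, 2, :5] = 1  # zone of 5 (not 26-connected to the first? rows 0,2 gap row 1)
        disc = make_disc(lv)
        f = glszm_features(disc)
        assert f["ZonePercentage"] == pytest.approx(2 / 8)

    def test_constant_roi_single_zone(self):
        disc = make_disc(np.ones((2, 3), int))
        f = glszm_features(disc)
        assert f["ZoneEntropy"] == 0.0
        assert f["ZonePercentage"] == pytest.approx(1 / 6)

    def test_matches_brute_force(self, hand_grid):
        ours = glszm_matrix(hand_grid)
        brute = brute_zones(hand_grid)
        w = max(ours.shape[1], brute.shape[1])
        o = np.zeros((ours.shape[0], w)); o[:, : ours.shape[1]] = ours
        b = np.zeros((brute.shape[0], w)); b[:, : brute.shape[1]] = brute
        assert np.array_equal(o, b)

    def test_level_permutation_leaves_size_features(self, hand_grid):
        perm = np.array([0, 3, 4, 1, 2])  # permutation of levels 1..4 (+0 slot)
        permuted_levels = perm[hand_grid.levels]
        disc2 = make_disc(permuted_levels, n_levels=4, mask=hand_grid.mask)
        f1, f2 = glszm_features(hand_grid), glszm_features(disc2)
        for name in ("SmallAreaEmphasis", "LargeAreaEmphasis", "ZonePercentage"):
            assert f1[name] == pytest.approx(f2[name])

    def test_exactly_fourteen_features(self, hand_grid):
        assert len(glszm_features(hand_grid)) == 14


class TestGLDM:
    def test_constant_center_dependence(self):
        disc = make_disc(np.ones((3, 3), int))
        dep = dependence_counts(disc, 1)
        assert dep[0, 1, 1] == 8

    def test_alternating_line_zero_dependence(self):
        # 1D checkerboard: under a Chebyshev neighborhood a 2D board's
        # diagonal neighbors share their level, so the no-dependence case
        # is the alternating line
        disc = make_disc(np.array([[1, 2, 1, 2, 1, 2]]))
        dep = dependence_counts(disc, 1)
        assert dep[disc.mask].max() == 0
        from radstage.radiomics import gldm_features

        f = gldm_features(disc, 1)
        assert f["SmallDependenceEmphasis"] == 1.0  # maximal

    @pytest.mark.parametrize("kernel", [1, 2])
    def test_matches_brute_force(self, hand_grid, kernel):
        assert np.array_equal(
            dependence_counts(hand_grid, kernel)[hand_grid.mask],
            brute_dependence(hand_grid, kernel)[hand_grid.mask],
        )

    def test_mean_dependence_monotone_in_kernel(self, hand_grid):
        means = [
            dependence_counts(hand_grid, k)[hand_grid.mask].mean() for k in (1, 2, 3)
        ]
        assert means[0] <= means[1] <= means[2]


class TestNGTDM:
    def test_constant_roi_contrast_zero(self):
        disc = make_disc(np.ones((3, 3), int))
        f = ngtdm_features(disc, 1)
        assert f["Contrast"] == 0.0
        assert f["Busyness"] is None  # single level: zero denominator

    def test_matches_brute_force(self, hand_grid):
        n_ours, s_ours = ngtdm_table(hand_grid, 1)
        n_brute, s_brute = brute_ngtdm(hand_grid, 1)
        assert np.allclose(n_ours, n_brute)
        assert np.allclose(s_ours, s_brute)

    def test_two_level_coarseness_closed_form(self):
        disc = make_disc(np.array([[1, 1, 2, 2]]))
        n_i, s_i = ngtdm_table(disc, 1)
        f = ngtdm_features(disc, 1)
        expected = 1.0 / float(np.sum((n_i / n_i.sum()) * s_i))
        assert f["Coarseness"] == pytest.approx(expected)


class TestAffineInvariance:
    def test_texture_features_invariant_to_affine_intensity(self, rng):
        data = rng.normal(size=(3, 6, 6))
        mask = TumorMask(np.ones((3, 6, 6), bool))
        v1 = ImageVolume(data)
        v2 = ImageVolume(2.5 * data + 40.0)
        d1 = discretize(minmax_normalize(v1), mask, 3)
        d2 = discretize(minmax_normalize(v2), mask, 3)
        assert np.array_equal(d1.levels, d2.levels)
        f1, f2 = ngtdm_features(d1, 1), ngtdm_features(d2, 1)
        for k in f1:
            if f1[k] is not None:
                assert f1[k] == pytest.approx(f2[k])
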