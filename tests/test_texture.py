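"""Texture matrices against independent brute-force builders.

Each oracle enumerates voxels/neighbours/zones with explicit Python loops,
structured differently from the library implementation, and must agree
exactly on small random ROIs.
"""

import numpy as np
import pytest

from pdxrad.radiomics import texture as tx


def _random_lvol(rng, shape=(4, 6, 6), n_levels=4, fill=0.8):
    lvol = rng.integers(1, n_levels + 1, size=shape)
    lvol[rng.random(shape) > fill] = 0
    if (lvol > 0).sum() < 2:
        lvol[0, 0, 0] = 1
        lvol[0, 0, 1] = 2
    return lvol.astype(np.int64)


def _inb(shape, z, y, x):
    return 0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]


def brute_glcm(lvol, n_levels):
    c = np.zeros((n_levels, n_levels))
    dirs = [tuple(d) for d in tx.DIRECTIONS_13] + [tuple(-d) for d in tx.DIRECTIONS_13]
    for z in range(lvol.shape[0]):
        for y in range(lvol.shape[1]):
            for x in range(lvol.shape[2]):
                a = lvol[z, y, x]
                if a == 0:
                    continue
                for dz, dy, dx in dirs:
                    if _inb(lvol.shape, z + dz, y + dy, x + dx):
                        b = lvol[z + dz, y + dy, x + dx]
                        if b > 0:
                            c[a - 1, b - 1] += 1
    return c / c.sum()


def brute_glrlm(lvol, n_levels):
    """Group voxels into lines per direction, then split runs with groupby."""
    from itertools import groupby

    runs = {}
    max_len = 1
    for d in tx.DIRECTIONS_13:
        lines = {}
        for z in range(lvol.shape[0]):
            for y in range(lvol.shape[1]):
                for x in range(lvol.shape[2]):
                    pos = np.array([z, y, x])
                    # anchor each voxel to the start of its line along d
                    t = int(min(
                        pos[i] if d[i] == 1
                        else (lvol.shape[i] - 1 - pos[i]) if d[i] == -1
                        else 10**9
                        for i in range(3)
                    ))
                    anchor = tuple(pos - t * d)
                    lines.setdefault(anchor, []).append((t, lvol[z, y, x]))
        for anchor, cells in lines.items():
            cells.sort()
            seq = [g for _, g in cells]
            for g, grp in groupby(seq):
                n = len(list(grp))
                if g > 0:
                    runs[(g, n)] = runs.get((g, n), 0) + 1
                    max_len = max(max_len, n)
    mat = np.zeros((n_levels, max_len))
    for (g, n), cnt in runs.items():
        mat[g - 1, n - 1] = cnt
    return mat


def brute_glszm(lvol, n_levels):
    """Flood-fill zones with an explicit stack."""
    seen = np.zeros(lvol.shape, dtype=bool)
    nbrs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    zones = []
    for z in range(lvol.shape[0]):
        for y in range(lvol.shape[1]):
            for x in range(lvol.shape[2]):
                if lvol[z, y, x] == 0 or seen[z, y, x]:
                    continue
                g = lvol[z, y, x]
                stack = [(z, y, x)]
                seen[z, y, x] = True
                members = []
                while stack:
                    cz, cy, cx = stack.pop()
                    members.append((cz, cy, cx))
                    for dz, dy, dx in nbrs:
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if (
                            _inb(lvol.shape, nz, ny, nx)
                            and not seen[nz, ny, nx]
                            and lvol[nz, ny, nx] == g
                        ):
                            seen[nz, ny, nx] = True
                            stack.append((nz, ny, nx))
                zones.append((g, members))
    return zones


def brute_glszm_matrix(lvol, n_levels):
    zones = brute_glszm(lvol, n_levels)
    max_size = max(len(m) for _, m in zones)
    mat = np.zeros((n_levels, max_size))
    for g, members in zones:
        mat[g - 1, len(members) - 1] += 1
    return mat


def brute_gldzm_matrix(lvol, n_levels):
    zones = brute_glszm(lvol, n_levels)
    mask = lvol > 0
    outside = [
        (z, y, x)
        for z in range(-1, lvol.shape[0] + 1)
        for y in range(-1, lvol.shape[1] + 1)
        for x in range(-1, lvol.shape[2] + 1)
        if not (_inb(lvol.shape, z, y, x) and mask[z, y, x])
    ]
    entries = []
    for g, members in zones:
        d = min(
            max(abs(z - oz), abs(y - oy), abs(x - ox))
            for (z, y, x) in members
            for (oz, oy, ox) in outside
        )
        entries.append((g, d))
    mat = np.zeros((n_levels, max(d for _, d in entries)))
    for g, d in entries:
        mat[g - 1, d - 1] += 1
    return mat


def brute_ngldm_matrix(lvol, n_levels):
    mat = np.zeros((n_levels, 27))
    nbrs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    max_k = 0
    for z in range(lvol.shape[0]):
        for y in range(lvol.shape[1]):
            for x in range(lvol.shape[2]):
                g = lvol[z, y, x]
                if g == 0:
                    continue
                k = sum(
                    1
                    for dz, dy, dx in nbrs
                    if _inb(lvol.shape, z + dz, y + dy, x + dx)
                    and lvol[z + dz, y + dy, x + dx] == g
                )
                mat[g - 1, k] += 1
                max_k = max(max_k, k)
    return mat[:, : max_k + 1]


def brute_ngtdm(lvol, n_levels):
    nbrs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    for z in range(lvol.shape[0]):
        for y in range(lvol.shape[1]):
            for x in range(lvol.shape[2]):
                g = lvol[z, y, x]
                if g == 0:
                    continue
                vals = [
                    lvol[z + dz, y + dy, x + dx]
                    for dz, dy, dx in nbrs
                    if _inb(lvol.shape, z + dz, y + dy, x + dx)
                    and lvol[z + dz, y + dy, x + dx] > 0
                ]
                if not vals:
                    continue
                n[g - 1] += 1
                s[g - 1] += abs(g - sum(vals) / len(vals))
    return n, s


@pytest.mark.parametrize("seed", [0, 1, 2])
class TestBruteForceAgreement:
    def test_glcm(self, seed):
        lvol = _random_lvol(np.random.default_rng(seed))
        np.testing.assert_allclose(
            tx.glcm_matrix(lvol, 4), brute_glcm(lvol, 4), atol=1e-12
        )

    def test_glrlm(self, seed):
        lvol = _random_lvol(np.random.default_rng(seed))
        np.testing.assert_array_equal(
            tx.glrlm_matrix(lvol, 4), brute_glrlm(lvol, 4)
        )

    def test_glszm(self, seed):
        lvol = _random_lvol(np.random.default_rng(seed))
        np.testing.assert_array_equal(
            tx.glszm_matrix(lvol, 4), brute_glszm_matrix(lvol, 4)
        )

    def test_gldzm(self, seed):
        lvol = _random_lvol(np.random.default_rng(seed))
        np.testing.assert_array_equal(
            tx.gldzm_matrix(lvol, 4), brute_gldzm_matrix(lvol, 4)
        )

    def test_ngldm(self, seed):
        lvol = _random_lvol(np.random.default_rng(seed))
        np.testing.assert_array_equal(
            tx.ngldm_matrix(lvol, 4), brute_ngldm_matrix(lvol, 4)
        )

    def test_ngtdm(self, seed):
        lvol = _random_lvol(np.random.default_rng(seed))
        n, s = tx.ngtdm_table(lvol, 4)
        bn, bs = brute_ngtdm(lvol, 4)
        np.testing.assert_array_equal(n, bn)
        np.testing.assert_allclose(s, bs, atol=1e-10)


class TestDegenerateAndHandExamples:
    def test_constant_roi_zero_contrast_and_entropy(self):
        lvol = np.zeros((3, 5, 5), dtype=np.int64)
        lvol[1:3, 1:4, 1:4] = 1
        f = tx.glcm_features(tx.glcm_matrix(lvol, 4))
        assert f["contrast"] == 0.0
        assert f["joint_entropy"] == 0.0
        assert np.isnan(f["correlation"])
        n, s = tx.ngtdm_table(lvol, 4)
        assert tx.ngtdm_features(n, s)["contrast"] == 0.0

    def test_checkerboard_glcm_unit_offset_pairs_all_differ(self):
        zz, yy, xx = np.mgrid[:4, :4, :4]
        lvol = ((zz + yy + xx) % 2 + 1).astype(np.int64)
        # restrict to a single unit offset: every pair differs by one level
        c = np.zeros((2, 2))
        sl_a = lvol[:, :, :-1].ravel()
        sl_b = lvol[:, :, 1:].ravel()
        for a, b in zip(sl_a, sl_b):
            c[a - 1, b - 1] += 1
        c = c + c.T
        p = c / c.sum()
        contrast = sum(
            (i - j) ** 2 * p[i - 1, j - 1] for i in (1, 2) for j in (1, 2)
        )
        assert contrast == pytest.approx(1.0)  # all unit-offset pairs differ

    def test_one_dimensional_run_counts_by_hand(self):
        lvol = np.array([[[1, 1, 2, 2, 2]]], dtype=np.int64)
        mat = tx.glrlm_matrix(lvol, 2)
        expected = np.zeros((2, 3))
        # along the line: one run of level 1 (len 2), one of level 2 (len 3)
        expected[0, 1] += 1
        expected[1, 2] += 1
        # the other 12 directions see every voxel as a length-1 run
        expected[0, 0] += 2 * 12
        expected[1, 0] += 3 * 12
        np.testing.assert_array_equal(mat, expected)

    def test_matrix_rows_normalize_and_entropies_nonnegative(self, rng):
        lvol = _random_lvol(rng, shape=(3, 6, 6))
        p = tx.glcm_matrix(lvol, 4)
        assert p.sum() == pytest.approx(1.0)
        f = tx.glcm_features(p)
        assert f["joint_entropy"] >= 0 and 0 < f["asm"] <= 1
        rl = tx.glrlm_features(tx.glrlm_matrix(lvol, 4), int((lvol > 0).sum()))
        assert rl["run_entropy"] >= 0
        assert 0 < rl["run_percentage"] <= 13.0
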