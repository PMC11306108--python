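import numpy as np
import pytest

from clearcount3d.detection import (
    DetectionParams,
    extract_candidates,
    filter_by_intensity,
    log_response,
)
from clearcount3d.io import Volume3D


def brute_force_log(data, h=(1.0, 1.0, 1.0)):
    """Direct per-voxel central second differences on the interior."""
    nz, ny, nx = data.shape
    out = np.zeros((nz - 2, ny - 2, nx - 2))
    for z in range(1, nz - 1):
        for y in range(1, ny - 1):
            for x in range(1, nx - 1):
                lap = (
                    (data[z + 1, y, x] - 2 * data[z, y, x] + data[z - 1, y, x]) / h[0] ** 2
                    + (data[z, y + 1, x] - 2 * data[z, y, x] + data[z, y - 1, x]) / h[1] ** 2
                    + (data[z, y, x + 1] - 2 * data[z, y, x] + data[z, y, x - 1]) / h[2] ** 2
                )
                out[z - 1, y - 1, x - 1] = -lap
    return out


def flood_fill_components(mask):
    """Brute-force 26-connected component extraction by BFS."""
    visited = np.zeros_like(mask, dtype=bool)
    components = []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        stack, comp = [start], []
        visited[start] = True
        while stack:
            vox = stack.pop()
            comp.append(vox)
            for dz, dy, dx in offsets:
                nb = (vox[0] + dz, vox[1] + dy, vox[2] + dx)
                if all(0 <= c < n for c, n in zip(nb, mask.shape)) and mask[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        components.append(frozenset(comp))
    return set(components)


class TestLogResponse:
    def test_quadratic_has_constant_laplacian(self):
        # central differences are exact on quadratics: f = x² ⇒ I_LoG = -2
        x = np.arange(9, dtype=float)
        data = np.broadcast_to(x**2, (9, 9, 9)).copy()
        out = log_response(Volume3D(data, (1, 1, 1))).data
        assert np.allclose(out[1:-1, 1:-1, 1:-1], -2.0, atol=1e-12)

    def test_gaussian_blob_sign_structure(self, gaussian_blob_volume):
        # the analytic Laplacian of a Gaussian changes sign on the shell r = s√3
        vol, s, r = gaussian_blob_volume
        out = log_response(vol).data
        r0 = s * np.sqrt(3.0)
        assert np.all(out[r < 0.8 * r0] > 0)
        assert np.all(out[r > 1.2 * r0] < 0)
        shell = np.abs(r - r0) <= 0.5
        assert abs(out[shell].mean()) < 0.02 * np.abs(out).max()

    def test_matches_brute_force_exactly(self, rng):
        data = rng.random((5, 5, 5))
        out = log_response(Volume3D(data, (1, 1, 1))).data
        assert np.array_equal(out[1:-1, 1:-1, 1:-1], brute_force_log(data))

    def test_physical_spacing_mode(self, rng):
        data = rng.random((5, 5, 5))
        spacing = (3.0, 3.26, 3.26)
        out = log_response(Volume3D(data, spacing), spacing_mode="physical").data
        assert np.allclose(out[1:-1, 1:-1, 1:-1], brute_force_log(data, spacing), atol=1e-12)

    def test_boundary_replicates_interior(self, rng):
        data = rng.random((5, 6, 7))
        out = log_response(Volume3D(data, (1, 1, 1))).data
        assert np.array_equal(out[0], out[1])
        assert np.array_equal(out[:, 0, :], out[:, 1, :])
        assert np.array_equal(out[:, :, -1], out[:, :, -2])

    def test_short_axis_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            log_response(Volume3D(np.zeros((2, 5, 5)), (1, 1, 1)))

    def test_linearity(self, rng):
        a = rng.random((6, 6, 6))
        b = rng.random((6, 6, 6))
        fa = log_response(Volume3D(a, (1, 1, 1))).data
        fb = log_response(Volume3D(b, (1, 1, 1))).data
        fab = log_response(Volume3D(a + b, (1, 1, 1))).data
        assert np.allclose(fab, fa + fb, atol=1e-12)


def _blob(shape, center, s, amplitude=1.0):
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return amplitude * np.exp(-r2 / (2 * s**2))


class TestExtractCandidates:
    def _volumes(self, data):
        vol = Volume3D(data, (1, 1, 1))
        return log_response(vol), vol

    def test_single_blob_gives_one_object(self):
        log_vol, id_vol = self._volumes(1.0 + _blob((24, 24, 24), (12, 12, 12), 3.0))
        objects = extract_candidates(log_vol, id_vol, DetectionParams(alpha=1e-3))
        assert len(objects) == 1
        assert objects[0].centroid == pytest.approx((12, 12, 12), abs=0.5)

    def test_alpha_above_max_gives_nothing(self):
        log_vol, id_vol = self._volumes(1.0 + _blob((16, 16, 16), (8, 8, 8), 2.0))
        assert extract_candidates(log_vol, id_vol, DetectionParams(alpha=1e6)) == []

    def test_two_blobs_match_flood_fill_oracle(self):
        data = 1.0 + _blob((40, 24, 24), (10, 12, 12), 2.5) + _blob((40, 24, 24), (30, 12, 12), 2.5)
        log_vol, id_vol = self._volumes(data)
        params = DetectionParams(alpha=1e-3, min_voxels=1)
        objects = extract_candidates(log_vol, id_vol, params)
        expected = flood_fill_components(log_vol.data > params.alpha)
        got = {frozenset(map(tuple, o.voxels)) for o in objects}
        assert got == expected
        assert len(objects) == 2

    def test_ids_are_deterministic_lexicographic(self):
        data = 1.0 + _blob((40, 24, 24), (30, 12, 12), 2.5) + _blob((40, 24, 24), (10, 12, 12), 2.5)
        log_vol, id_vol = self._volumes(data)
        objects = extract_candidates(log_vol, id_vol, DetectionParams())
        mins = [tuple(o.voxels[0]) for o in objects]
        assert mins == sorted(mins)
        assert [o.id for o in objects] == [1, 2]

    def test_alpha_monotonicity_is_refinement(self):
        data = 1.0 + _blob((32, 32, 32), (16, 16, 16), 4.0)
        log_vol, id_vol = self._volumes(data)
        low = extract_candidates(log_vol, id_vol, DetectionParams(alpha=1e-3, min_voxels=1))
        high = extract_candidates(log_vol, id_vol, DetectionParams(alpha=1e-2, min_voxels=1))
        low_sets = [set(map(tuple, o.voxels)) for o in low]
        for obj in high:
            vox = set(map(tuple, obj.voxels))
            assert any(vox <= parent for parent in low_sets)

    def test_volume_um3_uses_spacing(self):
        data = 1.0 + _blob((24, 24, 24), (12, 12, 12), 3.0)
        vol = Volume3D(data, (3.0, 3.26, 3.26))
        objects = extract_candidates(log_response(vol), vol, DetectionParams())
        obj = objects[0]
        assert obj.volume_um3 == pytest.approx(obj.volume_vox * 3.0 * 3.26 * 3.26)


class TestFilterByIntensity:
    def _make(self, max_ids):
        from clearcount3d.detection import CandidateObject

        return [
            CandidateObject(
                id=i + 1,
                voxels=np.array([[0, 0, i], [0, 1, i]]),
                centroid=(0, 0.5, i),
                volume_vox=2,
                volume_um3=2.0,
                max_Id=m,
                mean_Id=m,
            )
            for i, m in enumerate(max_ids)
        ]

    def test_threshold_keeps_only_bright_objects(self):
        kept, ledger = filter_by_intensity(self._make([1.05, 1.2]), DetectionParams(i_d_min=1.1))
        assert [o.max_Id for o in kept] == [1.2]
        assert ledger == {"n_in": 2, "n_kept": 1}

    def test_zero_threshold_keeps_all(self):
        kept, _ = filter_by_intensity(self._make([0.5, 1.0, 2.0]), DetectionParams(i_d_min=0.0))
        assert len(kept) == 3

    def test_empty_input(self):
        kept, ledger = filter_by_intensity([], DetectionParams())
        assert kept == [] and ledger == {"n_in": 0, "n_kept": 0}


class TestDetectionParams:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(alpha=0.0)
        with pytest.raises(ValueError):
            DetectionParams(connectivity=4)
        with pytest.raises(ValueError):
            DetectionParams(min_voxels=0)
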