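"""DI, CDF, structure-tensor coherency and FOV subsetting."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.stats import spearmanr

from neurocult import (
    BaselineReference,
    CoherencyParams,
    CultureSpec,
    FieldImage,
    ParameterError,
    SegmentationMasks,
    cluster_density_factor,
    disaggregation_index,
    generate_timecourse,
    label_somata,
    region_coherency,
    rescale_minmax,
    segment,
    select_coherency_fovs,
    structure_tensor_coherency,
)

from oracles import boundary_edge_count


def _objects_from(soma):
    return label_somata(SegmentationMasks(soma, np.zeros_like(soma, dtype=bool)))


class TestDisaggregationIndex:
    def test_definition(self):
        soma = np.zeros((10, 10), dtype=bool)
        soma[2:7, 2:4] = True  # one object of area 10
        objs = _objects_from(soma)
        assert disaggregation_index(BaselineReference(s0=10, m0=1), objs) == pytest.approx(1.0)

    def test_merging_lowers_di(self):
        four = np.zeros((24, 24), dtype=bool)
        for r0, c0 in [(2, 2), (2, 14), (14, 2), (14, 14)]:
            four[r0:r0 + 2, c0:c0 + 5] = True  # 4 objects of area 10
        one = np.zeros((24, 24), dtype=bool)
        one[4:8, 4:14] = True  # single object of area 40
        base = BaselineReference(s0=10, m0=4)
        assert disaggregation_index(base, _objects_from(four)) == pytest.approx(1.0)
        assert disaggregation_index(base, _objects_from(one)) == pytest.approx(0.25)

    def test_baseline_self_normalization_identity(self, default_timecourse):
        _, _, truth = default_timecourse
        objs = _objects_from(truth.soma_masks[0])
        base = BaselineReference.from_initial_objects(objs)
        assert disaggregation_index(base, objs) == pytest.approx(1.0)

    def test_di_non_increasing_under_aggregation(self):
        _, truth = generate_timecourse(CultureSpec(seed=6, n_days=5, cluster_attraction=0.4))
        base = BaselineReference.from_initial_objects(_objects_from(truth.soma_masks[0]))
        di = [disaggregation_index(base, _objects_from(m)) for m in truth.soma_masks]
        assert all(b <= a + 0.05 for a, b in zip(di, di[1:]))
        assert di[-1] < di[0]

    def test_empty_objects_missing(self):
        val = disaggregation_index(BaselineReference(s0=10, m0=1),
                                   _objects_from(np.zeros((4, 4), dtype=bool)))
        assert math.isnan(val)


class TestClusterDensityFactor:
    def test_square_definition(self):
        soma = np.zeros((14, 14), dtype=bool)
        soma[2:12, 2:12] = True  # 10x10 square, perimeter 40
        assert cluster_density_factor(BaselineReference(s0=1, m0=1),
                                      _objects_from(soma)) == pytest.approx(1 / 40)

    def test_merging_raises_cdf(self):
        separate = np.zeros((16, 26), dtype=bool)
        separate[3:13, 1:11] = True
        separate[3:13, 14:24] = True  # two 10x10 squares, total perimeter 80
        merged = np.zeros((16, 26), dtype=bool)
        merged[3:13, 3:23] = True  # one 10x20 block, perimeter 60
        base = BaselineReference(s0=1, m0=2)
        low = cluster_density_factor(base, _objects_from(separate))
        high = cluster_density_factor(base, _objects_from(merged))
        assert low == pytest.approx(2 / 80) and high == pytest.approx(2 / 60)

    def test_perimeter_matches_boundary_oracle(self, rng):
        for _ in range(10):
            mask = ndi.binary_dilation(rng.random((20, 20)) < 0.1)
            objs = _objects_from(mask)
            base = BaselineReference(s0=1, m0=3)
            expected = 3 / boundary_edge_count(mask)
            assert cluster_density_factor(base, objs) == pytest.approx(expected)

    def test_relabeling_invariance(self, default_timecourse):
        _, _, truth = default_timecourse
        mask = truth.soma_masks[0]
        base = BaselineReference(s0=30, m0=5)
        a = cluster_density_factor(base, _objects_from(mask))
        b = cluster_density_factor(base, _objects_from(mask[::-1, ::-1]))
        assert a == pytest.approx(b)


class TestStructureTensorCoherency:
    def test_parallel_stripes_near_one(self):
        stripes = np.tile(np.sin(np.arange(64) * 0.5), (64, 1))
        assert structure_tensor_coherency(stripes) > 0.95

    def test_constant_window_zero(self):
        assert structure_tensor_coherency(np.full((32, 32), 5.0)) == 0.0

    def test_isotropic_texture_low(self, rng):
        iso = ndi.gaussian_filter(rng.normal(size=(128, 128)), 2.0)
        assert structure_tensor_coherency(iso) < 0.2

    def test_intensity_scale_invariance(self, rng):
        win = ndi.gaussian_filter(rng.normal(size=(48, 48)), 1.5)
        win = win - win.min() + 1.0
        a = structure_tensor_coherency(win)
        b = structure_tensor_coherency(1000.0 * win)
        assert a == pytest.approx(b, rel=1e-9)

    def test_window_must_exceed_3x3(self):
        with pytest.raises(ParameterError, match="window"):
            structure_tensor_coherency(np.zeros((3, 3)))


class TestRegionCoherency:
    def test_radial_neurites_highly_coherent(self):
        shape = (128, 128)
        rr, cc = np.indices(shape)
        soma = (rr - 64) ** 2 + (cc - 64) ** 2 <= 36
        neurite = np.zeros(shape, dtype=bool)
        for dr, dc in [(0, 1), (0, -1), (1, 0), (-1, 0)]:
            for t in range(7, 55):
                neurite[64 + dr * t, 64 + dc * t] = True
                if dr == 0:
                    neurite[65, 64 + dc * t] = True
                else:
                    neurite[64 + dr * t, 65] = True
        neurite &= ~soma
        img = np.full(shape, 0.02)
        img[soma] = 1.0
        img[neurite] = 0.6
        res = region_coherency(FieldImage(pixels=img, bit_depth=32), _objects_from(soma), neurite)
        assert res.n_objects_used == 1
        assert res.image_coherency > 0.8

    def test_no_neurites_gives_missing(self):
        soma = np.zeros((64, 64), dtype=bool)
        soma[30:36, 30:36] = True
        img = FieldImage(pixels=soma.astype(float), bit_depth=32)
        res = region_coherency(img, _objects_from(soma), np.zeros((64, 64), dtype=bool))
        assert math.isnan(res.image_coherency) and res.n_objects_used == 0

    def test_values_bounded(self, default_timecourse):
        _, images, truth = default_timecourse
        img = rescale_minmax(images[-1])
        masks = segment(img)
        res = region_coherency(img, label_somata(masks), masks.neurite_mask)
        finite = res.per_object[np.isfinite(res.per_object)]
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_fasciculation_sweep_monotone(self):
        """Image coherency rises monotonically with fasciculation strength
        in dense cultures (several neurites per annulus sector)."""
        strengths = [0.0, 0.25, 0.5, 0.75, 1.0]
        values = []
        for f in strengths:
            acc = []
            for seed in (11, 12, 13):
                spec = CultureSpec(seed=seed, n_days=3, fasciculation_strength=f,
                                   n_somata_initial=18, n_neurites_per_soma=5)
                images, _ = generate_timecourse(spec)
                img = rescale_minmax(images[-1])
                masks = segment(img)
                res = region_coherency(img, label_somata(masks), masks.neurite_mask)
                acc.append(res.image_coherency)
            values.append(np.nanmean(acc))
        rho = spearmanr(strengths, values).statistic
        assert rho > 0.9


class TestSelectCoherencyFovs:
    def test_8x8_mosaic_thirds_rule(self):
        picks = select_coherency_fovs((8, 8))
        rows = sorted({p // 8 for p in picks})
        cols = sorted({p % 8 for p in picks})
        assert rows == [1, 4, 6] and cols == [1, 4, 6]
        assert len(picks) == 9

    def test_3x3_mosaic_takes_all(self):
        assert select_coherency_fovs((3, 3)) == list(range(9))

    def test_small_mosaic_uses_all(self):
        assert select_coherency_fovs((2, 2)) == [0, 1, 2, 3]
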