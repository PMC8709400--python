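import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petalvision._illuminants import d65_quanta, green_leaf_reflectance
from petalvision.spectra import Spectrum, make_grid
from petalvision.vision_models import (
    bee_hexagon,
    build_visual_system,
    butterfly_tetrahedron,
    catch_set,
    fly_categorical,
    load_default_config,
    luminance,
    pigment_template,
    quantum_catch,
    von_kries,
)

from .conftest import make_spectrum


class TestPigmentTemplate:
    @pytest.mark.parametrize("lmax", [330, 344, 436, 530, 556, 600])
    def test_peak_normalized_near_lambda_max(self, lmax):
        grid = make_grid(300, 700)
        s = pigment_template(lmax, grid)
        assert s.max() == pytest.approx(1.0)
        # α-peak sits at λmax; for UV pigments the nearby β-band can pull
        # the summed maximum a few nm short
        assert abs(grid[np.argmax(s)] - lmax) <= 6

    def test_unimodal_alpha_band(self):
        grid = make_grid(300, 700)
        for lmax in (440, 530, 600):
            s = pigment_template(lmax, grid)
            beta_peak = 189 + 0.315 * lmax
            lo = int(np.searchsorted(grid, max(beta_peak + 20, 300)))
            hi = int(np.searchsorted(grid, lmax))
            trough = np.argmin(s[lo:hi]) + lo
            # rising flank from the trough to the α peak: no local minima
            assert np.all(np.diff(s[trough:hi]) >= -1e-9)

    def test_flanks_bounded(self):
        grid = make_grid(300, 700)
        s = pigment_template(440, grid)
        for lam in (380, 500):
            v = s[int(np.searchsorted(grid, lam))]
            assert 0.0 < v < 1.0

    def test_lambda_max_out_of_range(self):
        with pytest.raises(ValueError, match="outside 300-700"):
            pigment_template(250, make_grid(300, 700))


class TestQuantumCatch:
    def test_unit_box_area(self):
        grid = make_grid(400, 500)
        ones = np.ones(grid.size)
        assert quantum_catch(ones, ones, ones, grid) == pytest.approx(100.0)

    def test_zero_reflectance_propagates_to_error(self):
        sys_ = build_visual_system("bee")
        sp = Spectrum(sys_.grid_nm, np.zeros(sys_.grid_nm.size), {"petal_id": "dark"})
        with pytest.raises(ValueError, match="zero quantum catch"):
            catch_set(sp, sys_)

    def test_matches_brute_force_trapezoid(self):
        grid = make_grid(400, 500, 1)
        tri = lambda c: np.clip(1 - np.abs(grid - c) / 50.0, 0, None)
        r, s, i = tri(420), tri(450), tri(480)
        # independent naive summation oracle
        total = 0.0
        for k in range(len(grid) - 1):
            f0 = r[k] * s[k] * i[k]
            f1 = r[k + 1] * s[k + 1] * i[k + 1]
            total += 0.5 * (f0 + f1) * (grid[k + 1] - grid[k])
        assert quantum_catch(r, s, i, grid) == pytest.approx(total, abs=1e-12)

    def test_von_kries_basics(self):
        assert von_kries(2.0, 1.0) == pytest.approx(2.0)
        assert von_kries(3.0, 3.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            von_kries(1.0, 0.0)


class TestVonKriesFixedPoint:
    """A petal spectrally identical to the background is achromatic."""

    @pytest.mark.parametrize("guild", ["bee", "fly", "butterfly"])
    def test_background_petal_is_achromatic(self, guild):
        sys_ = build_visual_system(guild)
        sp = Spectrum(sys_.grid_nm, sys_.background.copy(), {"petal_id": "leaf"})
        cs = catch_set(sp, sys_)
        for q in cs.adapted.values():
            assert q == pytest.approx(1.0, abs=1e-10)
        if guild == "bee":
            h = bee_hexagon(*(cs.adapted[k] for k in ("uv", "blue", "green")))
            assert abs(h.x) < 1e-10 and abs(h.y) < 1e-10
        elif guild == "fly":
            f = fly_categorical(*(cs.adapted[k] for k in ("r7p", "r7y", "r8p", "r8y")))
            assert abs(f.cx) < 1e-10 and abs(f.cy) < 1e-10
        else:
            t = butterfly_tetrahedron(*(cs.adapted[k] for k in ("u", "s", "m", "l")))
            assert np.linalg.norm([t.x, t.y, t.z]) < 1e-10


class TestHexagon:
    def test_equal_catches_center(self):
        h = bee_hexagon(1.0, 1.0, 1.0)
        assert (h.x, h.y) == (0.0, 0.0)
        assert h.sector == "achromatic"

    def test_pure_blue_vertex(self):
        h = bee_hexagon(1e-12, 1e12, 1e-12)
        assert h.x == pytest.approx(0.0, abs=1e-9)
        assert h.y == pytest.approx(1.0, abs=1e-9)
        assert h.sector == "Blue"

    def test_pure_green_vertex(self):
        h = bee_hexagon(1e-12, 1e-12, 1e12)
        assert h.x == pytest.approx(math.sqrt(3) / 2, abs=1e-9)
        assert h.y == pytest.approx(-0.5, abs=1e-9)
        assert h.sector == "Green"

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        q=st.tuples(
            st.floats(1e-6, 1e6), st.floats(1e-6, 1e6), st.floats(1e-6, 1e6)
        )
    )
    def test_locus_inside_unit_hexagon(self, q):
        h = bee_hexagon(*q)
        assert math.hypot(h.x, h.y) <= 1.0 + 1e-12

    def test_rejects_non_positive_catch(self):
        with pytest.raises(ValueError):
            bee_hexagon(0.0, 1.0, 1.0)


class TestFlyCategorical:
    def test_equal_catches_boundary(self):
        f = fly_categorical(1.0, 1.0, 1.0, 1.0)
        assert f.category == "boundary"

    def test_same_quadrant_same_category(self):
        a = fly_categorical(1.2, 0.9, 1.0, 1.0)   # (+, -)
        b = fly_categorical(1.1, 0.7, 1.0, 1.0)   # (+, -)
        assert a.category == b.category

    def test_quadrant_change_changes_category(self):
        a = fly_categorical(1.2, 1.1, 1.0, 1.0)   # (+, +)
        b = fly_categorical(1.2, 0.9, 1.0, 1.0)   # (+, -)
        assert a.category != b.category

    def test_illuminant_scaling_cancels(self):
        """Scaling the illuminant cancels in von Kries adaptation."""
        cfg = load_default_config()
        sys1 = build_visual_system("fly", config=cfg)
        sys2 = build_visual_system("fly", config=cfg)
        sys2.illuminant = 3.7 * sys2.illuminant
        rng = np.random.default_rng(0)
        r = rng.uniform(0.1, 0.9, sys1.grid_nm.size)
        sp = Spectrum(sys1.grid_nm, r, {"petal_id": "x"})
        q1 = catch_set(sp, sys1).adapted
        q2 = catch_set(sp, sys2).adapted
        for k in q1:
            assert q2[k] == pytest.approx(q1[k], rel=1e-12)


class TestTetrahedron:
    def test_equal_catches_centroid(self):
        t = butterfly_tetrahedron(1.0, 1.0, 1.0, 1.0)
        assert np.allclose([t.x, t.y, t.z], 0.0)
        assert sum(t.relative.values()) == pytest.approx(1.0)

    def test_pure_uv_maps_to_u_vertex(self):
        t = butterfly_tetrahedron(1.0, 1e-12, 1e-12, 1e-12)
        assert np.allclose([t.x, t.y, t.z], [0, 0, 1], atol=1e-9)
        assert math.dist([t.x, t.y, t.z], [0, 0, 0]) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        q=st.tuples(*(st.floats(1e-3, 1e3) for _ in range(4))),
        c=st.floats(1e-3, 1e3),
    )
    def test_relative_catches_scale_invariant_and_sum_one(self, q, c):
        t1 = butterfly_tetrahedron(*q)
        t2 = butterfly_tetrahedron(*(c * v for v in q))
        assert sum(t1.relative.values()) == pytest.approx(1.0, abs=1e-12)
        for k in t1.relative:
            assert t2.relative[k] == pytest.approx(t1.relative[k], rel=1e-9)


class TestLuminance:
    def test_bee_luminance_is_green_catch(self):
        sys_ = build_visual_system("bee")
        rng = np.random.default_rng(5)
        sp = Spectrum(
            sys_.grid_nm, rng.uniform(0.2, 0.8, sys_.grid_nm.size), {"petal_id": "x"}
        )
        cs = catch_set(sp, sys_)
        assert luminance(cs, sys_) == cs.adapted["green"]

    def test_background_luminance_is_one(self):
        sys_ = build_visual_system("butterfly")
        sp = Spectrum(sys_.grid_nm, sys_.background.copy(), {"petal_id": "leaf"})
        assert luminance(catch_set(sp, sys_), sys_) == pytest.approx(1.0, abs=1e-12)

    def test_doubling_reflectance_doubles_luminance(self):
        sys_ = build_visual_system("fly")
        rng = np.random.default_rng(6)
        r = rng.uniform(0.1, 0.45, sys_.grid_nm.size)
        l1 = luminance(catch_set(Spectrum(sys_.grid_nm, r, {"petal_id": "a"}), sys_), sys_)
        l2 = luminance(
            catch_set(Spectrum(sys_.grid_nm, 2 * r, {"petal_id": "a"}), sys_), sys_
        )
        assert l2 == pytest.approx(2 * l1, rel=1e-12)


def _hexagon_oracle(reflectance, grid):
    """Independent brute-force bee hexagon locus: naive loops throughout."""
    cfg = load_default_config()
    lmaxes = cfg["guilds"]["bee"]["receptors"]
    illum = d65_quanta(grid)
    background = green_leaf_reflectance(grid)
    es = {}
    for name in ("uv", "blue", "green"):
        s = pigment_template(float(lmaxes[name]), grid)
        q_num = 0.0
        q_den = 0.0
        for k in range(len(grid) - 1):
            dl = grid[k + 1] - grid[k]
            q_num += 0.5 * (
                reflectance[k] * s[k] * illum[k]
                + reflectance[k + 1] * s[k + 1] * illum[k + 1]
            ) * dl
            q_den += 0.5 * (
                background[k] * s[k] * illum[k]
                + background[k + 1] * s[k + 1] * illum[k + 1]
            ) * dl
        q = q_num / q_den
        es[name] = q / (q + 1.0)
    x = (math.sqrt(3) / 2.0) * (es["green"] - es["uv"])
    y = es["blue"] - (es["uv"] + es["green"]) / 2.0
    return x, y


def test_hexagon_matches_brute_force_oracle():
    """10 random spectra: pipeline hexagon coordinates vs naive-loop oracle."""
    sys_ = build_visual_system("bee")
    rng = np.random.default_rng(123)
    for _ in range(10):
        r = rng.uniform(0.02, 0.95, sys_.grid_nm.size)
        cs = catch_set(Spectrum(sys_.grid_nm, r, {"petal_id": "x"}), sys_)
        h = bee_hexagon(*(cs.adapted[k] for k in ("uv", "blue", "green")))
        ox, oy = _hexagon_oracle(r, sys_.grid_nm)
        assert h.x == pytest.approx(ox, abs=1e-10)
        assert h.y == pytest.approx(oy, abs=1e-10)
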