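"""Hexagon colour-space modelling of reflectance spectra."""

import numpy as np
import pytest

from floracues.colorvision import (
    DEFAULT_GRID,
    HexagonLocus,
    ReflectanceSpectrum,
    SpectrumError,
    VisionContext,
    detectable_against_background,
    discriminability,
    govardovskii_template,
    hexagon_distance,
    hexagon_locus,
    mean_species_spectrum,
    quantum_catch,
    receptor_excitation,
    resample_spectrum,
    spectrum_locus,
)


def spec(values, wl=None, part="mean", rid="r1", species="sp"):
    wl = DEFAULT_GRID if wl is None else np.asarray(wl, float)
    return ReflectanceSpectrum(species, rid, part, wl, np.asarray(values, float))


@pytest.fixture(scope="module")
def ctx():
    return VisionContext.default()


class TestResample:
    def test_identity_on_same_grid(self):
        s = spec(np.linspace(0, 50, 41))
        out = resample_spectrum(s, DEFAULT_GRID)
        np.testing.assert_allclose(out.reflectance, s.reflectance)

    def test_linear_midpoint(self):
        s = spec([10.0, 30.0], wl=[300.0, 320.0])
        out = resample_spectrum(s, np.array([310.0]))
        assert out.reflectance[0] == pytest.approx(20.0)

    def test_outside_span_rejected(self):
        s = spec(np.ones(41))
        with pytest.raises(SpectrumError, match="span"):
            resample_spectrum(s, np.array([290.0, 300.0]))


class TestMeanSpectrum:
    def test_tip_base_then_flower_average(self):
        reps = []
        for fid, level in (("f1", 10.0), ("f2", 20.0), ("f3", 30.0)):
            reps.append(spec(np.full(41, level - 5), part="tip", rid=fid))
            reps.append(spec(np.full(41, level + 5), part="base", rid=fid))
        m = mean_species_spectrum(reps)
        np.testing.assert_allclose(m.reflectance, 20.0)
        assert m.part == "mean"

    def test_single_flower_tip_base(self):
        reps = [spec(np.full(41, 40.0), part="tip"),
                spec(np.full(41, 60.0), part="base")]
        np.testing.assert_allclose(
            mean_species_spectrum(reps).reflectance, 50.0
        )

    def test_missing_base_rejected(self):
        reps = [spec(np.full(41, 40.0), part="tip", rid="f1"),
                spec(np.full(41, 60.0), part="base", rid="f1"),
                spec(np.full(41, 10.0), part="tip", rid="f2")]
        with pytest.raises(SpectrumError, match="f2"):
            mean_species_spectrum(reps)


class TestQuantumCatch:
    def test_background_gives_unit_catch(self, ctx):
        bg = spec(ctx.background)
        for curve in ctx.sensitivities.values():
            assert quantum_catch(bg, curve, ctx) == pytest.approx(1.0)

    def test_linearity_in_stimulus(self, ctx):
        twice = spec(2.0 * ctx.background)
        curve = ctx.sensitivities["green"]
        assert quantum_catch(twice, curve, ctx) == pytest.approx(2.0)

    def test_black_stimulus(self, ctx):
        black = spec(np.zeros(41))
        assert quantum_catch(black, ctx.sensitivities["uv"], ctx) == 0.0

    def test_degenerate_background_raises(self, ctx):
        bad = VisionContext(
            ctx.wavelengths_nm, dict(ctx.sensitivities),
            ctx.illuminant, np.zeros(41),
        )
        with pytest.raises(FloatingPointError):
            quantum_catch(spec(np.ones(41)), bad.sensitivities["uv"], bad)


class TestExcitation:
    @pytest.mark.parametrize("P,E", [(0.0, 0.0), (1.0, 0.5), (3.0, 0.75)])
    def test_hyperbolic_transduction(self, P, E):
        assert receptor_excitation(P) == pytest.approx(E)

    def test_negative_catch_rejected(self):
        with pytest.raises(ValueError):
            receptor_excitation(-0.1)


class TestHexagon:
    def test_background_point_is_achromatic_centre(self):
        l = hexagon_locus(0.5, 0.5, 0.5)
        assert (l.x, l.y) == (0.0, 0.0)
        assert l.category == "achromatic"

    def test_blue_axis(self):
        l = hexagon_locus(0.5, 1.0, 0.5)
        assert l.x == pytest.approx(0.0)
        assert l.y == pytest.approx(0.5)
        assert l.category == "blue"

    def test_green_axis(self):
        l = hexagon_locus(0.0, 0.0, 1.0)
        assert l.x == pytest.approx(np.sqrt(3) / 2)
        assert l.y == pytest.approx(-0.5)
        assert l.category == "green"

    def test_uv_axis(self):
        assert hexagon_locus(1.0, 0.0, 0.0).category == "UV"

    def test_category_partition_is_total(self, rng):
        # every non-centre point gets exactly one of the six labels
        cats = set()
        for _ in range(500):
            e = rng.uniform(0, 1, size=3)
            l = hexagon_locus(*e)
            if l.category != "achromatic":
                cats.add(l.category)
            assert l.category in {
                "blue", "UV-blue", "UV", "UV-green", "green",
                "blue-green", "achromatic",
            }
        assert len(cats) >= 4  # random excitations populate many sectors

    def test_distance_metric_properties(self, rng):
        pts = [hexagon_locus(*rng.uniform(0, 1, 3)) for _ in range(6)]
        for a in pts:
            assert hexagon_distance(a, a) == 0.0
            for b in pts:
                assert hexagon_distance(a, b) == pytest.approx(
                    hexagon_distance(b, a)
                )
                for c in pts:
                    assert (
                        hexagon_distance(a, c)
                        <= hexagon_distance(a, b) + hexagon_distance(b, c)
                        + 1e-12
                    )

    def test_unit_separation_example(self):
        a = hexagon_locus(0.5, 0.5, 0.5)
        b = hexagon_locus(0.5, 1.0, 0.5)
        assert hexagon_distance(a, b) == pytest.approx(0.5)


class TestDiscriminability:
    @pytest.mark.parametrize(
        "d,label",
        [(0.03, "poor"), (0.07, "intermediate"), (0.13, "easy")],
    )
    def test_behavioural_thresholds(self, d, label):
        assert discriminability(d) == label

    def test_detectability_uses_the_easy_cut(self):
        near = HexagonLocus(0, 0, 0, 0.05, 0.0, "blue-green")
        far = HexagonLocus(0, 0, 0, 0.3, 0.0, "blue-green")
        assert not detectable_against_background(near)
        assert detectable_against_background(far)


class TestVisionInvariants:
    def test_background_maps_to_centre_for_any_context(self, rng):
        wl = DEFAULT_GRID
        for _ in range(5):
            ctx = VisionContext(
                wavelengths_nm=wl,
                sensitivities={
                    "uv": rng.uniform(0.01, 1, 41),
                    "blue": rng.uniform(0.01, 1, 41),
                    "green": rng.uniform(0.01, 1, 41),
                },
                illuminant=rng.uniform(0.1, 100, 41),
                background=rng.uniform(0.01, 0.5, 41),
            )
            l = spectrum_locus(spec(ctx.background), ctx)
            assert abs(l.x) < 1e-9 and abs(l.y) < 1e-9

    def test_illuminant_scaling_cancels(self, ctx, rng):
        stim = spec(rng.uniform(0, 0.6, 41))
        scaled = VisionContext(
            ctx.wavelengths_nm, dict(ctx.sensitivities),
            ctx.illuminant * 13.7, ctx.background,
        )
        a = spectrum_locus(stim, ctx)
        b = spectrum_locus(stim, scaled)
        assert a.x == pytest.approx(b.x, abs=1e-12)
        assert a.y == pytest.approx(b.y, abs=1e-12)

    def test_single_receptor_stimulus_lands_on_its_axis(self):
        # excitations crafted so only one receptor leaves adaptation level
        axes = {
            "uv": (1.0, 0.5, 0.5, 210.0),
            "blue": (0.5, 1.0, 0.5, 90.0),
            "green": (0.5, 0.5, 1.0, 330.0),
        }
        for eu, eb, eg, expected_deg in axes.values():
            l = hexagon_locus(eu, eb, eg)
            ang = np.degrees(np.arctan2(l.y, l.x)) % 360
            assert ang == pytest.approx(expected_deg, abs=1e-9)

    def test_percent_and_fraction_spectra_agree(self, ctx):
        frac = spec(np.linspace(0.05, 0.6, 41))
        perc = spec(np.linspace(0.05, 0.6, 41) * 100)
        la, lb = spectrum_locus(frac, ctx), spectrum_locus(perc, ctx)
        assert la.x == pytest.approx(lb.x)
        assert la.y == pytest.approx(lb.y)


class TestTemplates:
    def test_receptor_templates_peak_at_lambda_max(self):
        wl = np.arange(300, 701, 1.0)
        for lmax in (344.0, 436.0, 544.0):
            s = govardovskii_template(wl, lmax)
            assert abs(wl[np.argmax(s)] - lmax) <= 3.0
            assert s.max() == pytest.approx(1.0)
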