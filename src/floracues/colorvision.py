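"""Bee colour-hexagon modelling of reflectance spectra.

A flower's reflectance spectrum is turned into the quantum catches of
the three bee photoreceptors (UV, blue, green) under a daylight
illuminant, von-Kries-adapted to a green-foliage background, passed
through the hyperbolic transduction E = P/(P+1), and projected into the
2-D hexagon colour space. Euclidean distance in that space approximates
behavioural discriminability: below 0.05 hexagon units two colours are
poorly discriminated, above 0.10 easily.

The shipped vision context uses honeybee-like receptor sensitivities
built from the Govardovskii rhodopsin template (lambda_max 344, 436 and
544 nm), the CIE D65 daylight spectrum tabulated at 10 nm, and a smooth
typical green-leaf reflectance; each component can be overridden with a
user-supplied curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

DEFAULT_GRID = np.arange(300, 701, 10, dtype=float)

# CIE standard illuminant D65, relative spectral power at 10 nm steps,
# 300-700 nm (normalised to 100 at 560 nm).
_D65 = np.array([
    0.0341, 3.2945, 20.2360, 37.0535, 39.9488, 44.9117, 46.6383, 52.0891,
    49.9755, 54.6482, 82.7549, 91.4860, 93.4318, 86.6823, 104.8650,
    117.0080, 117.8120, 114.8610, 115.9230, 108.8110, 109.3540, 107.8020,
    104.7900, 107.6890, 104.4050, 104.0460, 100.0000, 96.3342, 95.7880,
    88.6856, 90.0062, 89.5991, 87.6987, 83.2886, 83.6992, 80.0268,
    80.2146, 82.2778, 78.2842, 69.7213, 71.6091,
])

RECEPTOR_NAMES = ("uv", "blue", "green")
BEE_LAMBDA_MAX = {"uv": 344.0, "blue": 436.0, "green": 544.0}

CATEGORIES = ("blue", "UV-blue", "UV", "UV-green", "green", "blue-green")


class SpectrumError(ValueError):
    """Invalid spectrum input."""


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """One reflectance measurement on a wavelength grid.

    ``reflectance`` may be in percent or as fractions; percent is
    auto-detected (max > 1.5) and normalised when the spectrum enters
    the vision model.
    """

    species: str
    replicate_id: str
    part: str  # {"tip", "base", "mean"}
    wavelengths_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", rf)
        if wl.ndim != 1 or wl.shape != rf.shape:
            raise SpectrumError("wavelength and reflectance grids differ")
        if len(wl) < 1 or np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if np.any(rf < 0):
            raise SpectrumError("reflectance must be non-negative")

    def as_fraction(self) -> np.ndarray:
        """Reflectance as fractions; percent detected when max > 1.5."""
        if self.reflectance.max() > 1.5:
            return self.reflectance / 100.0
        return self.reflectance


@dataclass(frozen=True)
class VisionContext:
    """Receptor sensitivities, illuminant and adapting background.

    All curves share one wavelength grid; curves supplied on other grids
    must be resampled first. ``background`` is a reflectance spectrum
    (fractions or percent, like any stimulus).
    """

    wavelengths_nm: np.ndarray
    sensitivities: dict  # receptor name -> curve on the grid
    illuminant: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        for name in RECEPTOR_NAMES:
            if name not in self.sensitivities:
                raise ValueError(f"missing sensitivity curve: {name}")
        for name, curve in self.sensitivities.items():
            c = np.asarray(curve, dtype=float)
            if c.shape != wl.shape or np.any(c < 0):
                raise ValueError(f"bad sensitivity curve for {name}")
            self.sensitivities[name] = c
        for attr in ("illuminant", "background"):
            c = np.asarray(getattr(self, attr), dtype=float)
            if c.shape != wl.shape or np.any(c < 0):
                raise ValueError(f"{attr} curve does not match the grid")
            object.__setattr__(self, attr, c)

    @classmethod
    def default(cls, grid: np.ndarray = DEFAULT_GRID) -> "VisionContext":
        """Honeybee-like context on the 300-700 nm, 10 nm grid."""
        grid = np.asarray(grid, dtype=float)
        sens = {
            name: govardovskii_template(grid, lmax)
            for name, lmax in BEE_LAMBDA_MAX.items()
        }
        if np.array_equal(grid, DEFAULT_GRID):
            illum = _D65.copy()
        else:
            illum = np.interp(grid, DEFAULT_GRID, _D65)
        return cls(
            wavelengths_nm=grid,
            sensitivities=sens,
            illuminant=illum,
            background=green_leaf_reflectance(grid),
        )


def govardovskii_template(wl: np.ndarray, lmax: float) -> np.ndarray:
    """Rhodopsin absorbance template (alpha + beta band), peak-normalised."""
    wl = np.asarray(wl, dtype=float)
    x = lmax / wl
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lmax
    bw = -40.5 + 0.195 * lmax
    beta = 0.26 * np.exp(-(((wl - lmb) / bw) ** 2))
    s = alpha + beta
    return s / s.max()


def green_leaf_reflectance(wl: np.ndarray) -> np.ndarray:
    """Smooth typical green-leaf reflectance (fractions).

    Low in the UV and blue, a chlorophyll bump near 550 nm, and a
    moderate rise beyond 680 nm toward the red edge.
    """
    wl = np.asarray(wl, dtype=float)
    base = 0.04
    bump = 0.11 * np.exp(-(((wl - 550.0) / 45.0) ** 2))
    red_edge = 0.30 / (1.0 + np.exp(-(wl - 715.0) / 18.0))
    return base + bump + red_edge


# ----------------------------------------------------------- operations


def resample_spectrum(
    spectrum: ReflectanceSpectrum, grid: np.ndarray
) -> ReflectanceSpectrum:
    """Linear interpolation onto a new grid inside the measured span."""
    grid = np.asarray(grid, dtype=float)
    wl = spectrum.wavelengths_nm
    if grid.min() < wl.min() or grid.max() > wl.max():
        raise SpectrumError(
            f"requested grid [{grid.min()}, {grid.max()}] outside measured "
            f"span [{wl.min()}, {wl.max()}]"
        )
    values = np.interp(grid, wl, spectrum.reflectance)
    return replace(spectrum, wavelengths_nm=grid, reflectance=values)


def mean_species_spectrum(
    replicates: list[ReflectanceSpectrum],
) -> ReflectanceSpectrum:
    """Species mean spectrum: per-flower tip/base mean, then across flowers.

    Every flower (replicate id) must contribute exactly one tip and one
    base measurement on a common grid.
    """
    if not replicates:
        raise SpectrumError("no replicates given")
    grid = replicates[0].wavelengths_nm
    species = replicates[0].species
    flowers: dict[str, dict[str, ReflectanceSpectrum]] = {}
    for sp in replicates:
        if not np.array_equal(sp.wavelengths_nm, grid):
            raise SpectrumError("replicates are on different grids")
        if sp.part not in ("tip", "base"):
            raise SpectrumError(f"unexpected part {sp.part!r}")
        slot = flowers.setdefault(sp.replicate_id, {})
        if sp.part in slot:
            raise SpectrumError(
                f"duplicate {sp.part} measurement for flower {sp.replicate_id}"
            )
        slot[sp.part] = sp
    per_flower = []
    for rid, slot in flowers.items():
        if "tip" not in slot or "base" not in slot:
            raise SpectrumError(f"flower {rid} lacks a tip or base measurement")
        per_flower.append(
            0.5 * (slot["tip"].reflectance + slot["base"].reflectance)
        )
    return ReflectanceSpectrum(
        species=species,
        replicate_id="mean",
        part="mean",
        wavelengths_nm=grid,
        reflectance=np.mean(per_flower, axis=0),
    )


def quantum_catch(
    stimulus: ReflectanceSpectrum, receptor: np.ndarray, ctx: VisionContext
) -> float:
    """Von-Kries-normalised quantum catch.

    P = sum I_S(l) S(l) D(l) / sum I_B(l) S(l) D(l), a rectangle sum on
    the common uniform grid; the adapting background itself gives P = 1.
    """
    if not np.array_equal(stimulus.wavelengths_nm, ctx.wavelengths_nm):
        raise SpectrumError("stimulus not on the vision-context grid")
    receptor = np.asarray(receptor, dtype=float)
    bg = ctx.background / 100.0 if ctx.background.max() > 1.5 else ctx.background
    denom = float(np.sum(bg * receptor * ctx.illuminant))
    if denom <= 0:
        raise FloatingPointError(
            "degenerate background/sensitivity: zero adapting catch"
        )
    num = float(np.sum(stimulus.as_fraction() * receptor * ctx.illuminant))
    return num / denom


def receptor_excitation(P: float) -> float:
    """Hyperbolic transduction E = P/(P+1); E(1) = 0.5, E -> 1 as P -> inf."""
    if P < 0:
        raise ValueError("quantum catch must be non-negative")
    return P / (P + 1.0)


@dataclass(frozen=True)
class HexagonLocus:
    """A point in the bee colour hexagon with its colour category."""

    E_U: float
    E_B: float
    E_G: float
    x: float
    y: float
    category: str

    def distance_to(self, other: "HexagonLocus") -> float:
        return hexagon_distance(self, other)


_ACHROMATIC_RADIUS = 1e-9


def _category_from_xy(x: float, y: float) -> str:
    if np.hypot(x, y) < _ACHROMATIC_RADIUS:
        return "achromatic"
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    # receptor axes: blue at 90, UV at 210, green at 330 degrees;
    # sector boundaries on the midlines 0, 60, ..., 300
    if 60 <= ang < 120:
        return "blue"
    if 120 <= ang < 180:
        return "UV-blue"
    if 180 <= ang < 240:
        return "UV"
    if 240 <= ang < 300:
        return "UV-green"
    if 300 <= ang < 360:
        return "green"
    return "blue-green"  # [0, 60)


def hexagon_locus(E_U: float, E_B: float, E_G: float) -> HexagonLocus:
    """Project receptor excitations into the hexagon.

    x = (sqrt(3)/2)(E_G - E_U), y = E_B - (E_U + E_G)/2. The uniformly
    half-excited (background-adapted) point maps to the centre and is
    labelled achromatic.
    """
    for e in (E_U, E_B, E_G):
        if not 0.0 <= e <= 1.0:
            raise ValueError("excitations must lie in [0, 1]")
    x = (np.sqrt(3.0) / 2.0) * (E_G - E_U)
    y = E_B - (E_U + E_G) / 2.0
    return HexagonLocus(E_U, E_B, E_G, float(x), float(y),
                        _category_from_xy(float(x), float(y)))


def spectrum_locus(
    spectrum: ReflectanceSpectrum, ctx: VisionContext
) -> HexagonLocus:
    """Full stimulus-to-locus chain for one spectrum."""
    E = {
        name: receptor_excitation(
            quantum_catch(spectrum, ctx.sensitivities[name], ctx)
        )
        for name in RECEPTOR_NAMES
    }
    return hexagon_locus(E["uv"], E["blue"], E["green"])


def hexagon_distance(a: HexagonLocus, b: HexagonLocus) -> float:
    """Euclidean distance between two loci, in hexagon units."""
    return float(np.hypot(a.x - b.x, a.y - b.y))


DISCRIMINATION_POOR = 0.05
DISCRIMINATION_EASY = 0.10


def discriminability(d: float) -> str:
    """Behavioural discriminability class of a hexagon distance.

    Below 0.05 hexagon units colours are poorly discriminated, above
    0.10 easily; the same 0.10 cut flags detectability against the
    (centre-mapped) background.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d < DISCRIMINATION_POOR:
        return "poor"
    if d > DISCRIMINATION_EASY:
        return "easy"
    return "intermediate"


def detectable_against_background(locus: HexagonLocus) -> bool:
    """Distance from the uncoloured point exceeds 0.10 hexagon units."""
    return float(np.hypot(locus.x, locus.y)) > DISCRIMINATION_EASY
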