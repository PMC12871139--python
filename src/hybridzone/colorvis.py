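"""Spectral color metrics and receptor-noise pollinator visual models.

Segment-classification hue/chroma and 400-700 nm brightness describe a
spectrum without reference to a viewer.  The visual models compute photon
(quantum) catches of a receptor set against a reflectance spectrum,
chromatic contrasts in just-noticeable differences (JNDs) under the
receptor-noise-limited model, and coordinates in the bee colour hexagon.

Receptor spectral sensitivities are Govardovskii A1 visual-pigment templates
generated from lambda-max, normalised to unit area; the default receptor
sets (honeybee UV/S/M at 344/436/544 nm with 1:2:1 densities; average
violet-sensitive avian at 416/455/508/568 nm with 1:1:1:2) are literature
conventions and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-gridded reflectance; negative values are clipped to 0."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.shape != r.shape:
            raise ValueError("wavelengths and reflectance differ in length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", np.clip(r, 0.0, None))

    def interp(self, grid: np.ndarray) -> np.ndarray:
        return np.interp(grid, self.wavelengths, self.reflectance)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.reflectance * factor)


@dataclass(frozen=True)
class VisualSystem:
    """A receptor set: lambda-max values, relative densities, Weber fraction.

    The achromatic receptor is the longest-wavelength one; receptor noise is
    density-based ("neural"): e_i = w * sqrt(d_max / d_i) with d_max the
    density of the most abundant receptor class.
    """

    name: str
    lambda_max: tuple
    densities: tuple
    weber: float = 0.1

    def __post_init__(self):
        if len(self.lambda_max) != len(self.densities):
            raise ValueError("lambda_max and densities differ in length")
        if list(self.lambda_max) != sorted(self.lambda_max):
            raise ValueError("lambda_max must ascend")
        if any(d <= 0 for d in self.densities):
            raise ValueError("densities must be positive")

    @property
    def n_receptors(self) -> int:
        return len(self.lambda_max)

    def noise(self) -> np.ndarray:
        d = np.asarray(self.densities, dtype=float)
        return self.weber * np.sqrt(d.max() / d)


HONEYBEE = VisualSystem("honeybee", (344.0, 436.0, 544.0), (1.0, 2.0, 1.0))
AVIAN_VS = VisualSystem("avian_violet", (416.0, 455.0, 508.0, 568.0),
                        (1.0, 1.0, 1.0, 2.0))


@dataclass
class ColorLocus:
    """Per-receptor quantum catches, optionally hyperbolic-transformed."""

    Q: np.ndarray
    E: np.ndarray | None = None


# ---------------------------------------------------------------------------
# viewer-independent metrics


def segment_color_metrics(s: Spectrum):
    """Segment-classification (hue_deg, chroma, brightness).

    Brightness is the trapezoidal area of reflectance over 400-700 nm; that
    range is split into four equal segments with relative signals S1..S4
    (segment areas / brightness); chroma = sqrt((S4-S2)^2 + (S3-S1)^2) and
    hue = atan2(S4-S2, S3-S1) mapped to [0, 360).  A zero-brightness
    spectrum has chroma 0 and undefined (NaN) hue.
    """
    if s.wavelengths[0] > 400.0 or s.wavelengths[-1] < 700.0:
        raise ValueError("spectrum must cover 400-700 nm")
    edges = np.linspace(400.0, 700.0, 5)
    seg = np.empty(4)
    for i in range(4):
        grid = np.linspace(edges[i], edges[i + 1], 76)
        seg[i] = np.trapezoid(s.interp(grid), grid)
    brightness = seg.sum()
    if brightness <= 0:
        return np.nan, 0.0, 0.0
    rel = seg / brightness
    y = rel[3] - rel[1]
    x = rel[2] - rel[0]
    chroma = float(np.hypot(y, x))
    hue = float(np.degrees(np.arctan2(y, x))) % 360.0
    return hue, chroma, float(brightness)


def modified_hue(hue_deg: float) -> float:
    """Rotate hue so redder flowers always score higher.

    hue > 270 -> hue - 270; hue < 270 -> hue + 90; exactly 270 (the bluest
    value) -> 0.
    """
    hue_deg = float(hue_deg)
    if hue_deg > 270.0:
        return hue_deg - 270.0
    if hue_deg < 270.0:
        return hue_deg + 90.0
    return 0.0


# ---------------------------------------------------------------------------
# visual models


def govardovskii_template(wl: np.ndarray, lmax: float) -> np.ndarray:
    """Govardovskii et al. A1 visual-pigment absorbance template
    (alpha + beta band), unnormalised."""
    wl = np.asarray(wl, dtype=float)
    x = lmax / wl
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    lmb = 189.0 + 0.315 * lmax
    bwidth = -40.5 + 0.195 * lmax
    beta = 0.26 * np.exp(-(((wl - lmb) / bwidth) ** 2))
    return alpha + beta


def receptor_sensitivities(vs: VisualSystem, wl: np.ndarray) -> np.ndarray:
    """Unit-area sensitivity curves, shape (n_receptors, len(wl))."""
    out = np.stack([govardovskii_template(wl, lm) for lm in vs.lambda_max])
    area = np.trapezoid(out, wl, axis=1)
    return out / area[:, None]


def quantum_catch(s: Spectrum, vs: VisualSystem, illuminant: str = "ideal",
                  background: Spectrum | None = None, von_kries: bool = False,
                  transform: str = "none", wl_min: float = 300.0,
                  wl_max: float = 700.0, wl_step: float = 1.0) -> ColorLocus:
    """Quantum catches Q_i = integral of R * S_i * I over 300-700 nm.

    Spectra are linearly resampled to a common 1 nm grid; the "ideal"
    illuminant is flat (I = 1), "green_foliage" uses the background spectrum
    as the adapting surround only (the illuminant stays flat, as in ideal
    viewing conditions).  With ``von_kries`` each Q_i is divided by the
    background's Q_i; ``transform="hyperbolic"`` adds E_i = Q_i / (Q_i + 1).
    """
    if von_kries and background is None:
        raise ValueError("von Kries correction requires a background spectrum")
    wl = np.arange(wl_min, wl_max + wl_step / 2, wl_step)
    S = receptor_sensitivities(vs, wl)
    R = s.interp(wl)
    Q = np.trapezoid(R[None, :] * S, wl, axis=1)
    if von_kries:
        Rb = background.interp(wl)
        Qb = np.trapezoid(Rb[None, :] * S, wl, axis=1)
        if np.any(Qb <= 0):
            raise ValueError("background quantum catch is zero for a receptor")
        Q = Q / Qb
    E = Q / (Q + 1.0) if transform == "hyperbolic" else None
    return ColorLocus(Q=Q, E=E)


def jnd_contrast(a: ColorLocus, b: ColorLocus, vs: VisualSystem) -> float:
    """Receptor-noise chromatic contrast (delta S, in JND units).

    Receptor signals are f_i = ln(Q_i^a / Q_i^b); noise e_i from the visual
    system's densities and Weber fraction.  Implements the standard
    Vorobyev-Osorio formulas for 2, 3 and 4 receptor classes; symmetric and
    nonnegative.  Values < 1 JND are conventionally indistinguishable.
    """
    Qa, Qb = np.asarray(a.Q, float), np.asarray(b.Q, float)
    if np.any(Qa <= 0) or np.any(Qb <= 0):
        raise ValueError("JND contrast undefined for zero quantum catch")
    f = np.log(Qa / Qb)
    e = vs.noise()
    n = len(f)
    if n == 2:
        num = (f[0] - f[1]) ** 2
        den = e[0] ** 2 + e[1] ** 2
    elif n == 3:
        num = (e[0] ** 2 * (f[1] - f[2]) ** 2
               + e[1] ** 2 * (f[0] - f[2]) ** 2
               + e[2] ** 2 * (f[0] - f[1]) ** 2)
        den = ((e[0] * e[1]) ** 2 + (e[0] * e[2]) ** 2 + (e[1] * e[2]) ** 2)
    elif n == 4:
        num = ((e[0] * e[1]) ** 2 * (f[3] - f[2]) ** 2
               + (e[0] * e[2]) ** 2 * (f[3] - f[1]) ** 2
               + (e[0] * e[3]) ** 2 * (f[2] - f[1]) ** 2
               + (e[1] * e[2]) ** 2 * (f[3] - f[0]) ** 2
               + (e[1] * e[3]) ** 2 * (f[2] - f[0]) ** 2
               + (e[2] * e[3]) ** 2 * (f[1] - f[0]) ** 2)
        den = ((e[0] * e[1] * e[2]) ** 2 + (e[0] * e[1] * e[3]) ** 2
               + (e[0] * e[2] * e[3]) ** 2 + (e[1] * e[2] * e[3]) ** 2)
    else:
        raise ValueError("2-4 receptor classes supported")
    return float(np.sqrt(num / den))


def achromatic_contrast(a: ColorLocus, b: ColorLocus, vs: VisualSystem
                        ) -> float:
    """Long-wavelength-receptor (achromatic) contrast in Weber units."""
    i = vs.n_receptors - 1
    if a.Q[i] <= 0 or b.Q[i] <= 0:
        raise ValueError("achromatic contrast undefined for zero catch")
    return float(abs(np.log(a.Q[i] / b.Q[i])) / vs.noise()[i])


def hexagon_coords(locus: ColorLocus):
    """Bee colour-hexagon coordinates from hyperbolic catches (UV, B, G).

    x = (sqrt(3)/2) (E_G - E_UV); y = E_B - (E_UV + E_G)/2.  The adapted
    background (E = 0.5 everywhere) maps to the origin.
    """
    if locus.E is None or len(locus.E) != 3:
        raise ValueError("hexagon requires hyperbolic E for a trichromat")
    e_uv, e_b, e_g = locus.E
    x = (np.sqrt(3.0) / 2.0) * (e_g - e_uv)
    y = e_b - (e_uv + e_g) / 2.0
    return float(x), float(y)


def group_contrast_summary(spectra: dict, group_of: dict, vs: VisualSystem,
                           background: Spectrum):
    """Per-sample JND of flower vs background, group means, ANOVA + Tukey.

    ``spectra`` maps sample id -> Spectrum; ``group_of`` maps sample id ->
    group label.  Groups of size 1 are excluded from the tests with a
    warning.  Returns (per-sample DataFrame, group-mean Series, anova F and
    p, Tukey result table).
    """
    bg_locus = quantum_catch(background, vs)
    rows = []
    for sid, spec in spectra.items():
        locus = quantum_catch(spec, vs)
        rows.append((sid, group_of[sid],
                     jnd_contrast(locus, bg_locus, vs)))
    df = pd.DataFrame(rows, columns=["sample", "group", "jnd"])
    sizes = df.groupby("group")["jnd"].size()
    small = sizes[sizes < 2].index
    if len(small):
        import warnings
        warnings.warn(f"groups excluded from tests (n < 2): {list(small)}",
                      stacklevel=2)
    test_df = df[~df["group"].isin(small)]
    groups = [g["jnd"].to_numpy() for _, g in test_df.groupby("group")]
    if len(groups) >= 2:
        if np.ptp(np.concatenate(groups)) == 0:  # all values identical
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*groups)
        if np.ptp(test_df["jnd"].to_numpy()) == 0:
            labels = sorted(test_df["group"].unique())
            pairs = [(a, b) for i, a in enumerate(labels)
                     for b in labels[i + 1:]]
            tukey_frame = pd.DataFrame(
                [(a, b, 0.0, 1.0) for a, b in pairs],
                columns=["group1", "group2", "meandiff", "p-adj"])
        else:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd
            tukey = pairwise_tukeyhsd(test_df["jnd"].to_numpy(),
                                      test_df["group"].to_numpy())
            tukey_frame = pd.DataFrame(
                tukey.summary().data[1:], columns=tukey.summary().data[0])
    else:
        f_stat, p, tukey_frame = np.nan, np.nan, None
    means = df.groupby("group")["jnd"].mean()
    return df, means, (float(f_stat), float(p)), tukey_frame
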