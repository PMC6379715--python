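"""Two-state UV/CD melting thermodynamics and CD signature classification.

The folded fraction of a unimolecular two-state unfolding equilibrium is

    theta(T) = 1 / (1 + exp[(dH_vH / R) (1/Tm - 1/T)])      (T in Kelvin)

with van't Hoff enthalpy dH_vH > 0 (unfolding) and Tm the temperature
where theta = 0.5.  The observed signal is theta times a linear folded
baseline plus (1 - theta) times a linear unfolded baseline.  Fitting
emulates the manual two-baseline construction: the coolest and hottest
15% of points initialise the baselines, then all six parameters
(Tm, dH, four baseline coefficients) are refined by least squares.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

R_KCAL = 1.987e-3   # kcal/mol/K
T0_K = 273.15
BASELINE_FRACTION = 0.15
HYSTERESIS_LIMIT = 2.0  # deg C


class MeltingFitError(RuntimeError):
    pass


@dataclass
class MeltingCurve:
    temperatures: np.ndarray      # deg C, monotone in scan direction
    signal: np.ndarray
    direction: str = "heating"    # heating | cooling
    wavelength_nm: float = 295.0

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.temperatures) < 10:
            raise ValueError("melting curve needs >= 10 points")
        if self.direction not in ("heating", "cooling"):
            raise ValueError(f"unknown direction {self.direction!r}")
        d = np.diff(self.temperatures)
        if self.direction == "heating" and not np.all(d > 0):
            raise ValueError("heating curve temperatures must increase strictly")
        if self.direction == "cooling" and not np.all(d < 0):
            raise ValueError("cooling curve temperatures must decrease strictly")

    def to_csv(self) -> str:
        lines = ["temperature_C,signal,direction"]
        for t, s in zip(self.temperatures, self.signal):
            lines.append(f"{t:g},{s:.6g},{self.direction}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_csv(cls, text: str, wavelength_nm: float = 295.0) -> "MeltingCurve":
        rows = [ln.split(",") for ln in text.strip().splitlines()[1:]]
        return cls(
            temperatures=np.array([float(r[0]) for r in rows]),
            signal=np.array([float(r[1]) for r in rows]),
            direction=rows[0][2] if len(rows[0]) > 2 else "heating",
            wavelength_nm=wavelength_nm,
        )

    @classmethod
    def read(cls, path: str | Path) -> "MeltingCurve":
        return cls.from_csv(Path(path).read_text())


def folded_fraction(T_celsius, tm_celsius: float, dh_kcal: float):
    """theta(T) of the unimolecular two-state model."""
    T = np.asarray(T_celsius, dtype=float) + T0_K
    tm = tm_celsius + T0_K
    return 1.0 / (1.0 + np.exp((dh_kcal / R_KCAL) * (1.0 / tm - 1.0 / T)))


def simulate_melt(
    tm_celsius: float,
    dh_kcal: float = 45.0,
    folded_baseline: tuple[float, float] = (1.0, -0.0005),
    unfolded_baseline: tuple[float, float] = (0.8, -0.0002),
    t_grid=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    direction: str = "heating",
    wavelength_nm: float = 295.0,
) -> MeltingCurve:
    """Simulate a two-state melting curve with linear baselines and
    Gaussian noise; deterministic for a given seed.

    Baselines are (intercept, slope-per-degree-C) pairs.
    """
    if dh_kcal <= 0:
        raise ValueError("unfolding enthalpy must be positive")
    if t_grid is None:
        t_grid = np.arange(15.0, 95.0 + 1e-9, 0.5)
    T = np.asarray(t_grid, dtype=float)
    if direction == "cooling":
        T = T[::-1]
    th = folded_fraction(T, tm_celsius, dh_kcal)
    fb = folded_baseline[0] + folded_baseline[1] * T
    ub = unfolded_baseline[0] + unfolded_baseline[1] * T
    sig = th * fb + (1.0 - th) * ub
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, sig.shape)
    return MeltingCurve(temperatures=T, signal=sig, direction=direction,
                        wavelength_nm=wavelength_nm)


@dataclass
class TwoStateFit:
    """Fitted two-state parameters and derived series."""

    tm_celsius: float
    dh_kcal: float
    folded_baseline: tuple[float, float]
    unfolded_baseline: tuple[float, float]
    theta: np.ndarray
    residual_rms: float
    bse: dict = field(default_factory=dict)     # standard errors where available

    def __post_init__(self):
        assert np.all((self.theta >= -1e-9) & (self.theta <= 1 + 1e-9))


class TwoStateMeltModel:
    """Two-state melting model for one curve; ``fit()`` -> results."""

    def __init__(self, curve: MeltingCurve):
        self.curve = curve

    def _predict(self, T, params):
        tm, dh, f0, f1, u0, u1 = params
        th = folded_fraction(T, tm, dh)
        return th * (f0 + f1 * T) + (1 - th) * (u0 + u1 * T)

    def fit(self) -> "TwoStateMeltResults":
        from scipy.optimize import least_squares

        T = self.curve.temperatures
        y = self.curve.signal
        k = max(int(len(T) * BASELINE_FRACTION), 2)
        order = np.argsort(T)
        Ts, ys = T[order], y[order]
        f1, f0 = np.polyfit(Ts[:k], ys[:k], 1)
        u1, u0 = np.polyfit(Ts[-k:], ys[-k:], 1)
        # transition detectability: the baselines must be separated by
        # clearly more than the residual noise around them
        noise = 0.5 * (
            np.std(ys[:k] - (f0 + f1 * Ts[:k])) + np.std(ys[-k:] - (u0 + u1 * Ts[-k:]))
        )
        mid = 0.5 * (Ts[0] + Ts[-1])
        # a transition bends the curve away from any single straight line
        line = np.polyval(np.polyfit(Ts, ys, 1), Ts)
        resid = ys - line
        w = min(9, len(resid) // 2 * 2 - 1)
        smooth = np.convolve(resid, np.ones(w) / w, mode="valid")
        amplitude = float(smooth.max() - smooth.min())
        if amplitude < 3.0 * max(noise, 1e-12) or amplitude < 1e-12:
            raise MeltingFitError(
                "no two-state transition detected (curvature amplitude "
                f"{amplitude:.3g} below noise level {noise:.3g})"
            )
        # initial Tm: theta-proxy crossing 0.5
        with np.errstate(divide="ignore", invalid="ignore"):
            th0 = (ys - (u0 + u1 * Ts)) / ((f0 + f1 * Ts) - (u0 + u1 * Ts))
        th0 = np.clip(th0, 0.0, 1.0)
        cross = np.nonzero(np.diff(np.sign(th0 - 0.5)))[0]
        tm0 = float(Ts[cross[0]]) if len(cross) else float(mid)

        def resid(p):
            return self._predict(T, p) - y

        p0 = np.array([tm0, 45.0, f0, f1, u0, u1])
        sol = least_squares(resid, p0, xtol=1e-14, ftol=1e-14)
        tm, dh, f0, f1, u0, u1 = sol.x
        if dh < 0:  # enthalpy sign convention: unfolding positive
            dh = -dh
        th = folded_fraction(T, tm, dh)
        rms = float(np.sqrt(np.mean(sol.fun**2)))
        # parameter standard errors from the Jacobian (Gauss-Newton)
        bse = {}
        try:
            J = sol.jac
            dof = max(len(y) - len(sol.x), 1)
            cov = np.linalg.inv(J.T @ J) * (2 * sol.cost / dof)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            bse = {"tm_celsius": float(se[0]), "dh_kcal": float(se[1])}
        except np.linalg.LinAlgError:
            pass
        fit = TwoStateFit(
            tm_celsius=float(tm),
            dh_kcal=float(dh),
            folded_baseline=(float(f0), float(f1)),
            unfolded_baseline=(float(u0), float(u1)),
            theta=th,
            residual_rms=rms,
            bse=bse,
        )
        return TwoStateMeltResults(self, fit)


class TwoStateMeltResults:
    def __init__(self, model: TwoStateMeltModel, fit: TwoStateFit):
        self.model = model
        self.fit = fit

    @property
    def tm_celsius(self) -> float:
        return self.fit.tm_celsius

    @property
    def dh_kcal(self) -> float:
        return self.fit.dh_kcal

    @property
    def theta(self) -> np.ndarray:
        return self.fit.theta

    def summary(self) -> str:
        f = self.fit
        c = self.model.curve
        lines = [
            "Two-state melting fit",
            "=" * 34,
            f"direction            {c.direction} ({c.wavelength_nm:g} nm)",
            f"points               {len(c.temperatures)}"
            f" ({c.temperatures.min():g}..{c.temperatures.max():g} C)",
            f"Tm                   {f.tm_celsius:.2f}"
            + (f" +/- {f.bse['tm_celsius']:.2f}" if "tm_celsius" in f.bse else "")
            + " C",
            f"dH (van't Hoff)      {f.dh_kcal:.1f}"
            + (f" +/- {f.bse['dh_kcal']:.1f}" if "dh_kcal" in f.bse else "")
            + " kcal/mol",
            f"folded baseline      {f.folded_baseline[0]:.4g} + {f.folded_baseline[1]:.3g} T",
            f"unfolded baseline    {f.unfolded_baseline[0]:.4g} + {f.unfolded_baseline[1]:.3g} T",
            f"residual RMS         {f.residual_rms:.3g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        T = c.temperatures
        ax.plot(T, c.signal, ".", ms=3, label="data")
        p = (self.fit.tm_celsius, self.fit.dh_kcal, *self.fit.folded_baseline,
             *self.fit.unfolded_baseline)
        ax.plot(T, self.model._predict(T, p), "-", label="two-state fit")
        ax.axvline(self.fit.tm_celsius, ls=":", lw=1)
        ax.set_xlabel("temperature (deg C)")
        ax.set_ylabel("signal")
        ax.legend()
        return ax


def fit_two_state(curve: MeltingCurve) -> TwoStateFit:
    """Functional wrapper around :class:`TwoStateMeltModel`."""
    return TwoStateMeltModel(curve).fit().fit


def hysteresis(heat: MeltingCurve, cool: MeltingCurve) -> tuple[float, bool]:
    """|Tm(heating) - Tm(cooling)| and the equilibrium-consistency flag
    (difference below 2 deg C)."""
    tm_h = fit_two_state(heat).tm_celsius
    tm_c = fit_two_state(cool).tm_celsius
    d = abs(tm_h - tm_c)
    return d, d < HYSTERESIS_LIMIT


# ---------------------------------------------------------------------------
# CD signatures
# ---------------------------------------------------------------------------

def classify_cd(wavelength_nm, ellipticity) -> str:
    """Rule-based quadruplex CD classification.

    hybrid: positive peaks near 265 and 290 nm and a trough near 240 nm;
    parallel: single positive peak near 265 nm with a 240 nm trough;
    antiparallel: positive near 295 nm with a 265 nm trough.
    """
    from scipy.signal import argrelextrema, savgol_filter

    wl = np.asarray(wavelength_nm, dtype=float)
    y = np.asarray(ellipticity, dtype=float)
    order = np.argsort(wl)
    wl, y = wl[order], y[order]
    if wl[0] > 220.0 or wl[-1] < 320.0:
        return "unclassified"
    span = float(y.max() - y.min())
    if span < 1e-12:
        return "unclassified"
    win = min(len(y) // 2 * 2 - 1, 11)
    ys = savgol_filter(y, win, 3) if win >= 5 else y
    floor = 0.05 * span
    maxima = [wl[i] for i in argrelextrema(ys, np.greater, order=3)[0] if ys[i] > floor]
    minima = [wl[i] for i in argrelextrema(ys, np.less, order=3)[0] if ys[i] < -floor]

    def near(vals, target, tol=5.0):
        return any(abs(v - target) <= tol for v in vals)

    if near(maxima, 265) and near(maxima, 290) and near(minima, 240):
        return "hybrid"
    if near(maxima, 265) and near(minima, 240) and not near(maxima, 290) and not near(maxima, 295):
        return "parallel"
    if near(maxima, 295) and near(minima, 265):
        return "antiparallel"
    return "unclassified"


def cd_to_csv(wavelength_nm, ellipticity) -> str:
    lines = ["wavelength_nm,ellipticity"]
    for w, e in zip(wavelength_nm, ellipticity):
        lines.append(f"{w:g},{e:.6g}")
    return "\n".join(lines) + "\n"


def cd_from_csv(text: str):
    rows = [ln.split(",") for ln in text.strip().splitlines()[1:]]
    wl = np.array([float(r[0]) for r in rows])
    y = np.array([float(r[1]) for r in rows])
    return wl, y


def synthetic_cd_spectrum(peaks, wl=None, width: float = 8.0):
    """Sum-of-Gaussians CD spectrum, e.g. peaks=[(265, 1.0), (240, -0.8)]."""
    if wl is None:
        wl = np.arange(220.0, 321.0, 1.0)
    wl = np.asarray(wl, dtype=float)
    y = np.zeros_like(wl)
    for center, amp in peaks:
        y = y + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return wl, y
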