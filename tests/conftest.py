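import numpy as np
import pytest

from atrquant import core


@pytest.fixture(scope="session")
def ratio_cfg():
    return core.RatioConfig()


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Generator with every noise source switched off."""
    return core.GeneratorConfig().noiseless()


@pytest.fixture(scope="session")
def eq1_model():
    """Reference calibration line used as printed input (not fitted here)."""
    return core.CalibrationModel(
        slope=2.74, intercept=-2.52, se_slope=0.024, se_intercept=0.026,
        r_squared=0.999, residual_sd=float("nan"), n_points=6,
        fit_mode="on_means")


#: Printed calibration table: (TAZ % w/w, PIP % w/w, mean ratio, RSD %).
CALIBRATION_TABLE = (
    (50.0, 50.0, 2.925, 3.14),
    (45.0, 55.0, 2.493, 2.19),
    (25.0, 75.0, 1.138, 3.48),
    (15.0, 85.0, 0.699, 2.22),
    (10.0, 90.0, 0.517, 3.89),
    (5.0, 95.0, 0.367, 1.90),
)


@pytest.fixture(scope="session")
def calibration_table():
    return CALIBRATION_TABLE


def brute_force_heights(s, cfg, positions):
    """Independent oracle: explicit two-point line + explicit window scan.

    Kept deliberately naive (python loops, no shared code with the
    implementation) so it can arbitrate corrected_heights.
    """
    w = list(map(float, s.wavenumbers))
    a = list(map(float, s.absorbance))

    def interp(x):
        for i in range(len(w) - 1):
            if w[i] <= x <= w[i + 1]:
                t = (x - w[i]) / (w[i + 1] - w[i])
                return a[i] + t * (a[i + 1] - a[i])
        raise ValueError("out of range")

    yl, yr = interp(cfg.baseline_left), interp(cfg.baseline_right)

    def line(x):
        return yl + (yr - yl) * (x - cfg.baseline_left) / (
            cfg.baseline_right - cfg.baseline_left)

    out = {}
    for pos in positions:
        best_h, best_x = None, None
        for xi, yi in zip(w, a):
            if pos - cfg.apex_halfwidth <= xi <= pos + cfg.apex_halfwidth:
                h = yi - line(xi)
                if best_h is None or h > best_h:
                    best_h, best_x = h, xi
        out[pos] = (best_h, best_x)
    return out


def brute_force_ols(x, y):
    """Independent oracle for the simple-regression closed forms."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    xb = sum(x) / n
    yb = sum(y) / n
    sxx = sum((v - xb) ** 2 for v in x)
    sxy = sum((u - xb) * (v - yb) for u, v in zip(x, y))
    b = sxy / sxx
    a = yb - b * xb
    ssres = sum((v - (a + b * u)) ** 2 for u, v in zip(x, y))
    sstot = sum((v - yb) ** 2 for v in y)
    r2 = 1 - ssres / sstot if sstot else 1.0
    if n > 2:
        s2 = ssres / (n - 2)
        return b, a, (s2 / sxx) ** 0.5, (s2 * (1 / n + xb ** 2 / sxx)) ** 0.5, r2
    return b, a, float("nan"), float("nan"), r2


def random_toy_spectrum(rng):
    """Small random spectrum covering the 862-905 baseline window."""
    n = rng.integers(40, 120)
    start = rng.uniform(840.0, 860.0)
    steps = rng.uniform(0.5, 2.0, n)
    w = start + np.concatenate([[0.0], np.cumsum(steps)])
    while w[-1] < 910.0:
        w = np.append(w, w[-1] + rng.uniform(0.5, 2.0))
    a = rng.normal(0.2, 0.1, w.size)
    for _ in range(rng.integers(1, 4)):
        c = rng.uniform(865.0, 902.0)
        a += rng.uniform(0.05, 1.0) * np.exp(-0.5 * ((w - c) / rng.uniform(2, 6)) ** 2)
    return core.Spectrum(w, a)
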