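"""Synthetic LF-NMR decay curves and kernel images, calibrated per variety.

The study design this generator emulates is 11 maize varieties with 30
NMR-measured seeds each (330 samples) plus photographs of kernels on a
dark background.  Decay curves are three-exponential mixtures (fast,
medium, slow water pools); each variety's amplitudes and time constants
are calibrated by root finding so that the *extracted* features of the
noiseless curve reproduce that variety's published summary statistics
(max signal, 37%-crossing time, cut-off time, pool ratios) to well within
1%.  Per-sample variation enters through a common amplitude scale jitter,
independent relative jitter on the time constants, and additive Gaussian
noise on the echo amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import fsolve

from .decay import (
    DEFAULT_CONFIG,
    AcquisitionGrid,
    DecayCurve,
    NMRConfig,
    extract_t2_features,
)

__all__ = [
    "VarietyTargets",
    "VarietyGeneratorParams",
    "KernelImageParams",
    "VARIETIES",
    "TARGET_STATS",
    "CalibrationError",
    "calibrate_variety",
    "default_variety_params",
    "generate_decay_curve",
    "generate_dataset",
    "default_image_params",
    "generate_kernel_image",
]

#: The 11 varieties, in published order.
VARIETIES = (
    "JD209", "JD27", "JD407", "JD436", "JD50", "JD505",
    "JD626", "JD83", "JD953", "LY9915", "ZD958",
)

#: Published per-variety decay-feature statistics used as calibration
#: targets: (mean, sd) for max signal [a.u.], T2 value [ms], cut-off time
#: [ms], and the fast/medium/slow pool ratios.
TARGET_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "JD209":  {"max_signal": (76705.667, 32.226), "t2_value": (102.949, 0.732),
               "cutoff_time": (477.347, 2.673), "fast_ratio": (0.356, 0.002),
               "medium_ratio": (0.412, 0.000), "slow_ratio": (0.232, 0.001)},
    "JD27":   {"max_signal": (77147.600, 34.574), "t2_value": (102.685, 0.513),
               "cutoff_time": (477.806, 2.431), "fast_ratio": (0.357, 0.001),
               "medium_ratio": (0.413, 0.002), "slow_ratio": (0.230, 0.001)},
    "JD407":  {"max_signal": (71997.300, 52.692), "t2_value": (106.168, 0.704),
               "cutoff_time": (458.180, 2.513), "fast_ratio": (0.345, 0.001),
               "medium_ratio": (0.408, 0.001), "slow_ratio": (0.247, 0.001)},
    "JD436":  {"max_signal": (63854.300, 75.879), "t2_value": (116.304, 0.891),
               "cutoff_time": (522.460, 3.735), "fast_ratio": (0.332, 0.002),
               "medium_ratio": (0.413, 0.003), "slow_ratio": (0.255, 0.002)},
    "JD50":   {"max_signal": (76939.967, 56.369), "t2_value": (106.620, 0.805),
               "cutoff_time": (503.913, 3.355), "fast_ratio": (0.349, 0.002),
               "medium_ratio": (0.413, 0.002), "slow_ratio": (0.238, 0.001)},
    "JD505":  {"max_signal": (77511.633, 52.642), "t2_value": (111.208, 0.871),
               "cutoff_time": (510.927, 3.518), "fast_ratio": (0.340, 0.002),
               "medium_ratio": (0.411, 0.003), "slow_ratio": (0.249, 0.002)},
    "JD626":  {"max_signal": (76564.633, 680.551), "t2_value": (106.677, 0.793),
               "cutoff_time": (493.167, 3.251), "fast_ratio": (0.350, 0.002),
               "medium_ratio": (0.413, 0.001), "slow_ratio": (0.238, 0.002)},
    "JD83":   {"max_signal": (79038.033, 78.160), "t2_value": (110.852, 0.974),
               "cutoff_time": (529.487, 4.144), "fast_ratio": (0.343, 0.002),
               "medium_ratio": (0.415, 0.001), "slow_ratio": (0.242, 0.002)},
    "JD953":  {"max_signal": (75687.700, 52.365), "t2_value": (112.292, 0.889),
               "cutoff_time": (516.640, 3.589), "fast_ratio": (0.339, 0.002),
               "medium_ratio": (0.413, 0.002), "slow_ratio": (0.248, 0.002)},
    "LY9915": {"max_signal": (68638.200, 49.359), "t2_value": (117.512, 0.826),
               "cutoff_time": (561.973, 3.623), "fast_ratio": (0.332, 0.001),
               "medium_ratio": (0.414, 0.002), "slow_ratio": (0.254, 0.001)},
    "ZD958":  {"max_signal": (63720.533, 61.114), "t2_value": (104.125, 0.405),
               "cutoff_time": (485.087, 2.035), "fast_ratio": (0.356, 0.001),
               "medium_ratio": (0.415, 0.002), "slow_ratio": (0.229, 0.001)},
}


class CalibrationError(RuntimeError):
    """Raised when the generator cannot be calibrated to a target set."""


@dataclass(frozen=True)
class VarietyTargets:
    """Extracted-feature means a calibrated generator must reproduce."""

    max_signal: float
    t2_value: float
    cutoff_time: float
    fast_ratio: float
    medium_ratio: float
    slow_ratio: float

    def __post_init__(self) -> None:
        if not 0 < self.t2_value < self.cutoff_time:
            raise ValueError("targets require 0 < T2 value < cut-off time")
        if self.max_signal <= 0:
            raise ValueError("max signal target must be positive")


@dataclass(frozen=True)
class VarietyGeneratorParams:
    """Three-pool mixture parameters for one variety.

    amplitudes and time_constants are ordered (fast, medium, slow).
    amp_jitter is the relative SD of a common per-sample amplitude scale;
    tau_jitter the relative SD of a common per-sample time-constant scale
    (all pools shift together, as a moisture or temperature change would);
    noise_sd the additive Gaussian echo noise (a.u.).
    """

    variety_id: str
    amplitudes: tuple[float, float, float]
    time_constants: tuple[float, float, float]
    noise_sd: float = 0.0
    amp_jitter: float = 0.0
    tau_jitter: float = 0.0

    def __post_init__(self) -> None:
        a = np.array(self.amplitudes)
        tau = np.array(self.time_constants)
        if a.sum() <= 0 or np.any(a < 0):
            raise ValueError("amplitudes must be non-negative with positive sum")
        if np.any(tau <= 0) or not (tau[0] < tau[1] < tau[2]):
            raise ValueError("time constants must be positive and strictly ordered")
        if self.noise_sd < 0 or self.amp_jitter < 0 or self.tau_jitter < 0:
            raise ValueError("noise and jitter parameters must be non-negative")

    def noiseless_signal(self, time: np.ndarray) -> np.ndarray:
        a = np.array(self.amplitudes)
        tau = np.array(self.time_constants)
        return (a[None, :] * np.exp(-time[:, None] / tau[None, :])).sum(axis=1)


def _relative_mixture(t, fractions, taus):
    return sum(p * math.exp(-t / tau) for p, tau in zip(fractions, taus))


def _solve_time_constants(fractions, tau_fast, t2_target, cot_target, t_first, config):
    """Root finding for (tau_med, tau_slow).

    The noiseless relative curve must cross e^-1 of its first-echo value at
    the T2 target and the cut-off fraction at the cut-off target.  When one
    of the two pools carries (numerically) no amplitude the system
    degenerates to a single unknown, solved by bisection.
    """
    from scipy.optimize import brentq

    if fractions[2] < 1e-6 or fractions[1] < 1e-6:
        # single relevant pool: pin it by the T2 crossing alone
        slot = 1 if fractions[2] < 1e-6 else 2

        def residual(tau):
            taus = (tau_fast, tau, 10.0 * tau) if slot == 1 else (tau_fast, tau / 10.0, tau)
            ref = _relative_mixture(t_first, fractions, taus)
            return _relative_mixture(t2_target, fractions, taus) - math.exp(-1) * ref

        tau = brentq(residual, t2_target * 0.3, t2_target * 3.0, xtol=1e-12)
        return (float(tau), float(10.0 * tau)) if slot == 1 else (float(tau / 10.0), float(tau))

    def equations(logtaus):
        tm, ts = np.exp(np.clip(logtaus, -5, 12))
        taus = (tau_fast, tm, ts)
        ref = _relative_mixture(t_first, fractions, taus)
        return [
            _relative_mixture(t2_target, fractions, taus) - math.exp(-1) * ref,
            _relative_mixture(cot_target, fractions, taus) - config.cutoff_fraction * ref,
        ]

    x0 = np.log([t2_target * 1.05, cot_target * 0.95])
    sol, _info, ier, msg = fsolve(equations, x0, full_output=True)
    if ier != 1 or max(abs(v) for v in equations(sol)) > 1e-9:
        raise CalibrationError(f"time-constant solve failed: {msg}")
    return float(np.exp(sol[0])), float(np.exp(sol[1]))


def calibrate_variety(
    variety_id: str,
    targets: VarietyTargets,
    grid: AcquisitionGrid = AcquisitionGrid(),
    config: NMRConfig = DEFAULT_CONFIG,
    n_refine: int = 3,
    tolerance: float = 0.01,
) -> VarietyGeneratorParams:
    """Calibrate the three-pool generator to a set of extracted-feature targets.

    Amplitude fractions start at the pool ratios and tau_fast is pinned at
    the log-midpoint of the fast window; (tau_med, tau_slow) are solved by
    2-D root finding.  A short fixed-point refinement then re-targets the
    amplitude scale, the two crossing times, and the fractions against the
    actual extractor, absorbing discretization, smoothing, and inversion
    bias.  Raises CalibrationError naming the variety and worst target if
    the noiseless round trip misses by more than ``tolerance`` (relative).
    """
    b1 = config.pool_boundaries[0]
    tau_fast = math.sqrt(config.t2_grid_min * b1)
    time = grid.times
    t_first = float(time[0])

    fractions = np.array([targets.fast_ratio, targets.medium_ratio, targets.slow_ratio])
    if np.any(fractions < 0) or fractions.sum() <= 0:
        raise ValueError("pool-ratio targets must be non-negative with positive sum")
    fractions = fractions / fractions.sum()
    goal = fractions.copy()
    t2_adj, cot_adj = targets.t2_value, targets.cutoff_time
    amp_total = targets.max_signal
    params = None

    for _ in range(n_refine):
        tau_med, tau_slow = _solve_time_constants(
            fractions, tau_fast, t2_adj, cot_adj, t_first, config
        )
        if not tau_fast < tau_med < tau_slow:
            raise CalibrationError(
                f"{variety_id}: solved time constants are not ordered "
                f"({tau_fast:.3g}, {tau_med:.3g}, {tau_slow:.3g})"
            )
        params = VarietyGeneratorParams(
            variety_id=variety_id,
            amplitudes=tuple(amp_total * fractions),
            time_constants=(tau_fast, tau_med, tau_slow),
        )
        feats = extract_t2_features(
            DecayCurve(time, params.noiseless_signal(time), variety_id), config
        )
        # Fixed-point corrections toward the extractor's own readout.
        amp_total *= targets.max_signal / feats.max_signal
        t2_adj += targets.t2_value - feats.t2_value
        cot_adj += targets.cutoff_time - feats.cutoff_time
        extracted = np.array([feats.fast_ratio, feats.medium_ratio, feats.slow_ratio])
        fractions = np.clip(fractions + (goal - extracted), 1e-9, None)
        fractions = fractions / fractions.sum()

    feats = extract_t2_features(
        DecayCurve(time, params.noiseless_signal(time), variety_id), config
    )
    checks = {
        "max_signal": (feats.max_signal, targets.max_signal),
        "t2_value": (feats.t2_value, targets.t2_value),
        "cutoff_time": (feats.cutoff_time, targets.cutoff_time),
        "fast_ratio": (feats.fast_ratio, targets.fast_ratio),
        "medium_ratio": (feats.medium_ratio, targets.medium_ratio),
        "slow_ratio": (feats.slow_ratio, targets.slow_ratio),
    }
    for name, (got, want) in checks.items():
        denom = abs(want) if abs(want) > 1e-9 else 1.0  # absolute check for zero targets
        if abs(got - want) / denom > tolerance:
            raise CalibrationError(
                f"{variety_id}: calibration missed {name} "
                f"(target {want:.6g}, extracted {got:.6g})"
            )
    return params


@lru_cache(maxsize=4)
def default_variety_params(
    grid: AcquisitionGrid = AcquisitionGrid(),
    config: NMRConfig = DEFAULT_CONFIG,
) -> dict[str, VarietyGeneratorParams]:
    """Calibrated parameters for all 11 varieties.

    Jitter and noise levels are derived from the published per-variety
    SDs: the amplitude-scale jitter is sd/mean of the max signal, the
    time-constant jitter sd/mean of the T2 value, and the additive echo
    noise 0.3x the max-signal SD (so the combined extracted-feature SDs
    sit at the published order of magnitude).
    """
    out: dict[str, VarietyGeneratorParams] = {}
    for variety in VARIETIES:
        stats = TARGET_STATS[variety]
        targets = VarietyTargets(
            max_signal=stats["max_signal"][0],
            t2_value=stats["t2_value"][0],
            cutoff_time=stats["cutoff_time"][0],
            fast_ratio=stats["fast_ratio"][0],
            medium_ratio=stats["medium_ratio"][0],
            slow_ratio=stats["slow_ratio"][0],
        )
        base = calibrate_variety(variety, targets, grid, config)
        out[variety] = VarietyGeneratorParams(
            variety_id=variety,
            amplitudes=base.amplitudes,
            time_constants=base.time_constants,
            noise_sd=0.3 * stats["max_signal"][1],
            amp_jitter=stats["max_signal"][1] / stats["max_signal"][0],
            tau_jitter=stats["t2_value"][1] / stats["t2_value"][0],
        )
    return out


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_decay_curve(
    params: VarietyGeneratorParams,
    grid: AcquisitionGrid = AcquisitionGrid(),
    rng=None,
    sample_id: str = "",
) -> DecayCurve:
    """Draw one noisy decay curve from a calibrated generator."""
    rng = _as_rng(rng)
    scale = max(0.0, 1.0 + rng.normal(0.0, params.amp_jitter)) if params.amp_jitter else 1.0
    amps = np.clip(np.array(params.amplitudes) * scale, 0.0, None)
    taus = np.array(params.time_constants)
    if params.tau_jitter:
        # one common factor: crossing times scale linearly with it, so
        # jitter perturbs them without biasing their means
        taus = np.clip(taus * (1.0 + rng.normal(0.0, params.tau_jitter)), 1e-6, None)
    time = grid.times
    signal = (amps[None, :] * np.exp(-time[:, None] / taus[None, :])).sum(axis=1)
    if params.noise_sd:
        signal = signal + rng.normal(0.0, params.noise_sd, time.size)
    return DecayCurve(time=time, signal=signal, sample_id=sample_id or params.variety_id)


def generate_dataset(
    n_per_variety: int = 30,
    grid: AcquisitionGrid = AcquisitionGrid(),
    rng=None,
    params: dict[str, VarietyGeneratorParams] | None = None,
) -> tuple[list[DecayCurve], list[str]]:
    """Labeled decay curves, ``n_per_variety`` per variety (default 30 x 11 = 330)."""
    if n_per_variety < 1:
        raise ValueError("n_per_variety must be at least 1")
    rng = _as_rng(rng)
    if params is None:
        params = default_variety_params(grid)
    curves, labels = [], []
    for variety in sorted(params):
        for i in range(n_per_variety):
            curves.append(
                generate_decay_curve(
                    params[variety], grid, rng, sample_id=f"{variety}_{i:03d}"
                )
            )
            labels.append(variety)
    return curves, labels


# ---------------------------------------------------------------------------
# Kernel images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelImageParams:
    """Per-variety appearance of kernels photographed on a dark background."""

    variety_id: str
    major_axis_mean: float = 60.0  # px
    major_axis_sd: float = 4.0
    axis_ratio: float = 0.65  # minor / major
    axis_ratio_sd: float = 0.03
    base_color_mean: tuple[float, float, float] = (205.0, 160.0, 60.0)
    base_color_sd: tuple[float, float, float] = (8.0, 8.0, 6.0)
    texture_amplitude: float = 10.0  # grey levels
    background_level: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.axis_ratio <= 1:
            raise ValueError("axis_ratio must lie in (0, 1]")
        if any(not 0 <= c <= 255 for c in self.base_color_mean):
            raise ValueError("base colors must lie in [0, 255]")


def default_image_params() -> dict[str, KernelImageParams]:
    """Appearance parameters for the 11 varieties.

    Axis ratios and colors are spread across plausible yellow-dent ranges
    so geometric and color features separate varieties; values are fixed
    conventions of the generator, not published measurements.
    """
    out = {}
    for i, variety in enumerate(VARIETIES):
        out[variety] = KernelImageParams(
            variety_id=variety,
            major_axis_mean=52.0 + 2.2 * i,
            axis_ratio=0.52 + 0.035 * i,
            base_color_mean=(
                185.0 + 4.0 * i,
                135.0 + 5.0 * i,
                40.0 + 4.5 * i,
            ),
            texture_amplitude=6.0 + 0.8 * i,
        )
    return out


def generate_kernel_image(
    params: KernelImageParams,
    n_kernels: int,
    rng=None,
    image_size: tuple[int, int] = (512, 512),
    max_tries: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Render non-overlapping ellipse-like kernels on a dark background.

    Returns ``(rgb_image uint8 HxWx3, label_mask int HxW)`` where mask
    value k > 0 marks the k-th kernel.  Raises if a kernel cannot be
    placed without overlap within ``max_tries`` attempts.
    """
    if n_kernels < 0:
        raise ValueError("n_kernels must be non-negative")
    rng = _as_rng(rng)
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    image = np.clip(
        rng.normal(params.background_level, 2.0, (h, w, 3)), 0, 255
    )
    mask = np.zeros((h, w), dtype=np.int32)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, clearance radius)

    for k in range(1, n_kernels + 1):
        for attempt in range(max_tries):
            major = max(8.0, rng.normal(params.major_axis_mean, params.major_axis_sd))
            ratio = float(np.clip(rng.normal(params.axis_ratio, params.axis_ratio_sd), 0.2, 1.0))
            minor = major * ratio
            a, b = major / 2.0, minor / 2.0
            theta = rng.uniform(0, math.pi)
            margin = a + 3
            if 2 * margin >= min(h, w):
                raise ValueError("kernel too large for the image")
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (a + pr + 2) ** 2 for py, px, pr in placed):
                break
        else:
            raise RuntimeError(
                f"could not place kernel {k} without overlap after {max_tries} tries"
            )
        placed.append((cy, cx, a))
        ct, st = math.cos(theta), math.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        mask[inside] = k
        color = np.clip(
            rng.normal(params.base_color_mean, params.base_color_sd), 0, 255
        )
        texture = rng.normal(0.0, params.texture_amplitude, (int(inside.sum()), 3))
        image[inside] = np.clip(color[None, :] + texture, 0, 255)

    return image.astype(np.uint8), mask
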