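"""Second-order (non-Fourier) binocular energy pathway.

The pathway has two filtering stages.  First, monocular energy is
computed separately for each eye: the image is filtered by a quadrature
pair of fine-scale Gabors and the squared outputs are summed at every
location, a rectification that discards contrast polarity.  Second, the
two eyes' (mean-subtracted) energy maps feed an ordinary binocular
energy unit at a coarser scale.  Because stage one is polarity
invariant, reversing the contrast of one eye's image leaves the
response exactly unchanged — the mechanism by which this channel
signals depth in the natural direction for anticorrelated stereograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import correlate1d

from .first_order import (
    ARCMIN_PER_DEG,
    DEFAULT_PROBE_GRID,
    EnergyUnit,
    GaborParams,
    TuningCurve,
    energy_response,
    _check_inside_target,
)
from .stimulus import (
    DotField,
    StimulusSpec,
    Window,
    anticorrelate,
    apply_disparity,
    full_dot_field,
    rasterize,
    to_contrast,
)

#: First-stage carrier frequencies (cycles/degree) of the default bank.
DEFAULT_FIRST_STAGE_FREQUENCIES = (4.0, 8.0, 16.0)


@dataclass(frozen=True)
class SecondOrderUnit:
    """Two-stage unit: per-eye fine-scale energy, then coarse binocular energy.

    Both stages are vertically oriented quadrature pairs.  The
    interocular (position/phase) disparity lives entirely in the second
    stage; the first stage is identical for the two eyes.
    """

    centre: tuple[float, float] = (0.0, 0.0)
    first_frequency: float = 8.0            # cycles/degree
    first_envelope_sd: float = 3.75         # arcmin
    second_frequency: float = 2.0           # cycles/degree
    second_envelope_sd: float = 15.0        # arcmin
    position_disparity: float = 0.0         # arcmin
    phase_disparity: float = 0.0            # radians

    def __post_init__(self) -> None:
        if self.first_frequency <= self.second_frequency:
            raise ValueError("the first stage must be tuned to a higher "
                             "spatial frequency than the second stage")

    @property
    def stage_frequency_ratio(self) -> float:
        return self.first_frequency / self.second_frequency

    @property
    def first_stage(self) -> GaborParams:
        return GaborParams(centre=(0.0, 0.0), orientation=0.0,
                           spatial_frequency=self.first_frequency,
                           envelope_sd=self.first_envelope_sd)

    @property
    def second_stage(self) -> EnergyUnit:
        return EnergyUnit(centre=self.centre, orientation=0.0,
                          spatial_frequency=self.second_frequency,
                          envelope_sd=self.second_envelope_sd,
                          position_disparity=self.position_disparity,
                          phase_disparity=self.phase_disparity)


def build_second_order_unit(
    centre: tuple[float, float] = (0.0, 0.0),
    first_frequency: float = 8.0,
    stage_frequency_ratio: float = 4.0,
    position_disparity: float = 0.0,
    phase_disparity: float = 0.0,
    first_envelope_sd: float | None = None,
    second_envelope_sd: float | None = None,
) -> SecondOrderUnit:
    """Construct a unit; envelope SDs default to half a carrier period
    of the corresponding stage."""
    second_frequency = first_frequency / stage_frequency_ratio
    if first_envelope_sd is None:
        first_envelope_sd = 0.5 * ARCMIN_PER_DEG / first_frequency
    if second_envelope_sd is None:
        second_envelope_sd = 0.5 * ARCMIN_PER_DEG / second_frequency
    return SecondOrderUnit(
        centre=tuple(centre),
        first_frequency=first_frequency,
        first_envelope_sd=first_envelope_sd,
        second_frequency=second_frequency,
        second_envelope_sd=second_envelope_sd,
        position_disparity=position_disparity,
        phase_disparity=phase_disparity,
    )


def default_scale_bank(
    position_disparity: float = 0.0,
    frequencies: tuple[float, ...] = DEFAULT_FIRST_STAGE_FREQUENCIES,
    stage_frequency_ratio: float = 4.0,
    centre: tuple[float, float] = (0.0, 0.0),
) -> list[SecondOrderUnit]:
    """Units at several first-stage scales sharing one preferred disparity."""
    return [build_second_order_unit(centre=centre, first_frequency=f,
                                    stage_frequency_ratio=stage_frequency_ratio,
                                    position_disparity=position_disparity)
            for f in frequencies]


def _stage1_kernels(params: GaborParams, pitch: float):
    """Separable 1-D kernels: Gaussian along y, even/odd Gabor along x."""
    if params.orientation % 180.0 != 0.0:
        raise NotImplementedError("separable filtering requires vertical "
                                  "(orientation 0) first-stage filters")
    sd_px = params.envelope_sd / pitch
    half = int(math.ceil(3.0 * sd_px))
    t = np.arange(-half, half + 1, dtype=float)
    gauss = np.exp(-(t**2) / (2.0 * sd_px**2))
    f = params.spatial_frequency / ARCMIN_PER_DEG * pitch   # cycles/pixel
    even = gauss * np.cos(2.0 * math.pi * f * t)
    odd = gauss * np.cos(2.0 * math.pi * f * t + math.pi / 2.0)
    return gauss, even, odd


def monocular_energy_map(contrast_image: np.ndarray, first_stage: GaborParams,
                         pixel_pitch: float) -> np.ndarray:
    """Per-location even^2 + odd^2 quadrature output for one eye.

    Exactly invariant to a full-field flip of the image's contrast
    polarity.  Filtering is separable (Gaussian along y, Gabor carrier
    along x) with zero padding at the window border.
    """
    gauss, even, odd = _stage1_kernels(first_stage, pixel_pitch)
    if len(gauss) > min(contrast_image.shape):
        raise ValueError("first-stage filter is larger than the image")
    smoothed = correlate1d(contrast_image, gauss, axis=0, mode="constant")
    e = correlate1d(smoothed, even, axis=1, mode="constant")
    o = correlate1d(smoothed, odd, axis=1, mode="constant")
    return e**2 + o**2


def second_order_energy(
    unit: SecondOrderUnit,
    contrast_left: np.ndarray,
    contrast_right: np.ndarray,
    window: Window,
    demean: bool = True,
) -> float:
    """Scalar second-order binocular energy for one frame.

    The monocular energy maps are mean-subtracted within the window
    before the coarse binocular stage (the maps are non-negative, and
    without demeaning their DC level swamps the disparity signal).
    """
    pitch = window.pixel_pitch
    map_l = monocular_energy_map(contrast_left, unit.first_stage, pitch)
    map_r = monocular_energy_map(contrast_right, unit.first_stage, pitch)
    if demean:
        map_l = map_l - map_l.mean()
        map_r = map_r - map_r.mean()
    return energy_response(unit.second_stage.sample_fields(window), map_l, map_r)


@dataclass
class ScaleBankTuning:
    """Per-scale and scale-averaged second-order tuning curves."""

    per_scale: dict[float, dict[str, TuningCurve]]
    averaged: dict[str, TuningCurve]


def second_order_window(unit: SecondOrderUnit, spec: StimulusSpec,
                        probe_disparities: np.ndarray) -> Window:
    max_probe = float(np.max(np.abs(probe_disparities))) if len(probe_disparities) else 0.0
    split = max(spec.disparity_split, 1.0 - spec.disparity_split)
    half = (2.5 * unit.second_envelope_sd + 3.0 * unit.first_envelope_sd
            + abs(unit.position_disparity) / 2.0 + max_probe * split
            + spec.dot_size + spec.pixel_pitch)
    ox, oy = spec.centre_offset
    centre = (ox + unit.centre[0], oy + unit.centre[1])
    return Window.around(centre, half, spec.pixel_pitch)


def _gabor_1d(x: np.ndarray, centre: float, sd: float, freq_cpd: float,
              phase: float) -> np.ndarray:
    t = x - centre
    f = freq_cpd / ARCMIN_PER_DEG
    return np.exp(-(t**2) / (2.0 * sd**2)) * np.cos(2.0 * math.pi * f * t + phase)


def second_order_tuning(
    units: list[SecondOrderUnit],
    spec_template: StimulusSpec,
    probe_disparities: np.ndarray | None = None,
    n_frames: int = 500,
    rng: int | np.random.Generator | None = None,
    correlations: tuple[str, ...] | str = ("correlated", "anticorrelated"),
    method: str = "filter_shift",
    demean: bool = True,
) -> ScaleBankTuning:
    """Second-order disparity tuning averaged over a bank of first-stage scales.

    Every unit in the bank must share a common second-stage preferred
    disparity.  All scales see the same dot fields frame by frame, and
    the scale-averaged curve is the mean of per-frame, per-scale
    energies, so it equals the mean of the per-scale curves exactly.

    Methods are as for :func:`stereodepth.first_order.tuning_curve`:
    ``"filter_shift"`` (fast, subpixel, unit support inside the target
    region) or ``"rerender"`` (pixel-snapped re-rasterisation per probe
    disparity).
    """
    if not units:
        raise ValueError("empty unit bank")
    dps = {u.position_disparity for u in units}
    if len(dps) != 1:
        raise ValueError("all units in the bank must share a preferred disparity")
    single = isinstance(correlations, str)
    corrs = (correlations,) if single else tuple(correlations)
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2 for the s.e.m. to be defined")
    if probe_disparities is None:
        probe_disparities = DEFAULT_PROBE_GRID
    probes = np.asarray(probe_disparities, dtype=float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    spec = spec_template

    if method == "filter_shift":
        energies = _so_filter_shift(units, spec, probes, n_frames, rng, corrs, demean)
    elif method == "rerender":
        energies = _so_rerender(units, spec, probes, n_frames, rng, corrs, demean)
    else:
        raise ValueError(f"unknown method {method!r}")

    def curve(e, c):
        return TuningCurve(probes, e.mean(axis=0),
                           e.std(axis=0, ddof=1) / math.sqrt(n_frames),
                           n_frames, c)

    per_scale = {u.first_frequency: {c: curve(energies[(u.first_frequency, c)], c)
                                     for c in corrs}
                 for u in units}
    averaged = {}
    for c in corrs:
        stack = np.stack([energies[(u.first_frequency, c)] for u in units])
        averaged[c] = curve(stack.mean(axis=0), c)
    return ScaleBankTuning(per_scale=per_scale, averaged=averaged)


def _so_filter_shift(units, spec, probes, n_frames, rng, corrs, demean):
    pitch = spec.pixel_pitch
    windows, gys, gx_stacks, k1 = [], [], [], []
    for u in units:
        w = second_order_window(u, spec, probes)
        env = np.exp(-((w.x[None, :] - w.centre[0])**2
                       + (w.y[:, None] - w.centre[1])**2)
                     / (2.0 * u.second_envelope_sd**2))
        _check_inside_target(env, spec, w)
        windows.append(w)
        s2 = u.second_stage
        cy = s2.centre[1] + spec.centre_offset[1]
        gys.append(np.exp(-((w.y - cy)**2) / (2.0 * u.second_envelope_sd**2)))
        # 1-D carrier profiles for both eyes, parities and probe shifts
        ox = spec.centre_offset[0]
        stack = np.empty((2, len(probes), 2, len(w.x)))
        for ei, eye in enumerate(("left", "right")):
            p_half = s2.position_disparity / 2.0
            base_cx = s2.centre[0] + (p_half if eye == "left" else -p_half) + ox
            extra_phase = s2.phase_disparity if eye == "right" else 0.0
            for di, d in enumerate(probes):
                shift = -d * spec.disparity_split if eye == "left" \
                    else d * (1.0 - spec.disparity_split)
                for pi, ph in enumerate((0.0, math.pi / 2.0)):
                    stack[ei, di, pi] = _gabor_1d(
                        w.x, base_cx + shift, u.second_envelope_sd,
                        s2.spatial_frequency, ph + extra_phase)
        gx_stacks.append(stack)
        k1.append(_stage1_kernels(u.first_stage, pitch))

    base = replace(spec, target_disparity=0.0, correlation="correlated")
    energies = {(u.first_frequency, c): np.empty((n_frames, len(probes)))
                for u in units for c in corrs}
    for f in range(n_frames):
        dots = full_dot_field(base, rng)
        target = DotField(dots.positions[dots.is_target],
                          dots.polarities[dots.is_target],
                          dots.is_target[dots.is_target])
        for u, w, gy, gx, (gauss, even, odd) in zip(units, windows, gys,
                                                    gx_stacks, k1):
            # Both eyes share the base (zero-disparity) texture, and a
            # one-eye polarity flip leaves the monocular energy map exactly
            # unchanged, so one map serves both eyes and both correlations;
            # the probe disparity lives in the shifted second-stage filters.
            img = to_contrast(rasterize(target, spec, w), spec)
            sm = correlate1d(img, gauss, axis=0, mode="constant")
            e = correlate1d(sm, even, axis=1, mode="constant")
            o = correlate1d(sm, odd, axis=1, mode="constant")
            m = e**2 + o**2
            if demean:
                m = m - m.mean()
            v_l = gy @ m                       # collapse along y -> (nx,)
            v_r = v_l
            r_l = gx[0] @ v_l                  # (n_probes, 2)
            r_r = gx[1] @ v_r
            s = r_l + r_r
            e_all = (s**2).sum(axis=1)
            for c in corrs:
                energies[(u.first_frequency, c)][f] = e_all
    return energies


def _so_rerender(units, spec, probes, n_frames, rng, corrs, demean):
    windows = [second_order_window(u, spec, probes) for u in units]
    fields = [u.second_stage.sample_fields(w) for u, w in zip(units, windows)]
    k1 = [_stage1_kernels(u.first_stage, spec.pixel_pitch) for u in units]
    energies = {(u.first_frequency, c): np.empty((n_frames, len(probes)))
                for u in units for c in corrs}
    for f in range(n_frames):
        dots = full_dot_field(spec, rng)
        for di, d in enumerate(probes):
            left, right = apply_disparity(dots, d, spec.disparity_split)
            pairs = {"correlated": (left, right)}
            if "anticorrelated" in corrs:
                pairs["anticorrelated"] = anticorrelate(left, right,
                                                        spec.anticorrelated_eye)
            for u, w, flds, (gauss, even, odd) in zip(units, windows, fields, k1):
                for c in corrs:
                    dl, dr = pairs[c]
                    maps = []
                    for dd in (dl, dr):
                        img = to_contrast(rasterize(dd, spec, w), spec)
                        sm = correlate1d(img, gauss, axis=0, mode="constant")
                        e = correlate1d(sm, even, axis=1, mode="constant")
                        o = correlate1d(sm, odd, axis=1, mode="constant")
                        m = e**2 + o**2
                        if demean:
                            m = m - m.mean()
                        maps.append(m)
                    energies[(u.first_frequency, c)][f, di] = \
                        energy_response(flds, maps[0], maps[1])
    return energies
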