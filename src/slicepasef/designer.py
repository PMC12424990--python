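"""Construction of Slice-PASEF (1F/2F/4F) and reference dia-PASEF schemes.

The 1-Frame (1F) design slices the targeted 1/K0 range into contiguous
ion-mobility steps and, for each step, sets the Q1 window to the m/z
quantile envelope of the multiply charged ions releasing at that mobility
(padded and floored at a minimum width).  Because singly charged ions sit on
a higher-mobility trend line, the diagonal envelope excludes them by
construction.  Every targeted precursor is then fragmented in every frame —
a 100% MS/MS duty cycle.

Multi-frame variants (2F/4F) split each step's window into contiguous m/z
segments, trading duty cycle (1/2, 1/4) for spectral simplicity; window
boundaries may shift by half a segment between alternating subcycles
(overlapping-window acquisition) and can be placed at per-step intensity
quantiles to balance signal between frames.

The reference dia-PASEF design tiles the m/z range with fixed-width,
non-overlapping windows laid out diagonally across ion mobility, a few per
frame — the classical scheme Slice-PASEF is compared against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ion_cloud import IonCloud, lower_quantile
from .scheme import AcquisitionScheme, Frame, FrameKind, SliceStep, Subcycle

__all__ = [
    "DesignConfig",
    "CERamp",
    "DesignError",
    "design_1f",
    "design_multiframe",
    "design_diapasef_reference",
    "ce_at",
    "compute_frame_repeats",
]


class DesignError(ValueError):
    """Raised when a scheme cannot be designed from the given inputs."""


@dataclass
class CERamp:
    """Piecewise-linear collision-energy ramp over 1/K0.

    Default anchors follow common timsTOF practice: 20 eV at 1/K0 = 0.60
    rising to 59 eV at 1/K0 = 1.60.
    """

    anchors: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.60, 20.0), (1.60, 59.0)])

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("a CE ramp needs at least 2 anchors")
        xs = [a[0] for a in self.anchors]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("anchor 1/K0 values must be strictly increasing")


def ce_at(ramp: CERamp, inv_k0: float | np.ndarray) -> float | np.ndarray:
    """Collision energy at the given mobility: linear interpolation between
    anchors, clamped to the end anchors outside their range."""
    xs = np.array([a[0] for a in ramp.anchors])
    ys = np.array([a[1] for a in ramp.anchors])
    out = np.interp(inv_k0, xs, ys)
    return float(out) if np.isscalar(inv_k0) else out


@dataclass
class DesignConfig:
    """Parameters of the Slice-PASEF designer.

    ``q_lo``/``q_hi`` are the per-step m/z envelope quantiles over multiply
    charged ions; windows are padded by ``pad_mz`` on both sides and widened
    symmetrically to at least ``min_width_mz`` (default 50 Th — 1F windows
    run from ~50 to 300+ Th wide).  ``boundary_mode`` controls how 2F/4F
    split each window: at equal-width midpoints, or at per-step
    intensity-balanced quantiles.  ``im_range``/``mz_range`` default to the
    cloud's own bounds.
    """

    n_im_steps: int = 20
    q_lo: float = 0.005
    q_hi: float = 0.995
    pad_mz: float = 5.0
    min_width_mz: float = 50.0
    fill_time_ms: float = 100.0
    ms1_per_subcycle: int = 1
    boundary_mode: str = "midpoint"  # or "balanced"
    shift_subcycles: bool = False
    min_charge: int = 2
    im_range: tuple[float, float] | None = None
    mz_range: tuple[float, float] | None = None
    ce_ramp: CERamp | None = field(default_factory=CERamp)

    def validate(self) -> None:
        if self.n_im_steps < 1:
            raise ValueError("n_im_steps must be >= 1")
        if self.min_width_mz <= 0:
            raise ValueError("min_width_mz must be positive")
        if not (0.0 <= self.q_lo < self.q_hi <= 1.0):
            raise ValueError("require 0 <= q_lo < q_hi <= 1")
        if self.boundary_mode not in ("midpoint", "balanced"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.ms1_per_subcycle not in (0, 1):
            raise ValueError("ms1_per_subcycle must be 0 or 1")


def _step_windows(cloud: IonCloud, cfg: DesignConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-IM-step envelope windows: returns (im_edges, mz_lo[], mz_hi[])."""
    im_lo, im_hi = cfg.im_range or cloud.im_range
    mz_lo_b, mz_hi_b = cfg.mz_range or cloud.mz_range
    edges = np.linspace(im_lo, im_hi, cfg.n_im_steps + 1)

    sub = cloud.ions[cloud.ions["charge"] >= cfg.min_charge]
    sub = sub[(sub["inv_k0"] >= im_lo) & (sub["inv_k0"] < im_hi)]
    if sub.empty:
        raise DesignError(
            f"no ions with charge >= {cfg.min_charge} inside 1/K0 "
            f"[{im_lo:g}, {im_hi:g}) — cannot place windows")
    mz = sub["mz"].to_numpy(float)
    ik0 = sub["inv_k0"].to_numpy(float)

    lo = np.full(cfg.n_im_steps, np.nan)
    hi = np.full(cfg.n_im_steps, np.nan)
    for k in range(cfg.n_im_steps):
        vals = mz[(ik0 >= edges[k]) & (ik0 < edges[k + 1])]
        if vals.size == 0:
            continue
        lo[k] = lower_quantile(vals, cfg.q_lo) - cfg.pad_mz
        hi[k] = lower_quantile(vals, cfg.q_hi) + cfg.pad_mz

    # empty steps inherit linearly interpolated windows from their neighbours
    filled = np.flatnonzero(~np.isnan(lo))
    if filled.size == 0:  # pragma: no cover - guarded above
        raise DesignError("all IM steps empty")
    all_idx = np.arange(cfg.n_im_steps)
    lo = np.interp(all_idx, filled, lo[filled])
    hi = np.interp(all_idx, filled, hi[filled])

    # widen symmetrically to the minimum width, then clamp into bounds
    width = hi - lo
    deficit = np.maximum(cfg.min_width_mz - width, 0.0)
    lo -= deficit / 2
    hi += deficit / 2
    shift_r = np.maximum(mz_lo_b - lo, 0.0)
    lo += shift_r
    hi += shift_r
    shift_l = np.maximum(hi - mz_hi_b, 0.0)
    hi -= shift_l
    lo = np.maximum(lo - shift_l, mz_lo_b)
    return edges, lo, hi


def _ms1_frame(cfg: DesignConfig) -> Frame:
    return Frame(kind=FrameKind.MS1, steps=[], fill_time_ms=cfg.fill_time_ms)


def _apply_ce(steps: list[SliceStep], ramp: CERamp | None) -> None:
    if ramp is None:
        return
    for s in steps:
        s.ce_eV = ce_at(ramp, 0.5 * (s.im_lo + s.im_hi))


def design_1f(cloud: IonCloud, cfg: DesignConfig | None = None) -> AcquisitionScheme:
    """Design a 1-Frame Slice-PASEF scheme over the cloud.

    One subcycle with (optionally) an MS1 frame and a single MS2 frame of
    ``n_im_steps`` contiguous IM slices, each isolating the padded
    [q_lo, q_hi] m/z envelope of multiply charged ions at that mobility.
    """
    cfg = cfg or DesignConfig()
    cfg.validate()
    edges, lo, hi = _step_windows(cloud, cfg)
    steps = [SliceStep(im_lo=float(edges[k]), im_hi=float(edges[k + 1]),
                       mz_lo=float(lo[k]), mz_hi=float(hi[k]))
             for k in range(cfg.n_im_steps)]
    _apply_ce(steps, cfg.ce_ramp)
    frames: list[Frame] = []
    if cfg.ms1_per_subcycle:
        frames.append(_ms1_frame(cfg))
    frames.append(Frame(kind=FrameKind.MS2, steps=steps, fill_time_ms=cfg.fill_time_ms))
    return AcquisitionScheme(
        subcycles=[Subcycle(frames=frames, index=0)],
        mz_range=cfg.mz_range or cloud.mz_range,
        im_range=cfg.im_range or cloud.im_range,
        label="1F Slice-PASEF",
    )


def _boundaries_for_step(
    cloud_mz: np.ndarray, cloud_w: np.ndarray, lo: float, hi: float,
    n_frames: int, mode: str,
) -> np.ndarray:
    """Interior m/z boundaries (n_frames − 1 of them) splitting [lo, hi)."""
    if mode == "midpoint" or cloud_mz.size == 0:
        return lo + (hi - lo) * np.arange(1, n_frames) / n_frames
    order = np.argsort(cloud_mz)
    mzs, ws = cloud_mz[order], cloud_w[order]
    cum = np.cumsum(ws)
    cum /= cum[-1]
    bounds = np.interp(np.arange(1, n_frames) / n_frames, cum, mzs)
    return np.clip(bounds, lo, hi)


def design_multiframe(
    cloud: IonCloud, cfg: DesignConfig | None = None, n_frames: int = 2
) -> AcquisitionScheme:
    """Design a 2F or 4F Slice-PASEF scheme.

    Each IM step's 1F window is split into ``n_frames`` contiguous m/z
    segments; frame *j* of the subcycle takes segment *j* across all steps,
    so the per-step union of the frames reproduces the 1F window exactly.
    With ``shift_subcycles``, a second subcycle offsets every interior
    boundary by half a segment (clamped to the window edges) and the cycle
    alternates the two variants.  ``boundary_mode="balanced"`` places the
    boundaries at per-step intensity quantiles of the isolated ions instead
    of equal-width midpoints.
    """
    if n_frames not in (2, 4):
        raise ValueError("n_frames must be 2 or 4")
    cfg = cfg or DesignConfig()
    cfg.validate()
    edges, lo, hi = _step_windows(cloud, cfg)

    sub = cloud.ions[cloud.ions["charge"] >= cfg.min_charge]
    mz_all = sub["mz"].to_numpy(float)
    ik_all = sub["inv_k0"].to_numpy(float)
    w_all = sub["intensity"].to_numpy(float)

    base_bounds: list[np.ndarray] = []
    for k in range(cfg.n_im_steps):
        in_step = (ik_all >= edges[k]) & (ik_all < edges[k + 1]) & \
                  (mz_all >= lo[k]) & (mz_all < hi[k])
        base_bounds.append(_boundaries_for_step(
            mz_all[in_step], w_all[in_step], lo[k], hi[k], n_frames,
            cfg.boundary_mode))

    def build_subcycle(bounds: list[np.ndarray], index: int) -> Subcycle:
        frames: list[Frame] = []
        if cfg.ms1_per_subcycle:
            frames.append(_ms1_frame(cfg))
        for j in range(n_frames):
            steps = []
            for k in range(cfg.n_im_steps):
                cuts = np.concatenate(([lo[k]], bounds[k], [hi[k]]))
                a, b = float(cuts[j]), float(cuts[j + 1])
                if b <= a:  # collapsed segment after clamping: keep a sliver
                    b = a + 1e-4
                steps.append(SliceStep(im_lo=float(edges[k]), im_hi=float(edges[k + 1]),
                                       mz_lo=a, mz_hi=b))
            _apply_ce(steps, cfg.ce_ramp)
            frames.append(Frame(kind=FrameKind.MS2, steps=steps,
                                fill_time_ms=cfg.fill_time_ms))
        return Subcycle(frames=frames, index=index)

    subcycles = [build_subcycle(base_bounds, 0)]
    if cfg.shift_subcycles:
        shifted: list[np.ndarray] = []
        for k in range(cfg.n_im_steps):
            half_seg = (hi[k] - lo[k]) / (2 * n_frames)
            shifted.append(np.clip(base_bounds[k] + half_seg, lo[k], hi[k]))
        subcycles.append(build_subcycle(shifted, 1))

    return AcquisitionScheme(
        subcycles=subcycles,
        mz_range=cfg.mz_range or cloud.mz_range,
        im_range=cfg.im_range or cloud.im_range,
        label=f"{n_frames}F Slice-PASEF" + (" (shifting)" if cfg.shift_subcycles else ""),
    )


def design_diapasef_reference(
    mz_range: tuple[float, float],
    im_range: tuple[float, float],
    window_width: float,
    n_frames: int,
    windows_per_frame: int,
    fill_time_ms: float = 100.0,
) -> AcquisitionScheme:
    """Construct a classical dia-PASEF scheme with fixed-width windows.

    ``n_frames × windows_per_frame`` non-overlapping windows of
    ``window_width`` Th tile ``mz_range``, laid diagonally: the window of
    rank *i* in m/z occupies the *i*-th of equally many 1/K0 strata (low m/z
    at low 1/K0).  Frame *j* (0-based) collects the windows with rank ≡ j
    (mod n_frames), so each frame's strata are pairwise disjoint and every
    point of the covered polygon is isolated by exactly one frame per cycle.
    """
    n_win = n_frames * windows_per_frame
    span = mz_range[1] - mz_range[0]
    if not math.isclose(window_width * n_win, span, rel_tol=1e-9, abs_tol=1e-6):
        raise DesignError(
            f"{n_win} windows of {window_width:g} Th do not tile the m/z span "
            f"{span:g}; suggested width: {span / n_win:g} Th")
    mz_edges = mz_range[0] + window_width * np.arange(n_win + 1)
    im_edges = np.linspace(im_range[0], im_range[1], n_win + 1)

    frames: list[Frame] = []
    for j in range(n_frames):
        steps = []
        for r in range(windows_per_frame):
            i = j + r * n_frames  # window rank assigned to this frame
            steps.append(SliceStep(
                im_lo=float(im_edges[i]), im_hi=float(im_edges[i + 1]),
                mz_lo=float(mz_edges[i]), mz_hi=float(mz_edges[i + 1])))
        steps.sort(key=lambda s: s.im_lo)
        frames.append(Frame(kind=FrameKind.MS2, steps=steps, fill_time_ms=fill_time_ms))
    return AcquisitionScheme(
        subcycles=[Subcycle(frames=frames, index=0)],
        mz_range=mz_range, im_range=im_range,
        label=f"dia-PASEF {n_frames}x{windows_per_frame} @ {window_width:g} Th",
    )


def compute_frame_repeats(
    peak_fwhm_s: float,
    frame_time_s: float,
    ms2_frames_per_subcycle: int,
    ms1_per_subcycle: int = 1,
    min_points: float = 3.0,
) -> int:
    """Largest repeat count preserving ~``min_points`` cycles per LC peak FWHM.

    Returns the largest integer r ≥ 1 with
    ``peak_fwhm_s / ((ms1 + r · ms2) · frame_time_s) >= min_points``; if even
    r = 1 violates the floor, returns 1 with a warning — repeats raise
    signal-to-noise only as long as enough points per peak remain.
    """
    if peak_fwhm_s <= 0 or frame_time_s <= 0:
        raise ValueError("times must be positive")
    budget = peak_fwhm_s / (min_points * frame_time_s) - ms1_per_subcycle
    r = int(math.floor(budget / ms2_frames_per_subcycle + 1e-12))
    if r < 1:
        warnings.warn(
            f"even a single acquisition per frame yields fewer than {min_points:g} "
            "points per peak at FWHM; returning repeats=1", stacklevel=2)
        return 1
    return r
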