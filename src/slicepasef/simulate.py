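"""In-silico acquisition: cloud + scheme + gradient → annotated frame spectra.

The simulator tiles a retention-time window with DIA cycles and, for every
MS2 frame, emits one peak per fragment of every precursor whose (m/z, 1/K0)
is isolated by one of the frame's slice steps.  The defining feature of the
output — mirroring how Slice-PASEF data must be represented for processing —
is that every peak carries, besides m/z, intensity and ion mobility, the Q1
isolation boundaries that produced it.

Signal model: peak intensity = precursor intensity × run-level technical
factor × Gaussian elution factor at the frame time × fragment relative
intensity × (fill time / 100 ms).  Accumulation-time proportionality (the
100 ms reference) is the premise of the duty-cycle arithmetic: twice the
fill, twice the ions.  ``intensity_cv`` is a per-precursor, per-run
multiplicative log-normal factor modelling replicate-to-replicate technical
variation (injection, ionisation); per-peak measurement noise enters as ppm
jitter on m/z and Gaussian jitter on 1/K0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ion_cloud import IonCloud
from .scheme import AcquisitionScheme, Frame, FrameKind

__all__ = [
    "AnnotatedPeak",
    "FrameSpectrum",
    "SimConfig",
    "simulate_acquisition",
    "q1_switch_count",
    "q1_discontinuous_switch_count",
    "write_frame_stream",
    "read_frame_stream",
]

FOUR_LN2 = 4.0 * math.log(2.0)
_ELUTION_FLOOR = 1e-12  # elution factors below this emit no peak

STREAM_COLUMNS = ["rt_s", "subcycle", "frame", "repeat", "kind",
                  "mz", "intensity", "inv_k0", "q1_lo", "q1_hi"]


@dataclass(frozen=True)
class AnnotatedPeak:
    """A fragment-spectrum peak annotated with its Q1 isolation boundaries."""

    mz: float
    intensity: float
    inv_k0: float
    q1_lo: float
    q1_hi: float

    def __post_init__(self) -> None:
        if not self.q1_lo < self.q1_hi:
            raise ValueError("q1 boundaries must satisfy q1_lo < q1_hi")
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")


@dataclass
class FrameSpectrum:
    """One simulated TIMS frame's peak list, with cycle bookkeeping.

    Peaks are held as parallel numpy arrays sorted by m/z;
    :meth:`peaks` materialises :class:`AnnotatedPeak` objects.
    """

    rt_s: float
    cycle_index: int
    subcycle_index: int
    frame_index: int
    repeat_index: int
    kind: FrameKind
    mz: np.ndarray
    intensity: np.ndarray
    inv_k0: np.ndarray
    q1_lo: np.ndarray
    q1_hi: np.ndarray

    def __post_init__(self) -> None:
        self.kind = FrameKind(self.kind)
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            for name in ("mz", "intensity", "inv_k0", "q1_lo", "q1_hi"):
                setattr(self, name, getattr(self, name)[order])

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def peaks(self) -> list[AnnotatedPeak]:
        return [AnnotatedPeak(float(m), float(i), float(k), float(a), float(b))
                for m, i, k, a, b in zip(self.mz, self.intensity, self.inv_k0,
                                         self.q1_lo, self.q1_hi)]

    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass
class SimConfig:
    """Measurement-noise and acquisition-noise parameters.

    ``intensity_cv`` is a run-level multiplicative factor per precursor (see
    module docstring); the quadrupole-switch loss model, off by default,
    attenuates signal acquired in the first ``switch_loss_fraction`` of each
    slice step that follows a *discontinuous* Q1 jump (windows that do not
    touch), emulating the transmission dip during large quadrupole moves.
    """

    mz_jitter_ppm: float = 3.0
    im_jitter_sd: float = 0.005
    intensity_cv: float = 0.05
    noise_peaks_per_frame: int = 20
    noise_intensity_lognorm: tuple[float, float] = (math.log(50.0), 1.0)
    switch_loss_enabled: bool = False
    switch_loss_fraction: float = 0.10
    switch_loss_attenuation: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("mz_jitter_ppm", "im_jitter_sd", "intensity_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.noise_peaks_per_frame < 0:
            raise ValueError("noise_peaks_per_frame must be nonnegative")
        if not (0.0 <= self.switch_loss_fraction <= 1.0):
            raise ValueError("switch_loss_fraction must lie in [0, 1]")
        if not (0.0 <= self.switch_loss_attenuation <= 1.0):
            raise ValueError("switch_loss_attenuation must lie in [0, 1]")


def q1_switch_count(frame: Frame) -> int:
    """Number of step-to-step transitions with a Q1 window change during one
    TIMS ramp (steps traversed in ion-mobility order)."""
    if frame.kind is not FrameKind.MS2:
        raise ValueError("q1_switch_count is defined for MS2 frames")
    steps = sorted(frame.steps, key=lambda s: s.im_lo)
    return sum(1 for a, b in zip(steps, steps[1:])
               if (a.mz_lo, a.mz_hi) != (b.mz_lo, b.mz_hi))


def q1_discontinuous_switch_count(frame: Frame) -> int:
    """Transitions where the new Q1 window does not touch the previous one —
    the large quadrupole jumps of classical dia-PASEF, as opposed to the
    small continuous shifts of a sliced frame."""
    if frame.kind is not FrameKind.MS2:
        raise ValueError("q1_discontinuous_switch_count is defined for MS2 frames")
    steps = sorted(frame.steps, key=lambda s: s.im_lo)
    return sum(1 for a, b in zip(steps, steps[1:])
               if b.mz_lo > a.mz_hi or b.mz_hi < a.mz_lo)


def _step_loss_factors(frame: Frame, sim: SimConfig) -> np.ndarray:
    """Expected per-step signal retention under the switch-loss model."""
    steps = sorted(frame.steps, key=lambda s: s.im_lo)
    factors = np.ones(len(steps))
    if not sim.switch_loss_enabled:
        return factors
    for i in range(1, len(steps)):
        a, b = steps[i - 1], steps[i]
        if b.mz_lo > a.mz_hi or b.mz_hi < a.mz_lo:
            factors[i] = 1.0 - sim.switch_loss_fraction * (1.0 - sim.switch_loss_attenuation)
    return factors


def simulate_acquisition(
    cloud: IonCloud,
    scheme: AcquisitionScheme,
    sim: SimConfig | None = None,
    rt_window: tuple[float, float] = (0.0, 60.0),
) -> list[FrameSpectrum]:
    """Simulate acquisition of the cloud under the scheme over an RT window.

    Cycles tile ``rt_window`` (whole cycles only; the window must fit at
    least one).  MS2 peaks carry the isolating step's Q1 boundaries; MS1
    frames carry precursor peaks annotated with the full scheme m/z range.
    Fixed config (seed included) gives an identical stream.
    """
    sim = sim or SimConfig()
    sim.validate()
    rng = np.random.default_rng(sim.seed)
    if cloud.fragments.empty and not cloud.ions.empty:
        raise ValueError("cloud has no fragment ions; nothing to simulate at MS2")

    # ---- static per-frame precomputation -------------------------------
    ions = cloud.ions
    mz = ions["mz"].to_numpy(float)
    ik0 = ions["inv_k0"].to_numpy(float)
    inten = ions["intensity"].to_numpy(float)
    apex = ions["rt_apex_s"].to_numpy(float)
    fwhm = ions["rt_fwhm_s"].to_numpy(float)
    n_ions = len(ions)

    # fragment arrays grouped by parent position
    frag_parent = ions["id"].reset_index(drop=True)
    parent_pos = {pid: i for i, pid in enumerate(frag_parent)}
    fmask = cloud.fragments["parent_id"].map(parent_pos)
    frags = cloud.fragments[fmask.notna()]
    f_parent = frags["parent_id"].map(parent_pos).to_numpy(int)
    f_mz = frags["mz"].to_numpy(float)
    f_rel = frags["rel_intensity"].to_numpy(float)
    order = np.argsort(f_parent, kind="stable")
    f_parent, f_mz, f_rel = f_parent[order], f_mz[order], f_rel[order]
    frag_start = np.searchsorted(f_parent, np.arange(n_ions + 1))

    # per-run technical factor per precursor
    if sim.intensity_cv > 0:
        sigma = math.sqrt(math.log(1.0 + sim.intensity_cv ** 2))
        run_factor = rng.lognormal(-0.5 * sigma * sigma, sigma, size=n_ions)
    else:
        run_factor = np.ones(n_ions)

    # schedule of physical frames within one cycle
    schedule: list[tuple[int, int, int, Frame, float]] = []
    offset = 0.0
    for sc in scheme.subcycles:
        for fi, frame in enumerate(sc.frames):
            for rep in range(frame.repeats):
                schedule.append((sc.index, fi, rep, frame, offset))
                offset += frame.fill_time_ms
    cycle_ms = offset
    t0, t1 = rt_window
    n_cycles = int(math.floor((t1 - t0) * 1000.0 / cycle_ms))
    if n_cycles < 1:
        raise ValueError(
            f"rt_window of {t1 - t0:g} s is shorter than one cycle ({cycle_ms:g} ms)")

    # per distinct MS2 frame: isolating step index per precursor (-1 = none)
    frame_step: dict[int, np.ndarray] = {}
    frame_loss: dict[int, np.ndarray] = {}
    for key, frame in {id(f): f for _, _, _, f, _ in schedule}.items():
        if frame.kind is not FrameKind.MS2:
            continue
        steps = sorted(frame.steps, key=lambda s: s.im_lo)
        sidx = np.full(n_ions, -1)
        for si, s in enumerate(steps):
            hit = (s.im_lo <= ik0) & (ik0 < s.im_hi) & (s.mz_lo <= mz) & (mz < s.mz_hi)
            sidx[hit & (sidx < 0)] = si
        frame_step[key] = sidx
        frame_loss[key] = _step_loss_factors(frame, sim)

    if len(f_mz):
        noise_mz_span = (float(f_mz.min()), float(np.nextafter(f_mz.max(), np.inf)))
    else:
        noise_mz_span = scheme.mz_range

    out: list[FrameSpectrum] = []
    for cyc in range(n_cycles):
        cycle_start = t0 + cyc * cycle_ms / 1000.0
        for sc_idx, fi, rep, frame, off in schedule:
            t_mid = cycle_start + (off + frame.fill_time_ms / 2.0) / 1000.0
            fillf = frame.fill_time_ms / 100.0
            if frame.kind is FrameKind.MS2:
                sidx = frame_step[id(frame)]
                g = np.exp(-FOUR_LN2 * ((t_mid - apex) / fwhm) ** 2)
                active = np.flatnonzero((sidx >= 0) & (g > _ELUTION_FLOOR))
                steps = sorted(frame.steps, key=lambda s: s.im_lo)
                loss = frame_loss[id(frame)]
                counts = frag_start[active + 1] - frag_start[active]
                pk_parent = np.repeat(active, counts)
                take = np.concatenate(
                    [np.arange(frag_start[i], frag_start[i + 1]) for i in active]
                ) if active.size else np.empty(0, dtype=int)
                base = (inten[pk_parent] * run_factor[pk_parent] * g[pk_parent]
                        * f_rel[take] * fillf * loss[sidx[pk_parent]])
                pk_mz = f_mz[take]
                if sim.mz_jitter_ppm > 0 and pk_mz.size:
                    pk_mz = pk_mz * (1.0 + rng.normal(0.0, sim.mz_jitter_ppm * 1e-6,
                                                      size=pk_mz.size))
                pk_ik0 = ik0[pk_parent]
                if sim.im_jitter_sd > 0 and pk_ik0.size:
                    pk_ik0 = pk_ik0 + rng.normal(0.0, sim.im_jitter_sd, size=pk_ik0.size)
                q1lo = np.array([steps[s].mz_lo for s in sidx[pk_parent]]) \
                    if pk_parent.size else np.empty(0)
                q1hi = np.array([steps[s].mz_hi for s in sidx[pk_parent]]) \
                    if pk_parent.size else np.empty(0)
                if sim.noise_peaks_per_frame > 0 and steps:
                    k = sim.noise_peaks_per_frame
                    pick = rng.integers(0, len(steps), size=k)
                    nz_mz = rng.uniform(*noise_mz_span, size=k)
                    nz_ik = np.array([rng.uniform(steps[s].im_lo, steps[s].im_hi)
                                      for s in pick])
                    nz_in = rng.lognormal(*sim.noise_intensity_lognorm, size=k) * fillf
                    pk_mz = np.concatenate([pk_mz, nz_mz])
                    base = np.concatenate([base, nz_in])
                    pk_ik0 = np.concatenate([pk_ik0, nz_ik])
                    q1lo = np.concatenate([q1lo, [steps[s].mz_lo for s in pick]])
                    q1hi = np.concatenate([q1hi, [steps[s].mz_hi for s in pick]])
                out.append(FrameSpectrum(
                    rt_s=cycle_start + off / 1000.0, cycle_index=cyc,
                    subcycle_index=sc_idx, frame_index=fi, repeat_index=rep,
                    kind=FrameKind.MS2, mz=pk_mz, intensity=base,
                    inv_k0=pk_ik0, q1_lo=q1lo, q1_hi=q1hi))
            else:  # MS1 survey frame: precursor peaks, full-range boundaries
                g = np.exp(-FOUR_LN2 * ((t_mid - apex) / fwhm) ** 2)
                active = np.flatnonzero(g > _ELUTION_FLOOR)
                pk_mz = mz[active]
                if sim.mz_jitter_ppm > 0 and pk_mz.size:
                    pk_mz = pk_mz * (1.0 + rng.normal(0.0, sim.mz_jitter_ppm * 1e-6,
                                                      size=pk_mz.size))
                pk_ik0 = ik0[active]
                if sim.im_jitter_sd > 0 and pk_ik0.size:
                    pk_ik0 = pk_ik0 + rng.normal(0.0, sim.im_jitter_sd, size=pk_ik0.size)
                out.append(FrameSpectrum(
                    rt_s=cycle_start + off / 1000.0, cycle_index=cyc,
                    subcycle_index=sc_idx, frame_index=fi, repeat_index=rep,
                    kind=FrameKind.MS1, mz=pk_mz,
                    intensity=inten[active] * run_factor[active] * g[active] * fillf,
                    inv_k0=pk_ik0,
                    q1_lo=np.full(active.size, scheme.mz_range[0]),
                    q1_hi=np.full(active.size, scheme.mz_range[1])))
    return out


# ---------------------------------------------------------------------------
# Frame-stream serialization
# ---------------------------------------------------------------------------

def write_frame_stream(stream: list[FrameSpectrum], path) -> None:
    """Serialize a frame stream as TSV, one row per peak."""
    chunks = []
    for fs in stream:
        chunks.append(pd.DataFrame({
            "rt_s": np.full(fs.n_peaks, fs.rt_s),
            "subcycle": fs.subcycle_index, "frame": fs.frame_index,
            "repeat": fs.repeat_index, "kind": fs.kind.value,
            "mz": fs.mz, "intensity": fs.intensity, "inv_k0": fs.inv_k0,
            "q1_lo": fs.q1_lo, "q1_hi": fs.q1_hi,
        }))
    df = pd.concat(chunks, ignore_index=True) if chunks else \
        pd.DataFrame(columns=STREAM_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_frame_stream(path) -> list[FrameSpectrum]:
    """Read a frame stream written by :func:`write_frame_stream`.

    Cycle indices are reconstructed from the (rt, subcycle, frame, repeat)
    ordering: a new cycle starts whenever the position key does not advance.
    """
    df = pd.read_csv(path, sep="\t")
    out: list[FrameSpectrum] = []
    cyc = 0
    prev_key = None
    for (rt, sc, fr, rep, kind), grp in df.groupby(
            ["rt_s", "subcycle", "frame", "repeat", "kind"], sort=False):
        key = (sc, fr, rep)
        if prev_key is not None and key <= prev_key:
            cyc += 1
        prev_key = key
        out.append(FrameSpectrum(
            rt_s=float(rt), cycle_index=cyc, subcycle_index=int(sc),
            frame_index=int(fr), repeat_index=int(rep), kind=FrameKind(kind),
            mz=grp["mz"].to_numpy(float), intensity=grp["intensity"].to_numpy(float),
            inv_k0=grp["inv_k0"].to_numpy(float),
            q1_lo=grp["q1_lo"].to_numpy(float), q1_hi=grp["q1_hi"].to_numpy(float)))
    return out
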