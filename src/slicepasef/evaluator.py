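"""Analytic figures of merit for acquisition schemes.

The central quantity is the per-precursor MS/MS duty cycle: the fraction of
the cycle's total MS2 accumulation time during which ions of a given
(m/z, 1/K0) are directed to fragmentation.  A 1F Slice-PASEF scheme isolates
every targeted precursor in its single MS2 frame — duty cycle 1 (100%) —
while a classical 8-frame dia-PASEF scheme isolates each precursor in one
frame of eight, duty cycle 1/8 (12.5%).  MS1 frames contribute to the cycle
time but are excluded from the duty-cycle accounting (those figures hold
with or without survey scans).

Scheme-level metrics aggregate over a precursor cloud: intensity-weighted
mean duty cycle, coverage (fraction of intensity isolated at least once per
cycle), total cycle time, and LC points per peak (peak FWHM / cycle time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ion_cloud import IonCloud
from .scheme import AcquisitionScheme, isolates_many

__all__ = [
    "CycleMetrics",
    "precursor_duty_cycle",
    "duty_cycle_many",
    "cycle_time_ms",
    "scheme_metrics",
    "duty_ratio",
]


@dataclass(frozen=True)
class CycleMetrics:
    """Figures of merit for one scheme against one cloud."""

    cycle_time_ms: float
    duty_cycle: float
    coverage: float
    points_per_peak: float
    #: unweighted (per-ion) companions to the intensity-weighted figures
    duty_cycle_unweighted: float = float("nan")
    coverage_unweighted: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        if self.cycle_time_ms <= 0:
            raise ValueError("cycle_time_ms must be positive")
        for name in ("duty_cycle", "coverage"):
            v = getattr(self, name)
            if not np.isnan(v) and not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name} {v} outside [0, 1]")


def duty_cycle_many(
    scheme: AcquisitionScheme, mz: np.ndarray, inv_k0: np.ndarray
) -> np.ndarray:
    """Vectorised per-point MS/MS duty cycle.

    (Σ fill·repeats over MS2 frames isolating the point) /
    (Σ fill·repeats over all MS2 frames in the cycle).
    """
    mz = np.atleast_1d(np.asarray(mz, dtype=float))
    inv_k0 = np.atleast_1d(np.asarray(inv_k0, dtype=float))
    num = np.zeros(mz.shape)
    denom = 0.0
    for frame in scheme.ms2_frames():
        t = frame.fill_time_ms * frame.repeats
        denom += t
        num += t * isolates_many(frame, mz, inv_k0)
    if denom == 0.0:
        raise ValueError("scheme has no MS2 frames")
    return num / denom


def precursor_duty_cycle(scheme: AcquisitionScheme, mz: float, inv_k0: float) -> float:
    """MS/MS duty cycle of a single (m/z, 1/K0) point; see :func:`duty_cycle_many`."""
    return float(duty_cycle_many(scheme, np.array([mz]), np.array([inv_k0]))[0])


def cycle_time_ms(scheme: AcquisitionScheme) -> float:
    """Total duration of one full DIA cycle: Σ fill·repeats over all frames
    (MS1 included)."""
    return float(sum(f.fill_time_ms * f.repeats for f in scheme.all_frames()))


def scheme_metrics(
    scheme: AcquisitionScheme,
    cloud: IonCloud,
    peak_fwhm_s: float,
    min_charge: int = 2,
) -> CycleMetrics:
    """Evaluate a scheme against a cloud.

    Duty cycle and coverage are computed over multiply charged ions
    (``charge >= min_charge``), intensity-weighted; ion-count-weighted
    values are reported alongside.  An empty cloud yields NaN duty/coverage
    with a warning.
    """
    ct = cycle_time_ms(scheme)
    ppp = 1000.0 * peak_fwhm_s / ct
    sub = cloud.ions[cloud.ions["charge"] >= min_charge]
    if sub.empty:
        warnings.warn("empty cloud: duty cycle and coverage undefined", stacklevel=2)
        return CycleMetrics(cycle_time_ms=ct, duty_cycle=float("nan"),
                            coverage=float("nan"), points_per_peak=ppp,
                            label=scheme.label)
    duty = duty_cycle_many(scheme, sub["mz"].to_numpy(), sub["inv_k0"].to_numpy())
    w = sub["intensity"].to_numpy(float)
    wsum = w.sum()
    return CycleMetrics(
        cycle_time_ms=ct,
        duty_cycle=float((duty * w).sum() / wsum),
        coverage=float(w[duty > 0].sum() / wsum),
        points_per_peak=ppp,
        duty_cycle_unweighted=float(duty.mean()),
        coverage_unweighted=float((duty > 0).mean()),
        label=scheme.label,
    )


def duty_ratio(a: CycleMetrics, b: CycleMetrics) -> float:
    """Ratio of MS/MS duty cycles a/b — the expected MS/MS signal gain of
    scheme *a* over scheme *b* for jointly covered precursors."""
    if not (b.duty_cycle > 0):
        raise ValueError("reference duty cycle must be positive")
    return a.duty_cycle / b.duty_cycle
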