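"""Slice-PASEF data processing: boundary-aware matching and quantification.

Because a sliced frame spans a very wide precursor m/z range, deciding
whether a precursor should be queried against a frame takes both its m/z
and its expected ion mobility: a frame is a *candidate* for a precursor iff
it contains at least one peak whose recorded Q1 isolation boundaries contain
the precursor m/z and whose ion mobility lies within tolerance.  Downstream,
only peaks with matching isolation boundaries are considered.

In multi-frame schemes each fragment ion is compared against all frames of
a subcycle and the most intense matching peak defines the fragment's
intensity in that subcycle.  Frame repeats are merged first — peaks with
identical boundaries and m/z / mobility within tolerance are combined,
summing intensity — which raises signal-to-noise before peak selection.

Per-cycle summed fragment intensities form the precursor's XIC, from which a
quantity, the apex, the above-half-maximum area and the measured
points-per-peak at FWHM are derived.  Replicate quantities are summarised as
CVs: standard deviation (n−1 denominator) of untransformed quantities over
their mean, reported only for n ≥ 3 under the default policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ion_cloud import FragmentIon, PrecursorIon
from .scheme import FrameKind
from .simulate import FrameSpectrum

__all__ = [
    "MatchConfig",
    "XIC",
    "candidate_frames",
    "fragment_intensity_multiframe",
    "merge_repeats",
    "extract_xic",
    "quantify",
    "cv",
    "cv_summary",
]


@dataclass
class MatchConfig:
    """Matching tolerances: 15 ppm on m/z at both MS levels, 0.05 on 1/K0."""

    mz_tol_ppm: float = 15.0
    im_tol: float = 0.05

    def validate(self) -> None:
        if self.mz_tol_ppm <= 0 or self.im_tol <= 0:
            raise ValueError("tolerances must be positive")


def _frame_has_match(fs: FrameSpectrum, mz: float, inv_k0: float, im_tol: float) -> bool:
    if fs.n_peaks == 0:
        return False
    hit = (fs.q1_lo <= mz) & (mz < fs.q1_hi) & (np.abs(fs.inv_k0 - inv_k0) <= im_tol)
    return bool(hit.any())


def candidate_frames(
    precursor: PrecursorIon,
    frames: list[FrameSpectrum],
    cfg: MatchConfig | None = None,
) -> list[FrameSpectrum]:
    """Frames of one subcycle instance the precursor must be queried against.

    A frame qualifies iff it holds ≥ 1 peak whose Q1 boundaries contain the
    precursor m/z and whose ion mobility is within ``im_tol`` of the
    precursor's.
    """
    cfg = cfg or MatchConfig()
    cfg.validate()
    return [fs for fs in frames
            if fs.kind is FrameKind.MS2
            and _frame_has_match(fs, precursor.mz, precursor.inv_k0, cfg.im_tol)]


def fragment_intensity_multiframe(
    fragment: FragmentIon,
    precursor: PrecursorIon,
    frames: list[FrameSpectrum],
    cfg: MatchConfig | None = None,
) -> float:
    """Best-peak fragment intensity across the frames of one subcycle.

    Over all candidate frames, the maximum intensity among peaks matching
    the fragment m/z within tolerance under the precursor's boundary and
    ion-mobility constraints; 0 if nothing matches.  Ties go to the lowest
    frame index (frames are scanned in order and only strictly greater
    intensities replace the incumbent).
    """
    cfg = cfg or MatchConfig()
    cfg.validate()
    tol = cfg.mz_tol_ppm * 1e-6 * fragment.mz
    best = 0.0
    for fs in candidate_frames(precursor, frames, cfg):
        lo = np.searchsorted(fs.mz, fragment.mz - tol, side="left")
        hi = np.searchsorted(fs.mz, fragment.mz + tol, side="right")
        if hi <= lo:
            continue
        sel = slice(lo, hi)
        ok = ((fs.q1_lo[sel] <= precursor.mz) & (precursor.mz < fs.q1_hi[sel])
              & (np.abs(fs.inv_k0[sel] - precursor.inv_k0) <= cfg.im_tol))
        if ok.any():
            m = float(fs.intensity[sel][ok].max())
            if m > best:
                best = m
    return best


def merge_repeats(
    repeats: list[FrameSpectrum], cfg: MatchConfig | None = None
) -> FrameSpectrum:
    """Merge successive acquisitions of the same frame into one spectrum.

    Peaks sharing identical Q1 boundaries whose m/z and ion mobility agree
    within tolerance are combined: intensities summed, m/z and 1/K0 replaced
    by intensity-weighted means.  Unmatched peaks pass through unchanged, so
    total intensity is conserved exactly.
    """
    cfg = cfg or MatchConfig()
    cfg.validate()
    if not repeats:
        raise ValueError("no frames to merge")
    first = repeats[0]
    for fs in repeats[1:]:
        if (fs.subcycle_index, fs.frame_index, fs.kind) != \
                (first.subcycle_index, first.frame_index, first.kind):
            raise ValueError("merge_repeats: frames belong to different scheme positions")
    reps = sorted(fs.repeat_index for fs in repeats)
    if reps != list(range(reps[0], reps[0] + len(reps))):
        raise ValueError("merge_repeats: repeat indices not consecutive")
    if len(repeats) == 1:
        return first

    mz = np.concatenate([fs.mz for fs in repeats])
    inten = np.concatenate([fs.intensity for fs in repeats])
    ik0 = np.concatenate([fs.inv_k0 for fs in repeats])
    q1lo = np.concatenate([fs.q1_lo for fs in repeats])
    q1hi = np.concatenate([fs.q1_hi for fs in repeats])

    # cluster within identical-boundary groups, greedily along sorted m/z
    order = np.lexsort((ik0, mz, q1hi, q1lo))
    cluster = np.full(order.size, -1)
    cid = -1
    c_mz = c_ik0 = c_w = 0.0
    c_q1 = (np.nan, np.nan)
    for pos in order:
        tol = cfg.mz_tol_ppm * 1e-6 * mz[pos]
        same_group = (q1lo[pos], q1hi[pos]) == c_q1
        if (cid >= 0 and same_group and abs(mz[pos] - c_mz) <= tol
                and abs(ik0[pos] - c_ik0) <= cfg.im_tol):
            w = c_w + inten[pos]
            if w > 0:
                c_mz = (c_mz * c_w + mz[pos] * inten[pos]) / w
                c_ik0 = (c_ik0 * c_w + ik0[pos] * inten[pos]) / w
            c_w = w
        else:
            cid += 1
            c_mz, c_ik0, c_w = mz[pos], ik0[pos], inten[pos]
            c_q1 = (q1lo[pos], q1hi[pos])
        cluster[pos] = cid

    n = cid + 1
    sum_i = np.bincount(cluster, weights=inten, minlength=n)
    with np.errstate(invalid="ignore"):
        mean_mz = np.bincount(cluster, weights=mz * inten, minlength=n) / sum_i
        mean_ik = np.bincount(cluster, weights=ik0 * inten, minlength=n) / sum_i
    firsts = np.zeros(n, dtype=int)
    firsts[cluster[order][::-1]] = order[::-1]  # first member of each cluster
    zero = sum_i == 0  # zero-intensity clusters keep their first coordinates
    if zero.any():
        mean_mz[zero] = mz[firsts[zero]]
        mean_ik[zero] = ik0[firsts[zero]]
    out_q1lo = q1lo[firsts]
    out_q1hi = q1hi[firsts]

    return FrameSpectrum(
        rt_s=first.rt_s, cycle_index=first.cycle_index,
        subcycle_index=first.subcycle_index, frame_index=first.frame_index,
        repeat_index=0, kind=first.kind,
        mz=mean_mz, intensity=sum_i, inv_k0=mean_ik,
        q1_lo=out_q1lo, q1_hi=out_q1hi)


@dataclass
class XIC:
    """Per-cycle extracted trace of a precursor's summed fragment signal."""

    rt_s: np.ndarray
    intensity: np.ndarray
    apex: float
    area: float  # trapezoid over the contiguous region above half the apex
    total_signal: float  # sum of per-cycle intensities over the trace
    points_at_fwhm: int
    all_zero: bool

    def __post_init__(self) -> None:
        if np.any(np.diff(self.rt_s) <= 0):
            raise ValueError("XIC retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("XIC intensities must be nonnegative")


def _xic_stats(rt: np.ndarray, y: np.ndarray) -> tuple[float, float, int, bool]:
    if y.size == 0 or float(y.max()) <= 0.0:
        return 0.0, 0.0, 0, True
    i_apex = int(np.argmax(y))
    apex = float(y[i_apex])
    half = apex / 2.0
    lo = i_apex
    while lo > 0 and y[lo - 1] >= half:
        lo -= 1
    hi = i_apex
    while hi < y.size - 1 and y[hi + 1] >= half:
        hi += 1
    region = slice(lo, hi + 1)
    area = float(np.trapezoid(y[region], rt[region])) if hi > lo else 0.0
    return apex, area, hi - lo + 1, False


def extract_xic(
    precursor: PrecursorIon,
    fragments: list[FragmentIon],
    stream: list[FrameSpectrum],
    cfg: MatchConfig | None = None,
) -> XIC:
    """Extract the precursor's per-cycle summed fragment trace from a stream.

    Within each cycle, frame repeats are merged per scheme position, each
    subcycle contributes the sum over fragments of the best-peak intensity
    (:func:`fragment_intensity_multiframe`), and subcycle contributions are
    summed into the cycle's point.  The trace rt is the cycle's first frame
    time.
    """
    cfg = cfg or MatchConfig()
    cfg.validate()
    by_cycle: dict[int, list[FrameSpectrum]] = {}
    for fs in stream:
        by_cycle.setdefault(fs.cycle_index, []).append(fs)

    rts, ys = [], []
    for cyc in sorted(by_cycle):
        frames = by_cycle[cyc]
        rts.append(min(fs.rt_s for fs in frames))
        # group MS2 frames by (subcycle, frame position), merging repeats
        groups: dict[tuple[int, int], list[FrameSpectrum]] = {}
        for fs in frames:
            if fs.kind is FrameKind.MS2:
                groups.setdefault((fs.subcycle_index, fs.frame_index), []).append(fs)
        merged: dict[int, list[FrameSpectrum]] = {}
        for (sc, _fi), reps in sorted(groups.items()):
            merged.setdefault(sc, []).append(
                merge_repeats(sorted(reps, key=lambda f: f.repeat_index), cfg))
        total = 0.0
        for sc, sub_frames in merged.items():
            for frag in fragments:
                total += fragment_intensity_multiframe(frag, precursor, sub_frames, cfg)
        ys.append(total)
    rt = np.array(rts, dtype=float)
    y = np.array(ys, dtype=float)
    apex, area, pts, allzero = _xic_stats(rt, y)
    return XIC(rt_s=rt, intensity=y, apex=apex, area=area,
               total_signal=float(y.sum()), points_at_fwhm=pts, all_zero=allzero)


def quantify(xic: XIC, method: str = "sum") -> float:
    """Precursor quantity from an XIC.

    ``"sum"`` (default): total collected signal, the sum of per-cycle
    intensities — this is the quantity whose between-scheme ratio equals the
    MS/MS duty-cycle ratio.  ``"area_fwhm"``: trapezoidal area over the
    contiguous region above half the apex, a time-normalised alternative.
    An all-zero trace quantifies as 0 (flagged on the XIC).
    """
    if method == "sum":
        return xic.total_signal
    if method == "area_fwhm":
        return xic.area
    raise ValueError(f"unknown quantification method {method!r}")


def cv(values) -> float:
    """Coefficient of variation: sd (n−1 denominator) of untransformed
    values divided by their mean.  NaN when the mean is 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def cv_summary(quantities: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Per-precursor CV across replicate runs.

    ``quantities`` has columns ``precursor_id, run, quantity``.  Returns one
    row per precursor with ``n, mean, cv, suppressed``: CVs from fewer than
    ``min_n`` replicates (default 3) are computed but flagged suppressed and
    masked to NaN in the ``cv`` column (available as ``cv_unsuppressed``).
    """
    rows = []
    for pid, grp in quantities.groupby("precursor_id", sort=True):
        v = grp["quantity"].to_numpy(float)
        n = v.size
        raw = cv(v) if n >= 2 else float("nan")
        suppressed = n < min_n
        rows.append((pid, n, float(v.mean()) if n else float("nan"),
                     float("nan") if suppressed else raw, raw, suppressed))
    return pd.DataFrame(rows, columns=["precursor_id", "n", "mean", "cv",
                                       "cv_unsuppressed", "suppressed"])
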