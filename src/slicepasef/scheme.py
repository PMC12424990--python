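"""PASEF acquisition-scheme data model and method-table I/O.

An acquisition scheme is a hierarchy: a DIA *cycle* is an ordered list of
*subcycles*; each subcycle holds an optional MS1 frame followed by MS2
frames; each MS2 frame is an ordered list of *slice steps*, an ion-mobility
interval paired with the Q1 isolation window applied while ions of that
mobility are released from the TIMS device.  All intervals follow the
half-open convention [lo, hi) in both m/z and 1/K0, so abutting steps never
double-isolate a point.

Schemes round-trip through a plain-text comma-separated method table with
one row per slice step (header ``#MS Type,Cycle Id,Start IM,End IM,Start
Mass,End Mass,CE``); see :func:`write_method_table` for the dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "FrameKind",
    "SliceStep",
    "Frame",
    "Subcycle",
    "AcquisitionScheme",
    "Violation",
    "validate_scheme",
    "isolates",
    "isolates_many",
    "write_method_table",
    "read_method_table",
    "MethodTableError",
]

MIN_WINDOW_WIDTH_TH = 2.0  # instrument minimum Q1 width used by the validator


class FrameKind(str, Enum):
    MS1 = "MS1"
    MS2 = "MS2"


class MethodTableError(ValueError):
    """Raised on malformed method definition files."""


@dataclass
class SliceStep:
    """One (1/K0 interval × Q1 window) pairing within an MS2 frame."""

    im_lo: float
    im_hi: float
    mz_lo: float
    mz_hi: float
    ce_eV: float | None = None

    def __post_init__(self) -> None:
        if not self.im_lo < self.im_hi:
            raise ValueError(f"im interval empty: [{self.im_lo}, {self.im_hi})")
        if not self.mz_lo < self.mz_hi:
            raise ValueError(f"mz window empty: [{self.mz_lo}, {self.mz_hi})")

    @property
    def width_mz(self) -> float:
        return self.mz_hi - self.mz_lo

    def contains(self, mz: float, inv_k0: float) -> bool:
        return (self.im_lo <= inv_k0 < self.im_hi) and (self.mz_lo <= mz < self.mz_hi)


@dataclass
class Frame:
    """One TIMS accumulation-and-release event.

    ``repeats`` states how many times the frame is acquired in immediate
    succession; repeated physical frames are expanded by the simulator, not
    duplicated here.
    """

    kind: FrameKind
    steps: list[SliceStep] = field(default_factory=list)
    fill_time_ms: float = 100.0
    repeats: int = 1

    def __post_init__(self) -> None:
        self.kind = FrameKind(self.kind)
        if self.fill_time_ms <= 0:
            raise ValueError("fill_time_ms must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class Subcycle:
    """A group of frames covering the targeted precursor space once."""

    frames: list[Frame]
    index: int = 0

    def ms2_frames(self) -> list[Frame]:
        return [f for f in self.frames if f.kind is FrameKind.MS2]


@dataclass
class AcquisitionScheme:
    subcycles: list[Subcycle]
    mz_range: tuple[float, float]
    im_range: tuple[float, float]
    label: str = ""

    def all_frames(self) -> list[Frame]:
        return [f for sc in self.subcycles for f in sc.frames]

    def ms2_frames(self) -> list[Frame]:
        return [f for f in self.all_frames() if f.kind is FrameKind.MS2]


@dataclass(frozen=True)
class Violation:
    severity: str  # "error" | "warning"
    message: str
    location: str


def validate_scheme(
    scheme: AcquisitionScheme, min_window_width: float = MIN_WINDOW_WIDTH_TH
) -> list[Violation]:
    """Check a scheme for geometric violations; returns an empty list if clean.

    Flags: steps outside the scheme bounds, overlapping IM intervals within a
    frame, Q1 windows narrower than the instrument minimum, subcycles without
    MS2 frames, and schemes without subcycles.
    """
    out: list[Violation] = []
    if not scheme.subcycles:
        return [Violation("error", "scheme has no subcycles", "scheme")]
    mz_lo, mz_hi = scheme.mz_range
    im_lo, im_hi = scheme.im_range
    for sc in scheme.subcycles:
        loc_sc = f"subcycle {sc.index}"
        if not sc.ms2_frames():
            out.append(Violation("error", "subcycle has no MS2 frame", loc_sc))
        for fi, frame in enumerate(sc.frames):
            loc_f = f"{loc_sc}, frame {fi} ({frame.kind.value})"
            if frame.kind is FrameKind.MS1:
                continue
            ordered = sorted(frame.steps, key=lambda s: s.im_lo)
            for a, b in zip(ordered, ordered[1:]):
                if b.im_lo < a.im_hi:
                    out.append(Violation(
                        "error",
                        f"IM intervals overlap: [{a.im_lo:g},{a.im_hi:g}) and "
                        f"[{b.im_lo:g},{b.im_hi:g})", loc_f))
            for si, step in enumerate(frame.steps):
                loc_s = f"{loc_f}, step {si}"
                if step.im_lo >= step.im_hi:
                    out.append(Violation(
                        "error",
                        f"inverted/empty IM interval [{step.im_lo:g},{step.im_hi:g})",
                        loc_s))
                if step.mz_lo >= step.mz_hi:
                    out.append(Violation(
                        "error",
                        f"inverted/empty Q1 window [{step.mz_lo:g},{step.mz_hi:g})",
                        loc_s))
                    continue
                if step.mz_lo < mz_lo or step.mz_hi > mz_hi:
                    out.append(Violation(
                        "error",
                        f"Q1 window [{step.mz_lo:g},{step.mz_hi:g}) outside scheme "
                        f"m/z range [{mz_lo:g},{mz_hi:g}]", loc_s))
                if step.im_lo < im_lo or step.im_hi > im_hi:
                    out.append(Violation(
                        "error",
                        f"IM interval [{step.im_lo:g},{step.im_hi:g}) outside scheme "
                        f"1/K0 range [{im_lo:g},{im_hi:g}]", loc_s))
                if step.width_mz < min_window_width:
                    out.append(Violation(
                        "warning",
                        f"Q1 window width {step.width_mz:g} Th below instrument "
                        f"minimum {min_window_width:g} Th", loc_s))
    return out


def isolates(frame: Frame, mz: float, inv_k0: float) -> bool:
    """True iff some step of the MS2 frame isolates (mz, 1/K0), half-open."""
    if frame.kind is not FrameKind.MS2:
        raise ValueError("isolates() is defined for MS2 frames only")
    return any(s.contains(mz, inv_k0) for s in frame.steps)


def isolates_many(frame: Frame, mz: np.ndarray, inv_k0: np.ndarray) -> np.ndarray:
    """Vectorised :func:`isolates` over arrays of query points."""
    if frame.kind is not FrameKind.MS2:
        raise ValueError("isolates_many() is defined for MS2 frames only")
    mz = np.asarray(mz, dtype=float)
    inv_k0 = np.asarray(inv_k0, dtype=float)
    hit = np.zeros(mz.shape, dtype=bool)
    for s in frame.steps:
        hit |= (s.im_lo <= inv_k0) & (inv_k0 < s.im_hi) & \
               (s.mz_lo <= mz) & (mz < s.mz_hi)
    return hit


# ---------------------------------------------------------------------------
# Method-table I/O
# ---------------------------------------------------------------------------
#
# Dialect (one row per slice step):
#
#   ## slicepasef method table v1
#   ## label=<free text>
#   ## mz_range=400.0000,1000.0000
#   ## im_range=0.7500,1.2000
#   ## frame id=<cycle id> kind=<MS1|PASEF> fill_time_ms=<f> repeats=<r> subcycle=<i>
#   #MS Type,Cycle Id,Start IM,End IM,Start Mass,End Mass,CE
#   MS1,0,0.7500,1.2000,400.0000,1000.0000,
#   PASEF,1,0.7500,0.7725,420.0000,520.0000,24.5000
#   ...
#
# `Cycle Id` numbers frames within the full cycle: MS1 frames take the id 0
# when the cycle opens with a survey scan, MS2 (PASEF) frames are numbered
# from 1 in acquisition order.  CE is blank when unset; floats use 4
# decimals.  The `##` metadata lines carry the attributes the row table
# cannot (per-frame fill time and repeats, subcycle membership, bounds);
# files lacking them still parse, with frames defaulting to 100 ms / 1
# repeat and subcycles split at MS1 rows.

_HEADER = "#MS Type,Cycle Id,Start IM,End IM,Start Mass,End Mass,CE"


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def write_method_table(scheme: AcquisitionScheme, path) -> None:
    """Write the scheme as a plain-text method definition table."""
    lines = ["## slicepasef method table v1"]
    if scheme.label:
        lines.append(f"## label={scheme.label}")
    lines.append(f"## mz_range={_fmt(scheme.mz_range[0])},{_fmt(scheme.mz_range[1])}")
    lines.append(f"## im_range={_fmt(scheme.im_range[0])},{_fmt(scheme.im_range[1])}")

    rows: list[str] = []
    ms2_id = 0
    for sc in scheme.subcycles:
        for frame in sc.frames:
            if frame.kind is FrameKind.MS1:
                fid, kind = 0, "MS1"
            else:
                ms2_id += 1
                fid, kind = ms2_id, "PASEF"
            lines.append(
                f"## frame id={fid} kind={kind} fill_time_ms={frame.fill_time_ms:g} "
                f"repeats={frame.repeats} subcycle={sc.index}")
            if frame.kind is FrameKind.MS1:
                rows.append(",".join([
                    "MS1", "0", _fmt(scheme.im_range[0]), _fmt(scheme.im_range[1]),
                    _fmt(scheme.mz_range[0]), _fmt(scheme.mz_range[1]), ""]))
            else:
                for s in frame.steps:
                    ce = _fmt(s.ce_eV) if s.ce_eV is not None else ""
                    rows.append(",".join([
                        "PASEF", str(fid), _fmt(s.im_lo), _fmt(s.im_hi),
                        _fmt(s.mz_lo), _fmt(s.mz_hi), ce]))
    lines.append(_HEADER)
    lines.extend(rows)
    Path(path).write_text("\n".join(lines) + "\n")


def read_method_table(path) -> AcquisitionScheme:
    """Parse a method definition table back into an :class:`AcquisitionScheme`.

    Parsing is deliberately permissive about geometry (a row with im_lo >
    im_hi parses; :func:`validate_scheme` flags it) but strict about the
    dialect: unknown row types raise :class:`MethodTableError` with the line
    number.
    """
    text = Path(path).read_text()
    label = ""
    mz_range: tuple[float, float] | None = None
    im_range: tuple[float, float] | None = None
    frame_meta: dict[tuple[int, int], dict] = {}  # (order index) -> meta
    meta_order: list[dict] = []
    row_specs: list[tuple[int, str, int, float, float, float, float, float | None]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            body = line[2:].strip()
            if body.startswith("label="):
                label = body[len("label="):]
            elif body.startswith("mz_range="):
                a, b = body[len("mz_range="):].split(",")
                mz_range = (float(a), float(b))
            elif body.startswith("im_range="):
                a, b = body[len("im_range="):].split(",")
                im_range = (float(a), float(b))
            elif body.startswith("frame "):
                kv = dict(tok.split("=", 1) for tok in body[len("frame "):].split())
                meta_order.append({
                    "id": int(kv["id"]), "kind": kv["kind"],
                    "fill_time_ms": float(kv.get("fill_time_ms", 100.0)),
                    "repeats": int(kv.get("repeats", 1)),
                    "subcycle": int(kv.get("subcycle", 0)),
                })
            continue
        if line.startswith("#"):
            continue  # column header
        parts = line.split(",")
        if len(parts) != 7:
            raise MethodTableError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
        ms_type = parts[0].strip()
        if ms_type not in ("MS1", "PASEF"):
            raise MethodTableError(f"{path}:{lineno}: unknown row type {ms_type!r}")
        try:
            fid = int(parts[1])
            im_lo, im_hi, mz_lo, mz_hi = (float(p) for p in parts[2:6])
            ce = float(parts[6]) if parts[6].strip() else None
        except ValueError as exc:
            raise MethodTableError(f"{path}:{lineno}: bad numeric field ({exc})") from None
        row_specs.append((lineno, ms_type, fid, im_lo, im_hi, mz_lo, mz_hi, ce))

    # Build frames in row order; a frame is a maximal run of rows sharing
    # (type, id).  Metadata lines, when present, are consumed in order.
    frames: list[tuple[str, int, list]] = []
    for row in row_specs:
        _, ms_type, fid = row[:3]
        if frames and frames[-1][0] == ms_type and frames[-1][1] == fid \
                and ms_type == "PASEF":
            frames[-1][2].append(row)
        else:
            frames.append((ms_type, fid, [row]))

    if mz_range is None or im_range is None:
        mzs = [s for f in frames for s in f[2]]
        if mzs:
            mz_range = mz_range or (min(s[5] for s in mzs), max(s[6] for s in mzs))
            im_range = im_range or (min(s[3] for s in mzs), max(s[4] for s in mzs))
        else:
            mz_range = mz_range or (0.0, 1.0)
            im_range = im_range or (0.4, 2.0)

    built: list[tuple[int, Frame]] = []  # (subcycle index, frame)
    implicit_sc = 0
    for i, (ms_type, fid, specs) in enumerate(frames):
        meta = meta_order[i] if i < len(meta_order) else None
        fill = meta["fill_time_ms"] if meta else 100.0
        repeats = meta["repeats"] if meta else 1
        if meta is not None:
            sc_idx = meta["subcycle"]
        else:
            if ms_type == "MS1" and built:
                implicit_sc += 1
            sc_idx = implicit_sc
        if ms_type == "MS1":
            frame = Frame(kind=FrameKind.MS1, steps=[], fill_time_ms=fill,
                          repeats=repeats)
        else:
            steps = []
            for (_ln, _t, _id, im_lo, im_hi, mz_lo, mz_hi, ce) in specs:
                step = object.__new__(SliceStep)  # bypass geometric checks;
                step.im_lo, step.im_hi = im_lo, im_hi  # validate_scheme flags them
                step.mz_lo, step.mz_hi = mz_lo, mz_hi
                step.ce_eV = ce
                steps.append(step)
            frame = Frame(kind=FrameKind.MS2, steps=steps, fill_time_ms=fill,
                          repeats=repeats)
        built.append((sc_idx, frame))

    subcycles: list[Subcycle] = []
    for sc_idx, frame in built:
        if not subcycles or subcycles[-1].index != sc_idx:
            subcycles.append(Subcycle(frames=[], index=sc_idx))
        subcycles[-1].frames.append(frame)
    return AcquisitionScheme(subcycles=subcycles, mz_range=mz_range,
                             im_range=im_range, label=label)
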