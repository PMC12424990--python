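"""Precursor ion clouds in m/z × ion-mobility space.

A "cloud" is the set of charged peptide species a method designer cares
about: each precursor has an m/z, a charge, a reduced ion mobility (1/K0,
in V·s/cm²), an abundance, and a Gaussian LC elution profile given by its
apex time and FWHM.  On a TIMS instrument, m/z and 1/K0 are strongly
correlated within a charge state, so the cloud forms near-linear diagonal
bands — one per charge — and it is this geometry that isolation-scheme
design exploits.

The synthetic generator emulates that structure: per-charge linear
1/K0-vs-m/z trend lines with Gaussian scatter, per-charge log-normal
peptide masses converted to m/z, log-normal intensities, and uniform
elution apexes over the gradient.  Its defaults are calibrated so that
charge 2–3 ions at similar mobility span an interquartile m/z range of
about 70 Th, the figure characteristic of tryptic-digest ion maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PROTON_MASS",
    "PrecursorIon",
    "FragmentIon",
    "IonCloud",
    "CloudGenConfig",
    "CloudFormatError",
    "generate_synthetic_cloud",
    "load_cloud_table",
    "save_cloud_table",
    "fit_im_trendlines",
    "TrendFit",
    "mz_quantile_envelope",
    "mean_iqr_mz",
    "lower_quantile",
]

#: Mass of a proton in Da, used to convert neutral peptide mass to m/z.
PROTON_MASS = 1.00728

ION_COLUMNS = ["id", "mz", "charge", "inv_k0", "intensity", "rt_apex_s", "rt_fwhm_s"]
FRAGMENT_COLUMNS = ["parent_id", "mz", "rel_intensity"]


class CloudFormatError(ValueError):
    """Raised when a cloud table is malformed (missing columns, bad rows)."""


@dataclass(frozen=True)
class PrecursorIon:
    """One charged peptide species.

    Attributes
    ----------
    id : str
        Opaque identifier, unique within a cloud.
    mz : float
        Mass-to-charge ratio in Thomson.
    charge : int
        Ion charge state z (≥ 1).
    inv_k0 : float
        Reduced ion mobility 1/K0 in V·s/cm².
    intensity : float
        Nonnegative abundance in arbitrary units.
    rt_apex_s : float
        Elution apex in seconds.
    rt_fwhm_s : float
        LC peak full width at half maximum in seconds.
    """

    id: str
    mz: float
    charge: int
    inv_k0: float
    intensity: float
    rt_apex_s: float
    rt_fwhm_s: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if not (0.4 < self.inv_k0 < 2.0):
            raise ValueError(f"inv_k0 {self.inv_k0} outside plausible (0.4, 2.0)")
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")
        if self.rt_fwhm_s <= 0:
            raise ValueError("rt_fwhm_s must be positive")


@dataclass(frozen=True)
class FragmentIon:
    """A fragment ion carrying a fraction of its parent's signal."""

    parent_id: str
    mz: float
    rel_intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment mz must be positive")
        if not (0 < self.rel_intensity <= 1):
            raise ValueError("rel_intensity must be in (0, 1]")


@dataclass
class IonCloud:
    """A precursor ion cloud with optional fragment ions.

    Ions and fragments are stored as pandas DataFrames (columns
    ``ION_COLUMNS`` / ``FRAGMENT_COLUMNS``) for vectorised downstream use;
    :meth:`precursors` materialises :class:`PrecursorIon` objects on demand.
    """

    ions: pd.DataFrame
    fragments: pd.DataFrame
    mz_range: tuple[float, float]
    im_range: tuple[float, float]
    gradient_length_s: float

    def __post_init__(self) -> None:
        if list(self.ions.columns) != ION_COLUMNS:
            self.ions = self.ions.reindex(columns=ION_COLUMNS)
        if list(self.fragments.columns) != FRAGMENT_COLUMNS:
            self.fragments = self.fragments.reindex(columns=FRAGMENT_COLUMNS)
        ids = self.ions["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].unique()
            raise ValueError(f"duplicate precursor ids: {list(dups)[:5]}")

    @property
    def n_ions(self) -> int:
        return len(self.ions)

    def precursors(self) -> list[PrecursorIon]:
        return [
            PrecursorIon(
                id=str(r.id), mz=float(r.mz), charge=int(r.charge),
                inv_k0=float(r.inv_k0), intensity=float(r.intensity),
                rt_apex_s=float(r.rt_apex_s), rt_fwhm_s=float(r.rt_fwhm_s),
            )
            for r in self.ions.itertuples(index=False)
        ]

    def fragments_of(self, parent_id: str) -> pd.DataFrame:
        return self.fragments[self.fragments["parent_id"] == parent_id]

    def subset(self, ids: list[str]) -> "IonCloud":
        """Restrict the cloud to the given precursor ids (and their fragments)."""
        idset = set(ids)
        ions = self.ions[self.ions["id"].isin(idset)].reset_index(drop=True)
        frags = self.fragments[self.fragments["parent_id"].isin(idset)].reset_index(drop=True)
        return IonCloud(ions, frags, self.mz_range, self.im_range, self.gradient_length_s)


def _default_charge_probs() -> dict[int, float]:
    return {1: 0.15, 2: 0.55, 3: 0.25, 4: 0.05}


def _default_trends() -> dict[int, tuple[float, float]]:
    # (intercept, slope) of 1/K0 vs m/z per charge.  The charge-1 band sits
    # at higher mobility (larger 1/K0) than multiply charged ions of the
    # same m/z, so diagonal envelopes over z >= 2 exclude it naturally.
    return {
        1: (0.650, 9.5e-4),
        2: (0.400, 8.5e-4),
        3: (0.332, 8.5e-4),
        4: (0.300, 7.8e-4),
    }


def _default_mass_lognorm() -> dict[int, tuple[float, float]]:
    # (mu, sigma) of log neutral peptide mass, per charge: higher charges
    # come from longer peptides.
    return {
        1: (math.log(900.0), 0.30),
        2: (math.log(1300.0), 0.28),
        3: (math.log(2100.0), 0.25),
        4: (math.log(2800.0), 0.22),
    }


@dataclass
class CloudGenConfig:
    """Parameters of the synthetic cloud generator.

    The defaults describe a tryptic whole-proteome digest on a timsTOF-class
    instrument: mostly 2+ and 3+ precursors between m/z 400 and 1000, linear
    per-charge mobility trends, and enough ion-mobility scatter that charge
    2–3 ions in a narrow 1/K0 bin spread over an m/z IQR of ~70 Th.
    """

    n_ions: int = 50_000
    charge_probs: dict[int, float] = field(default_factory=_default_charge_probs)
    trends: dict[int, tuple[float, float]] = field(default_factory=_default_trends)
    im_scatter_sd: float = 0.026
    mass_lognorm: dict[int, tuple[float, float]] = field(default_factory=_default_mass_lognorm)
    intensity_lognorm: tuple[float, float] = (math.log(1.0e4), 1.2)
    rt_fwhm_s: float = 2.0
    mz_range: tuple[float, float] = (400.0, 1000.0)
    im_range: tuple[float, float] = (0.6, 1.45)
    gradient_length_s: float = 300.0
    ms2_range: tuple[float, float] = (200.0, 1700.0)
    fragments_per_ion: tuple[int, int] = (3, 10)
    seed: int = 0

    def validate(self) -> None:
        probs = np.array(list(self.charge_probs.values()), dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("charge probabilities must lie in [0, 1]")
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"charge probabilities must sum to 1, got {probs.sum()}")
        if self.im_scatter_sd <= 0:
            raise ValueError("im_scatter_sd must be positive")
        if self.rt_fwhm_s <= 0:
            raise ValueError("rt_fwhm_s must be positive")
        lo, hi = self.fragments_per_ion
        if not (1 <= lo <= hi):
            raise ValueError("fragments_per_ion must be a nondecreasing pair >= 1")
        for z in self.charge_probs:
            if z not in self.trends or z not in self.mass_lognorm:
                raise ValueError(f"no trend/mass parameters for charge {z}")


def generate_synthetic_cloud(config: CloudGenConfig | None = None) -> IonCloud:
    """Generate a synthetic precursor cloud with fragment ions.

    Per charge state, neutral masses are drawn log-normally and converted to
    m/z (rejection-sampled into ``mz_range``); 1/K0 follows the charge's
    linear trend plus Gaussian scatter, clipped to ``im_range``.  Each
    precursor receives 3–10 fragments at uniform m/z within ``ms2_range``
    with Dirichlet-distributed relative intensities.  Identical configs
    (including seed) give bit-identical clouds.
    """
    cfg = config or CloudGenConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = max(int(cfg.n_ions), 0)

    empty_ions = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        ION_COLUMNS, [str, float, int, float, float, float, float])})
    empty_frags = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        FRAGMENT_COLUMNS, [str, float, float])})
    if n == 0:
        return IonCloud(empty_ions, empty_frags, cfg.mz_range, cfg.im_range,
                        cfg.gradient_length_s)

    zs = np.array(sorted(cfg.charge_probs), dtype=int)
    probs = np.array([cfg.charge_probs[z] for z in zs], dtype=float)
    probs = probs / probs.sum()
    charges = rng.choice(zs, size=n, p=probs)

    mz = np.empty(n)
    inv_k0 = np.empty(n)
    mz_lo, mz_hi = cfg.mz_range
    for z in zs:
        mask = charges == z
        m = int(mask.sum())
        if m == 0:
            continue
        mu, sigma = cfg.mass_lognorm[z]
        vals = (rng.lognormal(mu, sigma, size=m) / z) + PROTON_MASS
        # rejection-resample until every m/z falls inside the cloud bounds
        for _ in range(10_000):
            bad = (vals < mz_lo) | (vals >= mz_hi)
            k = int(bad.sum())
            if k == 0:
                break
            vals[bad] = (rng.lognormal(mu, sigma, size=k) / z) + PROTON_MASS
        else:  # pragma: no cover - pathological config
            raise ValueError(f"cannot place charge-{z} ions inside mz_range {cfg.mz_range}")
        intercept, slope = cfg.trends[z]
        ik0 = intercept + slope * vals + rng.normal(0.0, cfg.im_scatter_sd, size=m)
        mz[mask] = vals
        inv_k0[mask] = np.clip(ik0, cfg.im_range[0], cfg.im_range[1])

    intensity = rng.lognormal(*cfg.intensity_lognorm, size=n)
    rt_apex = rng.uniform(0.0, cfg.gradient_length_s, size=n)
    width = len(str(n))
    ids = np.array([f"P{i:0{width}d}" for i in range(n)])

    ions = pd.DataFrame({
        "id": ids, "mz": mz, "charge": charges.astype(int), "inv_k0": inv_k0,
        "intensity": intensity, "rt_apex_s": rt_apex,
        "rt_fwhm_s": np.full(n, cfg.rt_fwhm_s),
    })

    f_lo, f_hi = cfg.fragments_per_ion
    n_frag = rng.integers(f_lo, f_hi + 1, size=n)
    total = int(n_frag.sum())
    frag_mz = rng.uniform(cfg.ms2_range[0], cfg.ms2_range[1], size=total)
    # flat Dirichlet per parent via normalised exponentials; sums to 1 exactly
    gammas = rng.exponential(1.0, size=total)
    parent_idx = np.repeat(np.arange(n), n_frag)
    sums = np.bincount(parent_idx, weights=gammas, minlength=n)
    rel = gammas / sums[parent_idx]
    fragments = pd.DataFrame({
        "parent_id": ids[parent_idx], "mz": frag_mz, "rel_intensity": rel,
    })

    return IonCloud(ions, fragments, cfg.mz_range, cfg.im_range, cfg.gradient_length_s)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def load_cloud_table(path, fragment_path=None) -> IonCloud:
    """Load a precursor cloud from a tab-separated table.

    The table must carry the header ``id  mz  charge  inv_k0  intensity
    rt_apex_s  rt_fwhm_s``; an optional fragment table carries ``parent_id
    mz  rel_intensity``.  Malformed rows are rejected with their (1-based
    data) row numbers named in the error.
    """
    ions = _read_tsv(path, ION_COLUMNS, {"mz", "charge", "inv_k0", "intensity",
                                         "rt_apex_s", "rt_fwhm_s"})
    ions["charge"] = ions["charge"].astype(int)
    if fragment_path is not None:
        frags = _read_tsv(fragment_path, FRAGMENT_COLUMNS, {"mz", "rel_intensity"})
    else:
        frags = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            FRAGMENT_COLUMNS, [str, float, float])})
    if len(ions):
        mz_range = (float(ions["mz"].min()), float(np.nextafter(ions["mz"].max(), np.inf)))
        im_range = (float(ions["inv_k0"].min()), float(np.nextafter(ions["inv_k0"].max(), np.inf)))
        gradient = float(ions["rt_apex_s"].max())
    else:
        mz_range, im_range, gradient = (0.0, 1.0), (0.4, 2.0), 0.0
    return IonCloud(ions, frags, mz_range, im_range, gradient)


def _read_tsv(path, columns: list[str], numeric: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise CloudFormatError(f"{path}: file is empty (no header)") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CloudFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[columns]
    bad_rows: list[int] = []
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad_rows.extend((np.flatnonzero(converted.isna() & df[col].notna()) + 1).tolist())
        if df[col].isna().any():
            bad_rows.extend((np.flatnonzero(df[col].isna()) + 1).tolist())
        df[col] = converted
    if bad_rows:
        rows = sorted(set(bad_rows))
        raise CloudFormatError(f"{path}: non-numeric or missing value(s) in row(s) {rows}")
    return df.reset_index(drop=True)


def save_cloud_table(cloud: IonCloud, path, fragment_path=None) -> None:
    """Write the cloud (and optionally its fragments) as TSV."""
    cloud.ions.to_csv(path, sep="\t", index=False)
    if fragment_path is not None:
        cloud.fragments.to_csv(fragment_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Geometry: trend lines and quantile envelopes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendFit:
    """Least-squares line 1/K0 = intercept + slope · m/z for one charge."""

    charge: int
    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float
    residual_sd: float
    n: int


def fit_im_trendlines(cloud: IonCloud, charges: set[int]) -> dict[int, TrendFit]:
    """Fit per-charge least-squares 1/K0-vs-m/z lines.

    Charges with fewer than two ions are omitted with a warning.
    """
    from scipy import stats

    out: dict[int, TrendFit] = {}
    for z in sorted(charges):
        sub = cloud.ions[cloud.ions["charge"] == z]
        if len(sub) < 2:
            warnings.warn(f"charge {z}: fewer than 2 ions, trend line omitted",
                          stacklevel=2)
            continue
        x = sub["mz"].to_numpy(float)
        y = sub["inv_k0"].to_numpy(float)
        res = stats.linregress(x, y)
        resid = y - (res.intercept + res.slope * x)
        ddof = 2 if len(sub) > 2 else 1
        out[z] = TrendFit(
            charge=z, slope=float(res.slope), intercept=float(res.intercept),
            slope_stderr=float(res.stderr), intercept_stderr=float(res.intercept_stderr),
            residual_sd=float(np.sqrt((resid ** 2).sum() / max(len(sub) - ddof, 1))),
            n=len(sub),
        )
    return out


def lower_quantile(values: np.ndarray, q: float) -> float:
    """Lower-interpolation empirical quantile: order statistic ceil(q·n), 1-based.

    ``q = 0`` returns the minimum; ``q = 1`` the maximum.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"quantile fraction {q} outside [0, 1]")
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample has no quantiles")
    k = max(math.ceil(q * v.size), 1)
    return float(v[k - 1])


def mz_quantile_envelope(
    cloud: IonCloud,
    im_bin_width: float,
    q_lo: float,
    q_hi: float,
    charges: set[int],
    im_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Empirical per-IM-bin m/z quantile envelope for the stated charges.

    Returns a DataFrame with columns ``im_lo, im_hi, mz_lo, mz_hi, n, empty``;
    bins with no ions are flagged empty (quantiles NaN).
    """
    if not (0.0 <= q_lo < q_hi <= 1.0):
        raise ValueError("require 0 <= q_lo < q_hi <= 1")
    if im_bin_width <= 0:
        raise ValueError("im_bin_width must be positive")
    lo, hi = im_range if im_range is not None else cloud.im_range
    n_bins = max(int(math.ceil((hi - lo) / im_bin_width - 1e-9)), 1)
    edges = lo + im_bin_width * np.arange(n_bins + 1)

    sub = cloud.ions[cloud.ions["charge"].isin(list(charges))]
    mz = sub["mz"].to_numpy(float)
    ik0 = sub["inv_k0"].to_numpy(float)

    rows = []
    for b in range(n_bins):
        in_bin = (ik0 >= edges[b]) & (ik0 < edges[b + 1])
        vals = mz[in_bin]
        if vals.size == 0:
            rows.append((edges[b], edges[b + 1], np.nan, np.nan, 0, True))
        else:
            rows.append((edges[b], edges[b + 1],
                         lower_quantile(vals, q_lo), lower_quantile(vals, q_hi),
                         int(vals.size), False))
    return pd.DataFrame(rows, columns=["im_lo", "im_hi", "mz_lo", "mz_hi", "n", "empty"])


def mean_iqr_mz(
    cloud: IonCloud,
    im_bin_width: float = 0.01,
    im_range: tuple[float, float] = (0.85, 1.15),
    charges: set[int] = frozenset({2, 3}),
) -> float:
    """Mean interquartile m/z range of the stated charges across narrow IM bins.

    The headline geometry statistic of multiply-charged tryptic ion maps:
    with defaults, charge 2–3 ions within 0.01-wide 1/K0 bins spanning
    0.85–1.15 cover an m/z IQR of about 70 Th.
    """
    env = mz_quantile_envelope(cloud, im_bin_width, 0.25, 0.75, set(charges),
                               im_range=im_range)
    filled = env[~env["empty"]]
    if filled.empty:
        return float("nan")
    return float((filled["mz_hi"] - filled["mz_lo"]).mean())
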