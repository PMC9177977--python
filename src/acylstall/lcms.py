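"""LC/MS chromatogram processing and acetylated-fraction quantification.

The measurement model: for every amino acid the acetyl-derivatized (toxin
product) and Fmoc-derivatized (chemically tagged, non-acetylated) forms of its
aminoacyl-adenosine elute as chromatographic peaks in extracted-ion traces.
Because the two derivatives ionise with different efficiencies, equal molar
amounts give unequal peak areas; the relative response factor

    RRF_i = S_Fmoc / S_Ac        (areas at equal molarity)

calibrates this away, and the acetylated fraction of each aminoacyl-tRNA is

    f_i = S_Ac / (S_Ac + S_Fmoc / RRF_i)

so that an equimolar acetyl/Fmoc pool yields f = 0.5 by construction.
Standard deviations are carried through every ratio by first-order (delta
method) propagation with inputs treated as independent.

Peak areas come either from direct trapezoidal integration of a baseline-
corrected window, or — for co-eluting isobaric pairs such as the Leu/Ile
adenosines — from a nonlinear least-squares fit of a sum of exponentially
modified Gaussian (EMG) peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from scipy.signal import find_peaks, savgol_filter
from scipy.special import erfc, erfcx
from uncertainties import ufloat

__all__ = [
    "Chromatogram",
    "EMGPeak",
    "PeakFit",
    "RRFEntry",
    "QuantifiedSpecies",
    "FitError",
    "smooth",
    "emg_profile",
    "fit_emg_peaks",
    "integrate_peak",
    "compute_rrf",
    "acetylated_fraction",
    "spike_normalize",
    "quantify_samples",
    "read_chromatogram",
    "write_chromatogram",
]

_SQRT2 = np.sqrt(2.0)


class FitError(RuntimeError):
    """Peak fit failed to converge or produced no usable covariance."""


@dataclass
class Chromatogram:
    """An extracted-ion chromatogram: strictly increasing retention times (min)
    and finite intensities (counts)."""

    time: np.ndarray
    intensity: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValueError("chromatogram needs at least two points")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("retention time must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.time.size


def read_chromatogram(path, label: str | None = None) -> Chromatogram:
    """Read a two-column ``time_min,intensity`` CSV."""
    df = pd.read_csv(path)
    if not {"time_min", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_min,intensity")
    return Chromatogram(df["time_min"].to_numpy(), df["intensity"].to_numpy(), label)


def write_chromatogram(chrom: Chromatogram, path) -> None:
    pd.DataFrame({"time_min": chrom.time, "intensity": chrom.intensity}).to_csv(
        path, index=False
    )


def smooth(
    chrom: Chromatogram, window_points: int = 31, poly_order: int = 4
) -> Chromatogram:
    """Savitzky-Golay smoothing on the same time grid.

    The default is a quartic polynomial over 31 points (an odd window is
    required by the filter; 31 is the nearest odd width to the conventional
    30-point quartic/quintic setting).
    """
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if window_points > len(chrom):
        raise ValueError("smoothing window longer than chromatogram")
    if poly_order >= window_points:
        raise ValueError("poly_order must be smaller than window_points")
    sm = savgol_filter(chrom.intensity, window_points, poly_order)
    return Chromatogram(chrom.time, sm, chrom.label)


@dataclass(frozen=True)
class EMGPeak:
    """Exponentially modified Gaussian peak.

    ``area`` is the integral of the curve over the whole line (signal x min);
    ``center`` (mu) and ``sigma`` parameterise the Gaussian component and
    ``tau`` the exponential tailing constant, all in minutes.
    """

    area: float
    center: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be positive")
        if self.area < 0:
            raise ValueError("area must be non-negative")


def emg_profile(peak: EMGPeak, t: np.ndarray) -> np.ndarray:
    """Evaluate the EMG curve

        h(t) = A/(2 tau) * exp(sigma^2/(2 tau^2) + (mu - t)/tau)
                         * erfc((sigma/tau + (mu - t)/sigma) / sqrt(2))

    using the scaled complement ``erfcx`` so that the exp/erfc product stays
    finite for large sigma/tau (the identity exp(a)*erfc(z) =
    erfcx(z)*exp(a - z^2) leaves only a Gaussian factor).
    """
    t = np.asarray(t, dtype=float)
    mu, sigma, tau, area = peak.center, peak.sigma, peak.tau, peak.area
    z = (sigma / tau + (mu - t) / sigma) / _SQRT2
    out = np.empty_like(t)
    pos = z >= 0
    # z >= 0 (left flank / apex): exp(a)*erfc(z) = erfcx(z)*exp(a - z^2) with
    # a - z^2 = -(t-mu)^2/(2 sigma^2), a pure Gaussian factor.
    out[pos] = erfcx(z[pos]) * np.exp(
        -((t[pos] - mu) ** 2) / (2.0 * sigma**2)
    )
    # z < 0 (right tail): erfc(z) -> 2 while exp(a) decays; direct evaluation
    # is stable there.
    a = sigma**2 / (2.0 * tau**2) + (mu - t[~pos]) / tau
    out[~pos] = erfc(z[~pos]) * np.exp(a)
    return area / (2.0 * tau) * out


def _emg_sum(t, params, n_peaks):
    out = params["b0"] + params["b1"] * (t - t[0])
    for i in range(n_peaks):
        out = out + emg_profile(
            EMGPeak(
                max(params[f"a{i}"], 0.0),
                params[f"mu{i}"],
                params[f"sigma{i}"],
                params[f"tau{i}"],
            ),
            t,
        )
    return out


def _candidate_inits(chrom: Chromatogram, n_peaks: int):
    """Deterministic starting-value candidates from the smoothed trace.

    The primary candidate uses the ``n_peaks`` highest local maxima (left
    peak = peak 1).  Heavily overlapped pairs can present a single maximum,
    so for two peaks additional candidates split the dominant maximum
    symmetrically at several fractions of its half-height width; the fit is
    run from each candidate and the lowest-residual solution kept.
    """
    window = min(31, len(chrom) - 1)
    if window >= 5:
        sm = smooth(chrom, window if window % 2 else window - 1, 3).intensity
    else:
        sm = chrom.intensity
    baseline = float(np.percentile(sm, 10))
    signal = sm - baseline
    top = max(float(signal.max()), 1e-12)
    dt = float(np.median(np.diff(chrom.time)))
    half = signal >= 0.5 * top
    fwhm = max(dt * int(half.sum()), 2 * dt)

    idx, props = find_peaks(signal, height=0.05 * top)
    order = np.argsort(props["peak_heights"])[::-1] if idx.size else np.array([], int)
    centers = list(chrom.time[idx[order[:n_peaks]]])
    heights = list(signal[idx[order[:n_peaks]]])
    if not centers:
        centers = [float(chrom.time[np.argmax(signal)])]
        heights = [top]

    def guess(c, h, sigma):
        sigma = max(sigma, dt)
        return dict(area=max(h, 1e-12) * sigma * np.sqrt(2 * np.pi) * 1.3,
                    center=c, sigma=sigma, tau=0.7 * max(sigma, dt))

    candidates = []
    if len(centers) >= n_peaks:
        sigma0 = fwhm / 2.355 / np.sqrt(n_peaks)
        pairs = sorted(zip(centers[:n_peaks], heights[:n_peaks]))
        candidates.append([guess(c, h, sigma0) for c, h in pairs])
    if n_peaks == 2:
        c0, h0 = centers[0], heights[0]
        for frac in (0.35, 0.7, 1.05):
            delta = frac * fwhm / 2
            sigma0 = fwhm / 2.355 / 2
            candidates.append(
                [guess(c0 - delta, 0.6 * h0, sigma0), guess(c0 + delta, 0.6 * h0, sigma0)]
            )
    if n_peaks == 1 and not candidates:
        candidates.append([guess(centers[0], heights[0], fwhm / 2.355)])
    return candidates, baseline


@dataclass
class PeakFit:
    """Result of an EMG peak fit: fitted peaks, linear baseline, per-peak area
    standard errors from the least-squares covariance, and diagnostics."""

    peaks: list[EMGPeak]
    area_stderr: list[float]
    baseline: tuple[float, float]
    covariance: np.ndarray | None
    residual_norm: float
    at_bounds: list[str] = field(default_factory=list)
    success: bool = True

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks])


def fit_emg_peaks(
    chrom: Chromatogram,
    n_peaks: int = 1,
    init: list[dict] | None = None,
    baseline: str = "linear",
    share_shape: bool = True,
    weighting: str = "cv",
    sigma_bounds: tuple[float, float] = (1e-4, 5.0),
    tau_bounds: tuple[float, float] = (1e-4, 5.0),
) -> PeakFit:
    """Fit ``n_peaks`` EMG peaks plus a constant/linear baseline.

    Initialisation defaults to the highest local maxima of the smoothed trace
    (left peak is peak 1); pass ``init`` as a list of dicts with keys
    ``area, center, sigma, tau`` to override.  Several deterministic starting
    points are tried and the lowest-residual solution returned, so the result
    is reproducible for a given chromatogram.

    With ``share_shape`` (the default) a two-peak fit constrains sigma and tau
    to be equal across peaks: co-eluting digest products of structural isomers
    (the Leu/Ile adenosine pair) are chemically near-identical and share their
    chromatographic peak shape, and without the constraint strongly overlapped
    pairs are only weakly identifiable.

    ``weighting="cv"`` (default) weights residuals by the reciprocal of the
    smoothed signal, the maximum-likelihood weighting when detector noise is
    proportional to intensity (the usual LC/MS regime); ``weighting="none"``
    gives ordinary least squares for homoscedastic noise.  Raises
    :class:`FitError` on non-convergence or a degenerate covariance;
    parameters pinned at their bounds are reported in ``at_bounds``.
    """
    if n_peaks not in (1, 2):
        raise ValueError("n_peaks must be 1 or 2")
    if baseline not in ("constant", "linear"):
        raise ValueError("baseline must be 'constant' or 'linear'")
    if init is not None:
        if len(init) != n_peaks:
            raise ValueError("init must supply one guess per peak")
        base0 = float(np.percentile(chrom.intensity, 10))
        candidates = [list(init)]
    else:
        candidates, base0 = _candidate_inits(chrom, n_peaks)

    best: PeakFit | None = None
    last_err: FitError | None = None
    for cand in candidates:
        try:
            fit = _fit_once(chrom, cand, n_peaks, baseline, base0,
                            share_shape, weighting, sigma_bounds, tau_bounds)
        except FitError as err:
            last_err = err
            continue
        if best is None or fit.residual_norm < best.residual_norm:
            best = fit
    if best is None:
        raise last_err if last_err is not None else FitError("no fit candidates")
    return best


def _fit_once(
    chrom: Chromatogram,
    init: list[dict],
    n_peaks: int,
    baseline: str,
    base0: float,
    share_shape: bool,
    weighting: str,
    sigma_bounds: tuple[float, float],
    tau_bounds: tuple[float, float],
) -> PeakFit:
    t = chrom.time
    if weighting == "cv":
        window = min(31, len(chrom) if len(chrom) % 2 else len(chrom) - 1)
        ref = smooth(chrom, window, min(4, window - 1)).intensity if window >= 5 \
            else chrom.intensity
        mag = np.abs(ref)
        weights = 1.0 / np.maximum(mag, 1e-2 * max(mag.max(), 1e-12))
    elif weighting == "none":
        weights = np.ones_like(t)
    else:
        raise ValueError("weighting must be 'cv' or 'none'")
    params = Parameters()
    big_area = max(
        10.0 * np.trapezoid(np.abs(chrom.intensity), t), 1e-6
    )
    for i, g in enumerate(init):
        params.add(f"a{i}", value=max(g["area"], 1e-9), min=0.0, max=big_area)
        params.add(f"mu{i}", value=float(np.clip(g["center"], t[0], t[-1])),
                   min=t[0], max=t[-1])
        if share_shape and i > 0:
            params.add(f"sigma{i}", expr="sigma0")
            params.add(f"tau{i}", expr="tau0")
        else:
            params.add(f"sigma{i}", value=np.clip(g["sigma"], *sigma_bounds),
                       min=sigma_bounds[0], max=sigma_bounds[1])
            params.add(f"tau{i}", value=np.clip(g["tau"], *tau_bounds),
                       min=tau_bounds[0], max=tau_bounds[1])
    params.add("b0", value=base0)
    params.add("b1", value=0.0, vary=baseline == "linear")

    def residual(p):
        vals = {k: p[k].value for k in p}
        return (_emg_sum(t, vals, n_peaks) - chrom.intensity) * weights

    result = minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitError(f"EMG fit did not converge: {result.message}")
    covar = getattr(result, "covar", None)
    if covar is None:
        raise FitError(
            "EMG fit produced no covariance (degenerate or signal-free data); "
            "check the trace or supply explicit init"
        )

    var_names = result.var_names
    peaks, ses, pinned = [], [], []
    for i in range(n_peaks):
        p = result.params
        peaks.append(
            EMGPeak(p[f"a{i}"].value, p[f"mu{i}"].value,
                    p[f"sigma{i}"].value, p[f"tau{i}"].value)
        )
        stderr = p[f"a{i}"].stderr
        if stderr is None and f"a{i}" in var_names:
            j = var_names.index(f"a{i}")
            stderr = float(np.sqrt(max(covar[j, j], 0.0)))
        ses.append(float(stderr) if stderr is not None else float("nan"))
        for name, bounds in ((f"sigma{i}", sigma_bounds), (f"tau{i}", tau_bounds)):
            v = p[name].value
            if np.isclose(v, bounds[0]) or np.isclose(v, bounds[1]):
                pinned.append(name)
        if np.isclose(p[f"a{i}"].value, 0.0, atol=1e-12):
            pinned.append(f"a{i}")
    order = np.argsort([pk.center for pk in peaks])
    peaks = [peaks[i] for i in order]
    ses = [ses[i] for i in order]
    return PeakFit(
        peaks=peaks,
        area_stderr=ses,
        baseline=(result.params["b0"].value, result.params["b1"].value),
        covariance=covar,
        residual_norm=float(np.sqrt(np.sum(result.residual**2))),
        at_bounds=pinned,
        success=True,
    )


def integrate_peak(
    chrom: Chromatogram,
    bounds: tuple[float, float],
    baseline: str = "none",
    flank_width: float = 0.2,
) -> tuple[float, float]:
    """Trapezoidal peak area over ``bounds`` with optional linear baseline.

    ``baseline="linear-endpoints"`` subtracts the straight line through the
    signal values at the two interval endpoints.  The reported standard
    deviation is a noise-floor estimate: the RMS residual of the raw trace to
    its smoothed version inside flanking windows of ``flank_width`` minutes on
    either side of the interval, scaled by sqrt(n_points) * dt.
    """
    lo, hi = bounds
    if hi <= lo:
        raise ValueError("empty integration interval")
    sel = (chrom.time >= lo) & (chrom.time <= hi)
    if sel.sum() < 2:
        raise ValueError("integration interval contains fewer than 2 samples")
    t, y = chrom.time[sel], chrom.intensity[sel]
    if baseline == "none":
        base = np.zeros_like(y)
    elif baseline == "linear-endpoints":
        base = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
    else:
        raise ValueError("baseline must be 'none' or 'linear-endpoints'")
    area = float(np.trapezoid(y - base, t))

    flanks = ((chrom.time >= lo - flank_width) & (chrom.time < lo)) | (
        (chrom.time > hi) & (chrom.time <= hi + flank_width)
    )
    dt = float(np.median(np.diff(chrom.time)))
    if flanks.sum() >= 7:
        win = min(7, flanks.sum() if flanks.sum() % 2 else flanks.sum() - 1)
        resid = chrom.intensity[flanks] - savgol_filter(
            chrom.intensity[flanks], win, 2
        )
        noise_rms = float(np.sqrt(np.mean(resid**2)))
    else:
        noise_rms = 0.0
    sd = noise_rms * np.sqrt(sel.sum()) * dt
    return area, sd


@dataclass(frozen=True)
class RRFEntry:
    amino_acid: str
    rrf: float
    rrf_sd: float

    def __post_init__(self) -> None:
        if self.rrf <= 0:
            raise ValueError("RRF must be positive")


def compute_rrf(
    fmoc_area: float,
    acetyl_area: float,
    fmoc_sd: float = 0.0,
    acetyl_sd: float = 0.0,
    amino_acid: str = "",
) -> RRFEntry:
    """Relative response factor RRF = S_Fmoc / S_Ac from the equimolar
    split-sample calibration, with first-order error propagation."""
    if acetyl_area <= 0:
        raise ValueError("acetyl calibration area must be positive")
    if fmoc_area <= 0:
        raise ValueError("Fmoc calibration area must be positive")
    if fmoc_sd == 0 and acetyl_sd == 0:
        return RRFEntry(amino_acid, fmoc_area / acetyl_area, 0.0)
    r = ufloat(fmoc_area, fmoc_sd) / ufloat(acetyl_area, acetyl_sd)
    return RRFEntry(amino_acid, r.nominal_value, r.std_dev)


def acetylated_fraction(
    s_ac: float,
    s_fmoc: float,
    rrf: float,
    s_ac_sd: float = 0.0,
    s_fmoc_sd: float = 0.0,
    rrf_sd: float = 0.0,
    rrf_orientation: str = "fmoc_over_acetyl",
) -> tuple[float, float]:
    """Acetylated fraction f = S_Ac / (S_Ac + S_Fmoc / RRF) with its sd.

    The RRF corrects the Fmoc-derivative area onto the acetyl response scale;
    dividing by ``RRF = S_Fmoc/S_Ac`` (equimolar calibration) guarantees that
    an equimolar pool gives exactly f = 0.5.  If a calibration table uses the
    reciprocal convention, pass ``rrf_orientation="acetyl_over_fmoc"``.
    Inputs are treated as independent; the sd is first-order propagation.
    """
    if s_ac < 0 or s_fmoc < 0:
        raise ValueError("areas must be non-negative")
    if rrf <= 0:
        raise ValueError("RRF must be positive")
    if s_ac + s_fmoc == 0:
        raise ValueError("both areas are zero")
    if rrf_orientation not in ("fmoc_over_acetyl", "acetyl_over_fmoc"):
        raise ValueError("rrf_orientation must be fmoc_over_acetyl or acetyl_over_fmoc")
    if s_ac == 0:
        return 0.0, 0.0
    if s_ac_sd == 0 and s_fmoc_sd == 0 and rrf_sd == 0:
        r = 1.0 / rrf if rrf_orientation == "acetyl_over_fmoc" else rrf
        return s_ac / (s_ac + s_fmoc / r), 0.0
    # exact (sd == 0) inputs enter as plain floats: ufloat(x, 0) is
    # deprecated upstream and adds nothing to the propagation
    rrf_eff = ufloat(rrf, rrf_sd) if rrf_sd else rrf
    if rrf_orientation == "acetyl_over_fmoc":
        rrf_eff = rrf_eff**-1
    ac = ufloat(s_ac, s_ac_sd) if s_ac_sd else s_ac
    fm = ufloat(s_fmoc, s_fmoc_sd) if s_fmoc_sd else s_fmoc
    f = ac / (ac + fm / rrf_eff)
    return f.nominal_value, f.std_dev


def spike_normalize(areas: pd.DataFrame, spike_area: float, column: str = "area") -> pd.DataFrame:
    """Divide peak areas by the internal-standard (15N-AMP) area of the sample.

    Returns a copy with ``column`` (and ``column + '_sd'`` when present)
    rescaled; the spike area must be positive.
    """
    if spike_area <= 0:
        raise ValueError("spike-in area must be positive")
    out = areas.copy()
    out[column] = out[column] / spike_area
    sd_col = f"{column}_sd"
    if sd_col in out.columns:
        out[sd_col] = out[sd_col] / spike_area
    return out


@dataclass(frozen=True)
class QuantifiedSpecies:
    amino_acid: str
    s_ac: float
    s_ac_sd: float
    s_fmoc: float
    s_fmoc_sd: float
    rrf: float
    rrf_sd: float
    fraction: float
    fraction_sd: float


def quantify_samples(
    areas: pd.DataFrame,
    rrf_table: pd.DataFrame,
    rrf_orientation: str = "fmoc_over_acetyl",
) -> pd.DataFrame:
    """Join per-sample acetyl/Fmoc areas with an RRF table and compute
    acetylated fractions.

    ``areas`` columns: ``sample, species, derivative in {acetyl,fmoc}, area,
    area_sd``; ``rrf_table`` columns: ``amino_acid, rrf, rrf_sd``.  Returns one
    row per (sample, species) with the fraction and its propagated sd.
    """
    required = {"sample", "species", "derivative", "area", "area_sd"}
    if not required <= set(areas.columns):
        raise ValueError(f"areas table needs columns {sorted(required)}")
    rrfs = rrf_table.set_index("amino_acid")
    rows = []
    wide = areas.pivot_table(
        index=["sample", "species"],
        columns="derivative",
        values=["area", "area_sd"],
        aggfunc="sum",
    )
    for (sample, species), row in wide.iterrows():
        if species not in rrfs.index:
            raise KeyError(f"no RRF entry for species {species!r}")
        s_ac = float(row.get(("area", "acetyl"), 0.0) or 0.0)
        s_fm = float(row.get(("area", "fmoc"), 0.0) or 0.0)
        sd_ac = float(row.get(("area_sd", "acetyl"), 0.0) or 0.0)
        sd_fm = float(row.get(("area_sd", "fmoc"), 0.0) or 0.0)
        rrf = float(rrfs.loc[species, "rrf"])
        rrf_sd = float(rrfs.loc[species, "rrf_sd"])
        f, f_sd = acetylated_fraction(
            s_ac, s_fm, rrf, sd_ac, sd_fm, rrf_sd, rrf_orientation
        )
        rows.append(
            dict(sample=sample, amino_acid=species, S_ac=s_ac, S_ac_sd=sd_ac,
                 S_fmoc=s_fm, S_fmoc_sd=sd_fm, rrf=rrf, fraction=f,
                 fraction_sd=f_sd)
        )
    return pd.DataFrame(rows)
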