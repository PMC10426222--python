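"""Curated highly-comparative time-series feature bank.

A few hundred interpretable statistics are computed per PPG window, spanning
the operation families that matter for pulse waveforms: distribution shape,
stationarity, autocorrelation, Gaussian auto-mutual information (on raw and
first-differenced series), coarse-grained motif proportions, AR model fits
with order selection, GARCH conditional-heteroskedasticity fits, exponential
smoothing, a least-squares state-space style train/predict fit, FFT spectral
summaries, a 2-D time-delay embedding, and wavelet fractional-Brownian-motion
scaling.

Feature identifiers follow a two-part scheme ``<tertiary>.<output>`` where the
tertiary name encodes the algorithm family, master operation, and defining
arguments (e.g. ``IN_AutoMutualInfoStats_diff_20_gaussian.ami3``).  Grouping
at "tertiary similarity" therefore means grouping on the part before the dot.

Features that evaluate to a non-finite number are emitted as missing; the
matrix builder applies the validity filter cohort-wide (a column missing for
any window is dropped for all windows), and max-min normalization rescales
every retained column to [0, 1] pooled across participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import optimize, signal as sps

from .dataset_io import LabeledWindow

__all__ = [
    "FeatureBankConfig",
    "FeatureMatrix",
    "extract",
    "build_matrix",
    "maxmin_normalize",
    "tertiary_family",
    "gaussian_ami",
    "ALL_FAMILIES",
    "FAST_FAMILIES",
]

ALL_FAMILIES = (
    "DN_Summaries",
    "DN_Diff",
    "SY_StatAv",
    "CO_AutoCorr",
    "IN_AutoMutualInfoStats_20_gaussian",
    "IN_AutoMutualInfoStats_diff_20_gaussian",
    "SB_MotifThree_diffquant",
    "MF_arfit_1_8_sbc",
    "MF_AR_arcov_5",
    "MF_GARCH_ar_P1_Q2",
    "MF_ExpSmoothing_05_best",
    "MF_StateSpace_ls_2",
    "SP_Summaries_fft",
    "CO_Embed2_Basic_tau",
    "WL_fBM",
)

#: everything except the iterative GARCH optimizer; for repeated simulation runs
FAST_FAMILIES = tuple(f for f in ALL_FAMILIES if f != "MF_GARCH_ar_P1_Q2")


@dataclass(frozen=True)
class FeatureBankConfig:
    families: tuple[str, ...] = ALL_FAMILIES
    ar_order_max: int = 8  # AR orders 1..max with SBC selection
    ami_max_delay: int = 20
    motif_word_lengths: tuple[int, ...] = (1, 2, 3, 4)
    garch_p: int = 1  # GARCH lags on conditional variance
    garch_q: int = 2  # GARCH lags on squared innovations
    embed_tau_cap: int = 20
    stationarity_blocks: tuple[int, ...] = (5, 10)

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("enabled families must be non-empty")
        unknown = set(self.families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        if self.ar_order_max < 1 or self.ami_max_delay < 1:
            raise ValueError("orders and delays must be >= 1")


@dataclass
class FeatureMatrix:
    """Windows x features table with identity metadata."""

    values: pd.DataFrame  # index window_id, columns feature ids
    metadata: pd.DataFrame  # index window_id
    normalization: str = "raw"  # "raw" | "maxmin"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def session_ids(self) -> pd.Series:
        return self.metadata["participant_id"].astype(str) + "-" + self.metadata["day"].astype(str)


def tertiary_family(feature_id: str) -> str:
    """Tertiary operation family of a feature id (the part before the dot)."""
    return feature_id.split(".", 1)[0]


# ---------------------------------------------------------------------------
# primitive statistics
# ---------------------------------------------------------------------------

def _acf(x: np.ndarray, nlags: int) -> np.ndarray:
    """Biased-normalized autocorrelation, FFT-based."""
    x = x - x.mean()
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx))[: nlags + 1] / n
    if acov[0] == 0:
        return np.full(nlags + 1, np.nan)
    return acov / acov[0]


def gaussian_ami(x: np.ndarray, lag: int) -> float:
    """Gaussian-estimator auto-mutual information at one lag.

    For a jointly Gaussian pair with correlation rho the mutual information is
    ``-0.5 * ln(1 - rho^2)``; the estimator plugs in the sample correlation of
    ``(x_t, x_{t+lag})``.
    """
    if lag >= len(x) - 1:
        return float("nan")
    a, b = x[:-lag], x[lag:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    rho = float(np.corrcoef(a, b)[0, 1])
    rho = min(max(rho, -0.999999), 0.999999)
    return -0.5 * np.log1p(-(rho**2))


def _ar_ols(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Least-squares AR fit; returns coefficients and residual variance."""
    n = len(x)
    X = np.column_stack([x[order - k - 1 : n - k - 1] for k in range(order)])
    y = x[order:]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid / len(y))


def _first_minimum(v: np.ndarray) -> int:
    for i in range(1, len(v) - 1):
        if v[i] < v[i - 1] and v[i] <= v[i + 1]:
            return i + 1  # lags are 1-based
    return len(v)


# ---------------------------------------------------------------------------
# family extractors (each returns {output_name: value})
# ---------------------------------------------------------------------------

def _f_dn_summaries(raw: np.ndarray) -> dict[str, float]:
    q = np.quantile(raw, [0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99])
    m, s = raw.mean(), raw.std()
    cs = float(np.mean(((raw - m) / s) ** 3)) if s > 0 else np.nan
    ck = float(np.mean(((raw - m) / s) ** 4)) if s > 0 else np.nan
    return {
        "mean": m,
        "std": s,
        "skew": cs,
        "kurtosis": ck,
        "median": q[3],
        "iqr": q[4] - q[2],
        "q01": q[0],
        "q05": q[1],
        "q95": q[5],
        "q99": q[6],
        "mad": float(np.mean(np.abs(raw - m))),
        "range": float(np.ptp(raw)),
        "cv": s / m if m != 0 else np.nan,
        "prop_above_mean": float(np.mean(raw > m)),
        "trimmed_mean_10": float(np.mean(np.sort(raw)[len(raw) // 10 : -len(raw) // 10 or None])),
    }


def _f_dn_diff(z: np.ndarray) -> dict[str, float]:
    d1, d2 = np.diff(z), np.diff(z, 2)
    return {
        "std_diff1": d1.std(),
        "std_diff2": d2.std(),
        "mean_abs_diff": float(np.mean(np.abs(d1))),
        "zcross_rate": float(np.mean(np.diff(np.signbit(z)) != 0)),
        "rmssd": float(np.sqrt(np.mean(d1**2))),
    }


def _f_sy_statav(z: np.ndarray, blocks: tuple[int, ...]) -> dict[str, float]:
    out = {}
    for nb in blocks:
        L = len(z) // nb
        segs = z[: L * nb].reshape(nb, L)
        mu, sd = segs.mean(axis=1), segs.std(axis=1)
        out[f"statav{nb}_mean"] = float(mu.std() / z.std()) if z.std() > 0 else np.nan
        out[f"statav{nb}_std"] = float(sd.std() / z.std()) if z.std() > 0 else np.nan
        out[f"statav{nb}_sdrange"] = float(np.ptp(sd) / (sd.mean() or np.nan))
        out[f"statav{nb}_trend"] = float(np.corrcoef(np.arange(nb), mu)[0, 1]) if mu.std() > 0 else np.nan
    return out


def _f_co_autocorr(z: np.ndarray) -> dict[str, float]:
    ac = _acf(z, 40)
    out = {f"ac{k}": float(ac[k]) for k in range(1, 41)}
    below = np.nonzero(ac[1:] < 0)[0]
    out["first_zero"] = float(below[0] + 1) if len(below) else 40.0
    out["sum_ac10"] = float(ac[1:11].sum())
    out["sum_ac2_40"] = float(np.sum(ac[1:41] ** 2))
    return out


def _f_ami(x: np.ndarray, max_delay: int) -> dict[str, float]:
    ami = np.array([gaussian_ami(x, k) for k in range(1, max_delay + 1)])
    out = {f"ami{k}": float(ami[k - 1]) for k in range(1, max_delay + 1)}
    with np.errstate(invalid="ignore"):
        out["mean"] = float(np.nanmean(ami))
        out["std"] = float(np.nanstd(ami))
        out["first_min"] = float(_first_minimum(ami))
        out["max"] = float(np.nanmax(ami))
    return out


def _f_motif3(z: np.ndarray, word_lengths: tuple[int, ...]) -> dict[str, float]:
    d = np.diff(z)
    thr = np.quantile(d, [1 / 3, 2 / 3])
    sym = np.digitize(d, thr)  # 0,1,2 equiprobable alphabet on differences
    out: dict[str, float] = {}
    letters = "abc"
    for L in word_lengths:
        if len(sym) < L:
            continue
        windows_view = np.lib.stride_tricks.sliding_window_view(sym, L)
        codes = windows_view @ (3 ** np.arange(L - 1, -1, -1))
        counts = np.bincount(codes, minlength=3**L).astype(float)
        props = counts / counts.sum()
        for c, p in enumerate(props):
            word = "".join(letters[(c // 3**k) % 3] for k in range(L - 1, -1, -1))
            out[f"p{L}_{word}"] = float(p)
        nz = props[props > 0]
        out[f"h{L}"] = float(-(nz * np.log(nz)).sum() / np.log(3**L)) if L > 0 else np.nan
    return out


def _f_arfit_sbc(z: np.ndarray, max_order: int) -> dict[str, float]:
    n = len(z)
    out: dict[str, float] = {}
    best_sbc, best_order, best_coef, best_rv = np.inf, 1, None, np.nan
    for p in range(1, max_order + 1):
        coef, rv = _ar_ols(z, p)
        neff = n - p
        sbc = neff * np.log(max(rv, 1e-300)) + p * np.log(neff)
        fpe = rv * (neff + p) / (neff - p)
        out[f"sbc_{p}"] = float(sbc)
        out[f"fpe_{p}"] = float(fpe)
        if sbc < best_sbc:
            best_sbc, best_order, best_coef, best_rv = sbc, p, coef, rv
    out["order"] = float(best_order)
    out["resid_var"] = best_rv
    for k in range(max_order):
        out[f"a{k + 1}"] = float(best_coef[k]) if k < len(best_coef) else 0.0
    # characteristic-root summary of the selected model
    poly = np.r_[1.0, -best_coef]
    roots = np.roots(poly)
    mods = np.abs(1.0 / roots[np.abs(roots) > 1e-12])
    out["max_root_mod"] = float(mods.max()) if len(mods) else np.nan
    out["mean_root_mod"] = float(mods.mean()) if len(mods) else np.nan
    return out


def _ar_covariance(z: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """AR fit from the sample autocovariance sequence (Yule-Walker style)."""
    ac = _acf(z, order)
    R = np.array([[ac[abs(i - j)] for j in range(order)] for i in range(order)])
    r = ac[1 : order + 1]
    coef = np.linalg.solve(R + 1e-12 * np.eye(order), r)
    rv = float(z.var() * (1.0 - coef @ r))
    return coef, rv


def _f_ar_arcov5(z: np.ndarray) -> dict[str, float]:
    coef, rv = _ar_covariance(z, 5)
    out = {f"a{k + 1}": float(c) for k, c in enumerate(coef)}
    out["resid_var"] = rv
    # one-step prediction residual diagnostics
    X = np.column_stack([z[5 - k - 1 : len(z) - k - 1] for k in range(5)])
    resid = z[5:] - X @ coef
    out["resid_ac1"] = float(_acf(resid, 1)[1])
    out["resid_std_ratio"] = float(resid.std() / z.std()) if z.std() > 0 else np.nan
    return out


def _garch_negloglik(params: np.ndarray, e2: np.ndarray, var0: float) -> float:
    omega, a1, a2, b1 = params
    if min(omega, a1, a2, b1) < 0 or a1 + a2 + b1 >= 0.9999:
        return 1e12
    x = omega + a1 * np.r_[var0, e2[:-1]] + a2 * np.r_[var0, var0, e2[:-2]]
    sigma2, _ = sps.lfilter([1.0], [1.0, -b1], x, zi=np.array([b1 * var0]))
    sigma2 = np.maximum(sigma2, 1e-12)
    return float(0.5 * np.sum(np.log(sigma2) + e2 / sigma2))


def _f_garch(z: np.ndarray, ar_max: int, p: int, q: int) -> dict[str, float]:
    """AR pre-whitening (SBC-selected order) then GARCH(p=1, q=2) by Gaussian
    quasi-maximum-likelihood on the innovations."""
    # pre-whiten
    best = (np.inf, 1)
    for k in range(1, ar_max + 1):
        _, rv = _ar_ols(z, k)
        neff = len(z) - k
        sbc = neff * np.log(max(rv, 1e-300)) + k * np.log(neff)
        if sbc < best[0]:
            best = (sbc, k)
    order = best[1]
    coef, _ = _ar_ols(z, order)
    X = np.column_stack([z[order - k - 1 : len(z) - k - 1] for k in range(order)])
    e = z[order:] - X @ coef
    e2 = e**2
    var0 = float(e2.mean())
    if var0 <= 0:
        return {k: np.nan for k in ("omega", "alpha1", "alpha2", "beta1",
                                    "persistence", "nll", "std_kurt", "std_ac1_sq")}
    x0 = np.array([0.1 * var0, 0.05, 0.05, 0.8])
    res = optimize.minimize(
        _garch_negloglik,
        x0,
        args=(e2, var0),
        method="Nelder-Mead",
        options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-6},
    )
    omega, a1, a2, b1 = res.x
    nll = _garch_negloglik(res.x, e2, var0)
    if nll >= 1e11:
        return {k: np.nan for k in ("omega", "alpha1", "alpha2", "beta1",
                                    "persistence", "nll", "std_kurt", "std_ac1_sq")}
    x = omega + a1 * np.r_[var0, e2[:-1]] + a2 * np.r_[var0, var0, e2[:-2]]
    sigma2, _ = sps.lfilter([1.0], [1.0, -b1], x, zi=np.array([b1 * var0]))
    std = e / np.sqrt(np.maximum(sigma2, 1e-12))
    return {
        "omega": float(omega),
        "alpha1": float(a1),
        "alpha2": float(a2),
        "beta1": float(b1),
        "persistence": float(a1 + a2 + b1),
        "nll": float(nll),
        "std_kurt": float(np.mean(std**4)),
        "std_ac1_sq": float(_acf(std**2, 1)[1]),
    }


def _f_expsmooth(z: np.ndarray) -> dict[str, float]:
    """Simple exponential smoothing; alpha trained on the first half."""
    half = len(z) // 2
    train, test = z[:half], z[half:]
    alphas = np.linspace(0.05, 0.95, 19)
    best_alpha, best_sse = np.nan, np.inf
    for a in alphas:
        level, _ = sps.lfilter([a], [1.0, -(1.0 - a)], train, zi=np.array([(1 - a) * train[0]]))
        sse = float(np.sum((train[1:] - level[:-1]) ** 2))
        if sse < best_sse:
            best_sse, best_alpha = sse, a
    a = best_alpha
    level, zf = sps.lfilter([a], [1.0, -(1.0 - a)], train, zi=np.array([(1 - a) * train[0]]))
    train_rmse = float(np.sqrt(best_sse / (half - 1)))
    level_test, _ = sps.lfilter([a], [1.0, -(1.0 - a)], test, zi=zf)
    resid = test[1:] - level_test[:-1]
    test_rmse = float(np.sqrt(np.mean(resid**2)))
    return {
        "alpha": float(a),
        "train_rmse": train_rmse,
        "test_rmse": test_rmse,
        "rmse_ratio": test_rmse / train_rmse if train_rmse > 0 else np.nan,
        "resid_ac1": float(_acf(resid, 1)[1]),
    }


def _f_statespace(z: np.ndarray) -> dict[str, float]:
    """Fixed-order linear predictor trained on the first half, scored on the
    second half (least-squares stand-in for subspace state-space fitting)."""
    order = 4
    half = len(z) // 2
    train, test = z[:half], z[half:]
    coef, rv = _ar_ols(train, order)
    X = np.column_stack([test[order - k - 1 : len(test) - k - 1] for k in range(order)])
    resid = test[order:] - X @ coef
    test_rmse = float(np.sqrt(np.mean(resid**2)))
    return {
        "coef_sum": float(coef.sum()),
        "train_rmse": float(np.sqrt(rv)),
        "test_rmse": test_rmse,
        "rmse_ratio": test_rmse / np.sqrt(rv) if rv > 0 else np.nan,
        "resid_ac1": float(_acf(resid, 1)[1]),
        "max_coef": float(np.abs(coef).max()),
    }


def _f_spectral(z: np.ndarray, fs: float = 64.0) -> dict[str, float]:
    f, pxx = sps.periodogram(z, fs=fs, window="hann")
    f, pxx = f[1:], pxx[1:]
    total = pxx.sum()
    if total <= 0:
        return {}
    p = pxx / total
    centroid = float((f * p).sum())
    spread = float(np.sqrt(((f - centroid) ** 2 * p).sum()))
    cum = np.cumsum(p)
    out = {
        "total_power": float(total),
        "centroid": centroid,
        "spread": spread,
        "peak_freq": float(f[np.argmax(pxx)]),
        "peak_power": float(p.max()),
        "entropy": float(-(p[p > 0] * np.log(p[p > 0])).sum() / np.log(len(p))),
        "flatness": float(np.exp(np.mean(np.log(pxx + 1e-300))) / pxx.mean()),
    }
    for qq in (5, 25, 50, 75, 95):
        out[f"f{qq}"] = float(f[np.searchsorted(cum, qq / 100.0)])
    bands = [(0.0, 0.1), (0.1, 0.5), (0.5, 1.5), (1.5, 4.0), (4.0, 8.0), (8.0, 32.0)]
    for lo, hi in bands:
        sel = (f >= lo) & (f < hi)
        out[f"band_{lo:g}_{hi:g}"] = float(p[sel].sum())
    return out


def _f_embed2(z: np.ndarray, tau_cap: int) -> dict[str, float]:
    ami = np.array([gaussian_ami(z, k) for k in range(1, tau_cap + 1)])
    tau = int(min(_first_minimum(ami), tau_cap))
    u, v = z[:-tau], z[tau:]
    d = np.abs(v - u) / np.sqrt(2.0)  # distance from the u = v diagonal
    r = np.sqrt(u**2 + v**2)
    return {
        "tau": float(tau),
        "inc_01": float(np.mean(d < 0.1)),
        "inc_05": float(np.mean(d < 0.5)),
        "incircle_1": float(np.mean(r < 1.0)),
        "incircle_2": float(np.mean(r < 2.0)),
        "mean_dist_diag": float(d.mean()),
        "std_dist_diag": float(d.std()),
        "coord_corr": float(np.corrcoef(u, v)[0, 1]),
    }


def _f_wl_fbm(z: np.ndarray) -> dict[str, float]:
    """Wavelet log-variance scaling: slope estimates the fBm/fGn exponent."""
    max_level = min(6, pywt.dwt_max_level(len(z), pywt.Wavelet("db3").dec_len))
    coeffs = pywt.wavedec(z, "db3", level=max_level)
    details = coeffs[1:][::-1]  # level 1 (finest) first
    logvar = np.array([np.log2(np.mean(c**2) + 1e-300) for c in details])
    levels = np.arange(1, len(logvar) + 1)
    slope, intercept = np.polyfit(levels, logvar, 1)
    resid = logvar - (slope * levels + intercept)
    hurst = (slope - 1.0) / 2.0  # fGn convention
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "hurst": float(hurst),
        "fit_resid": float(np.sqrt(np.mean(resid**2))),
        "ratio_fine_coarse": float(np.exp2(logvar[0] - logvar[-1])),
    }


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

def extract(samples: np.ndarray, config: FeatureBankConfig = FeatureBankConfig()) -> dict[str, float]:
    """Compute the enabled feature bank for one window.

    Returns ``{feature_id: value}``; non-finite evaluations are returned as
    NaN (missing).  Distribution features are computed on the raw samples,
    everything else on the z-scored window; an all-constant window yields
    missing values for every model-based family.
    """
    raw = np.asarray(samples, dtype=float)
    if len(raw) < 256:
        raise ValueError("window too short: need >= 256 samples")
    if not np.isfinite(raw).all():
        raise ValueError("non-finite samples in window")
    sd = raw.std()
    z = (raw - raw.mean()) / sd if sd > 0 else None

    out: dict[str, float] = {}

    def add(family: str, values: dict[str, float]) -> None:
        for k, v in values.items():
            out[f"{family}.{k}"] = float(v) if v is not None and np.isfinite(v) else np.nan

    for fam in config.families:
        if fam == "DN_Summaries":
            add(fam, _f_dn_summaries(raw))
            continue
        if z is None:
            # constant window: model families undefined
            continue
        if fam == "DN_Diff":
            add(fam, _f_dn_diff(z))
        elif fam == "SY_StatAv":
            add(fam, _f_sy_statav(z, config.stationarity_blocks))
        elif fam == "CO_AutoCorr":
            add(fam, _f_co_autocorr(z))
        elif fam == "IN_AutoMutualInfoStats_20_gaussian":
            add(fam, _f_ami(z, config.ami_max_delay))
        elif fam == "IN_AutoMutualInfoStats_diff_20_gaussian":
            add(fam, _f_ami(np.diff(z), config.ami_max_delay))
        elif fam == "SB_MotifThree_diffquant":
            add(fam, _f_motif3(z, config.motif_word_lengths))
        elif fam == "MF_arfit_1_8_sbc":
            add(fam, _f_arfit_sbc(z, config.ar_order_max))
        elif fam == "MF_AR_arcov_5":
            add(fam, _f_ar_arcov5(z))
        elif fam == "MF_GARCH_ar_P1_Q2":
            add(fam, _f_garch(z, config.ar_order_max, config.garch_p, config.garch_q))
        elif fam == "MF_ExpSmoothing_05_best":
            add(fam, _f_expsmooth(z))
        elif fam == "MF_StateSpace_ls_2":
            add(fam, _f_statespace(z))
        elif fam == "SP_Summaries_fft":
            add(fam, _f_spectral(z))
        elif fam == "CO_Embed2_Basic_tau":
            add(fam, _f_embed2(z, config.embed_tau_cap))
        elif fam == "WL_fBM":
            add(fam, _f_wl_fbm(z))
    return out


def build_matrix(
    windows: list[LabeledWindow],
    config: FeatureBankConfig = FeatureBankConfig(),
) -> FeatureMatrix:
    """Extract the bank for every window and apply the validity filter.

    Columns with any missing value across the cohort are dropped for all
    windows, mirroring the exclusion of calculations that do not evaluate to
    a real number.
    """
    if not windows:
        raise ValueError("window list is empty")
    ids = [w.window_id for w in windows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate window ids")
    rows = [extract(w.samples, config) for w in windows]
    values = pd.DataFrame(rows, index=pd.Index(ids, name="window_id"))
    valid = values.columns[values.notna().all(axis=0)]
    values = values[valid]
    metadata = pd.DataFrame(
        {
            "participant_id": [w.participant_id for w in windows],
            "day": [w.day for w in windows],
            "group": [w.group for w in windows],
            "anger": [w.anger for w in windows],
            "section_method": [w.section_method for w in windows],
            "t_start": [w.t_start for w in windows],
        },
        index=pd.Index(ids, name="window_id"),
    )
    return FeatureMatrix(values=values, metadata=metadata, normalization="raw")


def maxmin_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Rescale every column to [0, 1] over all windows pooled across
    participants; zero-range columns are dropped with a warning."""
    if matrix.normalization == "maxmin":
        return matrix
    if len(matrix.values) < 2:
        raise ValueError("need >= 2 windows to normalize")
    vals = matrix.values
    lo, hi = vals.min(axis=0), vals.max(axis=0)
    rng = hi - lo
    flat = rng[rng == 0].index
    if len(flat):
        warnings.warn(f"dropping {len(flat)} zero-range feature columns", stacklevel=2)
    keep = rng[rng > 0].index
    normed = (vals[keep] - lo[keep]) / rng[keep]
    return FeatureMatrix(values=normed, metadata=matrix.metadata, normalization="maxmin")
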