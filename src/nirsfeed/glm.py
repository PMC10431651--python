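"""Design matrices and the robust autoregressive GLM for channel activation.

Each long channel's ΔHbO2 series is modelled with HRF-convolved task and
rest regressors, a short-channel (scalp) nuisance regressor and an
intercept.  Fitting iterates: ordinary/weighted least squares → AR(p)
estimation on the residuals (order chosen by BIC) → prewhitening of data and
design by the AR filter → Tukey-bisquare reweighting of whitened residuals —
the AR-IRLS scheme that corrects both serial correlation and outliers.

Band-passed fNIRS noise is not AR-invertible (its spectrum is essentially
zero outside the pass-band), so after the AR step residual correlation
always survives.  Standard errors therefore come from a frequency-domain
sandwich: a multitaper estimate of the whitened-residual spectrum —
design-dominated bins interpolated away, the whole estimate constrained to
the known band-pass/AR power envelope — integrated against each regressor's
spectral influence, with Satterthwaite effective degrees of freedom.  This
keeps channel-wise type-I error at its nominal level under the strongly
band-limited residuals the offline pipeline produces.

A channel counts as activated when its task beta is positive and its
two-sided p-value clears a Bonferroni threshold computed per region of
interest (α/4 for the DL-PFC neurofeedback region, α/12 for the other
frontal channels, α/1 for motor).

Task regressors are normalised so that one 30-s trial's convolved response
peaks at 1; task betas therefore read directly as the peak ΔHbO2 (µM) evoked
per trial.  The same temporal filtering applied to the data (band-pass +
resampling) is applied to the task/rest columns so in-band response
amplitudes are estimated without attenuation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import signal, stats
from scipy.signal.windows import dpss
from statsmodels.tsa.stattools import levinson_durbin

from .preprocess import HemoTimeSeries, bandpass
from .probe_paradigm import Paradigm, ProbeLayout

__all__ = [
    "HrfModel",
    "DesignMatrix",
    "ChannelFit",
    "GLMResult",
    "canonical_hrf",
    "task_regressor",
    "build_design",
    "fit_ar_irls",
    "fit_glm",
    "trial_t_table",
    "roi_activation",
]

TUKEY_C = 4.685  # bisquare tuning constant, 95% Gaussian efficiency
BETA_TOL = 1e-6
MAX_ITER = 50

# multitaper parameters for the residual-spectrum variance estimator
MT_NW = 4.0
MT_K = 7
SPECTRUM_SMOOTH_BINS = 32      # half-width of the background averaging window
_LINE_THRESHOLD = float(stats.chi2.ppf(0.99, 2 * MT_K) / (2 * MT_K))

ROI_SIZES = {"nf_dlpfc": 4, "other_frontal": 12, "motor": 1}


# ---------------------------------------------------------------------------
# hemodynamic response function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HrfModel:
    """Canonical difference-of-gammas HRF.

    Positive lobe peaks at `peak_time`, undershoot at `undershoot_time`,
    support `duration`, undershoot amplitude = peak/`1/undershoot_ratio`.
    """

    fs: float
    peak_time: float = 4.0
    undershoot_time: float = 16.0
    duration: float = 32.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def canonical_hrf(fs: float, peak_time: float = 4.0, undershoot_time: float = 16.0,
                  duration: float = 32.0, undershoot_ratio: float = 1.0 / 6.0) -> HrfModel:
    """Difference of two unit-dispersion gamma densities, unit peak.

    With dispersion 1 the gamma density t^(a-1)·e^(−t)/Γ(a) has its mode at
    a−1, so shapes a = peak_time+1 and undershoot_time+1 put the lobes where
    requested; each lobe is peak-normalised before the weighted difference,
    making the undershoot-to-peak magnitude ratio equal to the requested one
    up to the (tiny) overlap of the lobes.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    t = np.arange(0.0, duration + 0.5 / fs, 1.0 / fs)

    def lobe(mode: float) -> np.ndarray:
        a = mode + 1.0
        g = stats.gamma.pdf(t, a)
        return g / g.max()

    kernel = lobe(peak_time) - undershoot_ratio * lobe(undershoot_time)
    kernel = kernel / kernel.max()
    return HrfModel(fs=fs, peak_time=peak_time, undershoot_time=undershoot_time,
                    duration=duration, undershoot_ratio=undershoot_ratio, kernel=kernel)


def _boxcar(onsets: np.ndarray, duration: float, fs: float, n_samples: int) -> np.ndarray:
    x = np.zeros(n_samples)
    for t0 in np.atleast_1d(onsets):
        i0 = int(round(t0 * fs))
        i1 = min(int(round((t0 + duration) * fs)), n_samples)
        if i0 < n_samples:
            x[i0:i1] = 1.0
    return x


def single_trial_peak(hrf: HrfModel, duration: float = 30.0) -> float:
    """Peak of one `duration`-s boxcar convolved with the HRF (normalisation unit)."""
    n = int(round((duration + hrf.duration) * hrf.fs)) + 1
    box = _boxcar(np.array([0.0]), duration, hrf.fs, n)
    resp = np.convolve(box, hrf.kernel)[:n]
    return float(resp.max())


def task_regressor(onsets: np.ndarray, duration: float, hrf: HrfModel,
                   n_samples: int, normalize: bool = True) -> np.ndarray:
    """Boxcar ⊛ HRF regressor; unit peak for a single 30-s style trial."""
    box = _boxcar(np.asarray(onsets, dtype=float), duration, hrf.fs, n_samples)
    x = np.convolve(box, hrf.kernel)[:n_samples]
    if normalize:
        x = x / single_trial_peak(hrf, duration)
    return x


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    values: np.ndarray  # (n_samples, n_columns)
    names: list[str]
    fs: float
    task_columns: list[str]

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.names):
            raise ValueError("column names do not match design shape")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError(
                f"rank-deficient design; check for collinear columns among {self.names}"
            )

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values))

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


def build_design(
    paradigm: Paradigm,
    hrf: HrfModel,
    n_samples: int,
    sc_series: np.ndarray | None = None,
    mode: str = "trialwise",
    selected_trials: Sequence[int] | None = None,
    filter_band: tuple[float, float] | None = None,
    include_drift: bool = True,
) -> DesignMatrix:
    """Assemble the GLM design at the analysis rate.

    trialwise: one task column per trial (15 at default), a rest column, the
    short-channel nuisance column (if given), a linear drift column and an
    intercept.  pooled: one task column over `selected_trials` (1-based)
    plus, when any trials are unselected, a nuisance column over the rest;
    rest/SC/drift/intercept as above.

    `filter_band` applies the offline zero-phase band-pass to the task, rest
    and drift columns so they live in the same band as the filtered data
    (a ramp is not fully removed by the high-pass — its filtered remnant
    must be modelled or it biases every fit); the SC series is expected to
    be preprocessed already.
    """
    fs = hrf.fs
    onsets = paradigm.onsets

    def maybe_filter(x: np.ndarray) -> np.ndarray:
        return bandpass(x, fs, filter_band) if filter_band is not None else x

    cols: list[np.ndarray] = []
    names: list[str] = []
    task_cols: list[str] = []
    if mode == "trialwise":
        for i in range(paradigm.n_trials):
            name = f"task_{i + 1:02d}"
            cols.append(maybe_filter(
                task_regressor(onsets[i:i + 1], paradigm.task_s, hrf, n_samples)))
            names.append(name)
            task_cols.append(name)
    elif mode == "pooled":
        if not selected_trials:
            raise ValueError("pooled mode requires a non-empty selected_trials")
        sel = sorted(set(int(t) for t in selected_trials))
        if any(t < 1 or t > paradigm.n_trials for t in sel):
            raise ValueError(f"selected_trials outside 1..{paradigm.n_trials}")
        unsel = [t for t in range(1, paradigm.n_trials + 1) if t not in sel]
        cols.append(maybe_filter(task_regressor(
            onsets[[t - 1 for t in sel]], paradigm.task_s, hrf, n_samples)))
        names.append("task")
        task_cols.append("task")
        if unsel:
            cols.append(maybe_filter(task_regressor(
                onsets[[t - 1 for t in unsel]], paradigm.task_s, hrf, n_samples)))
            names.append("task_unselected")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    cols.append(maybe_filter(task_regressor(
        paradigm.rest_onsets, paradigm.rest_s, hrf, n_samples)))
    names.append("rest")
    if include_drift:
        ramp = np.linspace(-0.5, 0.5, n_samples)
        cols.append(maybe_filter(ramp))
        names.append("drift")
    if sc_series is not None:
        sc = np.asarray(sc_series, dtype=float)
        if sc.shape[0] != n_samples:
            raise ValueError("sc_series length does not match n_samples")
        cols.append(sc)
        names.append("sc")
    cols.append(np.ones(n_samples))
    names.append("const")
    return DesignMatrix(values=np.column_stack(cols), names=names, fs=fs,
                        task_columns=task_cols)


# ---------------------------------------------------------------------------
# AR-IRLS fitting
# ---------------------------------------------------------------------------

@dataclass
class ChannelFit:
    channel: str
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    dof: np.ndarray  # effective dof per regressor
    ar_order: int
    n_iter: int
    converged: bool
    weight_mean: float

    def __getitem__(self, name: str) -> dict:
        j = self.names.index(name)
        return {"beta": self.beta[j], "se": self.se[j], "t": self.t[j],
                "p": self.p[j], "dof": float(np.atleast_1d(self.dof)[j] if np.ndim(self.dof) else self.dof)}


@dataclass
class GLMResult:
    fits: dict[str, ChannelFit]

    def __getitem__(self, channel: str) -> ChannelFit:
        return self.fits[channel]

    def to_frame(self):
        import pandas as pd

        rows = []
        for ch, fit in self.fits.items():
            for j, name in enumerate(fit.names):
                rows.append({"channel": ch, "regressor": name, "beta": fit.beta[j],
                             "se": fit.se[j], "t": fit.t[j], "p": fit.p[j],
                             "dof": float(np.atleast_1d(fit.dof)[j] if np.ndim(fit.dof) else fit.dof),
                             "ar_order": fit.ar_order,
                             "converged": fit.converged})
        return pd.DataFrame(rows)


def _select_ar(resid: np.ndarray, p_max: int) -> np.ndarray:
    """AR coefficients minimising BIC over order 0..p_max (Levinson–Durbin)."""
    n = resid.size
    v = resid - resid.mean()
    if p_max == 0 or np.allclose(v, 0):
        return np.empty(0)
    sigma_v, arcoefs, _, sigma, phi = levinson_durbin(v, nlags=p_max, isacov=False)
    # `sigma` holds innovation variances for orders 1..p_max; order 0 is var(v)
    var0 = float(np.mean(v * v))
    variances = np.concatenate([[var0], np.asarray(sigma)[1: p_max + 1]])
    variances = np.maximum(variances, 1e-300)
    orders = np.arange(p_max + 1)
    bic = n * np.log(variances) + orders * np.log(n)
    p = int(np.argmin(bic))
    if p == 0:
        return np.empty(0)
    return np.asarray(phi)[1: p + 1, p]


def _ar_whiten(x: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Innovation filter e_t = x_t − Σ φ_i x_{t−i}; first len(phi) samples dropped."""
    p = len(phi)
    if p == 0:
        return x
    y = x[p:].copy()
    for i in range(1, p + 1):
        y = y - phi[i - 1] * x[p - i: x.shape[0] - i]
    return y


def _bisquare_weights(r: np.ndarray, c: float = TUKEY_C) -> np.ndarray:
    s = 1.4826 * np.median(np.abs(r))
    if s <= 0:
        return np.ones_like(r)
    u = r / (c * s)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return w


@lru_cache(maxsize=8)
def _dpss_tapers(n: int) -> np.ndarray:
    return dpss(n, MT_NW, MT_K)


def _multitaper_spectrum(r: np.ndarray) -> np.ndarray:
    """Eigenspectrum average; unit-energy tapers make E[P(f)] the spectral density."""
    tapers = _dpss_tapers(r.size)
    return np.mean([np.abs(np.fft.rfft(t * r)) ** 2 for t in tapers], axis=0)


def _filter_envelope(
    n: int,
    fs: float,
    filter_band: tuple[float, float] | None,
    filter_fs: float | None,
    phi: np.ndarray,
) -> np.ndarray:
    """Known power envelope of the whitened residuals at the rfft frequencies.

    The data passed through the zero-phase band-pass (power gain |H|⁴) before
    fitting, and through the AR innovation filter 1 − Σφ_i z⁻ⁱ afterwards; the
    residual spectrum must follow that envelope, which pins the estimate where
    the data carry (essentially) no power.
    """
    fn = np.fft.rfftfreq(n, 1.0 / fs)
    env = np.ones(fn.size)
    if filter_band is not None:
        sos = signal.butter(3, list(filter_band), btype="bandpass",
                            fs=filter_fs or fs, output="sos")
        _, H = signal.sosfreqz(sos, worN=fn, fs=filter_fs or fs)
        env = np.abs(H) ** 4
    if len(phi):
        _, A = signal.freqz(np.r_[1.0, -phi], worN=fn, fs=fs)
        env = env * np.abs(A) ** 2
    m = env.max()
    return env / m if m > 0 else np.ones_like(env)


def _design_mask(Xw: np.ndarray, conf: np.ndarray) -> np.ndarray:
    """Bins dominated by design-column energy, dilated by the taper bandwidth.

    The residual periodogram is biased exactly where the regressors put their
    power (the projection redistributes noise there under colored residuals);
    those bins are excluded and interpolated from their neighbours.
    """
    norms = np.sum(Xw**2, axis=0)
    D = (np.abs(np.fft.rfft(Xw, axis=0)) ** 2 / norms).sum(axis=1)
    ref = np.median(D[conf]) if conf.any() else np.median(D)
    spikes = D > 10.0 * max(ref, 1e-300)
    halfbw = int(np.ceil(MT_NW)) + 2
    mask = np.zeros_like(spikes)
    for shift in range(-halfbw, halfbw + 1):
        mask |= np.roll(spikes, shift)
    mask[: halfbw + 1] |= spikes[0]  # roll wraps; keep DC block contiguous
    return mask


def _spectral_inference(
    Xw: np.ndarray,
    w: np.ndarray,
    r: np.ndarray,
    fs: float,
    filter_band: tuple[float, float] | None,
    filter_fs: float | None,
    phi: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Standard errors and effective dof from the residual spectrum.

    var(β) = G' Σ G with G the weighted-LS influence matrix and Σ a circulant
    noise covariance whose eigenvalues are a multitaper estimate of the
    whitened-residual spectrum — design-dominated bins interpolated away and
    the whole estimate constrained to the known filter/AR power envelope.
    Effective dof of the variance estimate follow Satterthwaite from the
    per-resolution-cell weights.
    """
    n, k = Xw.shape
    nh = n // 2 + 1
    fn = np.fft.rfftfreq(n, 1.0 / fs)
    env = _filter_envelope(n, fs, filter_band, filter_fs, phi)
    conf = env > 0.02
    if not conf.any():
        conf = np.ones_like(env, dtype=bool)
    mask = _design_mask(Xw, conf)
    P = _multitaper_spectrum(r)

    # Residual-spectrum estimate: the raw eigenspectrum average at usable
    # bins (its sampling noise is propagated into the Satterthwaite dof
    # below), and at design-dominated bins — where the projection biases the
    # periodogram — the local mean of usable neighbours, flattened by the
    # known envelope so the interpolation respects the filter shape.
    B = SPECTRUM_SMOOTH_BINS
    usable = conf & ~mask
    box = np.ones(2 * B + 1)

    def masked_mean(keep: np.ndarray) -> np.ndarray:
        flat = np.where(keep, P / np.maximum(env, 1e-12), 0.0)
        num = np.convolve(flat, box, mode="same")
        cnt = np.convolve(keep.astype(float), box, mode="same")
        with np.errstate(invalid="ignore"):
            out = num / np.maximum(cnt, 1.0)
        if keep.any():
            ik = np.where(keep)[0]
            empty = cnt == 0
            if empty.any():
                out[empty] = np.interp(fn[empty], fn[ik], out[ik])
        else:
            out[:] = P.mean() / max(env.mean(), 1e-12)
        return out

    bg = masked_mean(usable)
    # narrowband physiological lines: their power belongs at their own bins,
    # but the tapers smear it over +-NW neighbours, which would inflate the
    # background there.  Detect line bins against a first-pass background,
    # keep their raw power pointwise, and drop the smear zone from the
    # background average.
    line = usable & (P > _LINE_THRESHOLD * np.maximum(bg * env, 1e-300))
    if line.any():
        halo = line.copy()
        reach = int(np.ceil(MT_NW))
        for shift in range(-reach, reach + 1):
            halo |= np.roll(line, shift)
        clean = usable & ~halo
        if clean.sum() >= 8:
            bg = masked_mean(clean)
        keep_raw = usable & (line | ~halo)
    else:
        keep_raw = usable
    Spre = np.where(keep_raw, P / np.maximum(env, 1e-12), bg)
    Sh = Spre * env * (n / max(n - k, 1))
    Sfull = np.empty(n)
    Sfull[:nh] = Sh
    Sfull[nh:] = Sh[1:(n + 1) // 2][::-1]

    XtWX = Xw.T @ (Xw * w[:, None])
    XtWXi = np.linalg.inv(XtWX)
    G = (Xw * w[:, None]) @ XtWXi  # influence matrix: beta = G' y_w
    Gf = np.fft.fft(G, axis=0)
    cov = np.real(Gf.conj().T @ (Sfull[:, None] * Gf)) / n
    se = np.sqrt(np.maximum(np.diag(cov), 0))

    # Satterthwaite dof per regressor, tracing the variance estimate back to
    # the raw periodogram bins it pools: V = Σ_f u_f·Ŝ_f with Ŝ the smoothed
    # background, so V = Σ_g v_g·P_g with v the box-kernel transpose of u
    # restricted to usable bins.  Neighbouring bins within the taper
    # bandwidth share information, hence the 2·NW-bin cells.
    cnt = np.convolve(usable.astype(float), box, mode="same")
    dofs = np.empty(k)
    af2 = np.abs(np.fft.rfft(G, axis=0)) ** 2
    cellw = max(int(round(2 * MT_NW)), 1)
    starts = np.arange(0, nh, cellw)
    for j in range(k):
        u = af2[:, j] * Sh
        a = np.where(usable, 0.0, u / np.maximum(cnt, 1.0))
        v = (u + np.convolve(a, box, mode="same")) * usable
        vcell = np.add.reduceat(v, starts)
        denom = float(np.sum(vcell**2))
        dofs[j] = 2 * MT_K * float(vcell.sum()) ** 2 / denom if denom > 0 else n - k
    return se, dofs


def _fit_single(
    y: np.ndarray,
    X: np.ndarray,
    p_max: int,
    robust: bool,
    tol: float,
    max_iter: int,
    filter_band: tuple[float, float] | None,
    filter_fs: float | None,
    fs: float,
    cov: str,
) -> tuple[np.ndarray, np.ndarray, float, int, int, bool, float]:
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} samples insufficient for rank {k} design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    phi = np.empty(0)
    w = np.ones(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        phi = _select_ar(resid, p_max)
        yw = _ar_whiten(y, phi)
        Xw = _ar_whiten(X, phi)
        rw = yw - Xw @ beta
        w = _bisquare_weights(rw) if robust else np.ones_like(rw)
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(Xw * sw[:, None], yw * sw, rcond=None)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    yw = _ar_whiten(y, phi)
    Xw = _ar_whiten(X, phi)
    rw = yw - Xw @ beta
    if cov == "spectral":
        se, dof = _spectral_inference(Xw, w, rw, fs, filter_band, filter_fs, phi)
    elif cov == "ols":
        dof = np.full(k, float(max(yw.size - k, 1)))
        s2 = float(np.sum(w * rw**2) / max(yw.size - k, 1))
        XtWX = Xw.T @ (Xw * w[:, None])
        se = np.sqrt(np.maximum(np.diag(s2 * np.linalg.inv(XtWX)), 0))
    else:
        raise ValueError(f"unknown cov {cov!r}")
    return beta, se, dof, len(phi), it, converged, float(np.mean(w))


def fit_ar_irls(
    y: np.ndarray | HemoTimeSeries,
    X: DesignMatrix,
    channels: Sequence[str] | None = None,
    p_max: int | None = None,
    robust: bool = True,
    tol: float = BETA_TOL,
    max_iter: int = MAX_ITER,
    filter_band: tuple[float, float] | None = None,
    filter_fs: float | None = None,
    cov: str = "spectral",
) -> GLMResult:
    """Fit the robust AR GLM per channel against a shared design.

    `y` may be a raw array (n_samples,) or (n_channels, n_samples), or a
    HemoTimeSeries (the HbO2 series is fitted; its filter band is picked up
    automatically).  `p_max` defaults to ⌈4·fs⌉ — 4 s of AR memory at the
    analysis rate.  `robust=False` keeps unit IRLS weights, in which case
    (with AR order 0) the point estimates are exactly ordinary least squares.

    `cov` selects the variance estimator: ``"spectral"`` (default) uses the
    multitaper residual-spectrum sandwich, which stays calibrated when the
    band-pass leaves serial correlation that no finite AR order can whiten;
    ``"ols"`` is the classic whitened-weighted-LS formula.
    """
    if isinstance(y, HemoTimeSeries):
        names = [c.name for c in y.channels]
        Y = y.hbo2
        if filter_band is None:
            filter_band = y.filter_band
        if filter_fs is None:
            filter_fs = getattr(y, "filter_fs", None)
    else:
        Y = np.atleast_2d(np.asarray(y, dtype=float))
        names = list(channels) if channels is not None else [f"ch{i}" for i in range(Y.shape[0])]
    if p_max is None:
        p_max = int(np.ceil(4 * X.fs))
    fits: dict[str, ChannelFit] = {}
    for i, name in enumerate(names):
        beta, se, dof, p_ar, n_iter, conv, wmean = _fit_single(
            Y[i], X.values, p_max, robust, tol, max_iter,
            filter_band, filter_fs, X.fs, cov)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        pvals = np.clip(2 * stats.t.sf(np.abs(t), dof), np.finfo(float).tiny, 1.0)
        fits[name] = ChannelFit(channel=name, names=list(X.names), beta=beta, se=se,
                                t=t, p=pvals, dof=dof, ar_order=p_ar, n_iter=n_iter,
                                converged=conv, weight_mean=wmean)
    return GLMResult(fits=fits)


# ---------------------------------------------------------------------------
# subject-level convenience: per-channel designs with source-matched SC
# ---------------------------------------------------------------------------

def fit_glm(
    hemo: HemoTimeSeries,
    layout: ProbeLayout,
    paradigm: Paradigm,
    mode: str = "trialwise",
    selected_trials: Sequence[int] | None = None,
    sc: bool = True,
    sc_mode: str = "mean",
    channels: Sequence[str] | None = None,
    robust: bool = True,
    p_max: int | None = None,
) -> GLMResult:
    """Fit every requested long channel, each against its own design.

    The short-channel nuisance regressor is, by default, the mean of the
    eight (already preprocessed) short-channel HbO2 series — averaging
    divides the short channels' own measurement noise by 8, which matters
    because a noisy nuisance regressor under-corrects in proportion to its
    noise share.  ``sc_mode="matched"`` instead uses the single short
    channel sharing the long channel's source.
    """
    hrf = canonical_hrf(hemo.fs)
    n = hemo.n_times
    if channels is None:
        channels = [c.name for c in layout.long_channels()]
    sc_mean = None
    if sc and sc_mode == "mean":
        shorts = [hemo.channel_index(c.name) for c in layout.short_channels()]
        sc_mean = hemo.hbo2[shorts].mean(axis=0)
    elif sc and sc_mode != "matched":
        raise ValueError(f"unknown sc_mode {sc_mode!r}")
    fits: dict[str, ChannelFit] = {}
    for name in channels:
        ch = layout.channels[layout.index_of(name)]
        sc_series = None
        if sc:
            if sc_mode == "mean":
                sc_series = sc_mean
            else:
                short = layout.short_for_source(ch.source)
                sc_series = hemo.hbo2[hemo.channel_index(short.name)]
        X = build_design(paradigm, hrf, n, sc_series=sc_series, mode=mode,
                         selected_trials=selected_trials,
                         filter_band=hemo.filter_band)
        res = fit_ar_irls(hemo.hbo2[hemo.channel_index(name)][None, :], X,
                          channels=[name], robust=robust, p_max=p_max,
                          filter_band=hemo.filter_band,
                          filter_fs=getattr(hemo, "filter_fs", None))
        fits[name] = res[name]
    return GLMResult(fits=fits)


def trial_t_table(result: GLMResult, layout: ProbeLayout):
    """15×4 table of per-trial t-values on the four NF channels."""
    import pandas as pd

    nf = [c.name for c in layout.roi_channels("nf_dlpfc")]
    first = result[nf[0]]
    trial_cols = [n for n in first.names if n.startswith("task_") and n != "task_unselected"]
    data = {ch: [result[ch][col]["t"] for col in trial_cols] for ch in nf}
    return pd.DataFrame(data, index=[int(c.split("_")[1]) for c in trial_cols])


def roi_activation(
    result: GLMResult,
    layout: ProbeLayout,
    roi: str,
    alpha: float = 0.05,
    regressor: str = "task",
) -> set[str]:
    """Channels in `roi` with positive task beta and p < alpha/m (m = ROI size)."""
    if roi not in ROI_SIZES:
        raise ValueError(f"unknown roi {roi!r}; expected one of {sorted(ROI_SIZES)}")
    m = ROI_SIZES[roi]
    activated = set()
    for ch in layout.roi_channels(roi):
        if ch.name not in result.fits:
            continue
        cell = result[ch.name][regressor]
        if cell["beta"] > 0 and cell["p"] < alpha / m:
            activated.add(ch.name)
    return activated
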