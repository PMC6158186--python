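"""Latency-distribution construction and decomposition.

Release latencies in a train are separated into three components:
fast synchronous (tau ~0.5 ms), slow synchronous (tau ~2 ms) and
asynchronous release (the slowly varying envelope that persists between
and after APs). The asynchronous envelope is estimated from the late part
of each inter-AP interval (events in the first 4.6 ms after each AP at
200 Hz, or 5 ms at 100 Hz, are deleted; the gaps are bridged by straight
lines and the result smoothed); subtracting it leaves the synchronous
part, whose per-stimulus cumulative distributions are fitted with
double exponentials sharing tau_fast and tau_slow across stimuli.
Model orders are compared with the Gaussian-residual BIC, and the
crossover index is the first stimulus at which the slow amplitude
fraction reaches the fast one.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "AsyncSeparation",
    "BiexponentialFit",
    "separate_asynchronous",
    "deletion_window_ms",
    "fit_biexponential_shared",
    "fit_biexponential_curves",
    "cumulative_sync_curves",
    "fit_exponential_decay",
    "bic_compare",
    "crossover_index",
    "count_matrix",
    "covariance_windows",
    "variance_mean",
]


# --------------------------------------------------------------------------
# asynchronous-release separation


@dataclass
class AsyncSeparation:
    time_ms: np.ndarray  # bin centres
    total_rate: np.ndarray  # events/ms per AZ
    async_rate: np.ndarray
    sync_rate: np.ndarray
    deletion_window_ms: float


def deletion_window_ms(frequency_hz: float) -> float:
    """Post-AP deletion window used to isolate asynchronous release."""
    if frequency_hz == 200.0:
        return 4.6
    if frequency_hz == 100.0:
        return 5.0
    return 1e3 / frequency_hz - 0.4


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def separate_asynchronous(
    event_times_ms: np.ndarray,
    ap_times_ms: np.ndarray,
    n_trials: int,
    frequency_hz: float,
    t_end_ms: float | None = None,
    bin_ms: float = 0.2,
    pre_smooth_ms: float = 1.0,
    post_smooth_ms: float = 2.0,
) -> AsyncSeparation:
    """Split the release-rate histogram into synchronous and asynchronous parts.

    Events within the deletion window after each AP are removed; the rate
    estimated from the remaining late events is linearly interpolated across
    the deleted gaps and smoothed (moving averages before and after the
    interpolation) to give the asynchronous envelope. The synchronous rate
    is the residual total - asynchronous, floored at zero.
    """
    event_times_ms = np.asarray(event_times_ms, dtype=float)
    ap_times_ms = np.asarray(ap_times_ms, dtype=float)
    if event_times_ms.size == 0:
        raise ValueError("empty event list")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if t_end_ms is None:
        t_end_ms = float(event_times_ms.max()) + bin_ms
    edges = np.arange(0.0, t_end_ms + bin_ms, bin_ms)
    centres = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(event_times_ms, bins=edges)
    total = counts / (n_trials * bin_ms)

    win = deletion_window_ms(frequency_hz)
    deleted = np.zeros_like(centres, dtype=bool)
    for t_ap in ap_times_ms:
        deleted |= (centres >= t_ap) & (centres < t_ap + win)

    # filter the late (kept) data only: masked moving average so the deleted
    # synchronous peaks cannot bleed into the envelope
    kept = (~deleted).astype(float)
    n_pre = max(1, int(round(pre_smooth_ms / bin_ms)))
    kern = np.ones(n_pre)
    num = np.convolve(total * kept, kern, mode="same")
    den = np.convolve(kept, kern, mode="same")
    kept_s = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    async_rate = kept_s.copy()
    if deleted.any() and (~deleted).any():
        async_rate[deleted] = np.interp(
            centres[deleted], centres[~deleted], kept_s[~deleted]
        )
    n_post = max(1, int(round(post_smooth_ms / bin_ms)))
    async_rate = _moving_average(async_rate, n_post)
    async_rate = np.clip(async_rate, 0.0, None)
    # no floor: clipping would break count conservation (sync + async =
    # total); small negative excursions are subtraction noise
    sync = total - async_rate
    return AsyncSeparation(centres, total, async_rate, sync, win)


# --------------------------------------------------------------------------
# exponential fits


@dataclass
class BiexponentialFit:
    tau_fast_ms: float
    tau_slow_ms: float
    tau_fast_ci: tuple[float, float]
    tau_slow_ci: tuple[float, float]
    amplitudes: pd.DataFrame  # per stimulus: A_fast, A_slow, fractions
    result: lmfit.minimizer.MinimizerResult
    stimuli: list[int]

    @property
    def fast_fractions(self) -> np.ndarray:
        return self.amplitudes["fast_fraction"].to_numpy()

    @property
    def slow_fractions(self) -> np.ndarray:
        return self.amplitudes["slow_fraction"].to_numpy()


def _cumulative(latencies: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(latencies), grid, side="right").astype(float)


def fit_biexponential_shared(
    latencies_per_stimulus: dict[int, np.ndarray],
    fit_window_ms: float = 4.6,
    n_trials: int = 1,
    min_events: int = 20,
    grid_ms: float = 0.05,
    t0_fast: float = 0.4,
    t0_slow: float = 2.5,
    n_bootstrap: int = 30,
) -> BiexponentialFit:
    """Shared-tau double-exponential fit of cumulative latency distributions.

    Each stimulus contributes a cumulative curve on [0, fit_window_ms]
    fitted as A_f*(1-exp(-t/tau_f)) + A_s*(1-exp(-t/tau_s)) with the two
    time constants shared across stimuli and amplitudes free (in events per
    trial when ``n_trials`` is given). Stimuli with fewer than
    ``min_events`` events are excluded from the fit.
    """
    stimuli = sorted(
        k for k, v in latencies_per_stimulus.items() if len(v) >= min_events
    )
    if not stimuli:
        raise ValueError(f"no stimulus has >= {min_events} events")
    grid = np.arange(grid_ms, fit_window_ms + grid_ms / 2, grid_ms)

    def build(data: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
        return {k: _cumulative(np.asarray(data[k]), grid) / n_trials for k in stimuli}

    fit = fit_biexponential_curves(grid, build(latencies_per_stimulus),
                                   t0_fast=t0_fast, t0_slow=t0_slow)
    if n_bootstrap > 0:
        # nonparametric bootstrap over events: the sampling noise of the
        # empirical distributions dominates the tau uncertainty and is not
        # captured by least-squares standard errors on cumulative curves
        rng = np.random.default_rng(n_bootstrap)
        tf, ts = [], []
        for _ in range(n_bootstrap):
            resampled = {
                k: rng.choice(latencies_per_stimulus[k],
                              size=len(latencies_per_stimulus[k]))
                for k in stimuli
            }
            b = fit_biexponential_curves(
                grid, build(resampled), t0_fast=fit.tau_fast_ms,
                t0_slow=fit.tau_slow_ms, multistart=False,
            )
            tf.append(b.tau_fast_ms)
            ts.append(b.tau_slow_ms)

        def basic_ci(value: float, samples: list[float]) -> tuple[float, float]:
            lo, hi = np.percentile(samples, [2.5, 97.5])
            return (2 * value - hi, 2 * value - lo)  # reflected: corrects bias

        fit.tau_fast_ci = basic_ci(fit.tau_fast_ms, tf)
        fit.tau_slow_ci = basic_ci(fit.tau_slow_ms, ts)
    return fit


def fit_biexponential_curves(
    grid: np.ndarray,
    curves: dict[int, np.ndarray],
    t0_fast: float = 0.4,
    t0_slow: float = 2.5,
    multistart: bool = True,
) -> BiexponentialFit:
    """Shared-tau fit of precomputed per-stimulus cumulative curves.

    The slow time constant is parametrized as tau_fast + dtau with a floor
    on dtau, keeping the two components separated; a shared onset delay
    (the stimulus-to-release dead time, bounded by the 1.2 ms alignment
    allowance) is fitted jointly. Several starting points are tried and the
    best least-squares solution kept (the shared-tau problem has local
    minima when one component is small).
    """
    stimuli = sorted(curves)

    def make_params(tf0: float, ts0: float, d0: float) -> lmfit.Parameters:
        params = lmfit.Parameters()
        # bounds encode the identification of the two components: a fast
        # (sub-ms) constant and a slow constant separated from it by at
        # least ~0.5 ms
        params.add("tau_fast", value=tf0, min=0.1, max=1.0)
        params.add("dtau", value=max(ts0 - tf0, 0.5), min=0.5, max=20.0)
        params.add("tau_slow", expr="tau_fast + dtau")
        params.add("t0", value=d0, min=0.0, max=1.2)
        for k in stimuli:
            total = curves[k][-1]
            params.add(f"af_{k}", value=0.7 * total, min=0.0)
            params.add(f"as_{k}", value=0.3 * total, min=0.0)
        return params

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        tf = pars["tau_fast"].value
        ts = pars["tau_slow"].value
        tt = np.maximum(grid - pars["t0"].value, 0.0)
        res = []
        for k in stimuli:
            model = pars[f"af_{k}"] * (1 - np.exp(-tt / tf)) + pars[
                f"as_{k}"
            ] * (1 - np.exp(-tt / ts))
            res.append(model - curves[k])
        return np.concatenate(res)

    starts = [(t0_fast, t0_slow, 0.3)]
    if multistart:
        starts += [(0.3, 1.5, 0.3), (0.5, 2.0, 0.1), (0.6, 3.5, 0.4)]
    out = None
    for tf0, ts0, d0 in starts:
        cand = lmfit.minimize(residual, make_params(tf0, ts0, d0), method="leastsq")
        if out is None or cand.chisqr < out.chisqr:
            out = cand

    # residuals of a cumulative-curve fit are strongly autocorrelated, so
    # the raw least-squares stderr is optimistic; inflate by the square root
    # of the integrated autocorrelation time (effective-sample-size factor)
    r = out.residual
    if len(r) > 8 and np.std(r) > 0:
        rc = r - r.mean()
        denom = float(rc @ rc)
        tau_int = 1.0
        for lag in range(1, len(r) // 4):
            rho = float(rc[:-lag] @ rc[lag:]) / denom
            if rho < 0.05:
                break
            tau_int += 2.0 * rho
        infl = float(np.sqrt(tau_int))
    else:  # pragma: no cover
        infl = 1.0

    def ci(par: str) -> tuple[float, float]:
        v = out.params[par].value
        se = out.params[par].stderr
        if se is None or not np.isfinite(se):
            return (np.nan, np.nan)
        return (v - 1.96 * infl * se, v + 1.96 * infl * se)

    rows = []
    for k in stimuli:
        af = out.params[f"af_{k}"].value
        as_ = out.params[f"as_{k}"].value
        tot = af + as_
        rows.append(
            {"stimulus": k, "A_fast": af, "A_slow": as_,
             "fast_fraction": af / tot if tot > 0 else np.nan,
             "slow_fraction": as_ / tot if tot > 0 else np.nan}
        )
    amps = pd.DataFrame(rows).set_index("stimulus")
    return BiexponentialFit(
        out.params["tau_fast"].value,
        out.params["tau_slow"].value,
        ci("tau_fast"),
        ci("tau_slow"),
        amps,
        out,
        stimuli,
    )


def cumulative_sync_curves(
    sep: AsyncSeparation,
    ap_times_ms: np.ndarray,
    window_ms: float,
    event_times_ms: np.ndarray | None = None,
    n_trials: int = 1,
    grid_ms: float = 0.05,
    min_rate_integral: float = 0.0,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Per-stimulus cumulative synchronous release (SV per AZ) vs latency.

    When raw ``event_times_ms`` are given, each stimulus's cumulative curve
    is built at event-level resolution (``grid_ms``) and the integrated
    asynchronous envelope is subtracted from it; otherwise the coarser
    binned synchronous rate of ``sep`` is integrated. Stimuli whose final
    value falls below ``min_rate_integral`` are omitted.
    """
    ap_times_ms = np.asarray(ap_times_ms, dtype=float)
    curves: dict[int, np.ndarray] = {}
    if event_times_ms is not None:
        grid = np.arange(grid_ms, window_ms + grid_ms / 2, grid_ms)
        ev = np.asarray(event_times_ms, dtype=float)
        for k, t_ap in enumerate(ap_times_ms):
            lat = ev[(ev > t_ap) & (ev <= t_ap + window_ms)] - t_ap
            raw = _cumulative(lat, grid) / n_trials
            # integrated asynchronous envelope over [t_ap, t_ap + t]
            env = np.interp(t_ap + np.concatenate([[0.0], grid]),
                            sep.time_ms, sep.async_rate)
            env_cum = np.cumsum(0.5 * (env[1:] + env[:-1]) * grid_ms)
            curve = np.clip(raw - env_cum, 0.0, None)
            curve = np.maximum.accumulate(curve)  # keep it a CDF
            if curve[-1] >= min_rate_integral:
                curves[k + 1] = curve
        return grid, curves
    bin_ms = float(sep.time_ms[1] - sep.time_ms[0])
    n_bins = int(round(window_ms / bin_ms))
    grid = (np.arange(n_bins) + 1) * bin_ms
    for k, t_ap in enumerate(ap_times_ms):
        i0 = int(np.searchsorted(sep.time_ms, t_ap))
        seg = sep.sync_rate[i0 : i0 + n_bins]
        if len(seg) < n_bins:
            seg = np.pad(seg, (0, n_bins - len(seg)))
        curve = np.cumsum(seg) * bin_ms
        if curve[-1] >= min_rate_integral:
            curves[k + 1] = curve
    return grid, curves


def fit_exponential_decay(
    time_ms: np.ndarray,
    cumulative: np.ndarray,
    t_start_ms: float,
    t_end_ms: float = 3.0,
) -> float:
    """Time constant (ms) of C(t) = A - B*exp(-t/tau) on [t_start, t_end]."""
    sel = (time_ms >= t_start_ms) & (time_ms <= t_end_ms)
    t = time_ms[sel]
    c = cumulative[sel]
    if len(t) < 4:
        raise ValueError("fit window contains too few points")
    pars = lmfit.Parameters()
    pars.add("A", value=float(c[-1]))
    pars.add("B", value=float(max(c[-1] - c[0], 1e-9)), min=0)
    pars.add("tau", value=0.4, min=1e-3, max=20.0)

    def resid(p):
        return p["A"] - p["B"] * np.exp(-t / p["tau"]) - c

    out = lmfit.minimize(resid, pars, method="leastsq")
    return float(out.params["tau"].value)


def bic_compare(
    time_ms: np.ndarray, cumulative: np.ndarray
) -> dict[str, float | str]:
    """Gaussian-residual BIC comparison of mono- vs biexponential models.

    Both models are scored on the increments of the cumulative curve
    (increments of an empirical distribution are quasi-independent, unlike
    the heavily autocorrelated cumulative residuals), with
    BIC = n*ln(RSS/n) + k*ln(n); the lower score wins. k counts the free
    parameters (2 for mono: A, tau; 4 for bi).
    """
    t = np.asarray(time_ms, dtype=float)
    c = np.asarray(cumulative, dtype=float)
    n = len(t)
    if n <= 4:
        raise ValueError("need more points than parameters")
    d = np.diff(c, prepend=0.0)

    def cdf_mono(p, x):
        return p["A"] * (1 - np.exp(-x / p["tau"]))

    def cdf_bi(p, x):
        return p["af"] * (1 - np.exp(-x / p["tau_f"])) + p["as_"] * (
            1 - np.exp(-x / (p["tau_f"].value + p["dtau"].value))
        )

    def increments(cdf, p):
        vals = cdf(p, t)
        return np.diff(vals, prepend=0.0)

    def fit(cdf, pars, w):
        return lmfit.minimize(
            lambda p: (increments(cdf, p) - d) * w, pars, method="leastsq"
        )

    def mono_pars():
        pars = lmfit.Parameters()
        pars.add("A", value=float(c[-1]), min=0)
        pars.add("tau", value=0.5, min=1e-3, max=50)
        return pars

    def bi_pars():
        pars = lmfit.Parameters()
        pars.add("af", value=float(c[-1]) * 0.6, min=0)
        pars.add("as_", value=float(c[-1]) * 0.4, min=0)
        pars.add("tau_f", value=0.4, min=1e-3, max=50)
        pars.add("dtau", value=1.5, min=1e-6)
        return pars

    # counting noise on an increment scales with its expected mass: weight
    # by 1/sqrt(mass), estimated model-neutrally from the smoothed empirical
    # increments and floored so no bin dominates
    m = _moving_average(np.maximum(d, 0.0), max(3, n // 20))
    m = np.maximum(m, 0.1 * max(d.mean(), 1e-12))
    w = 1.0 / np.sqrt(m)

    def rss_mono() -> float:
        return float(np.sum(fit(cdf_mono, mono_pars(), w).residual ** 2))

    def rss_bi() -> float:
        return float(np.sum(fit(cdf_bi, bi_pars(), w).residual ** 2))

    rss_m, rss_b = rss_mono(), rss_bi()
    rss_b = min(rss_b, rss_m)  # bi nests mono; never worse at the optimum
    bic_m = n * np.log(max(rss_m, 1e-300) / n) + 2 * np.log(n)
    bic_b = n * np.log(max(rss_b, 1e-300) / n) + 4 * np.log(n)
    return {
        "bic_mono": bic_m,
        "bic_bi": bic_b,
        "winner": "mono" if bic_m <= bic_b else "bi",
        "rss_mono": rss_m,
        "rss_bi": rss_b,
    }


def crossover_index(
    fast_fractions: np.ndarray, slow_fractions: np.ndarray, stimuli: list[int] | None = None
) -> int | None:
    """First stimulus number at which the slow fraction reaches the fast one.

    Ties resolve to that stimulus. Returns None if the slow component never
    catches up.
    """
    fast = np.asarray(fast_fractions, dtype=float)
    slow = np.asarray(slow_fractions, dtype=float)
    if stimuli is None:
        stimuli = list(range(1, len(fast) + 1))
    for i, f, s in zip(stimuli, fast, slow):
        if s >= f:
            return int(i)
    return None


# --------------------------------------------------------------------------
# count statistics


def count_matrix(
    events: pd.DataFrame,
    ap_times_ms: np.ndarray,
    n_trials: int,
    window_ms: float = 5.0,
    post_windows_ms: tuple[tuple[float, float], ...] = ((0, 5), (5, 35), (35, 65)),
) -> pd.DataFrame:
    """Per-trial event counts in post-AP and post-train windows.

    Columns s1..sN count events within ``window_ms`` after each AP; columns
    ``post_a_b`` count events in (a, b] ms after the last AP.
    """
    ap_times_ms = np.asarray(ap_times_ms, dtype=float)
    cols: dict[str, np.ndarray] = {}
    t = events["time_ms"].to_numpy()
    trial = events["trial"].to_numpy()
    for k, t_ap in enumerate(ap_times_ms):
        c = np.zeros(n_trials)
        sel = (t > t_ap) & (t <= t_ap + window_ms)
        np.add.at(c, trial[sel], 1)
        cols[f"s{k + 1}"] = c
    t_last = ap_times_ms[-1]
    for a, b in post_windows_ms:
        c = np.zeros(n_trials)
        sel = (t > t_last + a) & (t <= t_last + b)
        np.add.at(c, trial[sel], 1)
        cols[f"post_{a:g}_{b:g}"] = c
    return pd.DataFrame(cols)


def covariance_windows(counts: pd.DataFrame, col_a: str, col_b: str) -> dict[str, float]:
    """Sample covariance of two per-trial counts, with its standard error."""
    a = counts[col_a].to_numpy(dtype=float)
    b = counts[col_b].to_numpy(dtype=float)
    n = len(a)
    if n < 2:
        raise ValueError("need at least two trials")
    da, db = a - a.mean(), b - b.mean()
    cov = float(np.sum(da * db) / (n - 1))
    # SE of the sample covariance via the delta method
    se = float(np.sqrt((np.mean((da * db) ** 2) - np.mean(da * db) ** 2) / n))
    return {"covariance": cov, "se": se, "n": n}


def variance_mean(counts: pd.DataFrame) -> pd.DataFrame:
    """Unbiased variance vs mean per count window plus the cumulative count."""
    if len(counts) < 2:
        raise ValueError("need at least two trials")
    stim_cols = [c for c in counts.columns if c.startswith("s")]
    rows = [
        {"window": c, "mean": counts[c].mean(), "variance": counts[c].var(ddof=1)}
        for c in stim_cols
    ]
    cum = counts[stim_cols].sum(axis=1)
    rows.append({"window": "cumulative", "mean": cum.mean(), "variance": cum.var(ddof=1)})
    return pd.DataFrame(rows)
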