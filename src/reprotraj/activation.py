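"""Per-gene activation dynamics along the progression axis.

The observed quantity is a gene's detection frequency in overlapping bins
placed uniformly along the progression axis. Three nested models predict the
frequency f(x) at progression x in [0, 1]:

* ``uniform`` — a straight line from the frequency at the start of the
  trajectory to the frequency at the end (random gradual change; the null);
* ``gauss1`` — f(x) = baseline + amplitude * Phi((x - mu) / sigma), the
  cumulative of a Gaussian "activation window" centered at the point of
  greatest change (negative amplitudes describe inactivating genes);
* ``gauss2`` — two cumulative-normal components, capturing transient
  (up-then-down) dynamics.

Gaussian models are fitted by derivative-free MSE minimisation with
multi-start Nelder-Mead under the box constraint 0 <= f(x) <= 1 (quadratic
penalty on a grid). Model comparison uses the small-sample corrected Akaike
criterion

    AICc = n * ln(MSE) + 2k + 2k(k + 1) / (n - k - 1)

with n the effective number of independent sample points (the
non-overlapping-equivalent bin count, range / bin_width) and k the
free-parameter count (2 / 4 / 7). Model adequacy is additionally checked
with a bootstrap lack-of-fit F-test: cells are repeatedly resampled within
non-overlapping bins and the systematic deviation of resampled frequencies
from the model prediction is compared against the binomial pure error.
"""

from __future__ import annotations

import dataclasses
import math
import zlib

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

__all__ = [
    "FrequencyCurve",
    "ActivationFit",
    "ActivationCurveModel",
    "bin_frequencies",
    "aicc",
    "bootstrap_ftest",
    "select_model",
    "activation_window",
]

MODEL_K = {"uniform": 2, "gauss1": 4, "gauss2": 7}


@dataclasses.dataclass
class FrequencyCurve:
    """Binned detection frequencies for one gene along the progression axis.

    ``freqs`` is NaN for empty bins; those bins are skipped in fitting.
    ``n_eff`` is the sample size used in AICc (by default the number of
    non-overlapping-equivalent bins, range / bin_width).
    """

    gene: str
    bin_centers: np.ndarray
    bin_counts: np.ndarray
    freqs: np.ndarray
    bin_width: float
    n_eff: float

    @property
    def mask(self) -> np.ndarray:
        return self.bin_counts > 0

    @property
    def x(self) -> np.ndarray:
        return self.bin_centers[self.mask]

    @property
    def y(self) -> np.ndarray:
        return self.freqs[self.mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.gene,
            "bin_center": self.bin_centers,
            "bin_count": self.bin_counts,
            "observed_freq": self.freqs,
        })


def bin_frequencies(detections, progressions, *, gene: str = "",
                    bin_width: float = 0.08, n_bins: int = 25,
                    n_eff_policy: str = "span") -> FrequencyCurve:
    """Detection frequency in overlapping bins of fixed width.

    ``n_bins`` bin centers are evenly spaced over [0, 1]; each bin covers
    ``[c - w/2, c + w/2]`` (truncated at the range ends). ``progressions``
    must already be clamped to [0, 1] and outlier cells excluded.

    ``n_eff_policy``: "span" (default) sets the AICc sample size to
    range / bin_width — the number of non-overlapping-equivalent bins, so
    that the overlap between adjacent bins does not inflate the apparent
    sample size; "bins" uses the raw number of non-empty bins.
    """
    det = np.asarray(detections, dtype=float)
    p = np.asarray(progressions, dtype=float)
    if det.shape != p.shape:
        raise ValueError("detections and progressions must align")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("progressions must be clamped to [0, 1]")
    centers = np.linspace(0.0, 1.0, n_bins)
    counts = np.zeros(n_bins, dtype=int)
    freqs = np.full(n_bins, np.nan)
    half = bin_width / 2.0
    for i, c in enumerate(centers):
        inb = (p >= c - half) & (p <= c + half)
        counts[i] = int(inb.sum())
        if counts[i]:
            freqs[i] = det[inb].mean()
    if counts.sum() == 0 or not np.any(counts > 0):
        raise ValueError("all bins empty")
    if n_eff_policy == "span":
        n_eff = 1.0 / bin_width
    elif n_eff_policy == "bins":
        n_eff = float((counts > 0).sum())
    else:
        raise ValueError(f"unknown n_eff_policy {n_eff_policy!r}")
    return FrequencyCurve(gene=gene, bin_centers=centers, bin_counts=counts,
                          freqs=freqs, bin_width=bin_width, n_eff=n_eff)


@dataclasses.dataclass
class ActivationFit:
    """One fitted frequency model for one gene."""

    gene: str
    kind: str  # uniform | gauss1 | gauss2
    baseline: float
    components: list[tuple[float, float, float]]  # (amplitude, mu, sigma)
    endpoint: float | None  # uniform model only: frequency at progression 1
    mse: float
    k: int
    n_eff: float
    f_reject_rate: float | None = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "uniform":
            return self.baseline + (self.endpoint - self.baseline) * x
        f = np.full_like(x, self.baseline, dtype=float)
        for amp, mu, sigma in self.components:
            f = f + amp * ndtr((x - mu) / sigma)
        return f

    @property
    def aicc(self) -> float:
        return aicc(self.n_eff, self.k, self.mse)

    def summary(self) -> str:
        lines = [f"{self.gene}: {self.kind} model  "
                 f"(k={self.k}, MSE={self.mse:.3g}, AICc={self.aicc:.2f})",
                 f"  baseline frequency {self.baseline:.3f}"]
        if self.kind == "uniform":
            lines.append(f"  endpoint frequency {self.endpoint:.3f}")
        for amp, mu, sigma in self.components:
            lines.append(f"  component: amplitude {amp:+.3f}, "
                         f"midpoint {mu:.3f}, spread {sigma:.3f}")
        if self.f_reject_rate is not None:
            lines.append(f"  bootstrap lack-of-fit rejection rate "
                         f"{self.f_reject_rate:.3f}")
        return "\n".join(lines)


def aicc(n_eff: float, k: int, mse: float) -> float:
    """Small-sample corrected Akaike criterion for least-squares fits."""
    if n_eff <= k + 1:
        raise ValueError(f"AICc undefined: n_eff={n_eff} <= k+1={k + 1}")
    if mse <= 0:
        raise ValueError("AICc undefined for mse <= 0")
    return n_eff * math.log(mse) + 2 * k + 2 * k * (k + 1) / (n_eff - k - 1)


class ActivationCurveModel:
    """Frequency-curve model for one gene, statsmodels-style.

    ``fit(kind=...)`` returns an :class:`ActivationFit`; ``fit_all()`` fits
    the three candidate models and returns them keyed by kind.
    """

    #: distance (in progression units) beyond which the anchor-estimation
    #: warning fires for the uniform model
    ANCHOR_WARN = 0.2
    #: half-width of the window of bins pooled into each anchor estimate
    ANCHOR_WINDOW = 0.15

    def __init__(self, curve: FrequencyCurve):
        if not np.any(curve.mask):
            raise ValueError("curve has no populated bins")
        self.curve = curve

    # -- uniform (null) model --------------------------------------------
    def _window_centroid(self, at: float):
        """Count-weighted (x, freq) centroid of the non-empty bins within
        ``ANCHOR_WINDOW`` of the trajectory end ``at``; falls back to the
        nearest non-empty bin (with a warning if it is far from the end)."""
        x, y = self.curve.x, self.curve.y
        n = self.curve.bin_counts[self.curve.mask]
        near = np.abs(x - at) <= self.ANCHOR_WINDOW
        if near.any():
            return (float(np.average(x[near], weights=n[near])),
                    float(np.average(y[near], weights=n[near])))
        i = int(np.argmin(np.abs(x - at)))
        if abs(x[i] - at) > self.ANCHOR_WARN:
            import warnings
            warnings.warn(
                f"{self.curve.gene}: nearest bin to progression {at} is "
                f"{abs(x[i] - at):.2f} away; anchor estimate may be poor")
        return float(x[i]), float(y[i])

    def _anchor(self, at: float) -> float:
        """Anchor frequency at a trajectory end: the line through the two
        end-window centroids, evaluated at ``at`` and clipped into [0, 1].
        Exact for linear curves; pooling a window of bins suppresses
        single-bin noise."""
        x0, y0 = self._window_centroid(0.0)
        x1, y1 = self._window_centroid(1.0)
        if x1 <= x0:  # degenerate: everything in one window
            return float(np.clip(y0, 0.0, 1.0))
        slope = (y1 - y0) / (x1 - x0)
        return float(np.clip(y0 + slope * (at - x0), 0.0, 1.0))

    def fit_uniform(self) -> ActivationFit:
        base = self._anchor(0.0)
        end = self._anchor(1.0)
        pred = base + (end - base) * self.curve.x
        mse = float(np.mean((self.curve.y - pred) ** 2))
        return ActivationFit(gene=self.curve.gene, kind="uniform",
                             baseline=base, components=[], endpoint=end,
                             mse=mse, k=2, n_eff=self.curve.n_eff)

    # -- Gaussian cumulative models --------------------------------------
    _PENALTY_GRID = np.linspace(0.0, 1.0, 41)
    _PENALTY_WEIGHT = 10.0

    @staticmethod
    def _predict_theta(theta: np.ndarray, x: np.ndarray, nc: int) -> np.ndarray:
        f = np.full_like(x, theta[0], dtype=float)
        for c in range(nc):
            amp, mu, logs = theta[1 + 3 * c: 4 + 3 * c]
            f = f + amp * ndtr((x - mu) * math.exp(min(max(-logs, -30.0), 30.0)))
        return f

    def _objective(self, theta: np.ndarray, nc: int) -> float:
        # single prediction over fitted bins + constraint grid
        xg = self._xgrid
        f = self._predict_theta(theta, xg, nc)
        nb = self._nbins_fit
        resid = self.curve.y - f[:nb]
        mse = float(np.mean(resid ** 2))
        g = f[nb:]
        pen = float(np.sum(np.clip(g - 1.0, 0, None) ** 2)
                    + np.sum(np.clip(-g, 0, None) ** 2))
        # amplitudes restricted to [-1, 1], midpoints near the axis
        for c in range(nc):
            amp, mu = theta[1 + 3 * c], theta[2 + 3 * c]
            pen += max(0.0, abs(amp) - 1.0) ** 2
            pen += max(0.0, abs(mu - 0.5) - 1.0) ** 2
        return mse + self._PENALTY_WEIGHT * pen

    def _starts(self, nc: int) -> list[np.ndarray]:
        y0 = self._anchor(0.0)
        y1 = self._anchor(1.0)
        amp0 = y1 - y0
        starts = []
        if nc == 1:
            for mu in (0.25, 0.5, 0.75):
                for s in (0.05, 0.15, 0.4):
                    a = amp0 if abs(amp0) > 0.05 else 0.5
                    starts.append(np.array([y0, a, mu, math.log(s)]))
        else:
            span = self.curve.y.max() - self.curve.y.min()
            a = max(span, 0.3)
            half = amp0 / 2 if abs(amp0) > 0.05 else 0.3
            for mu1, mu2 in ((0.25, 0.75), (0.2, 0.5), (0.5, 0.8), (0.3, 0.7)):
                starts.append(np.array([y0, a, mu1, math.log(0.08),
                                        -a, mu2, math.log(0.08)]))
                starts.append(np.array([y0, half, mu1, math.log(0.15),
                                        half, mu2, math.log(0.15)]))
        return starts

    def fit_gaussian(self, n_components: int = 1, seed: int | None = None,
                     extra_starts=None) -> ActivationFit:
        """Best-of-multi-start Nelder-Mead MSE fit.

        ``seed`` jitters the start points slightly (omit for the
        deterministic default grid). ``extra_starts`` appends additional
        start vectors (used to seed the two-component fit from the
        one-component solution, preserving model nesting).
        """
        if n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        nc = n_components
        self._xgrid = np.concatenate([self.curve.x, self._PENALTY_GRID])
        self._nbins_fit = len(self.curve.x)
        starts = self._starts(nc) + [np.asarray(s, dtype=float)
                                     for s in (extra_starts or [])]
        if seed is not None:
            rng = np.random.default_rng(seed)
            starts = [s + rng.normal(0, 0.01, size=s.shape) for s in starts]
        best = None
        maxfev = 2000 if nc == 1 else 4000
        for s0 in starts:
            res = optimize.minimize(
                self._objective, s0, args=(nc,), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxfev": maxfev},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(
                f"{self.curve.gene}: optimizer failed on all starts")
        theta = best.x
        comps = []
        for c in range(nc):
            amp, mu, logs = theta[1 + 3 * c: 4 + 3 * c]
            comps.append((float(amp), float(mu), float(math.exp(logs))))
        # order components by midpoint for stable reporting
        comps.sort(key=lambda t: t[1])
        pred = self._predict_theta(theta, self.curve.x, nc)
        mse = float(np.mean((self.curve.y - pred) ** 2))
        return ActivationFit(gene=self.curve.gene, kind=f"gauss{nc}",
                             baseline=float(theta[0]), components=comps,
                             endpoint=None, mse=mse, k=1 + 3 * nc,
                             n_eff=self.curve.n_eff)

    def fit(self, kind: str = "gauss1", seed: int | None = None) -> ActivationFit:
        if kind == "uniform":
            return self.fit_uniform()
        if kind in ("gauss1", "gauss2"):
            return self.fit_gaussian(int(kind[-1]), seed=seed)
        raise ValueError(f"unknown model kind {kind!r}")

    def fit_all(self, seed: int | None = None) -> dict[str, ActivationFit]:
        """Fit uniform, gauss1 and gauss2; the gauss2 search includes the
        gauss1 optimum (second amplitude 0) so the nesting
        mse(gauss2) <= mse(gauss1) holds up to optimizer tolerance."""
        uni = self.fit_uniform()
        g1 = self.fit_gaussian(1, seed=seed)
        amp, mu, sigma = g1.components[0]
        nested = [g1.baseline, amp, mu, math.log(sigma), 0.0, 0.7,
                  math.log(0.1)]
        g2 = self.fit_gaussian(2, seed=seed, extra_starts=[nested])
        return {"uniform": uni, "gauss1": g1, "gauss2": g2}


def select_model(fits: dict[str, ActivationFit]):
    """Minimum-AICc choice among fitted models, with the delta-AICc table.

    Returns (chosen kind, {kind: AICc - min AICc}).
    """
    scores = {k: f.aicc for k, f in fits.items()}
    best = min(scores, key=scores.get)
    lo = scores[best]
    return best, {k: s - lo for k, s in scores.items()}


def activation_window(fit: ActivationFit):
    """Mean and central 50% / 95% intervals of a gauss1 activation window.

    Returns (mu, (lo50, hi50), (lo95, hi95)); raw values, no clamping to the
    trajectory bounds.
    """
    if fit.kind != "gauss1":
        raise ValueError("activation window defined only for gauss1 models")
    _, mu, sigma = fit.components[0]
    q50, q95 = 0.6744897501960817, 1.959963984540054
    return (mu, (mu - q50 * sigma, mu + q50 * sigma),
            (mu - q95 * sigma, mu + q95 * sigma))


def _binned_lof(fit: ActivationFit, det: np.ndarray, p: np.ndarray,
                n_bins: int):
    """Per-bin counts, observed frequencies and mean model predictions over
    non-overlapping equal-width progression bins (bins with < 2 cells are
    dropped)."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    N, phat, m = [], [], []
    for b in range(n_bins):
        inb = idx == b
        nb = int(inb.sum())
        if nb < 2:
            continue
        N.append(nb)
        phat.append(det[inb].mean())
        m.append(float(np.mean(fit.predict(p[inb]))))
    if not N:
        raise ValueError("all bins empty")
    return np.asarray(N), np.asarray(phat), np.asarray(m)


def lack_of_fit_ftest(fit: ActivationFit, detections, progressions, *,
                      n_bins: int = 10, alpha: float = 0.05):
    """Single lack-of-fit F-test of a fitted model against binned data.

    The squared deviation of each bin's observed detection frequency from
    the model prediction is standardized by the pure-error (binomial)
    variance the model implies, v_i = m_i (1 - m_i) / N_i, and the mean
    standardized deviation F = sum(z_i^2) / B is compared to the
    F(B, sum(N_i - 1)) critical value.

    Returns (F, F_crit, reject).
    """
    det = np.asarray(detections, dtype=float)
    p = np.asarray(progressions, dtype=float)
    N, phat, m = _binned_lof(fit, det, p, n_bins)
    mc = np.clip(m, 0.0, 1.0)
    v = mc * (1.0 - mc) / N
    dev2 = (phat - mc) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(v > 0, dev2 / np.where(v > 0, v, 1.0),
                      np.where(dev2 > 0, np.inf, 0.0))
    B = len(N)
    F = float(z2.sum() / B)
    df_pe = int((N - 1).sum())
    fcrit = float(stats.f.ppf(1.0 - alpha, B, df_pe))
    return F, fcrit, F > fcrit


def bootstrap_ftest(fit: ActivationFit, detections, progressions, *,
                    n_bins: int = 10, reps: int = 1000, alpha: float = 0.05,
                    seed: int = 0, resample_counts=None) -> float:
    """Bootstrap lack-of-fit F-test; returns the fraction of replicates
    rejecting the model.

    Cells are partitioned into ``n_bins`` non-overlapping equal-width bins of
    progression. Each replicate resamples, with replacement, a fixed number
    of cells from every bin (default: that bin's own count) — since only the
    detection indicator matters this is a binomial draw — and compares the
    systematic deviation of resampled frequencies from the model prediction
    (lack of fit) against the binomial replicate variation (pure error):

        F = [sum_i w_i (ybar_i - m_i)^2 / B] / MS_pe,
        w_i = 1 / (1/N_i + 1/n_i),

    rejecting when F exceeds the F(B, sum(n_i - 1)) critical value at
    ``alpha``. Each squared deviation is standardized by the pure-error
    (binomial) variance the model implies for that bin,

        v_i = m_i (1 - m_i) (1/N_i + 1/n_i),

    which accounts for both sampling layers — the original bin frequency is
    itself a binomial estimate — and for the frequency-dependent replicate
    variance. The numerator dof is the number of populated bins B because
    the model is held fixed across replicates (it is not refit per
    replicate).

    Note: replicates share the one observed dataset, so this percentage is
    a per-gene stability summary, not a calibrated size — conditional on an
    unlucky sample it can sit well above or below alpha even when the model
    is true. For calibration statements use :func:`lack_of_fit_ftest` on
    independently generated datasets.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    det = np.asarray(detections, dtype=float)
    p = np.asarray(progressions, dtype=float)
    N, phat, m = _binned_lof(fit, det, p, n_bins)
    B = len(N)
    n_res = N if resample_counts is None else np.broadcast_to(
        np.asarray(resample_counts), N.shape)

    rng = np.random.default_rng(seed)
    ybar = rng.binomial(n_res, phat, size=(reps, B)) / n_res
    mc = np.clip(m, 0.0, 1.0)
    v = mc * (1.0 - mc) * (1.0 / N + 1.0 / n_res)
    dev2 = (ybar - mc) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(v > 0, dev2 / np.where(v > 0, v, 1.0),
                      np.where(dev2 > 0, np.inf, 0.0))
    F = z2.sum(axis=1) / B
    df_pe = int((n_res - 1).sum())
    fcrit = stats.f.ppf(1.0 - alpha, B, df_pe)
    return float(np.mean(F > fcrit))


def fit_all_genes(curves: dict[str, FrequencyCurve], *,
                  seed: int | None = None) -> dict[str, dict[str, ActivationFit]]:
    """Fit uniform/gauss1/gauss2 for every gene's frequency curve."""
    return {gene: ActivationCurveModel(curve).fit_all(seed=seed)
            for gene, curve in curves.items()}


def fit_gene_table(curves: dict[str, FrequencyCurve], *, seed: int | None = None,
                   detections: pd.DataFrame | None = None,
                   progressions=None, ftest_reps: int = 0,
                   ftest_bins: int = 10, alpha: float = 0.05,
                   all_fits: dict | None = None) -> pd.DataFrame:
    """Fit all three models per gene; return the per-gene model table.

    If ``ftest_reps`` > 0 (and detections/progressions given), the bootstrap
    lack-of-fit rejection rate is computed for the uniform and gauss1 fits.
    Pass ``all_fits`` (from :func:`fit_all_genes`) to reuse fitted models.
    """
    if all_fits is None:
        all_fits = fit_all_genes(curves, seed=seed)
    rows = []
    for gene in curves:
        fits = all_fits[gene]
        chosen, delta = select_model(fits)
        g1 = fits["gauss1"]
        amp, mu, sigma = g1.components[0]
        row = {
            "gene": gene, "chosen": chosen,
            "aicc_uniform": fits["uniform"].aicc,
            "aicc_gauss1": g1.aicc, "aicc_gauss2": fits["gauss2"].aicc,
            "delta_uniform": delta["uniform"], "delta_gauss1": delta["gauss1"],
            "delta_gauss2": delta["gauss2"],
            "mse_uniform": fits["uniform"].mse, "mse_gauss1": g1.mse,
            "mse_gauss2": fits["gauss2"].mse,
            "baseline": g1.baseline, "amplitude": amp, "mu": mu, "sigma": sigma,
        }
        if ftest_reps and detections is not None:
            det = detections[gene].to_numpy()
            for kind in ("uniform", "gauss1"):
                sub = zlib.crc32(f"{gene}:{kind}".encode()) ^ (seed or 0)
                row[f"f_reject_{kind}"] = bootstrap_ftest(
                    fits[kind], det, progressions, n_bins=ftest_bins,
                    reps=ftest_reps, alpha=alpha, seed=sub % (2 ** 31),
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
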