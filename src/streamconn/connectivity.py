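"""Undirected and directed functional connectivity from ROI time series.

Undirected functional connectivity (FC) is the pairwise Pearson correlation
of two ROI series.  Directed connectivity is frequency-domain Granger
causality evaluated on a bivariate vector autoregression (VAR): with noise
covariance ``Sigma`` and transfer function ``H(f) = (I - sum_k A_k
e^{-i 2 pi f k / fs})^{-1}``, the spectral matrix is ``S(f) = H Sigma H*``
and the causality from channel 2 to channel 1 is

    I_{2->1}(f) = ln[ S11(f) / (S11(f) - (Sigma22 - Sigma12^2/Sigma11) |H12(f)|^2) ]

The band-specific, time-domain-equivalent causality (TGC) is the bandwidth-
normalized integral ``F_{2->1} = (1/(f2-f1)) * int_{f1}^{f2} I_{2->1}(f) df``.
Over the full band [0, Nyquist] this reduces to Geweke's residual-variance
log-ratio, which the test suite uses as an independent oracle.

Model order is chosen by minimizing the spectral difference between the
VAR's parametric spectral matrix and a segment-averaged (Welch) cross-
spectral estimate of the same data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .atlas import Connection
from .errors import (
    ConditioningError,
    DegenerateSignalError,
    SizingError,
    StationarityError,
    StructuralError,
    ValidationError,
)

#: Default sampling rate: one volume per 535 ms repetition time.
DEFAULT_TR_S = 0.535
DEFAULT_FS_HZ = 1.0 / DEFAULT_TR_S

#: Analysis band (Hz) for band-integrated Granger causality.
DEFAULT_BAND_HZ = (0.05, 0.9)

#: Number of points of the frequency grid on [0, fs/2].
DEFAULT_N_FREQS = 513

#: Candidate VAR orders scanned by order selection.
DEFAULT_ORDER_CANDIDATES = tuple(range(2, 21))

#: Order used for cohort-level analyses.
DEFAULT_ORDER = 6


@dataclass
class VARModel:
    """A stationary VAR(p) with coefficient stack and innovation covariance."""

    coeffs: np.ndarray  # (p, k, k); coeffs[m] multiplies x(t - m - 1)
    sigma: np.ndarray  # (k, k) innovation covariance
    fs: float = DEFAULT_FS_HZ

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_3d(np.asarray(self.coeffs, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        k = self.sigma.shape[0]
        if self.sigma.shape != (k, k):
            raise ValidationError("sigma must be square")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValidationError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise ValidationError("sigma must be positive definite")
        if self.coeffs.shape[1:] != (k, k):
            raise ValidationError("coefficient matrices must match sigma's dimension")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be > 0")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.sigma.shape[0]

    def companion_spectral_radius(self) -> float:
        p, k = self.order, self.n_channels
        if p == 0:
            return 0.0
        top = self.coeffs.transpose(1, 0, 2).reshape(k, k * p)
        comp = np.zeros((k * p, k * p))
        comp[:k, :] = top
        if p > 1:
            comp[k:, : k * (p - 1)] = np.eye(k * (p - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())

    def is_stationary(self) -> bool:
        return self.companion_spectral_radius() < 1.0

    def require_stationary(self) -> "VARModel":
        rho = self.companion_spectral_radius()
        if rho >= 1.0:
            raise StationarityError(f"companion spectral radius {rho:.3f} >= 1")
        return self


@dataclass
class SpectralDecomposition:
    """Parametric transfer function and spectral matrix on a frequency grid."""

    freqs: np.ndarray  # (F,)
    H: np.ndarray  # (F, k, k) complex transfer function
    S: np.ndarray  # (F, k, k) complex spectral matrix, S = H Sigma H*


@dataclass
class GCResult:
    """Spectral Granger causality for one ordered ROI pair plus its band value."""

    direction: tuple[str, str]  # (source, target)
    freqs: np.ndarray
    spectral_gc: np.ndarray
    band: tuple[float, float]
    tgc: float
    n_clamped: int = 0  # grid points where the ln argument was clamped


def default_freq_grid(fs: float = DEFAULT_FS_HZ, n_freqs: int = DEFAULT_N_FREQS) -> np.ndarray:
    """Equally spaced grid of ``n_freqs`` points on [0, fs/2]."""
    return np.linspace(0.0, fs / 2.0, n_freqs)


def pearson_fc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between two ROI series (undirected FC)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be 1-D and of equal length")
    if x.size < 3:
        raise SizingError("need >= 3 samples")
    if x.std() < 1e-14 or y.std() < 1e-14:
        raise DegenerateSignalError("constant input has no defined correlation")
    return float(sstats.pearsonr(x, y).statistic)


def fit_var(x: np.ndarray, order: int, demean: bool = True) -> VARModel:
    """Fit a VAR(p) by multivariate least squares on lagged regressors.

    ``x`` is (T, k).  Each channel is demeaned before regression (per
    segment; callers split runs themselves).  The innovation covariance is
    the residual covariance with divisor ``T - p``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    T, k = x.shape
    p = int(order)
    if p < 1:
        raise ValidationError("order must be >= 1")
    if T <= 10 * p:
        raise SizingError(f"need T > 10*p samples (T={T}, p={p})")
    if np.any(x.std(axis=0) < 1e-14):
        raise DegenerateSignalError("constant channel cannot be modelled")
    if demean:
        x = x - x.mean(axis=0)
    Y = x[p:]
    Z = np.hstack([x[p - m : T - m] for m in range(1, p + 1)])  # (T-p, k*p)
    cond = np.linalg.cond(Z)
    if not np.isfinite(cond) or cond > 1e10:
        raise ConditioningError(f"regressor matrix condition number {cond:.2e}")
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)  # (k*p, k)
    resid = Y - Z @ B
    sigma = resid.T @ resid / (T - p)
    coeffs = B.T.reshape(k, p, k).transpose(1, 0, 2)
    return VARModel(coeffs=coeffs, sigma=sigma)


def simulate_var(
    model: VARModel,
    n_samples: int,
    rng: np.random.Generator,
    burn_in: int = 300,
) -> np.ndarray:
    """Draw one realization of a stationary VAR; returns (n_samples, k)."""
    model.require_stationary()
    p, k = model.order, model.n_channels
    total = n_samples + burn_in
    chol = np.linalg.cholesky(model.sigma)
    innov = rng.standard_normal((total, k)) @ chol.T
    out = np.zeros((total, k))
    coeffs = model.coeffs
    for t in range(total):
        acc = innov[t].copy()
        for m in range(min(p, t)):
            acc += coeffs[m] @ out[t - m - 1]
        out[t] = acc
    return out[burn_in:]


def var_transfer(model: VARModel, freqs: np.ndarray) -> np.ndarray:
    """Transfer function H(f) = (I - sum_k A_k e^{-i 2 pi f k / fs})^{-1}."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.min() < 0 or freqs.max() > model.fs / 2 + 1e-9:
        raise ValidationError("frequencies must lie in [0, fs/2]")
    p, k = model.order, model.n_channels
    lags = np.arange(1, p + 1)
    # phase: (F, p)
    phase = np.exp(-2j * np.pi * freqs[:, None] * lags[None, :] / model.fs)
    A = np.tensordot(phase, model.coeffs, axes=(1, 0))  # (F, k, k)
    char = np.eye(k)[None, :, :] - A
    dets = np.linalg.det(char)
    bad = np.abs(dets) < 1e-14
    if bad.any():
        raise ValidationError(
            f"characteristic matrix singular at f={freqs[np.argmax(bad)]:.4g} Hz"
        )
    return np.linalg.inv(char)


def var_spectrum(model: VARModel, freqs: np.ndarray) -> SpectralDecomposition:
    """Parametric spectral matrix S(f) = H(f) Sigma H(f)* on the grid."""
    H = var_transfer(model, freqs)
    S = H @ model.sigma @ H.conj().transpose(0, 2, 1)
    return SpectralDecomposition(freqs=np.asarray(freqs, dtype=float), H=H, S=S)


def spectral_gc(
    model: VARModel,
    freqs: np.ndarray,
    source: int = 1,
    target: int = 0,
    diagnostics: dict | None = None,
) -> np.ndarray:
    """Spectral Granger causality I_{source->target}(f) on the grid.

    Uses the bivariate formula with the partial innovation variance
    ``Sigma_ss - Sigma_ts^2 / Sigma_tt``.  Non-positive ln arguments from
    finite-sample degeneracy are clamped to 0; the count of clamped grid
    points is added to ``diagnostics['clamped']`` when a dict is supplied.
    """
    if model.n_channels != 2:
        raise ValidationError("spectral GC is defined for bivariate models")
    if source == target or source not in (0, 1) or target not in (0, 1):
        raise ValidationError("source/target must be distinct channels 0 and 1")
    sig = model.sigma
    if sig[target, target] <= 0:
        raise ValidationError("target innovation variance must be > 0")
    dec = var_spectrum(model, freqs)
    S_tt = dec.S[:, target, target].real
    H_ts = dec.H[:, target, source]
    partial = sig[source, source] - sig[target, source] ** 2 / sig[target, target]
    denom = S_tt - partial * np.abs(H_ts) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = S_tt / denom
        I = np.log(ratio)
    bad = ~np.isfinite(I) | (I < 0)
    # only violations beyond the numerical floor count as clamps
    n_clamped = int(np.count_nonzero(~np.isfinite(I) | (I < -1e-10)))
    I = np.where(bad, 0.0, I)
    if diagnostics is not None:
        diagnostics["clamped"] = diagnostics.get("clamped", 0) + n_clamped
    return I


def band_gc(I: np.ndarray, freqs: np.ndarray, f1: float, f2: float) -> float:
    """Bandwidth-normalized trapezoid integral of spectral GC over [f1, f2]."""
    freqs = np.asarray(freqs, dtype=float)
    I = np.asarray(I, dtype=float)
    if f1 >= f2:
        raise ValidationError("need f1 < f2")
    if f1 < freqs[0] - 1e-12 or f2 > freqs[-1] + 1e-12:
        raise ValidationError(
            f"band [{f1}, {f2}] outside the frequency grid [{freqs[0]}, {freqs[-1]}]"
        )
    inside = (freqs > f1) & (freqs < f2)
    grid = np.concatenate(([f1], freqs[inside], [f2]))
    vals = np.concatenate(
        ([np.interp(f1, freqs, I)], I[inside], [np.interp(f2, freqs, I)])
    )
    return float(np.trapezoid(vals, grid) / (f2 - f1))


def time_domain_gc(model: VARModel, source: int = 1, target: int = 0,
                   n_freqs: int = DEFAULT_N_FREQS) -> float:
    """Full-band ([0, fs/2]) band-integrated GC for a fitted bivariate model."""
    freqs = default_freq_grid(model.fs, n_freqs)
    I = spectral_gc(model, freqs, source=source, target=target)
    return band_gc(I, freqs, freqs[0], freqs[-1])


def welch_cross_spectra(
    x: np.ndarray,
    fs: float,
    nperseg: int = 256,
    noverlap: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment-averaged one-sided cross-spectral matrix; returns (freqs, S)."""
    x = np.asarray(x, dtype=float)
    T, k = x.shape
    nperseg = int(min(nperseg, T))
    S = None
    freqs = None
    for i in range(k):
        for j in range(k):
            f, cs = sps.csd(
                x[:, i], x[:, j], fs=fs, nperseg=nperseg, noverlap=noverlap,
                detrend="constant",
            )
            if S is None:
                freqs = f
                S = np.zeros((f.size, k, k), dtype=complex)
            S[:, i, j] = cs
    return freqs, S


def parametric_density(model: VARModel, freqs: np.ndarray) -> np.ndarray:
    """One-sided spectral density of the VAR on ``freqs`` (Welch scaling)."""
    S = var_spectrum(model, freqs).S / model.fs
    onesided = 2.0 * S
    if freqs[0] == 0.0:
        onesided[0] /= 2.0
    if np.isclose(freqs[-1], model.fs / 2.0):
        onesided[-1] /= 2.0
    return onesided


def spectral_difference(
    x: np.ndarray,
    model: VARModel,
    fs: float,
    nperseg: int = 256,
) -> float:
    """Integrated squared Frobenius distance between parametric and Welch spectra."""
    freqs, S_np = welch_cross_spectra(x, fs, nperseg=nperseg)
    S_par = parametric_density(model, freqs)
    return float(np.sum(np.abs(S_par - S_np) ** 2))


def select_order(
    x: np.ndarray,
    candidates: Iterable[int] = DEFAULT_ORDER_CANDIDATES,
    fs: float = DEFAULT_FS_HZ,
    nperseg: int = 256,
    overlap_frac: float = 0.875,
    n_skip_bins: int = 1,
) -> int:
    """Pick the VAR order whose parametric spectrum best matches a Welch estimate.

    The series is split in half.  For each candidate order a VAR is fit to
    each half and its parametric spectral density is compared (squared
    Frobenius norm summed over the Welch grid) against the segment-averaged
    cross-spectral estimate of the *other* half; the two distances are
    summed and the minimizing order returned, ties broken toward the smaller
    order.  The held-out reference keeps overfitted high orders from chasing
    periodogram noise they were fit on.  The DC bin (first ``n_skip_bins``)
    is excluded because per-segment demeaning biases the Welch estimate
    there, and these spectra peak at low frequency.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValidationError("need >= 1 candidate order")
    half = x.shape[0] // 2
    feasible = [p for p in candidates if half > 10 * p]
    if not feasible:
        raise SizingError("series too short for every candidate order")
    parts = (x[:half], x[half:])
    refs = []
    for part in parts:
        centered = part - part.mean(axis=0)
        freqs, S_np = welch_cross_spectra(
            centered, fs, nperseg=min(nperseg, half),
            noverlap=int(overlap_frac * min(nperseg, half)),
        )
        refs.append((freqs[n_skip_bins:], S_np[n_skip_bins:]))
    best_p, best_d = None, np.inf
    for p in feasible:
        d = 0.0
        for fit_on, (freqs, S_np) in zip(parts, refs[::-1]):
            model = fit_var(fit_on, p)
            model.fs = fs
            S_par = parametric_density(model, freqs)
            d += float(np.sum(np.abs(S_par - S_np) ** 2))
        if d < best_d:
            best_p, best_d = p, d
    return int(best_p)


def _split_runs(x: np.ndarray, run_lengths: Sequence[int] | None) -> list[np.ndarray]:
    if run_lengths is None:
        return [x]
    if sum(run_lengths) != x.shape[0]:
        raise ValidationError("run lengths do not sum to the series length")
    out, start = [], 0
    for n in run_lengths:
        out.append(x[start : start + n])
        start += n
    return out


def directed_gc(
    x: np.ndarray,
    order: int = DEFAULT_ORDER,
    fs: float = DEFAULT_FS_HZ,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    run_lengths: Sequence[int] | None = None,
    n_freqs: int = DEFAULT_N_FREQS,
    names: tuple[str, str] = ("ch0", "ch1"),
) -> tuple[GCResult, GCResult]:
    """Both directed GC results for a 2-channel series.

    With multiple runs, a VAR is fit per run and the spectral GC curves are
    averaged across runs weighted by run length before band integration.
    Returns ``(result_0->1, result_1->0)``.
    """
    x = np.asarray(x, dtype=float)
    runs = _split_runs(x, run_lengths)
    freqs = default_freq_grid(fs, n_freqs)
    weights = np.array([r.shape[0] for r in runs], dtype=float)
    weights /= weights.sum()
    curves = {(0, 1): np.zeros(n_freqs), (1, 0): np.zeros(n_freqs)}
    clamped = {(0, 1): 0, (1, 0): 0}
    for w, run in zip(weights, runs):
        model = fit_var(run, order)
        model.fs = fs
        for src, tgt in curves:
            diag: dict = {}
            curves[(src, tgt)] += w * spectral_gc(
                model, freqs, source=src, target=tgt, diagnostics=diag
            )
            clamped[(src, tgt)] += diag.get("clamped", 0)
    results = []
    for src, tgt in ((0, 1), (1, 0)):
        I = curves[(src, tgt)]
        results.append(
            GCResult(
                direction=(names[src], names[tgt]),
                freqs=freqs,
                spectral_gc=I,
                band=band,
                tgc=band_gc(I, freqs, band[0], band[1]),
                n_clamped=clamped[(src, tgt)],
            )
        )
    return results[0], results[1]


def pairwise_connectivity(
    series: pd.DataFrame,
    connections: Sequence[Connection],
    run_lengths: Sequence[int] | None = None,
    order: int = DEFAULT_ORDER,
    fs: float = DEFAULT_FS_HZ,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    n_freqs: int = DEFAULT_N_FREQS,
    subject_id: str | None = None,
) -> pd.DataFrame:
    """FC and both directed TGC values for every connection of one subject.

    ``series`` has one column per ROI.  Per-run FC values and GC spectra are
    averaged with run lengths as weights.  Returns a long table with columns
    ``subject_id, connection, direction, metric, value`` (direction is
    ``"undirected"`` for FC and ``"a->b"``/``"b->a"`` strings for TGC).
    """
    rows = []
    for con in connections:
        for roi in (con.roi_a, con.roi_b):
            if roi not in series.columns:
                raise StructuralError(f"series table is missing ROI column {roi!r}")
        x = series[[con.roi_a, con.roi_b]].to_numpy(dtype=float)
        runs = _split_runs(x, run_lengths)
        weights = np.array([r.shape[0] for r in runs], dtype=float)
        weights /= weights.sum()
        fc = float(sum(w * pearson_fc(r[:, 0], r[:, 1]) for w, r in zip(weights, runs)))
        res_ab, res_ba = directed_gc(
            x, order=order, fs=fs, band=band, run_lengths=run_lengths,
            n_freqs=n_freqs, names=(con.roi_a, con.roi_b),
        )
        rows.append((subject_id, con.label, "undirected", "fc", fc))
        rows.append((subject_id, con.label, f"{con.roi_a}->{con.roi_b}", "tgc", res_ab.tgc))
        rows.append((subject_id, con.label, f"{con.roi_b}->{con.roi_a}", "tgc", res_ba.tgc))
    return pd.DataFrame(rows, columns=["subject_id", "connection", "direction", "metric", "value"])
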