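"""Phasor-method lifetime analysis and linear lifetime unmixing.

A TCSPC decay histogram c_k over one laser period T is mapped to its
first-harmonic Fourier coordinates

    g = sum_k c_k cos(w t_k) / sum_k c_k,
    s = sum_k c_k sin(w t_k) / sum_k c_k,     w = 2*pi*harmonic / T,

with t_k the bin centers. A monoexponential decay of lifetime tau lands
exactly on the universal semicircle at g = 1/(1+(w tau)^2),
s = w tau/(1+(w tau)^2); intensity mixtures combine linearly in (g, s).
That linearity is what makes graphical unmixing work: a pixel containing
up to three lifetime species lies inside the triangle spanned by the three
reference phasors, and its barycentric coordinates are the intensity
fractions of the species.

Two lifetime estimators are provided: the phase / modulation lifetimes
read off a phasor, and a Poisson maximum-likelihood single-exponential
fit of the binned histogram (the estimator appropriate for cuvette TCSPC
data, where the period-wrapped tail and a flat background matter).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .errors import CollinearReferencesError, FitError


@dataclasses.dataclass
class DecayHistogram:
    """Time-binned photon counts over (part of) one laser period.

    ``bin_edges`` (ns) must be uniform and span at most the repetition
    period ``period`` (ns). Counts are non-negative; they may be
    non-integral (e.g. expected counts of a model decay).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts)+1 entries")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("bins must be uniform")
        if self.bin_edges[-1] - self.bin_edges[0] > self.period * (1 + 1e-9):
            raise ValueError("bins span more than one period")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_csv(cls, path: str | Path, period: float) -> "DecayHistogram":
        """Read a 2-column CSV (time_ns = bin centers, counts)."""
        df = pd.read_csv(path)
        centers = df["time_ns"].to_numpy(dtype=float)
        width = centers[1] - centers[0]
        edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
        return cls(bin_edges=edges, counts=df["counts"].to_numpy(dtype=float), period=period)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_ns": self.bin_centers, "counts": self.counts}).to_csv(
            path, index=False
        )


@dataclasses.dataclass
class Phasor:
    """First- (or higher-) harmonic Fourier coordinates of a decay."""

    g: float
    s: float
    omega: float  # rad/ns
    harmonic: int = 1

    def as_complex(self) -> complex:
        return complex(self.g, self.s)


def phasor_transform(decay: DecayHistogram, harmonic: int = 1) -> Phasor:
    """Phasor of a decay histogram, using bin-center time stamps.

    Bin centers (not edges) keep the transform unbiased to first order in
    the bin width; residual bias is O((w*dt)^2) and negligible at the
    binning used in practice.
    """
    if decay.total <= 0:
        raise ValueError("cannot transform a decay with zero total counts")
    omega = 2.0 * np.pi * harmonic / decay.period
    t = decay.bin_centers
    total = decay.counts.sum()
    g = float(np.dot(decay.counts, np.cos(omega * t)) / total)
    s = float(np.dot(decay.counts, np.sin(omega * t)) / total)
    return Phasor(g=g, s=s, omega=omega, harmonic=harmonic)


def reference_phasor(tau: float, omega: float, harmonic: int = 1) -> Phasor:
    """Ideal on-semicircle phasor of a monoexponential with lifetime tau (ns)."""
    if tau <= 0:
        raise ValueError(f"tau must be > 0 ns, got {tau}")
    wt = omega * tau
    denom = 1.0 + wt * wt
    return Phasor(g=1.0 / denom, s=wt / denom, omega=omega, harmonic=harmonic)


def phasor_lifetime(p: Phasor) -> tuple[float, float]:
    """(tau_phase, tau_mod) in ns read off a phasor.

    tau_phase = s/(w g); tau_mod = (1/w) sqrt(1/(g^2+s^2) - 1). The two
    agree for an ideal monoexponential; tau_phase < tau_mod flags a
    mixture (the phasor falls inside the semicircle).
    """
    if p.g <= 0:
        raise ValueError("phase lifetime undefined for g <= 0")
    m2 = p.g**2 + p.s**2
    if m2 > 1.0 + 1e-9:
        raise ValueError(f"phasor modulus {np.sqrt(m2):.4f} > 1; not a decay phasor")
    tau_phase = p.s / (p.omega * p.g)
    tau_mod = np.sqrt(max(1.0 / m2 - 1.0, 0.0)) / p.omega
    return float(tau_phase), float(tau_mod)


def calibrate_phasor(p: Phasor, measured_ref: Phasor, tau_ref: float) -> Phasor:
    """Instrument calibration against a reference of known lifetime.

    Divides (complex) by the measured reference phasor and multiplies by
    the ideal phasor of ``tau_ref``, removing the instrument response's
    phase shift and demodulation. This is the documented path for real
    instrument data in lieu of IRF deconvolution.
    """
    ideal = reference_phasor(tau_ref, p.omega, p.harmonic).as_complex()
    corrected = p.as_complex() / measured_ref.as_complex() * ideal
    return Phasor(g=corrected.real, s=corrected.imag, omega=p.omega, harmonic=p.harmonic)


# ---------------------------------------------------------------------------
# unmixing


def _triangle_matrix(refs: list[Phasor]) -> np.ndarray:
    M = np.array([[r.g for r in refs], [r.s for r in refs], [1.0, 1.0, 1.0]])
    # area check: twice the signed triangle area
    area2 = abs(np.linalg.det(M[:3, :3]))
    if area2 < 1e-12:
        raise CollinearReferencesError("reference phasors are collinear")
    return M


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return a + t * ab


def _project_to_triangle(point: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Closest point of the (g, s) triangle to ``point``."""
    candidates = [
        _project_to_segment(point, verts[i], verts[(i + 1) % 3]) for i in range(3)
    ]
    d = [np.linalg.norm(point - c) for c in candidates]
    return candidates[int(np.argmin(d))]


def unmix_three(p: Phasor, refs: list[Phasor]) -> np.ndarray:
    """Barycentric intensity fractions of a phasor w.r.t. three references.

    Solves [g; s; 1] = M f exactly. A phasor outside the reference
    triangle is first projected to the nearest triangle point (noise pushes
    pixels outside; a hard failure would shred images), so the returned
    fractions are always >= 0 and sum to 1.
    """
    fractions, _ = unmix_points(
        np.array([[p.g, p.s]]), refs
    )
    return fractions[0]


def unmix_points(points: np.ndarray, refs: list[Phasor]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized three-component unmixing of an (n, 2) array of (g, s).

    Returns (fractions (n, 3), residual (n,)) where residual is the
    distance moved by out-of-triangle projection (0 for interior points).
    """
    if len(refs) != 3:
        raise ValueError(f"need exactly 3 references, got {len(refs)}")
    M = _triangle_matrix(refs)
    Minv = np.linalg.inv(M)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    rhs = np.column_stack([points, np.ones(len(points))])
    fractions = rhs @ Minv.T
    residual = np.zeros(len(points))
    outside = (fractions < -1e-12).any(axis=1)
    if outside.any():
        verts = np.array([[r.g, r.s] for r in refs])
        for i in np.flatnonzero(outside):
            proj = _project_to_triangle(points[i], verts)
            residual[i] = np.linalg.norm(points[i] - proj)
            fractions[i] = Minv @ np.array([proj[0], proj[1], 1.0])
    fractions = np.clip(fractions, 0.0, None)
    fractions /= fractions.sum(axis=1, keepdims=True)
    return fractions, residual


def unmix_points_two(points: np.ndarray, refs: list[Phasor]) -> tuple[np.ndarray, np.ndarray]:
    """Two-component unmixing: orthogonal projection onto the reference segment."""
    if len(refs) != 2:
        raise ValueError(f"need exactly 2 references, got {len(refs)}")
    a = np.array([refs[0].g, refs[0].s])
    b = np.array([refs[1].g, refs[1].s])
    ab = b - a
    L2 = float(np.dot(ab, ab))
    if L2 < 1e-24:
        raise CollinearReferencesError("two-component references coincide")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    t = np.clip((points - a) @ ab / L2, 0.0, 1.0)
    proj = a + t[:, None] * ab
    residual = np.linalg.norm(points - proj, axis=1)
    fractions = np.column_stack([1.0 - t, t])
    return fractions, residual


@dataclasses.dataclass
class UnmixResult:
    """Per-pixel species fractions of a time-resolved image."""

    fractions: np.ndarray  # (n_refs, Y, X), NaN where masked
    mask: np.ndarray  # (Y, X) bool, True = analyzed
    residual: np.ndarray  # (Y, X) distance to reference simplex
    references: list[Phasor]
    reference_lifetimes: list[float]
    component_images: np.ndarray  # (n_refs, Y, X) intensity-weighted
    total_intensity: np.ndarray  # (Y, X)
    g: np.ndarray  # (Y, X) per-pixel phasor coords (after binning)
    s: np.ndarray

    def phasor_table(self) -> pd.DataFrame:
        """Long-form (pixel, g, s) table of analyzed pixels."""
        ys, xs = np.nonzero(self.mask)
        return pd.DataFrame(
            {"y": ys, "x": xs, "g": self.g[ys, xs], "s": self.s[ys, xs]}
        )


def unmix_image(
    stack: np.ndarray,
    refs: list[Phasor] | None = None,
    ref_lifetimes: list[float] | None = None,
    period: float = 25.0,
    harmonic: int = 1,
    intensity_threshold: float = 100.0,
    spatial_binning: int = 1,
) -> UnmixResult:
    """Phasor unmixing of a (T_bins, Y, X) photon-count stack.

    References are given either as phasors or as lifetimes (ns) placed on
    the semicircle at the stack's angular frequency; 2 or 3 references are
    supported. ``spatial_binning`` k > 1 sums each pixel's decay over a
    sliding k x k window before the phasor transform (standard FLIM
    binning: trades spatial resolution for photon statistics; the image
    grid is unchanged). Pixels whose (binned) total count is below
    ``intensity_threshold`` are masked. Component images split the
    *unbinned* per-pixel intensity by the recovered fractions, so their
    sum over components reproduces the masked total-intensity image.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("stack must be a non-empty (T_bins, Y, X) array")
    if intensity_threshold < 0:
        raise ValueError("intensity_threshold must be >= 0")
    omega = 2.0 * np.pi * harmonic / period
    if refs is None:
        if ref_lifetimes is None or len(ref_lifetimes) < 2:
            raise ValueError("need at least 2 references (phasors or lifetimes)")
        refs = [reference_phasor(tau, omega, harmonic) for tau in ref_lifetimes]
        taus = list(ref_lifetimes)
    else:
        taus = (
            list(ref_lifetimes)
            if ref_lifetimes is not None
            else [phasor_lifetime(r)[0] for r in refs]
        )
    if len(refs) < 2:
        raise ValueError("need at least 2 references for unmixing")

    n_bins, ny, nx = stack.shape
    # time axis: the stack is assumed to span exactly one period
    t = (np.arange(n_bins) + 0.5) * (period / n_bins)

    binned = stack
    if spatial_binning > 1:
        k = int(spatial_binning)
        binned = (
            ndimage.uniform_filter(stack, size=(1, k, k), mode="constant") * k * k
        )

    total_binned = binned.sum(axis=0)
    total_raw = stack.sum(axis=0)
    mask = total_binned >= intensity_threshold

    cos_t = np.cos(omega * t)
    sin_t = np.sin(omega * t)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.tensordot(cos_t, binned, axes=(0, 0)) / total_binned
        s = np.tensordot(sin_t, binned, axes=(0, 0)) / total_binned

    n_refs = len(refs)
    fractions = np.full((n_refs, ny, nx), np.nan)
    residual = np.zeros((ny, nx))
    ys, xs = np.nonzero(mask)
    if len(ys):
        pts = np.column_stack([g[ys, xs], s[ys, xs]])
        if n_refs == 3:
            frac, res = unmix_points(pts, refs)
        else:
            frac, res = unmix_points_two(pts, refs)
        fractions[:, ys, xs] = frac.T
        residual[ys, xs] = res

    component = np.where(mask, total_raw, 0.0) * np.nan_to_num(fractions, nan=0.0)
    return UnmixResult(
        fractions=fractions,
        mask=mask,
        residual=residual,
        references=refs,
        reference_lifetimes=taus,
        component_images=component,
        total_intensity=total_raw,
        g=np.where(mask, g, np.nan),
        s=np.where(mask, s, np.nan),
    )


# ---------------------------------------------------------------------------
# maximum-likelihood monoexponential fit


@dataclasses.dataclass
class MonoExpFit:
    tau: float  # ns
    tau_se: float  # ns, from observed information
    background: float  # flat background fraction of total counts
    n_photons: float
    converged: bool
    nll: float

    def __iter__(self):  # allows tau, se = fit_monoexponential(...)
        return iter((self.tau, self.tau_se))


def _wrapped_exp_bin_probs(edges: np.ndarray, tau: float, period: float) -> np.ndarray:
    """Bin masses of the period-wrapped exponential density, renormalized
    over the covered bins."""
    # wrapped density f(t) = exp(-t/tau) / (tau (1 - exp(-T/tau))) on [0, T)
    m = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
    return m / m.sum()


def fit_monoexponential(
    decay: DecayHistogram,
    fit_background: bool = True,
    min_counts: float = 1000.0,
) -> MonoExpFit:
    """Poisson maximum-likelihood single-exponential fit.

    Model: expected bin counts N * [(1-b) * wrapped-exp mass + b / n_bins],
    with lifetime tau and flat background fraction b. The wrapped
    exponential accounts for fluorescence from previous excitation cycles
    (tail wrap-around at short periods). The standard error of tau comes
    from the observed information (numerical Hessian at the optimum).
    """
    if decay.total < min_counts:
        raise ValueError(
            f"need >= {min_counts:g} total counts for a stable fit, have {decay.total:g}"
        )
    edges = decay.bin_edges
    counts = decay.counts
    n_bins = len(counts)
    total = counts.sum()

    def nll(params: np.ndarray) -> float:
        log_tau, b = params
        tau = np.exp(log_tau)
        p = (1.0 - b) * _wrapped_exp_bin_probs(edges, tau, decay.period) + b / n_bins
        p = np.maximum(p, 1e-300)
        return -float(np.dot(counts, np.log(p)))

    # moment-based initial guess from the mean arrival time of a wrapped exp
    tbar = float(np.dot(counts, decay.bin_centers) / total)
    tau0 = max(min(tbar, decay.period / 2), edges[1] - edges[0])
    x0 = np.array([np.log(tau0), 0.01 if fit_background else 0.0])
    bounds = [(np.log(1e-3), np.log(decay.period * 10))]
    bounds.append((0.0, 0.5) if fit_background else (0.0, 0.0))
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success:
        raise FitError(f"monoexponential fit did not converge: {res.message}")
    log_tau_hat, b_hat = res.x
    tau_hat = float(np.exp(log_tau_hat))

    # observed information for tau via central differences on the profile in log tau
    h = 1e-4
    f0 = nll(res.x)
    fp = nll(res.x + np.array([h, 0.0]))
    fm = nll(res.x - np.array([h, 0.0]))
    d2 = (fp - 2 * f0 + fm) / h**2
    # var(log tau) ~ 1/d2  ->  var(tau) = tau^2 * var(log tau)
    tau_se = tau_hat / np.sqrt(d2) if d2 > 0 else float("nan")
    return MonoExpFit(
        tau=tau_hat,
        tau_se=float(tau_se),
        background=float(b_hat),
        n_photons=float(total),
        converged=True,
        nll=float(f0),
    )
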