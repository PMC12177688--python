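"""Descriptor-lifetime correlation with per-model spread and bootstrap CI.

Structure predictors emit several models per protein; each descriptor is
correlated with lifetime once per model index, and the mean +/- sd over
those per-model Spearman coefficients summarizes the association (this is
how a value like rho = -0.52 +/- 0.17 is to be read). Significance is
assessed separately by a nonparametric bootstrap over proteins: proteins
are the exchangeable units, models are replicate predictions, so each
bootstrap replicate resamples proteins with replacement and draws one
model index per resampled protein. The 95% percentile interval of the
replicate rho distribution is reported; "significant" means it excludes 0.
No multiplicity correction is applied across descriptors — each is
assessed on its own.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantInputError, InsufficientDataError
from .pocket import DESCRIPTOR_COLUMNS


@dataclasses.dataclass
class LifetimeTable:
    """Protein id -> fluorescence lifetime (ns), with a source tag.

    ``source`` distinguishes in-vitro (cuvette / plate TCSPC) from in-cell
    (FLIM) measurements, which must not be mixed in one correlation.
    """

    entries: dict[str, float]
    source: str = "in_vitro"

    def __post_init__(self) -> None:
        if len(self.entries) != len(set(self.entries)):
            raise ValueError("duplicate protein ids")
        for pid, tau in self.entries.items():
            if not tau > 0:
                raise ValueError(f"lifetime for {pid} must be > 0 ns, got {tau}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifetimeTable":
        df = pd.read_csv(path)
        source = df["source"].iloc[0] if "source" in df else "in_vitro"
        return cls(entries=dict(zip(df["protein_id"], df["tau_ns"])), source=str(source))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"protein_id": list(self.entries), "tau_ns": list(self.entries.values()),
             "source": self.source}
        )


@dataclasses.dataclass
class CorrelationResult:
    descriptor: str
    rho_per_model: np.ndarray
    rho_mean: float
    rho_sd: float
    bootstrap_ci: tuple[float, float] | None = None
    significant: bool | None = None
    n_proteins: int = 0
    n_models: int = 0
    n_boot: int = 0
    seed: int | None = None


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson on average ranks (ties -> mean rank)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise InsufficientDataError(f"need >=3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _descriptor_matrix(
    properties: pd.DataFrame, lifetimes: LifetimeTable, descriptor: str
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Align descriptor values into a (protein x model) matrix plus tau vector."""
    present = sorted(set(properties["protein_id"]))
    missing = [p for p in present if p not in lifetimes.entries]
    if missing:
        warnings.warn(
            f"{len(missing)} protein(s) without lifetimes dropped: {missing}",
            stacklevel=3,
        )
    proteins = [p for p in present if p in lifetimes.entries]
    if len(proteins) < 3:
        raise InsufficientDataError(
            f"need >=3 proteins with both descriptors and lifetimes, have {len(proteins)}"
        )
    sub = properties[properties["protein_id"].isin(proteins)]
    pivot = sub.pivot_table(index="protein_id", columns="model", values=descriptor)
    if pivot.isna().any().any():
        raise ValueError("unequal model sets across proteins")
    pivot = pivot.loc[proteins]
    tau = np.array([lifetimes.entries[p] for p in proteins])
    return pivot.to_numpy(), tau, proteins, pivot.columns.to_numpy()


def correlate_over_models(
    properties: pd.DataFrame,
    lifetimes: LifetimeTable,
    descriptors: list[str] | None = None,
) -> list[CorrelationResult]:
    """Per-model Spearman rho of each descriptor against lifetime.

    For each model index m, rho_m = spearman(descriptor values of all
    proteins at model m, lifetimes); rho_mean and rho_sd (sample sd) are
    taken over the model indices.
    """
    descriptors = descriptors or [c for c in DESCRIPTOR_COLUMNS if c in properties]
    out = []
    for desc in descriptors:
        X, tau, proteins, model_ids = _descriptor_matrix(properties, lifetimes, desc)
        rhos = np.array([spearman(X[:, j], tau) for j in range(X.shape[1])])
        out.append(
            CorrelationResult(
                descriptor=desc,
                rho_per_model=rhos,
                rho_mean=float(rhos.mean()),
                rho_sd=float(rhos.std(ddof=1)) if len(rhos) > 1 else 0.0,
                n_proteins=len(proteins),
                n_models=X.shape[1],
            )
        )
    return out


def _rowwise_spearman(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Spearman rho per row of two equally-shaped (n_rep, n) arrays.

    Rows where either vector is constant yield NaN (degenerate resample).
    """
    rx = stats.rankdata(X, axis=1)
    ry = stats.rankdata(Y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def bootstrap_significance(
    properties: pd.DataFrame,
    lifetimes: LifetimeTable,
    descriptor: str,
    n_boot: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> tuple[float, float, bool]:
    """Percentile bootstrap CI for the descriptor-lifetime Spearman rho.

    Each replicate resamples proteins with replacement and picks one model
    index uniformly at random per resampled protein. Degenerate replicates
    (constant vectors, e.g. one protein drawn n times) are discarded and
    counted; more than 50% discarded raises.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for a stable percentile CI")
    X, tau, proteins, _ = _descriptor_matrix(properties, lifetimes, descriptor)
    n, n_models = X.shape
    rng = np.random.default_rng(seed)
    prot_idx = rng.integers(0, n, size=(n_boot, n))
    model_idx = rng.integers(0, n_models, size=(n_boot, n))
    Xb = X[prot_idx, model_idx]
    Yb = tau[prot_idx]
    rhos = _rowwise_spearman(Xb, Yb)
    ok = np.isfinite(rhos)
    n_bad = int((~ok).sum())
    if n_bad > n_boot // 2:
        raise InsufficientDataError(
            f"{n_bad}/{n_boot} bootstrap replicates degenerate; too few proteins"
        )
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(rhos[ok], [alpha, 1.0 - alpha])
    return float(lo), float(hi), bool(lo > 0 or hi < 0)


def correlation_report(
    properties: pd.DataFrame,
    lifetimes: LifetimeTable,
    descriptors: list[str] | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full report: per-model rho summary + bootstrap CI per descriptor."""
    results = correlate_over_models(properties, lifetimes, descriptors)
    rows = []
    for i, res in enumerate(results):
        sub_seed = None if seed is None else seed + i
        lo, hi, sig = bootstrap_significance(
            properties, lifetimes, res.descriptor, n_boot=n_boot, seed=sub_seed
        )
        res.bootstrap_ci = (lo, hi)
        res.significant = sig
        res.n_boot = n_boot
        res.seed = sub_seed
        rows.append(
            {
                "descriptor": res.descriptor,
                "rho_mean": res.rho_mean,
                "rho_sd": res.rho_sd,
                "ci_lo": lo,
                "ci_hi": hi,
                "significant": sig,
                "n_proteins": res.n_proteins,
                "n_models": res.n_models,
                "n_boot": n_boot,
                "seed": sub_seed,
            }
        )
    return pd.DataFrame(rows)
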