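"""Avalanche detection and criticality statistics.

An avalanche (cascade) is a maximal run of consecutive time bins each
containing at least one excitation event anywhere in the network, bounded
by silent bins.  Its size K is the total event count and its duration the
number of bins.  Near criticality the size distribution P(K) is expected
to follow a power law with exponent close to -3/2 (the branching-process
value); deviation from that reference law is quantified by a least-squares
log-log fit, a mean negative log-likelihood, and the kappa statistic
(kappa = 1 at the reference law, < 1 subcritical-like, > 1
supercritical-like).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "AvalancheCatalog",
    "PowerLawFit",
    "REFERENCE_EXPONENT",
    "detect_avalanches",
    "size_distribution",
    "fit_powerlaw_ls",
    "nll_reference",
    "kappa_statistic",
    "analyze_catalog",
]

#: branching-process critical exponent used as the reference law
REFERENCE_EXPONENT = -1.5


@dataclass(frozen=True)
class AvalancheCatalog:
    """Cascade sizes and durations detected from a binarized raster."""

    sizes: np.ndarray  # positive ints: events per cascade
    durations: np.ndarray  # positive ints: bins per cascade
    bin_dt: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", np.asarray(self.sizes, dtype=int))
        object.__setattr__(self, "durations", np.asarray(self.durations, dtype=int))
        if self.sizes.shape != self.durations.shape:
            raise ValueError("sizes and durations must align")
        if self.sizes.size and (self.sizes.min() < 1 or self.durations.min() < 1):
            raise ValueError("cascade sizes and durations must be >= 1")
        if self.bin_dt < 1:
            raise ValueError("bin_dt must be >= 1")

    @property
    def n_cascades(self) -> int:
        return self.sizes.size


@dataclass(frozen=True)
class PowerLawFit:
    """Summary of a size distribution against the reference power law."""

    exponent: float  # least-squares slope of log10 P(K) vs log10 K
    ls_error: float  # residual sum of squares of that fit
    nll: float  # mean NLL per cascade under the reference law
    kappa: float  # cumulative-distribution deviation statistic
    reference_exponent: float = REFERENCE_EXPONENT
    n_cascades: int = 0

    def to_dict(self) -> dict:
        return {
            "exponent": self.exponent,
            "ls_error": self.ls_error,
            "nll": self.nll,
            "kappa": self.kappa,
            "reference_exponent": self.reference_exponent,
            "n_cascades": self.n_cascades,
        }


def detect_avalanches(activity: np.ndarray, bin_dt: int = 1) -> AvalancheCatalog:
    """Detect cascades in an epoch x node binarized activity matrix.

    Epochs are grouped into consecutive bins of ``bin_dt`` (a trailing
    partial bin is dropped); the event count of a bin is the total number
    of excited entries across all nodes in it.  Maximal runs of bins with
    nonzero count, delimited by zero-count bins, are cascades; runs
    touching the ends of the record are kept.
    """
    if bin_dt < 1:
        raise ValueError("bin_dt must be >= 1")
    arr = np.asarray(activity)
    if arr.size == 0:
        raise ValueError("activity raster is empty")
    if arr.ndim == 1:
        arr = arr[:, None]
    n_bins = arr.shape[0] // bin_dt
    if n_bins == 0:
        return AvalancheCatalog(sizes=np.empty(0, int), durations=np.empty(0, int), bin_dt=bin_dt)
    counts = (
        arr[: n_bins * bin_dt].reshape(n_bins, bin_dt, arr.shape[1]).sum(axis=(1, 2))
    )
    active = counts > 0
    # run-length encode the active mask
    edges = np.diff(np.concatenate(([0], active.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    sizes = np.array([counts[a:b].sum() for a, b in zip(starts, ends)], dtype=int)
    durations = (ends - starts).astype(int)
    return AvalancheCatalog(sizes=sizes, durations=durations, bin_dt=bin_dt)


def size_distribution(catalog: AvalancheCatalog) -> dict[int, float]:
    """Empirical probability of each observed cascade size (sums to 1)."""
    if catalog.n_cascades == 0:
        raise ValueError("empty avalanche catalog")
    values, counts = np.unique(catalog.sizes, return_counts=True)
    total = counts.sum()
    return {int(k): float(cnt) / total for k, cnt in zip(values, counts)}


def fit_powerlaw_ls(dist: dict[int, float]) -> tuple[float, float]:
    """Least-squares power-law fit of a size distribution.

    Ordinary least squares of log10 P(K) on log10 K over the observed
    sizes (no logarithmic binning).  Returns the slope — the fitted
    exponent — and the residual sum of squares.
    """
    if len(dist) < 3:
        raise ValueError("need >= 3 distinct sizes for a least-squares fit")
    k = np.array(sorted(dist))
    p = np.array([dist[int(v)] for v in k], dtype=float)
    if np.any(p <= 0):
        raise ValueError("probabilities must be positive")
    x = np.log10(k)
    yv = np.log10(p)
    coeffs, residuals, *_ = np.polyfit(x, yv, 1, full=True)
    slope = float(coeffs[0])
    ls_error = float(residuals[0]) if residuals.size else 0.0
    return slope, ls_error


def _reference_pmf(lo: int, hi: int, exponent: float) -> np.ndarray:
    """Discrete power law k^exponent normalised on integers lo..hi."""
    k = np.arange(lo, hi + 1, dtype=float)
    w = k ** exponent
    return w / w.sum()


def nll_reference(
    catalog: AvalancheCatalog, reference_exponent: float = REFERENCE_EXPONENT
) -> float:
    """Mean negative log-likelihood per cascade of the reference power law.

    The discrete reference law is normalised over the observed size range
    [min K, max K] (a finite system truncates the law).
    """
    if catalog.n_cascades == 0:
        raise ValueError("empty avalanche catalog")
    lo, hi = int(catalog.sizes.min()), int(catalog.sizes.max())
    if lo == hi:
        raise ValueError("degenerate support: all cascade sizes identical")
    pmf = _reference_pmf(lo, hi, reference_exponent)
    logp = np.log(pmf[catalog.sizes - lo])
    return float(-logp.mean())


def kappa_statistic(
    catalog: AvalancheCatalog,
    reference_exponent: float = REFERENCE_EXPONENT,
    m: int = 10,
) -> float:
    """Kappa deviation from the reference power law.

    kappa = 1 + (1/m) * sum_k [F_ref(beta_k) - F_emp(beta_k)] over m
    logarithmically spaced size points beta_k between the smallest and
    largest observed size, where F_emp is the empirical cumulative size
    distribution and F_ref the reference-law CDF on the same support.
    Values below 1 indicate a subcritical-like (fast-decaying) size
    distribution, above 1 a supercritical-like excess of large cascades.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if catalog.n_cascades == 0:
        raise ValueError("empty avalanche catalog")
    sizes = np.sort(catalog.sizes)
    lo, hi = int(sizes[0]), int(sizes[-1])
    if lo == hi:
        raise ValueError("degenerate support: all cascade sizes identical")
    beta = np.logspace(np.log10(lo), np.log10(hi), m)
    pmf = _reference_pmf(lo, hi, reference_exponent)
    cdf_ref = np.cumsum(pmf)
    # F(beta) = P(K <= beta) evaluated on the integer support
    idx = np.clip(np.floor(beta).astype(int) - lo, 0, hi - lo)
    f_ref = cdf_ref[idx]
    f_emp = np.searchsorted(sizes, beta, side="right") / sizes.size
    return float(1.0 + (f_ref - f_emp).mean())


def analyze_catalog(
    catalog: AvalancheCatalog,
    reference_exponent: float = REFERENCE_EXPONENT,
    m: int = 10,
) -> PowerLawFit:
    """Full criticality summary (LS fit, NLL, kappa) of a catalog."""
    dist = size_distribution(catalog)
    exponent, ls_error = fit_powerlaw_ls(dist)
    return PowerLawFit(
        exponent=exponent,
        ls_error=ls_error,
        nll=nll_reference(catalog, reference_exponent),
        kappa=kappa_statistic(catalog, reference_exponent, m),
        reference_exponent=reference_exponent,
        n_cascades=catalog.n_cascades,
    )


def write_report(fit: PowerLawFit, catalog: AvalancheCatalog, path: str | Path) -> None:
    """JSON report: size histogram plus the fit summary."""
    values, counts = np.unique(catalog.sizes, return_counts=True)
    report = fit.to_dict()
    report["size_histogram"] = {int(k): int(c) for k, c in zip(values, counts)}
    Path(path).write_text(json.dumps(report, indent=2))
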