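"""Interspecific allele-frequency correlation scan.

Given per-deme allele-"1" frequencies for a host (N demes x n_H loci) and a
parasite (N x n_P), the scan computes, for every cross-species locus pair
(i, j):

* the spatial covariance C[i, j] = Cov(p_H,i, p_P,j) across demes,
* the correlation rho[i, j] = C[i, j] / (sigma_H,i * sigma_P,j),
* the statistic t[i, j] = rho * sqrt(N - 2) / sqrt(1 - rho**2),

and declares a pair significant when |t| exceeds the two-tailed critical
value of Student's t with N - 2 degrees of freedom at level alpha. The test
is exact only when demes and loci evolve independently; the simulator and
experiments modules exist precisely to measure how it degrades when gene
flow violates that assumption.

Pairs involving a monomorphic locus (zero spatial variance) have an
undefined correlation; they are reported as NaN, never significant, and are
retained in the type-I denominator since the error rates are defined over
all possible pairs.

Allele labels are arbitrary: relabeling 0 <-> 1 at a locus flips the sign of
its correlations but leaves |t| and every significance call unchanged, which
is why the screen is two-tailed by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sim_core import CoevArchitecture

__all__ = [
    "FrequencyTable",
    "ScanResult",
    "ErrorReport",
    "allele_frequencies",
    "covariance_matrix",
    "correlation_matrix",
    "t_statistic",
    "critical_t",
    "significant_pairs",
    "run_scan",
    "classify_errors",
]


@dataclass
class FrequencyTable:
    """N demes x n loci matrix of allele-"1" frequencies with axis labels."""

    freqs: np.ndarray
    demes: list[str]
    loci: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2:
            raise ValueError(f"freqs: expected a 2-D matrix, got ndim={self.freqs.ndim}")
        self.demes = [str(d) for d in self.demes]
        self.loci = [str(l) for l in self.loci]
        if len(self.demes) != self.freqs.shape[0]:
            raise ValueError(
                f"demes: {len(self.demes)} labels for {self.freqs.shape[0]} rows"
            )
        if len(self.loci) != self.freqs.shape[1]:
            raise ValueError(
                f"loci: {len(self.loci)} labels for {self.freqs.shape[1]} columns"
            )
        if len(set(self.demes)) != len(self.demes):
            dup = sorted({d for d in self.demes if self.demes.count(d) > 1})
            raise ValueError(f"demes: duplicate deme IDs {dup}")
        bad = np.flatnonzero(~((self.freqs >= 0.0) & (self.freqs <= 1.0)).all(axis=1))
        if bad.size:
            k = int(bad[0])
            j = int(np.flatnonzero(~((self.freqs[k] >= 0) & (self.freqs[k] <= 1)))[0])
            raise ValueError(
                f"freqs: value {self.freqs[k, j]} out of [0, 1] at deme "
                f"{self.demes[k]!r}, locus {self.loci[j]!r}"
            )

    @property
    def n_pops(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, index=pd.Index(self.demes, name="population"),
                            columns=self.loci)


def allele_frequencies(
    pops: Sequence[np.ndarray],
    deme_labels: Sequence[str] | None = None,
    locus_labels: Sequence[str] | None = None,
    locus_prefix: str = "L",
    sample_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> FrequencyTable:
    """Census frequencies of allele "1" per deme per locus.

    ``pops`` is one genotype matrix (individuals x loci) per deme; all demes
    must share the locus count but may differ in size. When ``sample_size``
    is given, frequencies are instead estimated from that many individuals
    drawn without replacement per deme (capped at the deme size), emulating
    finite genotyping effort.
    """
    if len(pops) == 0:
        raise ValueError("allele_frequencies: no demes supplied")
    mats = [np.asarray(p) for p in pops]
    if sample_size is not None:
        if rng is None:
            raise ValueError("allele_frequencies: sample_size requires rng")
        if sample_size < 1:
            raise ValueError(f"sample_size: must be >= 1, got {sample_size}")
        mats = [
            m[rng.choice(m.shape[0], size=min(sample_size, m.shape[0]), replace=False)]
            for m in mats
        ]
    n_loci = mats[0].shape[1]
    for k, m in enumerate(mats):
        if m.shape[0] == 0:
            raise ValueError(f"allele_frequencies: deme {k} is empty")
        if m.shape[1] != n_loci:
            raise ValueError(
                f"allele_frequencies: deme {k} has {m.shape[1]} loci, expected {n_loci}"
            )
    freqs = np.stack([m.mean(axis=0) for m in mats])
    demes = list(deme_labels) if deme_labels is not None else [
        f"pop{k}" for k in range(len(mats))
    ]
    loci = list(locus_labels) if locus_labels is not None else [
        f"{locus_prefix}{j}" for j in range(n_loci)
    ]
    return FrequencyTable(freqs, demes, loci)


def _freq_array(table: "FrequencyTable | np.ndarray") -> np.ndarray:
    if isinstance(table, FrequencyTable):
        return table.freqs
    return np.asarray(table, dtype=float)


def covariance_matrix(
    fh: "FrequencyTable | np.ndarray", fp: "FrequencyTable | np.ndarray"
) -> np.ndarray:
    """Spatial covariances across demes; rows = host loci, columns = parasite loci.

    Uses the population (divide-by-N) normalization; the choice cancels in
    the correlation and hence never affects t or significance.
    """
    x = _freq_array(fh)
    y = _freq_array(fp)
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"covariance_matrix: deme counts differ ({x.shape[0]} vs {y.shape[0]})"
        )
    if x.shape[0] < 2:
        raise ValueError("covariance_matrix: need at least 2 demes")
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    return xc.T @ yc / n


def correlation_matrix(
    fh: "FrequencyTable | np.ndarray", fp: "FrequencyTable | np.ndarray"
) -> tuple[np.ndarray, np.ndarray]:
    """Correlations rho[i, j] plus a mask of undefined (monomorphic) pairs.

    Undefined entries are NaN in the returned matrix. Defined entries are
    clipped into [-1, 1] against floating-point overshoot.
    """
    x = _freq_array(fh)
    y = _freq_array(fp)
    if x.shape[0] < 3:
        raise ValueError("correlation_matrix: need at least 3 demes")
    cov = covariance_matrix(x, y)
    sx = x.std(axis=0)
    sy = y.std(axis=0)
    undefined = (sx[:, None] == 0.0) | (sy[None, :] == 0.0)
    denom = np.where(undefined, 1.0, sx[:, None] * sy[None, :])
    rho = np.clip(cov / denom, -1.0, 1.0)
    rho[undefined] = np.nan
    return rho, undefined


def t_statistic(rho: "float | np.ndarray", n_pops: int) -> "float | np.ndarray":
    """t = rho * sqrt(N - 2) / sqrt(1 - rho**2), with df = N - 2.

    |rho| = 1 maps to a signed infinity (significant at any level); NaN
    (undefined correlation) propagates.
    """
    if n_pops < 3:
        raise ValueError(f"n_pops: need >= 3 for positive degrees of freedom, got {n_pops}")
    rho_arr = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_arr * np.sqrt(n_pops - 2) / np.sqrt(1.0 - rho_arr * rho_arr)
        t = np.where(np.abs(rho_arr) == 1.0, np.inf * np.sign(rho_arr), t)
    return float(t) if np.isscalar(rho) else t


def critical_t(alpha: float, n_pops: int) -> float:
    """Two-tailed critical value of Student's t at level alpha, df = N - 2."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha: must lie in (0, 1), got {alpha}")
    return float(stats.t.ppf(1.0 - alpha / 2.0, n_pops - 2))


def significant_pairs(
    t: np.ndarray, n_pops: int, alpha: float, two_tailed: bool = True
) -> np.ndarray:
    """Boolean matrix: |t| above the critical value; undefined pairs are False."""
    t = np.asarray(t, dtype=float)
    if two_tailed:
        crit = critical_t(alpha, n_pops)
        with np.errstate(invalid="ignore"):
            sig = np.abs(t) > crit
    else:
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha: must lie in (0, 1), got {alpha}")
        crit = float(stats.t.ppf(1.0 - alpha, n_pops - 2))
        with np.errstate(invalid="ignore"):
            sig = t > crit
    sig[np.isnan(t)] = False
    return sig


@dataclass
class ScanResult:
    """All per-pair scan outputs; rows = host loci, columns = parasite loci."""

    cov: np.ndarray
    rho: np.ndarray
    t: np.ndarray
    pvals: np.ndarray
    significant: np.ndarray
    undefined_mask: np.ndarray
    n_pops: int
    alpha: float
    host_loci: list[str] = field(default_factory=list)
    par_loci: list[str] = field(default_factory=list)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: one row per host x parasite locus pair."""
        n_h, n_p = self.cov.shape
        hl = self.host_loci or [f"H{i}" for i in range(n_h)]
        pl = self.par_loci or [f"P{j}" for j in range(n_p)]
        ii, jj = np.meshgrid(np.arange(n_h), np.arange(n_p), indexing="ij")
        return pd.DataFrame(
            {
                "host_locus": np.asarray(hl)[ii.ravel()],
                "parasite_locus": np.asarray(pl)[jj.ravel()],
                "covariance": self.cov.ravel(),
                "correlation": self.rho.ravel(),
                "t": self.t.ravel(),
                "p_value": self.pvals.ravel(),
                "significant": self.significant.ravel(),
            }
        )


def run_scan(
    fh: "FrequencyTable | np.ndarray",
    fp: "FrequencyTable | np.ndarray",
    alpha: float = 0.01,
    two_tailed: bool = True,
    correction: str | None = None,
) -> ScanResult:
    """Covariances, correlations, t statistics, p-values and calls in one pass.

    ``correction`` is an optional post-hoc multiple-testing adjustment of the
    significance calls ("bonferroni" or "fdr_bh"); the screen is studied at
    raw alpha, so it is off by default. Undefined (monomorphic) pairs are
    excluded from the correction's test count.
    """
    x = _freq_array(fh)
    y = _freq_array(fp)
    n = x.shape[0]
    cov = covariance_matrix(x, y)
    rho, undefined = correlation_matrix(x, y)
    t = t_statistic(rho, n)
    with np.errstate(invalid="ignore"):
        pvals = 2.0 * stats.t.sf(np.abs(t), n - 2)
    if correction is None:
        sig = significant_pairs(t, n, alpha, two_tailed=two_tailed)
    else:
        sig = _corrected_calls(pvals, undefined, alpha, correction)
    return ScanResult(
        cov=cov,
        rho=rho,
        t=t,
        pvals=pvals,
        significant=sig,
        undefined_mask=undefined,
        n_pops=n,
        alpha=alpha,
        host_loci=list(fh.loci) if isinstance(fh, FrequencyTable) else [],
        par_loci=list(fp.loci) if isinstance(fp, FrequencyTable) else [],
    )


def _corrected_calls(
    pvals: np.ndarray, undefined: np.ndarray, alpha: float, method: str
) -> np.ndarray:
    """Multiple-testing-adjusted significance calls over the defined pairs."""
    from statsmodels.stats.multitest import multipletests

    if method not in ("bonferroni", "fdr_bh"):
        raise ValueError(
            f"correction: expected 'bonferroni' or 'fdr_bh', got {method!r}"
        )
    sig = np.zeros(pvals.shape, dtype=bool)
    defined = ~undefined
    if defined.any():
        rejected, *_ = multipletests(pvals[defined], alpha=alpha, method=method)
        sig[defined] = rejected
    return sig


@dataclass
class ErrorReport:
    """Scan calls scored against the known functional pairs.

    Type I: significant pairs that are not functional, over all non-functional
    pairs. Type II: functional pairs not called, over all functional pairs.
    ``full_detection`` is the replicate-level success criterion: every
    functional pair significant (partial identification counts as failure).
    """

    type1_count: int
    type1_possible: int
    type1_rate: float
    type2_count: int
    type2_possible: int
    type2_rate: float
    detected_pairs: list[tuple[int, int]]
    full_detection: bool

    def to_dict(self) -> dict:
        return {
            "type1_count": self.type1_count,
            "type1_possible": self.type1_possible,
            "type1_rate": self.type1_rate,
            "type2_count": self.type2_count,
            "type2_possible": self.type2_possible,
            "type2_rate": self.type2_rate,
            "detected_pairs": [list(p) for p in self.detected_pairs],
            "full_detection": self.full_detection,
        }


def classify_errors(
    significant: np.ndarray,
    functional_pairs: "CoevArchitecture | Iterable[tuple[int, int]]",
) -> ErrorReport:
    """Score a significance matrix against the functional-pair truth set."""
    if isinstance(functional_pairs, CoevArchitecture):
        pairs = set(functional_pairs.functional_pairs)
    else:
        pairs = {(int(i), int(j)) for i, j in functional_pairs}
    sig = np.asarray(significant, dtype=bool)
    n_h, n_p = sig.shape
    for i, j in pairs:
        if not (0 <= i < n_h and 0 <= j < n_p):
            raise ValueError(f"functional pair {(i, j)} outside the {sig.shape} matrix")
    truth = np.zeros_like(sig)
    for i, j in pairs:
        truth[i, j] = True
    type1_count = int(np.sum(sig & ~truth))
    type1_possible = n_h * n_p - len(pairs)
    type2_count = int(np.sum(truth & ~sig))
    type2_possible = len(pairs)
    detected = sorted((i, j) for i, j in pairs if sig[i, j])
    return ErrorReport(
        type1_count=type1_count,
        type1_possible=type1_possible,
        type1_rate=type1_count / type1_possible if type1_possible else 0.0,
        type2_count=type2_count,
        type2_possible=type2_possible,
        type2_rate=type2_count / type2_possible if type2_possible else 0.0,
        detected_pairs=detected,
        full_detection=type2_count == 0,
    )
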