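"""Synthetic frequency tables with planted cross-species correlations.

Lets the scan be exercised and calibrated independently of the simulator: a
Gaussian copula on the logit scale plants a chosen correlation ``rho_true``
between designated host/parasite locus columns while keeping every frequency
inside (0, 1). Unpaired columns are independent logit-normal noise, i.e. a
pure null. Because the logistic map is monotone, the planted latent
correlation survives (mildly attenuated) in the frequency-scale Pearson
correlation, and Fisher-z arguments apply to the latent scale exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .scan import FrequencyTable

__all__ = ["SyntheticScanTruth", "synth_correlated_frequencies"]


@dataclass
class SyntheticScanTruth:
    """A host/parasite table pair with the planted-pair truth attached."""

    host: FrequencyTable
    par: FrequencyTable
    true_pairs: list[tuple[int, int, float]]  # (host locus, parasite locus, rho_true)
    neutral_host: list[int]
    neutral_par: list[int]

    def to_dict(self) -> dict:
        return {
            "true_pairs": [[i, j, r] for i, j, r in self.true_pairs],
            "neutral_host": self.neutral_host,
            "neutral_par": self.neutral_par,
        }


def synth_correlated_frequencies(
    n_pops: int,
    n_host_loci: int,
    n_par_loci: int,
    true_pairs: "list[tuple[int, int, float]] | None",
    rng: np.random.Generator,
    logit_mean: float = 0.0,
    logit_sd: float = 1.0,
) -> SyntheticScanTruth:
    """Draw correlated logit-normal frequency tables.

    Each true pair (i, j, rho_true) makes host column i and parasite column j
    a bivariate Gaussian with correlation rho_true on the logit scale, pushed
    through the logistic function. A host or parasite column may appear in at
    most one pair; all other columns are independent.
    """
    if n_pops < 4:
        raise ValueError(f"n_pops: need >= 4, got {n_pops}")
    true_pairs = [(int(i), int(j), float(r)) for i, j, r in (true_pairs or [])]
    hosts_used = [i for i, _, _ in true_pairs]
    pars_used = [j for _, j, _ in true_pairs]
    if len(set(hosts_used)) != len(hosts_used) or len(set(pars_used)) != len(pars_used):
        raise ValueError("true_pairs: a column may appear in at most one pair")
    for i, j, r in true_pairs:
        if not (0 <= i < n_host_loci and 0 <= j < n_par_loci):
            raise ValueError(f"true_pairs: pair ({i}, {j}) out of range")
        if not abs(r) < 1.0:
            raise ValueError(f"true_pairs: |rho_true| must be < 1, got {r}")

    zh = rng.standard_normal((n_pops, n_host_loci))
    zp = rng.standard_normal((n_pops, n_par_loci))
    for i, j, r in true_pairs:
        # correlate the pair's latent columns: zp = r*zh + sqrt(1-r^2)*noise
        zp[:, j] = r * zh[:, i] + np.sqrt(1.0 - r * r) * rng.standard_normal(n_pops)
    host = FrequencyTable(
        expit(logit_mean + logit_sd * zh),
        [f"pop{k}" for k in range(n_pops)],
        [f"H{i}" for i in range(n_host_loci)],
    )
    par = FrequencyTable(
        expit(logit_mean + logit_sd * zp),
        [f"pop{k}" for k in range(n_pops)],
        [f"P{j}" for j in range(n_par_loci)],
    )
    return SyntheticScanTruth(
        host=host,
        par=par,
        true_pairs=true_pairs,
        neutral_host=[i for i in range(n_host_loci) if i not in hosts_used],
        neutral_par=[j for j in range(n_par_loci) if j not in pars_used],
    )
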