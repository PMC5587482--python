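"""Individual-based forward simulator of haploid host-parasite coevolution.

A metapopulation of ``n_pops`` demes is arranged in a linear array. Each deme
holds one host and one parasite population of haploid individuals whose
genomes are vectors of diallelic (0/1) loci. A randomly chosen subset of loci
in each species is coevolving: those loci jointly determine the probability
that a parasite infects a host it encounters, under one of two infection
models:

* ``discrete_matching`` -- infection probability ``1 - beta * M`` where ``M``
  is the fraction of positionally paired coevolving loci at which host and
  parasite carry different alleles. As ``beta -> 1`` this converges on the
  classical matching-alleles model.
* ``quantitative_matching`` -- infection probability ``exp(-beta * delta**2)``
  where ``delta = z_h - z_p`` is the difference between host and parasite
  phenotypes, each phenotype being the fraction of "1" alleles at that
  species' coevolving loci (scaled to [0, 1]).

Each generation applies, in order: (1) species interactions (encounter and
viability selection), (2) sexual reproduction with recombination between
adjacent loci, (3) symmetric single-locus mutation at a per-genome rate, and
(4) symmetric stepping-stone migration between adjacent demes, with edge
demes experiencing half the interior per-individual rate.

All genotype state is stored as ``uint8`` arrays of shape
``(n_pops, eta, n_loci)`` so a full generation is a handful of vectorized
array operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "InfectionModel",
    "SimParams",
    "CoevArchitecture",
    "Metapopulation",
    "init_metapopulation",
    "phenotype",
    "infection_probability",
    "encounter_and_select",
    "reproduce",
    "mutate",
    "migrate",
    "run_simulation",
]


class InfectionModel(str, Enum):
    """Genetic model mapping host/parasite genotypes to infection probability."""

    discrete_matching = "discrete_matching"
    quantitative_matching = "quantitative_matching"


def _as_model(model: "InfectionModel | str") -> InfectionModel:
    return InfectionModel(model)


def _as_rec_rates(r, n_loci: int, name: str) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.ndim == 0:
        r = np.full(n_loci - 1, float(r))
    if r.shape != (n_loci - 1,):
        raise ValueError(
            f"{name}: expected {n_loci - 1} adjacent-locus rates, got shape {r.shape}"
        )
    if np.any((r < 0.0) | (r > 0.5)):
        raise ValueError(f"{name}: recombination rates must lie in [0, 0.5]")
    return r


@dataclass
class SimParams:
    """Full parameterization of one simulation run.

    Recombination rates may be given as a scalar (broadcast to every adjacent
    pair) or as a vector of length ``n_loci - 1``.
    """

    n_pops: int = 40
    n_loci_host: int = 100
    n_loci_par: int = 100
    n_coev: int = 1
    model: InfectionModel = InfectionModel.discrete_matching
    beta: float = 0.9
    s: float = 0.75
    eta_host: int = 225
    eta_par: int = 225
    mu_host: float = 0.03
    mu_par: float = 0.03
    m_host: float = 0.005
    m_par: float = 0.005
    r_host: np.ndarray | float = 0.25
    r_par: np.ndarray | float = 0.25
    generations: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        self.model = _as_model(self.model)
        for name in ("n_pops", "n_loci_host", "n_loci_par", "n_coev", "generations"):
            v = getattr(self, name)
            if int(v) != v:
                raise ValueError(f"{name}: must be an integer, got {v!r}")
            setattr(self, name, int(v))
        if self.n_pops < 1:
            raise ValueError(f"n_pops: must be >= 1, got {self.n_pops}")
        if self.generations < 0:
            raise ValueError(f"generations: must be >= 0, got {self.generations}")
        if not 1 <= self.n_coev <= min(self.n_loci_host, self.n_loci_par):
            raise ValueError(
                f"n_coev: must satisfy 1 <= n_coev <= min(n_loci_host, n_loci_par), "
                f"got {self.n_coev}"
            )
        for name in ("eta_host", "eta_par"):
            v = getattr(self, name)
            if int(v) != v or v < 2:
                raise ValueError(f"{name}: must be an integer >= 2, got {v!r}")
            setattr(self, name, int(v))
        for name in ("s", "mu_host", "mu_par", "m_host", "m_par"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must lie in [0, 1], got {v}")
            setattr(self, name, v)
        if self.beta < 0.0:
            raise ValueError(f"beta: must be >= 0, got {self.beta}")
        if self.model is InfectionModel.discrete_matching and self.beta > 1.0:
            raise ValueError(
                f"beta: discrete_matching requires beta <= 1 (else infection "
                f"probabilities go negative), got {self.beta}"
            )
        self.beta = float(self.beta)
        self.r_host = _as_rec_rates(self.r_host, self.n_loci_host, "r_host")
        self.r_par = _as_rec_rates(self.r_par, self.n_loci_par, "r_par")


@dataclass(frozen=True)
class CoevArchitecture:
    """Which loci interact across species, and the truth set of coupled pairs.

    ``functional_pairs`` is the set of (host locus, parasite locus) pairs a
    scan is scored against. Under discrete matching, host coevolving locus k
    is compared with parasite coevolving locus k, so only the positionally
    paired combinations are functional. Under quantitative matching the loci
    contribute additively and interchangeably to the phenotypes, so every
    cross-species combination of coevolving loci is functional.
    """

    host_coev_idx: tuple[int, ...]
    par_coev_idx: tuple[int, ...]
    functional_pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.host_coev_idx) != len(self.par_coev_idx):
            raise ValueError("host and parasite coevolving index lists differ in length")
        if len(set(self.host_coev_idx)) != len(self.host_coev_idx):
            raise ValueError("host_coev_idx: indices must be unique")
        if len(set(self.par_coev_idx)) != len(self.par_coev_idx):
            raise ValueError("par_coev_idx: indices must be unique")

    @property
    def n_coev(self) -> int:
        return len(self.host_coev_idx)

    @classmethod
    def from_indices(
        cls,
        host_idx: Sequence[int],
        par_idx: Sequence[int],
        model: "InfectionModel | str",
    ) -> "CoevArchitecture":
        host_idx = tuple(int(i) for i in host_idx)
        par_idx = tuple(int(i) for i in par_idx)
        if _as_model(model) is InfectionModel.discrete_matching:
            pairs = frozenset(zip(host_idx, par_idx))
        else:
            pairs = frozenset((h, p) for h in host_idx for p in par_idx)
        return cls(host_idx, par_idx, pairs)


@dataclass
class Metapopulation:
    """State of the linear metapopulation: genotypes plus the architecture.

    ``host`` and ``par`` have shape ``(n_pops, eta, n_loci)``; deme order
    defines stepping-stone adjacency (deme k neighbors k-1 and k+1).
    """

    host: np.ndarray
    par: np.ndarray
    arch: CoevArchitecture
    params: SimParams

    @property
    def n_pops(self) -> int:
        return self.host.shape[0]

    def demes(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-deme (host, parasite) genotype-matrix views, in deme order."""
        return [(self.host[k], self.par[k]) for k in range(self.n_pops)]

    def copy(self) -> "Metapopulation":
        return Metapopulation(self.host.copy(), self.par.copy(), self.arch, self.params)


# ---------------------------------------------------------------------------
# initialization


def init_metapopulation(params: SimParams, rng: np.random.Generator) -> Metapopulation:
    """Build a metapopulation with every allele Bernoulli(1/2).

    Coevolving locus indices are drawn uniformly without replacement within
    each species; the functional-pair truth set follows the model rule (see
    :class:`CoevArchitecture`).
    """
    host_idx = rng.choice(params.n_loci_host, size=params.n_coev, replace=False)
    par_idx = rng.choice(params.n_loci_par, size=params.n_coev, replace=False)
    arch = CoevArchitecture.from_indices(host_idx, par_idx, params.model)
    host = (
        rng.random((params.n_pops, params.eta_host, params.n_loci_host)) < 0.5
    ).astype(np.uint8)
    par = (
        rng.random((params.n_pops, params.eta_par, params.n_loci_par)) < 0.5
    ).astype(np.uint8)
    return Metapopulation(host, par, arch, params)


# ---------------------------------------------------------------------------
# species interactions


def phenotype(genome: np.ndarray, coev_idx: Sequence[int]) -> np.ndarray:
    """Scaled additive phenotype: fraction of "1" alleles at the coevolving loci.

    Accepts a single genome vector or any stack of genomes (loci on the last
    axis); returns a scalar or the matching stack of scalars in [0, 1].
    """
    coev_idx = np.asarray(coev_idx, dtype=np.intp)
    if coev_idx.size == 0:
        raise ValueError("coev_idx: must be nonempty")
    genome = np.asarray(genome)
    return genome[..., coev_idx].mean(axis=-1)


def _infection_prob_coev(
    host_coev: np.ndarray,
    par_coev: np.ndarray,
    model: InfectionModel,
    beta: float,
) -> np.ndarray:
    """Infection probability from the coevolving-allele blocks alone."""
    if model is InfectionModel.discrete_matching:
        mismatch = (host_coev != par_coev).mean(axis=-1)
        return 1.0 - beta * mismatch
    delta = host_coev.mean(axis=-1) - par_coev.mean(axis=-1)
    return np.exp(-beta * delta * delta)


def infection_probability(
    host_genome: np.ndarray,
    par_genome: np.ndarray,
    model: "InfectionModel | str",
    beta: float,
    arch: CoevArchitecture,
) -> np.ndarray:
    """Probability that the parasite infects the host on encounter.

    Only the coevolving loci named in ``arch`` enter the computation; all
    other loci are neutral. Vectorizes over any matching leading axes.
    """
    model = _as_model(model)
    if beta < 0.0:
        raise ValueError(f"beta: must be >= 0, got {beta}")
    if model is InfectionModel.discrete_matching and beta > 1.0:
        raise ValueError(f"beta: discrete_matching requires beta <= 1, got {beta}")
    hc = np.asarray(host_genome)[..., np.asarray(arch.host_coev_idx, dtype=np.intp)]
    pc = np.asarray(par_genome)[..., np.asarray(arch.par_coev_idx, dtype=np.intp)]
    return _infection_prob_coev(hc, pc, model, beta)


def _select(
    host: np.ndarray,
    par: np.ndarray,
    model: InfectionModel,
    beta: float,
    s: float,
    arch: CoevArchitecture,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched encounter + viability selection; returns survival masks."""
    n_pops, eta_h, _ = host.shape
    eta_p = par.shape[1]
    hidx = np.asarray(arch.host_coev_idx, dtype=np.intp)
    pidx = np.asarray(arch.par_coev_idx, dtype=np.intp)
    hc = host[:, :, hidx]
    pc = par[:, :, pidx]
    deme = np.arange(n_pops)[:, None]
    # each host encounters one parasite, drawn uniformly with replacement
    partner_p = rng.integers(0, eta_p, size=(n_pops, eta_h))
    p_host = _infection_prob_coev(hc, pc[deme, partner_p], model, beta)
    surv_h = rng.random((n_pops, eta_h)) < 1.0 - s * p_host
    # each parasite independently encounters one host
    partner_h = rng.integers(0, eta_h, size=(n_pops, eta_p))
    p_par = _infection_prob_coev(hc[deme, partner_h], pc, model, beta)
    surv_p = rng.random((n_pops, eta_p)) < p_par
    return surv_h, surv_p


def encounter_and_select(
    host_pop: np.ndarray,
    par_pop: np.ndarray,
    model: "InfectionModel | str",
    beta: float,
    s: float,
    arch: CoevArchitecture,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Run one deme's interaction stage; return the surviving genome rows.

    Each host survives with probability ``1 - s * P`` against its encountered
    parasite; each parasite survives with probability ``P`` against its
    encountered host. Empty survivor sets are legal (handled downstream by
    the reproduction fallback).
    """
    model = _as_model(model)
    host_pop = np.asarray(host_pop)
    par_pop = np.asarray(par_pop)
    if host_pop.shape[0] == 0 or par_pop.shape[0] == 0:
        raise ValueError("encounter_and_select: both populations must be nonempty")
    surv_h, surv_p = _select(
        host_pop[None], par_pop[None], model, beta, s, arch, rng
    )
    return host_pop[surv_h[0]], par_pop[surv_p[0]]


# ---------------------------------------------------------------------------
# reproduction


def _recombine(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    r: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate one gamete per parent pair (loci on the last axis).

    The gamete starts on a uniformly chosen parent and switches parental
    source between adjacent loci i, i+1 independently with probability r_i.
    """
    lead = parent_a.shape[:-1]
    n_rows = int(np.prod(lead)) if lead else 1
    n_loci = r.size + 1
    # Fortran order makes each locus column contiguous, so the cumulative
    # XOR below runs as n_loci-1 vectorized column operations
    source = np.empty((n_rows, n_loci), dtype=np.uint8, order="F")
    source[:, 0] = rng.random(n_rows) < 0.5
    source[:, 1:] = rng.random((n_rows, r.size), dtype=np.float32) < r
    for j in range(1, n_loci):
        source[:, j] ^= source[:, j - 1]
    source = source.reshape(lead + (n_loci,))
    # source is 0/1 per locus: blend the two parents without a boolean temp
    return parent_a ^ ((parent_a ^ parent_b) & source)


def reproduce(
    survivors: np.ndarray,
    r: np.ndarray,
    eta: int,
    fallback: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce exactly ``eta`` haploid offspring by random mating.

    Parents are drawn uniformly with replacement from ``survivors``; if fewer
    than two survivors remain, parents are drawn from ``fallback`` (the
    pre-selection population) instead, so a deme never silently dies out.
    """
    if eta < 1:
        raise ValueError(f"eta: must be >= 1, got {eta}")
    pool = np.asarray(survivors)
    if pool.shape[0] < 2:
        pool = np.asarray(fallback)
    r = np.asarray(r, dtype=float)
    pa = rng.integers(0, pool.shape[0], size=eta)
    pb = rng.integers(0, pool.shape[0], size=eta)
    return _recombine(pool[pa], pool[pb], r, rng)


def _reproduce_species(
    pop: np.ndarray,
    surv_mask: np.ndarray,
    r: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Batched reproduction across all demes of one species."""
    n_pops, eta, _ = pop.shape
    pa = np.empty((n_pops, eta), dtype=np.intp)
    pb = np.empty((n_pops, eta), dtype=np.intp)
    for k in range(n_pops):
        idx = np.flatnonzero(surv_mask[k])
        if idx.size < 2:  # extinction guard: fall back to pre-selection deme
            idx = np.arange(eta)
        pa[k] = idx[rng.integers(0, idx.size, size=eta)]
        pb[k] = idx[rng.integers(0, idx.size, size=eta)]
    deme = np.arange(n_pops)[:, None]
    return _recombine(pop[deme, pa], pop[deme, pb], r, rng)


# ---------------------------------------------------------------------------
# mutation and migration


def mutate(pop: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    """With probability ``mu`` per genome, flip one uniformly chosen locus.

    Mutation is symmetric (0 <-> 1) and at most one locus changes per genome
    per generation; ``mu`` is a per-genome, not per-locus, rate. Returns a
    new array; accepts a single population (2-D) or a deme stack (3-D).
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu: must lie in [0, 1], got {mu}")
    pop = np.asarray(pop)
    squeeze = pop.ndim == 2
    out = pop[None].copy() if squeeze else pop.copy()
    _mutate_inplace(out, mu, rng)
    return out[0] if squeeze else out


def _mutate_inplace(pop: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    n_pops, eta, n_loci = pop.shape
    hit = rng.random((n_pops, eta)) < mu
    loci = rng.integers(0, n_loci, size=(n_pops, eta))
    kk, ii = np.nonzero(hit)
    pop[kk, ii, loci[kk, ii]] ^= 1


def _migrate_species(pop: np.ndarray, m: float, rng: np.random.Generator) -> None:
    """In-place symmetric stepping-stone migration for one species.

    Each individual attempts a swap with each adjacent deme independently
    with probability m/2 per neighbor; a swap exchanges it with a uniformly
    chosen individual of the same species in that neighbor. Edge demes have
    one neighbor and hence half the interior per-individual rate. Deme sizes
    are conserved exactly. Demes are processed left to right with a single
    RNG stream, so runs are reproducible.
    """
    n_pops, eta, _ = pop.shape
    if n_pops < 2 or m == 0.0:
        return
    half = m / 2.0
    for k in range(n_pops):
        for nb in (k - 1, k + 1):
            if nb < 0 or nb >= n_pops:
                continue
            movers = np.flatnonzero(rng.random(eta) < half)
            for i in movers:
                j = int(rng.integers(0, eta))
                tmp = pop[k, i].copy()
                pop[k, i] = pop[nb, j]
                pop[nb, j] = tmp


def migrate(
    metapop: Metapopulation,
    m_host: float,
    m_par: float,
    rng: np.random.Generator,
) -> Metapopulation:
    """Return a new metapopulation after one round of stepping-stone migration."""
    for name, m in (("m_host", m_host), ("m_par", m_par)):
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"{name}: must lie in [0, 1], got {m}")
    out = metapop.copy()
    _migrate_species(out.host, m_host, rng)
    _migrate_species(out.par, m_par, rng)
    return out


# ---------------------------------------------------------------------------
# full life cycle


def run_simulation(
    params: SimParams, rng: np.random.Generator | None = None
) -> Metapopulation:
    """Simulate ``params.generations`` generations of the four-stage life cycle.

    Stage order within a generation is interaction -> reproduction ->
    mutation -> migration, with the host processed before the parasite at
    every stage. A single generator (seeded from ``params.seed`` when none is
    supplied) is threaded through all stages, so identical parameters and
    seed reproduce the final genotype matrices bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    mp = init_metapopulation(params, rng)
    for _ in range(params.generations):
        surv_h, surv_p = _select(
            mp.host, mp.par, params.model, params.beta, params.s, mp.arch, rng
        )
        mp.host = _reproduce_species(mp.host, surv_h, params.r_host, rng)
        mp.par = _reproduce_species(mp.par, surv_p, params.r_par, rng)
        _mutate_inplace(mp.host, params.mu_host, rng)
        _mutate_inplace(mp.par, params.mu_par, rng)
        _migrate_species(mp.host, params.m_host, rng)
        _migrate_species(mp.par, params.m_par, rng)
    return mp
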