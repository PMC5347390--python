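"""Fully-stochastic multistage carcinogenesis model in continuous time.

Cells are typed ``(alpha, beta)`` where ``alpha`` counts acquired driver
mutations and ``beta`` distinguishes stem (0) from transit (1) cells.  Each
cell may divide symmetrically at rate ``G(alpha, beta)``, die or terminally
differentiate at rate ``D(alpha, beta)``, or divide asymmetrically into an
equivalent daughter plus a cell carrying one further mutation at rate
``M(alpha, beta)``; stem cells additionally seed transit cells of the same
mutation stage at rate ``A(alpha, 0)``.  A cell that reaches ``k`` mutations
(``k_t`` for transit cells) is malignant and the process stops.

The process starts from a single unmutated stem cell at age 0.  During
gestation (length ``L_g``) the stem pool grows exponentially to an expected
``2**n1`` cells and the transit pool to a fraction ``p`` of that; after
birth the populations are held approximately constant (all ``G`` and ``D``
zero) unless the intermediate-growth variant is enabled.  Mutation rates
derive from per-division probabilities ``u`` spread over the ``n2``
asymmetric divisions of a lifetime ``L_t``, optionally scaled ``d**alpha``
by a genomic-destabilization multiplier and incremented after a mutagen
onset age.

The probability of cancer by age ``L_t`` is obtained from the backward
Kolmogorov equations for the per-cell extinction probabilities
``q_(alpha,beta)(t)`` (no malignant descendant by ``L_t``), integrated
piecewise over the rate regimes; an exact event-driven (Gillespie)
simulator of the same process serves as an independent oracle on small
tissues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from ._numeric import safe_ratio

__all__ = [
    "MultistageConfig",
    "CompartmentRates",
    "ExtinctionSolution",
    "build_rates",
    "solve_extinction",
    "cancer_probability",
    "relative_risk",
    "monte_carlo_oracle",
    "mean_populations",
]


@dataclass(frozen=True)
class MultistageConfig:
    """Parameters of the branching model.

    Rates are per cell per year; ``u_stem``/``u_transit`` are per-gene
    per-division mutation probabilities converted internally to rates.
    ``d`` scales the mutation rate by ``d**alpha`` after alpha mutations.
    Mutagen increments ``du_*`` add to the per-division probabilities after
    ``onset_age`` (default one third of the lifetime).
    """

    n1: int
    n2: int
    k: int = 2
    u_stem: float = 1e-8
    u_transit: float = 1e-6
    du_stem: float = 0.0
    du_transit: float = 0.0
    onset_age: Optional[float] = None
    d: float = 1.0
    k_t: Optional[int] = None
    l_g: float = 0.728
    l_t: float = 80.0
    p: float = 0.01
    intermediate_growth: bool = False
    mutagen_on_stem_only: bool = False
    mutagen_on_transit_only: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.l_g < self.l_t:
            raise ValueError("need 0 < l_g < l_t")
        if self.p <= 0:
            raise ValueError("p must be positive")
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        kt = self.k if self.k_t is None else self.k_t
        if kt not in (self.k, self.k + 1):
            raise ValueError("k_t must be k or k + 1")
        for name in ("u_stem", "u_transit", "du_stem", "du_transit"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mutagen_on_stem_only and self.mutagen_on_transit_only:
            raise ValueError("at most one mutagen-compartment restriction")

    @property
    def kt(self) -> int:
        return self.k if self.k_t is None else self.k_t

    @property
    def effective_onset_age(self) -> float:
        return self.l_t / 3.0 if self.onset_age is None else self.onset_age

    def without_mutagen(self) -> "MultistageConfig":
        return replace(self, du_stem=0.0, du_transit=0.0)


# intermediate-compartment birth/death rates for the sensitivity variant,
# per cell per year (lung-cancer-mortality-derived values)
_INTERMEDIATE_G = 1.1
_INTERMEDIATE_D = 0.71


def _mutation_rate(u: float, n2: int, l_t: float) -> float:
    """Per-cell per-year asymmetric mutation rate from a per-division
    probability: u = 1 - exp(-M * L_t / n2)."""
    if not 0.0 <= u < 1.0:
        raise ValueError(f"per-division mutation probability out of [0, 1): {u!r}")
    if n2 == 0:
        return 0.0
    return -n2 * math.log1p(-u) / l_t


@dataclass(frozen=True)
class CompartmentRates:
    """Piecewise-constant per-cell rates over the life course.

    Arrays have shape (n_regimes, n_types); ``types[i]`` is the
    ``(alpha, beta)`` label of column i.  ``next_type[i]`` is the index a
    mutation leads to (-1 = malignant); ``trans_type[i]`` the transit
    counterpart seeded by an asymmetric stem division (-1 = none).
    ``breakpoints`` has length n_regimes + 1 and spans [0, L_t].
    """

    types: tuple
    breakpoints: tuple
    G: np.ndarray
    D: np.ndarray
    M: np.ndarray
    A: np.ndarray
    next_type: np.ndarray
    trans_type: np.ndarray

    @property
    def n_types(self) -> int:
        return len(self.types)

    def regime_of(self, t: float) -> int:
        """Index of the rate regime containing time t (right-continuous)."""
        idx = int(np.searchsorted(self.breakpoints, t, side="right") - 1)
        return min(max(idx, 0), len(self.breakpoints) - 2)


def build_rates(config: MultistageConfig) -> CompartmentRates:
    """Assemble the piecewise-constant rate tables for a configuration."""
    k, kt = config.k, config.kt
    types = [(a, 0) for a in range(k)] + [(a, 1) for a in range(kt)]
    n_types = len(types)
    stem_idx = {a: i for i, (a, b) in enumerate(types) if b == 0}
    transit_idx = {a: i for i, (a, b) in enumerate(types) if b == 1}

    next_type = np.full(n_types, -1, dtype=np.int64)
    trans_type = np.full(n_types, -1, dtype=np.int64)
    for i, (a, b) in enumerate(types):
        if b == 0:
            next_type[i] = stem_idx.get(a + 1, -1)
            trans_type[i] = transit_idx[a]
        else:
            next_type[i] = transit_idx.get(a + 1, -1)

    cuts = sorted({0.0, config.l_g, config.effective_onset_age, config.l_t})
    breakpoints = tuple(c for c in cuts if 0.0 <= c <= config.l_t)
    n_regimes = len(breakpoints) - 1

    g00 = math.log(2.0**config.n1) / config.l_g
    g01 = 1.0 + g00
    t_g = config.p * 2.0**config.n1
    # stem -> transit seeding rate chosen so the expected transit pool at the
    # end of gestation is t_g given the two exponential growth rates
    a00 = t_g * (g00 - g01) / (
        math.exp(g00 * config.l_g) - math.exp(g01 * config.l_g)
    )

    G = np.zeros((n_regimes, n_types))
    D = np.zeros((n_regimes, n_types))
    M = np.zeros((n_regimes, n_types))
    A = np.zeros((n_regimes, n_types))

    du_stem = 0.0 if config.mutagen_on_transit_only else config.du_stem
    du_transit = 0.0 if config.mutagen_on_stem_only else config.du_transit

    for r in range(n_regimes):
        t_mid = 0.5 * (breakpoints[r] + breakpoints[r + 1])
        gestation = t_mid < config.l_g
        mutagen_on = t_mid >= config.effective_onset_age
        for i, (a, b) in enumerate(types):
            u = config.u_stem if b == 0 else config.u_transit
            if mutagen_on:
                u = u + (du_stem if b == 0 else du_transit)
            M[r, i] = config.d**a * _mutation_rate(u, config.n2, config.l_t)
            if (a, b) == (0, 0):
                G[r, i] = g00 if gestation else 0.0
            elif (a, b) == (0, 1):
                G[r, i] = g01 if gestation else 0.0
            elif config.intermediate_growth:
                G[r, i] = _INTERMEDIATE_G
                D[r, i] = _INTERMEDIATE_D
            if b == 0 and gestation:
                A[r, i] = a00

    return CompartmentRates(
        types=tuple(types),
        breakpoints=breakpoints,
        G=G,
        D=D,
        M=M,
        A=A,
        next_type=next_type,
        trans_type=trans_type,
    )


@dataclass(frozen=True)
class ExtinctionSolution:
    """Extinction probabilities q_(alpha,beta)(t) on a time grid.

    ``q`` is the probability that one cell of the given type present at age
    t leaves no malignant descendant by L_t.  Internally the complement
    ``p = 1 - q`` is stored, which stays accurate down to ~1e-300.
    """

    types: tuple
    t_grid: np.ndarray
    p_grid: np.ndarray  # shape (n_times, n_types), p = 1 - q

    def q_at_birth(self) -> np.ndarray:
        return 1.0 - self.p_grid[0]

    def p_at_birth(self) -> np.ndarray:
        return self.p_grid[0]

    def q(self, type_index: int, t: float) -> float:
        return 1.0 - float(np.interp(t, self.t_grid, self.p_grid[:, type_index]))


def solve_extinction(
    rates: CompartmentRates,
    config: MultistageConfig,
    rtol: float = 1e-9,
    atol: float = 1e-30,
) -> ExtinctionSolution:
    """Integrate the backward Kolmogorov system for the extinction
    probabilities, piecewise over the rate regimes, from t = L_t back to 0.

    For each live type, with q_next = 0 at the malignant boundary,

        -dq/dt = G (q^2 - q) + D (1 - q) + M (q q_next - q) + A (q q_trans - q)

    The system is integrated for the complement p = 1 - q,

        -dp/dt = -[G (p^2 - p) + D p + M (p p_next - p_next) + A (p p_trans - p_trans)]

    with p(L_t) = 0, which avoids the catastrophic cancellation in 1 - q
    when the cancer probability is far below machine epsilon of 1.
    """
    n = rates.n_types
    nxt = rates.next_type
    trn = rates.trans_type

    def rhs(regime):
        G, D, M, A = rates.G[regime], rates.D[regime], rates.M[regime], rates.A[regime]

        def f(_s, p):
            # malignant boundary: p_next = 1 (a malignant cell is cancer)
            p_next = np.where(nxt >= 0, p[np.clip(nxt, 0, n - 1)], 1.0)
            p_trans = np.where(trn >= 0, p[np.clip(trn, 0, n - 1)], 0.0)
            # backward time s = L_t - t: dp/ds = -dp/dt
            return -(
                G * (p * p - p)
                + D * p
                + M * (p * p_next - p_next)
                + A * (p * p_trans - p_trans)
            )

        return f

    p = np.zeros(n)
    t_chunks = [np.array([config.l_t])]
    p_chunks = [p[None, :].copy()]
    bps = rates.breakpoints
    for regime in range(len(bps) - 2, -1, -1):
        s0 = config.l_t - bps[regime + 1]
        s1 = config.l_t - bps[regime]
        sol = solve_ivp(
            rhs(regime),
            (s0, s1),
            p,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"extinction ODE failed in regime {regime}: {sol.message}")
        p = sol.y[:, -1]
        s_eval = np.linspace(s0, s1, 33)[1:]
        t_chunks.append(config.l_t - s_eval)
        p_chunks.append(sol.sol(s_eval).T)

    t_all = np.concatenate(t_chunks)
    p_all = np.clip(np.concatenate(p_chunks, axis=0), 0.0, 1.0)
    order = np.argsort(t_all)
    return ExtinctionSolution(types=rates.types, t_grid=t_all[order], p_grid=p_all[order])


def cancer_probability(config: MultistageConfig) -> float:
    """Probability that a tissue founded by one stem cell at age 0 produces
    a malignant cell by the end of life."""
    rates = build_rates(config)
    sol = solve_extinction(rates, config)
    return float(sol.p_at_birth()[0])


def relative_risk(config: MultistageConfig) -> float:
    """Cancer probability with the mutagen increments versus without."""
    return safe_ratio(
        cancer_probability(config),
        cancer_probability(config.without_mutagen()),
    )


# ---------------------------------------------------------------------------
# exact stochastic (event-driven) oracle


_MAX_POPULATION = 1_000_000
_MAX_STEPS = 200_000


def _gillespie(
    config: MultistageConfig,
    n_runs: int,
    rng: np.random.Generator,
    t_end: Optional[float] = None,
):
    """Exact simulation of the multitype process, vectorized across runs.

    Rates are piecewise constant; sampled waiting times that would cross a
    regime boundary are discarded and the clock moved to the boundary,
    which is exact by memorylessness.  Returns (cancer flags, counts at
    t_end, times) where counts are the populations when each run stopped.
    """
    if config.n1 > 12:
        raise ValueError("Gillespie oracle restricted to n1 <= 12")
    rates = build_rates(config)
    horizon = config.l_t if t_end is None else t_end
    n_types = rates.n_types

    counts = np.zeros((n_runs, n_types), dtype=np.int64)
    counts[:, 0] = 1  # one unmutated stem cell at age 0
    t = np.zeros(n_runs)
    cancer = np.zeros(n_runs, dtype=bool)
    running = np.ones(n_runs, dtype=bool)

    # channel layout per type: 0=G, 1=D, 2=M, 3=A
    channel_rates = np.stack([rates.G, rates.D, rates.M, rates.A], axis=2)
    bps = np.asarray(rates.breakpoints)

    for _step in range(_MAX_STEPS):
        idx = np.nonzero(running)[0]
        if idx.size == 0:
            break
        regime = np.clip(np.searchsorted(bps, t[idx], side="right") - 1, 0, len(bps) - 2)
        regime_end = np.minimum(bps[regime + 1], horizon)
        per_cell = channel_rates[regime]  # (m, n_types, 4)
        weights = counts[idx][:, :, None] * per_cell
        total = weights.sum(axis=(1, 2))

        # runs with no possible event coast to the end of the regime
        dead = total <= 0.0
        if dead.any():
            sel = idx[dead]
            t[sel] = regime_end[dead]
            running[sel] &= t[sel] < horizon

        alive = ~dead
        if not alive.any():
            continue
        sel = idx[alive]
        wait = rng.exponential(size=sel.size) / total[alive]
        t_next = t[sel] + wait
        crossed = t_next >= regime_end[alive]
        # crossing runs move to the boundary without an event
        t[sel[crossed]] = regime_end[alive][crossed]
        running[sel[crossed]] &= t[sel[crossed]] < horizon

        hit = sel[~crossed]
        if hit.size == 0:
            continue
        t[hit] = t_next[~crossed]
        w = weights[alive][~crossed].reshape(hit.size, -1)
        cum = np.cumsum(w, axis=1)
        u = rng.random(hit.size) * cum[:, -1]
        event = (cum < u[:, None]).sum(axis=1)
        etype, channel = np.divmod(event, 4)

        for ch, delta_self in ((0, 1), (1, -1)):
            m = channel == ch
            if m.any():
                np.add.at(counts, (hit[m], etype[m]), delta_self)
        m = channel == 2  # mutation: parent persists, further-mutated child
        if m.any():
            tgt = rates.next_type[etype[m]]
            malignant = tgt < 0
            runs_m = hit[m]
            if malignant.any():
                cancer[runs_m[malignant]] = True
                running[runs_m[malignant]] = False
            ok = ~malignant
            if ok.any():
                np.add.at(counts, (runs_m[ok], tgt[ok]), 1)
        m = channel == 3  # stem seeds a transit cell of the same stage
        if m.any():
            tgt = rates.trans_type[etype[m]]
            np.add.at(counts, (hit[m], tgt), 1)

        if counts.max() > _MAX_POPULATION:
            raise RuntimeError("population exceeded Gillespie guard")
    else:
        raise RuntimeError("Gillespie oracle exceeded the step guard")

    return cancer, counts, t


def monte_carlo_oracle(
    config: MultistageConfig, n_runs: int, seed: int
) -> tuple[float, float]:
    """Fraction of exact-simulation runs producing a malignant cell by L_t,
    with its binomial standard error."""
    rng = np.random.default_rng(seed)
    cancer, _, _ = _gillespie(config, n_runs, rng)
    p = cancer.mean()
    return float(p), math.sqrt(p * (1.0 - p) / n_runs)


def mean_populations(
    config: MultistageConfig, n_runs: int, seed: int, at_age: Optional[float] = None
) -> dict:
    """Mean cell counts per (alpha, beta) type at a given age (default: end
    of gestation), from the exact simulator."""
    age = config.l_g if at_age is None else at_age
    rng = np.random.default_rng(seed)
    _, counts, _ = _gillespie(config, n_runs, rng, t_end=age)
    rates = build_rates(config)
    means = counts.mean(axis=0)
    return {rates.types[i]: float(means[i]) for i in range(rates.n_types)}
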