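"""Monte-Carlo simulator of a stem/transit-amplifying tissue.

A tissue is founded by a single stem cell.  At each of the first ``n1``
synchronous cycles the stem cell divides asymmetrically into a daughter
stem cell and the root of a new transit-amplifying lineage; every transit
cell then divides symmetrically for ``n2`` further cycles, so a completed
tissue holds ``n1 * 2**n2`` transit cells plus the single stem cell.  At
every division each not-yet-mutated driver gene in each daughter is tested
independently: it mutates spontaneously (stem rate ``u_ss``, transit rate
``u_st``) or through a specified mutagen (``u_ms``, ``u_mt``); mutagen
rates are zero up to an onset cycle (by default the first third of the
``n1 + n2`` cycles) and constant afterwards.  Mutations are irreversible
and re-hits are ignored, so a cell's state is the four-way count of its
mutations by source (spontaneous/mutagen) and lineage of acquisition
(stem/transit).

The first cell to accumulate ``k`` driver mutations labels the cancer; from
its state the simulator classifies the cancer as mutagen-associated
(>= 1 mutagen mutation), wholly stem-derived, or partly stem-derived, and
estimates the corresponding probabilities, conditional probabilities and
the relative risk versus a mutagen-free tissue.

Cells are aggregated into (mutation-state, lineage-age) classes, so the
per-cycle cost is proportional to the number of occupied classes rather
than the number of cells; mutation events are sampled with a rare-event
binomial/multinomial scheme vectorized across replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._numeric import safe_ratio

__all__ = [
    "FrankConfig",
    "FrankRates",
    "CellState",
    "TissueOutcome",
    "RiskSummary",
    "run_single_tissue",
    "estimate",
    "relative_risk",
    "enumerate_exact_small",
]


@dataclass(frozen=True)
class FrankConfig:
    """Tissue geometry, mutation threshold and Monte-Carlo settings."""

    n1: int
    n2: int
    k: int
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("division counts must be non-negative")
        if not 1 <= self.k <= 7:
            raise ValueError("k must be in 1..7")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def n_cycles(self) -> int:
        return self.n1 + self.n2

    @property
    def n_cells(self) -> int:
        """Cells in a completed cancer-free tissue (transit cells + 1 stem)."""
        return self.n1 * 2**self.n2 + 1

    def default_onset_cycle(self) -> int:
        """Last mutagen-free cycle: exposure starts at cycle
        floor((n1 + n2) / 3), matching the boundary placement of the exact
        recurrence's rate schedule."""
        return max(math.floor(self.n_cycles / 3) - 1, 0)


@dataclass(frozen=True)
class FrankRates:
    """Per-gene per-division mutation probabilities.

    ``u_ss``/``u_ms``: spontaneous and mutagen rates for stem daughters;
    ``u_st``/``u_mt``: the same for transit cells (including the transit
    root created at an asymmetric division).  ``onset_cycle`` is the last
    cycle at which mutagen rates are still zero; ``None`` means the default
    floor((n1 + n2) / 3).
    """

    u_ss: float
    u_ms: float = 0.0
    u_st: float = 0.0
    u_mt: float = 0.0
    onset_cycle: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("u_ss", "u_ms", "u_st", "u_mt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v!r}")
        if self.u_ss + self.u_ms > 1.0 or self.u_st + self.u_mt > 1.0:
            raise ValueError("per-gene rates must satisfy u_S + u_M <= 1")

    def without_mutagen(self) -> "FrankRates":
        return FrankRates(self.u_ss, 0.0, self.u_st, 0.0, self.onset_cycle)


@dataclass(frozen=True)
class CellState:
    """Driver mutations of one cell, partitioned by source and lineage."""

    s_stem: int = 0
    m_stem: int = 0
    s_transit: int = 0
    m_transit: int = 0

    @property
    def total(self) -> int:
        return self.s_stem + self.m_stem + self.s_transit + self.m_transit

    @property
    def mutagen_involved(self) -> bool:
        return self.m_stem + self.m_transit >= 1

    @property
    def all_stem(self) -> bool:
        return self.s_transit == 0 and self.m_transit == 0

    @property
    def some_stem(self) -> bool:
        return self.s_stem + self.m_stem >= 1


@dataclass(frozen=True)
class TissueOutcome:
    """Result of one simulated tissue."""

    cancer: bool
    mutagen_involved: Optional[bool] = None
    all_stem: Optional[bool] = None
    some_stem: Optional[bool] = None
    cycle: Optional[int] = None


@dataclass(frozen=True)
class RiskSummary:
    """Cancer probabilities, conditional classification and relative risk.

    Conditional ratios are NaN ("NA") when their denominator estimate is 0.
    Standard errors are binomial (NaN for exact enumeration results).
    """

    c_tot: float
    c_mut: float
    c_stem_tot: float
    c_stem_part: float
    pr_m: float
    pr_stem_tot: float
    pr_stem_part: float
    n_samples: int
    se_c_tot: float = float("nan")
    se_c_mut: float = float("nan")
    se_c_stem_tot: float = float("nan")
    se_c_stem_part: float = float("nan")
    c_tot_baseline: Optional[float] = None
    rr_m: Optional[float] = None
    se_rr_m: Optional[float] = None


# ---------------------------------------------------------------------------
# vectorized class-count simulation


def _enumerate_states(k: int):
    """All live mutation-state 4-tuples (total < k), plus an index map."""
    states = []
    for ss in range(k):
        for ms in range(k - ss):
            for st in range(k - ss - ms):
                for mt in range(k - ss - ms - st):
                    states.append((ss, ms, st, mt))
    index = {s: i for i, s in enumerate(states)}
    return states, index


def _daughter_kernel(remaining: int, u_s: float, u_m: float):
    """Rare-event kernel for one daughter with ``remaining`` unmutated genes.

    Returns (p_any, outcomes, cond) where p_any is the probability the
    daughter acquires >= 1 new mutation, outcomes lists the possible
    (new spontaneous, new mutagen) pairs, and cond their probabilities
    conditional on at least one mutation.
    """
    u_0 = 1.0 - u_s - u_m
    p_none = u_0**remaining
    outcomes = []
    probs = []
    for a in range(remaining + 1):
        for b in range(remaining - a + 1):
            if a + b == 0:
                continue
            coeff = math.factorial(remaining) / (
                math.factorial(a) * math.factorial(b) * math.factorial(remaining - a - b)
            )
            p = coeff * u_s**a * u_m**b * u_0 ** (remaining - a - b)
            if p > 0.0:
                outcomes.append((a, b))
                probs.append(p)
    p_any = 1.0 - p_none
    if p_any <= 0.0 or not outcomes:
        return 0.0, [], np.zeros(0)
    cond = np.asarray(probs) / sum(probs)
    return p_any, outcomes, cond


class _SimState:
    """Mutable per-replicate bookkeeping for one vectorized run."""

    def __init__(self, n_reps: int, n_live: int, n2: int):
        self.counts = np.zeros((n_reps, n_live, n2 + 1), dtype=np.int64)
        self.stem = np.zeros(n_reps, dtype=np.int64)
        self.active = np.ones(n_reps, dtype=bool)
        self.cancer = np.zeros(n_reps, dtype=bool)
        self.mutagen = np.zeros(n_reps, dtype=bool)
        self.all_stem = np.zeros(n_reps, dtype=bool)
        self.some_stem = np.zeros(n_reps, dtype=bool)
        self.cycle = np.full(n_reps, -1, dtype=np.int64)


def _simulate(
    config: FrankConfig,
    rates: FrankRates,
    rng: np.random.Generator,
    n_reps: int,
    collect_population: bool = False,
):
    """Run ``n_reps`` tissues synchronously; returns a _SimState.

    If ``collect_population`` is set, also returns the final cell count per
    replicate (cancer-free replicates only carry a meaningful value).
    """
    k, n1, n2 = config.k, config.n1, config.n2
    onset = rates.onset_cycle if rates.onset_cycle is not None else config.default_onset_cycle()
    if not 0 <= onset <= config.n_cycles:
        raise ValueError("onset_cycle out of range")
    states, index = _enumerate_states(k)
    sim = _SimState(n_reps, len(states), n2)
    kernels: dict = {}

    def kernel(remaining: int, u_s: float, u_m: float):
        key = (remaining, u_s, u_m)
        if key not in kernels:
            kernels[key] = _daughter_kernel(remaining, u_s, u_m)
        return kernels[key]

    for cycle in range(1, config.n_cycles + 1):
        if not sim.active.any():
            break
        mutagen_on = cycle > onset
        u_ms = rates.u_ms if mutagen_on else 0.0
        u_mt = rates.u_mt if mutagen_on else 0.0

        new_counts = np.zeros_like(sim.counts)
        new_counts[:, :, n2] = sim.counts[:, :, n2]  # fully divided cells persist
        hits: dict[tuple[int, int, int, int], np.ndarray] = {}

        def add_hits(cls, cnt):
            if cls in hits:
                hits[cls] += cnt
            else:
                hits[cls] = cnt.astype(np.int64).copy()

        # symmetric transit divisions (all lineages younger than n2 divisions)
        occupied = np.nonzero(sim.counts.any(axis=0))
        for si, age in zip(*occupied):
            if age == n2:
                continue
            ss, ms, st, mt = states[si]
            remaining = k - (ss + ms + st + mt)
            n = sim.counts[:, si, age]
            daughters = 2 * n
            p_any, outcomes, cond = kernel(remaining, rates.u_st, u_mt)
            if p_any == 0.0:
                new_counts[:, si, age + 1] += daughters
                continue
            affected = rng.binomial(daughters, p_any)
            new_counts[:, si, age + 1] += daughters - affected
            if affected.any():
                draws = rng.multinomial(affected, cond)
                for o, (a, b) in enumerate(outcomes):
                    cnt = draws[:, o]
                    if not cnt.any():
                        continue
                    child = (ss, ms, st + a, mt + b)
                    if sum(child) == k:
                        add_hits(child, cnt)
                    else:
                        new_counts[:, index[child], age + 1] += cnt

        # asymmetric stem division: daughter stem + new transit-lineage root
        if cycle <= n1:
            new_stem = sim.stem.copy()
            for si in np.unique(sim.stem[sim.active]):
                mask = sim.active & (sim.stem == si)
                reps = np.nonzero(mask)[0]
                ss, ms, st, mt = states[si]
                remaining = k - (ss + ms + st + mt)
                for which in ("stem", "transit"):
                    if which == "stem":
                        p_any, outcomes, cond = kernel(remaining, rates.u_ss, u_ms)
                    else:
                        p_any, outcomes, cond = kernel(remaining, rates.u_st, u_mt)
                    if p_any == 0.0:
                        if which == "transit":
                            new_counts[reps, si, 0] += 1
                        continue
                    edges = np.concatenate([[1.0 - p_any], p_any * cond]).cumsum()
                    pick = np.searchsorted(edges, rng.random(reps.size), side="right")
                    for o, (a, b) in enumerate(outcomes):
                        sel = reps[pick == o + 1]
                        if sel.size == 0:
                            continue
                        child = (
                            (ss + a, ms + b, st, mt)
                            if which == "stem"
                            else (ss, ms, st + a, mt + b)
                        )
                        if sum(child) == k:
                            one = np.zeros(n_reps, dtype=np.int64)
                            one[sel] = 1
                            add_hits(child, one)
                        elif which == "stem":
                            new_stem[sel] = index[child]
                        else:
                            new_counts[sel, index[child], 0] += 1
                    if which == "stem":
                        unchanged = reps[pick == 0]
                        new_stem[unchanged] = si  # explicit no-op for clarity
                    else:
                        none_sel = reps[pick == 0]
                        new_counts[none_sel, si, 0] += 1
            sim.stem = new_stem

        # resolve cancers: label one cell uniformly among first arrivals
        if hits:
            classes = list(hits)
            table = np.stack([hits[c] for c in classes], axis=1)
            totals = table.sum(axis=1)
            for rep in np.nonzero((totals > 0) & sim.active)[0]:
                weights = table[rep].astype(float)
                pick = rng.choice(len(classes), p=weights / weights.sum())
                cell = CellState(*classes[pick])
                sim.cancer[rep] = True
                sim.mutagen[rep] = cell.mutagen_involved
                sim.all_stem[rep] = cell.all_stem
                sim.some_stem[rep] = cell.some_stem
                sim.cycle[rep] = cycle
                sim.active[rep] = False
                new_counts[rep] = 0

        sim.counts = new_counts

    if collect_population:
        population = sim.counts.sum(axis=(1, 2)) + 1  # + the stem cell
        return sim, population
    return sim


def run_single_tissue(
    config: FrankConfig, rates: FrankRates, rng: np.random.Generator
) -> TissueOutcome:
    """Simulate one tissue and report whether/how cancer arose."""
    sim = _simulate(config, rates, rng, n_reps=1)
    if not sim.cancer[0]:
        return TissueOutcome(cancer=False)
    return TissueOutcome(
        cancer=True,
        mutagen_involved=bool(sim.mutagen[0]),
        all_stem=bool(sim.all_stem[0]),
        some_stem=bool(sim.some_stem[0]),
        cycle=int(sim.cycle[0]),
    )


def _binomial_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n)


def _summarize(sim: _SimState, n: int) -> RiskSummary:
    c_tot = sim.cancer.mean()
    c_mut = (sim.cancer & sim.mutagen).mean()
    c_stem_tot = (sim.cancer & sim.all_stem).mean()
    c_stem_part = (sim.cancer & sim.some_stem).mean()
    return RiskSummary(
        c_tot=c_tot,
        c_mut=c_mut,
        c_stem_tot=c_stem_tot,
        c_stem_part=c_stem_part,
        pr_m=safe_ratio(c_mut, c_tot),
        pr_stem_tot=safe_ratio(c_stem_tot, c_tot),
        pr_stem_part=safe_ratio(c_stem_part, c_tot),
        n_samples=n,
        se_c_tot=_binomial_se(c_tot, n),
        se_c_mut=_binomial_se(c_mut, n),
        se_c_stem_tot=_binomial_se(c_stem_tot, n),
        se_c_stem_part=_binomial_se(c_stem_part, n),
    )


def estimate(
    config: FrankConfig,
    rates: FrankRates,
    rng: Optional[np.random.Generator] = None,
) -> RiskSummary:
    """Monte-Carlo estimates of the cancer probabilities over n_samples tissues."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sim = _simulate(config, rates, rng, config.n_samples)
    return _summarize(sim, config.n_samples)


def relative_risk(config: FrankConfig, rates: FrankRates) -> RiskSummary:
    """Mutagen-exposed versus baseline tissue, on independent seed streams."""
    child_a, child_b = np.random.SeedSequence(config.seed).spawn(2)
    exposed = estimate(config, rates, np.random.default_rng(child_a))
    baseline = estimate(config, rates.without_mutagen(), np.random.default_rng(child_b))
    rr = safe_ratio(exposed.c_tot, baseline.c_tot)
    if math.isnan(rr) or exposed.c_tot == 0.0:
        se_rr = float("nan")
    else:
        se_rr = rr * math.sqrt(
            (exposed.se_c_tot / exposed.c_tot) ** 2
            + (baseline.se_c_tot / baseline.c_tot) ** 2
        )
    return RiskSummary(
        c_tot=exposed.c_tot,
        c_mut=exposed.c_mut,
        c_stem_tot=exposed.c_stem_tot,
        c_stem_part=exposed.c_stem_part,
        pr_m=exposed.pr_m,
        pr_stem_tot=exposed.pr_stem_tot,
        pr_stem_part=exposed.pr_stem_part,
        n_samples=config.n_samples,
        se_c_tot=exposed.se_c_tot,
        se_c_mut=exposed.se_c_mut,
        se_c_stem_tot=exposed.se_c_stem_tot,
        se_c_stem_part=exposed.se_c_stem_part,
        c_tot_baseline=baseline.c_tot,
        rr_m=rr,
        se_rr_m=se_rr,
    )


# ---------------------------------------------------------------------------
# exact enumeration oracle for tiny tissues


def _total_daughter_tests(n1: int, n2: int) -> int:
    # per cycle <= n1: daughter stem + transit root; per lineage: 2 + 4 + ...
    return 2 * n1 + n1 * (2 ** (n2 + 1) - 2)


def enumerate_exact_small(config: FrankConfig, rates: FrankRates) -> RiskSummary:
    """Exact outcome probabilities by enumerating every daughter's mutations.

    Walks the full tree of per-daughter (spontaneous, mutagen) outcomes
    cycle by cycle, so the cost grows as a product over tested daughters;
    only tiny tissues are accepted (at most 16 daughter tests and k <= 2,
    e.g. n1 <= 2 with n2 <= 1).  Intended as an independent oracle for the
    Monte-Carlo simulator.
    """
    k, n1, n2 = config.k, config.n1, config.n2
    if k > 2 or _total_daughter_tests(n1, n2) > 16:
        raise ValueError("tissue too large for exact enumeration")
    onset = rates.onset_cycle if rates.onset_cycle is not None else config.default_onset_cycle()

    acc = {"c_tot": 0.0, "c_mut": 0.0, "c_stem_tot": 0.0, "c_stem_part": 0.0}

    def outcome_dist(state, u_s, u_m):
        remaining = k - sum(state)
        p_any, outcomes, cond = _daughter_kernel(remaining, u_s, u_m)
        dist = [((0, 0), 1.0 - p_any)] if p_any < 1.0 else []
        dist += [(o, p_any * c) for o, c in zip(outcomes, cond)]
        return dist

    def settle(hit_classes, prob):
        total = sum(n for _, n in hit_classes)
        for cls, n in hit_classes:
            w = prob * n / total
            cell = CellState(*cls)
            acc["c_tot"] += w
            if cell.mutagen_involved:
                acc["c_mut"] += w
            if cell.all_stem:
                acc["c_stem_tot"] += w
            if cell.some_stem:
                acc["c_stem_part"] += w

    def run_cycle(cycle, stem_state, transits, prob):
        if cycle > config.n_cycles or prob == 0.0:
            return
        mutagen_on = cycle > onset
        u_ms = rates.u_ms if mutagen_on else 0.0
        u_mt = rates.u_mt if mutagen_on else 0.0

        # tests: (parent_state, lineage_channel, next_age or None for stem daughter)
        tests = []
        if cycle <= n1:
            tests.append((stem_state, "stem", None))
            tests.append((stem_state, "transit", 0))
        for state, age in transits:
            if age < n2:
                tests.append((state, "transit", age + 1))
                tests.append((state, "transit", age + 1))
        survivors = [(s, a) for s, a in transits if a == n2]

        def rec(i, new_stem, new_transits, hit_classes, p):
            if i == len(tests):
                if hit_classes:
                    settle(hit_classes, p)
                elif cycle == config.n_cycles:
                    pass  # tissue completed without cancer
                else:
                    run_cycle(cycle + 1, new_stem, new_transits, p)
                return
            state, channel, age = tests[i]
            us, um = (rates.u_ss, u_ms) if channel == "stem" else (rates.u_st, u_mt)
            for (a, b), q in outcome_dist(state, us, um):
                if channel == "stem":
                    child = (state[0] + a, state[1] + b, state[2], state[3])
                else:
                    child = (state[0], state[1], state[2] + a, state[3] + b)
                if sum(child) == k:
                    rec(i + 1, new_stem if channel != "stem" else child,
                        new_transits, hit_classes + [(child, 1)], p * q)
                elif channel == "stem":
                    rec(i + 1, child, new_transits, hit_classes, p * q)
                else:
                    rec(i + 1, new_stem, new_transits + [(child, age)],
                        hit_classes, p * q)

        rec(0, stem_state, survivors, [], prob)

    run_cycle(1, (0, 0, 0, 0), [], 1.0)

    c_tot = acc["c_tot"]
    return RiskSummary(
        c_tot=c_tot,
        c_mut=acc["c_mut"],
        c_stem_tot=acc["c_stem_tot"],
        c_stem_part=acc["c_stem_part"],
        pr_m=safe_ratio(acc["c_mut"], c_tot),
        pr_stem_tot=safe_ratio(acc["c_stem_tot"], c_tot),
        pr_stem_part=safe_ratio(acc["c_stem_part"], c_tot),
        n_samples=0,
    )
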