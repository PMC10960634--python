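"""Sequence-property-informed null simulation of motif libraries.

Each motif is re-placed uniformly over all genome positions that can hold
it, preserving its exact length and, optionally, its guanine content within
a dynamically escalating tolerance: candidate placements are drawn and
rejected until one lands within ``tolerance`` of the template %G; after
``attempts_per_level`` consecutive rejections the tolerance widens by
``step``. Escalation is capped at ``max_tolerance`` (default 1.0, i.e. no
constraint), so the search always terminates; motifs that had to escalate
all the way are flagged in the simulation report.

Rejected-but-placeable candidates are cached in a :class:`SimulationPool`
keyed by (length, %G bin) and consumed by later motifs or replicates with
compatible traits, which amortises the search cost across a library.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Genome, GenomicInterval, MotifLibrary

__all__ = [
    "SimulatedMotif",
    "SimulationConfig",
    "SimulationPool",
    "SimulationResult",
    "ToleranceSchedule",
    "gc_mode_count",
    "simulate_library",
    "simulate_motif",
]

_BATCH = 128  # candidates evaluated per vectorised draw
_STREAM_SALT = 271_828  # namespaces this module's rng streams (see seed docs)


@dataclass(frozen=True)
class ToleranceSchedule:
    """Dynamic-tolerance hyper-parameters.

    ``start`` is the initial allowed |%G(simulated) - %G(template)|;
    ``step`` is added after every ``attempts_per_level`` consecutive
    rejections, up to ``max_tolerance``. Small start/step values buy
    fidelity at the price of more candidate draws.
    """

    start: float = 0.02
    step: float = 0.02
    attempts_per_level: int = 100
    max_tolerance: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.start <= self.max_tolerance <= 1.0):
            raise ValueError("require 0 <= start <= max_tolerance <= 1")
        if not (0.0 < self.step <= 1.0):
            raise ValueError("step must be in (0, 1]")
        if self.attempts_per_level < 1:
            raise ValueError("attempts_per_level must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """What to preserve and how many replicates to draw."""

    n_replicates: int = 100
    match_g_content: bool = True
    within_chromosome: bool = False
    seed: int = 0
    max_non_acgt_fraction: float = 0.1
    use_pool: bool = True
    composition: str = "G"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not (0.0 <= self.max_non_acgt_fraction <= 1.0):
            raise ValueError("max_non_acgt_fraction must be in [0, 1]")


class SimulationPool:
    """Cache of placeable candidates keyed by (length, %G bin).

    Entries are consumed without replacement, so a pooled placement is never
    issued twice within a run; per-key storage is capped to bound memory.
    Hit/miss/deposit counters support efficiency diagnostics.
    """

    def __init__(self, bin_width: float, max_per_key: int = 128):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.bin_width = float(bin_width)
        self.max_per_key = int(max_per_key)
        self.entries: dict[tuple[int, int], list[tuple[str, int, float]]] = {}
        self.hits = 0
        self.misses = 0
        self.deposits = 0

    def _bin(self, g: float) -> int:
        return min(int(g / self.bin_width), int(1.0 / self.bin_width))

    def put(self, length: int, chrom: str, start: int, g: float) -> None:
        key = (int(length), self._bin(g))
        bucket = self.entries.setdefault(key, [])
        if len(bucket) < self.max_per_key:
            bucket.append((chrom, start, float(g)))
            self.deposits += 1

    def take(
        self,
        length: int,
        g_target: float,
        tolerance: float,
        chrom: str | None = None,
    ) -> tuple[str, int, float] | None:
        """Pop a cached candidate with matching length and %G within tolerance."""
        lo = self._bin(max(0.0, g_target - tolerance))
        hi = self._bin(min(1.0, g_target + tolerance))
        for b in range(lo, hi + 1):
            bucket = self.entries.get((int(length), b))
            if not bucket:
                continue
            for i in range(len(bucket) - 1, -1, -1):
                c, s, g = bucket[i]
                if abs(g - g_target) <= tolerance + 1e-12 and (
                    chrom is None or c == chrom
                ):
                    bucket.pop(i)
                    self.hits += 1
                    return c, s, g
        self.misses += 1
        return None


class _PlacementDomain:
    """Uniform sampler over every valid start position for one motif length."""

    def __init__(self, genome: Genome, length: int, chroms: Sequence[str] | None):
        self.length = int(length)
        names = list(chroms) if chroms is not None else genome.names
        valid = np.array(
            [max(genome.length(c) - self.length + 1, 0) for c in names],
            dtype=np.int64,
        )
        self.names = names
        self.cum = np.concatenate([[0], np.cumsum(valid)])
        self.total = int(self.cum[-1])
        if self.total == 0:
            where = "its chromosome" if chroms is not None else "any chromosome"
            raise ValueError(
                f"no valid placement: motif of length {length} does not fit "
                f"{where}"
            )

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        u = rng.integers(0, self.total, size=n)
        ci = np.searchsorted(self.cum, u, side="right") - 1
        return ci, u - self.cum[ci]


@dataclass(frozen=True)
class SimulatedMotif:
    """One simulated placement plus provenance of the search."""

    interval: GenomicInterval
    final_tolerance: float
    flagged: bool
    n_fresh_draws: int
    from_pool: bool
    simulated_g: float = math.nan


def _candidate_traits(
    genome: Genome,
    domain: _PlacementDomain,
    ci: np.ndarray,
    starts: np.ndarray,
    kind: str,
) -> tuple[np.ndarray, np.ndarray]:
    g = np.empty(ci.size, dtype=float)
    bad = np.empty(ci.size, dtype=float)
    for c in np.unique(ci):
        m = ci == c
        name = domain.names[int(c)]
        g[m] = genome.fractions(name, starts[m], domain.length, kind)
        bad[m] = genome.fractions(name, starts[m], domain.length, "bad")
    return g, bad


def simulate_motif(
    genome: Genome,
    template: GenomicInterval,
    schedule: ToleranceSchedule | None = None,
    pool: SimulationPool | None = None,
    rng: np.random.Generator | None = None,
    config: SimulationConfig | None = None,
    _domain: _PlacementDomain | None = None,
) -> SimulatedMotif:
    """Re-place one motif, preserving length and (optionally) %G.

    Returns the placement, the final tolerance reached by the dynamic
    search, and whether the motif had to be accepted at ``max_tolerance``
    (flagged). In length-only mode the first in-bounds candidate is
    accepted. Never loops forever: tolerance escalation is capped and, once
    the cap is exhausted, any in-bounds candidate is accepted and flagged.
    """
    schedule = schedule or ToleranceSchedule()
    config = config or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    length = template.length
    restrict = [template.chrom] if config.within_chromosome else None
    domain = _domain or _PlacementDomain(genome, length, restrict)

    if not config.match_g_content:
        ci, st = domain.sample(rng, 1)
        chrom = domain.names[int(ci[0])]
        start = int(st[0])
        return SimulatedMotif(
            GenomicInterval(chrom, start, start + length, name=template.name),
            final_tolerance=0.0,
            flagged=False,
            n_fresh_draws=1,
            from_pool=False,
        )

    target = float(
        genome.fractions(template.chrom, [template.start], length, config.composition)[0]
    )
    tol = min(schedule.start, schedule.max_tolerance)
    fresh = 0
    while True:
        if pool is not None:
            got = pool.take(
                length, target, tol,
                chrom=template.chrom if config.within_chromosome else None,
            )
            if got is not None:
                chrom, start, g = got
                return SimulatedMotif(
                    GenomicInterval(chrom, start, start + length, name=template.name),
                    final_tolerance=tol,
                    flagged=tol >= schedule.max_tolerance - 1e-12,
                    n_fresh_draws=fresh,
                    from_pool=True,
                    simulated_g=g,
                )
        attempts = 0
        while attempts < schedule.attempts_per_level:
            nb = min(_BATCH, schedule.attempts_per_level - attempts)
            ci, st = domain.sample(rng, nb)
            g, bad = _candidate_traits(genome, domain, ci, st, config.composition)
            ok = bad <= config.max_non_acgt_fraction + 1e-12
            hit = ok & (np.abs(g - target) <= tol + 1e-12)
            if hit.any():
                i = int(np.argmax(hit))
                fresh += i + 1
                if pool is not None:
                    for j in np.nonzero(ok & ~hit)[0]:
                        pool.put(length, domain.names[int(ci[j])], int(st[j]), g[j])
                chrom = domain.names[int(ci[i])]
                start = int(st[i])
                return SimulatedMotif(
                    GenomicInterval(chrom, start, start + length, name=template.name),
                    final_tolerance=tol,
                    flagged=tol >= schedule.max_tolerance - 1e-12,
                    n_fresh_draws=fresh,
                    from_pool=False,
                    simulated_g=float(g[i]),
                )
            fresh += nb
            attempts += nb
            if pool is not None:
                for j in np.nonzero(ok)[0]:
                    pool.put(length, domain.names[int(ci[j])], int(st[j]), g[j])
        if tol >= schedule.max_tolerance - 1e-12:
            # Even unconstrained %G found nothing (everything failed the
            # non-ACGT filter): accept any in-bounds candidate, flagged.
            ci, st = domain.sample(rng, 1)
            g, _ = _candidate_traits(genome, domain, ci, st, config.composition)
            chrom = domain.names[int(ci[0])]
            start = int(st[0])
            return SimulatedMotif(
                GenomicInterval(chrom, start, start + length, name=template.name),
                final_tolerance=schedule.max_tolerance,
                flagged=True,
                n_fresh_draws=fresh + 1,
                from_pool=False,
                simulated_g=float(g[0]),
            )
        tol = min(tol + schedule.step, schedule.max_tolerance)


@dataclass
class SimulationResult:
    """Replicate libraries plus a per-motif simulation report.

    ``report`` columns: replicate, motif, chrom, start, end, length,
    template_g, simulated_g, final_tolerance, flagged, from_pool,
    fresh_draws.
    """

    replicates: list[MotifLibrary]
    report: pd.DataFrame
    pool: SimulationPool | None = None

    @property
    def n_flagged(self) -> int:
        return int(self.report["flagged"].sum())

    @property
    def total_fresh_draws(self) -> int:
        return int(self.report["fresh_draws"].sum())

    def tolerance_summary(self) -> dict[str, float]:
        tol = self.report["final_tolerance"]
        return {
            "mean_final_tolerance": float(tol.mean()),
            "max_final_tolerance": float(tol.max()),
            "fraction_flagged": float(self.report["flagged"].mean()),
        }


def simulate_library(
    genome: Genome,
    library: MotifLibrary,
    schedule: ToleranceSchedule | None = None,
    config: SimulationConfig | None = None,
) -> SimulationResult:
    """Draw ``config.n_replicates`` simulated counterparts of a library.

    Motif i of every replicate has exactly the length of motif i of the
    input. Replicate r uses the random stream seeded by (seed, r); in
    length-only mode placements are drawn in a single vectorised pass per
    replicate, so each replicate is independently reproducible from its
    (seed, index) pair. In %G-matched mode the simulation pool is shared
    across replicates (cache state carries forward), and the run as a whole
    is deterministic from the seed.
    """
    schedule = schedule or ToleranceSchedule()
    config = config or SimulationConfig()
    n = library.count
    if n == 0:
        raise ValueError("cannot simulate an empty library")
    lens = library.lengths
    restrict_per_motif = config.within_chromosome

    domains: dict[tuple[str | None, int], _PlacementDomain] = {}

    def get_domain(chrom: str | None, length: int) -> _PlacementDomain:
        key = (chrom, length)
        d = domains.get(key)
        if d is None:
            d = _PlacementDomain(genome, length, [chrom] if chrom else None)
            domains[key] = d
        return d

    replicates: list[MotifLibrary] = []
    rep_col: list[np.ndarray] = []
    motif_col: list[np.ndarray] = []
    chrom_col: list[np.ndarray] = []
    start_col: list[np.ndarray] = []
    tol_col: list[np.ndarray] = []
    flag_col: list[np.ndarray] = []
    g_col: list[np.ndarray] = []
    tg_col: list[np.ndarray] = []
    pool_col: list[np.ndarray] = []
    draws_col: list[np.ndarray] = []

    if not config.match_g_content:
        # Vectorised length-only path: group motifs sharing a placement domain.
        groups: dict[tuple[str | None, int], list[int]] = {}
        for i in range(n):
            key = (str(library.chroms[i]) if restrict_per_motif else None, int(lens[i]))
            groups.setdefault(key, []).append(i)
        template_g = np.full(n, np.nan)
        for rep in range(config.n_replicates):
            rng = np.random.default_rng([config.seed, _STREAM_SALT, rep])
            out_chrom = np.empty(n, dtype=object)
            out_start = np.empty(n, dtype=np.int64)
            for (chrom, length), idx in groups.items():
                d = get_domain(chrom, length)
                ci, st = d.sample(rng, len(idx))
                out_chrom[idx] = [d.names[int(c)] for c in ci]
                out_start[idx] = st
            replicates.append(
                MotifLibrary.from_arrays(
                    out_chrom, out_start, out_start + lens,
                    names=list(library.names), subtypes=list(library.subtypes),
                    genome=genome,
                )
            )
            rep_col.append(np.full(n, rep))
            motif_col.append(np.arange(n))
            chrom_col.append(out_chrom)
            start_col.append(out_start)
            tol_col.append(np.zeros(n))
            flag_col.append(np.zeros(n, dtype=bool))
            g_col.append(np.full(n, np.nan))
            tg_col.append(template_g)
            pool_col.append(np.zeros(n, dtype=bool))
            draws_col.append(np.ones(n, dtype=np.int64))
        pool = None
    else:
        targets = library.guanine_fractions(config.composition)
        bin_width = schedule.step if schedule.step > 0 else 0.02
        pool = SimulationPool(bin_width) if config.use_pool else None
        for rep in range(config.n_replicates):
            rng = np.random.default_rng([config.seed, _STREAM_SALT, rep])
            out_chrom = np.empty(n, dtype=object)
            out_start = np.empty(n, dtype=np.int64)
            tol = np.empty(n)
            flag = np.empty(n, dtype=bool)
            simg = np.empty(n)
            frompool = np.empty(n, dtype=bool)
            draws = np.empty(n, dtype=np.int64)
            for i in range(n):
                tmpl = library[i]
                d = get_domain(tmpl.chrom if restrict_per_motif else None, tmpl.length)
                sm = simulate_motif(
                    genome, tmpl, schedule, pool, rng, config, _domain=d
                )
                out_chrom[i] = sm.interval.chrom
                out_start[i] = sm.interval.start
                tol[i] = sm.final_tolerance
                flag[i] = sm.flagged
                simg[i] = sm.simulated_g
                frompool[i] = sm.from_pool
                draws[i] = sm.n_fresh_draws
            replicates.append(
                MotifLibrary.from_arrays(
                    out_chrom, out_start, out_start + lens,
                    names=list(library.names), subtypes=list(library.subtypes),
                    genome=genome,
                )
            )
            rep_col.append(np.full(n, rep))
            motif_col.append(np.arange(n))
            chrom_col.append(out_chrom)
            start_col.append(out_start)
            tol_col.append(tol)
            flag_col.append(flag)
            g_col.append(simg)
            tg_col.append(targets)
            pool_col.append(frompool)
            draws_col.append(draws)

    report = pd.DataFrame(
        {
            "replicate": np.concatenate(rep_col),
            "motif": np.concatenate(motif_col),
            "chrom": np.concatenate(chrom_col),
            "start": np.concatenate(start_col),
            "length": np.tile(lens, config.n_replicates),
            "template_g": np.concatenate(tg_col),
            "simulated_g": np.concatenate(g_col),
            "final_tolerance": np.concatenate(tol_col),
            "flagged": np.concatenate(flag_col),
            "from_pool": np.concatenate(pool_col),
            "fresh_draws": np.concatenate(draws_col),
        }
    )
    report["end"] = report["start"] + report["length"]
    return SimulationResult(replicates=replicates, report=report, pool=pool)


def gc_mode_count(
    values: Sequence[float] | np.ndarray,
    bin_width: float = 0.05,
    min_fraction: float = 0.10,
) -> int:
    """Number of modes of a %G sample, by runs of heavily loaded histogram bins.

    Bins of width ``bin_width`` over [0, 1] holding at least ``min_fraction``
    of the sample are grouped into maximal runs; each run is one mode. This
    deliberately coarse rule is meant for well-separated composition peaks
    (valley below threshold, peaks more than one bin apart), which is the
    regime the simulator's dual-peak preservation check operates in.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    nb = int(round(1.0 / bin_width))
    counts, _ = np.histogram(v, bins=np.linspace(0.0, 1.0, nb + 1))
    big = counts >= min_fraction * v.size
    return int(np.count_nonzero(big[1:] & ~big[:-1]) + (1 if big[0] else 0))
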