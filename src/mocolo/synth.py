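"""Synthetic genomes and motif libraries with plantable co-localization.

The generator emulates the statistical structure the co-localization test
operates on, without any external downloads:

* genomes with i.i.d. background nucleotides at a chosen %G, optionally
  overwritten with G-rich (or G-poor) islands — the composition confounder;
* a "host" feature of long regions (peak-like, median hundreds of bases)
  and a "query" feature of short motifs (tens of bases), the two length
  regimes the reciprocal test distinguishes;
* a co-localization fraction rho: that share of query motifs is planted
  fully inside randomly chosen hosts; a nesting factor k plants them in
  clusters of k per host, producing the asymmetric signature where many
  query motifs inhabit few hosts;
* per-subtype rho values, for the post-test comparison.

Cluster hosts are drawn *with replacement*, so the number of distinct hosts
receiving clusters follows the same collision process as independent
placement of the cluster seeds — the nested scenario then inflates the
query-side count k-fold while leaving the host-side count at chance level.
Everything is deterministic under the scenario seed.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np

from .core import Genome, GenomicInterval, MotifLibrary

__all__ = [
    "FeatureSpec",
    "GenomeSpec",
    "IslandSpec",
    "LognormalLength",
    "SubtypeSpec",
    "SyntheticGenome",
    "make_features",
    "make_genome",
    "make_subtyped_query",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STREAM_SALT = 314_159  # keeps generator streams disjoint from simulator streams


@dataclass(frozen=True)
class IslandSpec:
    """Composition islands overwriting the background: count x length at %G g."""

    count: int
    length: int
    g: float

    def __post_init__(self) -> None:
        if self.count < 1 or self.length < 1:
            raise ValueError("island count and length must be positive")
        if not (0.0 <= self.g <= 1.0):
            raise ValueError("island g must be in [0, 1]")


@dataclass(frozen=True)
class GenomeSpec:
    """Toy genome layout: chromosomes of i.i.d. bases plus optional islands."""

    n_chromosomes: int = 1
    chromosome_length: int = 1_000_000
    background_g: float = 0.25
    islands: IslandSpec | None = None

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if not (0.0 <= self.background_g <= 1.0):
            raise ValueError("background_g must be in [0, 1]")
        if self.islands is not None:
            per_chrom = math.ceil(self.islands.count / self.n_chromosomes)
            if per_chrom * self.islands.length > self.chromosome_length:
                raise ValueError("islands exceed chromosome capacity")


@dataclass(frozen=True)
class LognormalLength:
    """Lognormal length distribution parameterised by its median."""

    median: float
    sigma: float = 0.5
    min_length: int = 2


@dataclass(frozen=True)
class FeatureSpec:
    """One feature's motif count, length distribution and placement bias.

    ``length`` is a fixed integer, a two-length tuple (drawn 50/50), or a
    :class:`LognormalLength`. ``island_fraction`` places that share of the
    motifs fully inside composition islands (uniform over island
    positions), emulating features that prefer a composition class.
    """

    count: int
    length: int | tuple[int, int] | LognormalLength
    island_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("feature count must be positive")
        if not (0.0 <= self.island_fraction <= 1.0):
            raise ValueError("island_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SubtypeSpec:
    """A labelled query subtype: motif count, length and planted rho."""

    count: int
    length: int
    rho: float


@dataclass
class SyntheticGenome:
    """A generated genome plus the island intervals written into it."""

    genome: Genome
    islands: MotifLibrary
    spec: GenomeSpec


def _iid_codes(rng: np.random.Generator, n: int, g: float) -> np.ndarray:
    p_other = (1.0 - g) / 3.0
    return rng.choice(4, size=n, p=[p_other, p_other, g, p_other])


def make_genome(spec: GenomeSpec, seed: int = 0) -> SyntheticGenome:
    """Generate a genome per spec; deterministic under the seed.

    Islands are placed without overlap, uniformly among non-colliding
    draws, distributed round-robin across chromosomes.
    """
    rng = np.random.default_rng([seed, _STREAM_SALT, 0])
    seqs: dict[str, str] = {}
    names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    codes: dict[str, np.ndarray] = {}
    for name in names:
        codes[name] = _iid_codes(rng, spec.chromosome_length, spec.background_g)

    island_ivs: list[GenomicInterval] = []
    if spec.islands is not None:
        isl = spec.islands
        placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
        for k in range(isl.count):
            chrom = names[k % len(names)]
            limit = spec.chromosome_length - isl.length
            for _attempt in range(10_000):
                s = int(rng.integers(0, limit + 1))
                if all(s + isl.length <= a or s >= b for a, b in placed[chrom]):
                    break
            else:  # pragma: no cover - capacity is validated in GenomeSpec
                raise ValueError("could not place islands without overlap")
            placed[chrom].append((s, s + isl.length))
            codes[chrom][s : s + isl.length] = _iid_codes(rng, isl.length, isl.g)
            island_ivs.append(
                GenomicInterval(chrom, s, s + isl.length, name=f"island{k}")
            )

    for name in names:
        seqs[name] = _BASES[codes[name]].tobytes().decode("ascii")
    genome = Genome(seqs)
    islands = MotifLibrary(island_ivs, genome=genome) if island_ivs else MotifLibrary()
    return SyntheticGenome(genome=genome, islands=islands, spec=spec)


def _draw_lengths(
    spec: FeatureSpec, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(spec.length, LognormalLength):
        ln = spec.length
        raw = rng.lognormal(mean=math.log(ln.median), sigma=ln.sigma, size=spec.count)
        return np.maximum(np.rint(raw).astype(np.int64), ln.min_length)
    if isinstance(spec.length, tuple):
        a, b = spec.length
        return np.where(rng.random(spec.count) < 0.5, a, b).astype(np.int64)
    return np.full(spec.count, int(spec.length), dtype=np.int64)


def _uniform_positions(
    genome: Genome, lengths: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform placement over all (chromosome, start) pairs fitting each length."""
    names = genome.names
    chrom_lens = np.array([genome.length(c) for c in names], dtype=np.int64)
    chroms = np.empty(lengths.size, dtype=object)
    starts = np.empty(lengths.size, dtype=np.int64)
    for length in np.unique(lengths):
        m = lengths == length
        valid = np.maximum(chrom_lens - int(length) + 1, 0)
        cum = np.concatenate([[0], np.cumsum(valid)])
        if cum[-1] == 0:
            raise ValueError(f"no chromosome can hold length {int(length)}")
        u = rng.integers(0, cum[-1], size=int(m.sum()))
        ci = np.searchsorted(cum, u, side="right") - 1
        chroms[m] = [names[int(c)] for c in ci]
        starts[m] = u - cum[ci]
    return chroms, starts


def _positions_inside(
    hosts: MotifLibrary, lengths: np.ndarray, rng: np.random.Generator,
    host_choice: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Place motifs fully inside host intervals.

    With ``host_choice`` given (one host index per motif) hosts are taken as
    is; otherwise each motif independently picks a uniform host among those
    that fit it. Position within the host is uniform.
    """
    chroms = np.empty(lengths.size, dtype=object)
    starts = np.empty(lengths.size, dtype=np.int64)
    host_lens = hosts.lengths
    for i in range(lengths.size):
        length = int(lengths[i])
        if host_choice is not None:
            h = int(host_choice[i])
            if host_lens[h] < length:
                raise ValueError("chosen host is shorter than the motif")
        else:
            fits = np.nonzero(host_lens >= length)[0]
            if fits.size == 0:
                raise ValueError(
                    f"no host interval can contain a motif of length {length}"
                )
            h = int(fits[rng.integers(0, fits.size)])
        off = int(rng.integers(0, host_lens[h] - length + 1))
        chroms[i] = hosts.chroms[h]
        starts[i] = hosts.starts[h] + off
    return chroms, starts


def _place_feature(
    syn: SyntheticGenome, spec: FeatureSpec, rng: np.random.Generator,
    name_prefix: str,
) -> MotifLibrary:
    lengths = _draw_lengths(spec, rng)
    n_island = int(round(spec.island_fraction * spec.count))
    if n_island > 0 and syn.islands.count == 0:
        raise ValueError("island_fraction > 0 but the genome has no islands")
    chroms = np.empty(spec.count, dtype=object)
    starts = np.empty(spec.count, dtype=np.int64)
    if n_island > 0:
        chroms[:n_island], starts[:n_island] = _positions_inside(
            syn.islands, lengths[:n_island], rng
        )
    if n_island < spec.count:
        chroms[n_island:], starts[n_island:] = _uniform_positions(
            syn.genome, lengths[n_island:], rng
        )
    names = [f"{name_prefix}{i}" for i in range(spec.count)]
    return MotifLibrary.from_arrays(
        chroms, starts, starts + lengths, names=names, genome=syn.genome
    )


def make_features(
    syn: SyntheticGenome,
    f1_spec: FeatureSpec,
    f2_spec: FeatureSpec,
    rho: float = 0.0,
    nesting: int = 1,
    seed: int = 0,
) -> tuple[MotifLibrary, MotifLibrary]:
    """Generate the host feature f1 and query feature f2.

    A fraction ``rho`` of f2 motifs is planted fully inside f1 hosts; with
    ``nesting`` k > 1 the planted motifs arrive in clusters of k sharing a
    host, hosts drawn with replacement. Remaining motifs follow the f2
    spec's own placement (island-biased or uniform).
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be in [0, 1]")
    if nesting < 1:
        raise ValueError("nesting factor must be >= 1")
    rng = np.random.default_rng([seed, _STREAM_SALT, 1])
    f1 = _place_feature(syn, f1_spec, rng, "f1_")

    lengths = _draw_lengths(f2_spec, rng)
    n2 = f2_spec.count
    n_clusters = int(round(rho * n2 / nesting))
    n_planted = min(n_clusters * nesting, n2)
    chroms = np.empty(n2, dtype=object)
    starts = np.empty(n2, dtype=np.int64)
    if n_planted > 0:
        host_lens = f1.lengths
        max_f2 = int(lengths[:n_planted].max())
        if not (host_lens >= max_f2).any():
            raise ValueError(
                "rho > 0 but no f1 motif is long enough to host an f2 motif"
            )
        fitting = np.nonzero(host_lens >= max_f2)[0]
        cluster_hosts = fitting[rng.integers(0, fitting.size, size=n_clusters)]
        host_choice = np.repeat(cluster_hosts, nesting)[:n_planted]
        chroms[:n_planted], starts[:n_planted] = _positions_inside(
            f1, lengths[:n_planted], rng, host_choice=host_choice
        )
    if n_planted < n2:
        rest = FeatureSpec(
            count=n2 - n_planted, length=1,
            island_fraction=f2_spec.island_fraction,
        )
        n_island = int(round(rest.island_fraction * rest.count))
        if n_island > 0:
            chroms[n_planted : n_planted + n_island], starts[
                n_planted : n_planted + n_island
            ] = _positions_inside(
                syn.islands, lengths[n_planted : n_planted + n_island], rng
            )
        if n_planted + n_island < n2:
            chroms[n_planted + n_island :], starts[n_planted + n_island :] = (
                _uniform_positions(
                    syn.genome, lengths[n_planted + n_island :], rng
                )
            )
    names = [f"f2_{i}" for i in range(n2)]
    f2 = MotifLibrary.from_arrays(
        chroms, starts, starts + lengths, names=names, genome=syn.genome
    )
    return f1, f2


def make_subtyped_query(
    syn: SyntheticGenome,
    hosts: MotifLibrary,
    specs: Mapping[str, SubtypeSpec],
    seed: int = 0,
) -> MotifLibrary:
    """Generate one labelled query library with per-subtype planted rho.

    Each subtype contributes ``count`` motifs of its length; a fraction
    ``rho`` of them is planted inside the host library, the rest placed
    uniformly. Subtype blocks are concatenated in mapping order.
    """
    rng = np.random.default_rng([seed, _STREAM_SALT, 2])
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    lengths: list[np.ndarray] = []
    labels: list[str] = []
    for name, sp in specs.items():
        if sp.count < 1:
            raise ValueError(f"subtype {name!r} must have a positive count")
        if not (0.0 <= sp.rho <= 1.0):
            raise ValueError(f"subtype {name!r}: rho must be in [0, 1]")
        lens = np.full(sp.count, int(sp.length), dtype=np.int64)
        n_in = int(round(sp.rho * sp.count))
        c = np.empty(sp.count, dtype=object)
        s = np.empty(sp.count, dtype=np.int64)
        if n_in > 0:
            c[:n_in], s[:n_in] = _positions_inside(hosts, lens[:n_in], rng)
        if n_in < sp.count:
            c[n_in:], s[n_in:] = _uniform_positions(syn.genome, lens[n_in:], rng)
        chroms.append(c)
        starts.append(s)
        lengths.append(lens)
        labels.extend([name] * sp.count)
    st = np.concatenate(starts)
    ln = np.concatenate(lengths)
    return MotifLibrary.from_arrays(
        np.concatenate(chroms), st, st + ln,
        subtypes=labels, genome=syn.genome,
    )
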