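"""Genomic interval primitives, genome access and BED/FASTA input.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
A :class:`Genome` gives uppercase plus-strand sequence access and cached
cumulative base counts so that guanine fractions of arbitrary intervals can
be computed in O(1) after a one-time O(genome) pass.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "BedParseError",
    "GenomicInterval",
    "Genome",
    "MotifLibrary",
    "guanine_fraction",
    "overlap_length",
    "read_bed",
    "read_fasta",
    "write_bed",
]

_VALID_STRANDS = {"+", "-", "."}
_COMPOSITION_KINDS = {"G", "GC"}


class BedParseError(ValueError):
    """A BED line could not be parsed; the message carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """One motif or peak: a 0-based half-open span on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None
    subtype: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand is not None and self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bases of the intersection of ``a`` and ``b`` (0 if disjoint).

    Symmetric; intervals on different chromosomes never overlap, and
    half-open abutment (``a.end == b.start``) counts as no overlap.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class Genome:
    """An in-memory reference genome: ordered chromosomes with sequence access.

    Sequences are normalised to uppercase on construction. Per-chromosome
    cumulative counts of G (or G+C) and of non-ACGT characters are built
    lazily and cached, so interval composition queries are vectorised O(1).
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome has no sequences")
        self._seqs: dict[str, str] = {
            str(name): str(seq).upper() for name, seq in sequences.items()
        }
        for name, seq in self._seqs.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name} has an empty sequence")
        self.chromosomes: dict[str, int] = {
            name: len(seq) for name, seq in self._seqs.items()
        }
        self._codes: dict[str, np.ndarray] = {}
        self._cums: dict[tuple[str, str], np.ndarray] = {}

    # -- basic access -----------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise ValueError(f"unknown chromosome {chrom}") from None

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Uppercase plus-strand sequence of ``chrom[start:end)``."""
        n = self.length(chrom)
        if not (0 <= start < end <= n):
            raise ValueError(
                f"interval {chrom}:{start}-{end} out of bounds (length {n})"
            )
        return self._seqs[chrom][start:end]

    def check_interval(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self:
            raise ValueError(f"unknown chromosome {interval.chrom}")
        if interval.end > self.length(interval.chrom):
            raise ValueError(
                f"interval {interval} exceeds chromosome "
                f"{interval.chrom} length {self.length(interval.chrom)}"
            )

    # -- composition ------------------------------------------------------
    def _chrom_codes(self, chrom: str) -> np.ndarray:
        arr = self._codes.get(chrom)
        if arr is None:
            arr = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype=np.uint8)
            self._codes[chrom] = arr
        return arr

    def _cum(self, chrom: str, kind: str) -> np.ndarray:
        key = (chrom, kind)
        cum = self._cums.get(key)
        if cum is None:
            c = self._chrom_codes(chrom)
            if kind == "G":
                ind = c == ord("G")
            elif kind == "GC":
                ind = (c == ord("G")) | (c == ord("C"))
            elif kind == "bad":
                ind = ~(
                    (c == ord("A"))
                    | (c == ord("C"))
                    | (c == ord("G"))
                    | (c == ord("T"))
                )
            else:  # pragma: no cover - guarded by callers
                raise ValueError(f"unknown composition kind {kind!r}")
            cum = np.concatenate([[0], np.cumsum(ind, dtype=np.int64)])
            self._cums[key] = cum
        return cum

    def fractions(
        self,
        chrom: str,
        starts: Sequence[int] | np.ndarray,
        length: int,
        kind: str = "G",
    ) -> np.ndarray:
        """Composition fraction for same-length windows ``[s, s+length)``.

        ``kind`` is ``"G"`` (guanine only, the default used throughout),
        ``"GC"`` or ``"bad"`` (non-ACGT characters, used by the simulator's
        assembly-gap filter). Non-ACGT characters count toward window length
        but never toward G or GC.
        """
        if chrom not in self:
            raise ValueError(f"unknown chromosome {chrom}")
        s = np.asarray(starts, dtype=np.int64)
        if s.size and (s.min() < 0 or s.max() + length > self.length(chrom)):
            raise ValueError(f"window out of bounds on {chrom}")
        cum = self._cum(chrom, kind)
        return (cum[s + length] - cum[s]) / float(length)


def guanine_fraction(
    genome: Genome, interval: GenomicInterval, composition: str = "G"
) -> float:
    """Fraction of guanine (or G+C) bases in ``interval`` on the plus strand."""
    if composition not in _COMPOSITION_KINDS:
        raise ValueError(f"composition must be one of {sorted(_COMPOSITION_KINDS)}")
    genome.check_interval(interval)
    return float(
        genome.fractions(
            interval.chrom, [interval.start], interval.length, composition
        )[0]
    )


class MotifLibrary:
    """An ordered collection of intervals for one feature, array-backed.

    Coordinate arrays (``chroms``, ``starts``, ``ends``) are the primary
    storage so that overlap counting and simulation stay vectorised;
    :class:`GenomicInterval` objects are materialised on iteration. A genome
    may be attached to validate bounds and enable %G traits.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Genome | None = None,
    ):
        ivs = list(intervals)
        self.chroms = np.array([iv.chrom for iv in ivs], dtype=object)
        self.starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        self.ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        self.names: list[str | None] = [iv.name for iv in ivs]
        self.strands: list[str | None] = [iv.strand for iv in ivs]
        self.subtypes: list[str | None] = [iv.subtype for iv in ivs]
        self._genome: Genome | None = None
        self._gfrac: dict[str, np.ndarray] = {}
        if genome is not None:
            self.attach_genome(genome)

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str] | np.ndarray,
        starts: Sequence[int] | np.ndarray,
        ends: Sequence[int] | np.ndarray,
        names: Sequence[str | None] | None = None,
        strands: Sequence[str | None] | None = None,
        subtypes: Sequence[str | None] | None = None,
        genome: Genome | None = None,
    ) -> "MotifLibrary":
        lib = cls()
        lib.chroms = np.asarray(chroms, dtype=object)
        lib.starts = np.asarray(starts, dtype=np.int64)
        lib.ends = np.asarray(ends, dtype=np.int64)
        n = lib.chroms.size
        if lib.starts.size != n or lib.ends.size != n:
            raise ValueError("chroms/starts/ends must have equal lengths")
        if n and ((lib.starts < 0).any() or (lib.starts >= lib.ends).any()):
            raise ValueError("require 0 <= start < end for every interval")
        lib.names = list(names) if names is not None else [None] * n
        lib.strands = list(strands) if strands is not None else [None] * n
        lib.subtypes = list(subtypes) if subtypes is not None else [None] * n
        for attr in ("names", "strands", "subtypes"):
            if len(getattr(lib, attr)) != n:
                raise ValueError(f"{attr} length does not match interval count")
        if genome is not None:
            lib.attach_genome(genome)
        return lib

    # -- container protocol -----------------------------------------------
    @property
    def count(self) -> int:
        return int(self.chroms.size)

    def __len__(self) -> int:
        return self.count

    def __getitem__(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            chrom=str(self.chroms[i]),
            start=int(self.starts[i]),
            end=int(self.ends[i]),
            name=self.names[i],
            strand=self.strands[i],
            subtype=self.subtypes[i],
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        for i in range(self.count):
            yield self[i]

    # -- traits ------------------------------------------------------------
    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def genome(self) -> Genome | None:
        return self._genome

    def attach_genome(self, genome: Genome) -> None:
        """Attach a genome, validating that every interval is in bounds."""
        for chrom in dict.fromkeys(self.chroms.tolist()):
            if chrom not in genome:
                raise ValueError(f"unknown chromosome {chrom}")
            m = self.chroms == chrom
            if self.ends[m].size and self.ends[m].max() > genome.length(chrom):
                bad = int(np.nonzero(m & (self.ends > genome.length(chrom)))[0][0])
                raise ValueError(
                    f"interval {self[bad]} exceeds chromosome {chrom} "
                    f"length {genome.length(chrom)}"
                )
        self._genome = genome
        self._gfrac.clear()

    def guanine_fractions(self, composition: str = "G") -> np.ndarray:
        """Per-motif %G (or %GC) as a float array in [0, 1]; needs a genome."""
        if composition not in _COMPOSITION_KINDS:
            raise ValueError(
                f"composition must be one of {sorted(_COMPOSITION_KINDS)}"
            )
        if self._genome is None:
            raise ValueError("no genome attached; cannot compute %G traits")
        cached = self._gfrac.get(composition)
        if cached is None:
            out = np.empty(self.count, dtype=float)
            lens = self.lengths
            for chrom in dict.fromkeys(self.chroms.tolist()):
                m = self.chroms == chrom
                for length in np.unique(lens[m]):
                    mm = m & (lens == length)
                    out[mm] = self._genome.fractions(
                        chrom, self.starts[mm], int(length), composition
                    )
            cached = out
            self._gfrac[composition] = cached
        return cached

    # -- derived libraries --------------------------------------------------
    def subset(self, indices: Sequence[int] | np.ndarray) -> "MotifLibrary":
        idx = np.asarray(indices)
        lib = MotifLibrary.from_arrays(
            self.chroms[idx],
            self.starts[idx],
            self.ends[idx],
            names=[self.names[i] for i in idx],
            strands=[self.strands[i] for i in idx],
            subtypes=[self.subtypes[i] for i in idx],
        )
        lib._genome = self._genome
        return lib

    def with_subtypes(self, labels: Sequence[str]) -> "MotifLibrary":
        if len(labels) != self.count:
            raise ValueError("one subtype label required per motif")
        lib = self.subset(np.arange(self.count))
        lib.subtypes = [str(x) for x in labels]
        return lib


# -- I/O -------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-)FASTA file into a :class:`Genome`.

    Record ids become chromosome names; duplicate ids and empty files are
    errors; sequence is normalised to uppercase.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate record name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(seqs)


def read_bed(path: str | Path, genome: Genome | None = None) -> MotifLibrary:
    """Read a BED3+ file (tab-separated, 0-based half-open) in file order.

    Column 4 (if present and not ``.``) is kept as the interval name, column
    6 as the strand. With ``genome`` given, unknown chromosomes and
    out-of-bounds intervals raise immediately, and %G traits become
    available on the returned library.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str | None] = []
    strands: list[str | None] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected at least 3 columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from None
            if not (0 <= start < end):
                raise BedParseError(
                    f"{path}: line {lineno}: invalid span [{start}, {end})"
                )
            if genome is not None:
                if chrom not in genome:
                    raise ValueError(
                        f"{path}: line {lineno}: unknown chromosome {chrom}"
                    )
                if end > genome.length(chrom):
                    raise ValueError(
                        f"{path}: line {lineno}: interval {chrom}:{start}-{end} "
                        f"exceeds chromosome length {genome.length(chrom)}"
                    )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = (
                fields[5]
                if len(fields) > 5 and fields[5] in _VALID_STRANDS
                else None
            )
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            names.append(name)
            strands.append(strand)
    return MotifLibrary.from_arrays(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        names=names,
        strands=strands,
        genome=genome,
    )


def write_bed(library: MotifLibrary, path: str | Path) -> None:
    """Write a library as BED, reproducing coordinates bit-exactly.

    Emits BED3 when no names/strands are set; otherwise BED6 with ``.`` for
    missing fields and 0 for the unused score column. If subtype labels are
    present but names are not, subtypes are written into the name column
    (the on-disk convention for labelled libraries).
    """
    any_name = any(x is not None for x in library.names) or any(
        x is not None for x in library.subtypes
    )
    any_strand = any(x is not None for x in library.strands)
    with open(path, "w") as fh:
        for i in range(library.count):
            cols = [str(library.chroms[i]), str(int(library.starts[i])),
                    str(int(library.ends[i]))]
            if any_name or any_strand:
                name = library.names[i] or library.subtypes[i] or "."
                cols.append(name)
            if any_strand:
                cols += ["0", library.strands[i] or "."]
            fh.write("\t".join(cols) + "\n")


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    """Write a genome as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name in genome.names:
            fh.write(f">{name}\n")
            seq = genome.sequence(name, 0, genome.length(name))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
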