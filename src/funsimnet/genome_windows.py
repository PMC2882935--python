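"""Sliding-window scan of a genome for functionally coherent regions.

Each chromosome is scanned with a fixed-size window advanced by one
fifth of its size (so a gene away from the ends falls in exactly five
windows).  Window sizes around 10-30 kb are chosen so that a window
holds eight to ten genes on average across both strands.  For every
window the mean pairwise category GOscore and funSim among its member
genes is computed from a scored-pair table, and windows whose category
mean exceeds 0.7 or whose funSim mean exceeds 0.49 are selected for
term-overrepresentation analysis.

Coordinates are 0-based half-open internally; the TSV/GFF readers
convert from 1-based inclusive.  A gene belongs to a window when its
start coordinate lies in the window's half-open interval.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "GeneLocus",
    "WindowSpec",
    "WindowResult",
    "read_loci",
    "enumerate_windows",
    "window_similarity",
    "select_windows",
    "scan_genome",
    "suggest_window_size",
    "write_windows",
]

GO_THRESHOLD = 0.7
FUNSIM_THRESHOLD = 0.49


@dataclass(frozen=True)
class GeneLocus:
    """One gene: id, chromosome, 0-based half-open span, strand."""

    protein: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.protein}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.protein}: strand must be '+' or '-'")


@dataclass(frozen=True)
class WindowSpec:
    """Window size in bp; the slide is fixed at one fifth of the size."""

    size: int
    strand_mode: str = "both"  # "plus", "minus" or "both"

    def __post_init__(self):
        if self.size <= 0 or self.size % 5:
            raise ValueError("window size must be positive and divisible "
                             "by 5 so the slide is exactly size/5")
        if self.strand_mode not in ("plus", "minus", "both"):
            raise ValueError(f"unknown strand mode {self.strand_mode!r}")

    @property
    def slide(self) -> int:
        return self.size // 5


@dataclass
class Window:
    """A genomic interval and the genes whose starts fall inside it."""

    chromosome: str
    start: int
    size: int
    strand_mode: str
    members: tuple[GeneLocus, ...]

    @property
    def end(self) -> int:
        return self.start + self.size


@dataclass
class WindowResult:
    """Similarity means of one window and its selection flag."""

    window: Window
    bp: float | None
    cc: float | None
    mf: float | None
    funsim: float | None
    selected: bool = False

    @property
    def member_proteins(self) -> list[str]:
        return [g.protein for g in self.window.members]


def read_loci(source: TextIO | Iterable[str]) -> list[GeneLocus]:
    """Read gene coordinates from TSV or GFF3 gene lines.

    The TSV form is ``protein  chromosome  start  end  strand`` with
    1-based inclusive coordinates (header optional); GFF3 lines (9
    columns) are accepted with the gene id taken from the ``ID=``
    attribute.  Both are converted to 0-based half-open.
    """
    loci: list[GeneLocus] = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 9:  # GFF3
            if fields[2] not in ("gene", "CDS", "mRNA"):
                continue
            attrs = dict(
                item.split("=", 1)
                for item in fields[8].split(";") if "=" in item)
            name = attrs.get("ID") or attrs.get("Name")
            if name is None:
                raise ValueError(f"line {lineno}: GFF record without ID")
            chrom, start, end, strand = (fields[0], fields[3], fields[4],
                                         fields[6])
        elif len(fields) >= 5:
            name, chrom, start, end, strand = fields[:5]
            if lineno == 1 and not start.isdigit():
                continue  # header row
        else:
            raise ValueError(f"line {lineno}: expected 5 (TSV) or 9 (GFF) "
                             f"columns, got {len(fields)}")
        loci.append(GeneLocus(protein=name, chromosome=chrom,
                              start=int(start) - 1, end=int(end),
                              strand=strand))
    return loci


def _strand_filter(loci: Iterable[GeneLocus], mode: str) -> list[GeneLocus]:
    if mode == "plus":
        return [g for g in loci if g.strand == "+"]
    if mode == "minus":
        return [g for g in loci if g.strand == "-"]
    return list(loci)


def enumerate_windows(loci: Sequence[GeneLocus],
                      spec: WindowSpec) -> list[Window]:
    """All windows over every chromosome carrying at least one gene.

    Windows start at 0, slide, 2*slide, ... while the start is below
    the chromosome extent (the maximum gene end); membership is by gene
    start in ``[w, w + size)`` after the strand filter.
    """
    if not loci:
        raise ValueError("no gene loci given")
    windows: list[Window] = []
    by_chromosome: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chromosome.setdefault(locus.chromosome, []).append(locus)
    for chromosome in sorted(by_chromosome):
        genes = _strand_filter(by_chromosome[chromosome], spec.strand_mode)
        extent = max(g.end for g in by_chromosome[chromosome])
        genes.sort(key=lambda g: g.start)
        starts = np.array([g.start for g in genes])
        for w in range(0, extent, spec.slide):
            lo, hi = np.searchsorted(starts, [w, w + spec.size])
            windows.append(Window(
                chromosome=chromosome, start=w, size=spec.size,
                strand_mode=spec.strand_mode,
                members=tuple(genes[lo:hi])))
    return windows


def _pair_lookup(pairs: pd.DataFrame) -> dict[tuple[str, str], tuple]:
    lookup = {}
    for row in pairs.itertuples(index=False):
        key = (row.protein_a, row.protein_b)
        key = key if key[0] <= key[1] else (key[1], key[0])
        lookup[key] = (row.bp, row.cc, row.mf, row.funsim)
    return lookup


def window_similarity(window: Window, pairs: pd.DataFrame,
                      _lookup: dict | None = None) -> WindowResult:
    """Mean pairwise scores among a window's member genes.

    For each score kind the mean runs over the unordered member pairs
    whose score is present; a kind with no scoreable pair, or a window
    with fewer than two members, yields ``None``.
    """
    lookup = _lookup if _lookup is not None else _pair_lookup(pairs)
    sums = np.zeros(4)
    counts = np.zeros(4, dtype=int)
    proteins = [g.protein for g in window.members]
    for a, b in itertools.combinations(sorted(proteins), 2):
        values = lookup.get((a, b))
        if values is None:
            continue
        for i, value in enumerate(values):
            if value is not None and not (isinstance(value, float)
                                          and math.isnan(value)):
                sums[i] += value
                counts[i] += 1
    means = [s / c if c else None for s, c in zip(sums, counts)]
    return WindowResult(window=window, bp=means[0], cc=means[1],
                        mf=means[2], funsim=means[3])


def select_windows(results: Iterable[WindowResult],
                   go_threshold: float = GO_THRESHOLD,
                   funsim_threshold: float = FUNSIM_THRESHOLD,
                   ) -> list[WindowResult]:
    """Flag and return windows exceeding either similarity threshold.

    Selection is strict: any of the three category means > go_threshold,
    or the funSim mean > funsim_threshold.
    """
    selected = []
    for result in results:
        category_hit = any(
            value is not None and value > go_threshold
            for value in (result.bp, result.cc, result.mf))
        funsim_hit = (result.funsim is not None
                      and result.funsim > funsim_threshold)
        result.selected = category_hit or funsim_hit
        if result.selected:
            selected.append(result)
    return selected


def scan_genome(loci: Sequence[GeneLocus], pairs: pd.DataFrame,
                spec: WindowSpec, go_threshold: float = GO_THRESHOLD,
                funsim_threshold: float = FUNSIM_THRESHOLD,
                ) -> list[WindowResult]:
    """Enumerate, score and flag all windows (selection flags set)."""
    lookup = _pair_lookup(pairs)
    results = [window_similarity(w, pairs, _lookup=lookup)
               for w in enumerate_windows(loci, spec)]
    select_windows(results, go_threshold, funsim_threshold)
    return results


def suggest_window_size(loci: Sequence[GeneLocus],
                        mean_range: tuple[float, float] = (8.0, 10.0),
                        step: int = 5000, max_size: int = 200_000,
                        ) -> int | tuple[int, int]:
    """Smallest multiple of *step* whose windows average 8-10 genes.

    The mean counts genes of both strands over all windows of the
    chromosome set.  If the mean jumps across the target range between
    two consecutive sizes, the bracketing pair is returned.
    """
    if len(loci) < 10:
        raise ValueError("need at least 10 genes to calibrate a window size")
    lo, hi = mean_range
    previous: int | None = None
    for size in range(step, max_size + step, step):
        spec = WindowSpec(size=size, strand_mode="both")
        windows = enumerate_windows(loci, spec)
        mean = float(np.mean([len(w.members) for w in windows]))
        if lo <= mean <= hi:
            return size
        if mean > hi:
            return (previous, size) if previous is not None else size
        previous = size
    raise ValueError("genome too sparse: no window size up to "
                     f"{max_size} bp reaches a mean of {lo}-{hi} genes")


def write_windows(results: Sequence[WindowResult],
                  destination: TextIO | str) -> None:
    """Per-window TSV: coordinates, gene count, means, selection flag."""
    rows = [
        (r.window.chromosome, r.window.start, r.window.strand_mode,
         len(r.window.members), r.bp, r.cc, r.mf, r.funsim, r.selected)
        for r in results
    ]
    frame = pd.DataFrame(rows, columns=[
        "chrom", "start", "strand_mode", "n_genes",
        "bp", "cc", "mf", "funsim", "selected"])
    frame.to_csv(destination, sep="\t", index=False, na_rep="NA",
                 float_format="%.6g")
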