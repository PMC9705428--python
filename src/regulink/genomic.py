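"""Genomic interval algebra, BED I/O, peak partitioning and motif allele scoring.

Coordinates follow BED semantics: intervals are 0-based half-open ``[start, end)``.
Variant positions elsewhere in the package are 1-based and converted with
``pos - 1`` before interval membership tests.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "PWM",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "partition_peak_sets",
    "cooccupancy_fraction",
    "CooccupancyResult",
    "annotate_peaks_to_genes",
    "AnnotationResult",
    "pwm_allele_delta",
    "read_gene_models",
    "write_gene_models",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


class PeakSet:
    """A named collection of genomic intervals (one factor's binding sites).

    Internally a DataFrame with columns ``chrom``, ``start``, ``end``. A peak
    set is *normalized* when, within each chromosome, intervals are sorted and
    non-overlapping; :meth:`normalize` merges overlapping and touching
    intervals (union-peak semantics).
    """

    def __init__(self, name: str, intervals: pd.DataFrame | Iterable[GenomicInterval]):
        if isinstance(intervals, pd.DataFrame):
            df = intervals[["chrom", "start", "end"]].copy()
        else:
            rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
            df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and ((df["start"] < 0).any() or (df["start"] >= df["end"]).any()):
            bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])][0]
            raise ValueError(f"invalid interval at row {bad}: require 0 <= start < end")
        self.name = name
        self.df = df.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.df.sort_values(["chrom", "start", "end"]).reset_index(drop=True).equals(
            other.df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        )

    @property
    def total_span(self) -> int:
        """Total covered bases of the *normalized* set."""
        m = self.normalize()
        return int((m.df["end"] - m.df["start"]).sum())

    def intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in self.df.itertuples()]

    # -- pyranges bridge ---------------------------------------------------
    def _pr(self) -> pr.PyRanges:
        return pr.PyRanges(
            pd.DataFrame(
                {"Chromosome": self.df["chrom"], "Start": self.df["start"], "End": self.df["end"]}
            )
        )

    @classmethod
    def _from_pr(cls, name: str, g: pr.PyRanges) -> "PeakSet":
        df = g.df
        if len(df) == 0:
            return cls(name, pd.DataFrame(columns=["chrom", "start", "end"]))
        out = pd.DataFrame(
            {"chrom": df["Chromosome"].astype(str), "start": df["Start"], "end": df["End"]}
        ).sort_values(["chrom", "start"]).reset_index(drop=True)
        return cls(name, out)

    def normalize(self) -> "PeakSet":
        """Sorted, merged copy: overlapping and touching intervals coalesce."""
        if len(self.df) == 0:
            return PeakSet(self.name, self.df)
        return PeakSet._from_pr(self.name, self._pr().merge(slack=0))

    def is_normalized(self) -> bool:
        df = self.df
        for _, sub in df.groupby("chrom", sort=False):
            s = sub.sort_index()
            if not s["start"].is_monotonic_increasing:
                return False
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                return False
        return True


def merge_intervals(peaks: PeakSet) -> PeakSet:
    """Merge a peak set to sorted, non-overlapping intervals.

    Touching intervals (``[0,5), [5,9)``) merge, matching common peak-union
    semantics. The union of covered bases is preserved exactly.
    """
    return peaks.normalize()


# -- BED I/O ----------------------------------------------------------------

def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Read a BED(3+) file into a :class:`PeakSet`.

    Comment (``#``), ``track`` and ``browser`` lines are skipped. Malformed
    coordinates are rejected with the offending line number.
    """
    path = Path(path)
    rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}) (require 0 <= start < end)"
                )
            rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return PeakSet(name or path.stem, df)


def write_bed(peaks: PeakSet, path: str | Path) -> Path:
    """Write a peak set as 3-column BED."""
    path = Path(path)
    peaks.df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)
    return path


# -- partitioning and co-occupancy ------------------------------------------

def partition_peak_sets(a: PeakSet, b: PeakSet) -> tuple[PeakSet, PeakSet, PeakSet]:
    """Base-pair partition of two normalized peak sets.

    Returns ``(unique_a, common, unique_b)`` where ``common = a ∩ b``,
    ``unique_a = a − b`` and ``unique_b = b − a``. The three outputs are
    pairwise disjoint and together cover exactly the bases of ``a ∪ b``.
    """
    ga, gb = a._pr(), b._pr()
    common = PeakSet._from_pr(f"{a.name}_AND_{b.name}", ga.set_intersect(gb))
    unique_a = PeakSet._from_pr(f"{a.name}_only", ga.merge(slack=0).subtract(gb))
    unique_b = PeakSet._from_pr(f"{b.name}_only", gb.merge(slack=0).subtract(ga))
    return unique_a, common, unique_b


@dataclass(frozen=True)
class CooccupancyResult:
    """Peak-level co-occupancy of set ``a`` by set ``b``."""

    n_cooccupied: int
    n_total: int
    fraction: float

    def __iter__(self):
        return iter((self.n_cooccupied, self.n_total, self.fraction))


def cooccupancy_fraction(a: PeakSet, b: PeakSet) -> CooccupancyResult:
    """Fraction of ``a`` peaks sharing >=1 bp with any ``b`` peak.

    Asymmetric by design: the denominator counts the peaks of ``a``. This is
    the quantity behind statements such as "3,632 of 5,133 binding sites of
    one factor are co-occupied by a second factor".
    """
    if len(a) == 0:
        raise ValueError("cooccupancy_fraction: empty peak set 'a' (fraction undefined)")
    n_total = len(a)
    if len(b) == 0:
        return CooccupancyResult(0, n_total, 0.0)
    counts = a._pr().count_overlaps(b._pr()).df
    n_co = int((counts["NumberOverlaps"] > 0).sum())
    return CooccupancyResult(n_co, n_total, n_co / n_total)


# -- gene models and peak annotation ----------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene anchored at its transcription start site (1-based)."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int
    strand: str = "+"
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"{self.gene_id}: tss must be >= 1 (1-based)")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = [
        GeneModel(
            str(r.gene_id), str(r.symbol), str(r.chrom), int(r.tss), str(r.strand),
            bool(r.is_tf),
        )
        for r in df.itertuples()
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("gene_id column contains duplicates")
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> Path:
    pd.DataFrame(
        [(g.gene_id, g.symbol, g.chrom, g.tss, g.strand, g.is_tf) for g in genes],
        columns=["gene_id", "symbol", "chrom", "tss", "strand", "is_tf"],
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


@dataclass
class AnnotationResult:
    """Genes assigned to peaks plus a count of unassignable peaks."""

    genes: set[str]
    n_peaks: int
    n_unassigned: int
    assignments: pd.DataFrame = field(repr=False, default=None)


def annotate_peaks_to_genes(
    peaks: PeakSet, genes: Sequence[GeneModel], max_distance: int = 100_000
) -> AnnotationResult:
    """Assign each peak to the nearest-TSS gene within ``max_distance``.

    Distance is measured from the peak midpoint to the TSS. Equidistant ties
    break toward the gene with the lower TSS coordinate (then lexicographic
    gene_id). Peaks with no gene in range are dropped and counted.
    """
    if not genes:
        raise ValueError("annotate_peaks_to_genes: empty gene list")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    assigned: list[tuple[str, int, int, str, float]] = []
    n_unassigned = 0
    for row in peaks.df.itertuples():
        cands = by_chrom.get(row.chrom)
        if not cands:
            n_unassigned += 1
            continue
        mid = (row.start + row.end) / 2.0  # midpoint of [start, end); TSS converted to 0-based
        best = min(cands, key=lambda g: (abs(mid - (g.tss - 1)), g.tss, g.gene_id))
        dist = abs(mid - (best.tss - 1))
        if dist <= max_distance:
            assigned.append((row.chrom, int(row.start), int(row.end), best.gene_id, dist))
        else:
            n_unassigned += 1
    adf = pd.DataFrame(assigned, columns=["chrom", "start", "end", "gene_id", "distance"])
    return AnnotationResult(
        genes=set(adf["gene_id"]) if len(adf) else set(),
        n_peaks=len(peaks),
        n_unassigned=n_unassigned,
        assignments=adf,
    )


# -- position weight matrix allele scoring ----------------------------------

class PWM:
    """Position weight matrix: 4 x L base probabilities (rows A, C, G, T).

    Scores are log2 odds against a background distribution; a pseudocount of
    1e-3 is added to the probabilities before taking logs so that zero entries
    stay finite.
    """

    BASES = "ACGT"
    PSEUDOCOUNT = 1e-3

    def __init__(self, matrix: np.ndarray, background: Sequence[float] = (0.25,) * 4):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x L (rows A, C, G, T)")
        if not np.allclose(matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or not math.isclose(background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        if (background <= 0).any():
            raise ValueError("background probabilities must be positive")
        self.matrix = matrix
        self.background = background
        self._logodds = np.log2((matrix + self.PSEUDOCOUNT) / background[:, None])

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray, background: Sequence[float] = (0.25,) * 4) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(counts / counts.sum(axis=0, keepdims=True), background)

    @classmethod
    def from_jaspar(cls, path: str | Path) -> "PWM":
        """Parse a JASPAR-style text matrix: four lines ``A [ 1 2 ... ]`` etc."""
        rows: dict[str, list[float]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(">"):
                    continue
                base = line[0].upper()
                if base in "ACGT":
                    nums = line[1:].replace("[", " ").replace("]", " ").split()
                    rows[base] = [float(x) for x in nums]
        if set(rows) != set("ACGT"):
            raise ValueError("JASPAR matrix must provide A, C, G and T rows")
        return cls.from_counts(np.array([rows[b] for b in "ACGT"]))

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1], self.background[::-1])

    def score(self, window: str) -> float:
        """Log2-odds score of one window of length L (forward strand)."""
        idx = [self.BASES.index(b) for b in window]
        return float(self._logodds[idx, np.arange(self.length)].sum())

    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix.tolist(), "background": self.background.tolist()})


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlleleDeltaResult:
    best_ref_score: float
    best_alt_score: float
    delta: float

    def __iter__(self):
        return iter((self.best_ref_score, self.best_alt_score, self.delta))


def pwm_allele_delta(
    pwm: PWM, sequence: str, snp_offset: int, ref: str, alt: str
) -> AlleleDeltaResult:
    """Best motif score change between reference and alternate allele.

    Every window of motif length covering ``snp_offset`` is scored on both
    strands; ``delta = best_alt - best_ref`` summarises whether the alternate
    allele strengthens (positive) or weakens (negative) the best motif match.
    Windows containing ambiguous bases (anything outside ACGT) are skipped.
    """
    sequence = sequence.upper()
    ref, alt = ref.upper(), alt.upper()
    if not (0 <= snp_offset < len(sequence)):
        raise ValueError(f"snp_offset {snp_offset} outside sequence of length {len(sequence)}")
    if sequence[snp_offset] != ref:
        raise ValueError(
            f"sequence base at offset {snp_offset} is {sequence[snp_offset]!r}, expected ref {ref!r}"
        )
    L = pwm.length
    lo = max(0, snp_offset - L + 1)
    hi = min(len(sequence) - L, snp_offset)
    if hi < lo:
        raise ValueError("sequence too short to slide the motif over the SNP")
    alt_seq = sequence[:snp_offset] + alt + sequence[snp_offset + 1 :]
    best_ref = -math.inf
    best_alt = -math.inf
    for start in range(lo, hi + 1):
        for seq, is_ref in ((sequence, True), (alt_seq, False)):
            win = seq[start : start + L]
            if any(b not in PWM.BASES for b in win):
                continue
            s = max(pwm.score(win), pwm.score(_revcomp(win)))
            if is_ref:
                best_ref = max(best_ref, s)
            else:
                best_alt = max(best_alt, s)
    if math.isinf(best_ref) or math.isinf(best_alt):
        raise ValueError("no scoreable window over the SNP (ambiguous bases?)")
    return AlleleDeltaResult(best_ref, best_alt, best_alt - best_ref)
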