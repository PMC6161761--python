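"""Readers/writers and coordinate conventions shared by the whole package.

Every interval in the package is 0-based, half-open ``[start, end)`` (the BED
convention); GTF input (1-based, closed) is converted on read.  Strand is
discarded everywhere except TSS extraction, where the gene strand selects the
5' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

HISTONE_MARKS = ("H3K27ac", "H3K27me3", "H3K4me1", "H3K4me3", "H3K9me3")


class ParseError(ValueError):
    """A malformed line in an on-disk file; message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # floor keeps odd-length midpoints deterministic
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple[GenomicInterval, str | None, float | None]]:
    """Read a BED3/BED6 file, preserving input order.

    Returns ``(interval, name, score)`` triples; missing columns yield None.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                iv = GenomicInterval(fields[0], start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            out.append((iv, name, score))
    return out


def write_bed(path, records: Iterable[tuple[GenomicInterval, str | None, float | None]]) -> None:
    with open(path, "w") as fh:
        for iv, name, score in records:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if name is not None or score is not None:
                fields.append(name if name is not None else ".")
            if score is not None:
                fields.append(format_float(score))
            fh.write("\t".join(fields) + "\n")


def format_float(x: float) -> str:
    """Fixed decimal formatting used in all text outputs (round-trip stable)."""
    if float(x) == int(x):
        return str(int(x))
    return f"{x:.6f}".rstrip("0").rstrip(".")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path) -> dendropy.Tree:
    """Read a single rooted, dated tree (branch lengths in My).

    Duplicate tip labels or negative branch lengths are rejected; polytomies
    are accepted (resolved downstream with zero-length branches).
    """
    with open(path) as fh:
        return parse_newick_string(fh.read())


def parse_newick_string(text: str) -> dendropy.Tree:
    """As :func:`read_newick` but from an in-memory string."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises its own hierarchy
        msg = str(exc)
        if "multiple" in msg.lower() or "duplicate" in msg.lower():
            raise ValueError(f"duplicate tip labels: {msg}") from exc
        raise ValueError(f"invalid newick: {msg}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return tree


# ---------------------------------------------------------------------------
# Signal tracks (bedGraph)
# ---------------------------------------------------------------------------

class SignalTrack:
    """A sparse fold-enrichment track for one (tissue, mark).

    Bins are non-overlapping within a chromosome; positions outside every bin
    have value 0 (the bedGraph sparse convention).  Fold-enrichment 1.0 is the
    control/background level, so an all-baseline region must be listed
    explicitly.
    """

    def __init__(self, tissue: str, mark: str,
                 bins: Iterable[tuple[GenomicInterval, float]] = ()):
        self.tissue = tissue
        self.mark = mark
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in bins:
            if value < 0:
                raise ValueError("fold-enrichment must be >= 0")
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping bins on {chrom} near position {int(ends[i])}"
                )
            self._chrom[chrom] = (starts, ends, values)

    @classmethod
    def from_arrays(cls, tissue, mark, chrom, starts, ends, values) -> "SignalTrack":
        """Fast constructor from pre-sorted, non-overlapping arrays."""
        track = cls(tissue, mark)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping bins on {chrom}")
        if np.any(values < 0):
            raise ValueError("fold-enrichment must be >= 0")
        track._chrom[chrom] = (starts, ends, values)
        return track

    def _integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the (0-filled) piecewise-constant signal over [0, pos)."""
        if chrom not in self._chrom:
            return np.zeros(len(pos), dtype=float)
        starts, ends, values = self._chrom[chrom]
        cum = np.concatenate([[0.0], np.cumsum((ends - starts) * values)])
        idx = np.searchsorted(starts, pos, side="right")
        full = cum[idx]
        # subtract the part of bin idx-1 lying at/after pos
        prev = idx - 1
        valid = prev >= 0
        trailing = np.zeros(len(pos), dtype=float)
        trailing[valid] = (
            np.clip(ends[prev[valid]] - pos[valid], 0, None)
            * values[prev[valid]]
        )
        return full - trailing

    def mean_over(self, interval: GenomicInterval) -> float:
        """Base-weighted mean over the interval; unlisted bases count as 0."""
        lo, hi = self._integral(
            interval.chrom, np.array([interval.start, interval.end], dtype=np.int64)
        )
        return float((hi - lo) / interval.length)

    def window_means(self, chrom: str, starts: np.ndarray, width: int) -> np.ndarray:
        """Means over many equal-width windows ``[s, s+width)`` at once."""
        starts = np.asarray(starts, dtype=np.int64)
        lo = self._integral(chrom, starts)
        hi = self._integral(chrom, starts + width)
        return (hi - lo) / width

    def bins(self) -> list[tuple[GenomicInterval, float]]:
        out = []
        for chrom in sorted(self._chrom):
            starts, ends, values = self._chrom[chrom]
            for s, e, v in zip(starts, ends, values):
                out.append((GenomicInterval(chrom, int(s), int(e)), float(v)))
        return out


def read_track(path, tissue: str, mark: str) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`."""
    bins = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            bins.append((iv, value))
    return SignalTrack(tissue, mark, bins)


def write_track(path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for iv, value in track.bins():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{format_float(value)}\n")


# ---------------------------------------------------------------------------
# Alignment hit tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = ["query", "species", "chrom", "start", "end", "score"]


def read_hits(path) -> pd.DataFrame:
    """Read a tabular alignment hit table (stand-in for BLAT output).

    Columns: query id, target species, target chrom/start/end, score.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing hit-table columns {missing}")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: hit with start >= end")
    return df[HIT_COLUMNS].copy()


def write_hits(path, df: pd.DataFrame) -> None:
    df[HIT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Minimal GTF
# ---------------------------------------------------------------------------

@dataclass
class GtfFeature:
    feature: str          # gene | transcript | exon | UTR
    interval: GenomicInterval
    strand: str           # '+' or '-'
    gene_id: str
    gene_type: str        # e.g. protein_coding


def read_gtf(path) -> list[GtfFeature]:
    """Read a minimal GTF; converts 1-based closed to 0-based half-open."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand = fields[:7]
            attrs = fields[8]
            try:
                start0 = int(start) - 1
                end0 = int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                iv = GenomicInterval(chrom, start0, end0)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            feats.append(
                GtfFeature(
                    feature=feature,
                    interval=iv,
                    strand=strand,
                    gene_id=_gtf_attr(attrs, "gene_id"),
                    gene_type=_gtf_attr(attrs, "gene_type"),
                )
            )
    return feats


def _gtf_attr(attrs: str, key: str) -> str:
    for piece in attrs.split(";"):
        piece = piece.strip()
        if piece.startswith(key + " "):
            return piece.split(" ", 1)[1].strip().strip('"')
    return ""


def protein_coding_tss(features: Sequence[GtfFeature]) -> list[tuple[str, int]]:
    """(chrom, position) of each protein-coding gene TSS (strand-aware 5' end)."""
    out = []
    for f in features:
        if f.feature == "gene" and f.gene_type == "protein_coding":
            pos = f.interval.start if f.strand != "-" else f.interval.end - 1
            out.append((f.interval.chrom, pos))
    return out


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
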