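"""Sliding-window CpG-island prediction.

A window passes when its GC content exceeds ``gc_min`` percent AND the
observed/expected CpG ratio

    Obs/Exp = N_CpG * N / (N_C * N_G)

exceeds ``oe_min`` (both strictly).  Passing windows are merged when they
overlap or touch, merged ranges shorter than ``min_len`` are discarded, and
every reported island is re-scored over its full extent.  Coordinates are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO


@dataclass
class CpGIsland:
    """A called island with whole-interval statistics."""

    seq_id: str
    start: int
    end: int
    gc_pct: float
    obs_exp: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("island end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def _counts(window: str) -> tuple[int, int, int, int]:
    """Return (effective N excluding N bases, N_C, N_G, N_CpG)."""
    n_c = window.count("C")
    n_g = window.count("G")
    n_eff = sum(window.count(b) for b in "ACGT")
    n_cpg = window.count("CG")
    return n_eff, n_c, n_g, n_cpg


def window_stats(seq: str, start: int, win_len: int) -> tuple[float, float]:
    """GC percentage and Obs/Exp CpG ratio of seq[start:start+win_len]."""
    seq = seq.upper()
    if start < 0 or start + win_len > len(seq):
        raise ValueError(
            f"window [{start}, {start + win_len}) out of range for length {len(seq)}"
        )
    window = seq[start : start + win_len]
    n_eff, n_c, n_g, n_cpg = _counts(window)
    if n_eff == 0:
        return 0.0, 0.0
    gc_pct = 100.0 * (n_c + n_g) / n_eff
    obs_exp = (n_cpg * n_eff) / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return gc_pct, obs_exp


def find_cpg_islands(
    seq: str,
    win_len: int = 100,
    step: int = 1,
    gc_min: float = 60.0,
    oe_min: float = 0.6,
    min_len: int = 200,
    seq_id: str = "seq",
    max_n_frac: float = 0.2,
) -> list[CpGIsland]:
    """Scan one sequence and return disjoint, sorted island calls.

    Windows with more than ``max_n_frac`` N bases are skipped.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if win_len < 10:
        raise ValueError("win_len must be >= 10")
    seq = seq.upper()
    if len(seq) < win_len:
        raise ValueError(f"sequence length {len(seq)} shorter than window {win_len}")

    passing: list[tuple[int, int]] = []
    for start in range(0, len(seq) - win_len + 1, step):
        window = seq[start : start + win_len]
        if window.count("N") > max_n_frac * win_len:
            continue
        gc_pct, obs_exp = window_stats(seq, start, win_len)
        if gc_pct > gc_min and obs_exp > oe_min:
            passing.append((start, start + win_len))

    merged: list[list[int]] = []
    for s, e in passing:
        if merged and s <= merged[-1][1]:  # overlapping or adjacent
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    islands = []
    for s, e in merged:
        if e - s < min_len:
            continue
        gc_pct, obs_exp = window_stats(seq, s, e - s)
        islands.append(CpGIsland(seq_id=seq_id, start=s, end=e, gc_pct=gc_pct, obs_exp=obs_exp))
    return islands


def scan_fasta(
    path: str | Path,
    win_len: int = 100,
    step: int = 1,
    gc_min: float = 60.0,
    oe_min: float = 0.6,
    min_len: int = 200,
) -> list[CpGIsland]:
    """Run the island scan over every record of a FASTA file."""
    islands: list[CpGIsland] = []
    for record in SeqIO.parse(str(path), "fasta"):
        islands.extend(
            find_cpg_islands(
                str(record.seq),
                win_len=win_len,
                step=step,
                gc_min=gc_min,
                oe_min=oe_min,
                min_len=min_len,
                seq_id=record.id,
            )
        )
    return islands


def write_bed(islands: Iterable[CpGIsland], path: str | Path) -> None:
    """BED6-lite output: chrom, start, end, name, score = round(100*Obs/Exp)."""
    with open(path, "w") as fh:
        for i, isl in enumerate(islands, start=1):
            fh.write(
                f"{isl.seq_id}\t{isl.start}\t{isl.end}\tCpG_{i}\t{round(100 * isl.obs_exp)}\n"
            )
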