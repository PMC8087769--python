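"""Exact-match sgRNA quantification from adapter-trimmed FASTQ reads.

Each read increments at most one guide.  Two match policies:

* ``scan`` (default) — the spacer may sit anywhere in the read; the leftmost
  match wins (the shorter spacer on a tie at the same offset).  Robust to
  vector flanks and stagger bases of unknown layout.
* ``anchored`` — the spacer must start at a fixed offset.

No mismatch tolerance: the library is collision-free by construction, so a
read matches at most one guide and exact string lookup is sufficient.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Mapping

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .screen_model import CountMatrix, GuideLibrary, SampleSheet

__all__ = ["MatchPolicy", "SampleCounts", "count_sample", "count_screen", "FastqParseError"]

logger = logging.getLogger(__name__)


class FastqParseError(ValueError):
    """Malformed FASTQ record, annotated with the record index."""


@dataclass(frozen=True)
class MatchPolicy:
    """How a read is compared against the spacer catalogue."""

    mode: str = "scan"
    anchor_offset: int = 0
    min_read_length: int | None = None  # default: max guide length

    def __post_init__(self) -> None:
        if self.mode not in ("scan", "anchored"):
            raise ValueError(f"unknown match mode {self.mode!r}")
        if self.anchor_offset < 0:
            raise ValueError("anchor_offset must be >= 0")

    def resolve_min_length(self, library: GuideLibrary) -> int:
        base = self.min_read_length
        if base is None:
            base = library.max_guide_length()
        if self.mode == "anchored":
            need = self.anchor_offset + library.max_guide_length()
            if base < need:
                raise ValueError(
                    f"min_read_length {base} cannot satisfy anchor_offset "
                    f"{self.anchor_offset} + max guide length"
                )
        return base


@dataclass(frozen=True)
class SampleCounts:
    """One quantified sample: per-guide counts plus the read accounting."""

    counts: np.ndarray  # aligned to library.guide_ids
    unmatched: int
    short: int
    total_reads: int

    @property
    def matched(self) -> int:
        return int(self.counts.sum())

    @property
    def mapping_rate(self) -> float:
        usable = self.total_reads - self.short
        return self.matched / usable if usable else float("nan")


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(handle: IO[str]) -> Iterator[str]:
    """Yield read sequences, re-raising parse failures with a record index."""
    it = FastqGeneralIterator(handle)
    index = 0
    while True:
        try:
            _title, seq, _qual = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(f"FASTQ record {index}: {exc}") from exc
        yield seq.upper()
        index += 1


def count_sample(
    fastq: str | Path | IO[str],
    library: GuideLibrary,
    policy: MatchPolicy = MatchPolicy(),
) -> SampleCounts:
    """Count exact spacer matches in one FASTQ stream.

    Conservation invariant: ``matched + unmatched + short == total_reads``.
    """
    lookup = {r.sequence: i for i, r in enumerate(library.records)}
    lengths = sorted({len(r.sequence) for r in library.records})
    min_len = policy.resolve_min_length(library)
    counts = np.zeros(len(library), dtype=np.int64)
    unmatched = short = total = 0

    if hasattr(fastq, "read"):
        reads = _iter_fastq(fastq)  # type: ignore[arg-type]
    else:
        handle = _open_maybe_gzip(fastq)
        reads = _iter_fastq(handle)

    if policy.mode == "anchored":
        off = policy.anchor_offset
        for seq in reads:
            total += 1
            if len(seq) < min_len:
                short += 1
                continue
            for L in lengths:
                idx = lookup.get(seq[off : off + L])
                if idx is not None:
                    counts[idx] += 1
                    break
            else:
                unmatched += 1
    else:
        shortest = lengths[0]
        for seq in reads:
            total += 1
            if len(seq) < min_len:
                short += 1
                continue
            hit = None
            for start in range(len(seq) - shortest + 1):
                for L in lengths:
                    idx = lookup.get(seq[start : start + L])
                    if idx is not None:
                        hit = idx
                        break
                if hit is not None:
                    break
            if hit is None:
                unmatched += 1
            else:
                counts[hit] += 1

    return SampleCounts(counts=counts, unmatched=unmatched, short=short, total_reads=total)


def count_screen(
    sheet: SampleSheet,
    fastq_paths: Mapping[str, str | Path],
    library: GuideLibrary,
    policy: MatchPolicy = MatchPolicy(),
) -> CountMatrix:
    """Quantify every sample in the sheet; columns follow sheet order."""
    missing = [s for s in sheet.sample_ids if s not in fastq_paths]
    if missing:
        raise FileNotFoundError(f"no FASTQ given for sample(s): {missing}")
    columns = []
    unmatched: dict[str, int] = {}
    for sample_id in sheet.sample_ids:
        path = Path(fastq_paths[sample_id])
        if not path.exists():
            raise FileNotFoundError(f"sample {sample_id!r}: {path} does not exist")
        sc = count_sample(path, library, policy)
        if sc.total_reads == 0:
            logger.warning("sample %s: zero reads", sample_id)
        else:
            logger.info(
                "sample %s: %d reads, mapping rate %.3f",
                sample_id, sc.total_reads, sc.mapping_rate,
            )
        columns.append(sc.counts)
        unmatched[sample_id] = sc.unmatched
    counts = np.column_stack(columns) if columns else np.zeros((len(library), 0), int)
    return CountMatrix(library.guide_ids, sheet.sample_ids, counts, unmatched)
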