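"""Deconvolution of pooled-screen readouts into per-shRNA abundances.

Sequencing reads are assigned by exact prefix match against the hairpin
reference — the custom sequencing primer anneals immediately adjacent
to the hairpin, so every read starts at a fixed position on the forward
strand and zero mismatches are tolerated.  Presence calls follow the
platform conventions: an alignment-count threshold for sequencing, a
one-sided one-sample t-test on background-subtracted intensities for
arrays.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from poolscreen.library import LibrarySpec


@dataclass
class CountResult:
    """Exact-match counting result for one sample."""

    counts: pd.Series  # indexed by shRNA id
    unassigned: int

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum()) + self.unassigned


def _open_maybe_gz(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_read_seqs(reads) -> Iterator[str]:
    """Yield read sequences from a FASTQ path/handle or an iterable of
    strings/SeqRecords."""
    if isinstance(reads, (str, Path)):
        with _open_maybe_gz(reads) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)
        return
    for r in reads:
        yield r if isinstance(r, str) else str(r.seq)


def count_reads(
    reads,
    lib: LibrarySpec,
    read_len: int = 50,
    mode: str = "prefix",
) -> CountResult:
    """Tally reads against the hairpin reference by exact match.

    A read is assigned to clone *i* iff its first ``read_len`` bases
    equal the first ``read_len`` bases of clone *i*'s reference
    (``mode="prefix"``, the default: the sequencing primer fixes read
    start and orientation).  ``mode="substring"`` instead assigns a
    read when its prefix occurs anywhere on the forward strand of
    exactly one reference, for library designs without an anchored
    primer.  Unmatched reads are counted as unassigned;
    ``assigned + unassigned == total``.

    Raises at index build if two references share a ``read_len``
    prefix (ambiguous assignment).
    """
    if lib.hairpin_seqs is None:
        raise ValueError("library has no hairpin sequences")
    if mode not in ("prefix", "substring"):
        raise ValueError(f"unknown matching mode {mode!r}")
    index: dict[str, int] = {}
    for i, seq in enumerate(lib.hairpin_seqs):
        if len(seq) < read_len:
            raise ValueError(f"reference {lib.shrna_ids[i]} shorter than read_len={read_len}")
        key = seq[:read_len]
        if key in index:
            raise ValueError(
                f"ambiguous reference: {lib.shrna_ids[index[key]]} and "
                f"{lib.shrna_ids[i]} share a {read_len}-base prefix"
            )
        index[key] = i

    counts = np.zeros(lib.pool_size, dtype=np.int64)
    unassigned = 0
    if mode == "prefix":
        for seq in _iter_read_seqs(reads):
            i = index.get(seq[:read_len])
            if i is None:
                unassigned += 1
            else:
                counts[i] += 1
    else:
        for seq in _iter_read_seqs(reads):
            query = seq[:read_len]
            matches = [i for ref_seq, i in ((s, j) for j, s in enumerate(lib.hairpin_seqs)) if query in ref_seq]
            if len(matches) == 1:
                counts[matches[0]] += 1
            else:
                unassigned += 1
    return CountResult(counts=pd.Series(counts, index=lib.shrna_ids), unassigned=unassigned)


def presence_ngs(
    counts: pd.Series | np.ndarray,
    min_alignments: int = 50,
    inclusive: bool = False,
) -> tuple[pd.Series, float]:
    """Presence calls for a sequencing sample.

    A hairpin is present when it has more than ``min_alignments``
    alignments (strict ``>``; set ``inclusive=True`` for ``>=``).
    Returns (boolean flags, percent of the pool present).
    """
    values = pd.Series(counts) if not isinstance(counts, pd.Series) else counts
    flags = values >= min_alignments if inclusive else values > min_alignments
    return flags, 100.0 * float(flags.sum()) / len(values)


def presence_array(intensities) -> tuple[bool, float]:
    """Presence call for one clone on the array platform.

    One-sided one-sample t-test of the background-subtracted replicate
    intensities against 0 (alternative: mean > 0); present iff
    p < 0.05.  Returns (present, p_value).  Degenerate inputs follow
    the limit of the test: zero variance with positive mean is present
    (p -> 0), all-zero input is absent.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two replicate intensities")
    if np.ptp(x) == 0.0:
        if x[0] > 0:
            return True, 0.0
        return False, 1.0
    t, p = stats.ttest_1samp(x, 0.0, alternative="greater")
    return bool(p < 0.05), float(p)


def presence_array_matrix(probe_frames: Iterable[pd.DataFrame]) -> tuple[pd.Series, float]:
    """Vectorized presence calls across technical-replicate probe frames.

    ``probe_frames`` are per-sample DataFrames (clones x probes) of
    background-subtracted intensities; replicate measurements for each
    clone are pooled into one one-sided t-test per clone.
    """
    stacked = np.hstack([f.to_numpy() for f in probe_frames])
    index = next(iter(probe_frames)).index if isinstance(probe_frames, (list, tuple)) else None
    n = stacked.shape[1]
    if n < 2:
        raise ValueError("need at least two replicate intensities per clone")
    mean = stacked.mean(axis=1)
    sd = stacked.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = stats.t.sf(t, df=n - 1)
    p = np.where(sd == 0.0, np.where(mean > 0, 0.0, 1.0), p)
    flags = pd.Series(p < 0.05, index=index)
    return flags, 100.0 * float(flags.sum()) / len(flags)
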