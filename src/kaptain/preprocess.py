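"""Read quality filtering and nested yield downsampling.

Long-read shotgun samples are first quality filtered (reads longer than
1,000 bp with a mean Phred score of at least 10 are kept) and then
downsampled to a ladder of fixed base yields (e.g. 200M, 500M, 1000M, 1500M,
2000M bases) such that every higher-yield subset contains the lower-yield
subsets.  Nesting is obtained by drawing one seeded permutation of the
filtered reads and taking, for each target yield, the shortest prefix whose
cumulative base count reaches the target.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Literal, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

QualityMean = Literal["error_rate", "arithmetic"]


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with its per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def mean_quality(self, method: QualityMean = "error_rate") -> float:
        """Mean Phred score of the read.

        ``error_rate`` converts each Q to an error probability, averages the
        probabilities and converts back (-10*log10(mean(10^(-Q/10)))) — the
        convention of common read-QC tools; ``arithmetic`` is the plain mean
        of the Q values.  The error-rate mean is always <= the arithmetic
        mean, so it is the stricter filter criterion.
        """
        if not self.qualities:
            return 0.0
        q = np.asarray(self.qualities, dtype=float)
        if method == "arithmetic":
            return float(q.mean())
        if method == "error_rate":
            return float(-10.0 * math.log10(np.mean(10.0 ** (-q / 10.0))))
        raise ValueError(f"unknown quality mean method {method!r}")


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Parse FASTQ (optionally gzipped) into ReadRecords.

    A malformed record raises a parse error carrying the record index.
    """
    with _open_maybe_gzip(path) as handle:
        parser = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ record at index {index}: {exc}"
                ) from exc
            yield ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
            index += 1


def write_fastq(path: str | Path, reads: Iterable[ReadRecord]) -> int:
    """Write reads as 4-line FASTQ (gzipped if the path ends in .gz)."""
    n = 0
    with _open_maybe_gzip(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def quality_filter(
    reads: Iterable[ReadRecord],
    min_length: int = 1000,
    min_mean_q: float = 10.0,
    quality_mean: QualityMean = "error_rate",
) -> Iterator[ReadRecord]:
    """Keep reads strictly longer than ``min_length`` with mean Phred score
    at least ``min_mean_q``; input order is preserved.

    The length cutoff is exclusive ("longer than 1,000 bp") while the
    quality cutoff is inclusive ("at least 10"); both are configurable.
    """
    for read in reads:
        if read.length > min_length and read.mean_quality(quality_mean) >= min_mean_q:
            yield read


@dataclass(frozen=True)
class YieldSubset:
    """The reads selected for one target yield."""

    target_bases: int
    read_ids: frozenset[str]
    n_bases: int
    attained: bool

    def __len__(self) -> int:
        return len(self.read_ids)


def downsample_nested(
    reads: Sequence[ReadRecord],
    targets: Sequence[int],
    seed: int = 0,
) -> dict[int, YieldSubset]:
    """Downsample to each target base yield with the nested-subset property.

    A single permutation of the reads is drawn from ``seed``; the subset for
    a target is the shortest permutation prefix whose cumulative base count
    reaches the target, so for targets a < b, subset(a) is contained in
    subset(b).  A target exceeding the total base count gets all reads and
    is flagged unattained.  Deterministic for a fixed seed.
    """
    targets = list(targets)
    if targets != sorted(targets):
        raise ValueError("targets must be sorted ascending")
    if any(t <= 0 for t in targets):
        raise ValueError("targets must be positive base counts")
    if not reads:
        logger.warning("downsample_nested: empty input; all subsets empty")
        return {
            t: YieldSubset(t, frozenset(), 0, attained=False) for t in targets
        }
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    lengths = np.array([reads[i].length for i in order], dtype=np.int64)
    cumulative = np.cumsum(lengths)
    result: dict[int, YieldSubset] = {}
    for target in targets:
        cut = int(np.searchsorted(cumulative, target, side="left")) + 1
        attained = cut <= len(reads) and cumulative[cut - 1] >= target
        cut = min(cut, len(reads))
        ids = frozenset(reads[i].read_id for i in order[:cut])
        if not attained:
            logger.warning(
                "target yield %d exceeds total bases %d; subset = all reads",
                target, int(cumulative[-1]),
            )
        result[target] = YieldSubset(
            target_bases=target,
            read_ids=ids,
            n_bases=int(cumulative[cut - 1]),
            attained=attained,
        )
    return result


def parse_yield(text: str) -> int:
    """Parse a yield label such as '200M', '1.5G' or '5000000' into bases."""
    text = text.strip()
    multipliers = {"K": 10**3, "M": 10**6, "G": 10**9}
    if text and text[-1].upper() in multipliers:
        return int(float(text[:-1]) * multipliers[text[-1].upper()])
    return int(float(text))
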