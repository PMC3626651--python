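"""Per-library insert-size profiling and upper-threshold estimation.

The threshold drives discordant-pair screening: the first 5000 correctly
oriented pairs with positive insert size are binned at 10 bp; the modal
bin is the library's typical insert; scanning upward from the mode, the
threshold is the upper edge of the first bin whose count ratio to the next
bin falls below 1.1 (the histogram has flattened into its tail), plus a
50 bp safety margin.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable

from .mapping import ReadPairRecord


class InsertProfileError(ValueError):
    pass


@dataclass(frozen=True)
class InsertProfile:
    library: str
    histogram: dict[int, int]  # bin lower edge -> count, 10 bp bins
    mode_bin: int
    upper_threshold: int
    n_used: int
    bin_width: int = 10

    @property
    def library_class(self) -> str:
        """"short" or "long" insert library (split at a 1 kb mode)."""
        return "short" if self.mode_bin < 1000 else "long"

    def to_json(self) -> str:
        return json.dumps(
            {
                "library": self.library,
                "mode_bin": self.mode_bin,
                "upper_threshold": self.upper_threshold,
                "n_used": self.n_used,
                "bin_width": self.bin_width,
                "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            }
        )


def scan_threshold(
    histogram: dict[int, int],
    mode_bin: int,
    bin_width: int = 10,
    ratio: float = 1.1,
    margin: int = 50,
) -> int:
    """Upward scan from the mode for the first count ratio < ``ratio``.

    An empty next bin marks the end of the library's contiguous insert
    distribution and stops the scan there (rearrangement-spanning pairs
    can place isolated counts far beyond the distribution; scanning into
    them would inflate the threshold by orders of magnitude). In either
    case the threshold is the stopping bin's upper edge plus the
    ``margin`` (50 bp).
    """
    b = mode_bin
    while True:
        nxt = histogram.get(b + bin_width, 0)
        if nxt == 0:
            return b + bin_width + margin
        if histogram.get(b, 0) / nxt < ratio:
            return b + bin_width + margin
        b += bin_width


def estimate_insert_profile(
    pairs: Iterable[ReadPairRecord],
    library: str,
    sample_size: int = 5000,
    bin_width: int = 10,
    ratio: float = 1.1,
    margin: int = 50,
    min_pairs: int = 100,
) -> InsertProfile:
    """Profile a library from the first ``sample_size`` eligible pairs.

    Eligible pairs are same-sequence, forward/reverse oriented, with
    insert size > 0, taken in stream order (the estimate deliberately
    depends on the stream head, mirroring estimation from the first lane
    of sequencing).
    """
    inserts: list[int] = []
    for rec in pairs:
        if rec.library != library:
            continue
        ins = rec.insert_size
        if ins > 0:
            inserts.append(ins)
            if len(inserts) >= sample_size:
                break
    if len(inserts) < min_pairs:
        raise InsertProfileError(
            f"library {library!r}: only {len(inserts)} eligible pairs "
            f"(need >= {min_pairs})"
        )
    histogram: dict[int, int] = {}
    for ins in inserts:
        b = (ins // bin_width) * bin_width
        histogram[b] = histogram.get(b, 0) + 1
    mode_bin = max(histogram, key=lambda b: (histogram[b], -b))
    if len(histogram) == 1:
        warnings.warn(
            f"library {library!r}: degenerate single-bin insert histogram",
            stacklevel=2,
        )
    threshold = scan_threshold(histogram, mode_bin, bin_width, ratio, margin)
    return InsertProfile(
        library=library,
        histogram=histogram,
        mode_bin=mode_bin,
        upper_threshold=threshold,
        n_used=len(inserts),
        bin_width=bin_width,
    )


def thresholds_for_categorization(
    profiles: dict[str, InsertProfile]
) -> dict[str, tuple[int, str]]:
    """Adapt profiles to the (threshold, library class) mapping the mapper uses."""
    return {
        lib: (p.upper_threshold, p.library_class) for lib, p in profiles.items()
    }
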