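"""The published top-20 instrument ranking and its percentage convention.

The source ranking prints, for each of the 20 most-used instruments, a
document count and a percentage of all scale occurrences in the corpus.
The percentage denominator (the corpus-wide occurrence total) is not
printed; :func:`recover_total` finds it by brute-force scan as the unique
total under which two-decimal *truncation* of ``100*count/total``
reproduces every printed percentage cell.
"""

from __future__ import annotations

from importlib import resources

from .network import truncate2

__all__ = ["published_ranking", "recover_total", "count_over_threshold"]


def published_ranking() -> list[tuple[int, str, int, float]]:
    """(rank, canonical_name, count, printed_percentage) rows of the
    published top-20 ranking (packaged data)."""
    text = resources.files("scalemine.data").joinpath("table1.tsv").read_text("utf-8")
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rank, name, count, pct = line.split("\t")
        rows.append((int(rank), name, int(count), float(pct)))
    return rows


def recover_total(
    counts: list[int],
    percentages: list[float],
    lo: int = 1000,
    hi: int = 1300,
) -> list[int]:
    """All totals T in [lo, hi] under which truncation reproduces every cell."""
    hits = []
    for total in range(lo, hi + 1):
        if all(abs(truncate2(c, total) - p) < 1e-9 for c, p in zip(counts, percentages)):
            hits.append(total)
    return hits


def count_over_threshold(rows, threshold: int = 100) -> list[str]:
    """Names of instruments whose published count exceeds ``threshold``."""
    return [name for _, name, count, _ in rows if count > threshold]
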