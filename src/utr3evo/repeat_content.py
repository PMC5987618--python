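"""Repeat coverage of genomic features and the paired signed-rank test.

Repeat annotations (RepeatMasker ``.out`` or BED) are normalized to
0-based half-open intervals, merged class-agnostically per chromosome,
and intersected with feature intervals (3'UTR, 5'UTR, CDS) to give the
fraction of feature bases covered by repeats; the genome-wide fraction
uses full chromosome lengths.  The per-species paired comparison of
genome vs 3'UTR fractions uses an exact two-sided Wilcoxon signed-rank
test (full sign-assignment distribution up to n = 25, normal
approximation with continuity correction beyond).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

Interval = tuple[int, int]  # 0-based half-open

__all__ = [
    "RepeatFractionReport",
    "merge_intervals",
    "intersect_size",
    "read_bed",
    "read_repeatmasker_out",
    "repeat_fraction",
    "signed_rank_distribution",
    "paired_signed_rank",
]


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals on one chromosome: sorted, disjoint."""
    out: list[list[int]] = []
    for a, b in sorted(intervals):
        if a > b:
            raise ValueError(f"inverted interval ({a}, {b})")
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def intersect_size(a: list[Interval], b: list[Interval]) -> int:
    """Total overlap (in bases) between two interval sets on one chromosome."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def read_bed(source) -> pd.DataFrame:
    """BED3+ -> DataFrame(chrom, start, end[, family]); 0-based half-open."""
    df = pd.read_csv(source, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "family"})
    cols = ["chrom", "start", "end"] + (["family"] if 3 in df.columns or "family" in df.columns else [])
    return df[[c for c in ["chrom", "start", "end", "family"] if c in df.columns]]


def read_repeatmasker_out(source) -> pd.DataFrame:
    """RepeatMasker ``.out`` -> DataFrame(chrom, start, end, family).

    Skips the two header lines; coordinates are converted from 1-based
    inclusive to 0-based half-open.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    rows = []
    with (open(source) if isinstance(source, str) else _as_handle(source)) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue  # header / blank lines
            chrom, start, end = parts[4], int(parts[5]), int(parts[6])
            family = parts[10] if len(parts) > 10 else "unknown"
            rows.append({"chrom": chrom, "start": start - 1, "end": end, "family": family})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])


class _as_handle:
    def __init__(self, handle):
        self.handle = handle

    def __enter__(self):
        return self.handle

    def __exit__(self, *exc):
        return False


@dataclass
class RepeatFractionReport:
    """Repeat-covered fraction (and base counts) per feature class."""

    species: str
    fractions: dict[str, float]  # class -> fraction in [0,1] (NaN if undefined)
    repeat_bases: dict[str, int]
    feature_bases: dict[str, int]


def _by_chrom(df_or_list) -> dict[str, list[Interval]]:
    if isinstance(df_or_list, pd.DataFrame):
        out: dict[str, list[Interval]] = {}
        for chrom, sub in df_or_list.groupby("chrom"):
            out[str(chrom)] = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
        return out
    out = {}
    for chrom, a, b in df_or_list:
        out.setdefault(chrom, []).append((int(a), int(b)))
    return out


def repeat_fraction(
    features: dict[str, list | pd.DataFrame],
    repeats,
    chrom_sizes: dict[str, int],
    species: str = "",
) -> RepeatFractionReport:
    """Fraction of repeat-covered bases per feature class and genome-wide.

    ``features`` maps class name (e.g. utr3, utr5, cds) to intervals as
    (chrom, start, end) triples or a DataFrame; ``repeats`` likewise.
    A class with no bases gets fraction NaN (reported missing).
    """
    rep = {c: merge_intervals(iv) for c, iv in _by_chrom(repeats).items()}
    fractions: dict[str, float] = {}
    repeat_bases: dict[str, int] = {}
    feature_bases: dict[str, int] = {}

    genome_total = sum(chrom_sizes.values())
    genome_repeat = sum(sum(b - a for a, b in ivs) for ivs in rep.values())
    fractions["genome"] = genome_repeat / genome_total if genome_total else math.nan
    repeat_bases["genome"] = genome_repeat
    feature_bases["genome"] = genome_total

    for cls, ivs in features.items():
        per_chrom = {c: merge_intervals(v) for c, v in _by_chrom(ivs).items()}
        nbase = sum(sum(b - a for a, b in v) for v in per_chrom.values())
        novl = sum(
            intersect_size(v, rep.get(c, [])) for c, v in per_chrom.items()
        )
        feature_bases[cls] = nbase
        repeat_bases[cls] = novl
        fractions[cls] = novl / nbase if nbase else math.nan
    return RepeatFractionReport(species, fractions, repeat_bases, feature_bases)


def signed_rank_distribution(ranks: list[float]) -> dict[int, float]:
    """Exact null distribution of the signed-rank sum for given |ranks|.

    Ranks may be half-integers (average ranks under ties); internally
    doubled to integers.  Returns {2*W: probability}.
    """
    doubled = [int(round(2 * r)) for r in ranks]
    if any(abs(2 * r - d) > 1e-9 for r, d in zip(ranks, doubled)):
        raise ValueError("ranks must be multiples of 0.5")
    dist = {0: 1.0}
    for r in doubled:
        new: dict[int, float] = {}
        for s, p in dist.items():
            new[s] = new.get(s, 0.0) + 0.5 * p
            new[s + r] = new.get(s + r, 0.0) + 0.5 * p
        dist = new
    return dist


def paired_signed_rank(pairs: list[tuple[float, float]]) -> float:
    """Exact two-sided Wilcoxon signed-rank p for paired fractions.

    ``pairs`` are per-species (genome_fraction, utr3_fraction) tuples.
    Zero differences are dropped before ranking (classic convention);
    all-zero input is an error.  For n <= 25 the p-value comes from the
    full 2^n sign-assignment distribution (via the equivalent
    rank-convolution); larger n uses the normal approximation with
    tie correction and continuity correction.
    """
    diffs = np.array([b - a for a, b in pairs], dtype=float)
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        raise ValueError("all differences are zero")
    order = np.abs(diffs)
    ranks = pd.Series(order).rank(method="average").to_numpy()
    w_pos = float(ranks[diffs > 0].sum())
    if n <= 25:
        dist = signed_rank_distribution(list(ranks))
        w2 = int(round(2 * w_pos))
        lower = sum(p for s, p in dist.items() if s <= w2)
        upper = sum(p for s, p in dist.items() if s >= w2)
        return min(1.0, 2.0 * min(lower, upper))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(order, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / math.sqrt(var)
    from scipy.stats import norm

    return float(2.0 * norm.sf(abs(z)))
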