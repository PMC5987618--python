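"""Gene families from pairwise protein similarity, and 1:1 orthologs.

Input is precomputed all-against-all BLASTP in tabular form (outfmt 6).
High-scoring segment pairs (HSPs) between a gene pair are conjoined by
maximum-weight colinear chaining of bit scores; genes are then clustered
into families by hierarchical average-linkage agglomeration on the
conjoined scores (weight floor 5 bits, merge-ratio 0.33, size cap
100000 by default), and families with exactly one member in every
species form the 1:1 ortholog table.

Gene identifiers are species-qualified as ``species|gene``; the species
accessor is pluggable for other naming schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

DEFAULT_EVALUE_CUTOFF = 1e-10
DEFAULT_MIN_WEIGHT = 5.0
DEFAULT_MIN_RATIO = 0.33
DEFAULT_MAX_SIZE = 100000


@dataclass(frozen=True)
class HSP:
    """One local alignment segment (1-based inclusive coordinates)."""

    qstart: int
    qend: int
    sstart: int
    send: int
    bits: float
    evalue: float = 0.0


def default_species_of(gene_id: str) -> str:
    return gene_id.split("|", 1)[0]


def read_similarity(
    source, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> dict[tuple[str, str], list[HSP]]:
    """Parse BLAST outfmt-6 into HSP lists per directed gene pair.

    HSPs with E-value above the cutoff and self hits are dropped;
    malformed rows are skipped with a log message.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        if not set(BLAST6_COLUMNS) <= set(df.columns):
            df.columns = BLAST6_COLUMNS[: len(df.columns)]
    else:
        df = pd.read_csv(
            source, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#"
        )
    pairs: dict[tuple[str, str], list[HSP]] = {}
    for row in df.itertuples(index=False):
        try:
            q, s = str(row.qseqid), str(row.sseqid)
            hsp = HSP(
                qstart=int(row.qstart),
                qend=int(row.qend),
                sstart=int(row.sstart),
                send=int(row.send),
                bits=float(row.bitscore),
                evalue=float(row.evalue),
            )
        except (TypeError, ValueError) as exc:
            log.warning("skipping malformed similarity row %r: %s", row, exc)
            continue
        if q == s:
            continue
        if hsp.evalue > evalue_cutoff:
            continue
        pairs.setdefault((q, s), []).append(hsp)
    return pairs


def conjoin_hsps(hsps: list[HSP]) -> float:
    """Score of the best colinear non-overlapping chain of HSPs.

    Dynamic programming over HSPs sorted by query start: a chain may
    extend an earlier HSP only if it starts strictly after that HSP ends
    in both query and subject; the chain weight is the summed bit
    scores.
    """
    if not hsps:
        raise ValueError("no HSPs")
    order = sorted(hsps, key=lambda h: (h.qstart, h.qend, h.sstart))
    best = [h.bits for h in order]
    for i, hi in enumerate(order):
        for j in range(i):
            hj = order[j]
            if hj.qend < hi.qstart and hj.send < hi.sstart:
                cand = best[j] + hi.bits
                if cand > best[i]:
                    best[i] = cand
    return max(best)


def build_edges(
    pairs: dict[tuple[str, str], list[HSP]]
) -> dict[frozenset, float]:
    """Symmetric conjoined-score edges: max over the two directions."""
    edges: dict[frozenset, float] = {}
    for (q, s), hsps in pairs.items():
        key = frozenset((q, s))
        score = conjoin_hsps(hsps)
        if score > edges.get(key, 0.0):
            edges[key] = score
    return edges


def cluster_families(
    genes: list[str],
    edges: dict[frozenset, float],
    min_weight: float = DEFAULT_MIN_WEIGHT,
    min_ratio: float = DEFAULT_MIN_RATIO,
    max_size: int = DEFAULT_MAX_SIZE,
) -> list[set[str]]:
    """Average-linkage agglomeration with a merge-quality ratio test.

    Edges below ``min_weight`` are removed.  Repeatedly, the cluster
    pair with the highest between-cluster average similarity (absent
    edges count as 0; ties broken by the lexicographically smallest
    member pair) is merged, provided the between average is at least
    ``min_ratio`` times the internal average similarity of the smaller
    cluster (size ties resolved to the cluster holding the
    lexicographically smallest member; singletons always pass) and the
    merged size is within
    ``max_size``.  Stops when no candidate pair passes.  Every input
    gene ends up in exactly one family.
    """
    genes = sorted(set(genes))
    clusters: dict[str, set[str]] = {g: {g} for g in genes}
    # incremental sums: between[(r1, r2)] = total cross weight (only kept
    # when > 0); internal[r] = total within weight
    between: dict[tuple[str, str], float] = {}
    internal: dict[str, float] = {g: 0.0 for g in genes}
    for k, w in edges.items():
        if w < min_weight:
            continue
        a, b = sorted(k)
        if a in internal and b in internal:
            between[(a, b)] = between.get((a, b), 0.0) + w

    while True:
        candidates = []
        for (r1, r2), total in between.items():
            n1, n2 = len(clusters[r1]), len(clusters[r2])
            candidates.append((-total / (n1 * n2), r1, r2))
        candidates.sort()
        merged = None
        for neg_ab, r1, r2 in candidates:
            c1, c2 = clusters[r1], clusters[r2]
            if len(c1) + len(c2) > max_size:
                continue
            # smaller cluster (size ties -> smaller lexicographic rep,
            # which is r1 since r1 < r2)
            if len(c1) != len(c2):
                small = r1 if len(c1) < len(c2) else r2
            else:
                small = r1
            n_small = len(clusters[small])
            if n_small > 1:
                avg_int = internal[small] / (n_small * (n_small - 1) / 2)
                if -neg_ab < min_ratio * avg_int:
                    continue
            merged = (r1, r2)
            break
        if merged is None:
            return [clusters[r] for r in sorted(clusters)]
        r1, r2 = merged
        union = clusters[r1] | clusters[r2]
        new = min(union)
        internal_new = (
            internal[r1] + internal[r2] + between.pop((r1, r2), 0.0)
        )
        neighbor_sums: dict[str, float] = {}
        for pair in [p for p in between if r1 in p or r2 in p]:
            a, b = pair
            other = b if a in (r1, r2) else a
            neighbor_sums[other] = neighbor_sums.get(other, 0.0) + between.pop(pair)
        del clusters[r1], clusters[r2], internal[r1], internal[r2]
        clusters[new] = union
        internal[new] = internal_new
        for other, total in neighbor_sums.items():
            between[tuple(sorted((new, other)))] = total


def one_to_one(
    families: list[set[str]],
    species: list[str],
    species_of=default_species_of,
) -> pd.DataFrame:
    """Families with exactly one member per species, as a species table."""
    if not species:
        raise ValueError("species list is empty")
    rows = []
    for fam_idx, fam in enumerate(families):
        by_sp: dict[str, list[str]] = {}
        for g in sorted(fam):
            by_sp.setdefault(species_of(g), []).append(g)
        if set(by_sp) == set(species) and all(
            len(v) == 1 for v in by_sp.values()
        ):
            rows.append(
                {"family_id": f"fam{fam_idx:05d}", **{sp: by_sp[sp][0] for sp in species}}
            )
    return pd.DataFrame(rows, columns=["family_id", *species])
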