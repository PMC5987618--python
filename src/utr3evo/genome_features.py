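"""Transcript models, canonical-transcript selection, and UTR extraction.

GFF3 coordinates are 1-based inclusive throughout the public types
(matching the format); interval arithmetic converts at the boundary.
A gene's canonical transcript is its stop-codon-bearing isoform with the
longest spliced coding region: transcripts whose annotated CDS does not
end in TAA/TAG/TGA are taken as degraded or partial models and never
selected.  The 3'UTR is everything in the spliced mRNA strictly
downstream of the stop codon (the annotated CDS is assumed to include
the stop codon); zero-length UTRs are real observations and are kept in
summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptModel:
    """One isoform's exon/CDS structure on a chromosome.

    ``exons`` are 1-based inclusive genomic intervals, sorted and
    non-overlapping; ``cds_start``/``cds_end`` span the CDS including
    the stop codon.  ``stop_ok`` records whether the spliced CDS ends in
    a stop codon (set during parsing, when the genome is at hand).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    stop_ok: bool = True

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        for (a, b) in self.exons:
            if a > b or a < 1:
                raise ValueError(f"{self.transcript_id}: bad exon ({a},{b})")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c <= b:
                raise ValueError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
        if not (self.cds_start <= self.cds_end):
            raise ValueError(f"{self.transcript_id}: inverted CDS span")

        def inside(p):
            return any(a <= p <= b for a, b in self.exons)

        if not (inside(self.cds_start) and inside(self.cds_end)):
            raise ValueError(f"{self.transcript_id}: CDS outside exon union")
        cds_len = self.spliced_cds_length()
        if cds_len <= 0 or cds_len % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: spliced CDS length {cds_len} "
                "not a positive multiple of 3"
            )

    def spliced_cds_length(self) -> int:
        return sum(
            max(0, min(b, self.cds_end) - max(a, self.cds_start) + 1)
            for a, b in self.exons
        )

    def spliced_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)


@dataclass
class FeatureSequences:
    """5'UTR / CDS / 3'UTR of one transcript, in mRNA orientation."""

    utr5_seq: str
    cds_seq: str
    utr3_seq: str

    @property
    def L5(self) -> int:
        return len(self.utr5_seq)

    @property
    def Lc(self) -> int:
        return len(self.cds_seq)

    @property
    def L3(self) -> int:
        return len(self.utr3_seq)


@dataclass
class LengthSummary:
    """Per-species 3'UTR length summary (Table-1-style)."""

    n: int
    total: int
    percent_of_genome: float
    mean: float
    median: float
    q25: float
    q75: float
    maximum: int


def read_genome(fasta) -> dict[str, str]:
    """Chromosome sequences from a FASTA path or handle."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta, "fasta")}


def parse_annotation(
    gff3, genome: dict[str, str]
) -> tuple[dict[str, list[TranscriptModel]], list[tuple[str, str]]]:
    """Parse a GFF3 into per-gene transcript models.

    Accepts a path or raw GFF3 text.  Returns (transcripts grouped by
    gene_id, rejected records as (transcript_id, reason)).  Transcripts
    failing structural invariants (CDS outside exons, CDS length not a
    multiple of 3, unknown chromosome, missing parent) are rejected with
    a logged reason; transcripts whose spliced CDS lacks a terminal stop
    codon are kept but flagged ``stop_ok=False``.
    """
    from_string = isinstance(gff3, str) and "\n" in gff3
    db = gffutils.create_db(
        gff3,
        dbfn=":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    by_gene: dict[str, list[TranscriptModel]] = {}
    rejected: list[tuple[str, str]] = []
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id
        parents = mrna.attributes.get("Parent", [])
        if not parents:
            rejected.append((tid, "missing Parent link"))
            log.warning("rejected %s: missing Parent link", tid)
            continue
        gene_id = parents[0]
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_parts = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        if not exons or not cds_parts:
            rejected.append((tid, "no exon or no CDS records"))
            log.warning("rejected %s: no exon or no CDS records", tid)
            continue
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
            cds_start=cds_parts[0][0],
            cds_end=cds_parts[-1][1],
        )
        if model.chrom not in genome:
            rejected.append((tid, f"unknown chromosome {model.chrom}"))
            log.warning("rejected %s: unknown chromosome %s", tid, model.chrom)
            continue
        try:
            model.validate()
        except ValueError as exc:
            rejected.append((tid, str(exc)))
            log.warning("rejected %s: %s", tid, exc)
            continue
        if model.exons[-1][1] > len(genome[model.chrom]):
            rejected.append((tid, "exon beyond chromosome end"))
            log.warning("rejected %s: exon beyond chromosome end", tid)
            continue
        feats = extract_features(model, genome)
        model.stop_ok = feats.cds_seq[-3:] in STOP_CODONS
        by_gene.setdefault(gene_id, []).append(model)
    return by_gene, rejected


def select_canonical(isoforms: list[TranscriptModel]) -> TranscriptModel | None:
    """Stop-codon-bearing isoform with the longest spliced CDS.

    Ties break to the lexicographically smallest transcript_id; returns
    None when no isoform carries a stop codon.
    """
    if not isoforms:
        raise ValueError("no isoforms given")
    with_stop = [t for t in isoforms if t.stop_ok]
    if not with_stop:
        return None
    return min(with_stop, key=lambda t: (-t.spliced_cds_length(), t.transcript_id))


def extract_features(
    t: TranscriptModel, genome: dict[str, str]
) -> FeatureSequences:
    """Splice the transcript and cut it at the CDS boundaries.

    Minus-strand transcripts are reverse-complemented so all returned
    sequences read 5'->3' on the mRNA; the 3'UTR is strictly downstream
    of the stop codon.
    """
    chrom_seq = genome[t.chrom]
    if t.exons[-1][1] > len(chrom_seq):
        raise ValueError(f"{t.transcript_id}: exon beyond chromosome end")
    spliced = "".join(chrom_seq[a - 1 : b] for a, b in t.exons)
    # spliced index of each genomic position, in plus orientation
    in_cds = np.concatenate(
        [
            (np.arange(a, b + 1) >= t.cds_start) & (np.arange(a, b + 1) <= t.cds_end)
            for a, b in t.exons
        ]
    )
    if t.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
        in_cds = in_cds[::-1]
    idx = np.flatnonzero(in_cds)
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    return FeatureSequences(
        utr5_seq=spliced[:lo], cds_seq=spliced[lo:hi], utr3_seq=spliced[hi:]
    )


def feature_intervals(t: TranscriptModel) -> dict[str, list[tuple[str, int, int]]]:
    """Genomic intervals (chrom, start, end; 0-based half-open) of the
    transcript's 5'UTR, CDS and 3'UTR pieces, split by exon."""
    out: dict[str, list[tuple[str, int, int]]] = {"utr5": [], "cds": [], "utr3": []}
    before, after = ("utr5", "utr3") if t.strand == "+" else ("utr3", "utr5")
    for a, b in t.exons:  # 1-based inclusive
        lo, hi = a - 1, b  # 0-based half-open
        cut1 = min(max(t.cds_start - 1, lo), hi)
        cut2 = min(max(t.cds_end, lo), hi)
        if cut1 > lo:
            out[before].append((t.chrom, lo, cut1))
        if cut2 > cut1:
            out["cds"].append((t.chrom, cut1, cut2))
        if hi > cut2:
            out[after].append((t.chrom, cut2, hi))
    return out


def length_histogram(lengths, window: int = 50) -> np.ndarray:
    """Counts of lengths in half-open bins [i*window, (i+1)*window)."""
    if window <= 0:
        raise ValueError("window must be positive")
    lengths = np.asarray(list(lengths), dtype=float)
    if lengths.size == 0:
        return np.zeros(0, dtype=int)
    if (lengths < 0).any():
        raise ValueError("negative length")
    bins = (lengths // window).astype(int)
    return np.bincount(bins)


def summarize_lengths(lengths, genome_size: int) -> LengthSummary:
    """Table-1-style summary; quantiles by linear interpolation."""
    lengths = np.asarray(list(lengths), dtype=float)
    if lengths.size == 0:
        raise ValueError("empty length list")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    total = int(lengths.sum())
    return LengthSummary(
        n=int(lengths.size),
        total=total,
        percent_of_genome=100.0 * total / genome_size,
        mean=float(lengths.mean()),
        median=float(np.median(lengths)),
        q25=float(np.percentile(lengths, 25)),
        q75=float(np.percentile(lengths, 75)),
        maximum=int(lengths.max()),
    )
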