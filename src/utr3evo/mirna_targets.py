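"""Strict-seed miRNA target scanning with a duplex free-energy cutoff.

A candidate target site requires perfect Watson-Crick complementarity
(no G:U wobble, no gaps) between miRNA positions 2-8 (the 7-nt seed) and
the 3'UTR.  Each candidate is scored by extending the seed pairing in
both directions along an ungapped duplex until the first mismatch, then
summing nearest-neighbor stacking free energies over the contiguous
helix; sites whose energy exceeds the cutoff (default -20 kcal/mol) are
discarded.  The stacking parameters ship with the package as a TSV and
are loaded at import of the scan, so a truncated table is a fatal
configuration error rather than a silent zero.

UTRs are handled as DNA (T) and miRNAs as RNA (U); normalization is
internal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

DEFAULT_ENERGY_CUTOFF = -20.0

_RNA = set("ACGU")
# miRNA base -> complementary target base (target handled in DNA)
_PAIR_DNA = {"A": "T", "U": "A", "G": "C", "C": "G"}

__all__ = [
    "DEFAULT_ENERGY_CUTOFF",
    "MatureMiRNA",
    "TargetSite",
    "StackTableError",
    "load_stack_table",
    "read_mirna_fasta",
    "seed_sites",
    "duplex_energy",
    "scan_utrs",
    "summarize_targets",
]


class StackTableError(RuntimeError):
    """The nearest-neighbor parameter table is missing or incomplete."""


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: name and 5'->3' RNA sequence (length >= 8)."""

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValueError(f"{self.name}: miRNA shorter than 8 nt")
        if set(seq) - _RNA:
            raise ValueError(f"{self.name}: non-ACGU characters in miRNA")

    @property
    def seed(self) -> str:
        """Positions 2-8 (1-based), the 7-nt seed."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class TargetSite:
    """One predicted binding site on a UTR (0-based half-open interval)."""

    utr_id: str
    start: int
    end: int
    seed_start: int
    mirna: str
    energy: float


def load_stack_table(path=None) -> dict[str, float]:
    """Load the Watson-Crick dinucleotide stacking table (kcal/mol).

    Raises StackTableError unless all 16 dinucleotide stacks are present.
    """
    if path is None:
        source = resources.files("utr3evo").joinpath("data/stack_energies.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    table = dict(zip(df["dinucleotide"].str.upper(), df["delta_g"].astype(float)))
    expected = {a + b for a in "ACGU" for b in "ACGU"}
    missing = expected - set(table)
    if missing:
        raise StackTableError(
            f"stacking table missing entries: {sorted(missing)}"
        )
    return table


def read_mirna_fasta(path) -> list[MatureMiRNA]:
    from Bio import SeqIO

    return [
        MatureMiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]


def _seed_complement(mirna: MatureMiRNA) -> str:
    """DNA string the UTR must contain for a strict seed match."""
    return "".join(_PAIR_DNA[b] for b in reversed(mirna.seed))


def seed_sites(utr_seq: str, mirna: MatureMiRNA) -> list[int]:
    """0-based UTR positions where the reverse complement of the seed
    (perfect Watson-Crick, no wobble) occurs.

    Windows containing ambiguity codes can never equal the ACGT-only
    seed complement, so they are skipped implicitly.
    """
    utr = utr_seq.upper().replace("U", "T")
    pat = _seed_complement(mirna)
    hits = []
    j = utr.find(pat)
    while j != -1:
        hits.append(j)
        j = utr.find(pat, j + 1)
    return hits


def _duplex_pairs(utr: str, mirna: MatureMiRNA, seed_start: int):
    """Maximal contiguous perfectly paired stretch through the seed.

    miRNA position i (1-based) pairs with UTR position seed_start+8-i.
    Extends from the seed toward miRNA position 1 and toward the 3' end,
    stopping at the first mismatch, non-ACGT base, or sequence end.
    Returns the (inclusive) miRNA position range [i_lo, i_hi].
    """
    m = mirna.sequence

    def paired(i: int) -> bool:
        j = seed_start + 8 - i
        if not (1 <= i <= len(m)) or not (0 <= j < len(utr)):
            return False
        return _PAIR_DNA[m[i - 1]] == utr[j]

    i_lo, i_hi = 2, 8
    while paired(i_lo - 1):
        i_lo -= 1
    while paired(i_hi + 1):
        i_hi += 1
    return i_lo, i_hi


def duplex_energy(
    utr_seq: str,
    mirna: MatureMiRNA,
    seed_start: int,
    table: dict[str, float] | None = None,
) -> float:
    """Nearest-neighbor stacking energy (kcal/mol) of the maximal
    contiguous duplex through a confirmed seed match.

    The energy is the sum of stack terms over adjacent base pairs; a
    degenerate duplex with fewer than two pairs scores 0.0.  More
    pairing can only add non-positive terms, so energy is monotonically
    non-increasing in duplex length.
    """
    if table is None:
        table = load_stack_table()
    utr = utr_seq.upper().replace("U", "T")
    i_lo, i_hi = _duplex_pairs(utr, mirna, seed_start)
    m = mirna.sequence
    energy = 0.0
    for i in range(i_lo, i_hi):
        key = m[i - 1] + m[i]
        if key not in table:
            raise StackTableError(f"no stacking entry for {key}")
        energy += table[key]
    return energy


def _site_from_seed(utr, mirna, seed_start, table):
    i_lo, i_hi = _duplex_pairs(utr, mirna, seed_start)
    energy = duplex_energy(utr, mirna, seed_start, table)
    start = seed_start + 8 - i_hi  # leftmost paired UTR base
    end = seed_start + 8 - i_lo + 1  # half-open
    return start, end, energy


def scan_utrs(
    utrs: dict[str, str],
    mirnas: list[MatureMiRNA],
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
    table: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scan UTRs for strict-seed sites passing the energy cutoff.

    Overlapping sites of the same miRNA on one UTR are collapsed
    greedily left to right.  Returns (site table, per-UTR site counts
    summed over miRNAs; every input UTR appears in the counts, with 0
    when nothing was found).
    """
    if table is None:
        table = load_stack_table()
    sites: list[TargetSite] = []
    counts = {}
    for utr_id in sorted(utrs):
        utr = utrs[utr_id].upper().replace("U", "T")
        n = 0
        for mirna in mirnas:
            last_end = -1
            for seed_start in seed_sites(utr, mirna):
                start, end, energy = _site_from_seed(utr, mirna, seed_start, table)
                if energy > energy_cutoff:
                    continue
                if start < last_end:  # overlaps previously kept site
                    continue
                sites.append(
                    TargetSite(utr_id, start, end, seed_start, mirna.name, energy)
                )
                last_end = end
                n += 1
        counts[utr_id] = n
    df = pd.DataFrame(
        [s.__dict__ for s in sites],
        columns=["utr_id", "start", "end", "seed_start", "mirna", "energy"],
    )
    return df, pd.Series(counts, name="n_sites", dtype=int)


def summarize_targets(counts: pd.Series) -> dict:
    """Per-species style aggregates of per-UTR site counts.

    The mean is taken over target-bearing UTRs (count >= 1); with no
    targets at all the mean is reported as NaN.
    """
    counts = pd.Series(counts, dtype=float)
    bearing = counts[counts >= 1]
    return {
        "total_sites": float(counts.sum()),
        "n_utrs": int(counts.size),
        "n_target_utrs": int(bearing.size),
        "mean_sites_per_target_utr": (
            float(bearing.mean()) if bearing.size else math.nan
        ),
        "max_sites": float(counts.max()) if counts.size else math.nan,
    }
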