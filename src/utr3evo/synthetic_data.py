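"""Self-contained synthetic datasets with known planted parameters.

Every stage of the 3'UTR pipeline can be exercised against data whose
ground truth is known exactly: a nine-taxon time-calibrated tree with a
five-species focal clade, per-gene 3'UTR lengths evolved under
clade-specific Brownian motion, toy genomes (FASTA + GFF3) whose
canonical transcripts carry those lengths, repeat tracks planted at
feature-specific densities, miRNA target sites written into UTRs with
guaranteed sub-threshold duplex energy, BLAST-like similarity tables
with planted gene families, and GO-style term maps with planted
enrichment.  All generators are pure functions of (config, seed).

The default tree mirrors the teleost phylogeny used throughout the
package: five cichlids (M. zebra, P. nyererei, H. burtoni,
N. brichardi, O. niloticus) as the focal clade and four model teleosts
(O. latipes, P. formosa, A. mexicanus, D. rerio) as background.  Node
ages are configurable defaults in Myr, not estimates.
"""

from __future__ import annotations

import dataclasses
import io
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clade_divergence as cd
from .clade_divergence import BACKGROUND, FOCAL

FOCAL_SPECIES = ("M_zebra", "P_nyererei", "H_burtoni", "N_brichardi", "O_niloticus")
BACKGROUND_SPECIES = ("O_latipes", "P_formosa", "A_mexicanus", "D_rerio")

#: Default node ages (Myr) for the 9-taxon tree; free parameters of the
#: simulation, chosen as round, order-of-magnitude-realistic values.
DEFAULT_NODE_AGES = {
    "root": 230.0,
    "otophysi": 150.0,  # A. mexicanus + D. rerio
    "ovalentaria": 110.0,  # cichlids + atherinomorphs
    "atherinomorpha": 90.0,  # O. latipes + P. formosa
    "cichlid_crown": 25.0,
    "lamprologini": 12.0,  # N. brichardi vs haplochromines
    "haplochromini": 6.0,  # H. burtoni vs (M. zebra, P. nyererei)
    "mbuna": 2.0,  # M. zebra vs P. nyererei
}

STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

#: Small fixed repeat library (labels only loosely evoke repeat classes;
#: coverage fractions, not biology, are what the simulation controls).
REPEAT_LIBRARY = {
    "SINE-like": "GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGA",
    "LINE-like": "AGGAGAATCGCTTGAACCCGGGAGGCGGAGGTTGCAGTGAGCCGAGATCG"
    "CGCCACTGCACTCCAGCCTGGGCGACAGAGCGAGACTCCGTCTCAAAAAA",
    "DNA-like": "CAGTGGTATCAACGCAGAGTACGCGGGGTTTTTTTTTTTTTTTTTTGGCA",
}


@dataclass
class SimulationConfig:
    """Planted parameters for one synthetic dataset.

    Rates are in nt^2/Myr, lengths in nt, densities as fractions of
    feature bases covered by repeats.
    """

    seed: int
    n_genes: int = 200
    sigma2_focal: float = 1.0
    sigma2_background: float = 1.0
    root_length: float = 800.0
    min_utr3: int = 50
    focal_length_factor: float = 1.0  # multiplies focal tip lengths post-BM
    utr5_length: int = 150
    cds_length: int = 300  # includes the stop codon; multiple of 3
    intron_length: int = 90
    intron_every: int = 3  # every k-th gene gets an intron in its 3'UTR
    intergenic_length: int = 300
    decoy_isoform_rate: float = 0.3
    stopless_decoy_rate: float = 0.2
    repeat_densities: dict = field(
        default_factory=lambda: {
            "utr3": 0.10,
            "utr5": 0.08,
            "cds": 0.02,
            "intergenic": 0.35,
        }
    )
    n_mirnas: int = 20
    mirna_length: int = 22
    planted_sites_per_utr: int = 1
    node_ages: dict = field(default_factory=lambda: dict(DEFAULT_NODE_AGES))
    focal_species: tuple = FOCAL_SPECIES
    background_species: tuple = BACKGROUND_SPECIES

    def __post_init__(self):
        if self.sigma2_focal < 0 or self.sigma2_background < 0:
            raise ValueError("rates must be >= 0")
        for k, v in self.repeat_densities.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"repeat density {k}={v} outside [0,1]")
        if self.cds_length % 3 != 0:
            raise ValueError("cds_length must be a multiple of 3")

    @property
    def species(self) -> tuple:
        return tuple(self.focal_species) + tuple(self.background_species)


# ---------------------------------------------------------------------------
# tree + traits


def default_newick(node_ages: dict | None = None) -> str:
    """Newick string of the default 9-taxon ultrametric tree."""
    a = dict(DEFAULT_NODE_AGES)
    if node_ages:
        a.update(node_ages)
    return (
        "((((((M_zebra:{mb},P_nyererei:{mb}):{hb_mb},H_burtoni:{hap}):{lam_hap},"
        "N_brichardi:{lam}):{cr_lam},O_niloticus:{cr}):{ov_cr},"
        "(O_latipes:{ath},P_formosa:{ath}):{ov_ath}):{rt_ov},"
        "(A_mexicanus:{oto},D_rerio:{oto}):{rt_oto});"
    ).format(
        mb=a["mbuna"],
        hb_mb=a["haplochromini"] - a["mbuna"],
        hap=a["haplochromini"],
        lam_hap=a["lamprologini"] - a["haplochromini"],
        lam=a["lamprologini"],
        cr_lam=a["cichlid_crown"] - a["lamprologini"],
        cr=a["cichlid_crown"],
        ov_cr=a["ovalentaria"] - a["cichlid_crown"],
        ath=a["atherinomorpha"],
        ov_ath=a["ovalentaria"] - a["atherinomorpha"],
        rt_ov=a["root"] - a["ovalentaria"],
        oto=a["otophysi"],
        rt_oto=a["root"] - a["otophysi"],
    )


def make_default_tree(config: SimulationConfig):
    """Build the default painted tree: (dendropy tree, regime painting)."""
    tree = cd.read_tree(default_newick(config.node_ages), is_path=False)
    cd.check_ultrametric(tree)
    painting = cd.paint_regimes(tree, set(config.focal_species))
    return tree, painting


def simulate_traits(
    tree,
    painting,
    sigma2_f: float,
    sigma2_b: float,
    root: float,
    n_genes: int,
    seed: int,
    focal_length_factor: float = 1.0,
) -> pd.DataFrame:
    """Per-gene tip values under two-regime BM (genes x species DataFrame).

    Tip values are the raw Brownian states (may be negative); flooring
    for genome building is applied separately so rate-fitting tests can
    use the exact model.  ``focal_length_factor`` multiplies focal tip
    values after simulation to plant a mean-length inflation.
    """
    rng = np.random.default_rng(seed)
    focal_tips = {
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if painting[leaf] == FOCAL
    }
    states = {id(tree.seed_node): np.full(n_genes, float(root))}
    tip_values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        rate = sigma2_f if painting[node] == FOCAL else sigma2_b
        sd = np.sqrt(rate * node.edge.length)
        states[id(node)] = states[id(node.parent_node)] + rng.normal(
            0.0, sd, n_genes
        )
        if node.is_leaf():
            tip_values[node.taxon.label] = states[id(node)]
    labels = sorted(tip_values)
    mat = np.column_stack([tip_values[lb] for lb in labels])
    if focal_length_factor != 1.0:
        for j, lb in enumerate(labels):
            if lb in focal_tips:
                mat[:, j] *= focal_length_factor
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    return pd.DataFrame(mat, index=genes, columns=labels)


def floor_lengths(traits: pd.DataFrame, min_utr3: int) -> pd.DataFrame:
    """Integer 3'UTR lengths for genome building: floor at min_utr3."""
    return traits.round().clip(lower=min_utr3).astype(int)


# ---------------------------------------------------------------------------
# genomes


@dataclass
class SyntheticGenome:
    """One species' toy genome with its annotation and ground truth."""

    species: str
    chrom: str
    sequence: str
    gff3: str
    truth: pd.DataFrame  # gene_id, transcript_id, strand, L5, Lc, L3
    #: genomic intervals (0-based half-open) of canonical-transcript
    #: features and intergenic filler, for repeat planting and checks
    feature_intervals: dict


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_cds(rng, n_nt: int) -> str:
    """CDS of n_nt nt ending in TAA, internal codons never stops."""
    n_codons = n_nt // 3 - 1
    body = rng.choice(_NONSTOP_CODONS, size=n_codons)
    return "".join(body) + "TAA"


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def build_genomes(
    lengths: pd.DataFrame, config: SimulationConfig
) -> dict[str, SyntheticGenome]:
    """Toy genome + GFF3 per species from floored 3'UTR lengths.

    Each gene gets a canonical isoform whose 3'UTR length equals the
    planted value; a configurable fraction of genes also carry a
    shorter-CDS decoy isoform and a stop-codon-free decoy isoform that
    canonical selection must never pick.  Strands alternate, and every
    ``intron_every``-th gene has an intron inside its 3'UTR.
    """
    genomes = {}
    for s_idx, species in enumerate(lengths.columns):
        rng = np.random.default_rng([config.seed, 1000 + s_idx])
        chrom = "chr1"
        parts: list[str] = []
        gff: list[str] = ["##gff-version 3"]
        truth_rows = []
        intervals: dict[str, list] = {
            "utr3": [],
            "utr5": [],
            "cds": [],
            "intergenic": [],
        }
        pos = 0  # 0-based running offset

        def filler(n):
            nonlocal pos
            parts.append(_random_seq(rng, n))
            intervals["intergenic"].append((pos, pos + n))
            pos += n

        filler(config.intergenic_length)
        for g_idx, gene_id in enumerate(lengths.index):
            l3 = int(lengths.loc[gene_id, species])
            u5, lc = config.utr5_length, config.cds_length
            strand = "+" if g_idx % 2 == 0 else "-"
            utr5 = _random_seq(rng, u5)
            cds = _random_cds(rng, lc)
            utr3 = _random_seq(rng, l3)
            spliced = utr5 + cds + utr3

            has_intron = (
                config.intron_every > 0
                and g_idx % config.intron_every == 0
                and l3 >= 60
            )
            if has_intron:
                cut = u5 + lc + min(30, l3 // 2)  # spliced cut inside 3'UTR
                intron = "GT" + _random_seq(rng, config.intron_length - 4) + "AG"
                genomic_sense = spliced[:cut] + intron + spliced[cut:]
                exons_sense = [(0, cut), (cut + config.intron_length, len(genomic_sense))]
            else:
                genomic_sense = spliced
                exons_sense = [(0, len(genomic_sense))]
            cds_sense = (u5, u5 + lc)  # contiguous: introns only in 3'UTR

            glen = len(genomic_sense)
            offset = pos
            if strand == "+":
                segment = genomic_sense
                to_genomic = lambda a, b: (offset + a, offset + b)
            else:
                segment = revcomp(genomic_sense)
                to_genomic = lambda a, b: (offset + glen - b, offset + glen - a)
            parts.append(segment)
            pos += glen

            # ground-truth feature intervals (canonical transcript)
            for a, b in exons_sense:
                for lo, hi, cls in (
                    (max(a, 0), min(b, u5), "utr5"),
                    (max(a, u5), min(b, u5 + lc), "cds"),
                    (max(a, u5 + lc), b, "utr3"),
                ):
                    if hi > lo:
                        intervals[cls].append(to_genomic(lo, hi))

            gstart, gend = offset + 1, offset + glen  # 1-based inclusive
            gff.append(
                f"{chrom}\tsim\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                f"ID={gene_id};Name={gene_id}"
            )

            isoforms = [("t1", exons_sense, cds_sense)]
            if config.decoy_isoform_rate > 0 and rng.random() < config.decoy_isoform_rate:
                isoforms.append(("t2", exons_sense, (u5 + 60, u5 + lc)))
            if config.stopless_decoy_rate > 0 and rng.random() < config.stopless_decoy_rate:
                isoforms.append(("t3", exons_sense, (u5, u5 + lc - 3)))
            for iso, exons, (ca, cb) in isoforms:
                tid = f"{gene_id}.{iso}"
                gff.append(
                    f"{chrom}\tsim\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                    f"ID={tid};Parent={gene_id}"
                )
                for k, (a, b) in enumerate(exons, 1):
                    xa, xb = to_genomic(a, b)
                    gff.append(
                        f"{chrom}\tsim\texon\t{xa + 1}\t{xb}\t.\t{strand}\t.\t"
                        f"ID={tid}.exon{k};Parent={tid}"
                    )
                ca_g, cb_g = to_genomic(ca, cb)
                gff.append(
                    f"{chrom}\tsim\tCDS\t{ca_g + 1}\t{cb_g}\t.\t{strand}\t0\t"
                    f"ID={tid}.cds;Parent={tid}"
                )
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": f"{gene_id}.t1",
                    "strand": strand,
                    "L5": u5,
                    "Lc": lc,
                    "L3": l3,
                }
            )
            filler(config.intergenic_length)

        genomes[species] = SyntheticGenome(
            species=species,
            chrom=chrom,
            sequence="".join(parts),
            gff3="\n".join(gff) + "\n",
            truth=pd.DataFrame(truth_rows),
            feature_intervals={k: sorted(v) for k, v in intervals.items()},
        )
    return genomes


def genome_fasta(genome: SyntheticGenome, width: int = 80) -> str:
    buf = io.StringIO()
    buf.write(f">{genome.chrom} {genome.species}\n")
    seq = genome.sequence
    for i in range(0, len(seq), width):
        buf.write(seq[i : i + width] + "\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# repeats


def plant_repeats(
    genome: SyntheticGenome,
    densities: dict[str, float],
    seed: int,
    block: int = 50,
) -> tuple[SyntheticGenome, pd.DataFrame]:
    """Overwrite blocks of feature sequence with repeat-library copies.

    Each feature interval is tiled into ``block``-nt blocks and a planted
    fraction of blocks (matching the class density) is overwritten with
    repeat sequence, so coordinates never shift.  Returns the modified
    genome and a BED-like table (chrom, start, end, family) in 0-based
    half-open coordinates.
    """
    rng = np.random.default_rng(
        [seed, zlib.crc32(genome.species.encode()) % (2**31)]
    )
    seq = bytearray(genome.sequence, "ascii")
    rows = []
    families = sorted(REPEAT_LIBRARY)
    for cls, ivs in genome.feature_intervals.items():
        density = densities.get(cls, 0.0)
        if density <= 0:
            continue
        if cls == "cds":
            # never overwrite a stop codon: keep 3 nt clear at both ends
            # (strand-agnostic), so annotations stay structurally valid
            ivs = [(a + 3, b - 3) for a, b in ivs if b - a > 6 + block]
        blocks = []
        for a, b in ivs:
            blocks.extend(
                (s, min(s + block, b)) for s in range(a, b, block) if min(s + block, b) - s == block
            )
        n_pick = int(round(density * sum(b - a for a, b in ivs) / block))
        n_pick = min(n_pick, len(blocks))
        if n_pick == 0:
            continue
        chosen = rng.choice(len(blocks), size=n_pick, replace=False)
        for bi in sorted(chosen):
            a, b = blocks[bi]
            fam = families[int(rng.integers(len(families)))]
            copy = (REPEAT_LIBRARY[fam] * ((b - a) // len(REPEAT_LIBRARY[fam]) + 1))[
                : b - a
            ]
            seq[a:b] = copy.encode("ascii")
            rows.append(
                {"chrom": genome.chrom, "start": a, "end": b, "family": fam}
            )
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "family"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )
    modified = dataclasses.replace(genome, sequence=seq.decode("ascii"))
    return modified, bed


# ---------------------------------------------------------------------------
# miRNAs


def make_mirnas(n: int, length: int, seed: int) -> list[tuple[str, str]]:
    """Synthetic mature miRNAs (RNA alphabet), GC-balanced so that a
    perfect full-length duplex is always comfortably below -20 kcal/mol."""
    rng = np.random.default_rng([seed, 77])
    out = []
    for i in range(1, n + 1):
        while True:
            s = "".join(rng.choice(list("ACGU"), size=length))
            gc = (s.count("G") + s.count("C")) / length
            if 0.4 <= gc <= 0.7:
                break
        out.append((f"syn-miR-{i}", s))
    return out


def _seed_complement_dna(mirna_seq: str) -> str:
    """DNA reverse complement of miRNA seed (positions 2-8)."""
    seed_rna = mirna_seq[1:8]
    return revcomp(seed_rna.replace("U", "T"))


def scrub_seed_matches(seq: str, mirnas: list[tuple[str, str]], seed: int) -> str:
    """Rewrite a DNA sequence until it contains no seed complement of any
    miRNA in the set (used for guaranteed-negative backgrounds)."""
    rng = np.random.default_rng([seed, 13])
    sites = [_seed_complement_dna(s) for _, s in mirnas]
    s = seq
    for _ in range(200):
        dirty = False
        for pat in sites:
            j = s.find(pat)
            while j != -1:
                dirty = True
                s = s[:j] + _random_seq(rng, len(pat)) + s[j + len(pat) :]
                j = s.find(pat, j)
        if not dirty:
            return s
    raise RuntimeError("could not scrub seed matches")


def plant_mirna_sites(
    utrs: dict[str, str],
    mirnas: list[tuple[str, str]],
    counts: dict[str, int] | int,
    seed: int,
    pair_length: int = 18,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write perfect-complement miRNA sites into scrubbed UTR sequences.

    Each planted site is the DNA reverse complement of the miRNA's first
    ``pair_length`` bases, so the strict seed (positions 2-8) matches and
    the contiguous duplex is long enough to clear the -20 kcal/mol
    cutoff under the shipped stacking table.  The background is scrubbed
    of all chance seed matches first and each placement is re-checked, so
    the returned truth table is exact: a scan must find these sites and
    nothing else.  Returns (modified UTRs, truth table).
    """
    from .mirna_targets import MatureMiRNA, duplex_energy

    rng = np.random.default_rng([seed, 29])
    pats = {name: _seed_complement_dna(s) for name, s in mirnas}
    truth = []
    out = {}
    for utr_id in sorted(utrs):
        want = counts if isinstance(counts, int) else counts.get(utr_id, 0)
        seq = scrub_seed_matches(utrs[utr_id], mirnas, seed=int(rng.integers(2**31)))
        if want == 0:
            out[utr_id] = seq
            continue
        if len(seq) < want * (pair_length + 2):
            raise ValueError(f"UTR {utr_id} too short for {want} sites")
        for attempt in range(200):
            placed = []
            s = seq
            slots = sorted(
                rng.choice(
                    len(seq) - pair_length, size=want, replace=False
                ).tolist()
            )
            if any(b - a < pair_length for a, b in zip(slots, slots[1:])):
                continue
            midx = rng.integers(len(mirnas), size=want)
            for p, mi in zip(slots, midx):
                name, mseq = mirnas[int(mi)]
                site = revcomp(mseq[:pair_length].replace("U", "T"))
                s = s[:p] + site + s[p + pair_length :]
                placed.append((p, name, mseq))
            # exactness re-check: each miRNA's seed complement occurs only
            # where planted
            found = []
            for name, _ in mirnas:
                pat = pats[name]
                j = s.find(pat)
                while j != -1:
                    found.append((name, j))
                    j = s.find(pat, j + 1)
            expected = sorted(
                (name, p + pair_length - 8) for p, name, _ in placed
            )
            if sorted(found) != expected:
                continue
            ok_energy = True
            for p, name, mseq in placed:
                m = MatureMiRNA(name, mseq)
                seed_start = p + pair_length - 8
                e = duplex_energy(s, m, seed_start)
                if e > -20.0:
                    ok_energy = False
                    break
                truth.append(
                    {
                        "utr_id": utr_id,
                        "mirna": name,
                        "seed_start": seed_start,
                        "site_start": p,
                        "site_end": p + pair_length,
                        "energy": e,
                    }
                )
            if ok_energy:
                seq = s
                break
            truth = [t for t in truth if t["utr_id"] != utr_id]
        else:
            raise RuntimeError(f"failed to plant sites in {utr_id}")
        out[utr_id] = seq
    cols = ["utr_id", "mirna", "seed_start", "site_start", "site_end", "energy"]
    return out, pd.DataFrame(truth, columns=cols)


# ---------------------------------------------------------------------------
# similarity tables (gene families)


def make_similarity_table(
    n_families: int,
    species: list[str],
    seed: int,
    duplicated_species: dict[int, str] | None = None,
    missing_species: dict[int, str] | None = None,
    family_names: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """BLAST-outfmt-6-like table with planted 1:1 families.

    Within-family cross-species hits are strong and split into two
    colinear HSPs (to exercise chaining); between-family hits are either
    below the score floor or above the E-value cutoff.  ``duplicated_species``
    maps a family index to a species that gets a second copy;
    ``missing_species`` drops one species from a family.  Returns the
    table and the truth partition {family_id: set of gene ids}.
    """
    rng = np.random.default_rng([seed, 53])
    rows = []
    truth: dict[str, set[str]] = {}
    genes_by_family: list[list[str]] = []
    for f in range(n_families):
        fam = family_names[f] if family_names else f"fam{f:03d}"
        members = []
        for sp in species:
            if missing_species and missing_species.get(f) == sp:
                continue
            members.append(f"{sp}|{fam}")
            if duplicated_species and duplicated_species.get(f) == sp:
                members.append(f"{sp}|{fam}b")
        truth[fam] = set(members)
        genes_by_family.append(members)

    def hit(q, s, bits, evalue, qs, qe, ss, se):
        rows.append(
            {
                "qseqid": q,
                "sseqid": s,
                "pident": 90.0,
                "length": qe - qs + 1,
                "mismatch": 5,
                "gapopen": 0,
                "qstart": qs,
                "qend": qe,
                "sstart": ss,
                "send": se,
                "evalue": evalue,
                "bitscore": bits,
            }
        )

    for members in genes_by_family:
        for i, q in enumerate(members):
            hit(q, q, 400.0, 0.0, 1, 200, 1, 200)  # self hit
            for s in members[i + 1 :]:
                b1 = float(rng.uniform(150, 250))
                b2 = float(rng.uniform(80, 140))
                # two colinear HSPs -> conjoined score b1 + b2
                hit(q, s, b1, 1e-80, 1, 100, 1, 100)
                hit(q, s, b2, 1e-40, 121, 200, 121, 200)
                hit(s, q, b1, 1e-80, 1, 100, 1, 100)
                hit(s, q, b2, 1e-40, 121, 200, 121, 200)
    # weak between-family noise: below the weight floor or failing E-value
    flat = [m for ms in genes_by_family for m in ms]
    n_noise = min(len(flat), 3 * n_families)
    for _ in range(n_noise):
        q, s = rng.choice(flat, size=2, replace=False)
        if q.split("|")[1].rstrip("b") == s.split("|")[1].rstrip("b"):
            continue
        if rng.random() < 0.5:
            hit(q, s, 3.0, 1e-20, 1, 30, 1, 30)  # kept but < weight floor
        else:
            hit(q, s, 60.0, 1e-4, 1, 60, 1, 60)  # dropped by E-value cutoff
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# term maps


def assign_terms(
    genes: list[str],
    seed: int,
    n_terms: int = 30,
    background_freq: float = 0.05,
    planted_term: str | None = None,
    top_set: set[str] | None = None,
    planted_freq: float = 0.4,
) -> pd.DataFrame:
    """Gene -> term map with optional planted over-representation.

    Every term is assigned independently at ``background_freq``; the
    ``planted_term`` is additionally assigned at ``planted_freq`` within
    ``top_set``.  Columns: gene_id, term_id, term_name, category.
    """
    if not 0 <= background_freq <= 1 or not 0 <= planted_freq <= 1:
        raise ValueError("frequencies must lie in [0,1]")
    rng = np.random.default_rng([seed, 97])
    cats = ["CC", "BP", "MF", "KEGG"]
    terms = [f"TERM:{i:04d}" for i in range(n_terms)]
    rows = []
    for g in genes:
        for t_idx, t in enumerate(terms):
            freq = background_freq
            if planted_term == t and top_set and g in top_set:
                freq = planted_freq
            if rng.random() < freq:
                rows.append(
                    {
                        "gene_id": g,
                        "term_id": t,
                        "term_name": f"synthetic term {t_idx}",
                        "category": cats[t_idx % len(cats)],
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name", "category"])
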