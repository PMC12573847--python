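"""Synthetic genomes with planted duplication structure.

The generator emulates the migrate-and-expand dynamics of duplication-prone
genic regions: for each duplication-prone gene family one ancestral unit
(carrying a single gene) is dispersed to a small number of distant loci, and
at each locus an independent tandem array is grown by repeated in-place
duplication of contiguous blocks of one or more existing units.  Because each
landing site draws fresh flanking sequence and grows its own array, the
tandem structure at different sites of one family is not similar — only the
units themselves are.

Around that planted structure the genome carries:

* background gene families (singletons and small multi-member families)
  placed uniformly, whose members share only their sub-Kbp CDS;
* LTR-retrotransposon-like elements: a pair of near-identical ~1-2 Kbp
  terminal direct repeats flanking an internal body, so a single element
  yields only a short (sub-filter) self-hit, as real lone LTR elements do;
* i.i.d. background nucleotides at a configurable GC content, so the
  self-alignment noise floor is negligible and planted structure dominates.

Arms-race labels are assigned at the family level such that the log-odds of
an arms-race label for a planted-array family exceeds that of a background
family by ``log(association_strength)``; strength 1 encodes the null of no
label-placement dependence.  All outputs are bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .alignments import LocalAlignment, canonicalize, write_paf
from .io import write_bed, write_fasta, write_gff3

__all__ = [
    "SimConfig",
    "TruthSet",
    "ArrayPlacement",
    "SimResult",
    "CapacityError",
    "simulate_genome",
    "emit_truth_alignments",
    "write_simulation",
    "simulate_protein_families",
    "simulate_association_flags",
    "simulate_cluster_evidence",
]


class CapacityError(ValueError):
    """Requested planted content does not fit in the configured chromosomes."""


@dataclass
class SimConfig:
    """Parameters of the synthetic genome.

    Lengths are in bp.  ``association_strength`` is the odds multiplier
    linking the arms-race label to planted-array membership at the family
    level; 1 means no dependence.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_families: int = 60
    singleton_fraction: float = 0.67
    n_ldpr_sites: int = 6
    units_per_array: tuple[int, int] = (4, 8)
    unit_length: tuple[int, int] = (2_000, 4_000)
    dispersal_sites_per_family: tuple[int, int] = (1, 3)
    substitution_rate: float = 0.01
    te_density: float = 2.0          # elements per Mbp
    te_length: tuple[int, int] = (1_000, 2_000)   # terminal direct-repeat length
    arms_race_fraction_of_families: float = 0.15
    association_strength: float = 25.0
    gc_content: float = 0.44
    max_duplication_block: int = 3   # units duplicated per growth step
    housekeeping_fraction: float = 0.2  # of non-arms-race families

    def validate(self) -> None:
        fracs = {
            "singleton_fraction": self.singleton_fraction,
            "substitution_rate": self.substitution_rate,
            "arms_race_fraction_of_families": self.arms_race_fraction_of_families,
            "gc_content": self.gc_content,
            "housekeeping_fraction": self.housekeeping_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.unit_length[0] < 1_000:
            raise ValueError("unit_length minimum must be >= 1000 (Kbp-scale units)")
        for name in ("units_per_array", "unit_length", "dispersal_sites_per_family", "te_length"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be an increasing range of ints >= 1")
        if self.association_strength < 1.0:
            raise ValueError("association_strength must be >= 1")
        if self.n_chromosomes < 1 or self.chrom_length < 1 or self.n_families < 1:
            raise ValueError("counts and lengths must be >= 1")


@dataclass
class ArrayPlacement:
    """One planted tandem array: its interval and the ordered unit copies."""

    chrom: str
    start: int
    end: int
    family_id: str
    copies: list[tuple[int, int, str]] = field(default_factory=list)  # (start, end, gene_id)
    mutation_loads: list[int] = field(default_factory=list)


@dataclass
class TruthSet:
    """Ground truth recorded by the simulator for recovery tests."""

    planted_ldprs: list[tuple[str, int, int]]
    family_of_gene: dict[str, str]
    pool_label_of_gene: dict[str, str]  # arms_race | housekeeping | neutral
    placements: list[ArrayPlacement]


@dataclass
class SimResult:
    genome: dict[str, str]
    genes: pd.DataFrame       # gene_id, chrom, start, end, protein, family_id, in_array
    metadata: pd.DataFrame    # gene_id, descriptor, go_terms, pool_label
    truth: TruthSet
    config: SimConfig


# ---------------------------------------------------------------------------
# Descriptor / GO vocabularies (family-level annotation of the synthetic genes)
# ---------------------------------------------------------------------------

GO_INTERSPECIES_ROOT = "GO:0044419"

ARMS_DESCRIPTORS = [
    "NBS-LRR disease resistance protein",
    "leucine-rich repeat receptor-like kinase",
    "pathogenesis-related protein 1",
    "thionin-like peptide",
    "jacalin-like lectin",
    "jasmonate-induced protein",
]
ARMS_GO_TERMS = ["GO:0009617", "GO:0050832", "GO:0042742", "GO:0009624"]

HOUSEKEEPING_DESCRIPTORS = [
    "actin",
    "alpha-tubulin",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "elongation factor 1-alpha",
    "ubiquitin-conjugating enzyme",
]
NEUTRAL_DESCRIPTORS = [
    "MADS-box protein",
    "cytochrome P450 family protein",
    "ABC transporter family protein",
    "zinc finger protein",
    "cortical cell-delineating protein",
    "protein of unknown function",
]

#: child term -> ancestors, emitted as the GO-closure fixture
GO_CLOSURE: dict[str, list[str]] = {
    t: [GO_INTERSPECIES_ROOT, "GO:0008150"] for t in ARMS_GO_TERMS
}
GO_CLOSURE[GO_INTERSPECIES_ROOT] = ["GO:0008150"]

_BASES = b"ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {  # one unambiguous codon per amino acid (back-translation)
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
def _codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


_FULL_TABLE = _codon_table()


def translate(cds: str) -> str:
    """Translate a CDS; internal stops and ambiguous codons become X."""
    aa = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3].upper()
        r = _FULL_TABLE.get(codon, "X")
        aa.append("X" if r == "*" else r)
    return "".join(aa)


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> bytearray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return bytearray(np.frombuffer(_BASES, dtype=np.uint8)[codes].tobytes())


def _mutate(seq: bytes, rate: float, rng: np.random.Generator) -> tuple[bytearray, int]:
    """Substitute bases at the given per-base rate; returns (seq, n_subs)."""
    out = bytearray(seq)
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return out, 0
    positions = rng.choice(len(seq), size=n, replace=False)
    for pos in sorted(int(p) for p in positions):
        old = out[pos]
        choices = [b for b in _BASES if b != old]
        out[pos] = choices[rng.integers(0, 3)]
    return out, n


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + random non-stop codons + stop; deterministic for a given rng."""
    aas = [_AA[rng.integers(0, len(_AA))] for _ in range(n_aa - 1)]
    return "ATG" + "".join(_CODON[a] for a in aas) + "TAA"


# ---------------------------------------------------------------------------
# Core generator
# ---------------------------------------------------------------------------

_MIN_BIG_GAP = 50_000   # spacer between repeat-bearing features (arrays, TEs)
_GENE_MARGIN = 2_000    # clearance around background gene cassettes


def _solve_base_rate(f: float, strength: float, n_arr: int, n_bg: int) -> float:
    """Background-family arms-race probability giving overall fraction f."""
    if f <= 0.0:
        return 0.0
    if f >= 1.0:
        return 1.0
    if strength == 1.0 or n_arr == 0:
        return f
    n_tot = n_arr + n_bg

    def boosted(p0: float) -> float:
        odds = p0 / (1 - p0) * strength
        return odds / (1 + odds)

    def gap(p0: float) -> float:
        return (n_arr * boosted(p0) + n_bg * p0) / n_tot - f

    return brentq(gap, 1e-12, 1 - 1e-12, xtol=1e-12)


def simulate_genome(config: SimConfig) -> SimResult:
    """Build the genome, annotation, metadata and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    # ---- family plan -----------------------------------------------------
    n_fam = config.n_families
    site_alloc: list[int] = []  # sites per array family
    remaining = config.n_ldpr_sites
    lo_d, hi_d = config.dispersal_sites_per_family
    while remaining > 0:
        k = min(int(rng.integers(lo_d, hi_d + 1)), remaining)
        site_alloc.append(k)
        remaining -= k
    n_arr_fam = len(site_alloc)
    if n_arr_fam > n_fam:
        raise CapacityError(
            f"{config.n_ldpr_sites} planted sites need {n_arr_fam} families "
            f"but only {n_fam} configured"
        )
    n_bg_fam = n_fam - n_arr_fam
    n_singleton = int(round(config.singleton_fraction * n_bg_fam))
    bg_sizes = [1] * n_singleton + [
        int(rng.integers(2, 6)) for _ in range(n_bg_fam - n_singleton)
    ]

    family_ids = [f"fam_{i:04d}" for i in range(n_fam)]
    arr_families = family_ids[:n_arr_fam]
    bg_families = family_ids[n_arr_fam:]

    # ---- labels ----------------------------------------------------------
    p0 = _solve_base_rate(
        config.arms_race_fraction_of_families,
        config.association_strength,
        n_arr_fam,
        n_bg_fam,
    )
    if p0 in (0.0, 1.0) or config.association_strength == 1.0:
        p_arr = p0
    else:
        odds = p0 / (1 - p0) * config.association_strength
        p_arr = odds / (1 + odds)
    fam_label: dict[str, str] = {}
    for fam in family_ids:
        p = p_arr if fam in set(arr_families) else p0
        if rng.random() < p:
            fam_label[fam] = "arms_race"
        elif rng.random() < config.housekeeping_fraction:
            fam_label[fam] = "housekeeping"
        else:
            fam_label[fam] = "neutral"

    # ---- ancestral units for array families ------------------------------
    lo_u, hi_u = config.unit_length
    ancestral: dict[str, tuple[bytes, int, int]] = {}  # fam -> (unit, cds_off, cds_len)
    for fam in arr_families:
        u = int(rng.integers(lo_u, hi_u + 1))
        cds_len = max(300, (int(u * 0.5) // 3) * 3)
        cds_len = min(cds_len, ((u - 200) // 3) * 3)
        n_aa = cds_len // 3
        cds = _random_cds(rng, n_aa)
        cds_len = len(cds)
        flank_total = u - cds_len
        left = flank_total // 2
        unit = bytes(_random_seq(rng, left, config.gc_content)) + cds.encode() + bytes(
            _random_seq(rng, flank_total - left, config.gc_content)
        )
        ancestral[fam] = (unit, left, cds_len)

    # ---- background family CDS (sub-Kbp, so nothing repeated >= 1 Kbp) ---
    bg_cds: dict[str, str] = {}
    for fam in bg_families:
        n_aa = int(rng.integers(150, 300))  # CDS 450-900 bp
        bg_cds[fam] = _random_cds(rng, n_aa)

    # ---- plan big features per chromosome --------------------------------
    lo_n, hi_n = config.units_per_array
    big_features: dict[str, list[tuple[str, object]]] = {c: [] for c in chroms}

    site_records = []  # (family, chrom, copies list built later)
    for fam, n_sites in zip(arr_families, site_alloc):
        for _ in range(n_sites):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            n_units = int(rng.integers(lo_n, hi_n + 1))
            site_records.append((fam, chrom, n_units))

    for fam, chrom, n_units in site_records:
        unit, cds_off, cds_len = ancestral[fam]
        founder, n0 = _mutate(unit, config.substitution_rate, rng)
        copies: list[bytearray] = [founder]
        loads: list[int] = [n0]
        while len(copies) < n_units:
            block = int(rng.integers(1, min(config.max_duplication_block, len(copies)) + 1))
            block = min(block, n_units - len(copies))
            start = int(rng.integers(0, len(copies) - block + 1))
            fresh = []
            fresh_loads = []
            for c in copies[start : start + block]:
                m, nm = _mutate(bytes(c), config.substitution_rate, rng)
                fresh.append(m)
                fresh_loads.append(nm)
            copies[start + block : start + block] = fresh
            loads[start + block : start + block] = fresh_loads
        seq = b"".join(bytes(c) for c in copies)
        big_features[chrom].append(
            ("array", {"family": fam, "seq": seq, "unit_len": len(unit),
                       "cds_off": cds_off, "cds_len": cds_len,
                       "n_units": len(copies), "loads": loads})
        )

    lo_t, hi_t = config.te_length
    for chrom in chroms:
        n_te = rng.poisson(config.te_density * config.chrom_length / 1e6)
        for _ in range(int(n_te)):
            ltr = bytes(_random_seq(rng, int(rng.integers(lo_t, hi_t + 1)), config.gc_content))
            body = bytes(_random_seq(rng, int(rng.integers(3_000, 7_001)), config.gc_content))
            ltr2, _ = _mutate(ltr, 0.02, rng)
            big_features[chrom].append(("te", {"seq": ltr + body + bytes(ltr2)}))

    # ---- background genes plan -------------------------------------------
    bg_gene_plan: dict[str, list[tuple[str, str]]] = {c: [] for c in chroms}  # (family, cds)
    for fam, size in zip(bg_families, bg_sizes):
        for _ in range(size):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            bg_gene_plan[chrom].append((fam, bg_cds[fam]))

    # ---- assemble chromosomes --------------------------------------------
    genome: dict[str, str] = {}
    placements: list[ArrayPlacement] = []
    gene_rows = []  # (chrom, start, end, protein, family, in_array)
    L = config.chrom_length
    for chrom in chroms:
        seq = _random_seq(rng, L, config.gc_content)
        feats = big_features[chrom]
        total = sum(len(payload["seq"]) for _, payload in feats)
        n_f = len(feats)
        slack = L - total - (n_f + 1) * _MIN_BIG_GAP
        if slack < 0:
            raise CapacityError(
                f"{chrom}: planted features need {total + (n_f + 1) * _MIN_BIG_GAP} bp "
                f"but chromosome is {L} bp"
            )
        cuts = np.sort(rng.integers(0, slack + 1, size=n_f)) if n_f else np.empty(0, int)
        gaps = np.diff(np.concatenate(([0], cuts, [slack]))) + _MIN_BIG_GAP
        occupied: list[tuple[int, int]] = []
        pos = 0
        for (kind, payload), gap in zip(feats, gaps[:-1] if n_f else []):
            pos += int(gap)
            fseq = payload["seq"]
            seq[pos : pos + len(fseq)] = fseq
            occupied.append((pos, pos + len(fseq)))
            if kind == "array":
                fam = payload["family"]
                unit_len = payload["unit_len"]
                copies = []
                for ci in range(payload["n_units"]):
                    cs = pos + ci * unit_len
                    gs = cs + payload["cds_off"]
                    copies.append((cs, cs + unit_len, gs))  # gene start as placeholder
                    ge = gs + payload["cds_len"]
                    cds = bytes(seq[gs:ge]).decode()
                    gene_rows.append((chrom, gs, ge, translate(cds), fam, True))
                placements.append(
                    ArrayPlacement(chrom, pos, pos + len(fseq), fam, copies,
                                   list(payload["loads"]))
                )
            pos += len(fseq)

        # background genes: rejection-sampled uniform placement
        for fam, cds in bg_gene_plan[chrom]:
            glen = len(cds)
            placed = False
            for _try in range(2_000):
                s = int(rng.integers(0, L - glen))
                e = s + glen
                lo, hi = s - _GENE_MARGIN, e + _GENE_MARGIN
                if any(not (hi <= os or lo >= oe) for os, oe in occupied):
                    continue
                seq[s:e] = cds.encode()
                occupied.append((s, e))
                gene_rows.append((chrom, s, e, translate(cds), fam, False))
                placed = True
                break
            if not placed:
                raise CapacityError(f"{chrom}: could not place background gene of {glen} bp")
        genome[chrom] = bytes(seq).decode()

    # ---- gene IDs in genomic order ---------------------------------------
    gene_rows.sort(key=lambda r: (r[0], r[1], r[2]))
    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "protein", "family_id", "in_array"]
    )
    genes.insert(0, "gene_id", [f"gene_{i + 1:05d}" for i in range(len(genes))])

    coord_to_gid = {
        (r.chrom, r.start): r.gene_id for r in genes.itertuples()
    }
    for pl in placements:
        pl.copies = [
            (cs, ce, coord_to_gid[(pl.chrom, gs)]) for cs, ce, gs in pl.copies
        ]

    planted = sorted((pl.chrom, pl.start, pl.end) for pl in placements)

    family_of_gene = dict(zip(genes.gene_id, genes.family_id))
    pool_label_of_gene = {
        gid: fam_label[fam] for gid, fam in family_of_gene.items()
    }

    # ---- metadata ---------------------------------------------------------
    fam_desc: dict[str, str] = {}
    fam_go: dict[str, str] = {}
    for fam in family_ids:
        label = fam_label[fam]
        if label == "arms_race":
            fam_desc[fam] = ARMS_DESCRIPTORS[int(rng.integers(0, len(ARMS_DESCRIPTORS)))]
            fam_go[fam] = ARMS_GO_TERMS[int(rng.integers(0, len(ARMS_GO_TERMS)))]
        elif label == "housekeeping":
            fam_desc[fam] = HOUSEKEEPING_DESCRIPTORS[
                int(rng.integers(0, len(HOUSEKEEPING_DESCRIPTORS)))
            ]
            fam_go[fam] = "GO:0008152"
        else:
            fam_desc[fam] = NEUTRAL_DESCRIPTORS[int(rng.integers(0, len(NEUTRAL_DESCRIPTORS)))]
            fam_go[fam] = "GO:0008150"
    metadata = pd.DataFrame(
        {
            "gene_id": genes.gene_id,
            "descriptor": [fam_desc[f] for f in genes.family_id],
            "go_terms": [fam_go[f] for f in genes.family_id],
            "pool_label": [pool_label_of_gene[g] for g in genes.gene_id],
        }
    )

    truth = TruthSet(planted, family_of_gene, pool_label_of_gene, placements)
    return SimResult(genome, genes, metadata, truth, config)


def emit_truth_alignments(truth: TruthSet, genome: dict[str, str]) -> list[LocalAlignment]:
    """Pairwise alignments between same-chromosome planted copies of a unit.

    One record per unordered pair; the score is the number of matching bases
    between the two copies under their recorded mutation loads.
    """
    by_fam_chrom: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for pl in truth.placements:
        if pl.chrom not in genome:
            raise ValueError(f"truth refers to unknown chromosome {pl.chrom}")
        if pl.end > len(genome[pl.chrom]):
            raise ValueError(f"planted array {pl.chrom}:{pl.start}-{pl.end} out of bounds")
        by_fam_chrom.setdefault((pl.family_id, pl.chrom), []).extend(
            (cs, ce) for cs, ce, _gid in pl.copies
        )
    out = []
    for (fam, chrom), copies in sorted(by_fam_chrom.items()):
        seq = np.frombuffer(genome[chrom].encode(), dtype=np.uint8)
        copies = sorted(copies)
        for i in range(len(copies)):
            for j in range(i + 1, len(copies)):
                (s1, e1), (s2, e2) = copies[i], copies[j]
                matches = int(np.count_nonzero(seq[s1:e1] == seq[s2:e2]))
                out.append(LocalAlignment(chrom, s1, e1, s2, e2, "+", float(matches)))
    return canonicalize(out)


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------

def write_simulation(sim: SimResult, outdir) -> dict[str, Path]:
    """Write the simulated study inputs; returns the path of each artefact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff3": outdir / "genes.gff3",
        "proteins": outdir / "proteins.fa",
        "metadata": outdir / "metadata.tsv",
        "go_closure": outdir / "go_closure.tsv",
        "truth_ldprs": outdir / "truth_ldprs.bed",
        "truth_alignments": outdir / "truth_alignments.paf",
    }
    write_fasta(sim.genome, paths["fasta"])
    write_gff3(sim.genes, paths["gff3"])
    with open(paths["proteins"], "w") as fh:
        for row in sim.genes.itertuples():
            fh.write(f">{row.gene_id}\n{row.protein}\n")
    sim.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    with open(paths["go_closure"], "w") as fh:
        fh.write("term\tancestor\n")
        for term in sorted(GO_CLOSURE):
            for anc in GO_CLOSURE[term]:
                fh.write(f"{term}\t{anc}\n")
    write_bed(
        sim.truth.planted_ldprs,
        paths["truth_ldprs"],
        names=[f"planted_{i + 1}" for i in range(len(sim.truth.planted_ldprs))],
    )
    chrom_lengths = {c: len(s) for c, s in sim.genome.items()}
    write_paf(emit_truth_alignments(sim.truth, sim.genome), paths["truth_alignments"], chrom_lengths)
    return paths


# ---------------------------------------------------------------------------
# Lightweight generators for the statistical layers
# ---------------------------------------------------------------------------

def simulate_protein_families(
    n_families: int = 20,
    members_range: tuple[int, int] = (2, 30),
    length_range: tuple[int, int] = (120, 400),
    substitution_rate: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Planted protein families for clustering-recovery tests.

    Members of one family are the ancestral protein with amino-acid
    substitutions (pairwise within-family identity ~= (1 - rate)^2, kept
    above 0.8 by the default rate); between families the
    sequences are independent random proteins of varying length, whose global
    identity stays far below any sensible clustering cutoff.
    """
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    labels: dict[str, str] = {}
    gid = 0
    for f in range(n_families):
        fam = f"fam_{f:03d}"
        n_aa = int(rng.integers(length_range[0], length_range[1] + 1))
        ancestral = "".join(_AA[rng.integers(0, len(_AA))] for _ in range(n_aa))
        size = int(rng.integers(members_range[0], members_range[1] + 1))
        for _ in range(size):
            seq = list(ancestral)
            n_sub = rng.binomial(n_aa, substitution_rate)
            for pos in rng.choice(n_aa, size=n_sub, replace=False):
                choices = [a for a in _AA if a != seq[pos]]
                seq[int(pos)] = choices[rng.integers(0, len(choices))]
            gid += 1
            name = f"gene_{gid:05d}"
            proteins[name] = "".join(seq)
            labels[name] = fam
    return proteins, labels


def simulate_cluster_evidence(
    n_clusters: int = 300,
    beta0: float = -2.5,
    beta1: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster (pool labels, association p-values) from a logistic model.

    Association evidence x = -log(p) is exponential(1) — i.e. p uniform, the
    null distribution of a p-value — and labels are Bernoulli with
    ``logit P(pool) = beta0 + beta1 * x``.  ``beta1 = 0`` gives label sets
    independent of the evidence (the type-I-error regime).
    """
    rng = np.random.default_rng(seed)
    x = rng.exponential(1.0, n_clusters)
    prob = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    y = (rng.random(n_clusters) < prob).astype(float)
    return y, np.exp(-x)


def simulate_association_flags(
    seed: int = 0,
    n_clusters: int = 250,
    n_planted: int = 5,
    planted_size: int = 8,
    singleton_fraction: float = 0.5,
    size_range: tuple[int, int] = (2, 6),
    bg_ldpr_rate: float = 0.05,
):
    """Cluster/flag layout for null calibration of the per-cluster test.

    Planted clusters sit entirely inside duplication-prone regions (their
    association is real); every other gene lands in such a region
    independently with probability ``bg_ldpr_rate``, so the independence null
    holds for all non-planted clusters.

    Returns ``(clusters, flags, planted_ids)`` where clusters is a mapping
    cluster_id -> member gene IDs and flags maps gene_id -> bool.
    """
    rng = np.random.default_rng(seed)
    clusters: dict[str, list[str]] = {}
    flags: dict[str, bool] = {}
    planted_ids = set()
    gid = 0
    n_single = int(round(singleton_fraction * (n_clusters - n_planted)))
    sizes = (
        [planted_size] * n_planted
        + [1] * n_single
        + [int(rng.integers(size_range[0], size_range[1] + 1))
           for _ in range(n_clusters - n_planted - n_single)]
    )
    for ci, size in enumerate(sizes):
        cid = f"cl_{ci + 1:05d}"
        members = []
        for _ in range(size):
            gid += 1
            g = f"g{gid:06d}"
            members.append(g)
            if ci < n_planted:
                flags[g] = True
            else:
                flags[g] = bool(rng.random() < bg_ldpr_rate)
        clusters[cid] = members
        if ci < n_planted:
            planted_ids.add(cid)
    return clusters, flags, planted_ids
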