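"""Synthetic viral community generation.

Ground-truth communities emulate a river-water DNA virome: lognormal genome
lengths in the tens of kb, power-law rank abundances, a dsDNA/ssDNA mix,
strain groups that remain a single species (ANI >= 95%, AF >= 85%) while
differing by intergenic SNVs and strain-specific gene cassettes, and an
optional bacterial "background" genome with an offset GC content whose reads
contaminate bead libraries.

Coordinates are 0-based half-open throughout.  Minus-strand genes are
annotated on the forward sequence and translated from the reverse
complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

TAXONOMY_RANKS = ("realm", "kingdom", "phylum", "class", "family", "genus")

GENE_ROLES = ("structural", "replication", "AMG", "MTase", "other")

AMG_CATEGORIES = (
    "organic_nitrogen",
    "carbon_utilization",
    "energy",
    "transporters",
    "misc",
)

MIN_GENOME_LENGTH = 1_000
MAX_GENOME_LENGTH = 300_000

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParameterError(ValueError):
    """Invalid generator parameters."""


class PlacementError(ValueError):
    """A cassette cannot be placed in any inter-gene gap."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene on a genome (0-based half-open coordinates)."""

    gene_id: str
    start: int
    end: int
    strand: str
    og_label: str
    role: str = "other"
    amg_category: str | None = None
    aux_score: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError(f"gene {self.gene_id}: end must exceed start")
        if (self.end - self.start) % 3 != 0:
            raise ParameterError(f"gene {self.gene_id}: length not divisible by 3")
        if self.strand not in "+-":
            raise ParameterError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if (self.role == "AMG") != (self.aux_score is not None):
            raise ParameterError(
                f"gene {self.gene_id}: aux_score present iff role is AMG"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ViralGenome:
    genome_id: str
    sequence: str
    topology: str = "linear"
    nucleic_type: str = "dsDNA"
    taxonomy: tuple[str, ...] = ()
    strain_group_id: str | None = None
    genes: tuple[GeneAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_GENOME_LENGTH:
            raise ParameterError(
                f"{self.genome_id}: genome shorter than {MIN_GENOME_LENGTH} bp"
            )
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ParameterError(f"gene {g.gene_id} extends past genome end")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene_sequence(self, gene: GeneAnnotation) -> str:
        sub = self.sequence[gene.start : gene.end]
        return sub if gene.strand == "+" else reverse_complement(sub)


@dataclass(frozen=True)
class HostGenome:
    """Bacterial background genome co-sequenced with the viral fraction."""

    genome_id: str
    sequence: str
    abundance: float


@dataclass(frozen=True)
class Community:
    genomes: tuple[ViralGenome, ...]
    abundances: tuple[float, ...]
    background_genome: HostGenome | None = None

    def __post_init__(self) -> None:
        if not self.genomes:
            raise ParameterError("community needs at least one genome")
        if len(self.genomes) != len(self.abundances):
            raise ParameterError("one abundance per genome required")
        a = np.asarray(self.abundances)
        if (a < 0).any() or abs(a.sum() - 1.0) > 1e-9:
            raise ParameterError("abundances must be >= 0 and sum to 1")

    def genome(self, genome_id: str) -> ViralGenome:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    @property
    def abundance_map(self) -> dict[str, float]:
        return {g.genome_id: a for g, a in zip(self.genomes, self.abundances)}


@dataclass(frozen=True)
class Cassette:
    """A flexible gene cassette (e.g. one MTase subtype) insertable between genes."""

    og_label: str
    sequence: str
    role: str = "MTase"

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0 or len(self.sequence) < 60:
            raise ParameterError("cassette length must be >= 60 and divisible by 3")


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random ACGT sequence with the given expected GC fraction."""
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    arr = rng.choice(_BASES, size=length, p=p)
    return arr.tobytes().decode("ascii")


def _lineage(genus_index: int) -> tuple[str, ...]:
    # Small synthetic taxonomy: 3 genera per family, 3 families per class, one
    # phylum/kingdom/realm.  Stands in for a reference taxonomy database.
    fam = genus_index // 3
    cls = fam // 3
    return (
        "Synthoviria",
        "Simulavirae",
        "Benchmarviricota",
        f"class_{cls:02d}",
        f"family_{fam:03d}",
        f"genus_{genus_index:03d}",
    )


def generate_community(
    n_genomes: int,
    length_median: float = 40_000.0,
    length_sigma: float = 0.7,
    abundance_exponent: float = 1.5,
    seed: int = 0,
    ssdna_fraction: float = 0.1,
    gc_mean: float = 0.45,
    gc_sd: float = 0.04,
    with_background: bool = True,
    background_length: int = 1_000_000,
    background_gc_offset: float = 0.12,
    background_abundance: float = 0.05,
) -> Community:
    """Generate a ground-truth viral community.

    Genome lengths are lognormal around ``length_median`` truncated to
    [1 kb, 300 kb]; ssDNA genomes are small circular genomes (1.7-7 kb).
    Relative abundances follow a discrete power law p_i ~ i^-exponent over
    rank i.  The optional background genome is a single bacterial sequence
    with a GC content offset from the viral mean so composition-based
    binning can learn the separation.
    """
    if n_genomes < 1:
        raise ParameterError("n_genomes must be >= 1")
    if length_median <= 0 or length_sigma < 0:
        raise ParameterError("invalid length distribution parameters")
    if abundance_exponent < 0:
        raise ParameterError("abundance_exponent must be >= 0")
    rng = np.random.default_rng(seed)

    genomes = []
    for i in range(n_genomes):
        ssdna = rng.random() < ssdna_fraction
        if ssdna:
            length = int(rng.integers(1_700, 7_001))
            topology, ntype = "circular", "ssDNA"
        else:
            length = 0
            while not (MIN_GENOME_LENGTH <= length <= MAX_GENOME_LENGTH):
                length = int(round(rng.lognormal(np.log(length_median), length_sigma)))
            topology, ntype = "linear", "dsDNA"
        gc = float(np.clip(rng.normal(gc_mean, gc_sd), 0.25, 0.65))
        genus = int(rng.integers(0, max(1, n_genomes // 3) + 1))
        genomes.append(
            ViralGenome(
                genome_id=f"vg{i:04d}",
                sequence=random_sequence(rng, length, gc),
                topology=topology,
                nucleic_type=ntype,
                taxonomy=_lineage(genus),
            )
        )

    ranks = np.arange(1, n_genomes + 1, dtype=float)
    ab = ranks ** (-abundance_exponent)
    ab /= ab.sum()
    # Renormalise in float to guarantee the 1e-9 sum invariant.
    ab = ab / ab.sum()

    background = None
    if with_background:
        background = HostGenome(
            genome_id="host_bacterium",
            sequence=random_sequence(
                rng, background_length, gc_mean + background_gc_offset
            ),
            abundance=background_abundance,
        )

    return Community(
        genomes=tuple(genomes),
        abundances=tuple(float(x) for x in ab),
        background_genome=background,
    )


def _draw_gene_length(rng: np.random.Generator) -> int:
    # 300-1500 nt in codon steps, mode near 900 nt.
    return int(rng.integers(100, 501)) * 3


@dataclass(frozen=True)
class OGDefinition:
    """A shared orthologous-group gene: canonical sequence plus role.

    Genomes planting the same OG copy this sequence (with small per-genome
    divergence), so protein clustering can later recover the family.
    """

    og_label: str
    sequence: str
    role: str = "other"
    amg_category: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            raise ParameterError("OG sequence length must be divisible by 3")


_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


def random_cds(rng: np.random.Generator, length: int) -> str:
    """Random coding sequence: ATG, sense codons, one terminal stop."""
    if length % 3 != 0 or length < 9:
        raise ParameterError("CDS length must be >= 9 and divisible by 3")
    n_mid = length // 3 - 2
    mid = rng.choice(len(_SENSE_CODONS), size=n_mid)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in mid) + _STOPS[rng.integers(0, 3)]


def make_og_definitions(
    n_backbone: int,
    n_amg: int,
    rng: np.random.Generator | int = 0,
    prefix: str = "OG",
) -> dict[str, OGDefinition]:
    """Generate a pool of shared OG genes (backbone + AMG) as proper coding
    sequences, so ORF callers can rediscover planted genes."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    defs: dict[str, OGDefinition] = {}
    for i in range(n_backbone + n_amg):
        label = f"{prefix}{i:05d}"
        is_amg = i >= n_backbone
        defs[label] = OGDefinition(
            og_label=label,
            sequence=random_cds(rng, _draw_gene_length(rng)),
            role="AMG" if is_amg else str(
                rng.choice(["structural", "replication", "other"], p=[0.35, 0.25, 0.40])
            ),
            amg_category=(
                AMG_CATEGORIES[int(rng.integers(0, len(AMG_CATEGORIES)))]
                if is_amg
                else None
            ),
        )
    return defs


def _mutate_sequence(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    for i in np.flatnonzero(rng.random(arr.size) < rate):
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Mutate a coding sequence without destroying its reading frame:
    the start and stop codons are untouched and substitutions that would
    introduce an internal in-frame stop are skipped."""
    if rate <= 0:
        return cds
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    bases = "ACGT"
    for ci in range(1, len(codons) - 1):
        codon = codons[ci]
        changed = list(codon)
        for j in range(3):
            if rng.random() < rate:
                changed[j] = bases[int(rng.integers(0, 4))]
        cand = "".join(changed)
        if cand not in _STOPS:
            codons[ci] = cand
    return "".join(codons)


def plant_genes(
    genome: ViralGenome,
    gene_density: float = 1.0,
    amg_fraction: float = 0.05,
    seed: int = 0,
    og_pool: list[str] | None = None,
    og_pool_size: int = 2_000,
    og_sequences: dict[str, OGDefinition] | None = None,
    divergence: float = 0.02,
) -> ViralGenome:
    """Tile a genome with annotated genes.

    ``gene_density`` is genes per kb and controls the inter-gene gap width;
    genes cover >= 60% of the genome at density >= 0.7/kb.  OG labels are
    drawn from a shared pool (default ``OG00000..``) so that independently
    generated genomes can share orthologous groups.

    Two modes:

    - label mode (default): genes are annotation intervals on the existing
      random sequence; a fraction ``amg_fraction`` become AMGs with
      auxiliary scores drawn in 1-3.
    - sequence-pool mode (``og_sequences`` given): each planted gene copies
      the OG's canonical sequence into the genome with ``divergence``
      per-site substitutions, and role/category come from the OG
      definition (AMG genes draw auxiliary scores in 1-4, of which 1-3
      pass the downstream AMG gate).  This gives genomes genuinely shared
      protein families.
    """
    if not 0 <= amg_fraction <= 1:
        raise ParameterError("amg_fraction must be in [0,1]")
    if gene_density <= 0:
        raise ParameterError("gene_density must be > 0")
    rng = np.random.default_rng(seed)
    if og_pool is None:
        og_pool = (
            sorted(og_sequences) if og_sequences is not None
            else [f"OG{i:05d}" for i in range(og_pool_size)]
        )

    mean_gene = 900.0
    gap_mean = max(20.0, 1000.0 / gene_density - mean_gene)

    seq_arr = (
        bytearray(genome.sequence.encode("ascii")) if og_sequences is not None else None
    )
    genes: list[GeneAnnotation] = []
    pos = int(rng.integers(10, 80))
    idx = 0
    remaining = list(og_pool)
    used_ogs: set[str] = set()
    while True:
        if og_sequences is not None:
            if remaining:
                og = remaining.pop(int(rng.integers(0, len(remaining))))
            else:  # pool exhausted on a long genome: recycle with replacement
                og = og_pool[int(rng.integers(0, len(og_pool)))]
            definition = og_sequences[og]
            gene_seq = mutate_cds(rng, definition.sequence, divergence)
            glen = len(gene_seq)
            role, amg_cat = definition.role, definition.amg_category
            aux = (
                int(rng.choice([1, 2, 3, 4], p=[0.3, 0.3, 0.25, 0.15]))
                if role == "AMG"
                else None
            )
        else:
            glen = _draw_gene_length(rng)
            og = og_pool[int(rng.integers(0, len(og_pool)))]
            while og in used_ogs:
                og = og_pool[int(rng.integers(0, len(og_pool)))]
            role = str(
                rng.choice(["structural", "replication", "other"], p=[0.35, 0.25, 0.40])
            )
            amg_cat = None
            aux = None
            if rng.random() < amg_fraction:
                role = "AMG"
                amg_cat = AMG_CATEGORIES[int(rng.integers(0, len(AMG_CATEGORIES)))]
                aux = int(rng.integers(1, 4))
            gene_seq = None
        if pos + glen > genome.length - 10:
            break
        used_ogs.add(og)
        strand = "+" if rng.random() < 0.7 else "-"
        if seq_arr is not None and gene_seq is not None:
            placed = gene_seq if strand == "+" else reverse_complement(gene_seq)
            seq_arr[pos : pos + glen] = placed.encode("ascii")
        genes.append(
            GeneAnnotation(
                gene_id=f"{genome.genome_id}_g{idx:04d}",
                start=pos,
                end=pos + glen,
                strand=strand,
                og_label=og,
                role=role,
                amg_category=amg_cat,
                aux_score=aux,
            )
        )
        idx += 1
        pos += glen + max(5, int(round(rng.normal(gap_mean, gap_mean * 0.3))))

    if not genes:
        warnings.warn(
            f"{genome.genome_id}: too short for a single gene; no genes planted"
        )
    new_seq = seq_arr.decode("ascii") if seq_arr is not None else genome.sequence
    return replace(genome, sequence=new_seq, genes=tuple(genes))


def _apply_intergenic_snvs(
    rng: np.random.Generator, sequence: str, genes: tuple[GeneAnnotation, ...], rate: float
) -> str:
    """Substitute bases at ``rate`` per site, restricted to intergenic sites."""
    if rate <= 0:
        return sequence
    mask = np.ones(len(sequence), dtype=bool)
    for g in genes:
        mask[g.start : g.end] = False
    sites = np.flatnonzero(mask)
    hit = sites[rng.random(sites.size) < rate]
    if hit.size == 0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def spawn_strains(
    genome: ViralGenome,
    n_strains: int,
    snv_rate: float = 0.005,
    flexible_cassettes: list[Cassette] | None = None,
    seed: int = 0,
    cassette_prob: float = 0.5,
) -> list[ViralGenome]:
    """Derive strains of one species from a parent genome.

    Each strain carries point substitutions at ``snv_rate`` per intergenic
    site (core genes stay identical, so conserved markers keep 100%
    identity) plus a strain-specific subset (>= 1) of the flexible cassettes
    inserted at inter-gene positions, never splitting a core gene.  All
    strains share a strain_group_id; parent genes are the core gene set and
    cassette OGs are flexible by construction.
    """
    if n_strains < 1:
        raise ParameterError("n_strains must be >= 1")
    if snv_rate > 0.02:
        raise ParameterError("snv_rate > 0.02 would break species-level identity")
    rng = np.random.default_rng(seed)
    cassettes = list(flexible_cassettes or [])

    order = sorted(genome.genes, key=lambda g: g.start)
    gaps = []  # (insert position, width) between consecutive genes
    for left, right in zip(order, order[1:]):
        width = right.start - left.end
        if width >= 2:
            gaps.append(((left.end + right.start) // 2, width))
    if cassettes and not gaps:
        # Insertions extend the genome, so only an inter-gene insertion
        # point is required, not a gap as wide as the cassette.
        raise PlacementError("no inter-gene gap available for cassette insertion")

    group_id = f"{genome.genome_id}_sg"
    take_sets: list[list[Cassette]] = []
    if cassettes:
        for _ in range(n_strains):
            take = [c for c in cassettes if rng.random() < cassette_prob]
            if not take:
                take = [cassettes[int(rng.integers(0, len(cassettes)))]]
            take_sets.append(take)
        if n_strains >= 2:
            # keep every used cassette genuinely flexible: a cassette drawn
            # into all strains is removed from one of them
            for c in cassettes:
                carriers = [i for i, t in enumerate(take_sets) if c in t]
                if len(carriers) == n_strains:
                    drop = carriers[int(rng.integers(0, len(carriers)))]
                    if len(take_sets[drop]) > 1:
                        take_sets[drop] = [x for x in take_sets[drop] if x is not c]
    else:
        take_sets = [[] for _ in range(n_strains)]

    strains: list[ViralGenome] = []
    for s in range(n_strains):
        take = take_sets[s]
        seq = _apply_intergenic_snvs(rng, genome.sequence, genome.genes, snv_rate)

        # Insert back-to-front so earlier coordinates stay valid.
        slots = rng.choice(len(gaps), size=len(take), replace=False) if take else []
        events = sorted(
            zip((gaps[i][0] for i in slots), take), key=lambda e: -e[0]
        )
        new_genes = [replace(g, gene_id=f"{genome.genome_id}_s{s}_{g.gene_id.split('_')[-1]}") for g in order]
        for k, (ins_pos, cassette) in enumerate(events):
            seq = seq[:ins_pos] + cassette.sequence + seq[ins_pos:]
            shifted = []
            for g in new_genes:
                if g.start >= ins_pos:
                    g = replace(g, start=g.start + len(cassette.sequence),
                                end=g.end + len(cassette.sequence))
                shifted.append(g)
            new_genes = shifted
            new_genes.append(
                GeneAnnotation(
                    gene_id=f"{genome.genome_id}_s{s}_cas{k}",
                    start=ins_pos,
                    end=ins_pos + len(cassette.sequence),
                    strand="+",
                    og_label=cassette.og_label,
                    role=cassette.role,
                )
            )
        new_genes.sort(key=lambda g: g.start)
        strains.append(
            replace(
                genome,
                genome_id=f"{genome.genome_id}_s{s}",
                sequence=seq,
                strain_group_id=group_id,
                genes=tuple(new_genes),
            )
        )
    return strains


def core_flexible_truth(
    parent: ViralGenome, cassettes: list[Cassette]
) -> dict[str, str]:
    """Ground-truth OG classification for a strain group."""
    truth = {g.og_label: "core" for g in parent.genes}
    truth.update({c.og_label: "flexible" for c in cassettes})
    return truth


def make_mtase_cassettes(
    n: int, rng: np.random.Generator | int = 0, length: int = 900
) -> list[Cassette]:
    """Generate distinct MTase-subtype cassettes for strain simulation."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return [
        Cassette(og_label=f"MTASE_{i:02d}", sequence=random_cds(rng, length))
        for i in range(n)
    ]
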