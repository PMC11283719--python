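"""Gel-bead encapsulation and whole-genome-amplification simulation.

Particles are loaded into beads with Poisson statistics; each loaded genome
is amplified by an MDA surrogate producing a spatially correlated lognormal
depth field with window dropout (phi29 bias), from which paired reads and
assembly-surrogate contigs are derived.  Contigs are the maximal
continuously amplified intervals >= 1 kb — fragmentation at dropout windows
reproduces the property downstream binning relies on (one bead, several
fragments of the same genome) without running an assembler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .community import Community, ParameterError, _BASES, reverse_complement

AMPLIFICATION_WINDOW = 200  # bp resolution of the depth field
MIN_CONTIG_LENGTH = 1_000
READ_GATE = 50_000  # minimum trimmed reads for downstream analysis
SMALL_DATA_PAIRS = 5_000


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    source_id: str  # genome of origin (ground truth)
    start: int  # fragment start on the source (0-based)


@dataclass(frozen=True)
class Contig:
    contig_id: str
    bead_id: str
    sequence: str
    source_genome_id: str
    source_interval: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Bead:
    bead_id: str
    loaded_genomes: tuple[str, ...] = ()
    positive: bool = False
    coverage_profiles: dict[str, np.ndarray] = field(default_factory=dict)
    reads: list[ReadPair] = field(default_factory=list)
    contigs: list[Contig] = field(default_factory=list)

    @property
    def n_loaded(self) -> int:
        return len(self.loaded_genomes)


@dataclass
class RunManifest:
    method_label: str
    seed: int
    n_beads_generated: int = 0
    n_beads_positive: int = 0
    n_beads_sorted: int = 0
    records: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        if not (
            self.n_beads_sorted <= self.n_beads_positive <= self.n_beads_generated
        ):
            raise ParameterError("manifest counts must be sorted<=positive<=generated")


@dataclass(frozen=True)
class BiasModel:
    """MDA bias parameters: lognormal sigma of the depth field, window
    dropout probability, correlation length of the field, and a yield
    multiplier for ssDNA templates (phi29 amplifies ssDNA readily)."""

    sigma: float = 1.2
    dropout: float = 0.05
    correlation_bp: int = 2_000
    ssdna_multiplier: float = 1.5
    base_depth: float = 30.0


def passes_read_gate(n_pairs: int, gate_reads: int = READ_GATE) -> bool:
    """Retention gate: a bead library is analysed only when its trimmed
    read count strictly exceeds ``gate_reads`` (so exactly 25 000 pairs at
    the default gate of 50 000 reads does not pass)."""
    return 2 * n_pairs > gate_reads


def encapsulate(
    community: Community, n_beads: int, mean_loading: float, seed: int = 0
) -> list[Bead]:
    """Poisson-load community particles into ``n_beads`` gel beads.

    Per-bead particle count ~ Poisson(mean_loading); each particle's genome
    is drawn from the community relative abundances.  Beads stay
    non-positive until amplified.
    """
    if mean_loading <= 0:
        raise ParameterError("mean_loading must be > 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean_loading, size=n_beads)
    ids = np.array([g.genome_id for g in community.genomes])
    p = np.asarray(community.abundances)
    beads = []
    for i, k in enumerate(counts):
        loaded = tuple(rng.choice(ids, size=int(k), p=p)) if k else ()
        beads.append(Bead(bead_id=f"bead{i:06d}", loaded_genomes=loaded))
    return beads


def _depth_field(
    rng: np.random.Generator, length: int, bias: BiasModel, ssdna: bool
) -> np.ndarray:
    """Per-base MDA depth: smoothed lognormal field with window dropout."""
    n_win = max(1, -(-length // AMPLIFICATION_WINDOW))
    if bias.sigma > 0:
        z = rng.normal(0.0, 1.0, size=n_win)
        k = max(1, bias.correlation_bp // AMPLIFICATION_WINDOW)
        if k > 1:  # moving-average smoothing sets the correlation length
            kernel = np.ones(k) / k
            z = np.convolve(z, kernel, mode="same") * np.sqrt(k)
        field = np.exp(bias.sigma * z - bias.sigma**2 / 2.0)
    else:
        field = np.ones(n_win)
    if bias.dropout > 0:
        field[rng.random(n_win) < bias.dropout] = 0.0
    field = field * bias.base_depth
    if ssdna:
        field = field * bias.ssdna_multiplier
    return np.repeat(field, AMPLIFICATION_WINDOW)[:length].astype(np.float32)


def amplify(
    bead: Bead,
    community: Community,
    bias: BiasModel | None = None,
    seed: int = 0,
    yield_threshold: float = 0.0,
) -> Bead:
    """Whole-genome-amplify every particle loaded in a bead.

    Each loaded genome receives an independent depth profile.  The bead is
    positive when its total amplified yield exceeds ``yield_threshold``
    (default: any amplification at all — the fluorescence chemistry is not
    modelled)."""
    bias = bias or BiasModel()
    rng = np.random.default_rng(seed)
    profiles: dict[str, np.ndarray] = {}
    for gid in bead.loaded_genomes:
        g = community.genome(gid)
        prof = _depth_field(rng, g.length, bias, g.nucleic_type == "ssDNA")
        if gid in profiles:  # same genome loaded twice: profiles add
            profiles[gid] = profiles[gid] + prof
        else:
            profiles[gid] = prof
    total_yield = float(sum(p.sum() for p in profiles.values()))
    bead.coverage_profiles = profiles
    bead.positive = total_yield > yield_threshold
    return bead


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < error_rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def generate_reads(
    bead: Bead,
    community: Community,
    n_pairs: int,
    read_len: int = 150,
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    error_rate: float = 0.0,
    background_fraction: float = 0.0,
    seed: int = 0,
) -> Bead:
    """Simulate paired-end reads from a bead's amplified DNA.

    Fragment start positions are sampled proportional to the local
    amplification depth; ``background_fraction`` of pairs derive from the
    community's background genome (carry-over DNA in the reagents)."""
    if read_len < 50:
        raise ParameterError("read_len must be >= 50")
    rng = np.random.default_rng(seed)

    weights = []
    sources = []
    for gid, prof in bead.coverage_profiles.items():
        tot = float(prof.sum())
        if tot > 0:
            sources.append(gid)
            weights.append(tot)
    n_bg = int(round(n_pairs * background_fraction))
    n_viral = n_pairs - n_bg
    if not sources and n_bg == 0:
        warnings.warn(f"{bead.bead_id}: no amplified DNA and no background; no reads")
        bead.reads = []
        return bead

    reads: list[ReadPair] = []
    if sources and n_viral > 0:
        w = np.asarray(weights) / sum(weights)
        per_source = rng.multinomial(n_viral, w)
        for gid, n_src in zip(sources, per_source):
            if n_src == 0:
                continue
            g = community.genome(gid)
            prof = bead.coverage_profiles[gid].astype(float)
            cdf = np.cumsum(prof)
            cdf /= cdf[-1]
            starts = np.searchsorted(cdf, rng.random(n_src))
            inserts = np.maximum(
                2 * read_len, rng.normal(insert_mean, insert_sd, size=n_src)
            ).astype(int)
            for j, (s, ins) in enumerate(zip(starts, inserts)):
                s = int(min(s, max(0, g.length - ins)))
                frag = g.sequence[s : s + ins]
                r1 = _mutate(rng, frag[:read_len], error_rate)
                r2 = _mutate(
                    rng, reverse_complement(frag[-read_len:]), error_rate
                )
                reads.append(
                    ReadPair(
                        read_id=f"{bead.bead_id}:{gid}:{len(reads)}",
                        seq1=r1,
                        seq2=r2,
                        source_id=gid,
                        start=s,
                    )
                )
    if n_bg > 0 and community.background_genome is not None:
        bg = community.background_genome
        starts = rng.integers(0, len(bg.sequence) - int(insert_mean), size=n_bg)
        for s in starts:
            frag = bg.sequence[s : s + int(insert_mean)]
            reads.append(
                ReadPair(
                    read_id=f"{bead.bead_id}:{bg.genome_id}:{len(reads)}",
                    seq1=_mutate(rng, frag[:read_len], error_rate),
                    seq2=_mutate(rng, reverse_complement(frag[-read_len:]), error_rate),
                    source_id=bg.genome_id,
                    start=int(s),
                )
            )
    bead.reads = reads
    return bead


def fragment_to_contigs(
    bead: Bead,
    community: Community,
    min_contig: int = MIN_CONTIG_LENGTH,
    depth_floor: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> Bead:
    """Assembly surrogate: emit maximal amplified intervals as contigs.

    Contigs are intervals where depth > ``depth_floor`` of length
    >= ``min_contig``; their sequences are genome slices with optional
    simulated consensus errors.  A bead whose profiles contain no such
    interval yields no contigs ("no viral sequence detected")."""
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    for gid, prof in bead.coverage_profiles.items():
        g = community.genome(gid)
        above = prof > depth_floor
        # boundaries of True runs
        padded = np.concatenate([[False], above, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            if e - s < min_contig:
                continue
            seq = _mutate(rng, g.sequence[s:e], error_rate)
            contigs.append(
                Contig(
                    contig_id=f"{bead.bead_id}_c{len(contigs):03d}",
                    bead_id=bead.bead_id,
                    sequence=seq,
                    source_genome_id=gid,
                    source_interval=(int(s), int(e)),
                )
            )
    bead.contigs = contigs
    return bead


def simulate_run(
    community: Community,
    n_beads: int,
    mean_loading: float,
    bias: BiasModel | None = None,
    seed: int = 0,
    method_label: str = "I",
    sort_limit: int | None = None,
    min_contig: int = MIN_CONTIG_LENGTH,
) -> tuple[list[Bead], RunManifest]:
    """Full bead-level simulation: encapsulate, amplify, fragment.

    Positive beads (up to ``sort_limit``) are "sorted" for sequencing;
    contigs are generated for sorted beads only.  Reads are not generated
    here — callers needing read sets call :func:`generate_reads` per bead.
    """
    bias = bias or BiasModel()
    rng = np.random.default_rng(seed)
    beads = encapsulate(community, n_beads, mean_loading, seed=int(rng.integers(2**31)))
    manifest = RunManifest(
        method_label=method_label, seed=seed, n_beads_generated=n_beads
    )
    positive = []
    for bead in beads:
        amplify(bead, community, bias, seed=int(rng.integers(2**31)))
        if bead.positive:
            positive.append(bead)
    manifest.n_beads_positive = len(positive)
    sorted_beads = positive if sort_limit is None else positive[:sort_limit]
    for bead in sorted_beads:
        fragment_to_contigs(
            bead, community, min_contig=min_contig, seed=int(rng.integers(2**31))
        )
        manifest.records.append(
            {
                "bead_id": bead.bead_id,
                "n_loaded": bead.n_loaded,
                "loaded_genomes": ";".join(bead.loaded_genomes),
                "n_contigs": len(bead.contigs),
                "sorted": True,
            }
        )
    manifest.n_beads_sorted = len(sorted_beads)
    manifest.validate()
    return sorted_beads, manifest
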