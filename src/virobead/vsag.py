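"""Per-bead vSAG construction.

A bead's contigs pass a virality filter, are binned on canonical
tetranucleotide frequency (TNF) plus pooled-read abundance, concatenated
with poly-N linkers, scored for completeness against an expected-length
model, and reduced to a single vSAG: the highest-completeness bin (>0%);
all other bins are excluded as potential contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .beads import Bead, Contig
from .community import Community, ParameterError

MIN_BIN_SIZE = 10_000
LINKER_LENGTH = 100
MIN_LINKER_RUN = 10  # any N-run at least this long is treated as a linker
TIER_HIGH = 90.0
TIER_MEDIUM = 50.0

# --- canonical tetranucleotide classes -------------------------------------

_ASCII_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ASCII_CODE[_b] = _i
    _ASCII_CODE[_b + 32] = _i  # lowercase


def _rc_code(code: int) -> int:
    b = [(code >> s) & 3 for s in (6, 4, 2, 0)]
    rb = [3 - x for x in reversed(b)]
    return (rb[0] << 6) | (rb[1] << 4) | (rb[2] << 2) | rb[3]


_CANON = np.empty(256, dtype=np.int64)
_canon_index: dict[int, int] = {}
for _c in range(256):
    key = min(_c, _rc_code(_c))
    if key not in _canon_index:
        _canon_index[key] = len(_canon_index)
    _CANON[_c] = _canon_index[key]
N_TNF_CLASSES = len(_canon_index)  # 136
assert N_TNF_CLASSES == 136


def compute_tnf(sequence: str) -> np.ndarray:
    """Canonical tetranucleotide frequency vector (136 classes, unit sum).

    Forward-strand 4-mers are pooled with their reverse complements;
    windows containing non-ACGT symbols are skipped, so the vector is
    invariant to reverse complementation and to N-linkers.
    """
    if len(sequence) < 1000:
        raise ParameterError("TNF requires sequences >= 1 kb")
    a = _ASCII_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    valid = a != 255
    a = np.where(valid, a, 0).astype(np.int64)
    codes = (a[:-3] << 6) | (a[1:-2] << 4) | (a[2:-1] << 2) | a[3:]
    ok = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    counts = np.bincount(_CANON[codes[ok]], minlength=N_TNF_CLASSES).astype(float)
    total = counts.sum()
    if total == 0:
        raise ParameterError("no valid 4-mer window in sequence")
    return counts / total


# --- features and virality filter -------------------------------------------


@dataclass(frozen=True)
class ContigFeatures:
    contig_id: str
    tnf: np.ndarray
    abundance: float
    length: int


def virality_score(contig: Contig, community: Community) -> float:
    """Surrogate viral score: fraction of the contig covered by annotated
    genes of its source genome (ground-truth-aware; background contigs have
    no viral genes and score 0).  Pluggable scorers replace this in
    real-data mode."""
    try:
        genome = community.genome(contig.source_genome_id)
    except KeyError:  # background / unknown provenance
        return 0.0
    s0, e0 = contig.source_interval
    covered = 0
    for g in genome.genes:
        covered += max(0, min(g.end, e0) - max(g.start, s0))
    return covered / max(1, e0 - s0)


def virality_filter(
    contigs: list[Contig],
    community: Community | None = None,
    score_threshold: float = 0.3,
    scorer=None,
) -> tuple[list[Contig], dict[str, float]]:
    """Keep contigs whose viral score reaches ``score_threshold``."""
    if scorer is None:
        if community is None:
            raise ParameterError("need a community (simulation) or a scorer")
        scorer = lambda c: virality_score(c, community)
    scores = {c.contig_id: float(scorer(c)) for c in contigs}
    kept = [c for c in contigs if scores[c.contig_id] >= score_threshold]
    return kept, scores


def contig_features(
    contigs: list[Contig],
    community: Community | None = None,
    abundances: dict[str, float] | None = None,
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> list[ContigFeatures]:
    """TNF + abundance features per contig.

    Abundance is the contig's mean depth in the pooled ("metagenomic") read
    set.  In simulation mode it is derived from the community relative
    abundance of the source genome with lognormal measurement noise;
    alternatively a precomputed ``abundances`` table (contig_id -> depth)
    is consumed.
    """
    rng = np.random.default_rng(seed)
    feats = []
    for c in contigs:
        if abundances is not None:
            ab = abundances.get(c.contig_id, 0.0)
        elif community is not None:
            try:
                base = community.abundance_map[c.source_genome_id]
            except KeyError:
                base = (
                    community.background_genome.abundance
                    if community.background_genome is not None
                    else 1e-6
                )
            ab = base * float(rng.lognormal(0.0, noise_sigma))
        else:
            raise ParameterError("need community or abundances table")
        feats.append(
            ContigFeatures(
                contig_id=c.contig_id,
                tnf=compute_tnf(c.sequence),
                abundance=float(ab),
                length=len(c.sequence),
            )
        )
    return feats


# --- binning -----------------------------------------------------------------


@dataclass
class Bin:
    bin_id: str
    bead_id: str
    contig_ids: list[str]
    total_length: int
    concatenated_sequence: str = ""
    completeness: float | None = None
    quality_tier: str = "low"


@dataclass(frozen=True)
class VSAG:
    vsag_id: str
    bead_id: str
    selected: Bin
    excluded_bins: tuple[Bin, ...]
    n_contigs: int
    is_single_contig: bool


def bin_bead(
    features: list[ContigFeatures],
    bead_id: str = "",
    min_bin_size: int = MIN_BIN_SIZE,
    tnf_weight: float = 1.0,
    abund_weight: float = 0.5,
    cutoff: float = 0.25,
) -> list[Bin]:
    """Cluster one bead's contigs into bins.

    Pairwise distance = tnf_weight * Euclidean TNF distance
    + abund_weight * |log abundance ratio|; single-linkage clustering cut at
    ``cutoff``.  Clusters whose total length falls below ``min_bin_size``
    are discarded (the bead may end up bin-free).
    """
    if not features:
        return []
    if len(features) == 1:
        groups = {1: [features[0]]}
    else:
        X = np.stack([f.tnf for f in features])
        d_tnf = pdist(X, metric="euclidean")
        la = np.log(np.maximum(1e-12, [f.abundance for f in features]))
        d_ab = pdist(la[:, None], metric="cityblock")
        Z = linkage(tnf_weight * d_tnf + abund_weight * d_ab, method="single")
        labels = fcluster(Z, t=cutoff, criterion="distance")
        groups = {}
        for f, lab in zip(features, labels):
            groups.setdefault(int(lab), []).append(f)
    bins = []
    for lab in sorted(groups, key=lambda l: -sum(f.length for f in groups[l])):
        members = groups[lab]
        total = sum(f.length for f in members)
        if total < min_bin_size:
            continue
        bins.append(
            Bin(
                bin_id=f"{bead_id}_bin{len(bins):02d}",
                bead_id=bead_id,
                contig_ids=[f.contig_id for f in members],
                total_length=total,
            )
        )
    return bins


def concatenate_with_polyN(
    bin_: Bin, sequences: dict[str, str], linker_len: int = LINKER_LENGTH
) -> str:
    """Join a bin's contigs (descending length) with poly-N linkers."""
    if not bin_.contig_ids:
        raise ParameterError("empty bin")
    seqs = sorted(
        (sequences[cid] for cid in bin_.contig_ids), key=len, reverse=True
    )
    joined = ("N" * linker_len).join(seqs)
    bin_.concatenated_sequence = joined
    return joined


def split_on_linkers(sequence: str, min_run: int = MIN_LINKER_RUN) -> list[str]:
    """Inverse of poly-N concatenation: split on maximal N-runs >= min_run."""
    parts = []
    cur = []
    run = 0
    for ch in sequence:
        if ch == "N":
            run += 1
            continue
        if run >= min_run and cur:
            parts.append("".join(cur))
            cur = []
        elif run and cur:
            cur.extend("N" * run)
        run = 0
        cur.append(ch)
    if cur:
        parts.append("".join(cur))
    return parts


def ungapped_length(bin_: Bin) -> int:
    if bin_.concatenated_sequence:
        return sum(len(p) for p in split_on_linkers(bin_.concatenated_sequence))
    return bin_.total_length


def estimate_completeness(
    bin_: Bin, expected_length: float | None
) -> float | None:
    """Expected-length completeness surrogate.

    completeness = 100 * min(1, ungapped bin length / expected genome
    length).  Quality tiers follow the common convention: high >= 90%,
    medium >= 50%, low otherwise.  Without a length model the bin is kept
    with tier "low" and completeness None.
    """
    if not bin_.contig_ids:
        raise ParameterError("cannot score an empty bin")
    if expected_length is None or expected_length <= 0:
        bin_.completeness = None
        bin_.quality_tier = "low"
        return None
    c = 100.0 * min(1.0, ungapped_length(bin_) / float(expected_length))
    bin_.completeness = c
    bin_.quality_tier = "high" if c >= TIER_HIGH else "medium" if c >= TIER_MEDIUM else "low"
    return c


def select_vsag(bins: list[Bin], vsag_id: str | None = None) -> VSAG | None:
    """Pick the bead's vSAG: the bin with highest completeness > 0.

    Ties break toward larger total length, then lexically smaller bin id.
    All other bins are recorded as excluded.  Returns None when no bin
    qualifies (the bead counts as "no viral sequence").
    """
    if not bins:
        return None
    scored = [b for b in bins if (b.completeness or 0) > 0]
    if not scored:
        return None
    best = min(scored, key=lambda b: (-(b.completeness or 0), -b.total_length, b.bin_id))
    others = tuple(b for b in bins if b is not best)
    return VSAG(
        vsag_id=vsag_id or best.bin_id.replace("_bin", "_vsag"),
        bead_id=best.bead_id,
        selected=best,
        excluded_bins=others,
        n_contigs=len(best.contig_ids),
        is_single_contig=len(best.contig_ids) == 1,
    )


def build_vsags_for_bead(
    bead: Bead,
    community: Community,
    score_threshold: float = 0.3,
    min_bin_size: int = MIN_BIN_SIZE,
    cutoff: float = 0.25,
    abund_weight: float = 0.5,
    seed: int = 0,
) -> tuple[VSAG | None, list[Bin]]:
    """Full per-bead pipeline: filter -> features -> bin -> concatenate ->
    completeness -> selection (simulation mode, ground-truth provenance)."""
    kept, _ = virality_filter(bead.contigs, community, score_threshold)
    if not kept:
        return None, []
    feats = contig_features(kept, community, seed=seed)
    bins = bin_bead(
        feats,
        bead_id=bead.bead_id,
        min_bin_size=min_bin_size,
        cutoff=cutoff,
        abund_weight=abund_weight,
    )
    seq_by_id = {c.contig_id: c.sequence for c in kept}
    src_by_id = {c.contig_id: c.source_genome_id for c in kept}
    len_by_id = {c.contig_id: len(c.sequence) for c in kept}
    for b in bins:
        concatenate_with_polyN(b, seq_by_id)
        # Expected length: the majority-provenance source genome (by length).
        by_src: dict[str, int] = {}
        for cid in b.contig_ids:
            by_src[src_by_id[cid]] = by_src.get(src_by_id[cid], 0) + len_by_id[cid]
        major = max(by_src, key=lambda s: by_src[s])
        estimate_completeness(b, community.genome(major).length)
    return select_vsag(bins), bins


def bin_purity(bin_: Bin, contigs_by_id: dict[str, Contig]) -> float:
    """Length-weighted purity of a bin by ground-truth provenance."""
    by_src: dict[str, int] = {}
    for cid in bin_.contig_ids:
        c = contigs_by_id[cid]
        by_src[c.source_genome_id] = by_src.get(c.source_genome_id, 0) + c.length
    return max(by_src.values()) / sum(by_src.values())
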