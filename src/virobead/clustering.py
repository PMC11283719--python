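"""Genome- and protein-level clustering.

Three layers mirror standard uncultivated-virus practice:

- vOTUs: species-level genome clusters under the MiUViG criteria
  (ANI >= 95% over an aligned fraction >= 85% of the shorter sequence),
  built by greedy centroid clustering from fragment-based ANI estimates;
- PCs: protein clusters from a k-mer similarity graph partitioned by
  Markov clustering (MCL);
- VCs: genus/subfamily-level viral clusters from the protein-sharing
  network, with hypergeometric edge significance and MCL partitioning.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import scipy.sparse as sp
from scipy.stats import hypergeom

from .community import ParameterError, reverse_complement

ANI_SPECIES = 95.0
AF_SPECIES = 85.0

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODONS = {"ATG", "GTG", "TTG"}

_CODON_TABLE = {}
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_B = "TCAG"
for _i, (_b1, _b2, _b3) in enumerate(
    (a, b, c) for a in _B for b in _B for c in _B
):
    _CODON_TABLE[_b1 + _b2 + _b3] = _AA[_i]


@dataclass(frozen=True)
class ANIRecord:
    query_id: str
    target_id: str
    ani: float  # percent; nan when no fragment aligns
    af: float  # percent of the shorter sequence aligned

    @property
    def is_species_match(self) -> bool:
        return (not np.isnan(self.ani)) and self.ani >= ANI_SPECIES and self.af >= AF_SPECIES


@dataclass
class VOTU:
    votu_id: str
    centroid_id: str
    member_ids: list[str]


@dataclass
class ProteinCluster:
    pc_id: str
    members: list[tuple[str, str]]  # (genome_id, gene_id)
    is_amg_pc: bool = False
    n_vcs_touched: int = 0


@dataclass
class ViralCluster:
    vc_id: str
    member_ids: list[str]
    representative_id: str


@dataclass(frozen=True)
class PredictedGene:
    gene_id: str
    start: int
    end: int
    strand: str
    protein: str


def _strip_n(seq: str) -> str:
    return seq.replace("N", "").replace("n", "")


def compute_ani_af(
    a: str,
    b: str,
    query_id: str = "a",
    target_id: str = "b",
    fragment: int = 1000,
    kmer_seed: int = 15,
    seed_stride: int = 25,
    min_fragment_identity: float = 0.7,
) -> ANIRecord:
    """Fragment-based ANI and aligned fraction between two sequences.

    ``a`` is cut into non-overlapping fragments; each fragment is located
    on ``b`` by shared-k-mer offset voting and aligned with an infix edit
    alignment.  ANI is the length-weighted mean identity of fragments that
    align at >= ``min_fragment_identity``; AF is their total length over
    the shorter (N-stripped) sequence.
    """
    a_clean, b_clean = _strip_n(a), _strip_n(b)
    if len(a_clean) < 1000 or len(b_clean) < 1000:
        raise ParameterError("ANI requires both sequences >= 1 kb after N-stripping")

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(0, len(b_clean) - kmer_seed + 1):
        km = b_clean[i : i + kmer_seed]
        if len(index[km]) < 8:
            index[km].append(i)

    def align_piece(piece: str) -> list[tuple[int, float]]:
        """Align one piece of ``a`` to ``b``; split and retry when the match
        is poor (an insertion in either sequence corrupts part of a piece
        without invalidating the rest)."""
        votes: Counter[int] = Counter()
        for off in range(0, len(piece) - kmer_seed + 1, seed_stride):
            for pos in index.get(piece[off : off + kmer_seed], ()):
                votes[pos - off] += 1
        identity = -1.0
        if votes:
            offset = votes.most_common(1)[0][0]
            margin = max(50, len(piece) // 10)
            lo = max(0, offset - margin)
            hi = min(len(b_clean), offset + len(piece) + margin)
            window = b_clean[lo:hi]
            if len(window) >= len(piece) // 2:
                res = edlib.align(piece, window, mode="HW", task="distance")
                identity = 1.0 - res["editDistance"] / len(piece)
        if identity >= 0.95:
            return [(len(piece), identity)]
        if len(piece) >= 500:  # refine: half-pieces re-seed independently
            mid = len(piece) // 2
            return align_piece(piece[:mid]) + align_piece(piece[mid:])
        if identity >= min_fragment_identity:
            return [(len(piece), identity)]
        return []

    aligned_len = 0
    weighted_id = 0.0
    for fs in range(0, len(a_clean) - fragment // 2 + 1, fragment):
        frag = a_clean[fs : fs + fragment]
        if len(frag) < fragment // 2:
            continue
        for plen, pid in align_piece(frag):
            aligned_len += plen
            weighted_id += pid * plen
    shorter = min(len(a_clean), len(b_clean))
    af = 100.0 * aligned_len / shorter
    ani = 100.0 * weighted_id / aligned_len if aligned_len else float("nan")
    return ANIRecord(query_id=query_id, target_id=target_id, ani=ani, af=min(af, 100.0))


def cluster_votus(
    genomes: list[tuple[str, float, int]],
    ani_records: list[ANIRecord],
    ani_min: float = ANI_SPECIES,
    af_min: float = AF_SPECIES,
) -> list[VOTU]:
    """Greedy centroid clustering into species-level vOTUs.

    ``genomes`` is (genome_id, completeness, length).  Genomes are ranked
    by completeness then length (descending, id as final tie-break); each
    genome joins the first centroid it matches at ANI >= 95 and AF >= 85,
    otherwise founds a new vOTU.  The outcome is order-independent given
    the deterministic ranking.
    """
    match: dict[tuple[str, str], bool] = {}
    for r in ani_records:
        ok = (not np.isnan(r.ani)) and r.ani >= ani_min and r.af >= af_min
        match[(r.query_id, r.target_id)] = ok or match.get((r.query_id, r.target_id), False)
        match[(r.target_id, r.query_id)] = ok or match.get((r.target_id, r.query_id), False)

    order = sorted(genomes, key=lambda g: (-g[1], -g[2], g[0]))
    votus: list[VOTU] = []
    for gid, _c, _l in order:
        placed = False
        for v in votus:
            if match.get((gid, v.centroid_id), False):
                v.member_ids.append(gid)
                placed = True
                break
        if not placed:
            votus.append(
                VOTU(votu_id=f"vOTU{len(votus) + 1:04d}", centroid_id=gid, member_ids=[gid])
            )
    return votus


# --- ORF calling -------------------------------------------------------------


def _translate(seq: str) -> str:
    return "".join(
        _CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def find_orfs(sequence: str, min_aa: int = 60, id_prefix: str = "orf") -> list[PredictedGene]:
    """Simple six-frame ORF scan (start codon to stop, standard code).

    Within each stop-bounded region the first ATG/GTG/TTG start is used;
    ORFs shorter than ``min_aa`` are dropped, and overlapping calls are
    resolved longest-first.  Coordinates are 0-based half-open on the
    forward strand; minus-strand proteins are translated from the reverse
    complement.
    """
    L = len(sequence)
    candidates: list[tuple[int, int, str, str]] = []
    for strand, seq in (("+", sequence.upper()), ("-", reverse_complement(sequence.upper()))):
        for frame in range(3):
            region_start = frame
            i = frame
            while i + 3 <= len(seq):
                codon = seq[i : i + 3]
                if codon in STOP_CODONS:
                    _scan_region(seq, region_start, i + 3, min_aa, strand, L, candidates)
                    region_start = i + 3
                i += 3
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen: list[tuple[int, int, str, str]] = []
    occupied: list[tuple[int, int]] = []
    for c in candidates:
        if all(c[1] <= s or c[0] >= e for s, e in occupied):
            chosen.append(c)
            occupied.append((c[0], c[1]))
    chosen.sort(key=lambda c: c[0])
    return [
        PredictedGene(
            gene_id=f"{id_prefix}_{i:04d}", start=s, end=e, strand=st, protein=prot
        )
        for i, (s, e, st, prot) in enumerate(chosen)
    ]


def _scan_region(seq, region_start, stop_end, min_aa, strand, L, out) -> None:
    """Find the first start codon in a stop-bounded region; emit the ORF."""
    for j in range(region_start, stop_end - 3, 3):
        if seq[j : j + 3] in START_CODONS:
            aa_len = (stop_end - j) // 3 - 1  # exclude the stop
            if aa_len >= min_aa:
                prot = _translate(seq[j : stop_end - 3])
                if strand == "+":
                    out.append((j, stop_end, "+", prot))
                else:
                    out.append((L - stop_end, L - j, "-", prot))
            return


# --- protein clustering (MCL) ------------------------------------------------


def protein_kmer_jaccard(a: str, b: str, k: int = 4) -> float:
    sa = {a[i : i + k] for i in range(len(a) - k + 1)}
    sb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def markov_cluster(
    adjacency: sp.spmatrix,
    inflation: float = 2.0,
    expansion: int = 2,
    pruning: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[list[list[int]], bool]:
    """Markov clustering on a (symmetric, non-negative) adjacency matrix.

    Adds self-loops, column-normalises, then iterates expansion (matrix
    power), inflation (elementwise power + renormalisation) and pruning
    until the matrix is stable.  Clusters are the connected components of
    the converged matrix's nonzero pattern.  Returns (clusters, converged).
    """
    n = adjacency.shape[0]
    M = sp.csr_matrix(adjacency, dtype=float)
    M = M + sp.eye(n, format="csr")
    M = _normalize_columns(M)
    converged = False
    for _ in range(max_iter):
        last = M.copy()
        for _e in range(expansion - 1):
            M = M @ M
        M = M.power(inflation)
        M.data[M.data < pruning] = 0.0
        M.eliminate_zeros()
        M = _normalize_columns(M)
        diff = abs(M - last)
        if diff.nnz == 0 or diff.max() < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn("MCL did not converge; emitting current hard clustering")
    pattern = M + M.T
    n_comp, labels = sp.csgraph.connected_components(pattern, directed=False)
    clusters: list[list[int]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        clusters[lab].append(i)
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters, converged


def _normalize_columns(M: sp.csr_matrix) -> sp.csr_matrix:
    col_sums = np.asarray(M.sum(axis=0)).ravel()
    col_sums[col_sums == 0] = 1.0
    D = sp.diags(1.0 / col_sums)
    return (M @ D).tocsr()


def cluster_proteins(
    proteins: dict[tuple[str, str], str],
    jaccard_threshold: float = 0.5,
    inflation: float = 2.0,
    kmer: int = 4,
    similarity=None,
) -> list[ProteinCluster]:
    """Cluster proteins into PCs via a similarity graph partitioned by MCL.

    ``proteins`` maps (genome_id, gene_id) -> amino-acid sequence.  The
    default similarity is amino-acid 4-mer Jaccard with edges at >= 0.5; a
    custom ``similarity(a, b) -> float`` may replace it.
    """
    if not proteins:
        raise ParameterError("no proteins to cluster")
    keys = sorted(proteins)
    sim = similarity or (lambda a, b: protein_kmer_jaccard(a, b, k=kmer))
    n = len(keys)

    # MinHash prescreen: pairs sharing >= 2 of 16 minimum k-mer hashes are
    # candidate edges; pairs below ~0.1 Jaccard almost never qualify, which
    # keeps the candidate set near-linear in the number of proteins.
    from zlib import crc32

    n_hashes = 16
    kmer_sets = []
    sketches = []
    for key in keys:
        s = proteins[key]
        ks = {s[j : j + kmer] for j in range(len(s) - kmer + 1)}
        kmer_sets.append(ks)
        hashes = sorted(crc32(km.encode()) for km in ks)
        sketches.append(hashes[:n_hashes])
    buckets: dict[int, list[int]] = defaultdict(list)
    for i, sk in enumerate(sketches):
        for h in sk:
            buckets[h].append(i)
    shared_count: Counter[tuple[int, int]] = Counter()
    for h, idxs in buckets.items():
        if len(idxs) < 2:
            continue
        for x in range(len(idxs)):
            for y in range(x + 1, len(idxs)):
                shared_count[(idxs[x], idxs[y])] += 1
    candidates = {pair for pair, c in shared_count.items() if c >= 2}

    rows, cols, vals = [], [], []
    for i, j in candidates:
        w = (
            len(kmer_sets[i] & kmer_sets[j]) / len(kmer_sets[i] | kmer_sets[j])
            if similarity is None
            else sim(proteins[keys[i]], proteins[keys[j]])
        )
        if w >= jaccard_threshold:
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    clusters, _ = markov_cluster(A, inflation=inflation)
    return [
        ProteinCluster(pc_id=f"PC{c:05d}", members=[keys[i] for i in idxs])
        for c, idxs in enumerate(clusters)
    ]


# --- protein-sharing viral-cluster network ----------------------------------


def build_vc_network(
    genome_pcs: dict[str, set[str]],
    completeness: dict[str, float],
    lengths: dict[str, int],
    significance: float = 1.0,
    inflation: float = 2.0,
    min_pcs: int = 2,
) -> tuple[list[ViralCluster], list[tuple[str, str, float]]]:
    """Cluster genomes into VCs from their shared-PC profiles.

    Edge weight between two genomes = -log10 of the hypergeometric
    upper-tail probability of sharing at least the observed number of PCs
    given each genome's PC count and the PC universe; edges below
    ``significance`` are dropped, the surviving graph is partitioned by
    MCL, and each VC's representative is its highest-completeness member
    (longer genome on ties).  Genomes with fewer than ``min_pcs`` PCs, or
    sharing no PC with any other genome, are outliers and join no VC.
    """
    universe: set[str] = set()
    for pcs in genome_pcs.values():
        universe |= pcs
    if not universe:
        raise ParameterError("empty PC universe")
    N = len(universe)
    nodes = sorted(g for g, pcs in genome_pcs.items() if len(pcs) >= min_pcs)
    edges: list[tuple[str, str, float]] = []
    rows, cols, vals = [], [], []
    idx = {g: i for i, g in enumerate(nodes)}
    for x in range(len(nodes)):
        for y in range(x + 1, len(nodes)):
            a, b = nodes[x], nodes[y]
            shared = len(genome_pcs[a] & genome_pcs[b])
            if shared == 0:
                continue
            p = float(hypergeom.sf(shared - 1, N, len(genome_pcs[a]), len(genome_pcs[b])))
            w = -np.log10(max(p, 1e-300))
            if w >= significance:
                edges.append((a, b, float(w)))
                rows += [x, y]
                cols += [y, x]
                vals += [w, w]
    A = sp.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    clusters, _ = markov_cluster(A, inflation=inflation)
    vcs: list[ViralCluster] = []
    for idxs in clusters:
        members = [nodes[i] for i in idxs]
        if len(members) < 2:
            continue  # singletons in the network are outliers, not VCs
        rep = min(
            members,
            key=lambda g: (-completeness.get(g, 0.0), -lengths.get(g, 0), g),
        )
        vcs.append(
            ViralCluster(
                vc_id=f"VC{len(vcs) + 1:03d}", member_ids=members, representative_id=rep
            )
        )
    return vcs, edges


def annotate_pc_vc_incidence(
    pcs: list[ProteinCluster], vcs: list[ViralCluster]
) -> None:
    """Fill each PC's n_vcs_touched from the VC membership of its genomes."""
    vc_of = {}
    for vc in vcs:
        for g in vc.member_ids:
            vc_of[g] = vc.vc_id
    for pc in pcs:
        touched = {vc_of[g] for g, _ in pc.members if g in vc_of}
        pc.n_vcs_touched = len(touched)
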