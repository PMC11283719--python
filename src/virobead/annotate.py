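"""Taxonomy, AMG and comparative-genomics analytics.

Implements the decision logic layered on top of external homology results:
consensus taxonomy by protein-hit voting, marker-gene conflict resolution,
AMG identification gated on auxiliary scores 1-3, the AMG-vs-PC-sharing
contingency analysis (exact Fisher test), read-recruitment diversity
curves, and within-species core/flexible orthologous-group comparison with
cassette-insertion detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde, hypergeom

from .community import ParameterError, ViralGenome
from .clustering import ProteinCluster


@dataclass(frozen=True)
class TaxonomyCall:
    genome_id: str
    lineage: tuple[str, ...]
    method: str  # vote | marker | none
    support: tuple[float, ...] = ()


@dataclass(frozen=True)
class AMGRecord:
    genome_id: str
    gene_id: str
    amg_category: str | None
    aux_score: int
    pc_id: str | None = None


@dataclass
class OGMatrix:
    og_ids: list[str]  # ordered core-first
    genome_ids: list[str]
    counts: np.ndarray  # ogs x genomes presence counts
    core: set[str]
    flexible: set[str]

    def presence(self, og: str, genome: str) -> int:
        return int(
            self.counts[self.og_ids.index(og), self.genome_ids.index(genome)]
        )


@dataclass(frozen=True)
class InsertionEvent:
    genome_id: str
    og_run: tuple[str, ...]
    left_flank: str | None
    right_flank: str | None

    @property
    def partial_flank(self) -> bool:
        return self.left_flank is None or self.right_flank is None


@dataclass
class RecruitmentCurve:
    identity: np.ndarray  # percent identity grid
    percentage: np.ndarray  # % of recruited reads per identity value
    n_reads: int
    reads_per_base: float | None = None


# --- taxonomy ----------------------------------------------------------------


def vote_taxonomy(
    genome_id: str,
    n_proteins: int,
    best_hit_lineages: list[tuple[str, ...]],
    min_hit_fraction: float = 0.30,
    majority: float = 0.50,
) -> TaxonomyCall:
    """Consensus lineage by per-protein best-hit voting.

    A call is made only when strictly more than ``min_hit_fraction`` of the
    genome's proteins have a reference hit.  Ranks are then assigned from
    the top downward to the value held by strictly more than ``majority``
    of hit proteins, stopping at the first rank without a majority.
    """
    if n_proteins <= 0:
        raise ParameterError("n_proteins must be > 0")
    hits = [l for l in best_hit_lineages if l]
    if len(hits) / n_proteins <= min_hit_fraction:
        return TaxonomyCall(genome_id, (), "none")
    lineage: list[str] = []
    support: list[float] = []
    depth = max(len(l) for l in hits)
    for rank in range(depth):
        votes: dict[str, int] = {}
        for l in hits:
            if rank < len(l):
                votes[l[rank]] = votes.get(l[rank], 0) + 1
        if not votes:
            break
        top = max(votes, key=lambda v: (votes[v], v))
        frac = votes[top] / len(hits)
        if frac <= majority:
            break
        lineage.append(top)
        support.append(frac)
    method = "vote" if lineage else "none"
    return TaxonomyCall(genome_id, tuple(lineage), method, tuple(support))


def marker_taxonomy(
    genome_id: str,
    marker_hits: list[tuple[tuple[str, ...], float, float]],
    score_min: float = 40.0,
    evalue_max: float = 1e-5,
) -> TaxonomyCall:
    """Marker-gene lineage with conflict resolution.

    ``marker_hits`` is (lineage, score, evalue).  Hits below the inclusive
    score minimum or above the E-value ceiling are dropped; the call is the
    longest common prefix of the surviving marker lineages (conflicting
    markers truncate the annotation to the rank at which they agree).
    """
    surviving = [
        l for l, s, e in marker_hits if s >= score_min and e <= evalue_max and l
    ]
    if not surviving:
        return TaxonomyCall(genome_id, (), "none")
    prefix: list[str] = []
    for vals in zip(*surviving):
        if len(set(vals)) == 1:
            prefix.append(vals[0])
        else:
            break
    return TaxonomyCall(
        genome_id, tuple(prefix), "marker", tuple(1.0 for _ in prefix)
    )


# --- AMGs --------------------------------------------------------------------


def identify_amgs(
    genomes: list[ViralGenome],
    aux_score_range: set[int] = frozenset({1, 2, 3}),
    pc_of_gene: dict[tuple[str, str], str] | None = None,
) -> list[AMGRecord]:
    """Collect AMG records: genes with role AMG and auxiliary score in range."""
    pc_of_gene = pc_of_gene or {}
    records = []
    for g in genomes:
        for gene in g.genes:
            if gene.role == "AMG" and gene.aux_score in aux_score_range:
                records.append(
                    AMGRecord(
                        genome_id=g.genome_id,
                        gene_id=gene.gene_id,
                        amg_category=gene.amg_category,
                        aux_score=gene.aux_score,
                        pc_id=pc_of_gene.get((g.genome_id, gene.gene_id)),
                    )
                )
    return records


def fisher_exact_2x2(table: list[list[int]]) -> dict:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    Enumerates the table's support at fixed margins and sums the
    probabilities of all tables no more probable than the observed one.
    Degenerate margins give p = 1.0 with a flag; the odds ratio uses the
    Haldane (+0.5) correction when any cell is zero.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ParameterError("cell counts must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if any(x == 0 for x in (r1, r2, c1, b + d)):
        odds = np.nan if (b == 0 and c == 0) or (a == 0 and d == 0) else 0.0
        return {"table": table, "p_value": 1.0, "odds_ratio": odds, "degenerate": True}
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    probs = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = float(probs[probs <= p_obs * (1.0 + 1e-7)].sum())
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return {
        "table": table,
        "p_value": min(1.0, p),
        "odds_ratio": float(odds),
        "degenerate": False,
    }


def amg_sharing_test(pcs: list[ProteinCluster]) -> dict:
    """Are AMG-containing PCs over-represented among PCs shared by multiple
    VCs?  Builds the 2x2 table (rows: PC in multiple VCs / single VC;
    columns: AMG-containing / not) and runs the exact Fisher test.
    """
    if any(pc.n_vcs_touched < 1 for pc in pcs):
        raise ParameterError("every PC must touch at least one VC")
    a = sum(1 for pc in pcs if pc.n_vcs_touched >= 2 and pc.is_amg_pc)
    b = sum(1 for pc in pcs if pc.n_vcs_touched >= 2 and not pc.is_amg_pc)
    c = sum(1 for pc in pcs if pc.n_vcs_touched == 1 and pc.is_amg_pc)
    d = sum(1 for pc in pcs if pc.n_vcs_touched == 1 and not pc.is_amg_pc)
    result = fisher_exact_2x2([[a, b], [c, d]])
    result["multi_vc_pc_fraction"] = (a + b) / max(1, len(pcs))
    return result


# --- abundance and recruitment ----------------------------------------------


def reads_per_base(mapped_read_count: int, reference_length: int) -> float:
    """Mapped reads per base of the reference (CoverM-style rpb metric)."""
    if reference_length <= 0:
        raise ParameterError("reference_length must be > 0")
    return mapped_read_count / reference_length


def recruitment_curve(
    identities: np.ndarray,
    query_coverages: np.ndarray,
    evalues: np.ndarray,
    id_min: float = 50.0,
    qcov_min: float = 80.0,
    evalue_max: float = 1e-5,
    smooth_bandwidth: float = 0.5,
    grid_step: float = 0.25,
    rpb: float | None = None,
) -> RecruitmentCurve:
    """Read-recruitment (diversity) curve for one VC representative.

    Reads are kept when identity >= ``id_min``, query coverage strictly
    exceeds ``qcov_min``, and E-value <= ``evalue_max``.  The identity
    density is Gaussian-kernel smoothed (bandwidth factor 0.5 of the data
    SD) on a 50-100% grid and scaled so the curve integrates to 100% of
    recruited reads.  A narrow peak near 100% indicates a clonal
    population; spread toward lower identities indicates microdiversity.
    """
    identities = np.asarray(identities, dtype=float)
    query_coverages = np.asarray(query_coverages, dtype=float)
    evalues = np.asarray(evalues, dtype=float)
    keep = (
        (identities >= id_min)
        & (query_coverages > qcov_min)
        & (evalues <= evalue_max)
    )
    kept = identities[keep]
    grid = np.arange(50.0, 100.0 + grid_step, grid_step)
    if kept.size == 0:
        return RecruitmentCurve(grid, np.zeros_like(grid), 0, rpb)
    if kept.size == 1 or float(np.std(kept)) == 0.0:
        pct = np.zeros_like(grid)
        pct[int(np.argmin(np.abs(grid - kept[0])))] = 100.0 / grid_step
    else:
        kde = gaussian_kde(kept, bw_method=smooth_bandwidth)
        dens = kde(grid)
        area = np.trapezoid(dens, grid)
        pct = dens / area * 100.0 if area > 0 else np.zeros_like(grid)
    return RecruitmentCurve(grid, pct, int(kept.size), rpb)


def curve_iqr(curve: RecruitmentCurve) -> float:
    """Interquartile range (percent identity) of a recruitment curve."""
    if curve.n_reads == 0:
        return 0.0
    w = curve.percentage
    cum = np.cumsum(w)
    if cum[-1] == 0:
        return 0.0
    cum = cum / cum[-1]
    q1 = float(np.interp(0.25, cum, curve.identity))
    q3 = float(np.interp(0.75, cum, curve.identity))
    return q3 - q1


# --- core/flexible comparative genomics -------------------------------------


def build_og_matrix(members: dict[str, list[tuple[str, str]]]) -> OGMatrix:
    """Orthologous-group presence matrix for one vOTU.

    ``members`` maps genome_id -> [(gene_id, og_label)] in genome order.
    An OG is core when present in every member, flexible otherwise; rows
    are ordered core-first.  OG labels typically come from within-vOTU
    protein clustering (or ground truth in simulation mode).
    """
    if len(members) < 2:
        raise ParameterError("an OG matrix needs >= 2 member genomes")
    genome_ids = sorted(members)
    all_ogs = sorted({og for genes in members.values() for _, og in genes})
    counts = np.zeros((len(all_ogs), len(genome_ids)), dtype=int)
    og_index = {og: i for i, og in enumerate(all_ogs)}
    for j, gid in enumerate(genome_ids):
        if not members[gid]:
            import warnings

            warnings.warn(f"{gid}: no genes; zero column in OG matrix")
        for _, og in members[gid]:
            counts[og_index[og], j] += 1
    core = {og for og in all_ogs if (counts[og_index[og]] > 0).all()}
    flexible = set(all_ogs) - core
    order = sorted(all_ogs, key=lambda og: (og not in core, og))
    counts = counts[[og_index[og] for og in order]]
    return OGMatrix(
        og_ids=order, genome_ids=genome_ids, counts=counts, core=core, flexible=flexible
    )


def detect_insertions(
    members: dict[str, list[tuple[str, str]]], matrix: OGMatrix
) -> list[InsertionEvent]:
    """Find flexible-gene insertions bounded by core flanks.

    For each member genome, maximal runs of consecutive flexible-OG genes
    are reported with the nearest core OG on each side (partial flanks at
    genome ends).  The per-member event tables drive strain-level cassette
    comparisons such as MTase subtype profiling.
    """
    events: list[InsertionEvent] = []
    for gid in matrix.genome_ids:
        ogs = [og for _, og in members[gid]]
        i = 0
        while i < len(ogs):
            if ogs[i] in matrix.flexible:
                j = i
                while j < len(ogs) and ogs[j] in matrix.flexible:
                    j += 1
                left = ogs[i - 1] if i > 0 and ogs[i - 1] in matrix.core else None
                right = ogs[j] if j < len(ogs) and ogs[j] in matrix.core else None
                events.append(
                    InsertionEvent(
                        genome_id=gid,
                        og_run=tuple(ogs[i:j]),
                        left_flank=left,
                        right_flank=right,
                    )
                )
                i = j
            else:
                i += 1
    return events
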