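"""ANI/AF, vOTU clustering, ORF calling, MCL protein clusters, VC network."""

import numpy as np
import pytest
import scipy.sparse as sp

from virobead import clustering as cl
from virobead.community import (
    Cassette,
    ParameterError,
    random_cds,
    random_sequence,
    reverse_complement,
)


class TestANI:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        s = random_sequence(rng, 20_000, 0.5)
        r = cl.compute_ani_af(s, s)
        assert r.ani == pytest.approx(100.0)
        assert r.af == pytest.approx(100.0)

    def test_unrelated_sequences_barely_align(self):
        rng = np.random.default_rng(1)
        a = random_sequence(rng, 20_000, 0.5)
        b = random_sequence(rng, 20_000, 0.5)
        r = cl.compute_ani_af(a, b)
        assert r.af < 10.0

    def test_symmetry_on_simulated_pair(self, strain_group):
        _, _, strains = strain_group
        r1 = cl.compute_ani_af(strains[0].sequence, strains[2].sequence)
        r2 = cl.compute_ani_af(strains[2].sequence, strains[0].sequence)
        assert abs(r1.ani - r2.ani) <= 1.0

    def test_n_linkers_stripped(self):
        rng = np.random.default_rng(2)
        s = random_sequence(rng, 10_000, 0.5)
        with_n = s[:5000] + "N" * 200 + s[5000:]
        r = cl.compute_ani_af(with_n, s)
        assert r.ani > 99.5 and r.af > 95.0

    def test_short_input_rejected(self):
        with pytest.raises(ParameterError):
            cl.compute_ani_af("ACGT" * 100, "ACGT" * 1000)


class TestClusterVotus:
    def _records(self, ids, matcher):
        recs = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ani, af = matcher(ids[i], ids[j])
                recs.append(cl.ANIRecord(ids[i], ids[j], ani, af))
        return recs

    def test_species_group_merges(self):
        ids = [f"s{i}" for i in range(7)]
        recs = self._records(ids, lambda a, b: (99.5, 95.0))
        genomes = [(g, 90.0 - i, 40_000 - 100 * i) for i, g in enumerate(ids)]
        votus = cl.cluster_votus(genomes, recs)
        assert len(votus) == 1
        assert sorted(votus[0].member_ids) == sorted(ids)

    def test_distinct_genomes_stay_singletons(self):
        ids = ["a", "b", "c"]
        recs = self._records(ids, lambda a, b: (70.0, 30.0))
        votus = cl.cluster_votus([(g, 50.0, 30_000) for g in ids], recs)
        assert len(votus) == 3

    def test_order_invariance(self):
        ids = [f"g{i}" for i in range(6)]
        recs = self._records(ids, lambda a, b: (96.0, 90.0) if a[1] < "3" and b[1] < "3" else (80.0, 50.0))
        genomes = [(g, float(i), 30_000) for i, g in enumerate(ids)]
        v1 = cl.cluster_votus(genomes, recs)
        v2 = cl.cluster_votus(list(reversed(genomes)), recs)
        assert [sorted(v.member_ids) for v in v1] == [sorted(v.member_ids) for v in v2]

    def test_member_centroid_thresholds_hold(self):
        # vOTU soundness is assertable post hoc from the records
        ids = ["a", "b", "c"]
        recs = [
            cl.ANIRecord("a", "b", 99.0, 90.0),
            cl.ANIRecord("a", "c", 80.0, 90.0),
            cl.ANIRecord("b", "c", 80.0, 90.0),
        ]
        votus = cl.cluster_votus([(g, 50.0, 30_000) for g in ids], recs)
        lookup = {(r.query_id, r.target_id): r for r in recs}
        for v in votus:
            for m in v.member_ids:
                if m != v.centroid_id:
                    r = lookup.get((m, v.centroid_id)) or lookup.get((v.centroid_id, m))
                    assert r.ani >= 95 and r.af >= 85


class TestFindORFs:
    def test_planted_gene_recovered_exactly(self):
        rng = np.random.default_rng(3)
        gene = random_cds(rng, 300)
        seq = "TAATAA" + gene + "TAATAA"
        orfs = cl.find_orfs(seq, min_aa=50)
        assert any(seq[o.start : o.end] == gene and o.strand == "+" for o in orfs)

    def test_reverse_complement_flips_strands(self):
        rng = np.random.default_rng(4)
        gene = random_cds(rng, 600)
        seq = "TAATAA" + gene + "TAATAA" + random_sequence(rng, 500, 0.5)
        fwd = cl.find_orfs(seq)
        rev = cl.find_orfs(reverse_complement(seq))
        fwd_set = {(o.start, o.end, o.strand, o.protein) for o in fwd}
        L = len(seq)
        rev_map = {
            (L - o.end, L - o.start, "+" if o.strand == "-" else "-", o.protein)
            for o in rev
        }
        assert fwd_set == rev_map

    def test_recovers_planted_genes_on_simulated_genomes(self):
        from virobead import community as cm

        total = hit = 0
        for seed in range(5):
            defs = cm.make_og_definitions(80, 5, rng=seed)
            c = cm.generate_community(2, seed=10 + seed, with_background=False)
            g = cm.plant_genes(c.genomes[0], seed=20 + seed, og_sequences=defs)
            orfs = cl.find_orfs(g.sequence)
            pred = {
                (o.end, o.strand) if o.strand == "+" else (o.start, o.strand)
                for o in orfs
            }
            for gene in g.genes:
                total += 1
                key = (gene.end, "+") if gene.strand == "+" else (gene.start, "-")
                hit += key in pred
        assert hit / total >= 0.9


def dense_mcl_oracle(A, inflation=2.0, iters=200, prune=1e-5, tol=1e-6):
    """Independent dense-numpy Markov clustering for cross-checking; stops
    at the same stability criterion as the implementation under test."""
    M = np.asarray(A, dtype=float) + np.eye(A.shape[0])
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(iters):
        last = M.copy()
        M = M @ M
        M = M**inflation
        M[M < prune] = 0.0
        s = M.sum(axis=0, keepdims=True)
        s[s == 0] = 1
        M /= s
        if np.abs(M - last).max() < tol:
            break
    n, labels = sp.csgraph.connected_components(
        sp.csr_matrix((M + M.T) > 0), directed=False
    )
    return labels


class TestMCLAndProteinClusters:
    def test_two_cliques_split(self):
        A = np.zeros((6, 6))
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        A[i, j] = 1.0
        A[2, 3] = A[3, 2] = 0.05  # weak bridge
        clusters, converged = cl.markov_cluster(sp.csr_matrix(A))
        assert converged
        assert sorted(sorted(c) for c in clusters) == [[0, 1, 2], [3, 4, 5]]

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(4, 12))
            A = (rng.random((n, n)) < 0.3).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            clusters, _ = cl.markov_cluster(sp.csr_matrix(A))
            labels = dense_mcl_oracle(A)
            mine = np.empty(n, dtype=int)
            for ci, idxs in enumerate(clusters):
                mine[idxs] = ci
            # same partition up to label names
            pairs_mine = {(i, j) for i in range(n) for j in range(n) if mine[i] == mine[j]}
            pairs_orc = {(i, j) for i in range(n) for j in range(n) if labels[i] == labels[j]}
            assert pairs_mine == pairs_orc

    def test_identical_proteins_share_pc(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
        pcs = cl.cluster_proteins({("g1", "p1"): prot, ("g2", "p2"): prot})
        assert len(pcs) == 1 and len(pcs[0].members) == 2

    def test_planted_families_recovered(self):
        # families at ~3% amino-acid divergence must be recovered with high
        # agreement against the planted labels
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(6)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        proteins, truth = {}, []
        for fam in range(12):
            base = "".join(rng.choice(list(aas), size=250))
            for copy in range(4):
                p = list(base)
                for i in range(len(p)):
                    if rng.random() < 0.03:
                        p[i] = aas[int(rng.integers(0, 20))]
                proteins[(f"g{fam}_{copy}", f"p{fam}_{copy}")] = "".join(p)
                truth.append(fam)
        pcs = cl.cluster_proteins(proteins)
        label_of = {}
        for ci, pc in enumerate(pcs):
            for m in pc.members:
                label_of[m] = ci
        pred = [label_of[k] for k in sorted(proteins)]
        truth_sorted = [int(k[0].split("_")[0][1:]) for k in sorted(proteins)]
        assert adjusted_rand_score(truth_sorted, pred) >= 0.9


class TestVCNetwork:
    def test_full_overlap_strong_edge(self):
        from scipy.stats import hypergeom

        pcs = {f"PC{i}" for i in range(20)}
        universe = {f"PC{i}" for i in range(100)}
        genome_pcs = {"a": set(pcs), "b": set(pcs), "pad": set(universe)}
        vcs, edges = cl.build_vc_network(
            genome_pcs, {"a": 90.0, "b": 80.0, "pad": 10.0}, {"a": 1, "b": 1, "pad": 1}
        )
        w = next(w for s, t, w in edges if {s, t} == {"a", "b"})
        expected = -np.log10(hypergeom.sf(19, 100, 20, 20))
        assert w == pytest.approx(expected, rel=1e-9)
        assert w > 10

    def test_no_shared_pcs_no_edge(self):
        genome_pcs = {"a": {"PC1", "PC2"}, "b": {"PC3", "PC4"}}
        vcs, edges = cl.build_vc_network(genome_pcs, {}, {})
        assert edges == [] and vcs == []

    def test_representative_is_highest_completeness(self):
        pcs = {f"PC{i}" for i in range(10)}
        pad = {f"OTHER{i}" for i in range(90)}  # enlarge the PC universe
        genome_pcs = {"a": pcs, "b": pcs, "c": pcs, "pad": pad}
        vcs, _ = cl.build_vc_network(
            genome_pcs,
            {"a": 50.0, "b": 95.0, "c": 70.0, "pad": 10.0},
            {"a": 1, "b": 1, "c": 1, "pad": 1},
        )
        assert len(vcs) == 1
        assert sorted(vcs[0].member_ids) == ["a", "b", "c"]
        assert vcs[0].representative_id == "b"

    def test_genus_recovery_from_pc_overlap(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(7)
        genome_pcs, truth = {}, {}
        shared_global = [f"S{i}" for i in range(40)]
        for genus in range(4):
            pool = [f"g{genus}_PC{i}" for i in range(40)]
            for member in range(6):
                gid = f"genome_{genus}_{member}"
                own = rng.choice(pool, size=25, replace=False)
                extra = rng.choice(shared_global, size=1)
                genome_pcs[gid] = set(own) | set(extra)
                truth[gid] = genus
        vcs, _ = cl.build_vc_network(genome_pcs, {}, {})
        label = {g: -1 - i for i, g in enumerate(sorted(genome_pcs))}
        for ci, vc in enumerate(vcs):
            for g in vc.member_ids:
                label[g] = ci
        ids = sorted(genome_pcs)
        assert adjusted_rand_score([truth[g] for g in ids], [label[g] for g in ids]) >= 0.8

    def test_pc_vc_incidence(self):
        pcs = [
            cl.ProteinCluster("PC1", [("a", "x"), ("b", "y")]),
            cl.ProteinCluster("PC2", [("a", "z")]),
        ]
        vcs = [
            cl.ViralCluster("VC1", ["a"], "a"),
            cl.ViralCluster("VC2", ["b"], "b"),
        ]
        cl.annotate_pc_vc_incidence(pcs, vcs)
        assert pcs[0].n_vcs_touched == 2
        assert pcs[1].n_vcs_touched == 1
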