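"""End-to-end pipeline: simulate -> QC -> vSAGs -> clustering -> annotation
-> comparison -> report.

Every stage is deterministic for a fixed seed and writes its artifacts
(TSV/FASTA/CSV/JSON) under the output directory.  Desk-scale defaults
(~25 genomes, 1500 beads) keep a full run on one CPU in the low minutes;
all sizes are configuration values.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from . import annotate, beads as beads_mod, clustering, community as community_mod
from . import io as io_mod
from . import qc as qc_mod
from . import report as report_mod
from . import vsag as vsag_mod

log = logging.getLogger("virobead")

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "method_label": "I",
    "community": {
        "n_genomes": 25,
        "length_median": 40_000.0,
        "length_sigma": 0.6,
        "abundance_exponent": 1.5,
        "ssdna_fraction": 0.1,
    },
    "genes": {"gene_density": 1.0, "amg_fraction": 0.06},
    "strains": {"n_strains": 6, "snv_rate": 0.005, "n_cassettes": 6},
    "beads": {"n_beads": 1500, "mean_loading": 0.13, "sigma": 1.0, "dropout": 0.05},
    "reads": {
        "n_pairs_per_bead": 20_000,
        "pair_sigma": 0.8,
        "background_fraction": 0.05,
        "read_length": 150,
    },
    "vsag": {
        "score_threshold": 0.3,
        "min_bin_size": 10_000,
        "cutoff": 0.25,
        "abund_weight": 0.5,
    },
    "taxonomy": {"hit_rate": 0.6},
    "recruitment": {"reads_per_member": 150, "identity_sd": 1.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def make_config(override: dict | None = None) -> dict:
    return _merge(DEFAULT_CONFIG, override or {})


def build_community(cfg: dict, rng: np.random.Generator):
    """Generate the community, plant shared-pool genes, and embed one
    strain group.

    Gene content follows a genus-structured pool model: each genus has its
    own backbone OG pool (strong intra-genus protein sharing, none between
    genera) while AMGs come from one community-wide pool, so AMG protein
    clusters can recur across unrelated lineages — the pattern the
    protein-sharing analysis is designed to detect.
    """
    ccfg, gcfg, scfg = cfg["community"], cfg["genes"], cfg["strains"]
    comm = community_mod.generate_community(seed=int(rng.integers(2**31)), **ccfg)

    amg_defs = community_mod.make_og_definitions(
        0, gcfg.get("n_amg_ogs", 30), rng=int(rng.integers(2**31)), prefix="AMGOG"
    )
    genera: dict[str, list[int]] = {}
    for i, g in enumerate(comm.genomes):
        genera.setdefault(g.taxonomy[-1], []).append(i)
    pool_of_genus: dict[str, list[str]] = {}
    all_defs = dict(amg_defs)
    amg_labels = sorted(amg_defs)
    for genus, idxs in sorted(genera.items()):
        max_len = max(comm.genomes[i].length for i in idxs)
        n_backbone = max(60, max_len // 900 + 20)
        defs = community_mod.make_og_definitions(
            n_backbone, 0, rng=int(rng.integers(2**31)), prefix=f"{genus}_OG"
        )
        all_defs.update(defs)
        k = min(len(amg_labels), gcfg.get("amgs_per_genus", 8))
        picked = list(rng.choice(amg_labels, size=k, replace=False)) if k else []
        pool_of_genus[genus] = sorted(defs) + picked
    genomes = [
        community_mod.plant_genes(
            g,
            gene_density=gcfg["gene_density"],
            seed=int(rng.integers(2**31)),
            og_pool=pool_of_genus[g.taxonomy[-1]],
            og_sequences=all_defs,
        )
        for g in comm.genomes
    ]
    cassettes: list[community_mod.Cassette] = []
    abundances = list(comm.abundances)
    if scfg.get("n_strains", 0) > 1:
        # the most abundant dsDNA genome becomes a strain group
        parent_idx = next(
            i for i in np.argsort(-np.asarray(abundances))
            if genomes[i].nucleic_type == "dsDNA"
        )
        parent = genomes[parent_idx]
        cassettes = community_mod.make_mtase_cassettes(
            scfg["n_cassettes"], rng=int(rng.integers(2**31))
        )
        strains = community_mod.spawn_strains(
            parent,
            n_strains=scfg["n_strains"],
            snv_rate=scfg["snv_rate"],
            flexible_cassettes=cassettes,
            seed=int(rng.integers(2**31)),
        )
        share = abundances[parent_idx] / len(strains)
        genomes = [g for i, g in enumerate(genomes) if i != parent_idx] + strains
        abundances = [a for i, a in enumerate(abundances) if i != parent_idx] + [
            share
        ] * len(strains)
    total = sum(abundances)
    comm = community_mod.Community(
        genomes=tuple(genomes),
        abundances=tuple(a / total for a in abundances),
        background_genome=comm.background_genome,
    )
    return comm, cassettes


def simulate_mapping_counts(
    bead: beads_mod.Bead,
    community: community_mod.Community,
    n_reads: int,
    background_fraction: float,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Per-reference mapped-read counts for one bead (multinomial over the
    amplified yields plus the background carry-over fraction)."""
    weights = {g: float(p.sum()) for g, p in bead.coverage_profiles.items()}
    counts: dict[str, int] = {}
    n_bg = rng.binomial(n_reads, background_fraction) if background_fraction > 0 else 0
    if community.background_genome is not None and n_bg:
        counts[community.background_genome.genome_id] = int(n_bg)
    n_viral = n_reads - n_bg
    tot = sum(weights.values())
    if tot > 0 and n_viral > 0:
        gids = sorted(weights)
        p = np.array([weights[g] for g in gids]) / tot
        draw = rng.multinomial(n_viral, p)
        for g, c in zip(gids, draw):
            if c:
                counts[g] = counts.get(g, 0) + int(c)
    return counts


def ani_candidate_pairs(
    sequences: dict[str, str], k: int = 15, stride: int = 100, min_shared: int = 5
) -> list[tuple[str, str]]:
    """k-mer sketch prescreen: only sequence pairs sharing >= ``min_shared``
    sampled k-mers are worth a full fragment-ANI computation."""
    sketches = {}
    for gid, seq in sequences.items():
        s = seq.replace("N", "")
        sketches[gid] = frozenset(
            s[i : i + k] for i in range(0, max(1, len(s) - k), stride)
        )
    ids = sorted(sequences)
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if len(sketches[ids[i]] & sketches[ids[j]]) >= min_shared:
                pairs.append((ids[i], ids[j]))
    return pairs


def recovered_genes(
    vsag: vsag_mod.VSAG, contigs_by_id, community: community_mod.Community
):
    """Ground-truth genes fully contained in a vSAG's recovered intervals,
    ordered along the majority source genome."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    for cid in vsag.selected.contig_ids:
        c = contigs_by_id[cid]
        intervals.setdefault(c.source_genome_id, []).append(c.source_interval)
    genes = []
    for gid, ivs in intervals.items():
        try:
            genome = community.genome(gid)
        except KeyError:
            continue
        for gene in genome.genes:
            if any(s <= gene.start and gene.end <= e for s, e in ivs):
                genes.append((gid, gene))
    genes.sort(key=lambda t: (t[0], t[1].start))
    return genes


def run_pipeline(config: dict | None = None, outdir: str | Path = "run") -> dict:
    """Execute the full pipeline and write all artifacts under ``outdir``.

    Returns a dictionary of the key computed quantities (QC statistics,
    counts, clustering summaries) for programmatic use.
    """
    cfg = make_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_mod.save_config(outdir / "config.json", cfg)
    rng = np.random.default_rng(cfg["seed"])
    results: dict = {"seed": cfg["seed"]}

    # --- stage 1: simulate ---------------------------------------------------
    comm, cassettes = build_community(cfg, rng)
    sim_dir = outdir / "simulate"
    io_mod.write_community(sim_dir, comm)
    bcfg = cfg["beads"]
    bias = beads_mod.BiasModel(sigma=bcfg["sigma"], dropout=bcfg["dropout"])
    sorted_beads, manifest = beads_mod.simulate_run(
        comm,
        n_beads=bcfg["n_beads"],
        mean_loading=bcfg["mean_loading"],
        bias=bias,
        seed=int(rng.integers(2**31)),
        method_label=cfg["method_label"],
    )
    io_mod.write_manifest(sim_dir / "manifest.tsv", manifest)
    io_mod.write_tsv(sim_dir / "contig_truth.tsv", io_mod.contigs_table(sorted_beads))
    io_mod.write_fasta(
        sim_dir / "contigs.fasta",
        {c.contig_id: c.sequence for b in sorted_beads for c in b.contigs},
    )

    # --- stage 2: QC ---------------------------------------------------------
    qc_dir = outdir / "qc"
    qc_dir.mkdir(exist_ok=True)
    p_pos = manifest.n_beads_positive / manifest.n_beads_generated
    lam_hat = qc_mod.estimate_mean_loading(p_pos)
    conc = qc_mod.concentration_from_loading(lam_hat)
    decision = qc_mod.dilution_decision(p_pos)
    if decision["decision"] == "dilute":
        log.warning(
            "positive rate %.1f%% exceeds 20%%: dilute and regenerate beads",
            100 * p_pos,
        )
    rcfg = cfg["reads"]
    bg_refs = (
        {comm.background_genome.genome_id} if comm.background_genome else set()
    )
    pairs_per_bead: dict[str, int] = {}
    qc_rows = []
    for bead in sorted_beads:
        n_pairs = int(
            rng.lognormal(np.log(rcfg["n_pairs_per_bead"]), rcfg["pair_sigma"])
        )
        pairs_per_bead[bead.bead_id] = n_pairs
        counts = simulate_mapping_counts(
            bead, comm, n_pairs, rcfg["background_fraction"], rng
        )
        cls = qc_mod.classify_bead(counts, bg_refs, bead_id=bead.bead_id)
        ginis, breadths = [], []
        for gid, prof in bead.coverage_profiles.items():
            if prof.sum() > 0:
                ginis.append(qc_mod.gini_coefficient(prof))
                breadths.append(qc_mod.genome_breadth(prof))
        qc_rows.append(
            {
                "bead_id": bead.bead_id,
                "n_pairs": n_pairs,
                "majority_ref": cls.majority_ref or "",
                "minor_viral_fraction": round(cls.minor_viral_fraction, 5),
                "contaminated": cls.contaminated,
                "background_fraction": round(cls.background_fraction, 5),
                "gini": round(float(np.mean(ginis)), 4) if ginis else "",
                "breadth": round(float(np.mean(breadths)), 4) if breadths else "",
            }
        )
    qc_df = pd.DataFrame(qc_rows)
    io_mod.write_tsv(qc_dir / "qc_report.tsv", qc_df)
    with open(qc_dir / "loading.json", "w") as fh:
        json.dump(
            {
                "p_positive": p_pos,
                "lambda_hat": lam_hat,
                "concentration_per_ml": conc,
                **decision,
            },
            fh,
            indent=2,
        )
    results.update(
        p_positive=p_pos,
        lambda_hat=lam_hat,
        concentration_per_ml=conc,
        dilution_decision=decision["decision"],
    )

    # --- stage 3: vSAG construction ------------------------------------------
    vdir = outdir / "vsags"
    vdir.mkdir(exist_ok=True)
    vcfg = cfg["vsag"]
    contigs_by_id = {c.contig_id: c for b in sorted_beads for c in b.contigs}
    vsags: list[vsag_mod.VSAG] = []
    status_rows, bin_rows = [], []
    n_multi_bin = 0
    n_beads_with_contigs = 0
    for bead in sorted_beads:
        if pairs_per_bead[bead.bead_id] < beads_mod.SMALL_DATA_PAIRS:
            status_rows.append({"bead_id": bead.bead_id, "status": "small_data"})
            continue
        v, bins = vsag_mod.build_vsags_for_bead(
            bead,
            comm,
            score_threshold=vcfg["score_threshold"],
            min_bin_size=vcfg["min_bin_size"],
            cutoff=vcfg["cutoff"],
            abund_weight=vcfg["abund_weight"],
            seed=int(rng.integers(2**31)),
        )
        if bins:
            n_beads_with_contigs += 1
            if len(bins) > 1:
                n_multi_bin += 1
        for b in bins:
            bin_rows.append(
                {
                    "bin_id": b.bin_id,
                    "bead_id": b.bead_id,
                    "n_contigs": len(b.contig_ids),
                    "total_length": b.total_length,
                    "completeness": round(b.completeness or 0.0, 2),
                    "quality_tier": b.quality_tier,
                    "contig_ids": ";".join(b.contig_ids),
                }
            )
        if v is None:
            status_rows.append({"bead_id": bead.bead_id, "status": "no_viral"})
        else:
            status_rows.append({"bead_id": bead.bead_id, "status": "vsag"})
            vsags.append(v)
    io_mod.write_tsv(vdir / "status.tsv", pd.DataFrame(status_rows))
    io_mod.write_tsv(vdir / "bins.tsv", pd.DataFrame(bin_rows))
    io_mod.write_fasta(
        vdir / "vsags.fasta",
        {v.vsag_id: v.selected.concatenated_sequence for v in vsags},
    )

    # --- stage 4: clustering --------------------------------------------------
    cdir = outdir / "cluster"
    cdir.mkdir(exist_ok=True)
    seqs = {v.vsag_id: v.selected.concatenated_sequence for v in vsags}
    meta = [
        (v.vsag_id, v.selected.completeness or 0.0, vsag_mod.ungapped_length(v.selected))
        for v in vsags
    ]
    ani_records = []
    for a, b in ani_candidate_pairs(seqs):
        try:
            ani_records.append(
                clustering.compute_ani_af(seqs[a], seqs[b], query_id=a, target_id=b)
            )
        except community_mod.ParameterError:
            continue
    votus = clustering.cluster_votus(meta, ani_records)
    io_mod.write_tsv(
        cdir / "votus.tsv",
        pd.DataFrame(
            [
                {"votu_id": v.votu_id, "centroid_id": v.centroid_id,
                 "member_ids": ";".join(v.member_ids)}
                for v in votus
            ]
        ),
    )

    vsag_genes = {
        v.vsag_id: recovered_genes(v, contigs_by_id, comm) for v in vsags
    }
    proteins = {}
    truth_role = {}
    for vid, genes in vsag_genes.items():
        for gid, gene in genes:
            key = (vid, gene.gene_id)
            proteins[key] = clustering._translate(
                comm.genome(gid).gene_sequence(gene)
            )
            truth_role[key] = gene
    pcs = clustering.cluster_proteins(proteins) if proteins else []
    for pc in pcs:
        pc.is_amg_pc = any(truth_role[m].role == "AMG" for m in pc.members)
    genome_pcs: dict[str, set[str]] = {v.vsag_id: set() for v in vsags}
    for pc in pcs:
        for g, _ in pc.members:
            genome_pcs[g].add(pc.pc_id)
    completeness = {v.vsag_id: v.selected.completeness or 0.0 for v in vsags}
    lengths = {m[0]: m[2] for m in meta}
    vcs, edges = clustering.build_vc_network(genome_pcs, completeness, lengths)
    clustering.annotate_pc_vc_incidence(pcs, vcs)
    io_mod.write_tsv(
        cdir / "pcs.tsv",
        pd.DataFrame(
            [
                {"pc_id": pc.pc_id, "n_members": len(pc.members),
                 "is_amg_pc": pc.is_amg_pc, "n_vcs_touched": pc.n_vcs_touched,
                 "members": ";".join(f"{g}:{x}" for g, x in pc.members)}
                for pc in pcs
            ]
        ),
    )
    io_mod.write_tsv(
        cdir / "vcs.tsv",
        pd.DataFrame(
            [
                {"vc_id": vc.vc_id, "representative_id": vc.representative_id,
                 "member_ids": ";".join(vc.member_ids)}
                for vc in vcs
            ]
        ),
    )
    io_mod.write_tsv(
        cdir / "edges.tsv",
        pd.DataFrame(edges, columns=["source", "target", "weight"]),
    )

    # --- stage 5: annotation ---------------------------------------------------
    adir = outdir / "annotate"
    adir.mkdir(exist_ok=True)
    tax_rows = []
    hit_rate = cfg["taxonomy"]["hit_rate"]
    src_of_vsag = {}
    for v in vsags:
        by_src = Counter(
            contigs_by_id[cid].source_genome_id for cid in v.selected.contig_ids
        )
        src_of_vsag[v.vsag_id] = by_src.most_common(1)[0][0]
    for v in vsags:
        genes = vsag_genes[v.vsag_id]
        if not genes:
            continue
        lineage_truth = comm.genome(src_of_vsag[v.vsag_id]).taxonomy
        hits = [
            lineage_truth for _ in range(rng.binomial(len(genes), hit_rate))
        ]
        call = annotate.vote_taxonomy(v.vsag_id, len(genes), hits)
        tax_rows.append(
            {"genome_id": v.vsag_id, "method": call.method,
             "lineage": ";".join(call.lineage)}
        )
    io_mod.write_tsv(adir / "taxonomy.tsv", pd.DataFrame(tax_rows))

    pseudo = [
        SimpleNamespace(genome_id=vid, genes=[g for _, g in genes])
        for vid, genes in vsag_genes.items()
    ]
    pc_of_gene = {m: pc.pc_id for pc in pcs for m in pc.members}
    amgs = annotate.identify_amgs(pseudo, pc_of_gene=pc_of_gene)
    io_mod.write_tsv(
        adir / "amgs.tsv",
        pd.DataFrame(
            [
                {"genome_id": a.genome_id, "gene_id": a.gene_id,
                 "amg_category": a.amg_category or "", "aux_score": a.aux_score,
                 "pc_id": a.pc_id or ""}
                for a in amgs
            ]
        ),
    )
    pcs_in_vcs = [pc for pc in pcs if pc.n_vcs_touched >= 1]
    fisher = (
        annotate.amg_sharing_test(pcs_in_vcs)
        if pcs_in_vcs
        else {"p_value": None}
    )
    with open(adir / "amg_fisher.json", "w") as fh:
        json.dump({k: v for k, v in fisher.items() if k != "table"} |
                  {"table": fisher.get("table")}, fh, indent=2)

    # recruitment curves per VC from simulated read identities
    rc_cfg = cfg["recruitment"]
    ani_lookup = {}
    for r in ani_records:
        ani_lookup[(r.query_id, r.target_id)] = r.ani
        ani_lookup[(r.target_id, r.query_id)] = r.ani
    curve_rows = []
    for vc in vcs:
        rep = vc.representative_id
        ids = []
        for m in vc.member_ids:
            base = 100.0 if m == rep else ani_lookup.get((m, rep), 92.0)
            if np.isnan(base):
                base = 92.0
            ids.extend(
                rng.normal(base, rc_cfg["identity_sd"], size=rc_cfg["reads_per_member"])
            )
        ids = np.clip(ids, 50.0, 100.0)
        curve = annotate.recruitment_curve(
            ids, np.full(len(ids), 100.0), np.full(len(ids), 1e-30)
        )
        curve_rows.append(
            {"vc_id": vc.vc_id, "n_reads": curve.n_reads,
             "iqr": round(annotate.curve_iqr(curve), 3)}
        )
    io_mod.write_tsv(adir / "recruitment.tsv", pd.DataFrame(curve_rows))

    # --- stage 6: comparison ----------------------------------------------------
    mdir = outdir / "compare"
    mdir.mkdir(exist_ok=True)
    multi = [v for v in votus if len(v.member_ids) >= 2]
    insertion_rows = []
    og_df = pd.DataFrame()
    if multi:
        focus = max(multi, key=lambda v: len(v.member_ids))
        members = {
            m: [(g.gene_id, g.og_label) for _, g in vsag_genes.get(m, [])]
            for m in focus.member_ids
        }
        members = {m: genes for m, genes in members.items() if genes}
        if len(members) >= 2:
            matrix = annotate.build_og_matrix(members)
            og_df = pd.DataFrame(
                matrix.counts, index=matrix.og_ids, columns=matrix.genome_ids
            )
            og_df.insert(
                0, "og_class",
                ["core" if og in matrix.core else "flexible" for og in matrix.og_ids],
            )
            og_df.index.name = "og_id"
            og_df.reset_index().to_csv(
                mdir / "og_matrix.tsv", sep="\t", index=False, lineterminator="\n"
            )
            for ev in annotate.detect_insertions(members, matrix):
                insertion_rows.append(
                    {"genome_id": ev.genome_id, "og_run": ";".join(ev.og_run),
                     "left_flank": ev.left_flank or "",
                     "right_flank": ev.right_flank or ""}
                )
    io_mod.write_tsv(mdir / "insertions.tsv", pd.DataFrame(insertion_rows))

    # --- stage 7: report ---------------------------------------------------------
    rdir = outdir / "report"
    rdir.mkdir(exist_ok=True)
    status = pd.DataFrame(status_rows)
    gb = manifest.n_beads_sorted * rcfg["n_pairs_per_bead"] * 2 * rcfg["read_length"] / 1e9
    method = report_mod.MethodCounts(
        method_label=cfg["method_label"],
        n_beads_sorted=manifest.n_beads_sorted,
        n_beads_with_vsag=int((status["status"] == "vsag").sum()) if len(status) else 0,
        n_beads_no_viral=int((status["status"] == "no_viral").sum()) if len(status) else 0,
        n_beads_small_data=int((status["status"] == "small_data").sum()) if len(status) else 0,
        gb_sequenced=gb,
        n_vsags=len(vsags),
    )
    tiers = Counter(v.selected.quality_tier for v in vsags)
    amg_per_genome = Counter(a.genome_id for a in amgs)
    summary = report_mod.summarize_run(
        [method],
        n_vsags=len(vsags),
        n_single_contig_vsags=sum(v.is_single_contig for v in vsags),
        n_multi_bin_beads=n_multi_bin,
        n_beads_with_contigs=n_beads_with_contigs,
        quality_tiers=dict(tiers),
        n_votus=len(votus),
        n_multi_member_votus=sum(len(v.member_ids) >= 2 for v in votus),
        n_pcs=len(pcs),
        n_multi_vc_pcs=sum(pc.n_vcs_touched >= 2 for pc in pcs),
        n_vcs=len(vcs),
        n_amgs=len(amgs),
        n_amg_types=len({a.amg_category for a in amgs}),
        max_amgs_per_genome=max(amg_per_genome.values(), default=0),
    )
    with open(rdir / "summary.txt", "w") as fh:
        fh.write(summary.as_text())
    results.update(
        n_beads_sorted=manifest.n_beads_sorted,
        n_vsags=len(vsags),
        recovery_pct=summary.recovery_pct(cfg["method_label"]) if len(status) else None,
        single_contig_pct=summary.single_contig_pct() if vsags else None,
        n_votus=len(votus),
        n_multi_member_votus=summary.n_multi_member_votus,
        n_pcs=len(pcs),
        n_vcs=len(vcs),
        multi_vc_pc_pct=summary.multi_vc_pc_pct() if pcs else None,
        n_amgs=len(amgs),
        fisher_p=fisher.get("p_value"),
        summary=summary,
    )
    return results
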