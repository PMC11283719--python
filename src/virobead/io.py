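"""File formats: FASTA/FASTQ, TSV tables, JSON config.

All tables are UTF-8 TSV with a header row and ``\\n`` line endings so that
write -> read -> write round-trips byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .beads import Bead, ReadPair, RunManifest
from .community import Community, ViralGenome


def write_fasta(path, records: dict[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fastq_pair(path1, path2, reads: list[ReadPair]) -> None:
    """Paired FASTQ with /1 /2 read-name suffixes and flat quality."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            f1.write(f"@{r.read_id}/1\n{r.seq1}\n+\n{'I' * len(r.seq1)}\n")
            f2.write(f"@{r.read_id}/2\n{r.seq2}\n+\n{'I' * len(r.seq2)}\n")


def genes_table(genomes: list[ViralGenome]) -> pd.DataFrame:
    rows = []
    for g in genomes:
        for gene in g.genes:
            rows.append(
                {
                    "genome_id": g.genome_id,
                    "gene_id": gene.gene_id,
                    "start": gene.start,
                    "end": gene.end,
                    "strand": gene.strand,
                    "og_label": gene.og_label,
                    "role": gene.role,
                    "amg_category": gene.amg_category or "",
                    "aux_score": "" if gene.aux_score is None else gene.aux_score,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "gene_id", "start", "end", "strand",
            "og_label", "role", "amg_category", "aux_score",
        ],
    )


def write_community(outdir, community: Community) -> None:
    """Community as multi-FASTA + gene/taxonomy/abundance truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = {g.genome_id: g.sequence for g in community.genomes}
    if community.background_genome is not None:
        seqs[community.background_genome.genome_id] = community.background_genome.sequence
    write_fasta(outdir / "community.fasta", seqs)
    write_tsv(outdir / "genes.tsv", genes_table(list(community.genomes)))
    write_tsv(
        outdir / "taxonomy.tsv",
        pd.DataFrame(
            {
                "genome_id": [g.genome_id for g in community.genomes],
                "lineage": [";".join(g.taxonomy) for g in community.genomes],
                "nucleic_type": [g.nucleic_type for g in community.genomes],
                "topology": [g.topology for g in community.genomes],
                "strain_group_id": [g.strain_group_id or "" for g in community.genomes],
            }
        ),
    )
    write_tsv(
        outdir / "abundances.tsv",
        pd.DataFrame(
            {
                "genome_id": [g.genome_id for g in community.genomes],
                "abundance": list(community.abundances),
                "length": [g.length for g in community.genomes],
            }
        ),
    )


def manifest_table(manifest: RunManifest) -> pd.DataFrame:
    return pd.DataFrame(manifest.records)


def write_manifest(path, manifest: RunManifest) -> None:
    df = manifest_table(manifest)
    header = pd.DataFrame(
        [
            {
                "bead_id": f"#method={manifest.method_label} seed={manifest.seed} "
                f"generated={manifest.n_beads_generated} "
                f"positive={manifest.n_beads_positive} "
                f"sorted={manifest.n_beads_sorted}",
            }
        ]
    )
    with open(path, "w") as fh:
        fh.write(header.iloc[0, 0] + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def contigs_table(beads: list[Bead]) -> pd.DataFrame:
    rows = []
    for b in beads:
        for c in b.contigs:
            rows.append(
                {
                    "contig_id": c.contig_id,
                    "bead_id": c.bead_id,
                    "length": c.length,
                    "source_genome_id": c.source_genome_id,
                    "source_start": c.source_interval[0],
                    "source_end": c.source_interval[1],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id", "bead_id", "length",
            "source_genome_id", "source_start", "source_end",
        ],
    )


def load_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
        fh.write("\n")
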