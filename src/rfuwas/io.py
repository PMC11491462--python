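"""Plain-text readers and writers for the pipeline's tabular formats.

Repertoires travel as AIRR-style TSV (repertoire_id, junction_aa,
duplicate_count) with a configurable-column dialect for ImmuneAccess-like
exports; genotypes as a variants x individuals dosage TSV with
CHROM/POS/ID/REF/ALT/LOCUS metadata columns (optionally a minimal VCF);
centroids, abundance matrices (stage tag in a header comment), phenotypes
and QC reports as TSV/CSV.
"""

from __future__ import annotations

import pandas as pd

from .quantify import AbundanceMatrix, Repertoire, RFUCentroids
from .qc import GenotypeMatrix, QCReport


# -- repertoires -----------------------------------------------------------

def write_repertoires(repertoires: list[Repertoire], path) -> None:
    rows = []
    for r in repertoires:
        for seq, count in r.clones.items():
            rows.append((r.individual_id, seq, count))
    pd.DataFrame(rows, columns=["repertoire_id", "junction_aa", "duplicate_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_repertoires(
    path,
    id_col: str = "repertoire_id",
    seq_col: str = "junction_aa",
    count_col: str = "duplicate_count",
) -> list[Repertoire]:
    """Read an AIRR-style TSV; override column names for other dialects
    (e.g. ``seq_col="amino_acid", count_col="seq_reads"``)."""
    table = pd.read_csv(path, sep="\t")
    for col in (id_col, seq_col, count_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    out = []
    for ind, sub in table.groupby(id_col, sort=True):
        clones: dict[str, int] = {}
        for seq, count in zip(sub[seq_col], sub[count_col]):
            clones[seq] = clones.get(seq, 0) + int(count)
        out.append(Repertoire(individual_id=str(ind), clones=clones))
    return out


# -- genotypes -------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, path) -> None:
    meta = g.variants
    table = pd.DataFrame({
        "CHROM": meta["chrom"].to_numpy(),
        "POS": meta["pos"].to_numpy(),
        "ID": meta.index,
        "REF": meta.get("ref", pd.Series(".", index=meta.index)).to_numpy(),
        "ALT": meta.get("alt", pd.Series(".", index=meta.index)).to_numpy(),
        "LOCUS": meta["locus"].to_numpy(),
    })
    dosage_t = g.dosages.T.reset_index(drop=True)
    pd.concat([table.reset_index(drop=True), dosage_t], axis=1).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t")
    meta_cols = ["CHROM", "POS", "ID", "REF", "ALT", "LOCUS"]
    variants = pd.DataFrame({
        "chrom": table["CHROM"].astype(str),
        "pos": table["POS"].astype(int),
        "locus": table["LOCUS"],
        "ref": table["REF"],
        "alt": table["ALT"],
    })
    variants.index = pd.Index(table["ID"], name="id")
    dosages = table.drop(columns=meta_cols).T
    dosages.columns = variants.index
    return GenotypeMatrix(dosages, variants)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal unphased VCF with hard-called genotypes from dosages."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rfuwas\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in g.individual_ids) + "\n"
        )
        for vid in g.variant_ids:
            row = g.variants.loc[vid]
            calls = "\t".join(
                gt_map.get(int(round(d)), "./.") for d in g.dosages[vid]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row.get('ref', '.')}\t"
                f"{row.get('alt', '.')}\t.\tPASS\tLOCUS={row['locus']}\tGT\t{calls}\n"
            )


# -- centroids and abundance matrices --------------------------------------

def write_centroids(centroids: RFUCentroids, path) -> None:
    table = pd.DataFrame(centroids.matrix, index=pd.Index(centroids.rfu_ids, name="rfu_id"))
    table.columns = [f"d{j}" for j in range(table.shape[1])]
    table.to_csv(path, sep="\t")


def read_centroids(path) -> RFUCentroids:
    table = pd.read_csv(path, sep="\t", index_col="rfu_id")
    return RFUCentroids(matrix=table.to_numpy(float), rfu_ids=list(table.index))


def write_abundance(a: AbundanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage: {a.stage}\n")
        a.data.to_csv(fh, sep="\t", index_label="individual_id")


def read_abundance(path) -> AbundanceMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        stage = first.split("# stage:")[1].strip() if first.startswith("# stage:") else "raw"
        data = pd.read_csv(fh, sep="\t", index_col="individual_id")
    return AbundanceMatrix(data, stage=stage)


# -- reports ---------------------------------------------------------------

def write_qc_report(report: QCReport, path_prefix) -> None:
    report.removed_individuals.to_csv(f"{path_prefix}.individuals.tsv", sep="\t", index=False)
    report.removed_variants.to_csv(f"{path_prefix}.variants.tsv", sep="\t", index=False)
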