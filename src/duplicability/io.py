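"""Tab-delimited readers/writers for the pipeline's table dialects.

All tables are plain TSV with a header row:

* gene table: ``gene_id  chromosome  order_index  intron_count  segment_id``
* pair table: ``gene_a  gene_b  duplication_node``
* ohnolog set: ``gene_a  gene_b``
* consensus labels: ``gene_id  label  exclusion_reason  singleton_subtype``
* expression matrix: ``gene_id`` + one column per condition (TPM)
* feature table: ``gene_id`` + one column per feature
* annotations: ``term_id  gene_id``

CDS sequences travel as FASTA.
"""

from __future__ import annotations

import pandas as pd


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    required = {"gene_id", "chromosome", "order_index", "intron_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    if "segment_id" not in df.columns:
        df["segment_id"] = pd.NA
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    cols = ["gene_id", "chromosome", "order_index", "intron_count", "segment_id"]
    genes[cols].to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b", "duplication_node"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    return df


def write_pair_table(pairs: pd.DataFrame, path) -> None:
    pairs[["gene_a", "gene_b", "duplication_node"]].to_csv(path, sep="\t", index=False)


def read_ohnolog_set(path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        (a, b) if a <= b else (b, a) for a, b in zip(df["gene_a"], df["gene_b"])
    }


def write_ohnolog_set(pairs, path) -> None:
    rows = sorted(tuple(sorted(p)) for p in pairs)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_expression_matrix(expression: pd.DataFrame, path) -> None:
    expression.rename_axis("gene_id").to_csv(path, sep="\t")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_feature_table(features: pd.DataFrame, path) -> None:
    features.rename_axis("gene_id").to_csv(path, sep="\t")


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_annotation_map(path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {term: set(sub["gene_id"]) for term, sub in df.groupby("term_id")}


def write_annotation_map(annotations: dict[str, set], path) -> None:
    rows = [(t, g) for t in sorted(annotations) for g in sorted(annotations[t])]
    pd.DataFrame(rows, columns=["term_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_cds_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader returning id -> sequence (CDS dialect)."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
            else:
                raise ValueError("FASTA sequence data before first header")
    return {n: "".join(parts) for n, parts in seqs.items()}


def write_cds_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
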