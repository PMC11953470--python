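"""Readers and writers for the pipeline's tabular and interval formats.

TSV matrices are probes/genes x samples with the id in the first column.
Interval files are BED (0-based half-open); TFBS BED carries the factor name
in column 4 (narrowPeak input also works — extra columns are ignored).  Gene
models come either from a transcript TSV (gene_id, chrom, strand, start, end)
or from a GTF, from which transcript/exon records are collapsed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotation import GeneModel, GenomicInterval, build_consensus_gene_models


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_beta(path) -> pd.DataFrame:
    beta = read_matrix(path)
    return beta


def read_purity(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("purity")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    return df


def read_bed(path) -> list[GenomicInterval]:
    ivs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            ivs.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return ivs


def read_tfbs_bed(path) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[3] if len(fields) > 3 else "TF"
            out.setdefault(name, []).append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            )
    return out


def read_gene_models(path) -> dict[str, GeneModel]:
    """Gene models from a transcript TSV or a GTF (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        records = _gtf_records(path)
    else:
        df = pd.read_csv(path, sep="\t")
        records = df.to_dict("records")
    return build_consensus_gene_models(records)


def _gtf_records(path) -> list[dict]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in {"transcript", "exon", "gene"}:
                continue
            attrs = dict(
                item.strip().split(" ", 1)
                for item in f[8].rstrip(";").split(";")
                if item.strip()
            )
            gid = attrs.get("gene_id", "").strip('"')
            if not gid:
                continue
            records.append(
                {
                    "gene_id": gid,
                    "chrom": f[0],
                    "strand": f[6],
                    "start": int(f[3]),
                    "end": int(f[4]),
                }
            )
    return records


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(frame: pd.DataFrame, path, index_label="id") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)
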