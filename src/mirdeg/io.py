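"""Readers/writers for the plain-text formats used by the pipeline.

FASTA via Biopython; count/FPKM matrices and annotation maps as TSV with a
header row; optional GFF3 gene models (1-based, inclusive); YAML configs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_reads(path) -> list[str]:
    """Read sequences from FASTA or FASTQ (by extension), one entry per read."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(p, fmt)]


def write_annotation(annotation: Mapping[str, Iterable[str]], path) -> None:
    """Two-column map: feature id, term id (one row per assignment)."""
    with open(path, "w") as fh:
        fh.write("feature\tterm\n")
        for feat in sorted(annotation):
            for term in sorted(annotation[feat]):
                fh.write(f"{feat}\t{term}\n")


def read_annotation(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for feat, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(feat), set()).add(str(term))
    return out


def write_term_info(term_info: Mapping[str, tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tname\tnamespace\n")
        for term in sorted(term_info):
            name, ns = term_info[term]
            fh.write(f"{term}\t{name}\t{ns}\n")


def read_term_info(path) -> dict[str, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.term): (str(r.name), str(r.namespace)) for r in df.itertuples()}


def write_gff3(transcripts: Mapping[str, str], path, source: str = "mirdeg") -> None:
    """Minimal GFF3 gene models: one gene + mRNA + exon per transcript."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tid in sorted(transcripts):
            end = len(transcripts[tid])
            gene = tid.split("-")[0]
            fh.write(f"{tid}\t{source}\tgene\t1\t{end}\t.\t+\t.\tID=gene:{gene}\n")
            fh.write(f"{tid}\t{source}\tmRNA\t1\t{end}\t.\t+\t.\tID=mRNA:{tid};Parent=gene:{gene}\n")
            fh.write(f"{tid}\t{source}\texon\t1\t{end}\t.\t+\t.\tParent=mRNA:{tid}\n")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
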