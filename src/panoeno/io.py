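"""Readers and writers for the plain-text formats used across the package.

Formats follow the conventions of pan-genome ortholog tooling:

* protein FASTA, one file per strain;
* a combined tab-separated "att" table with columns
  ``contig_id, orf_id, start, end, annotation, strain_tag`` (1-based
  inclusive coordinates; minus-strand ORFs are written with start > end);
* VCF v4.2 per strain against a designated reference strain;
* a "matchtable"-style cluster TSV (one row per cluster, one column per
  strain, ``----------`` marking absence) plus a long-form member table;
* a 12-column BLAST tabular match file for externally supplied similarity.
"""

from __future__ import annotations

import os

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ABSENT_MARK = "----------"

ATT_COLUMNS = ["contig_id", "orf_id", "start", "end", "annotation", "strain_tag"]

BLAST_COLUMNS = [
    "query", "subject", "pct_identity", "aln_len", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------- FASTA

def write_fasta(path, sequences: dict[str, str],
                descriptions: dict[str, str] | None = None) -> None:
    records = []
    for name in sequences:
        desc = (descriptions or {}).get(name, "")
        records.append(SeqRecord(Seq(sequences[name]), id=name, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- att table

def write_att_table(path, rows: list[dict]) -> None:
    df = pd.DataFrame(rows, columns=ATT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_att_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "orf_id": str,
                                            "annotation": str, "strain_tag": str})
    missing = set(ATT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"att table {path} lacks columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------- VCF

def write_vcf(path, strain: str, reference_name: str, reference_length: int,
              variants: list[tuple[int, str, str]]) -> None:
    """Write a minimal VCF v4.2 of SNPs for one strain.

    ``variants`` are (1-based position, ref allele, alt allele).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference_name},length={reference_length}>\n")
        fh.write(f"##source=panoeno\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, ref, alt in sorted(variants):
            fh.write(f"{reference_name}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def read_vcf(path) -> list[tuple[int, str, str]]:
    """Read biallelic SNPs from a VCF as (1-based position, ref, alt).

    Indels and multi-allelic records are skipped so pseudo-genomes stay
    length-aligned; use :func:`read_vcf_full` to get the skipped count.
    """
    variants, _ = read_vcf_full(path)
    return variants


def read_vcf_full(path) -> tuple[list[tuple[int, str, str]], int]:
    variants: list[tuple[int, str, str]] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            variants.append((rec.pos, rec.ref, alts[0]))
    return variants, skipped


# ---------------------------------------------------------------- clusters

def write_matchtable(path, clusters, strains: list[str]) -> None:
    """PanOCT-style matchtable: one row per cluster, one column per strain."""
    rows = []
    for cl in clusters:
        by_strain = {m.strain: m.orf_id for m in cl.members}
        rows.append([cl.cluster_id] + [by_strain.get(s, ABSENT_MARK)
                                       for s in strains])
    df = pd.DataFrame(rows, columns=["cluster_id"] + list(strains))
    df.to_csv(path, sep="\t", index=False)


def write_cluster_members(path, clusters) -> None:
    rows = []
    for cl in clusters:
        for m in cl.members:
            rows.append({
                "cluster_id": cl.cluster_id,
                "orf_id": m.orf_id,
                "strain": m.strain,
                "length_aa": m.length_aa,
                "percent_of_longest": round(m.percent_of_longest, 4),
                "is_centroid": int(m.orf_id == cl.centroid),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cluster_members(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "orf_id": str,
                                              "strain": str})


# ---------------------------------------------------------------- presence

def write_presence_matrix(path, presence: pd.DataFrame) -> None:
    presence.astype(int).to_csv(path, sep="\t", index=True, index_label="strain")


def read_presence_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="strain")
    return df.astype(bool)


# ---------------------------------------------------------------- BLAST table

def read_blast_table(path) -> pd.DataFrame:
    """Parse a 12-column tab-separated BLAST match file.

    Raises :class:`ParseError` naming the first malformed line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"columns, got {len(parts)}")
            try:
                rows.append({
                    "query": parts[0], "subject": parts[1],
                    "pct_identity": float(parts[2]),
                    "aln_len": int(parts[3]), "mismatches": int(parts[4]),
                    "gaps": int(parts[5]), "qstart": int(parts[6]),
                    "qend": int(parts[7]), "sstart": int(parts[8]),
                    "send": int(parts[9]), "evalue": float(parts[10]),
                    "bitscore": float(parts[11]),
                })
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


# ---------------------------------------------------------------- misc

def sha256_of(path) -> str:
    import hashlib
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
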