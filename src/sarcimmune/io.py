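"""On-disk formats: TSV tables, a minimal somatic VCF dialect, protein FASTA.

All tables are plain tab-separated text with a header row.  The variant
table has a mirrored per-patient VCF dialect carrying the same fields as
INFO keys (NCALLERS, DPT, DPN, ALTT, VAFD, VAFR, CSQCLASS, PS plus the
protein-level annotation keys); the TSV is the primary dialect, the VCF is
provided for interoperability and is read back through pysam.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

VARIANT_COLUMNS: dict[str, type] = {
    "patient_id": str, "variant_id": str, "chrom": str, "pos": int,
    "ref": str, "alt": str, "n_callers": int, "depth_tumor": int,
    "depth_normal": int, "alt_reads_tumor": int, "vaf_dna": float,
    "vaf_rna": float, "consequence": str, "phase_set": str,
    "transcript_ids": str, "protein_id": str, "protein_pos": int,
    "aa_ref": str, "aa_alt": str, "fs_tail": str,
}
FUSION_COLUMNS: dict[str, type] = {
    "patient_id": str, "fusion_id": str, "gene5": str, "gene3": str,
    "junction_seq5": str, "junction_seq3": str, "frame": str, "confidence": str,
}
CANDIDATE_COLUMNS: dict[str, type] = {
    "patient_id": str, "peptide": str, "protein_id": str, "allele": str,
    "ap_score": float, "abundance": float, "source_variant_ids": str,
}
CLINICAL_COLUMNS: dict[str, type] = {
    "patient_id": str, "subtype": str, "pfs_days": float, "event": int,
    "response": str,
}
TPM_COLUMNS: dict[str, type] = {"patient_id": str, "transcript_id": str, "tpm": float}
HLA_COLUMNS: dict[str, type] = {"patient_id": str, "allele": str}
MIXTURE_COLUMNS: dict[str, type] = {"patient_id": str, "gene": str, "expression": float}

_VCF_INFO_KEYS = [
    ("NCALLERS", "Integer", "Number of supporting somatic callers (of six)"),
    ("DPT", "Integer", "Read depth in tumor"),
    ("DPN", "Integer", "Read depth in normal"),
    ("ALTT", "Integer", "Alt-supporting reads in tumor"),
    ("VAFD", "Float", "Variant allele frequency (DNA)"),
    ("VAFR", "Float", "Variant allele frequency (RNA)"),
    ("CSQCLASS", "String", "Consequence class"),
    ("PS", "String", "Phase set tag"),
    ("TIDS", "String", "Harboring transcript ids"),
    ("PROT", "String", "Protein id"),
    ("PPOS", "Integer", "1-based residue index in protein"),
    ("AAREF", "String", "Reference residues"),
    ("AAALT", "String", "Alternate residues"),
    ("FSTAIL", "String", "Novel translation after frameshift"),
]


def apply_schema(df: pd.DataFrame, schema: Mapping[str, type]) -> pd.DataFrame:
    """Coerce/order columns to a schema; missing string columns become empty."""
    out = pd.DataFrame(index=df.index if len(df) else None)
    for col, typ in schema.items():
        if col in df.columns:
            s = df[col]
            if typ is str:
                s = s.fillna("").astype(str)
            else:
                s = s.astype(typ)
            out[col] = s
        else:
            out[col] = pd.Series([], dtype=(object if typ is str else typ))
    return out.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"expected table at {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return apply_schema(df, schema)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in proteins.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio.SeqIO import parse as seqio_parse

    if not Path(path).exists():
        raise FileNotFoundError(f"expected FASTA at {path}")
    return {rec.id: str(rec.seq) for rec in seqio_parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# minimal VCF dialect


def write_variants_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Write one patient's variants as a minimal VCF mirroring the TSV fields."""
    lines = ["##fileformat=VCFv4.2",
             '##FILTER=<ID=PASS,Description="All filters passed">']
    for key, typ, desc in _VCF_INFO_KEYS:
        lines.append(f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">')
    for chrom in dict.fromkeys(variants["chrom"].astype(str)):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for _, row in variants.iterrows():
        info = ";".join([
            f"NCALLERS={int(row.n_callers)}",
            f"DPT={int(row.depth_tumor)}",
            f"DPN={int(row.depth_normal)}",
            f"ALTT={int(row.alt_reads_tumor)}",
            f"VAFD={float(row.vaf_dna)!r}",
            f"VAFR={float(row.vaf_rna)!r}",
            f"CSQCLASS={row.consequence}",
            f"PS={row.phase_set or '.'}",
            # '|' avoids VCF's comma-separated multi-value INFO semantics
            f"TIDS={str(row.transcript_ids).replace(',', '|') or '.'}",
            f"PROT={row.protein_id or '.'}",
            f"PPOS={int(row.protein_pos)}",
            f"AAREF={row.aa_ref or '.'}",
            f"AAALT={row.aa_alt or '.'}",
            f"FSTAIL={row.fs_tail or '.'}",
        ])
        lines.append("\t".join([str(row.chrom), str(int(row.pos)), str(row.variant_id),
                                str(row.ref), str(row.alt), ".", "PASS", info]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants_vcf(path: str | Path, patient_id: str) -> pd.DataFrame:
    """Read the minimal VCF dialect back into the variant-table schema."""
    import pysam

    if not Path(path).exists():
        raise FileNotFoundError(f"expected VCF at {path}")
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info

            def _s(key: str) -> str:
                v = info.get(key, ".")
                return "" if v in (".", None) else str(v)

            rows.append({
                "patient_id": patient_id,
                "variant_id": rec.id or "",
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else "",
                "n_callers": int(info["NCALLERS"]),
                "depth_tumor": int(info["DPT"]),
                "depth_normal": int(info["DPN"]),
                "alt_reads_tumor": int(info["ALTT"]),
                "vaf_dna": float(info["VAFD"]),
                "vaf_rna": float(info["VAFR"]),
                "consequence": str(info["CSQCLASS"]),
                "phase_set": _s("PS"),
                "transcript_ids": _s("TIDS").replace("|", ","),
                "protein_id": _s("PROT"),
                "protein_pos": int(info.get("PPOS", 0)),
                "aa_ref": _s("AAREF"),
                "aa_alt": _s("AAALT"),
                "fs_tail": _s("FSTAIL"),
            })
    return apply_schema(pd.DataFrame(rows), VARIANT_COLUMNS)


def variants_frame_to_records(df: pd.DataFrame):
    """Variant-table rows as :class:`~sarcimmune.variants.SomaticVariant` objects."""
    from .variants import SomaticVariant

    out = []
    for _, r in df.iterrows():
        tids = tuple(t for t in str(r.transcript_ids).split(",") if t)
        out.append(SomaticVariant(
            id=r.variant_id, chrom=str(r.chrom), position=int(r.pos),
            ref=r.ref, alt=r.alt, n_callers=int(r.n_callers),
            depth_tumor=int(r.depth_tumor), depth_normal=int(r.depth_normal),
            alt_reads_tumor=int(r.alt_reads_tumor), vaf_dna=float(r.vaf_dna),
            vaf_rna=float(r.vaf_rna), consequence=r.consequence,
            phase_set=r.phase_set, transcript_ids=tids,
            protein_id=r.protein_id, protein_pos=int(r.protein_pos),
            aa_ref=r.aa_ref, aa_alt=r.aa_alt, fs_tail=r.fs_tail))
    return out


def fusions_frame_to_records(df: pd.DataFrame):
    from .variants import FusionEvent

    return [FusionEvent(id=r.fusion_id, gene5=r.gene5, gene3=r.gene3,
                        junction_seq5=r.junction_seq5, junction_seq3=r.junction_seq3,
                        frame=r.frame, confidence=r.confidence)
            for _, r in df.iterrows()]


def sha256_file(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
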