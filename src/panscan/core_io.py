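"""Shared domain types, coordinate conventions, and file readers/writers.

All genomic and protein intervals are 0-based half-open internally.  Text
formats keep their native conventions at the boundary: GFF3/GTF coordinates
are 1-based inclusive on disk and converted on read/write, FASTA and TSV
carry no coordinates of their own.

Gene order ranks (the gene-count positions duplication typing works on) are
derived from start positions within each (genome, chromosome) at load time,
with ties broken by gene_id, so every table read through this module shares
one total order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "TISSUES",
    "ParseError",
    "ValidationError",
    "SchemaError",
    "ConfigError",
    "GenomeID",
    "GeneRecord",
    "ProteinRecord",
    "TranscriptModel",
    "ExpressionMatrix",
    "read_fasta",
    "write_fasta",
    "read_gff_transcripts",
    "write_gff3_transcripts",
    "write_gtf_transcripts",
    "read_table",
    "read_gene_orders",
    "read_expression",
]

#: The 20 standard residues plus the ambiguity code X.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Tissue vocabulary accepted in expression sample metadata.
TISSUES = ("root", "stem", "leaf", "panicle", "SAM", "rhizome", "shoot")


class ParseError(ValueError):
    """A text file violates its format (reported with a line number)."""


class ValidationError(ValueError):
    """Parsed data violates a semantic invariant."""


class SchemaError(ValueError):
    """A table is missing or mistypes a required column."""


class ConfigError(ValueError):
    """A configuration value is out of its documented range."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_PLOIDY_ROLES = ("diploid", "subgenome_of_allotetraploid", "outgroup")


@dataclass(frozen=True)
class GenomeID:
    """A genome or subgenome, e.g. the BB subgenome of an allotetraploid."""

    species: str
    subgenome: str = ""
    ploidy_role: str = "diploid"

    def __post_init__(self) -> None:
        if self.ploidy_role not in _PLOIDY_ROLES:
            raise ValidationError(f"unknown ploidy_role {self.ploidy_role!r}")
        if (self.ploidy_role == "subgenome_of_allotetraploid") != bool(self.subgenome):
            raise ValidationError(
                "subgenome must be non-empty iff ploidy_role is "
                f"subgenome_of_allotetraploid (got {self})"
            )

    @property
    def label(self) -> str:
        return f"{self.species}-{self.subgenome}" if self.subgenome else self.species


FAMILIES = ("CCaMK", "CPK", "CRK", "PEPRK", "PPCK")


@dataclass
class GeneRecord:
    """One gene locus with its position in the chromosome gene order."""

    gene_id: str
    genome: GenomeID
    chromosome: str
    start: int
    end: int
    strand: str
    order_rank: int = -1
    family: str = "none"
    ortholog_group: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if self.family != "none" and self.family not in FAMILIES:
            raise ValidationError(f"{self.gene_id}: unknown family {self.family!r}")


@dataclass
class ProteinRecord:
    """An amino-acid sequence over the 20 standard residues plus X."""

    protein_id: str
    gene_id: str = ""
    transcript_id: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.protein_id}: illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript, intervals ordered 5'->3'."""

    transcript_id: str
    gene_id: str
    strand: str
    chromosome: str = ""
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, ivals in (("exons", self.exons), ("cds", self.cds)):
            genomic = sorted(ivals)
            for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"{self.transcript_id}: overlapping {name} intervals"
                    )
        for c in self.cds:
            if not any(e[0] <= c[0] and c[1] <= e[1] for e in self.exons):
                raise ValidationError(
                    f"CDS outside exon bounds in transcript {self.transcript_id}"
                )


@dataclass
class ExpressionMatrix:
    """FPKM values (genes x samples) plus per-sample species/tissue metadata.

    ``values`` is indexed by gene_id with one column per sample; ``sample_meta``
    is indexed by sample name with columns species, tissue, replicate.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative FPKM value in expression matrix")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        for col in ("species", "tissue"):
            if col not in self.sample_meta.columns:
                raise SchemaError(f"sample metadata missing column {col!r}")
        bad = set(self.sample_meta["tissue"]) - set(TISSUES)
        if bad:
            raise ValidationError(f"unknown tissue label(s): {sorted(bad)}")

    def samples_for(self, tissue: str, species: str | None = None) -> list[str]:
        meta = self.sample_meta.loc[list(self.values.columns)]
        mask = meta["tissue"] == tissue
        if species is not None:
            mask &= meta["species"] == species
        return list(meta.index[mask])

    def tissue_means(self, genes: Sequence[str] | None = None) -> pd.DataFrame:
        """Mean FPKM per gene per tissue (replicates averaged)."""
        sub = self.values if genes is None else self.values.loc[list(genes)]
        tissue = self.sample_meta.loc[list(sub.columns), "tissue"]
        return sub.T.groupby(tissue.to_numpy()).mean().T

    @property
    def tissues(self) -> list[str]:
        present = set(self.sample_meta.loc[list(self.values.columns), "tissue"])
        return [t for t in TISSUES if t in present]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into records.

    Sequences are uppercased; a single trailing '*' stop symbol is stripped.
    Malformed headers or residues outside the alphabet raise :class:`ParseError`
    naming the offending line.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ParseError(f"line {header_line}: record {header!r} has no sequence")
        records.append(ProteinRecord(protein_id=header, sequence=seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"line {lineno}: sequence before first header")
                seq = line.upper()
                body = seq[:-1] if seq.endswith("*") else seq
                bad = set(body) - AA_ALPHABET
                if bad:
                    raise ParseError(
                        f"line {lineno}: illegal residue(s) {sorted(bad)}"
                    )
                chunks.append(seq)
    flush()
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as '>protein_id' FASTA, wrapping sequence lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / GTF transcript models
# ---------------------------------------------------------------------------

def _sniff_dialect(path: str | Path) -> str:
    """Return 'gff3' or 'gtf' from the attribute syntax of column 9."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            attrs = cols[8]
            if "=" in attrs and '"' not in attrs:
                return "gff3"
            return "gtf"
    return "gff3"


def read_gff_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from GFF3 or GTF (dialect auto-detected).

    File coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention; minus-strand exon/CDS lists are ordered 5'->3'.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # Map transcript id -> gene id from transcript-level features when present.
    tx_gene: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        for f in db.features_of_type(ftype):
            tid = f.attributes.get("ID", [f.id])[0]
            gid = (
                f.attributes.get("gene_id", [""])[0]
                or f.attributes.get("Parent", [""])[0]
            )
            tx_gene[tid] = gid

    def tids_of(feature) -> list[str]:
        attrs = feature.attributes
        if "transcript_id" in attrs:
            return list(attrs["transcript_id"])
        if "Parent" in attrs:
            return list(attrs["Parent"])
        raise ParseError(
            f"feature without transcript_id/Parent at {feature.seqid}:{feature.start}"
        )

    acc: dict[str, TranscriptModel] = {}
    for ftype, attr in (("exon", "exons"), ("CDS", "cds")):
        for f in db.features_of_type(ftype):
            for tid in tids_of(f):
                model = acc.get(tid)
                if model is None:
                    gid = f.attributes.get("gene_id", [""])[0] or tx_gene.get(tid, "")
                    model = TranscriptModel(
                        transcript_id=tid,
                        gene_id=gid,
                        strand=f.strand,
                        chromosome=f.seqid,
                    )
                    acc[tid] = model
                getattr(model, attr).append((f.start - 1, f.end))

    models = []
    for model in acc.values():
        reverse = model.strand == "-"
        model.exons.sort(key=lambda iv: iv[0], reverse=reverse)
        model.cds.sort(key=lambda iv: iv[0], reverse=reverse)
        # Re-run invariant checks now that intervals are populated.
        model.__post_init__()
        models.append(model)
    return models


def _gff_lines(models: Iterable[TranscriptModel], dialect: str) -> Iterable[str]:
    for m in models:
        genomic_exons = sorted(m.exons)
        genomic_cds = sorted(m.cds)
        span = (genomic_exons[0][0], genomic_exons[-1][1]) if genomic_exons else (0, 1)
        if dialect == "gff3":
            attrs_tx = f"ID={m.transcript_id};Parent={m.gene_id}"
            yield "\t".join(
                [m.chromosome or ".", "panscan", "mRNA", str(span[0] + 1),
                 str(span[1]), ".", m.strand, ".", attrs_tx]
            )
        rows = [("exon", iv) for iv in genomic_exons] + [("CDS", iv) for iv in genomic_cds]
        for ftype, (s, e) in rows:
            if dialect == "gff3":
                attrs = f"Parent={m.transcript_id}"
            else:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                )
            yield "\t".join(
                [m.chromosome or ".", "panscan", ftype, str(s + 1), str(e),
                 ".", m.strand, "." if ftype == "exon" else "0", attrs]
            )


def write_gff3_transcripts(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in _gff_lines(models, "gff3"):
            fh.write(line + "\n")


def write_gtf_transcripts(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for line in _gff_lines(models, "gtf"):
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_table(
    path: str | Path,
    required: dict[str, type] | None = None,
    nonnegative: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a TSV with header; check required columns and value ranges.

    Unknown extra columns are accepted and carried through unchanged.
    """
    df = pd.read_csv(path, sep="\t")
    for col, dtype in (required or {}).items():
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"column {col!r} in {path} is not {dtype}: {exc}")
    for col in nonnegative:
        if col in df.columns and (df[col] < 0).any():
            raise ValidationError(f"negative value in column {col!r} of {path}")
    return df


GENE_ORDER_COLUMNS = {
    "gene_id": str,
    "genome": str,
    "chromosome": str,
    "start": int,
    "end": int,
    "strand": str,
}


def read_gene_orders(path: str | Path) -> pd.DataFrame:
    """Read a gene-order TSV and derive order_rank per (genome, chromosome).

    Rank is the 0-based position along the chromosome when genes are sorted
    by start, ties broken by gene_id.
    """
    df = read_table(path, required=GENE_ORDER_COLUMNS)
    return assign_order_ranks(df)


def assign_order_ranks(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(
        ["genome", "chromosome", "start", "gene_id"], kind="stable"
    ).reset_index(drop=True)
    df["order_rank"] = df.groupby(["genome", "chromosome"]).cumcount()
    return df


def read_expression(values_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read an FPKM matrix (gene_id + one column per sample) and its metadata."""
    values = pd.read_csv(values_path, sep="\t")
    if "gene_id" not in values.columns:
        raise SchemaError(f"missing required column 'gene_id' in {values_path}")
    values = values.set_index("gene_id")
    if (values.to_numpy() < 0).any():
        raise ValidationError(f"negative expression value in {values_path}")
    meta = read_table(
        meta_path, required={"sample": str, "species": str, "tissue": str}
    ).set_index("sample")
    return ExpressionMatrix(values=values, sample_meta=meta)
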