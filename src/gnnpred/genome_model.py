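"""Data model and I/O for ordered, family-annotated prokaryotic genomes.

Positions are *gene ordinals* — 0-based ranks in a contig's gene order —
not base pairs: neighborhood windows are defined in genes, so base-pair
distances are never modeled. Strand is stored for realism but ignored by
neighborhood extraction, which is agnostic to transcription-unit layout.
Genes may carry zero or more protein-family accessions (Pfam-style);
unannotated genes occupy window slots but contribute no family counts.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import FormatError, ValidationError

GENE_TABLE_COLUMNS = [
    "genome_id",
    "phylum",
    "contig_id",
    "ordinal",
    "strand",
    "protein_id",
    "family_ids",
    "circular",
]


@dataclass(frozen=True)
class GeneRecord:
    """One gene in a contig's gene order.

    ``family_ids`` is the (possibly empty) set of protein-family accessions
    the gene product is annotated with; multi-domain proteins carry several.
    """

    genome_id: str
    contig_id: str
    ordinal: int
    strand: str
    protein_id: str
    family_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"strand of {self.protein_id!r} must be '+' or '-', got {self.strand!r}"
            )
        if self.ordinal < 0:
            raise ValidationError(f"negative ordinal for {self.protein_id!r}")


@dataclass
class Contig:
    """An ordered list of genes; circular contigs wrap at the ends."""

    contig_id: str
    genes: list[GeneRecord]
    circular: bool = False

    def __post_init__(self) -> None:
        for i, g in enumerate(self.genes):
            if g.ordinal != i:
                raise ValidationError(
                    f"contig {self.contig_id!r}: ordinals are not consecutive from 0 "
                    f"(position {i} has ordinal {g.ordinal})"
                )
        if self.circular and len(self.genes) < 2:
            raise ValidationError(
                f"circular contig {self.contig_id!r} must hold at least 2 genes"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GenomeAnnotation:
    """A genome: phylum label plus one or more contigs."""

    genome_id: str
    phylum: str
    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.phylum:
            raise ValidationError(f"genome {self.genome_id!r} has an empty phylum label")
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"genome {self.genome_id!r} has duplicate contig_ids")

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.contigs)


class GenomeDataset:
    """A collection of genomes with a global protein index.

    Enforces global uniqueness of protein identifiers and supports O(1)
    lookup of a protein's (genome, contig, ordinal) location.
    """

    def __init__(self, genomes: Iterable[GenomeAnnotation]):
        self.genomes: list[GenomeAnnotation] = list(genomes)
        self._loc: dict[str, tuple[GenomeAnnotation, Contig, int]] = {}
        for genome in self.genomes:
            for contig in genome.contigs:
                for gene in contig.genes:
                    if gene.protein_id in self._loc:
                        raise ValidationError(
                            f"duplicate protein_id {gene.protein_id!r} in dataset"
                        )
                    self._loc[gene.protein_id] = (genome, contig, gene.ordinal)

    def __len__(self) -> int:
        return len(self.genomes)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._loc

    def locate(self, protein_id: str) -> tuple[GenomeAnnotation, Contig, int]:
        try:
            return self._loc[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein_id {protein_id!r}") from None

    def proteins_of_family(self, family_id: str) -> list[str]:
        """All protein ids annotated with ``family_id``, in dataset order."""
        out = []
        for genome in self.genomes:
            for contig in genome.contigs:
                for gene in contig.genes:
                    if family_id in gene.family_ids:
                        out.append(gene.protein_id)
        return out


def as_dataset(genomes: Iterable[GenomeAnnotation] | GenomeDataset) -> GenomeDataset:
    if isinstance(genomes, GenomeDataset):
        return genomes
    return GenomeDataset(genomes)


# ---------------------------------------------------------------------------
# gene-order TSV
# ---------------------------------------------------------------------------

def _parse_families(raw: str) -> frozenset[str]:
    if not raw or pd.isna(raw):
        return frozenset()
    return frozenset(tok for tok in str(raw).split(";") if tok)


def _parse_bool(raw) -> bool:
    if isinstance(raw, bool):
        return raw
    return str(raw).strip().lower() in ("true", "1", "yes")


def read_gene_table(path: str | Path) -> list[GenomeAnnotation]:
    """Read a gene-order TSV into genomes, enforcing all invariants.

    Rows may arrive unsorted; records are sorted by (genome, contig, ordinal).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in GENE_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    seen: set[str] = set()
    genomes: list[GenomeAnnotation] = []
    for genome_id, gdf in df.groupby("genome_id", sort=False):
        phyla = gdf["phylum"].unique()
        if len(phyla) != 1:
            raise ValidationError(
                f"genome {genome_id!r} has conflicting phylum labels {sorted(phyla)}"
            )
        contigs = []
        for contig_id, cdf in gdf.groupby("contig_id", sort=False):
            cdf = cdf.copy()
            try:
                cdf["ordinal"] = cdf["ordinal"].astype(int)
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer ordinal in contig {contig_id!r}") from exc
            cdf = cdf.sort_values("ordinal", kind="stable")
            ordinals = cdf["ordinal"].tolist()
            if ordinals != list(range(len(ordinals))):
                raise ValidationError(
                    f"contig {contig_id!r} of genome {genome_id!r}: ordinals "
                    f"are not consecutive integers starting at 0"
                )
            circ_vals = {_parse_bool(v) for v in cdf["circular"]}
            if len(circ_vals) != 1:
                raise ValidationError(
                    f"contig {contig_id!r}: inconsistent circular flags"
                )
            genes = []
            for row in cdf.itertuples(index=False):
                if row.protein_id in seen:
                    raise ValidationError(f"duplicate protein_id {row.protein_id!r}")
                seen.add(row.protein_id)
                genes.append(
                    GeneRecord(
                        genome_id=str(genome_id),
                        contig_id=str(contig_id),
                        ordinal=int(row.ordinal),
                        strand=row.strand,
                        protein_id=row.protein_id,
                        family_ids=_parse_families(row.family_ids),
                    )
                )
            contigs.append(Contig(contig_id=str(contig_id), genes=genes, circular=circ_vals.pop()))
        genomes.append(GenomeAnnotation(genome_id=str(genome_id), phylum=phyla[0], contigs=contigs))
    return genomes


def write_gene_table(genomes: Iterable[GenomeAnnotation], path: str | Path) -> None:
    """Write the gene-order TSV with deterministic row order."""
    rows = []
    for genome in genomes:
        for contig in genome.contigs:
            for gene in contig.genes:
                rows.append(
                    {
                        "genome_id": genome.genome_id,
                        "phylum": genome.phylum,
                        "contig_id": contig.contig_id,
                        "ordinal": gene.ordinal,
                        "strand": gene.strand,
                        "protein_id": gene.protein_id,
                        "family_ids": ";".join(sorted(gene.family_ids)),
                        "circular": str(contig.circular).lower(),
                    }
                )
    df = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(["genome_id", "contig_id", "ordinal"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF3_NCOLS = 9


def _split_family_value(value: str) -> frozenset[str]:
    # accept standard comma-separated multi-values as well as
    # (percent-encoded) semicolon-separated accessions
    decoded = urllib.parse.unquote(value)
    return frozenset(tok for chunk in decoded.split(";") for tok in chunk.split(",") if tok)


def read_gff3(
    path: str | Path,
    family_attribute: str,
    genome_id: str | None = None,
    phylum: str = "unassigned",
) -> list[GenomeAnnotation]:
    """Read gene/CDS features of a GFF3 file into one genome.

    Features of each sequence region are sorted by 1-based start coordinate
    and assigned consecutive ordinals from 0. Family accessions are taken
    from ``family_attribute`` (comma- or encoded-semicolon-separated);
    features lacking it get empty family sets. CDS features are used when
    present, otherwise gene features.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    features: dict[str, list[tuple[int, int, str, str, frozenset[str]]]] = {}
    circular: dict[str, bool] = {}
    order_counter = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF3_NCOLS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_GFF3_NCOLS} tab-separated columns, got {len(cols)}"
                )
            seqid, _source, ftype, start_s, _end_s, _score, strand, _phase, attrs_s = cols
            try:
                start = int(start_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer start {start_s!r}") from None
            attrs: dict[str, str] = {}
            for item in attrs_s.split(";"):
                if not item:
                    continue
                if "=" not in item:
                    raise FormatError(f"{path}:{lineno}: malformed attribute {item!r}")
                key, _, value = item.partition("=")
                attrs[key] = value
            if ftype == "region" and attrs.get("Is_circular", "").lower() == "true":
                circular[seqid] = True
                continue
            if ftype not in ("gene", "CDS"):
                continue
            fams = _split_family_value(attrs[family_attribute]) if family_attribute in attrs else frozenset()
            pid = attrs.get("protein_id") or attrs.get("ID") or f"{seqid}_{order_counter}"
            if strand not in ("+", "-"):
                strand = "+"
            features.setdefault(seqid, []).append((start, order_counter, ftype, pid, strand, fams))
            order_counter += 1
    contigs = []
    for seqid, feats in features.items():
        has_cds = any(f[2] == "CDS" for f in feats)
        keep = [f for f in feats if f[2] == ("CDS" if has_cds else "gene")]
        keep.sort(key=lambda f: (f[0], f[1]))  # by start, input order breaks ties
        genes = [
            GeneRecord(
                genome_id=genome_id,
                contig_id=seqid,
                ordinal=i,
                strand=f[4],
                protein_id=f[3],
                family_ids=f[5],
            )
            for i, f in enumerate(keep)
        ]
        contigs.append(Contig(contig_id=seqid, genes=genes, circular=circular.get(seqid, False)))
    return [GenomeAnnotation(genome_id=genome_id, phylum=phylum, contigs=contigs)]


def write_gff3(
    genome: GenomeAnnotation,
    path: str | Path,
    family_attribute: str = "pfam",
    gene_span: int = 900,
    gene_spacing: int = 1000,
) -> None:
    """Serialize one genome as GFF3 CDS features (synthetic coordinates).

    Gene ordinals are mapped to evenly spaced 1-based coordinate blocks so
    that re-reading reproduces the gene order exactly.
    """
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("##gff-version 3\n")
        for contig in genome.contigs:
            end = max(len(contig) * gene_spacing, 1)
            handle.write(f"##sequence-region {contig.contig_id} 1 {end}\n")
            if contig.circular:
                handle.write(
                    f"{contig.contig_id}\tgnnpred\tregion\t1\t{end}\t.\t+\t.\t"
                    f"ID=region-{contig.contig_id};Is_circular=true\n"
                )
            for gene in contig.genes:
                start = gene.ordinal * gene_spacing + 1
                stop = start + gene_span - 1
                attrs = [f"ID={gene.protein_id}", f"protein_id={gene.protein_id}"]
                if gene.family_ids:
                    attrs.append(f"{family_attribute}={','.join(sorted(gene.family_ids))}")
                handle.write(
                    f"{contig.contig_id}\tgnnpred\tCDS\t{start}\t{stop}\t.\t{gene.strand}\t0\t"
                    + ";".join(attrs)
                    + "\n"
                )
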