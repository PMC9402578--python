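"""Transcript annotation model: GTF/protein-FASTA readers, CDS-identity
isoform grouping, and CDS-incomplete isoform classification.

Coordinates are 1-based inclusive throughout (GTF convention). Transcription
start/end sites are strand-aware: the TSS of a minus-strand transcript is the
highest genomic coordinate of its exon chain.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

# GENCODE machine-readable flags for a CDS truncated at either end.
CDS_START_TAG = "cds_start_NF"
CDS_END_TAG = "cds_end_NF"

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message carries the line number."""


@dataclass
class IsoformRecord:
    """One transcript with its exon chain and CDS-completeness flags."""

    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = ""
    cds_incomplete_start: bool = False
    cds_incomplete_end: bool = False
    protein_key: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b), (c, _) in zip(self.exons, self.exons[1:]):
            if c <= b:
                raise ValueError(
                    f"{self.isoform_id}: overlapping exons ({a},{b}) and ({c},..)"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        """(donor, acceptor) coordinate pairs in genomic order: first base
        after the upstream exon through last base before the downstream exon."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def is_cds_incomplete(self) -> bool:
        return self.cds_incomplete_start or self.cds_incomplete_end


@dataclass
class IsoformCatalog:
    """All isoforms keyed by id, with a gene -> isoform-id index."""

    isoforms: dict[str, IsoformRecord] = field(default_factory=dict)
    genes: dict[str, list[str]] = field(default_factory=dict)

    def add(self, rec: IsoformRecord) -> None:
        if rec.isoform_id in self.isoforms:
            raise ValueError(f"duplicate isoform id {rec.isoform_id}")
        self.isoforms[rec.isoform_id] = rec
        self.genes.setdefault(rec.gene_id, []).append(rec.isoform_id)

    def __len__(self) -> int:
        return len(self.isoforms)

    def __iter__(self):
        return iter(self.isoforms.values())

    def gene_span(self, gene_id: str) -> tuple[str, int, int, str]:
        """(chrom, tss, tes, strand) of the union span of a gene's isoforms."""
        recs = [self.isoforms[i] for i in self.genes[gene_id]]
        chrom = recs[0].chrom
        strand = recs[0].strand
        lo = min(r.start for r in recs)
        hi = max(r.end for r in recs)
        if strand == "+":
            return chrom, lo, hi, strand
        return chrom, hi, lo, strand


@dataclass
class CdsGroupSet:
    """Partition of isoforms into groups sharing an identical protein."""

    groups: dict[str, list[str]] = field(default_factory=dict)
    membership: dict[str, str] = field(default_factory=dict)
    unkeyed: set[str] = field(default_factory=set)

    def multi_member_groups(self) -> dict[str, list[str]]:
        return {g: m for g, m in self.groups.items() if len(m) >= 2}

    def n_isoforms_in_multi_groups(self) -> int:
        return sum(len(m) for m in self.multi_member_groups().values())


def _parse_attributes(attr_field: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for key, val in _ATTR_RE.findall(attr_field):
        out.setdefault(key, []).append(val)
    return out


def normalize_protein(seq: str) -> str:
    """Exact-identity key: uppercase, terminal stop symbols stripped."""
    return seq.strip().upper().rstrip("*.")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA keyed by transcript id.

    GENCODE pc_translations headers are |-delimited; the transcript id is
    the first field. Plain headers are used as-is. Trailing version-free
    lookups are the caller's concern; keys are stored verbatim.
    """
    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        key = rec.id.split("|")[0]
        proteins[key] = normalize_protein(str(rec.seq))
    return proteins


def read_annotation(
    gtf_path: str | Path,
    protein_fasta_path: str | Path | None = None,
) -> IsoformCatalog:
    """Build an :class:`IsoformCatalog` from a GENCODE-dialect GTF.

    Transcript rows supply ids, biotype and tags (``cds_start_NF`` /
    ``cds_end_NF`` set the CDS-incompleteness flags); exon rows supply the
    exon chain. Transcripts that never receive an exon are dropped with a
    warning. A protein FASTA, when given, attaches ``protein_key`` to
    transcripts it covers (matching with and without the id version suffix).
    """
    meta: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("transcript", "exon"):
                continue
            attr = _parse_attributes(attrs)
            try:
                tid = attr["transcript_id"][0]
                gid = attr["gene_id"][0]
            except KeyError as exc:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: missing {exc.args[0]} attribute"
                ) from None
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: non-integer coordinates"
                ) from None

            if tid not in meta:
                meta[tid] = {
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": "",
                    "cds_incomplete_start": False,
                    "cds_incomplete_end": False,
                }
                order.append(tid)
            if feature == "transcript":
                tags = attr.get("tag", [])
                biotype = attr.get("transcript_type", attr.get("transcript_biotype", [""]))[0]
                meta[tid]["biotype"] = biotype
                meta[tid]["cds_incomplete_start"] = CDS_START_TAG in tags
                meta[tid]["cds_incomplete_end"] = CDS_END_TAG in tags
            else:
                exons.setdefault(tid, []).append((start_i, end_i))

    proteins = (
        read_protein_fasta(protein_fasta_path) if protein_fasta_path else {}
    )

    catalog = IsoformCatalog()
    for tid in order:
        if tid not in exons:
            logger.warning("transcript %s has zero exons; record rejected", tid)
            continue
        info = meta[tid]
        key = proteins.get(tid)
        if key is None and "." in tid:
            key = proteins.get(tid.split(".")[0])
        catalog.add(
            IsoformRecord(
                isoform_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=exons[tid],
                biotype=info["biotype"],
                cds_incomplete_start=info["cds_incomplete_start"],
                cds_incomplete_end=info["cds_incomplete_end"],
                protein_key=key,
            )
        )
    return catalog


def write_gtf(catalog: IsoformCatalog, path: str | Path) -> None:
    """Write the catalog back to a GENCODE-dialect GTF (transcript + exon rows)."""
    with open(path, "w") as fh:
        for rec in catalog:
            tags = ""
            if rec.cds_incomplete_start:
                tags += f' tag "{CDS_START_TAG}";'
            if rec.cds_incomplete_end:
                tags += f' tag "{CDS_END_TAG}";'
            base = (
                f'gene_id "{rec.gene_id}"; transcript_id "{rec.isoform_id}"; '
                f'transcript_type "{rec.biotype}";'
            )
            fh.write(
                "\t".join(
                    [
                        rec.chrom, "cdssqtl", "transcript",
                        str(rec.start), str(rec.end),
                        ".", rec.strand, ".", base + tags,
                    ]
                )
                + "\n"
            )
            for a, b in rec.exons:
                fh.write(
                    "\t".join(
                        [rec.chrom, "cdssqtl", "exon", str(a), str(b),
                         ".", rec.strand, ".", base]
                    )
                    + "\n"
                )


def build_cds_groups(
    catalog: IsoformCatalog,
    isoform_ids: Iterable[str] | None = None,
) -> CdsGroupSet:
    """Partition isoforms into CDS-identity groups within each gene.

    Isoforms of one gene with byte-identical ``protein_key`` share a group;
    isoforms lacking a key fall into flagged singleton groups. Group ids are
    deterministic: the gene id joined with the sorted member ids.
    """
    if isoform_ids is None:
        isoform_ids = list(catalog.isoforms)
    by_key: dict[tuple[str, str], list[str]] = {}
    unkeyed: list[str] = []
    for iid in isoform_ids:
        rec = catalog.isoforms[iid]
        if rec.protein_key is None:
            unkeyed.append(iid)
        else:
            by_key.setdefault((rec.gene_id, rec.protein_key), []).append(iid)

    gset = CdsGroupSet()
    for (gene_id, _key), members in by_key.items():
        members = sorted(members)
        gid = gene_id + "|" + "+".join(members)
        gset.groups[gid] = members
        for m in members:
            gset.membership[m] = gid
    for iid in unkeyed:
        rec = catalog.isoforms[iid]
        gid = rec.gene_id + "|" + iid
        gset.groups[gid] = [iid]
        gset.membership[iid] = gid
        gset.unkeyed.add(iid)
    if unkeyed:
        logger.info("%d isoforms without protein_key placed in singleton groups",
                    len(unkeyed))
    return gset


def classify_cdsi(catalog: IsoformCatalog) -> set[str]:
    """Isoform ids flagged CDS-incomplete at either end."""
    return {rec.isoform_id for rec in catalog if rec.is_cds_incomplete}
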