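"""Genome / annotation input and upstream (promoter) sequence extraction.

A "promoter" here is the fixed-length region immediately upstream of the
translation start codon (ATG), read 5'->3' toward the ATG.  It may include
5'UTR sequence; no attempt is made to locate the transcription start site.
External coordinates are 1-based inclusive (the GFF3 convention); internal
string arithmetic is 0-based half-open.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene anchored by the position of its start codon.

    ``atg_pos`` is the 1-based forward-strand coordinate of the A of the
    ATG: for a minus-strand gene this is the *highest* coordinate of the
    coding region.
    """

    gene_id: str
    seq_id: str
    strand: str
    atg_pos: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.atg_pos < 1:
            raise ValueError(f"atg_pos must be >= 1, got {self.atg_pos}")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


@dataclass
class PromoterSet:
    """Gene-indexed upstream sequences for one species.

    ``entries`` maps gene_id -> uppercase sequence over {A,C,G,T,N}.  The
    obtained length of a promoter is simply ``len(entries[gene_id])``; it is
    below ``requested_length`` only for genes truncated by a contig edge.
    """

    species_label: str
    requested_length: int = 1000
    entries: dict[str, str] = field(default_factory=dict)

    def obtained_length(self, gene_id: str) -> int:
        return len(self.entries[gene_id])

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def load_genome(fasta_path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a map seq_id -> uppercase sequence.

    seq_id is the first whitespace-delimited header token.  Characters
    outside {A,C,G,T,N} (ambiguity codes, gaps) are masked to N and the
    replacement count is logged; N never matches any motif downstream.
    """
    store: dict[str, str] = {}
    masked = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in store:
            raise ValueError(f"duplicate sequence id in {fasta_path}: {rec.id!r}")
        seq = str(rec.seq).upper()
        clean = "".join(c if c in VALID_BASES else "N" for c in seq)
        masked += sum(1 for a, b in zip(seq, clean) if a != b)
        store[rec.id] = clean
    if not store:
        raise ValueError(f"no sequences found in {fasta_path}")
    if masked:
        log.info("masked %d non-ACGTN characters to N while reading %s", masked, fasta_path)
    return store


def _parse_tsv_annotation(path: Path) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}")
            gene_id, seq_id, strand, atg = parts
            # Unicode minus tolerated on input.
            strand = strand.replace("−", "-")
            if lineno == 1 and not atg.strip().lstrip("-").isdigit():
                continue  # optional header row
            try:
                atg_pos = int(atg)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer atg_pos {atg!r}") from exc
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            records.append(GeneRecord(gene_id, seq_id, strand, atg_pos))
    return records


def _parse_gff3_annotation(path: Path) -> list[GeneRecord]:
    # CDS rows are grouped by Parent (resolved through mRNA/transcript
    # parents to the gene where possible, falling back to the immediate
    # Parent or the CDS ID) and the translation start is min(start) on the
    # + strand, max(end) on the - strand.
    from gffutils.iterators import DataIterator

    gene_ids: list[str] = []
    transcript_parent: dict[str, str] = {}
    cds_groups: dict[str, list[tuple[str, str, int, int]]] = {}

    for feat in DataIterator(str(path)):
        ftype = feat.featuretype
        attrs = feat.attributes
        if ftype == "gene":
            gid = attrs.get("ID", [None])[0]
            if gid is not None:
                gene_ids.append(gid)
        elif ftype in {"mRNA", "transcript"}:
            tid = attrs.get("ID", [None])[0]
            parent = attrs.get("Parent", [None])[0]
            if tid is not None and parent is not None:
                transcript_parent[tid] = parent
        elif ftype == "CDS":
            parent = attrs.get("Parent", attrs.get("ID", [None]))[0]
            if parent is None:
                raise ValueError(f"CDS feature without Parent/ID in {path}")
            group = transcript_parent.get(parent, parent)
            cds_groups.setdefault(group, []).append(
                (feat.seqid, feat.strand, int(feat.start), int(feat.end))
            )

    records: list[GeneRecord] = []
    for gid, rows in cds_groups.items():
        seq_id = rows[0][0]
        strand = rows[0][1]
        if strand not in {"+", "-"}:
            raise ValueError(f"gene {gid!r}: strand {strand!r} not in {{+,-}}")
        if strand == "+":
            atg_pos = min(r[2] for r in rows)
        else:
            atg_pos = max(r[3] for r in rows)
        records.append(GeneRecord(gid, seq_id, strand, atg_pos))

    with_cds = set(cds_groups)
    for gid in gene_ids:
        if gid not in with_cds:
            log.warning("gene %s has no CDS rows; skipped", gid)

    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r} in {path}")
        seen.add(rec.gene_id)
    return records


def load_annotation(path: str | Path, format: str = "tsv") -> list[GeneRecord]:
    """Load gene records from a 4-column TSV or a GFF3 file.

    TSV columns: gene_id, seq_id, strand, atg_pos (header row optional).
    For GFF3, the translation start is inferred from CDS spans.
    """
    path = Path(path)
    if format == "tsv":
        return _parse_tsv_annotation(path)
    if format == "gff3":
        return _parse_gff3_annotation(path)
    raise ValueError(f"unknown annotation format {format!r} (expected 'tsv' or 'gff3')")


def extract_upstream(
    store: Mapping[str, str],
    genes: Iterable[GeneRecord],
    requested_length: int = 1000,
    species_label: str = "",
) -> PromoterSet:
    """Extract the upstream region of each gene, 5'->3' toward the ATG.

    Plus strand: forward bases at 1-based positions
    [max(1, atg_pos - L) .. atg_pos - 1].  Minus strand: reverse complement
    of forward positions [atg_pos + 1 .. min(contig_end, atg_pos + L)].
    Genes truncated by a contig edge are retained with a shorter sequence
    (counted in the log), never dropped, so promoter counts stay comparable
    across species.
    """
    pset = PromoterSet(species_label=species_label, requested_length=requested_length)
    truncated = 0
    for g in genes:
        if g.seq_id not in store:
            raise KeyError(f"gene {g.gene_id}: seq_id {g.seq_id!r} not present in genome")
        contig = store[g.seq_id]
        if g.atg_pos > len(contig):
            raise ValueError(
                f"gene {g.gene_id}: atg_pos {g.atg_pos} beyond contig {g.seq_id} "
                f"length {len(contig)}"
            )
        if g.strand == "+":
            start = max(1, g.atg_pos - requested_length)
            seq = contig[start - 1 : g.atg_pos - 1]
        else:
            end = min(len(contig), g.atg_pos + requested_length)
            seq = revcomp(contig[g.atg_pos : end])
        if len(seq) < requested_length:
            truncated += 1
            if len(seq) == 0:
                log.warning("gene %s: empty promoter (start codon at contig edge)", g.gene_id)
        if g.gene_id in pset.entries:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in annotation")
        pset.entries[g.gene_id] = seq
    if truncated:
        log.info(
            "%d/%d promoters shorter than %d nt (contig edge)",
            truncated, len(pset), requested_length,
        )
    return pset


def write_promoters(pset: PromoterSet, fasta_path: str | Path) -> None:
    """Write a PromoterSet to FASTA; headers carry the round-trip metadata."""
    records = []
    for gid, seq in pset.entries.items():
        desc = (
            f"obtained_length={len(seq)} species={pset.species_label or '.'} "
            f"requested_length={pset.requested_length}"
        )
        records.append(SeqRecord(Seq(seq), id=gid, description=desc))
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
        # SeqIO writes nothing for an empty list; the open() still yields a
        # valid (empty) FASTA file.


def read_promoters(fasta_path: str | Path) -> PromoterSet:
    """Inverse of :func:`write_promoters` (round-trip identity)."""
    pset = PromoterSet(species_label="", requested_length=1000)
    first = True
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        meta = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        if first:
            label = meta.get("species", ".")
            pset.species_label = "" if label == "." else label
            pset.requested_length = int(meta.get("requested_length", 1000))
            first = False
        if rec.id in pset.entries:
            raise ValueError(f"duplicate gene_id {rec.id!r} in {fasta_path}")
        pset.entries[rec.id] = str(rec.seq).upper()
    return pset
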