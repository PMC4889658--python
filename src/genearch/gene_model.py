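"""Gene models: annotation parsing, isoform sampling, structure extraction.

The unit of analysis is one randomly selected protein-coding isoform per
gene. From it we derive positionally classified exon and intron records,
apply the survey filters (minimum intron size, canonical GT--AG termini,
no nested genes, and a per-gene minimum of two retained introns), and
assemble intron-plus-next-exon (IpE) units.

Coordinate conventions: GTF input is 1-based inclusive; everything internal
is 0-based half-open on the plus strand of the reference. Sequences stored
on records are in transcript orientation (reverse-complemented for minus-
strand genes).
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd

from .genome import GenomeSequence, reverse_complement

# Splice-site window geometry (exonic + intronic nt around each boundary).
DONOR_EXONIC = 3
DONOR_INTRONIC = 6
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3
DONOR_WIDTH = DONOR_EXONIC + DONOR_INTRONIC
ACCEPTOR_WIDTH = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC

MIN_INTRON_LEN = 32
CAP_PROXIMAL_BOUNDARY = 250


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: ordered exon intervals in transcript orientation.

    ``exons`` are genomic 0-based half-open intervals, ordered 5'->3' along
    the transcript (descending genomic coordinate for minus-strand genes).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript without exons")
        starts = [e[0] for e in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"{self.transcript_id}: exons not ordered in transcript orientation")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def first_exon_len(self) -> int:
        s, e = self.exons[0]
        return e - s


@dataclass
class ExonRecord:
    gene_id: str
    transcript_id: str
    ordinal: int  # 1-based, transcript orientation
    pos_class: str  # first | second | internal | last
    length: int
    sequence: str  # transcript orientation
    chrom: str = ""
    start: int = 0  # genomic, 0-based half-open
    end: int = 0
    strand: str = "+"


@dataclass
class IntronRecord:
    gene_id: str
    transcript_id: str
    ordinal: int
    pos_class: str  # first | internal | last
    length: int
    sequence: str  # transcript orientation
    donor_dinuc: str
    acceptor_dinuc: str
    donor_window: str | None  # 9-mer: 3 exonic + 6 intronic; None if unavailable
    acceptor_window: str | None  # 23-mer: 20 intronic + 3 exonic
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    canonical: bool = False
    min_size_ok: bool = False
    nested_gene_overlap: bool | None = None  # filled by apply_filters
    donor_score: float | None = None  # filled by scoring stage
    acceptor_score: float | None = None

    @property
    def donor_window_ok(self) -> bool:
        return self.donor_window is not None and "N" not in self.donor_window

    @property
    def acceptor_window_ok(self) -> bool:
        return self.acceptor_window is not None and "N" not in self.acceptor_window


@dataclass
class IpEUnit:
    """An intron plus its immediately following exon.

    The unit's size is the distance between two consecutive donor splice
    sites; first units are split at a first-exon length of
    ``CAP_PROXIMAL_BOUNDARY`` (inclusive) into cap-proximal vs cap-distal.
    """

    intron: IntronRecord
    next_exon: ExonRecord
    size: int
    pos_class: str  # first_cap_proximal | first_cap_distal | internal | last
    first_exon_len: int
    upstream_5ss_score: float | None = None


# ---------------------------------------------------------------------------
# Annotation parsing


def _is_protein_coding(feature) -> bool:
    for key in ("gene_biotype", "transcript_biotype", "gene_type", "transcript_type"):
        if key in feature.attributes:
            return "protein_coding" in feature.attributes[key]
    # Ensembl GTFs always carry a biotype; absence means we cannot confirm.
    return False


def parse_annotation(
    gtf_path: str | Path,
) -> tuple[dict[str, list[TranscriptModel]], dict[str, tuple[str, int, int]]]:
    """Parse an Ensembl-dialect GTF.

    Returns ``(transcripts_by_gene, gene_spans)`` where transcripts_by_gene
    holds protein-coding transcripts only, and gene_spans covers *all* genes
    in the annotation (any biotype, either strand) for the nested-gene test.
    Spans are genomic 0-based half-open.
    """
    path = Path(gtf_path)
    if not path.exists():
        raise FileNotFoundError(f"GTF file not found: {path}")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons_by_tx: dict[str, list] = {}
    tx_meta: dict[str, tuple[str, str, str, bool]] = {}  # tx -> (gene, chrom, strand, coding)
    spans: dict[str, tuple[str, int, int]] = {}
    for ex in db.features_of_type("exon"):
        gene_id = ex.attributes["gene_id"][0]
        tx_id = ex.attributes["transcript_id"][0]
        exons_by_tx.setdefault(tx_id, []).append((ex.start - 1, ex.end))
        tx_meta[tx_id] = (gene_id, ex.seqid, ex.strand, _is_protein_coding(ex))
        chrom, lo, hi = spans.get(gene_id, (ex.seqid, ex.start - 1, ex.end))
        spans[gene_id] = (chrom, min(lo, ex.start - 1), max(hi, ex.end))
    # Gene features (if present) may extend beyond exons; prefer them.
    for g in db.features_of_type("gene"):
        gene_id = g.attributes["gene_id"][0]
        spans[gene_id] = (g.seqid, g.start - 1, g.end)

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx_id in sorted(exons_by_tx):
        gene_id, chrom, strand, coding = tx_meta[tx_id]
        if not coding:
            continue
        exons = sorted(exons_by_tx[tx_id])
        if strand == "-":
            exons = exons[::-1]
        tm = TranscriptModel(
            gene_id=gene_id,
            transcript_id=tx_id,
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
        )
        by_gene.setdefault(gene_id, []).append(tm)
    return by_gene, spans


def select_isoform(
    transcripts: Sequence[TranscriptModel], rng: np.random.Generator
) -> TranscriptModel:
    """Choose one isoform uniformly at random (deterministic given the rng).

    Candidates are ordered by transcript_id so the draw depends only on the
    rng state, not on annotation file order.
    """
    if not transcripts:
        raise ValueError("no protein-coding transcripts to select from")
    ordered = sorted(transcripts, key=lambda t: t.transcript_id)
    return ordered[int(rng.integers(len(ordered)))]


def select_isoforms(
    by_gene: dict[str, list[TranscriptModel]], seed_or_rng
) -> dict[str, TranscriptModel]:
    """One isoform per gene, iterating genes in sorted order for determinism."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return {g: select_isoform(txs, rng) for g, txs in sorted(by_gene.items())}


# ---------------------------------------------------------------------------
# Structure extraction


def _exon_pos_class(ordinal: int, n_exons: int) -> str:
    if ordinal == 1:
        return "first"
    if ordinal == n_exons:
        return "last"
    if ordinal == 2:
        return "second"
    return "internal"


def _intron_pos_class(ordinal: int, n_introns: int) -> str:
    if ordinal == 1:
        return "first"
    if ordinal == n_introns:
        return "last"
    return "internal"


def premrna_sequence(transcript: TranscriptModel, genome: GenomeSequence) -> str:
    """Unspliced transcript sequence (gene span) in transcript orientation."""
    lo, hi = transcript.span
    seq = genome.fetch(transcript.chrom, lo, hi)
    return reverse_complement(seq) if transcript.strand == "-" else seq


def _local_exons(transcript: TranscriptModel) -> list[tuple[int, int]]:
    """Exon intervals in pre-mRNA (transcript-oriented local) coordinates."""
    lo, hi = transcript.span
    if transcript.strand == "+":
        return [(s - lo, e - lo) for s, e in transcript.exons]
    return [(hi - e, hi - s) for s, e in transcript.exons]


def _to_genomic(local_start: int, local_end: int, transcript: TranscriptModel) -> tuple[int, int]:
    lo, hi = transcript.span
    if transcript.strand == "+":
        return (lo + local_start, lo + local_end)
    return (hi - local_end, hi - local_start)


def extract_structure(
    transcript: TranscriptModel, genome: GenomeSequence
) -> tuple[list[ExonRecord], list[IntronRecord]]:
    """Extract classified exon and intron records for one transcript.

    Introns are the gaps between consecutive exons in transcript
    orientation; zero-length gaps are an error. Donor/acceptor windows that
    would extend past the flanking exon or past the intron interior are
    marked unavailable (None).
    """
    pre = premrna_sequence(transcript, genome)
    local = _local_exons(transcript)
    n_ex = len(local)
    exons: list[ExonRecord] = []
    for i, (a, b) in enumerate(local, start=1):
        gs, ge = _to_genomic(a, b, transcript)
        exons.append(
            ExonRecord(
                gene_id=transcript.gene_id,
                transcript_id=transcript.transcript_id,
                ordinal=i,
                pos_class=_exon_pos_class(i, n_ex),
                length=b - a,
                sequence=pre[a:b],
                chrom=transcript.chrom,
                start=gs,
                end=ge,
                strand=transcript.strand,
            )
        )
    introns: list[IntronRecord] = []
    n_in = n_ex - 1
    for i in range(n_in):
        a = local[i][1]  # intron start (end of exon i)
        b = local[i + 1][0]  # intron end (start of exon i+1)
        if b <= a:
            raise ValueError(
                f"{transcript.transcript_id}: zero-length intron after exon {i + 1}"
            )
        seq = pre[a:b]
        length = b - a
        up_len = local[i][1] - local[i][0]
        down_len = local[i + 1][1] - local[i + 1][0]
        donor_window = (
            pre[a - DONOR_EXONIC : a + DONOR_INTRONIC]
            if up_len >= DONOR_EXONIC and length >= DONOR_INTRONIC
            else None
        )
        acceptor_window = (
            pre[b - ACCEPTOR_INTRONIC : b + ACCEPTOR_EXONIC]
            if down_len >= ACCEPTOR_EXONIC and length >= ACCEPTOR_INTRONIC
            else None
        )
        gs, ge = _to_genomic(a, b, transcript)
        introns.append(
            IntronRecord(
                gene_id=transcript.gene_id,
                transcript_id=transcript.transcript_id,
                ordinal=i + 1,
                pos_class=_intron_pos_class(i + 1, n_in),
                length=length,
                sequence=seq,
                donor_dinuc=seq[:2],
                acceptor_dinuc=seq[-2:],
                donor_window=donor_window,
                acceptor_window=acceptor_window,
                chrom=transcript.chrom,
                start=gs,
                end=ge,
                strand=transcript.strand,
                canonical=(seq[:2] == "GT" and seq[-2:] == "AG"),
                min_size_ok=(length >= MIN_INTRON_LEN),
            )
        )
    return exons, introns


def annotated_site_positions(transcript: TranscriptModel) -> tuple[list[int], list[int]]:
    """Local (pre-mRNA) coordinates of annotated donor starts and acceptor ends."""
    local = _local_exons(transcript)
    donors = [local[i][1] for i in range(len(local) - 1)]
    acceptors = [local[i + 1][0] for i in range(len(local) - 1)]
    return donors, acceptors


# ---------------------------------------------------------------------------
# Filters


def flag_nested_genes(
    introns: Iterable[IntronRecord],
    gene_spans: dict[str, tuple[str, int, int]],
    mode: str = "containment",
) -> None:
    """Set ``nested_gene_overlap`` on each intron, in place.

    ``mode='containment'`` (default): flagged when another gene's span lies
    entirely within the intron interval. ``mode='overlap'``: flagged on any
    >= 1 nt overlap with another gene's span (either strand).
    """
    if mode not in ("containment", "overlap"):
        raise ValueError(f"unknown nested-gene mode {mode!r}")
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, (chrom, s, e) in gene_spans.items():
        by_chrom.setdefault(chrom, []).append((s, e, gid))
    arr = {
        c: (
            np.array([x[0] for x in v]),
            np.array([x[1] for x in v]),
            np.array([x[2] for x in v]),
        )
        for c, v in by_chrom.items()
    }
    for intron in introns:
        if intron.chrom not in arr:
            intron.nested_gene_overlap = False
            continue
        starts, ends, gids = arr[intron.chrom]
        if mode == "containment":
            hit = (starts >= intron.start) & (ends <= intron.end)
        else:
            hit = (starts < intron.end) & (ends > intron.start)
        hit &= gids != intron.gene_id
        intron.nested_gene_overlap = bool(hit.any())


def apply_filters(
    introns: Sequence[IntronRecord],
    gene_spans: dict[str, tuple[str, int, int]],
    nested_mode: str = "containment",
    min_len: int = MIN_INTRON_LEN,
    min_introns_per_gene: int = 2,
) -> list[IntronRecord]:
    """The survey filter cascade.

    An intron is retained iff length >= ``min_len``, the splice sites are
    canonical GT--AG, and it hosts no nested gene. Genes left with fewer
    than ``min_introns_per_gene`` retained introns are dropped entirely.
    """
    introns = list(introns)
    flag_nested_genes(introns, gene_spans, mode=nested_mode)
    retained = [
        i
        for i in introns
        if i.length >= min_len and i.canonical and not i.nested_gene_overlap
    ]
    per_gene: dict[str, int] = {}
    for i in retained:
        per_gene[i.gene_id] = per_gene.get(i.gene_id, 0) + 1
    return [i for i in retained if per_gene[i.gene_id] >= min_introns_per_gene]


# ---------------------------------------------------------------------------
# IpE units


def build_ipe_units(
    exons: Sequence[ExonRecord],
    introns: Sequence[IntronRecord],
    cap_boundary: int = CAP_PROXIMAL_BOUNDARY,
) -> list[IpEUnit]:
    """Pair each intron with its next exon for one transcript.

    First units are cap-proximal when the first exon length (distance proxy
    to the cap-binding complex) is <= ``cap_boundary`` nt, inclusive.
    """
    exon_by_ord = {e.ordinal: e for e in exons}
    first_exon_len = exon_by_ord[1].length
    units = []
    for intron in introns:
        nxt = exon_by_ord[intron.ordinal + 1]
        if intron.pos_class == "first":
            cls = (
                "first_cap_proximal"
                if first_exon_len <= cap_boundary
                else "first_cap_distal"
            )
        else:
            cls = intron.pos_class
        units.append(
            IpEUnit(
                intron=intron,
                next_exon=nxt,
                size=intron.length + nxt.length,
                pos_class=cls,
                first_exon_len=first_exon_len,
                upstream_5ss_score=intron.donor_score,
            )
        )
    return units


# ---------------------------------------------------------------------------
# Tabular export


def introns_to_frame(introns: Sequence[IntronRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [i.gene_id for i in introns],
            "transcript_id": [i.transcript_id for i in introns],
            "ordinal": [i.ordinal for i in introns],
            "pos_class": [i.pos_class for i in introns],
            "length": [i.length for i in introns],
            "chrom": [i.chrom for i in introns],
            "start": [i.start for i in introns],
            "end": [i.end for i in introns],
            "strand": [i.strand for i in introns],
            "donor_dinuc": [i.donor_dinuc for i in introns],
            "acceptor_dinuc": [i.acceptor_dinuc for i in introns],
            "canonical": [i.canonical for i in introns],
            "donor_score": [i.donor_score for i in introns],
            "acceptor_score": [i.acceptor_score for i in introns],
        }
    )


def exons_to_frame(exons: Sequence[ExonRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in exons],
            "transcript_id": [e.transcript_id for e in exons],
            "ordinal": [e.ordinal for e in exons],
            "pos_class": [e.pos_class for e in exons],
            "length": [e.length for e in exons],
            "chrom": [e.chrom for e in exons],
            "start": [e.start for e in exons],
            "end": [e.end for e in exons],
            "strand": [e.strand for e in exons],
        }
    )


def ipe_to_frame(units: Sequence[IpEUnit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [u.intron.gene_id for u in units],
            "intron_ordinal": [u.intron.ordinal for u in units],
            "pos_class": [u.pos_class for u in units],
            "size": [u.size for u in units],
            "intron_length": [u.intron.length for u in units],
            "next_exon_length": [u.next_exon.length for u in units],
            "first_exon_len": [u.first_exon_len for u in units],
            "upstream_5ss_score": [u.upstream_5ss_score for u in units],
        }
    )


def export_bed6(introns: Sequence[IntronRecord], path: str | Path) -> None:
    """BED6 of surveyed introns (0-based half-open, name gene:ordinal)."""
    with open(path, "w") as fh:
        for i in sorted(introns, key=lambda x: (x.chrom, x.start)):
            fh.write(
                f"{i.chrom}\t{i.start}\t{i.end}\t{i.gene_id}:{i.ordinal}\t0\t{i.strand}\n"
            )
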