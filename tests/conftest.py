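"""Shared fixtures: hand-built toy annotations and a small synthetic genome."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from genearch.genome import reverse_complement, write_fasta
from genearch.synthetic_data import SyntheticGenomeSpec, generate


PASS_INTRON = "GT" + "A" * 28 + "AG"  # 32 nt, canonical
SHORT_INTRON = "GT" + "A" * 27 + "AG"  # 31 nt, canonical but below threshold
GC_INTRON = "GC" + "A" * 28 + "AG"  # noncanonical donor
AC_INTRON = "GT" + "A" * 28 + "AC"  # noncanonical acceptor
BIG_INTRON = "GT" + "C" * 96 + "AG"  # 100 nt, canonical (can host a nested gene)
EXON = "CCCCCCCCCCCCCCCCCCCC"  # 20 nt


@dataclass
class ToyDataset:
    fasta: str
    gtf: str
    #: gene_id -> number of surveyed introns expected after the filter cascade
    expected_survivors: dict


def _interleave(exons, introns):
    parts = [exons[0]]
    for i, intr in enumerate(introns):
        parts.append(intr)
        parts.append(exons[i + 1])
    return "".join(parts)


def build_toy_dataset(tmp_path) -> ToyDataset:
    """Ten hand-built genes exercising every branch of the filter cascade.

    Survivors (hand enumeration): gA keeps its 3 passing introns; gB drops
    (one of two introns below 32 nt leaves it with one); gC drops (GC
    donor); gD (minus strand) keeps 2; gE drops (nested gene gF inside its
    big intron leaves one retained intron); gF (single exon, nested) and gG
    (single exon) are never surveyed; gH drops (AC acceptor); gI keeps 3 of
    4 (one short intron discarded, three remain); gJ keeps 2.
    """
    genes = {}  # gene_id -> (strand, [exons], [introns])
    genes["gA"] = ("+", [EXON] * 4, [PASS_INTRON] * 3)
    genes["gB"] = ("+", [EXON] * 3, [PASS_INTRON, SHORT_INTRON])
    genes["gC"] = ("+", [EXON] * 3, [PASS_INTRON, GC_INTRON])
    genes["gD"] = ("-", [EXON] * 3, [PASS_INTRON] * 2)
    genes["gE"] = ("+", [EXON] * 3, [PASS_INTRON, BIG_INTRON])
    genes["gG"] = ("+", [EXON], [])
    genes["gH"] = ("+", [EXON] * 3, [AC_INTRON, PASS_INTRON])
    genes["gI"] = ("+", [EXON] * 5, [PASS_INTRON, SHORT_INTRON, PASS_INTRON, PASS_INTRON])
    genes["gJ"] = ("+", [EXON] * 3, [PASS_INTRON] * 2)

    spacer = "T" * 50
    chrom_parts = []
    gtf_lines = []
    pos = 0
    nested_span = None
    for gid in ["gA", "gB", "gC", "gD", "gE", "gG", "gH", "gI", "gJ"]:
        strand, exons, introns = genes[gid]
        chrom_parts.append(spacer)
        pos += len(spacer)
        tx = _interleave(exons, introns)
        start = pos
        # transcript-local exon intervals
        local, cursor = [], 0
        for i, e in enumerate(exons):
            local.append((cursor, cursor + len(e)))
            cursor += len(e)
            if i < len(introns):
                cursor += len(introns[i])
        if strand == "+":
            chrom_parts.append(tx)
            genomic = [(start + a, start + b) for a, b in local]
        else:
            chrom_parts.append(reverse_complement(tx))
            genomic = [(start + len(tx) - b, start + len(tx) - a) for a, b in local]
        pos += len(tx)
        end = pos
        attrs = (
            f'gene_id "{gid}"; transcript_id "{gid}.t1"; '
            f'gene_biotype "protein_coding"; transcript_biotype "protein_coding";'
        )
        gtf_lines.append(f"chrT\ttoy\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tgene_id \"{gid}\"; gene_biotype \"protein_coding\";\n")
        gtf_lines.append(f"chrT\ttoy\ttranscript\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n")
        for a, b in sorted(genomic):
            gtf_lines.append(f"chrT\ttoy\texon\t{a + 1}\t{b}\t.\t{strand}\t.\t{attrs}\n")
        if gid == "gE":
            # gF: nested single-exon gene inside gE's 100-nt second intron.
            intron2_start = start + 20 + 32 + 20  # exon1 + intron1 + exon2
            nested_span = (intron2_start + 20, intron2_start + 60)
    na, nb = nested_span
    nattrs = (
        'gene_id "gF"; transcript_id "gF.t1"; '
        'gene_biotype "protein_coding"; transcript_biotype "protein_coding";'
    )
    gtf_lines.append(f"chrT\ttoy\tgene\t{na + 1}\t{nb}\t.\t+\t.\tgene_id \"gF\"; gene_biotype \"protein_coding\";\n")
    gtf_lines.append(f"chrT\ttoy\ttranscript\t{na + 1}\t{nb}\t.\t+\t.\t{nattrs}\n")
    gtf_lines.append(f"chrT\ttoy\texon\t{na + 1}\t{nb}\t.\t+\t.\t{nattrs}\n")

    fasta = tmp_path / "toy.fa"
    gtf = tmp_path / "toy.gtf"
    write_fasta({"chrT": "".join(chrom_parts) + spacer}, fasta)
    gtf.write_text("".join(gtf_lines))
    return ToyDataset(
        fasta=str(fasta),
        gtf=str(gtf),
        expected_survivors={"gA": 3, "gD": 2, "gI": 3, "gJ": 2},
    )


@pytest.fixture
def toy_dataset(tmp_path):
    return build_toy_dataset(tmp_path)


@pytest.fixture(scope="session")
def small_synth(tmp_path_factory):
    """A 60-gene synthetic genome, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("synth60")
    spec = SyntheticGenomeSpec(n_genes=60)
    syn = generate(spec, seed=11)
    paths = syn.write(outdir)
    return syn, paths


@pytest.fixture(scope="session")
def small_survey(small_synth):
    from genearch.pipeline import extract_survey

    syn, paths = small_synth
    return extract_survey(paths["fasta"], paths["gtf"], seed=11)
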