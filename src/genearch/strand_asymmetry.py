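"""DNA strand asymmetry (DSA) of sequence motifs, and motif co-occurrence.

Chargaff's second parity rule predicts that a motif and its reverse
complement occur equally often on one DNA strand. Departures are measured
as S = (Ns - Na) / (Ns + Na), where Ns counts the motif and Na its reverse
complement on the sense (transcribed) strand; negative S reads as
counter-selection of the motif on the sense strand.

Counting is overlap-inclusive, and regions are trimmed before counting to
drop boundary nucleotides that are systematic sources of bias: 3 nt at
both exon ends, 6 nt at the intron 5' end (donor consensus), and 40 nt at
the intron 3' end (branch point / polypyrimidine tract).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import reverse_complement

DEFAULT_MOTIFS = (
    "AATAAA",  # canonical polyadenylation signal
    "ATTAAA",  # weaker PAS variants
    "AATATA",
    "TATAAA",
    "GGTAAG",  # 5'ss-like (cryptic donor) hexamer
    "TAAAAA",  # AATAAA anagram controls
    "AAAAAT",
)


def load_motif_list(path) -> tuple[str, ...]:
    """Read motifs from plain text, one per line; blank lines and lines
    starting with '#' are skipped."""
    motifs = []
    for line in open(path):
        word = line.strip().upper()
        if not word or word.startswith("#"):
            continue
        if any(b not in "ACGT" for b in word):
            raise ValueError(f"motif {word!r} is not over ACGT")
        motifs.append(word)
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return tuple(motifs)


@dataclass(frozen=True)
class TrimRule:
    """(5'-trim, 3'-trim) in nt per region kind; regions shorter than the
    trim sum yield an empty interior."""

    exon: tuple[int, int] = (3, 3)
    intron: tuple[int, int] = (6, 40)

    def for_kind(self, kind: str) -> tuple[int, int]:
        if kind == "exon":
            return self.exon
        if kind == "intron":
            return self.intron
        raise ValueError(f"unknown region kind {kind!r}")


DEFAULT_TRIM = TrimRule()


def trim_region(kind: str, sequence: str, rule: TrimRule = DEFAULT_TRIM) -> str:
    """Interior of a region after dropping the rule's 5' and 3' flanks."""
    lo, hi = rule.for_kind(kind)
    if len(sequence) <= lo + hi:
        return ""
    return sequence[lo : len(sequence) - hi]


def find_occurrences(sequence: str, motif: str) -> list[int]:
    """Overlap-inclusive start offsets of exact motif matches (N never matches)."""
    if not motif:
        raise ValueError("empty motif")
    m = len(motif)
    return [i for i in range(len(sequence) - m + 1) if sequence[i : i + m] == motif]


def count_motif(sequence: str, motif: str) -> tuple[int, int]:
    """(Ns, Na): overlap-inclusive counts of the motif and of its reverse
    complement on the given (sense) strand."""
    ns = len(find_occurrences(sequence, motif))
    na = len(find_occurrences(sequence, reverse_complement(motif)))
    return ns, na


def dsa(ns_total: int, na_total: int) -> float:
    """S = (Ns - Na)/(Ns + Na); NaN (undefined) when both counts are zero."""
    if ns_total < 0 or na_total < 0:
        raise ValueError("counts must be non-negative")
    total = ns_total + na_total
    if total == 0:
        return float("nan")
    return (ns_total - na_total) / total


def dsa_profile(
    regions: pd.DataFrame,
    motifs: Sequence[str] = DEFAULT_MOTIFS,
    group_cols: Sequence[str] = ("region_class",),
    sequence_col: str = "interior",
) -> pd.DataFrame:
    """Pooled-count DSA per (motif x group).

    ``regions`` must hold one row per trimmed region with the interior
    sequence in ``sequence_col`` and the grouping columns. S is computed
    from pooled counts (sum Ns, sum Na across the group's regions, then
    the asymmetry ratio); ``mean_region_S`` is the secondary per-region
    mean, excluding regions where both counts are zero.
    """
    rows = []
    for motif in motifs:
        counts = regions[sequence_col].map(lambda s: count_motif(s, motif))
        ns = counts.map(lambda t: t[0])
        na = counts.map(lambda t: t[1])
        df = regions[list(group_cols)].copy()
        df["Ns"] = ns
        df["Na"] = na
        for key, grp in df.groupby(list(group_cols), sort=True, dropna=False):
            if not isinstance(key, tuple):
                key = (key,)
            total_ns, total_na = int(grp["Ns"].sum()), int(grp["Na"].sum())
            per_region = (grp["Ns"] - grp["Na"]) / (grp["Ns"] + grp["Na"])
            rows.append(
                dict(
                    zip(group_cols, key),
                    motif=motif,
                    n_regions=len(grp),
                    Ns=total_ns,
                    Na=total_na,
                    S=dsa(total_ns, total_na),
                    mean_region_S=float(per_region.mean()),
                )
            )
    cols = ["motif", *group_cols, "n_regions", "Ns", "Na", "S", "mean_region_S"]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# Co-occurrence analyses


@dataclass
class CooccurrenceTable:
    """Contingency counts with the associated Pearson chi-square test."""

    table: pd.DataFrame
    chi2: float
    dof: int
    p: float
    defined: bool = True
    note: str = ""


def _safe_chi2_contingency(table: np.ndarray) -> tuple[float, int, float, bool, str]:
    table = np.asarray(table, dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 0, float("nan"), False, "degenerate table (zero margin)"
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p), True, ""


def cooccurrence_by_size(
    introns: pd.DataFrame,
    motif_a: str = "GGTAAG",
    motif_b: str = "AATAAA",
    size_cut: int = 500,
    sequence_col: str = "interior",
    length_col: str = "length",
) -> CooccurrenceTable:
    """Co-occurrence of two motifs vs intron size class.

    One row per intron; an intron co-occurs when its trimmed interior
    contains at least one copy of each motif. 2x2 table of size class
    (<= cut / > cut) against co-occurrence, Pearson chi-square without
    continuity correction.
    """
    has_a = introns[sequence_col].map(lambda s: motif_a in s)
    has_b = introns[sequence_col].map(lambda s: motif_b in s)
    both = has_a & has_b
    large = introns[length_col] > size_cut
    table = pd.DataFrame(
        {
            "co_occur": [int((both & ~large).sum()), int((both & large).sum())],
            "not_co_occur": [int((~both & ~large).sum()), int((~both & large).sum())],
        },
        index=[f"size<={size_cut}", f"size>{size_cut}"],
    )
    chi2, dof, p, defined, note = _safe_chi2_contingency(table.to_numpy())
    return CooccurrenceTable(table=table, chi2=chi2, dof=dof, p=p, defined=defined, note=note)


def positional_cooccurrence(
    introns: pd.DataFrame,
    motif_a: str = "GGTAAG",
    motif_b: str = "AATAAA",
    length_band: tuple[int, int] = (900, 1100),
    boundary: int = 500,
    sequence_col: str = "interior",
    length_col: str = "length",
    trim: TrimRule = DEFAULT_TRIM,
) -> CooccurrenceTable:
    """Where does the PAS motif sit in co-occurring introns of a length band?

    Among introns whose full length falls in ``length_band`` and whose
    trimmed interior contains both motifs, each occurrence of ``motif_b``
    is classified by its offset from the intron 5' end as within vs
    downstream of the first ``boundary`` nt. The observed split is tested
    (goodness of fit) against the expectation proportional to the number
    of searchable window positions on either side of the boundary.
    """
    lo5, _ = trim.for_kind("intron")
    m = len(motif_b)
    band = introns[
        (introns[length_col] >= length_band[0]) & (introns[length_col] <= length_band[1])
    ]
    obs_within = obs_down = 0
    exp_within = exp_down = 0.0
    n_introns = 0
    for _, row in band.iterrows():
        seq = row[sequence_col]
        if motif_a not in seq:
            continue
        offsets = [p + lo5 for p in find_occurrences(seq, motif_b)]
        if not offsets:
            continue
        n_introns += 1
        n_occ = len(offsets)
        obs_within += sum(1 for p in offsets if p < boundary)
        obs_down += sum(1 for p in offsets if p >= boundary)
        total_windows = len(seq) - m + 1
        within_windows = min(max(boundary - lo5, 0), total_windows)
        exp_within += n_occ * within_windows / total_windows
        exp_down += n_occ * (total_windows - within_windows) / total_windows
    table = pd.DataFrame(
        {
            "observed": [obs_within, obs_down],
            "expected": [exp_within, exp_down],
        },
        index=[f"within_first_{boundary}nt", f"downstream_of_{boundary}nt"],
    )
    if obs_within + obs_down == 0 or exp_within <= 0 or exp_down <= 0:
        return CooccurrenceTable(
            table=table, chi2=float("nan"), dof=0, p=float("nan"), defined=False,
            note=f"no co-occurring introns in band {length_band}" if n_introns == 0 else "degenerate expectation",
        )
    chi2, p = stats.chisquare([obs_within, obs_down], f_exp=[exp_within, exp_down])
    return CooccurrenceTable(table=table, chi2=float(chi2), dof=1, p=float(p))


def motif_ordering(
    introns: pd.DataFrame,
    motif_a: str = "GGTAAG",
    motif_b: str = "AATAAA",
    sequence_col: str = "interior",
) -> CooccurrenceTable:
    """Orientation of the closest (motif_a, motif_b) pair per intron.

    For each intron containing both motifs, the pair with the smallest
    |offset difference| is taken (ties resolved toward the 5'-most starts)
    and classified by whether ``motif_b`` lies downstream of ``motif_a``.
    Goodness-of-fit chi-square of the downstream/upstream split vs 50:50.
    """
    downstream = upstream = 0
    for seq in introns[sequence_col]:
        pos_a = find_occurrences(seq, motif_a)
        pos_b = find_occurrences(seq, motif_b)
        if not pos_a or not pos_b:
            continue
        best = min(
            ((a, b) for a in pos_a for b in pos_b),
            key=lambda ab: (abs(ab[1] - ab[0]), ab[0], ab[1]),
        )
        if best[1] > best[0]:
            downstream += 1
        else:
            upstream += 1
    table = pd.DataFrame(
        {"count": [downstream, upstream]},
        index=[f"{motif_b}_downstream", f"{motif_b}_upstream"],
    )
    n = downstream + upstream
    if n == 0:
        return CooccurrenceTable(
            table=table, chi2=float("nan"), dof=0, p=float("nan"), defined=False,
            note="no introns contain both motifs",
        )
    chi2, p = stats.chisquare([downstream, upstream])
    return CooccurrenceTable(table=table, chi2=float(chi2), dof=1, p=float(p))
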