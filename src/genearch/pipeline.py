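"""End-to-end pipeline: extraction -> scoring -> asymmetry -> statistics.

``run_pipeline`` executes the full survey on a FASTA/GTF pair and writes a
report bundle of tab-separated tables plus a JSON manifest holding every
parameter and seed, so a run can be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .gene_model import (
    IntronRecord,
    IpEUnit,
    apply_filters,
    build_ipe_units,
    export_bed6,
    exons_to_frame,
    extract_structure,
    introns_to_frame,
    ipe_to_frame,
    parse_annotation,
    select_isoforms,
)
from .genome import parse_genome
from .genestats import (
    ipe_randomization_test,
    kendall_tau_b,
    kruskal_wallis,
    partial_kendall_tau,
    sliding_window_median,
)
from .maxent_splice import (
    assign_quartiles,
    collect_background_windows,
    collect_training_windows,
    save_model,
    train_acceptor_model,
    train_donor_model,
)
from .strand_asymmetry import (
    DEFAULT_MOTIFS,
    cooccurrence_by_size,
    dsa_profile,
    motif_ordering,
    positional_cooccurrence,
    trim_region,
)

logger = logging.getLogger("genearch")

INTRON_CLASSES = ("first", "internal", "last")
EXON_CLASSES = ("first", "second", "internal", "last")
IPE_CLASSES = ("first_cap_proximal", "first_cap_distal", "internal", "last")


@dataclass
class RunConfig:
    fasta: str = ""
    gtf: str = ""
    outdir: str = "genearch_out"
    seed: int = 0
    min_intron_len: int = 32
    cap_boundary: int = 250
    nested_mode: str = "containment"
    size_cut: int = 500
    length_band: tuple[int, int] = (900, 1100)
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    pseudocount: float = 1.0
    maxent_tol: float = 1e-4
    maxent_max_iter: int = 10_000
    max_background_windows: int = 50_000
    window: int = 2000
    n_sim: int = 100_000
    alpha: float = 0.05
    save_models: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in data.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if isinstance(cfg.length_band, list):
            cfg.length_band = tuple(cfg.length_band)
        if isinstance(cfg.motifs, list):
            cfg.motifs = tuple(cfg.motifs)
        return cfg

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Fan one global seed out to named, independent substreams."""
    names = ("isoform", "background", "randomization")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SurveyData:
    """Surveyed records of one genome: the substrate for every analysis."""

    introns: list  # IntronRecord, filters applied, scores attached
    exons_by_tx: dict  # transcript_id -> list[ExonRecord]
    units: list  # IpEUnit
    donor_model: object = None
    acceptor_model: object = None

    @property
    def intron_frame(self) -> pd.DataFrame:
        return introns_to_frame(self.introns)

    @property
    def unit_frame(self) -> pd.DataFrame:
        return ipe_to_frame(self.units)


def extract_survey(
    fasta: str | Path,
    gtf: str | Path,
    seed: int = 0,
    min_intron_len: int = 32,
    cap_boundary: int = 250,
    nested_mode: str = "containment",
    pseudocount: float = 1.0,
    maxent_tol: float = 1e-4,
    maxent_max_iter: int = 10_000,
    max_background_windows: int = 50_000,
    train_models: bool = True,
) -> SurveyData:
    """Run extraction, filtering, model training and scoring."""
    rngs = _substreams(seed)
    genome = parse_genome(fasta)
    by_gene, spans = parse_annotation(gtf)
    chosen = select_isoforms(by_gene, rngs["isoform"])

    all_introns: list[IntronRecord] = []
    exons_by_tx: dict[str, list] = {}
    tx_by_id = {}
    for gene_id in sorted(chosen):
        tx = chosen[gene_id]
        exons, introns = extract_structure(tx, genome)
        exons_by_tx[tx.transcript_id] = exons
        tx_by_id[tx.transcript_id] = tx
        all_introns.extend(introns)

    surveyed = apply_filters(
        all_introns, spans, nested_mode=nested_mode, min_len=min_intron_len
    )
    logger.info(
        "surveyed %d introns in %d genes (from %d extracted introns, %d genes)",
        len(surveyed), len({i.gene_id for i in surveyed}), len(all_introns), len(chosen),
    )

    donor_model = acceptor_model = None
    if train_models and surveyed:
        surveyed_tx = [tx_by_id[t] for t in sorted({i.transcript_id for i in surveyed})]
        donor_model = train_donor_model(
            collect_training_windows(surveyed, "donor"),
            collect_background_windows(
                surveyed_tx, genome, "donor", rngs["background"], max_background_windows
            ),
            pseudocount, maxent_tol, maxent_max_iter,
        )
        acceptor_model = train_acceptor_model(
            collect_training_windows(surveyed, "acceptor"),
            collect_background_windows(
                surveyed_tx, genome, "acceptor", rngs["background"], max_background_windows
            ),
            pseudocount, maxent_tol, maxent_max_iter,
        )
        for intron in surveyed:
            if intron.donor_window_ok:
                intron.donor_score = donor_model.score(intron.donor_window)
            if intron.acceptor_window_ok:
                intron.acceptor_score = acceptor_model.score(intron.acceptor_window)

    units: list[IpEUnit] = []
    by_tx: dict[str, list[IntronRecord]] = {}
    for i in surveyed:
        by_tx.setdefault(i.transcript_id, []).append(i)
    for tx_id, introns in sorted(by_tx.items()):
        units.extend(build_ipe_units(exons_by_tx[tx_id], introns, cap_boundary))

    return SurveyData(
        introns=surveyed,
        exons_by_tx=exons_by_tx,
        units=units,
        donor_model=donor_model,
        acceptor_model=acceptor_model,
    )


def table1_summary(survey: SurveyData) -> pd.DataFrame:
    """Per-positional-class survey summary: counts, intron and next-exon
    sizes, and donor/acceptor strengths (mean and median)."""
    rows = []
    units_by_intron = {(u.intron.gene_id, u.intron.ordinal): u for u in survey.units}
    for cls in INTRON_CLASSES:
        sub = [i for i in survey.introns if i.pos_class == cls]
        n = len(sub)
        row = {"pos_class": cls, "n": n}
        if n == 0:
            rows.append(row)
            continue

        def _ms(vals):
            arr = np.asarray([v for v in vals if v is not None and np.isfinite(v)], dtype=float)
            if arr.size == 0:
                return float("nan"), float("nan")
            return float(arr.mean()), float(np.median(arr))

        row["intron_size_mean"], row["intron_size_median"] = _ms([i.length for i in sub])
        nxt = [units_by_intron[(i.gene_id, i.ordinal)].next_exon.length for i in sub
               if (i.gene_id, i.ordinal) in units_by_intron]
        row["exon_size_mean"], row["exon_size_median"] = _ms(nxt)
        row["donor_mean"], row["donor_median"] = _ms([i.donor_score for i in sub])
        row["acceptor_mean"], row["acceptor_median"] = _ms([i.acceptor_score for i in sub])
        rows.append(row)
    return pd.DataFrame(rows)


def ipe_by_quartile(survey: SurveyData) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median IpE unit size per positional class x donor-strength quartile,
    with a Kruskal-Wallis test of size across quartiles per class."""
    scores = [u.upstream_5ss_score for u in survey.units]
    quartiles, labels = assign_quartiles(scores)
    rows, tests = [], []
    for cls in IPE_CLASSES:
        groups = {}
        for u, lab in zip(survey.units, labels):
            if u.pos_class != cls or lab == "undefined":
                continue
            groups.setdefault(lab, []).append(u.size)
        for lab, sizes in groups.items():
            rows.append(
                dict(pos_class=cls, quartile=lab, n=len(sizes),
                     median_size=float(np.median(sizes)), mean_size=float(np.mean(sizes)))
            )
        if len(groups) >= 2:
            h, p = kruskal_wallis(list(groups.values()))
            tests.append(dict(pos_class=cls, H=h, p=p, k=len(groups)))
    qcols = pd.DataFrame(
        dict(cut=["q25", "q50", "q75"], value=list(quartiles.cuts))
    )
    table = pd.DataFrame(rows)
    tests_df = pd.DataFrame(tests)
    return table, pd.concat(
        [tests_df, qcols], axis=0, ignore_index=True
    ) if not tests_df.empty else qcols


def intron_region_frame(survey: SurveyData) -> pd.DataFrame:
    """One row per surveyed intron with the trimmed interior and metadata."""
    scores = [i.donor_score for i in survey.introns]
    finite = [s for s in scores if s is not None and np.isfinite(s)]
    q = None
    if len(finite) >= 4:
        q, _ = assign_quartiles(scores)
    rows = []
    for i in survey.introns:
        rows.append(
            dict(
                gene_id=i.gene_id,
                region_class=i.pos_class,
                length=i.length,
                interior=trim_region("intron", i.sequence),
                donor_score=i.donor_score if i.donor_score is not None else float("nan"),
                quartile=(
                    q.label(i.donor_score)
                    if q is not None and i.donor_score is not None and np.isfinite(i.donor_score)
                    else "undefined"
                ),
            )
        )
    return pd.DataFrame(rows)


def exon_region_frame(survey: SurveyData) -> pd.DataFrame:
    """One row per exon of surveyed transcripts with the trimmed interior."""
    surveyed_tx = {i.transcript_id for i in survey.introns}
    rows = []
    for tx_id in sorted(surveyed_tx):
        for e in survey.exons_by_tx[tx_id]:
            rows.append(
                dict(
                    gene_id=e.gene_id,
                    region_class=e.pos_class,
                    length=e.length,
                    interior=trim_region("exon", e.sequence),
                )
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full survey and write the report bundle.

    Returns a dict of in-memory results; all tables are also written to
    ``config.outdir`` as TSV, with a JSON manifest and a log file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {"manifest": config.manifest()}
    stage = "extract"
    try:
        survey = extract_survey(
            config.fasta, config.gtf, seed=config.seed,
            min_intron_len=config.min_intron_len, cap_boundary=config.cap_boundary,
            nested_mode=config.nested_mode, pseudocount=config.pseudocount,
            maxent_tol=config.maxent_tol, maxent_max_iter=config.maxent_max_iter,
            max_background_windows=config.max_background_windows,
        )
        results["survey"] = survey
        survey.intron_frame.to_csv(outdir / "introns.tsv", sep="\t", index=False)
        survey.unit_frame.to_csv(outdir / "ipe_units.tsv", sep="\t", index=False)
        exons_to_frame(
            [e for exs in survey.exons_by_tx.values() for e in exs]
        ).to_csv(outdir / "exons.tsv", sep="\t", index=False)
        export_bed6(survey.introns, outdir / "surveyed_introns.bed")
        if config.save_models and survey.donor_model is not None:
            save_model(survey.donor_model, outdir / "donor_model.txt")
            save_model(survey.acceptor_model, outdir / "acceptor_model.txt")

        stage = "summary"
        results["table1"] = table1_summary(survey)
        results["table1"].to_csv(outdir / "table1_summary.tsv", sep="\t", index=False)

        stage = "ipe_by_quartile"
        ipe_table, ipe_tests = ipe_by_quartile(survey)
        results["ipe_by_quartile"] = ipe_table
        results["ipe_quartile_tests"] = ipe_tests
        ipe_table.to_csv(outdir / "ipe_by_quartile.tsv", sep="\t", index=False)
        ipe_tests.to_csv(outdir / "ipe_quartile_tests.tsv", sep="\t", index=False)

        stage = "sliding_window"
        units = survey.unit_frame.dropna(subset=["upstream_5ss_score"])
        if len(units) >= config.window:
            sw = sliding_window_median(
                units, "first_exon_len",
                ["size", "intron_length", "next_exon_length", "upstream_5ss_score"],
                window=config.window,
            )
            results["sliding_window"] = sw
            sw.frame.to_csv(outdir / "sliding_window.csv", index=False)
        else:
            logger.warning(
                "sliding-window stage skipped: %d records < window %d",
                len(units), config.window,
            )
            results["sliding_window"] = None

        stage = "correlations"
        idf = survey.intron_frame.dropna(subset=["donor_score", "acceptor_score"])
        corr_rows = []
        if len(idf) >= 3:
            for col, name in (("donor_score", "5ss"), ("acceptor_score", "3ss")):
                tau, p = kendall_tau_b(idf["length"], idf[col])
                corr_rows.append(
                    dict(x="intron_length", y=name, tau=tau, p=p, n=len(idf))
                )
        results["correlations"] = pd.DataFrame(corr_rows)
        results["correlations"].to_csv(outdir / "correlations.tsv", sep="\t", index=False)

        stage = "dsa"
        iframe = intron_region_frame(survey)
        eframe = exon_region_frame(survey)
        regions = pd.concat(
            [iframe.assign(kind="intron"), eframe.assign(kind="exon")],
            ignore_index=True,
        )
        results["dsa_by_class"] = dsa_profile(
            regions, config.motifs, group_cols=("kind", "region_class")
        )
        results["dsa_by_class"].to_csv(outdir / "dsa_by_class.tsv", sep="\t", index=False)
        results["dsa_by_quartile"] = dsa_profile(
            iframe[iframe["quartile"] != "undefined"],
            ("AATAAA", "GGTAAG"),
            group_cols=("region_class", "quartile"),
        )
        results["dsa_by_quartile"].to_csv(
            outdir / "dsa_by_quartile.tsv", sep="\t", index=False
        )

        stage = "cooccurrence"
        results["cooccurrence_by_size"] = cooccurrence_by_size(
            iframe, size_cut=config.size_cut
        )
        results["positional_cooccurrence"] = positional_cooccurrence(
            iframe, length_band=config.length_band, boundary=config.size_cut
        )
        results["motif_ordering"] = motif_ordering(iframe)
        with open(outdir / "cooccurrence.tsv", "w") as fh:
            for key in ("cooccurrence_by_size", "positional_cooccurrence", "motif_ordering"):
                r = results[key]
                fh.write(f"# {key}: chi2={r.chi2} df={r.dof} p={r.p} defined={r.defined}\n")
                fh.write(r.table.to_csv(sep="\t"))

        stage = "randomization"
        rngs = _substreams(config.seed)
        rand_rows = []
        results["randomization"] = {}
        uf = survey.unit_frame
        for cls in ("first", "internal", "last"):
            mask = (
                uf["pos_class"].isin(["first_cap_proximal", "first_cap_distal"])
                if cls == "first"
                else uf["pos_class"] == cls
            )
            grp = uf[mask]
            if len(grp) < 5:
                continue
            res = ipe_randomization_test(
                grp["size"].to_numpy(),
                grp["intron_length"].to_numpy(),
                grp["next_exon_length"].to_numpy(),
                n_sim=config.n_sim,
                alpha=config.alpha,
                seed=rngs["randomization"],
            )
            res.seed = config.seed
            results["randomization"][cls] = res
            rand_rows.append(
                dict(pos_class=cls, n_units=res.n_units, n_sim=res.n_sim,
                     alpha=res.alpha, overall_p=res.overall_p, seed=config.seed)
            )
        pd.DataFrame(rand_rows).to_csv(outdir / "randomization.tsv", sep="\t", index=False)

        (outdir / "manifest.json").write_text(
            json.dumps(results["manifest"], indent=2, sort_keys=True) + "\n"
        )
    except Exception:
        (outdir / "PARTIAL_RESULTS").write_text(f"failed at stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results
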