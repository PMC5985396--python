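"""End-to-end orchestration: catalog -> DE -> RIP calling -> control set ->
neighbors -> peaks -> feature encoding -> two discrimination runs -> TAD and
enhancer statistics, with one structured JSON-able report."""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .count_model import (
    CountMatrix,
    build_nona,
    call_ara,
    call_differential,
    nb_test,
    replicate_correlation,
)
from .enhancer_profile import (
    acetylation_ratio,
    neighbor_response_compare,
    peak_tss_distance,
    stringency_correlation,
)
from .genome_intervals import NeighborPair, closest_tss
from .peak_caller import call_peaks
from .signature_ml import (
    encode_features,
    importance_null,
    significant_features,
    train_classifier,
)
from .synthetic_data import StudyConfig, SyntheticStudy, generate_study, write_study
from .tad_profile import (
    assign_to_tads,
    boundary_distance,
    tad_expression_compare,
    tad_group_flags,
    tad_peak_counts,
)

__all__ = ["ResponseSubsets", "subset_by_response", "run_study", "AnalysisReport"]


@dataclass
class ResponseSubsets:
    """ARA lincRNAs partitioned by their own androgen response and the DE
    direction of their protein-coding neighbor, plus matched NonA subsets."""

    ara_up: list[str]
    ara_up_nbr_up: list[str]
    ara_up_nbr_down: list[str]
    nona_up: list[str]
    nona_up_nbr_up: list[str]
    nona_up_nbr_down: list[str]

    def __post_init__(self) -> None:
        up_set = set(self.ara_up)
        if not (set(self.ara_up_nbr_up) | set(self.ara_up_nbr_down)) <= up_set:
            raise ValueError("neighbor subsets must be contained in ara_up")


def subset_by_response(
    ara: Sequence[str],
    nona: Sequence[str],
    linc_up: set[str],
    pc_up: set[str],
    pc_down: set[str],
    pairs: Sequence[NeighborPair],
) -> ResponseSubsets:
    """Partition the ARA set by androgen activation and neighbor DE direction,
    and mirror it in the NonA ranking order.

    ``nona`` must be in build_nona ranking order: matched subsets take the
    best-ranked NonA lincRNAs satisfying the same condition, truncated to the
    ARA subset size when the pool permits.
    """
    nbr = {p.lincrna_id: p.pc_id for p in pairs}

    def split(linc_ids: Sequence[str]) -> tuple[list[str], list[str], list[str]]:
        up = [g for g in linc_ids if g in linc_up]
        nbr_up = [g for g in up if nbr.get(g) in pc_up]
        nbr_down = [g for g in up if nbr.get(g) in pc_down]
        return up, nbr_up, nbr_down

    ara_up, ara_nbr_up, ara_nbr_down = split(sorted(ara))
    nona_up, nona_nbr_up, nona_nbr_down = split(list(nona))
    return ResponseSubsets(
        ara_up=ara_up,
        ara_up_nbr_up=ara_nbr_up,
        ara_up_nbr_down=ara_nbr_down,
        nona_up=nona_up[: len(ara_up)] if len(nona_up) > len(ara_up) else nona_up,
        nona_up_nbr_up=nona_nbr_up[: len(ara_nbr_up)]
        if len(nona_nbr_up) > len(ara_nbr_up)
        else nona_nbr_up,
        nona_up_nbr_down=nona_nbr_down[: len(ara_nbr_down)]
        if len(nona_nbr_down) > len(ara_nbr_down)
        else nona_nbr_down,
    )


@dataclass
class AnalysisReport:
    sections: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.sections, indent=2, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, set):
        return sorted(x)
    raise TypeError(f"cannot serialize {type(x)}")


def _classifier_run(
    fm,
    run_ids: Sequence[str],
    tree_grid: Sequence[int],
    folds: int,
    n_shuffles: int,
    seed: int,
) -> dict:
    sub = fm.subset(run_ids)
    n_per_class = min(sum(1 for l in sub.labels if l == c) for c in ("ARA", "NonA")) if sub.row_ids else 0
    if n_per_class < folds:
        return {
            "n_rows": len(sub.row_ids),
            "skipped": f"fewer than {folds} rows in a class",
        }
    report = train_classifier(sub, tree_grid=tree_grid, folds=folds, seed=seed)
    out = {
        "n_rows": len(sub.row_ids),
        "tree_grid": report.tree_grid,
        "chosen_trees": report.chosen_trees,
        "cv_accuracy": report.cv_accuracy,
        "cv_accuracy_by_size": report.cv_accuracy_by_size,
        "oob_score": report.oob_score,
        "importances": dict(zip(report.feature_names, report.importances.tolist())),
    }
    if n_shuffles > 0:
        null = importance_null(sub, n_shuffles=n_shuffles, trees=report.chosen_trees,
                               seed=seed)
        imp = significant_features(report, null, sub)
        out["significant_features"] = imp.significant()
        out["importance_table"] = imp.table.reset_index().to_dict(orient="records")
    else:
        out["significant_features"] = None
    return out


def run_study(
    config: StudyConfig | None = None,
    study: SyntheticStudy | None = None,
    out_dir: str | Path | None = None,
    tree_grid: Sequence[int] = (100, 500, 1000),
    folds: int = 5,
    n_shuffles: int = 200,
    peak_fdr: float = 0.001,
    ara_fdr: float = 0.10,
    de_q: float = 0.05,
    de_fc: float = 2.0,
) -> AnalysisReport:
    """Run every stage on a synthetic study (generated from ``config`` unless
    ``study`` is given) and return the combined report.

    The default tree grid and shuffle count are scaled down from the
    reference procedure's (100/500/1000/10000 trees, 1000 shuffles) to keep a
    laptop-scale run in minutes; both are configurable.
    """
    if study is None:
        if config is None:
            raise ValueError("need a config or a study")
        study = generate_study(config)
    cfg = study.config
    t0 = time.time()
    timings: dict[str, float] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_study(study, out / "study")

    def tick(stage: str) -> None:
        timings[stage] = round(time.time() - t0, 2)

    lincs, pcs = study.lincs, study.pcs
    by_gene = {t.gene_id: t for t in study.annotation}
    report = AnalysisReport()
    report.sections["provenance"] = {
        "seed": cfg.seed,
        "config": json.loads(json.dumps(cfg.__dict__, default=_jsonify)),
        "version": __version__,
        "n_shuffles": n_shuffles,
        "tree_grid": list(tree_grid),
    }

    # catalog
    expressed_lincs = [t for t in lincs if t.max_fpkm() >= 1.0]
    expressed_pcs = [t for t in pcs if t.max_fpkm() > 1.0]
    report.sections["catalog"] = {
        "n_lincrna": len(lincs),
        "n_protein_coding": len(pcs),
        "n_expressed_lincrna": len(expressed_lincs),
        "n_expressed_pc": len(expressed_pcs),
    }
    tick("catalog")

    # differential expression (androgen vs vehicle)
    de = nb_test(study.rnaseq_counts, numerator="androgen")
    up, down = call_differential(de, q=de_q, fc=de_fc)
    linc_ids = {t.gene_id for t in lincs}
    pc_ids = {t.gene_id for t in pcs}
    report.sections["differential_expression"] = {
        "n_up": len(up),
        "n_down": len(down),
        "n_linc_up": len(up & linc_ids),
        "n_linc_down": len(down & linc_ids),
        "n_pc_up": len(up & pc_ids),
        "n_pc_down": len(down & pc_ids),
    }
    tick("de")

    # RIP enrichment -> ARA and NonA sets
    rip = nb_test(study.rip_counts, numerator="antiAR")
    ara = call_ara(rip, fdr=ara_fdr)
    nona = build_nona(rip, study.rip_counts, n=len(ara), exclude=ara)
    rep_corr = {
        lvl: replicate_correlation(study.rip_counts, lvl)
        for lvl in study.rip_counts.levels()
    }
    report.sections["rip"] = {
        "n_ara": len(ara),
        "n_nona": len(nona),
        "ara": sorted(ara),
        "nona": list(nona),
        "replicate_correlation": rep_corr,
    }
    tick("rip")

    # neighbors
    pairs = closest_tss(lincs, pcs, fpkm_min=1.0)
    pair_table = pd.DataFrame(
        [
            {
                "lincrna_id": p.lincrna_id,
                "pc_id": p.pc_id,
                "tss_distance": p.tss_distance,
                "orientation": p.orientation,
            }
            for p in pairs
        ]
    )
    report.sections["neighbors"] = {"n_pairs": len(pairs)}
    tick("neighbors")

    # peaks
    peaks_by_mark = {tr.mark: call_peaks(tr, fdr=peak_fdr) for tr in study.tracks}
    peak_ivs = {m: [pk.interval for pk in pks] for m, pks in peaks_by_mark.items()}
    report.sections["peaks"] = {m: len(pks) for m, pks in peaks_by_mark.items()}
    tick("peaks")

    # feature encoding over the labeled universe
    labels = {g: "ARA" for g in sorted(ara)}
    labels.update({g: "NonA" for g in nona})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fm = encode_features(pairs, study.tracks, labels, by_gene, flank=cfg.tss_flank)
    report.sections["features"] = {
        "n_rows": len(fm.row_ids),
        "n_features": len(fm.feature_names),
        "n_skipped": fm.n_skipped,
    }
    tick("features")

    # response subsets and the two discrimination runs
    subsets = subset_by_response(sorted(ara), nona, up & linc_ids, up & pc_ids,
                                 down & pc_ids, pairs)
    report.sections["response_subsets"] = {
        "ara_up": len(subsets.ara_up),
        "ara_up_nbr_up": len(subsets.ara_up_nbr_up),
        "ara_up_nbr_down": len(subsets.ara_up_nbr_down),
        "nona_up": len(subsets.nona_up),
        "nona_up_nbr_up": len(subsets.nona_up_nbr_up),
        "nona_up_nbr_down": len(subsets.nona_up_nbr_down),
    }
    report.sections["classifier_all"] = _classifier_run(
        fm, list(labels), tree_grid, folds, n_shuffles, cfg.seed
    )
    report.sections["classifier_activated"] = _classifier_run(
        fm,
        subsets.ara_up_nbr_up + subsets.nona_up_nbr_up,
        tree_grid, folds, n_shuffles, cfg.seed + 1,
    )
    report.sections["classifier_inhibited"] = _classifier_run(
        fm,
        subsets.ara_up_nbr_down + subsets.nona_up_nbr_down,
        tree_grid, folds, n_shuffles, cfg.seed + 2,
    )
    tick("classifier")

    # TAD profiling
    assignment = assign_to_tads(study.annotation, study.tads)
    flags = tad_group_flags(assignment, set(ara), set(nona))
    ara_tads = set(flags.index[flags["contains_ara"]])
    nona_tads = set(flags.index[flags["contains_nona"]])
    counts, tad_pvals = tad_peak_counts(study.tads, peak_ivs, ara_tads, nona_tads)
    tad_by_id = {t.id: t for t in study.tads}
    bdist = {}
    for group, ids in (("ARA", sorted(ara)), ("NonA", list(nona))):
        vals = [
            boundary_distance(by_gene[g].tss, tad_by_id[assignment[g]])
            for g in ids
            if g in assignment
        ]
        bdist[group] = vals
    from scipy import stats as _st

    if len(bdist["ARA"]) >= 2 and len(bdist["NonA"]) >= 2:
        bd_p = float(
            _st.ttest_ind(bdist["ARA"], bdist["NonA"], equal_var=False,
                          alternative="less").pvalue
        )
    else:
        bd_p = None
    pc_assignment = {g: t for g, t in assignment.items() if g in pc_ids}
    fpkm_mean = study.fpkm.mean(axis=1).to_dict()
    try:
        expr_cmp = tad_expression_compare(ara_tads, nona_tads, pc_assignment, fpkm_mean)
    except ValueError as exc:
        expr_cmp = {"notice": str(exc)}
    report.sections["tads"] = {
        "n_tads": len(study.tads),
        "n_ara_tads": len(ara_tads),
        "n_nona_tads": len(nona_tads),
        "peak_count_pvalues": tad_pvals,
        "boundary_distance_means": {
            g: (float(np.mean(v)) if v else None) for g, v in bdist.items()
        },
        "boundary_distance_p": bd_p,
        "expression_compare": expr_cmp,
    }
    tick("tads")

    # enhancer statistics
    track_of = {tr.mark: tr for tr in study.tracks}
    enhancer: dict = {}
    if "H3K27ac" in track_of and "H3K27me3" in track_of:
        groups_models = {
            "ARA": [by_gene[g] for g in sorted(ara)],
            "NonA": [by_gene[g] for g in nona],
        }
        _, ks_stat, ks_p = acetylation_ratio(
            groups_models, track_of["H3K27ac"], track_of["H3K27me3"], flank=cfg.tss_flank
        )
        enhancer["acetylation_ratio"] = {"ks_stat": ks_stat, "ks_p": ks_p}
    de_lfc = de.table["log2fc"].to_dict()
    group_map = {g: "ARA" for g in ara}
    group_map.update({g: "NonA" for g in nona})
    if "H3K4me1" in track_of and "H3K27ac" in track_of:
        ladder = stringency_correlation(
            pairs, group_map, de_lfc, de_lfc, track_of["H3K4me1"], track_of["H3K27ac"],
            by_gene, flank=cfg.tss_flank,
        )
        enhancer["stringency_correlation"] = {
            g: [r.__dict__ for r in rungs] for g, rungs in ladder.items()
        }
    tss_by_group = {
        "ARA": [(by_gene[g].chrom, by_gene[g].tss) for g in sorted(ara)],
        "NonA": [(by_gene[g].chrom, by_gene[g].tss) for g in nona],
    }
    _, dist_p = peak_tss_distance(peak_ivs, tss_by_group)
    enhancer["peak_tss_distance_p"] = dist_p
    if "PolII" in track_of:
        enhancer["neighbor_response"] = neighbor_response_compare(
            pairs, group_map, de_lfc, track_of["PolII"], by_gene,
            up_pc=up & pc_ids, down_pc=down & pc_ids,
            polII_peaks=peak_ivs.get("PolII"), flank=cfg.tss_flank,
        )
    report.sections["enhancer"] = enhancer
    tick("enhancer")

    report.sections["timings_s"] = timings
    if out is not None:
        report.to_json(out / "report.json")
        pair_table.to_csv(out / "neighbors.tsv", sep="\t", index=False)
        fm.to_frame().to_csv(out / "features.tsv", sep="\t")
        counts.to_csv(out / "tad_peak_counts.tsv", sep="\t")
        de.table.to_csv(out / "de_table.tsv", sep="\t")
        rip.table.to_csv(out / "rip_table.tsv", sep="\t")
    return report
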