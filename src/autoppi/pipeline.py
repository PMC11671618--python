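"""End-to-end pipeline orchestration.

``run_pipeline`` drives the full discovery workflow from on-disk inputs:
gold-standard assembly -> feature computation and binning -> training of
the three classifiers under the 7:3 split / 10-fold CV protocol with the
error-ceiling acceptance rule -> per-model candidate scoring at each
model's operating threshold -> strict-consensus intersection and
exclusion of known interactions -> network construction, hub ranking and
dense-module extraction.  Every stage logs the counts it produced, all
randomness derives from ``config.random_seed``, and all outputs are
written atomically.

``run_fixture`` generates the packaged synthetic benchmark (a universe
with planted interactions, 70% of which are treated as "known" training
positives and 30% hidden among the candidates) and runs the pipeline on
it, reporting recovery of the hidden planted pairs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io
from .classifiers import (BinnedNaiveBayes, GiniDecisionTree, StandardizedKNN,
                          fit_and_report, learning_curve, save_model,
                          stratified_split)
from .config import PipelineConfig
from .consensus import (exclude_known, intersect_predictions, predict_positives,
                        recovery_metrics)
from .evaluation import evaluate_scores, plot_curves
from .features import (BINNED_PREFIX, FEATURES, compute_feature_table,
                       fit_binning, score_features)
from .gold import (GoldStandard, build_negative_pairs, enumerate_candidates,
                   merge_positive_sources, select_process_proteins,
                   subsample_balanced)
from .network import build_graph, degree_ranking, find_modules, module_table
from .synthetic import UniverseConfig, fixture_config, generate_universe

log = logging.getLogger("autoppi")

BINNED_COLS = [BINNED_PREFIX + f for f in FEATURES]
RAW_COLS = list(FEATURES)

MODEL_NAMES = ("NB", "DT", "KNN")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _seed_for(base: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the run seed."""
    h = base & 0x7FFFFFFF
    for ch in stage:
        h = (h * 31 + ord(ch)) % (2**31)
    return h


def _feature_cols(name: str) -> list[str]:
    return RAW_COLS if name == "KNN" else BINNED_COLS


def _make_models(config: PipelineConfig, scheme) -> dict[str, object]:
    n_cats = [scheme.n_categories(f) for f in FEATURES]
    return {
        "NB": BinnedNaiveBayes(alpha=config.nb_alpha, n_categories=n_cats),
        "DT": GiniDecisionTree(max_depth=config.dt_max_depth, min_leaf=config.dt_min_leaf),
        "KNN": StandardizedKNN(k=config.knn_k),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the run report (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: getattr(config, k) for k in
                               ("train_fraction", "cv_folds", "n_bins", "error_ceiling",
                                "node_score_cutoff", "k_core", "random_seed")},
                    "counts": {}}
    counts = report["counts"]

    # -- stage: gold standard -------------------------------------------
    try:
        paths = [p for p in config.positive_pairs.split(";") if p]
        sources = [[r.pair for r in io.read_pair_list(p)] for p in paths]
        positives, provenance = merge_positive_sources(sources, names=paths)
        known = set(positives)
        if config.known_pairs:
            known |= {r.pair for r in io.read_pair_list(config.known_pairs)}
        localization = io.read_annotation_table(config.localization, namespace="localization")
        negatives = build_negative_pairs(localization, known)
        gold = GoldStandard(positives=positives, negatives=negatives, provenance=provenance)
        n_bal = min(len(positives), len(negatives))
        gold = subsample_balanced(gold, n_bal, n_bal, _seed_for(config.random_seed, "subsample"))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"gold-standard stage failed: {exc}") from exc
    counts["positives_read"] = len(positives)
    counts["negatives_built"] = len(negatives)
    counts["gold_positives"] = len(gold.positives)
    counts["gold_negatives"] = len(gold.negatives)
    log.info("gold standard: %d positives read, %d negatives built, balanced to %d/%d",
             len(positives), len(negatives), len(gold.positives), len(gold.negatives))
    io.write_pair_list(
        [io.PairRecord(*p, label="positive") for p in sorted(gold.positives)]
        + [io.PairRecord(*p, label="negative") for p in sorted(gold.negatives)],
        out / "gold.tsv", labeled=True)

    # -- stage: features ------------------------------------------------
    try:
        go = io.read_annotation_table(config.go_annotations, namespace="GO")
        kegg = io.read_annotation_table(config.kegg_annotations, namespace="KEGG")
        expression = io.read_expression_matrix(config.expression)
        labels = {p: 1 for p in gold.positives} | {p: 0 for p in gold.negatives}
        table = compute_feature_table(sorted(labels), go, kegg, expression, labels=labels)
        feature_scores = score_features(table)
    except Exception as exc:
        raise StageError(f"feature stage failed: {exc}") from exc
    counts["features_computed"] = len(table)
    log.info("features: %d pair vectors computed", len(table))
    feature_scores.to_csv(out / "feature_scores.tsv", sep="\t", index=False)
    report["feature_scores"] = feature_scores.to_dict(orient="records")

    # -- stage: training ------------------------------------------------
    try:
        train, test = stratified_split(table, config.train_fraction,
                                       _seed_for(config.random_seed, "split"))
        scheme = fit_binning(train, config.n_bins)
        train_b, test_b = scheme.transform(train), scheme.transform(test)
        models = _make_models(config, scheme)
        fit_reports, eval_reports, thresholds = {}, {}, {}
        cv_seed = _seed_for(config.random_seed, "cv")
        for name, model in models.items():
            cols = _feature_cols(name)
            Xtr, ytr = train_b[cols].to_numpy(float), train_b["label"].to_numpy(int)
            Xte, yte = test_b[cols].to_numpy(float), test_b["label"].to_numpy(int)
            fr = fit_and_report(model, name, Xtr, ytr, Xte, yte,
                                k_folds=config.cv_folds, seed=cv_seed,
                                error_ceiling=config.error_ceiling)
            scores = model.predict_proba(Xte)[:, 1]
            ev = evaluate_scores(scores, yte, model_name=name, rule=config.threshold_rule)
            fit_reports[name], eval_reports[name] = fr, ev
            thresholds[name] = ev.optimal_threshold
            save_model(model, out / "models" / f"{name.lower()}.json")
            plot_curves(ev, out / "plots" / f"roc_{name.lower()}.png",
                        out / "plots" / f"pr_{name.lower()}.png")
    except Exception as exc:
        raise StageError(f"training stage failed: {exc}") from exc
    report["models"] = {name: {**fit_reports[name].to_dict(),
                               "auc": eval_reports[name].auc,
                               "optimal_threshold": thresholds[name],
                               "f1_at_optimal": eval_reports[name].f1_at_optimal,
                               "accuracy_at_optimal": eval_reports[name].accuracy_at_optimal}
                        for name in models}
    accepted = [n for n in models if fit_reports[n].accepted]
    if len(accepted) < 2:
        raise StageError(f"training stage: only {len(accepted)} model(s) met the "
                         f"error ceiling {config.error_ceiling}; need >= 2 for consensus")
    for name in models:
        if name not in accepted:
            log.warning("model %s rejected (errors above %.2f); excluded from consensus",
                        name, config.error_ceiling)

    # -- stage: candidates ----------------------------------------------
    try:
        if config.candidate_pairs:
            candidates = sorted({r.pair for r in io.read_pair_list(config.candidate_pairs)}
                                - known)
        else:
            process = select_process_proteins(go, config.process_keyword)
            if len(process) < 2:
                process = set(expression.index)
            candidates = enumerate_candidates(process, known, config.n_candidates,
                                              _seed_for(config.random_seed, "candidates"))
        cand_table = scheme.transform(
            compute_feature_table(candidates, go, kegg, expression))
    except Exception as exc:
        raise StageError(f"candidate stage failed: {exc}") from exc
    counts["candidates"] = len(candidates)
    log.info("candidates: %d pairs featurized", len(candidates))

    # -- stage: consensus -----------------------------------------------
    try:
        per_model, all_scores = {}, {}
        for name in accepted:
            pos, scores = predict_positives(models[name], cand_table,
                                            _feature_cols(name), thresholds[name])
            per_model[name] = pos
            all_scores[name] = scores
        result = intersect_predictions(per_model)
        novel, removed = exclude_known(result.intersection, known)
        result.excluded_known = removed
    except Exception as exc:
        raise StageError(f"consensus stage failed: {exc}") from exc
    counts.update(result.counts())
    counts["novel_consensus"] = len(novel)
    report["venn"] = result.venn
    rows = [{"protein_a": a, "protein_b": b,
             **{f"score_{n.lower()}": round(all_scores[n][(a, b)], 6) for n in accepted}}
            for a, b in sorted(novel)]
    io._atomic_write_text(out / "consensus.tsv", "".join(
        ["\t".join(rows[0].keys()) + "\n"] + ["\t".join(str(v) for v in r.values()) + "\n"
                                              for r in rows]) if rows else "")

    if config.truth_pairs:
        truth = {r.pair for r in io.read_pair_list(config.truth_pairs)}
        report["recovery"] = recovery_metrics(novel, truth, set(candidates))
        log.info("recovery vs planted truth: precision=%.3f recall=%.3f",
                 report["recovery"]["precision"], report["recovery"]["recall"])

    # -- stage: network -------------------------------------------------
    try:
        if novel:
            graph = build_graph(novel)
            hubs = degree_ranking(graph)
            modules = find_modules(graph, config.node_score_cutoff, config.k_core)
            io.write_network(graph, "sif", out / "network.sif")
            io.write_network(graph, "edgelist", out / "network.tsv")
            io.write_network(graph, "graphml", out / "network.graphml")
            io._atomic_write_text(out / "hubs.tsv", "protein\tdegree\n" + "".join(
                f"{p}\t{d}\n" for p, d in hubs))
            report["modules"] = module_table(modules)[: config.top_modules]
            counts["modules"] = len(modules)
            report["top_hubs"] = hubs[:10]
        else:
            log.warning("consensus empty; skipping network stage")
            report["modules"], report["top_hubs"] = [], []
            counts["modules"] = 0
    except Exception as exc:
        raise StageError(f"network stage failed: {exc}") from exc

    io.write_json_report(report, out / "run_report.json")
    return report


# ----------------------------------------------------------------------
# packaged synthetic benchmark
# ----------------------------------------------------------------------

def write_universe_inputs(universe, out_dir: str | Path,
                          known: set | None = None) -> dict[str, str]:
    """Write a universe's tables in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    positives = sorted(known if known is not None else universe.planted)
    io.write_pair_list([io.PairRecord(*p) for p in positives], out / "positives.tsv")
    io.write_pair_list([io.PairRecord(*p) for p in sorted(universe.planted)],
                       out / "truth.tsv")
    io.write_annotation_table(universe.go, out / "go.tsv")
    io.write_annotation_table(universe.kegg, out / "kegg.tsv")
    io.write_annotation_table(universe.localization, out / "localization.tsv")
    io.write_expression_matrix(universe.expression, out / "expression.tsv")
    return {name: str(out / f"{name}.tsv")
            for name in ("positives", "truth", "go", "kegg", "localization", "expression")}


def fixture_pipeline_config(seed: int, work_dir: str | Path,
                            universe: UniverseConfig | None = None,
                            hidden_fraction: float = 0.3,
                            n_decoys_per_hidden: int = 2) -> PipelineConfig:
    """Generate the benchmark universe and assemble a ready-to-run config.

    A ``hidden_fraction`` of the planted interactions is withheld from
    the known-positive list and mixed into the candidate pool with
    ``n_decoys_per_hidden`` random non-interacting pairs per hidden
    pair, so consensus recovery can be scored against ground truth.
    """
    work = Path(work_dir)
    ucfg = universe or fixture_config(seed=_seed_for(seed, "universe"))
    uni = generate_universe(ucfg)
    planted = sorted(uni.planted)
    rng = np.random.default_rng(_seed_for(seed, "holdout"))
    n_hidden = int(round(hidden_fraction * len(planted)))
    hidden_idx = set(rng.choice(len(planted), size=n_hidden, replace=False).tolist())
    hidden = {planted[i] for i in hidden_idx}
    known = set(planted) - hidden
    paths = write_universe_inputs(uni, work / "inputs", known=known)

    process = select_process_proteins(uni.go, ucfg.process_keyword)
    decoys = enumerate_candidates(process, set(planted), n_decoys_per_hidden * n_hidden,
                                  _seed_for(seed, "decoys"))
    candidates = sorted(hidden | set(decoys))
    io.write_pair_list([io.PairRecord(*p) for p in candidates],
                       work / "inputs" / "candidates.tsv")

    return PipelineConfig(
        positive_pairs=paths["positives"],
        go_annotations=paths["go"],
        kegg_annotations=paths["kegg"],
        localization=paths["localization"],
        expression=paths["expression"],
        candidate_pairs=str(work / "inputs" / "candidates.tsv"),
        truth_pairs=paths["truth"],
        out_dir=str(work / "run"),
        random_seed=seed,
    ).validate()


def run_fixture(seed: int, work_dir: str | Path, **kwargs) -> dict:
    """Generate the packaged benchmark and run the full pipeline on it."""
    config = fixture_pipeline_config(seed, work_dir, **kwargs)
    return run_pipeline(config)
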