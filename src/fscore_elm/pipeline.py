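"""End-to-end orchestration: simulate → preprocess → extract → rank → search.

Each stage writes its artifact in the corresponding plain-text format so any
stage can also be run (and re-read) in isolation from the CLI.  The result
JSON contains only seed-deterministic content — rerunning with the same
config and seed reproduces it byte for byte; wall-clock timings go to the
human-readable report.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io
from .config import RunConfig
from .features import extract_features
from .fscore import rank_features
from .optimizer import FScoreELMSearch
from .preprocess import preprocess_dataset
from .simulate import generate_dataset

__all__ = ["run_pipeline", "format_report"]

log = logging.getLogger("fscore_elm")


def format_report(search: FScoreELMSearch, title: str = "F-score_ELM") -> str:
    """One-model performance table: timings, train/test rates ± SD, NHN, NFS."""
    sd = lambda v: float(np.std(np.asarray(v), ddof=1)) if len(v) > 1 else 0.0
    tr_sen_sd = sd(search.fold_ba_train_)  # spread of per-fold training BA
    lines = [
        f"{'Model':<14}{'TTR(s)':>9}{'TTE(s)':>9}{'TR_sen':>14}{'TR_spe':>14}"
        f"{'TE_sen':>14}{'TE_spe':>14}{'NHN':>5}{'NFS':>5}",
        f"{title:<14}"
        f"{search.train_seconds_:>9.2f}{search.test_seconds_:>9.4f}"
        f"{search.tr_sen_:>9.2f}"
        f"{'':>5}{search.tr_spe_:>9.2f}{'':>5}"
        f"{search.te_sen_:>7.2f}±{sd(search.fold_te_sen_):<5.2f}"
        f"{search.te_spe_:>7.2f}±{sd(search.fold_te_spe_):<5.2f}"
        f"{search.k_opt_:>5d}{search.s_opt_:>5d}",
        "",
        f"BA_train = {search.ba_train_:.2f}%   (per-fold SD {tr_sen_sd:.2f})",
        f"BA_test  = {search.ba_test_:.2f}%",
        "",
        "Per-subject test accuracy (%):",
    ]
    for sid in sorted(search.subject_accuracy_):
        lines.append(f"  {sid}: {search.subject_accuracy_[sid]:.1f}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig, out_dir) -> FScoreELMSearch:
    """Run all stages, writing epochs, features, ranking, result and report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulating %d subjects/class", config.sim.n_subjects_per_class)
    trials = generate_dataset(config.sim)
    io.write_epochs(trials, out / "epochs.tsv")

    log.info("preprocessing: baseline + %d-trial averaging", config.preprocess.group_size)
    averaged = preprocess_dataset(
        trials, group_size=config.preprocess.group_size, baseline=config.preprocess.baseline
    )
    io.write_epochs(averaged, out / "averaged.tsv")

    log.info("extracting features from %d averaged responses", len(averaged))
    fc = config.features
    table = extract_features(
        averaged,
        burg_order=fc.burg_order,
        n_freq=fc.n_freq,
        band_lo=fc.band_lo,
        band_hi=fc.band_hi,
        wavelet=fc.wavelet,
        level=fc.level,
        mode=fc.mode,
    )
    io.write_feature_table(table, out / "features.csv")

    ranking = rank_features(table)  # whole-table ranking, reporting only
    io.write_json(ranking.to_dict(), out / "ranking.json")

    sc = config.search
    log.info("grid search: selector=%s k_span=%d", sc.selector, sc.k_span)
    search = FScoreELMSearch(
        selector=sc.selector,
        k_span=sc.k_span,
        inner_folds=sc.inner_folds,
        parsimony=sc.parsimony,
        global_ranking=sc.global_ranking,
        random_state=config.search_seed(),
    ).fit(table)

    result = {"config": config.to_dict(), **search.result_dict()}
    io.write_json(result, out / "result.json")
    (out / "report.txt").write_text(format_report(search))
    log.info(
        "done: NFS=%d NHN=%d BA_train=%.2f%% BA_test=%.2f%%",
        search.s_opt_,
        search.k_opt_,
        search.ba_train_,
        search.ba_test_,
    )
    return search
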