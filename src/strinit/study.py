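"""End-to-end synthetic study: every stage of the analysis on generated data.

Runs the full loop — simulate a world, recompute per-orientation initiation
signals from coverage, train regression and classification models, measure
held-out accuracy against the generative (Bayes-optimal) ceiling, run
shuffled-label nulls, interpret the regression model by random mutagenesis,
check the cap G-bias fixtures, and test eQTL sign concordance — and returns
the headline numbers. Problem sizes default to the generator's defaults
(10,000 catalog STRs, i.e. 20,000 oriented examples).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from . import cnn_engine as ce
from . import interpretation as ip
from . import seq_dataset as sq
from . import str_signal as ss
from . import synthetic_data as sd
from . import variant_effects as ve
from .cap_bias import first_base_tally, g_bias_report
from .genomic_io import MINUS, PLUS, GenomicInterval, window_overlap


def _seed(base: int, k: int) -> int:
    return (base * 7919 + k) % (2**31)


def run_synthetic_study(
    seed: int = 1,
    n_strs: int = 10_000,
    max_epochs: int = 40,
    n_variants: int = 400,
    mutagenesis_windows: int = 400,
    mutations_per_window: int = 20,
) -> Dict[str, Dict[str, float]]:
    """Full pipeline on a default synthetic world; returns named metrics.

    Every metric is recomputed from scratch at call time; nothing is cached
    or looked up.
    """
    out: Dict[str, Dict[str, float]] = {}

    # ----- world + coverage -------------------------------------------------
    world = sd.generate_world(n_strs=n_strs, seed=_seed(seed, 1))
    cov = sd.generate_coverage(world, seed=_seed(seed, 2))

    # ----- quantification: recompute signals from the coverage track --------
    oriented: List[ss.OrientedStr] = []
    abs_d_directional, abs_d_balanced = [], []
    directional = dict(zip(world.truth["name"], world.truth["directional"]))
    for rec in world.catalog:
        plus, minus = ss.orient_str(rec, cov)
        oriented.extend((plus, minus))
        d = ss.directionality(plus.signal, minus.signal)
        if d.defined:
            (abs_d_directional if directional[rec.name] else abs_d_balanced).append(
                abs(d.value))
    out["directional_median_abs_directionality"] = {
        "value": float(np.median(abs_d_directional)), "n": len(abs_d_directional)}
    out["bidirectional_median_abs_directionality"] = {
        "value": float(np.median(abs_d_balanced)), "n": len(abs_d_balanced)}

    # ----- regression on full 101-bp windows --------------------------------
    # trained on log1p targets (the signal noise is multiplicative lognormal,
    # so log-scale squared error is the natural loss); ranks — hence every
    # Spearman below — are unchanged, and predictions are mapped back with
    # expm1 wherever the natural scale matters (the 0.2 error cut)
    ds = sq.build_dataset(world.store, oriented, width=sq.DEFAULT_WIDTH,
                          log1p=True)
    split = sq.make_split(len(ds), seed=_seed(seed, 3))
    cfg = ce.TrainConfig(max_epochs=max_epochs, seed=_seed(seed, 4))
    spec = ce.ModelSpec(input_width=sq.DEFAULT_WIDTH)
    model = ce.build_model(spec, seed=_seed(seed, 5))
    tm = ce.train(model, ds.X[split.train_idx], ds.y[split.train_idx],
                  ds.X[split.val_idx], ds.y[split.val_idx], cfg)
    test_pred = tm.predict(ds.X[split.test_idx])
    rep = ce.eval_regression(test_pred, ds.y[split.test_idx])
    out["heldout_spearman"] = {"value": rep.value, "n": rep.n}

    # Bayes ceiling: the generative expectation against the same targets
    mu_map = {(r["name"], r["strand"]): r["expected_signal"]
              for _, r in world.truth.iterrows()}
    bayes_pred = np.array([
        mu_map[(row["name"], row["strand"])]
        for _, row in ds.meta.iloc[split.test_idx].iterrows()])
    bayes = ce.eval_regression(bayes_pred, ds.y[split.test_idx])
    out["bayes_spearman"] = {"value": bayes.value, "n": bayes.n}

    # shuffled-label null: permute all targets, retrain, evaluate held-out
    # performance on the permuted dataset (the standard permutation null)
    rng = np.random.default_rng(_seed(seed, 6))
    y_shuf = rng.permutation(ds.y)
    null_model = ce.build_model(spec, seed=_seed(seed, 7))
    tm_null = ce.train(null_model, ds.X[split.train_idx], y_shuf[split.train_idx],
                       ds.X[split.val_idx], y_shuf[split.val_idx], cfg)
    null_rep = ce.eval_regression(tm_null.predict(ds.X[split.test_idx]),
                                  y_shuf[split.test_idx])
    out["shuffled_label_abs_spearman"] = {
        "value": abs(null_rep.value), "n": null_rep.n}

    # permutation baseline of the targets themselves
    base = ce.randomized_baseline(ds.y, reps=10, seed=_seed(seed, 8))
    out["randomized_baseline_max_abs_spearman"] = {
        "value": float(max(base)), "n": len(ds.y)}

    # ----- flank-only regression (masked inputs) ----------------------------
    ds_flank = sq.build_dataset(world.store, oriented, width=sq.DEFAULT_WIDTH,
                                mask=sq.MASK_FLANK_ONLY, log1p=True)
    spec_flank = ce.ModelSpec(input_width=sq.FLANK_ONLY_WIDTH)
    model_flank = ce.build_model(spec_flank, seed=_seed(seed, 9))
    tm_flank = ce.train(model_flank, ds_flank.X[split.train_idx],
                        ds_flank.y[split.train_idx],
                        ds_flank.X[split.val_idx], ds_flank.y[split.val_idx], cfg)
    flank_rep = ce.eval_regression(tm_flank.predict(ds_flank.X[split.test_idx]),
                                   ds_flank.y[split.test_idx])
    out["flank_only_spearman"] = {"value": flank_rep.value, "n": flank_rep.n}

    # ----- pairwise flank-bias classification -------------------------------
    cls_a, cls_b = world.class_specs[0].motif, world.class_specs[-1].motif
    keep = ds_flank.meta["str_class"].isin([cls_a, cls_b]).to_numpy()
    # class key of the catalog record, independent of strand
    labels_all = (ds_flank.meta["str_class"] == cls_b).to_numpy().astype(float)
    idx = np.flatnonzero(keep)
    bal = idx[sq.balance_classes(labels_all[idx], seed=_seed(seed, 10))]
    Xc, yc = ds_flank.X[bal], labels_all[bal]
    csplit = sq.make_split(len(bal), seed=_seed(seed, 11))
    cspec = ce.ModelSpec(input_width=sq.FLANK_ONLY_WIDTH, task=ce.CLASSIFICATION)
    ccfg = ce.TrainConfig(max_epochs=min(max_epochs, 20), seed=_seed(seed, 12))
    cmodel = ce.build_model(cspec, seed=_seed(seed, 13))
    tm_c = ce.train(cmodel, Xc[csplit.train_idx], yc[csplit.train_idx],
                    Xc[csplit.val_idx], yc[csplit.val_idx], ccfg)
    auc = ce.eval_classification(tm_c.predict(Xc[csplit.test_idx]),
                                 yc[csplit.test_idx])
    out["flank_classification_auc"] = {"value": auc.value, "n": auc.n}

    yc_shuf = np.random.default_rng(_seed(seed, 14)).permutation(yc)
    cnull = ce.build_model(cspec, seed=_seed(seed, 15))
    tm_cn = ce.train(cnull, Xc[csplit.train_idx], yc_shuf[csplit.train_idx],
                     Xc[csplit.val_idx], yc_shuf[csplit.val_idx], ccfg)
    auc_null = ce.eval_classification(tm_cn.predict(Xc[csplit.test_idx]),
                                      yc_shuf[csplit.test_idx])
    out["shuffled_label_auc"] = {"value": auc_null.value, "n": auc_null.n}

    # ----- mutagenesis profile on the trained regression model --------------
    prof = ip.mutagenesis_profile(
        tm, ds.X[split.test_idx][:mutagenesis_windows],
        mutations_per_window=mutations_per_window, seed=_seed(seed, 16))
    peak_offset = int(prof.offsets[int(np.argmax(prof.variances))])
    out["mutagenesis_peak_offset"] = {
        "value": float(peak_offset),
        "n": int(prof.counts.sum())}
    in_motif = any(lo <= peak_offset < hi
                   for lo, hi in world.signal_model.motif_offset_ranges())
    out["mutagenesis_peak_inside_planted_motif"] = {
        "value": float(in_motif), "n": int(prof.counts.sum())}

    # ----- cap G-bias fixtures ----------------------------------------------
    anchor_sub = [o for o in oriented[: 2 * 400]]
    anchors = [GenomicInterval(o.interval.chrom, o.three_prime_index,
                               o.three_prime_index + 3, o.strand)
               for o in anchor_sub]
    capped = sd.generate_alignments(world.store, anchors, n_per_anchor=5,
                                    cap_g_rate=0.5, seed=_seed(seed, 17))
    control = sd.generate_alignments(world.store, anchors, n_per_anchor=5,
                                     cap_g_rate=0.0, seed=_seed(seed, 18))
    rep_cap = g_bias_report(first_base_tally(capped, anchors))
    rep_ctl = g_bias_report(first_base_tally(control, anchors))
    out["capped_g_share_of_mismatches"] = {
        "value": rep_cap["base_share_of_mismatched"]["G"],
        "n": rep_cap["total_intersecting"]}
    out["capped_first_base_mismatch_fraction"] = {
        "value": rep_cap["mismatch_fraction"], "n": rep_cap["total_intersecting"]}
    out["control_first_base_mismatch_fraction"] = {
        "value": rep_ctl["mismatch_fraction"], "n": rep_ctl["total_intersecting"]}

    # ----- shuffle baseline for anchor overlap ------------------------------
    hit = {i for i, _ in window_overlap(
        [r.interval for r in world.catalog[:2000]], anchors, w=5)}
    out["str_anchor_overlap_fraction"] = {
        "value": len(hit) / 2000, "n": 2000}
    baseline = ss.random_overlap_baseline(
        world.catalog[:2000], anchors, world.chrom_sizes(), seed=_seed(seed, 19))
    out["shuffled_anchor_overlap_fraction"] = {"value": baseline, "n": 2000}

    # ----- eQTL sign concordance --------------------------------------------
    variants, gene_starts = sd.generate_variants(world, n=n_variants,
                                                 seed=_seed(seed, 20))
    obs = {(o.record.name, o.strand): o.signal for o in oriented}
    results, table = ve.eqtl_sign_concordance(
        tm, world.store, variants, oriented, gene_starts, observed=obs,
        transform=np.expm1)
    low = next((r for r in results if r.stratum.startswith("error<=")), None)
    if low is not None:
        out["eqtl_concordance_low_error"] = {"value": low.concordance, "n": low.n}
        out["eqtl_concordance_low_error_p"] = {"value": low.p_value, "n": low.n}
    rand_model = ce.build_model(spec, seed=_seed(seed, 21))
    rresults, rtable = ve.eqtl_sign_concordance(
        rand_model, world.store, variants, oriented, gene_starts, observed=obs)
    if len(rtable):
        out["eqtl_concordance_random_predictor"] = {
            "value": float(rtable["concordant"].mean()), "n": len(rtable)}

    return out
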