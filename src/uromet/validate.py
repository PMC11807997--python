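"""Planted-truth benchmarking experiments.

Each function here builds a synthetic cohort (or matrix) with known ground
truth, runs the relevant pipeline stage, and reports a recovery or
calibration metric: how much of what was planted the method gets back, and
how the method behaves when nothing was planted. They are used by the test
suite and the reproduction script alike.

Note on cross-contrast leakage: a feature planted for one comparison shifts
only that comparison's case group, so it is genuinely differential in any
other contrast involving that group (a feature doubled in AD differs from
both CN and MCI). Recovery metrics therefore score each comparison against
its own planted set, count false calls only among features planted for no
comparison, and judge pathway enrichment as "every truth-enriched pathway
ranks above every background pathway".
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .io import Comparison, COMPARISONS
from .config import PipelineConfig
from .simulate import CohortSpec, PlantedEffect, SyntheticTruth, generate_cohort
from .preprocess import preprocess_table
from .latent import autoscale, fit_oplsda, permutation_test
from .screen import screen_comparison, ComparisonScreen
from .enrich import enrich
from .staging import select_key_panel, random_sampling_validation, KeyPanel


def screen_recovery(screen: ComparisonScreen, truth: SyntheticTruth) -> dict:
    """Fraction of this comparison's planted features called with the
    correct direction, and the false-call rate among never-planted
    features."""
    planted = truth.differential_features.get(screen.comparison, {})
    status_by_id = {r.feature_id: r.status for r in screen.records}
    hits = 0
    scored = 0
    for fid, fc in planted.items():
        if fid not in status_by_id:
            continue  # removed by QC filtering (never happens for planted)
        scored += 1
        want = "up" if fc > 1 else "down"
        hits += status_by_id[fid] == want
    all_planted = truth.planted_ids()
    null_ids = [f for f in status_by_id if f not in all_planted]
    false_calls = sum(status_by_id[f] != "ns" for f in null_ids)
    return {
        "recovered_rate": hits / scored if scored else float("nan"),
        "false_call_rate": false_calls / len(null_ids) if null_ids else float("nan"),
        "n_planted_scored": scored,
        "n_null": len(null_ids),
    }


def two_group_spec(n_per_group: int, planted: list[PlantedEffect],
                   n_features_neg: int, n_features_pos: int,
                   seed: int, **kwargs) -> CohortSpec:
    """A CN/AD-only cohort spec for focused two-group experiments."""
    return CohortSpec(
        group_sizes={"CN": n_per_group, "AD": n_per_group},
        n_features_neg=n_features_neg, n_features_pos=n_features_pos,
        planted_effects=planted, seed=seed, **kwargs,
    )


def vip_effect_rank_correlation(seed: int, n_per_group: int = 30,
                                n_features: int = 200,
                                n_planted: int = 20) -> float:
    """Spearman correlation between planted |log FC| and VIP.

    Plants ``n_planted`` features with fold changes spread over
    [1/3.5, 1/1.3] and [1.3, 3.5] and fits one OPLS-DA model over a single
    p-feature matrix; returns the rank correlation across planted features.
    All effects go into one ion mode because VIP is normalised within a
    fitted model (mean VIP^2 = 1), so scores from separately fitted models
    are not rank-comparable.
    """
    rng = np.random.default_rng(seed)
    ids = [f"neg_f{i:03d}" for i in range(n_features)]
    chosen = rng.choice(ids, size=n_planted, replace=False)
    magnitudes = np.exp(rng.uniform(np.log(1.3), np.log(3.5), size=n_planted))
    up = rng.uniform(size=n_planted) < 0.5
    fcs = np.where(up, magnitudes, 1.0 / magnitudes)
    planted = [PlantedEffect(f, "CN-AD", float(fc)) for f, fc in zip(chosen, fcs)]
    spec = two_group_spec(n_per_group, planted, n_features, 1,
                          seed=seed, missing_rate_random=0.0,
                          missing_low_prob=0.0, frac_high_cv=0.0)
    neg, _, meta, _, _ = generate_cohort(spec)
    bio = neg.subset_samples(meta.biological_ids)
    X = autoscale(bio.data.T, log_transform=True)
    labels = meta.groups.loc[bio.sample_ids].to_numpy()
    model = fit_oplsda(X, labels, n_ortho=1, case_group="AD")
    vips = dict(zip(X.feature_ids, model.vip))
    effect = np.abs(np.log(fcs))
    vip_vals = np.array([vips[f] for f in chosen])
    return float(spearmanr(effect, vip_vals).statistic)


def run_cohort_screens(spec: CohortSpec, config: PipelineConfig | None = None
                       ) -> tuple[dict[str, ComparisonScreen], dict, SyntheticTruth]:
    """Generate, preprocess, and screen all three comparisons."""
    config = config or PipelineConfig(seed=spec.seed)
    neg, pos, meta, pmap, truth = generate_cohort(spec)
    clean = {}
    for t in (neg, pos):
        clean[t.ion_mode], _, _ = preprocess_table(
            t, meta, config.cv_threshold, config.knn_fraction)
    screens = {
        c.name: screen_comparison(clean["negative"], clean["positive"],
                                  meta, c, config)
        for c in COMPARISONS
        if meta.ids_in_group(c.case_group) and meta.ids_in_group(c.reference_group)
    }
    env = {"tables": clean, "metadata": meta, "pathway_map": pmap}
    return screens, env, truth


def enrichment_rank_success(spec: CohortSpec) -> bool:
    """True when every comparison's own truth-enriched pathway scores a
    smaller enrichment p-value than all background pathways.

    Only the pathway planted for the comparison at hand is required to win:
    pathways planted for other contrasts may or may not be enriched here
    depending on which group their effects shifted.
    """
    screens, env, truth = run_cohort_screens(spec)
    pmap = env["pathway_map"]
    annotated = pmap.annotated_ids()
    tables = env["tables"]
    background_ids = sorted(
        (set(tables["negative"].feature_ids) | set(tables["positive"].feature_ids))
        & annotated
    )
    enriched_ids = truth.enriched_pathway_ids
    own_pathway = {comp: pid for pid, comp in truth.enriched_pathways.items()}
    for name, screen in screens.items():
        if name not in own_pathway:
            continue
        diff = sorted(set(screen.differential_ids) & set(background_ids))
        results = enrich(diff, background_ids, pmap)
        p_by_id = {r.pathway_id: r.p_value for r in results}
        own_p = p_by_id[own_pathway[name]]
        best_background = min(p for pid, p in p_by_id.items()
                              if pid not in enriched_ids)
        if own_p >= best_background:
            return False
    return True


def enrichment_rank_rate(n_repeats: int, base_seed: int) -> float:
    wins = sum(enrichment_rank_success(CohortSpec(seed=base_seed + 1000 * r))
               for r in range(n_repeats))
    return wins / n_repeats


def strong_effect_spec(seed: int, n_per_group: int = 50) -> tuple[CohortSpec, set[str]]:
    """Two-group cohort with 10 strong (FC 2.5 / 0.4) and 40 moderate
    (FC 1.5 / 0.67) planted effects among 100 features; returns the spec
    and the strong-feature ids."""
    planted: list[PlantedEffect] = []
    strong: set[str] = set()
    for mode, n_mode in (("neg", 50), ("pos", 50)):
        for i in range(5):
            fid = f"{mode}_f{i:03d}"
            fc = 2.5 if i % 2 == 0 else 0.4
            planted.append(PlantedEffect(fid, "CN-AD", fc))
            strong.add(fid)
        for i in range(5, 25):
            fid = f"{mode}_f{i:03d}"
            fc = 1.5 if i % 2 == 0 else 1 / 1.5
            planted.append(PlantedEffect(fid, "CN-AD", fc))
    spec = two_group_spec(n_per_group, planted, 50, 50, seed=seed,
                          frac_high_cv=0.0)
    return spec, strong


def panel_recovery_counts(n_seeds: int, base_seed: int,
                          n_keys: int = 10) -> list[int]:
    """How many of the 10 strong planted effects land in the key panel,
    per seed."""
    counts = []
    comp = Comparison("CN", "AD")
    config = PipelineConfig()
    for s in range(n_seeds):
        seed = base_seed + 131 * s
        spec, strong = strong_effect_spec(seed)
        neg, pos, meta, _, _ = generate_cohort(spec)
        clean = {}
        for t in (neg, pos):
            clean[t.ion_mode], _, _ = preprocess_table(t, meta)
        screen = screen_comparison(clean["negative"], clean["positive"],
                                   meta, comp, config)
        panel = select_key_panel(screen, clean["negative"], clean["positive"],
                                 meta, comp, enrichment=None, n_keys=n_keys,
                                 seed=seed, config=config)
        counts.append(len(strong & set(panel.feature_ids)))
    return counts


def null_permutation_pvalues(n_repeats: int, base_seed: int,
                             n_perm: int = 50, n: int = 40,
                             p: int = 30) -> np.ndarray:
    """Permutation p-values for Q2 on pure-noise data.

    Labels are independent of the log-normal feature matrix, so the
    permutation p-value should be approximately uniform on the attainable
    grid over repeats.
    """
    pvals = np.empty(n_repeats)
    for r in range(n_repeats):
        rng = np.random.default_rng(base_seed + 977 * r)
        X = np.exp(rng.normal(13.0, 0.5, size=(n, p)))
        labels = np.array(["CN"] * (n // 2) + ["AD"] * (n - n // 2))
        res = permutation_test(X, labels, n_ortho=1, n_perm=n_perm,
                               seed=base_seed + 977 * r + 1, folds=5,
                               case_group="AD")
        pvals[r] = res.p_q2
    return pvals


def null_resampling_auc(seed: int, n_per_group: int = 30,
                        n_resamples: int = 100) -> float:
    """Mean held-out AUC of the staging model on a cohort with no planted
    effects; should centre on 0.5. The null cohort carries no missingness so
    the experiment calibrates the staging model itself rather than
    group-wise imputation artifacts."""
    spec = two_group_spec(n_per_group, [], 30, 30, seed=seed,
                          frac_high_cv=0.0, missing_rate_random=0.0,
                          missing_low_prob=0.0)
    neg, pos, meta, _, _ = generate_cohort(spec)
    clean = {}
    for t in (neg, pos):
        clean[t.ion_mode], _, _ = preprocess_table(t, meta)
    comp = Comparison("CN", "AD")
    # arbitrary fixed panel: the screen calls nothing on null data
    panel = KeyPanel(comparison=comp.name, seed=seed,
                     features=[(f, 0.0) for f in clean["negative"].feature_ids[:10]])
    report = random_sampling_validation(panel, clean["negative"], clean["positive"],
                                        meta, comp, n_resamples=n_resamples,
                                        test_fraction=0.30, seed=seed)
    return report.mean_auc
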