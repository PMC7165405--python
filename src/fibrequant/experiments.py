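"""Reference validation experiments on synthetic sections with known truth.

Each function generates the stated study condition (fibre counts, coverage
grids, noise level, effect sizes), runs the full pipeline, and scores the
result against the generator's ground truth.  They are used by the acceptance
test-suite and the reproduction script; seeds are explicit so every run is
repeatable.
"""

from __future__ import annotations

import numpy as np

from .evaluation import expected_class, jaccard_per_truth_fibre, match_records_to_truth
from .myosin import derive_myosin_threshold
from .pipeline import analyse_section
from .sarcolemmal import angular_sweep_coverage, circumference_positivity
from .summary import compare_replicates
from .synthetic_section import SectionSpec, generate_control_panel, generate_section

COVERAGE_GRID = tuple(i / 10 for i in range(11))

#: study conditions: additive noise sd 500 AU on a 8000 AU cytoplasmic
#: background, membrane staining at 30000 AU
NOISE_SD = 500.0
BACKGROUND = 8000.0


def coverage_recovery(seed: int = 0, n_fibres: int = 200) -> dict:
    """Circumference-Positivity recovery over the full coverage grid at realistic noise."""
    spec = SectionSpec(n_fibres=n_fibres, primary_coverage_fractions=list(COVERAGE_GRID),
                       noise_sd=NOISE_SD, sarcoplasm_background=BACKGROUND, seed=seed)
    stack, truth, labels = generate_section(spec)
    res = analyse_section(stack)
    matched = match_records_to_truth(res.records, truth)
    matched = matched[matched["quantifiable"]]
    err = matched["coverage_error_pts"].abs()
    off_boundary = matched[
        np.minimum.reduce([abs(matched["true_coverage_pct"] - b) for b in (25.0, 50.0, 75.0)]) >= 3.0
    ]
    class_ok = [
        row["coverage_class"] == expected_class(row["true_coverage_pct"])
        for _, row in off_boundary.iterrows()
    ]
    return {
        "n_fibres": int(len(matched)),
        "pct_within_5pts": float(100.0 * (err <= 5.0).mean()),
        "max_abs_error_pts": float(err.max()),
        "class_accuracy_pct": float(100.0 * np.mean(class_ok)),
    }


def estimator_cross_validation(seed: int = 0, n_fibres: int = 44) -> dict:
    """Agreement of both coverage estimators and the angular brute-force oracle, noise-free.

    Estimates are compared at each grid coverage (mean over that coverage's
    fibres, four per grid point by default); the reported figure is the worst
    pairwise disagreement across the grid.
    """
    spec = SectionSpec(n_fibres=n_fibres, primary_coverage_fractions=list(COVERAGE_GRID),
                       noise_sd=0.0, seed=seed)
    stack, truth, labels = generate_section(spec)
    res = analyse_section(stack)
    matched = match_records_to_truth(res.records, truth).set_index("label")
    by_coverage: dict[float, list[tuple[float, float, float]]] = {}
    for part in res.partitions:
        objs = res.objects[part.label]
        proj = circumference_positivity(objs, part, "projection")
        lit = circumference_positivity(objs, part, "literal")
        pos = np.zeros_like(part.ring)
        for o in objs:
            pos[o.pixels[:, 0], o.pixels[:, 1]] = True
        centre = (part.centroid[0] - part.offset[0], part.centroid[1] - part.offset[1])
        oracle = angular_sweep_coverage(part.ring, pos, centre)
        cov = float(matched.loc[part.label, "true_coverage_pct"])
        by_coverage.setdefault(cov, []).append((proj, lit, oracle))
    worst = 0.0
    for cov, triples in by_coverage.items():
        proj, lit, oracle = (float(np.mean([t[i] for t in triples])) for i in range(3))
        worst = max(worst, abs(proj - lit), abs(proj - oracle), abs(lit - oracle))
    return {"n_fibres": int(len(res.partitions)), "max_disagreement_pts": float(worst)}


def segmentation_fidelity(seed: int = 0, n_fibres: int = 200) -> dict:
    """Detection rate and overlap quality against the true label image."""
    spec = SectionSpec(n_fibres=n_fibres, noise_sd=NOISE_SD, seed=seed)
    stack, truth, labels = generate_section(spec)
    res = analyse_section(stack)
    jac = jaccard_per_truth_fibre(labels, res.label_map.labels)
    return {
        "n_fibres": int(len(truth.fibres)),
        "pct_detected_jaccard_ge_08": float(100.0 * (jac >= 0.8).mean()),
        "mean_jaccard": float(jac.mean()),
        "all_rejections_have_reasons": bool(all(r for _, r in res.rejected)),
    }


def artefact_exclusion(seed: int = 0, n_fibres: int = 50) -> dict:
    """Fold-streak exclusion rate and fibre-pixel collateral damage."""
    from .segmentation import detect_tissue, exclude_artefacts

    spec = SectionSpec(n_fibres=n_fibres, noise_sd=NOISE_SD, seed=seed,
                       artefact_spec=[{"kind": "fold", "width_um": 3.0}])
    stack, truth, labels = generate_section(spec)
    tissue = exclude_artefacts(stack, detect_tissue(stack))
    art = truth.artefact_mask
    fibre = labels > 0
    return {
        "n_fibres": int(n_fibres),
        "pct_artefact_excluded": float(100.0 * (tissue.excluded & art).sum() / art.sum()),
        "pct_fibre_collateral": float(100.0 * (tissue.excluded & fibre & ~art).sum() / fibre.sum()),
    }


def colocalisation_recovery(seed: int = 0, n_fibres: int = 40) -> dict:
    """Recovery of a two-fold tertiary enrichment on primary-positive sarcolemma."""
    spec = SectionSpec(n_fibres=n_fibres, primary_coverage_fractions=0.5,
                       tertiary_intensity_pos=24000.0, tertiary_intensity_neg=12000.0,
                       noise_sd=NOISE_SD, seed=seed)
    stack, truth, labels = generate_section(spec)
    res = analyse_section(stack)
    s = res.summary
    return {
        "n_fibres": int(s.n_fibres_analysed),
        "tertiary_enrichment_ratio": float(
            s.coloc_tertiary_in_primary_pos / s.coloc_tertiary_in_primary_neg),
    }


def myosin_recovery(seed: int = 0, n_controls: int = 5, control_fibres: int = 100,
                    test_fibres: int = 200) -> dict:
    """Sensitivity/specificity of myosin calls against a control-derived threshold."""
    control_spec = SectionSpec(n_fibres=control_fibres, tertiary_mode="sarcoplasmic",
                               myosin_positive_fraction=0.0, tertiary_intensity_pos=4 * BACKGROUND,
                               noise_sd=NOISE_SD, seed=seed)
    panel = generate_control_panel(control_spec, n_controls)
    control_means: list[float] = []
    for stack, _ in panel:
        res = analyse_section(stack)
        control_means += [p.tertiary_sarcoplasm_mean for p in res.profiles if p.quantifiable]
    thr = derive_myosin_threshold(control_means)

    test_spec = SectionSpec(n_fibres=test_fibres, tertiary_mode="sarcoplasmic",
                            myosin_positive_fraction=0.3, tertiary_intensity_pos=4 * BACKGROUND,
                            noise_sd=NOISE_SD, seed=seed + 1000)
    stack, truth, _ = generate_section(test_spec)
    res = analyse_section(stack, myosin_threshold=thr)

    fresh_spec = SectionSpec(n_fibres=test_fibres, tertiary_mode="sarcoplasmic",
                             myosin_positive_fraction=0.0, tertiary_intensity_pos=4 * BACKGROUND,
                             noise_sd=NOISE_SD, seed=seed + 2000)
    stack0, _, _ = generate_section(fresh_spec)
    res0 = analyse_section(stack0, myosin_threshold=thr)
    return {
        "n_control_fibres": int(thr.n_control_fibres),
        "n_test_fibres": int(res.summary.n_fibres_analysed),
        "threshold_au": float(thr.value),
        "pct_myosin_recovered": float(res.summary.pct_myosin_positive),
        "pct_false_positive": float(res0.summary.pct_myosin_positive),
    }


def replicate_variability(seed: int = 0, n_sections: int = 5, n_fibres: int = 50) -> dict:
    """Natural analysis variability across same-condition, different-seed sections."""
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_sections)
    summaries = []
    for s in sub_seeds:
        spec = SectionSpec(n_fibres=n_fibres, primary_coverage_fractions=1.0,
                           noise_sd=NOISE_SD, seed=int(s))
        stack, _, _ = generate_section(spec)
        summaries.append(analyse_section(stack).summary)
    rep = compare_replicates(summaries)
    return {
        "n_sections": int(n_sections),
        "n_fibres_per_section": int(n_fibres),
        "intensity_percent_variability": float(
            rep["mean_sarcolemma_intensity"]["percent_variability"]),
        "pct_positive_min": float(rep["pct_positive"]["min"]),
    }
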