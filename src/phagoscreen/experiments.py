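"""Planted-truth validation experiments for the whole pipeline.

Each function runs one self-contained recovery study on synthetic data with
known ground truth and returns summary statistics: hit-calling sensitivity
and false-discovery proportion on a full-size simulated screen, EC50
recovery across the dose ladder, Cox hazard-ratio recovery and confidence
interval coverage, IPW/matching de-confounding, planted-gene regression
ranking, and an exhaustive-enumeration check of the hypergeometric tail.
They are used by the test suite and by ``scripts/acceptance.py``; every
function takes an explicit seed.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import cohort_study as cs
from .enrichment import EnrichmentCounts, hypergeom_tail
from .hit_calling import (
    CompoundDoseSeries,
    classify_screen,
    fit_dose_response,
    four_param_logistic,
)
from .network_meta import disease_gene_overlap, group_gene_regression, one_hot_matrix
from .plate_screen import normalize_screen
from .synthetic_data import (
    DEFAULT_DOSES_UM,
    CohortSimConfig,
    NetworkSimConfig,
    ScreenSimConfig,
    _lognormal_noise,
    gen_network_tables,
    gen_screen,
    simulate_survival_rows,
)


def screen_recovery(seed: int, cv_noise: float = 0.05, n_compounds: int = 3280) -> dict:
    """Run the full screen simulation and score calls against planted truth.

    Uses the screen's own conditions: 5 doses in singlicate, 5% planted
    increase (140% of plate median), 5% decrease (50%), 2% toxic, and the
    requested multiplicative noise.  Sensitivity counts a planted
    increase/decrease compound as recovered only when called in its exact
    class; the false-discovery proportion pools increase and decrease calls.
    """
    cfg = ScreenSimConfig(n_compounds=n_compounds, cv_noise=cv_noise, seed=seed)
    sim = gen_screen(cfg)
    calls, _ = classify_screen(normalize_screen(sim.wells))
    merged = calls.merge(sim.truth, on="compound_id")

    out = {"n_compounds": n_compounds}
    tp_all = fp_all = pos_all = 0
    for direction in ("increase", "decrease"):
        truth = merged["true_class"] == direction
        called = merged["call"] == direction
        tp = int((truth & called).sum())
        out[f"sensitivity_{direction}"] = tp / int(truth.sum())
        tp_all += tp
        fp_all += int((~truth & called).sum())
        pos_all += int(called.sum())
    out["sensitivity"] = tp_all / int(
        merged["true_class"].isin(["increase", "decrease"]).sum()
    )
    out["fdp"] = fp_all / pos_all if pos_all else 0.0
    out["exact"] = bool((merged["call"] == merged["true_class"]).all())
    return out


def ec50_recovery(
    seed: int,
    n_curves: int = 200,
    cv_noise: float = 0.05,
    ec50_range=(1.0, 20.0),
) -> dict:
    """EC50 recovery on simulated dose-response curves at the screen doses.

    Curves follow a standard-slope (Hill 1) logistic falling from 100% to
    40%, with the EC50 drawn log-uniformly over ``ec50_range`` (the natural
    scale for a concentration).  Noise-free curves are fit with the free
    four-parameter model; noisy curves with the screen configuration
    (zero-dose asymptote anchored at 100, slope 1, log-scale residuals,
    matching the multiplicative noise).  Returns the worst noise-free
    relative error and the fraction of noisy fits within two-fold.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(DEFAULT_DOSES_UM)
    max_err_free = 0.0
    n_within = 0
    for i in range(n_curves):
        ec50 = float(np.exp(rng.uniform(np.log(ec50_range[0]), np.log(ec50_range[1]))))
        pct = four_param_logistic(doses, 40.0, 100.0, ec50, 1.0)

        s = CompoundDoseSeries(f"free{i}", tuple((d, p, False) for d, p in zip(doses, pct)))
        fit = fit_dose_response(s)
        max_err_free = max(max_err_free, abs(fit.ec50_um / ec50 - 1.0))

        noisy = pct * _lognormal_noise(rng, cv_noise, doses.size)
        s = CompoundDoseSeries(
            f"noisy{i}", tuple((d, p, False) for d, p in zip(doses, noisy))
        )
        fit = fit_dose_response(s, baseline=100.0, fix_slope=1.0, loss="log")
        n_within += 0.5 <= fit.ec50_um / ec50 <= 2.0
    return {
        "n_curves": n_curves,
        "max_rel_err_noise_free": max_err_free,
        "frac_within_twofold_noisy": n_within / n_curves,
    }


def cox_recovery(
    seed: int,
    n_replicates: int = 100,
    n_patients: int = 20000,
    true_hr: float = 0.75,
) -> dict:
    """Cox hazard-ratio recovery: bias and 95% CI coverage.

    Unconfounded two-arm design (exposure a fair coin), exponential event
    times at 0.06 events/person-year baseline, 10-year administrative
    censoring (~40% events).
    """
    rng = np.random.default_rng(seed)
    hrs, covered, events = [], 0, []
    for _ in range(n_replicates):
        cfg = CohortSimConfig(
            n_patients=n_patients,
            true_hr=true_hr,
            confounders=(),
            exposure_intercept=0.0,
            baseline_hazard=0.06,
            max_followup_years=10.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        rows = simulate_survival_rows(cfg)
        est = cs.fit_cox(rows)
        hrs.append(est.hr)
        covered += est.ci_low <= true_hr <= est.ci_high
        events.append(rows["event"].mean())
    return {
        "n_replicates": n_replicates,
        "n_patients": n_patients,
        "true_hr": true_hr,
        "mean_hr": float(np.mean(hrs)),
        "ci_coverage": covered / n_replicates,
        "mean_event_fraction": float(np.mean(events)),
    }


def deconfounding_study(seed: int, n_seeds: int = 10, caliper_sd: float = 0.05) -> dict:
    """Crude vs IPW vs matched hazard ratios under planted confounding.

    The default cohort conditions plant a strong binary confounder (an
    asthma-like indicator driving both exposure and outcome) plus a milder
    continuous one, at true HR 0.75.  Reports per-seed estimates, the
    smallest crude inflation, the largest adjusted deviation from truth and
    the worst post-adjustment standardized mean difference.
    """
    rng = np.random.default_rng(seed)
    crude, ipw, matched, smds = [], [], [], []
    true_hr = None
    for _ in range(n_seeds):
        rows = simulate_survival_rows(
            CohortSimConfig(seed=int(rng.integers(2**31 - 1)))
        )
        true_hr = rows.attrs["true_hr"]
        rep = cs.study_report(rows, design="both", caliper_sd=caliper_sd)
        crude.append(rep["crude"]["hr"])
        ipw.append(rep["estimates"]["IPW"]["hr"])
        matched.append(rep["estimates"]["matched"]["hr"])
        smds.append(
            max(
                abs(b["smd_after"])
                for design in rep["balance"]
                for b in rep["balance"][design]
            )
        )
    return {
        "true_hr": true_hr,
        "crude_hr": crude,
        "ipw_hr": ipw,
        "matched_hr": matched,
        "min_crude_inflation": min(c / true_hr for c in crude),
        "max_ipw_rel_dev": max(abs(h / true_hr - 1) for h in ipw),
        "max_matched_rel_dev": max(abs(h / true_hr - 1) for h in matched),
        "max_smd_after": max(smds),
    }


def regression_ranking(seed: int, n_seeds: int = 20, n_drugs_per_group: int = 100) -> dict:
    """Planted discriminative gene: how often it tops its group's ranking.

    Each replicate simulates drug networks where one gene appears in 90% of
    "decrease"-group drugs and 10% of others over a 500-gene universe, runs
    the one-hot encoding and the one-vs-rest logistic ranking, and checks
    whether the planted gene holds rank 1 for its group.
    """
    rng = np.random.default_rng(seed)
    planted = "G00001"
    successes = 0
    for _ in range(n_seeds):
        cfg = NetworkSimConfig(
            n_drugs={g: n_drugs_per_group for g in ("increase", "decrease", "no_effect")},
            gene_universe_size=500,
            planted_genes={planted: {"decrease": 0.9}},
            background_presence=0.1,
            seed=int(rng.integers(2**31 - 1)),
        )
        nets = gen_network_tables(cfg)
        overlaps = disease_gene_overlap(nets, set(cfg.universe()))
        gene_order = sorted(set().union(*overlaps.values()))
        matrix = one_hot_matrix(overlaps, gene_order)
        table = group_gene_regression(matrix, nets.drug_groups)
        top = table[(table["group"] == "decrease") & (table["rank"] == 1)]
        successes += top["gene"].iloc[0] == planted
    return {"n_seeds": n_seeds, "n_top_ranked": successes}


def hypergeom_enumeration_check(max_n: int = 12) -> dict:
    """Exhaustive subset-enumeration oracle for the hypergeometric tail.

    For every (N <= max_n, B <= N, n <= N, b), lists all C(N, n) target
    draws, counts those containing at least b of the B marked genes, and
    compares the exact ratio with the computed tail probability.
    """
    worst = 0.0
    n_checked = 0
    for N in range(1, max_n + 1):
        items = tuple(range(N))
        for B in range(0, N + 1):
            marked = set(range(B))
            for n in range(0, N + 1):
                tallies = np.zeros(n + 1, dtype=np.int64)
                total = 0
                for draw in itertools.combinations(items, n):
                    tallies[len(marked.intersection(draw))] += 1
                    total += 1
                # tail counts for every feasible b at once
                tail = np.cumsum(tallies[::-1])[::-1]
                for b in range(0, min(n, B) + 1):
                    p = hypergeom_tail(EnrichmentCounts(N, B, n, b))
                    exact = tail[b] / total
                    worst = max(worst, abs(p - exact))
                    n_checked += 1
    return {"n_checked": n_checked, "max_abs_error": worst}
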