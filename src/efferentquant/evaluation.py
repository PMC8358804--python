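"""Self-validation suite: property and simulation checks with known truth.

Each function here recomputes one verifiable quantity from scratch by
running the package against an independent oracle — a brute-force scan, a
closed form, an enumeration, or simulator ground truth — and returns the
measured value(s).  The test suite asserts on these; the acceptance script
reports them.  Oracles are deliberately naive (per-sample loops, full
enumeration) so they share no code path with the implementation they check.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from .abr import Waveform, baseline_stats, detect_response, estimate_threshold
from .cochleogram import (
    RAT_MAP,
    SpiralTrace,
    frequency_to_place,
    locate_frequency_frames,
    place_to_frequency,
)
from .pipeline import PipelineConfig, run_pipeline
from .quant import (
    ImageFrame,
    default_calibration,
    field_od_stats,
    normalized_od,
    segment_buttons,
)
from .stats import anova_oneway_posthoc, friedman_statistic, mann_whitney
from .synthetic import (
    ABRSimConfig,
    ANALYSIS_FREQUENCIES_KHZ,
    CochleaSimConfig,
    StudyDesign,
    simulate_abr_series,
    simulate_cochlea_image,
)

__all__ = [
    "detection_oracle_agreement",
    "threshold_recovery",
    "false_positive_censoring",
    "segmentation_exactness",
    "normalization_identity",
    "place_map_checks",
    "profile_peak_recovery",
    "stats_oracles",
    "null_calibration",
    "end_to_end_reproduction",
]


# -- 1. detection oracle ----------------------------------------------------


def _brute_force_detect(w: Waveform, mean, sd, window, k, min_run) -> bool:
    """Naive per-sample scan: the independent oracle for detect_response."""
    run = best = 0
    for t, v in zip(w.time_ms, w.voltage_uv):
        if window[0] <= t <= window[1]:
            if sd == 0:
                if v != mean:
                    return True
                continue
            if abs(v - mean) > k * sd:
                run += 1
                best = max(best, run)
            else:
                run = 0
    if sd == 0:
        return False
    return best >= min_run


def detection_oracle_agreement(seed: int = 0, n: int = 1000) -> dict:
    """Fraction of random waveforms on which the detector matches a
    brute-force per-sample scan (expected: 1.0)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n):
        fs = rng.choice([12.2, 24.4, 48.8])
        t = np.arange(int(10 * fs) + 1) / fs
        v = rng.normal(0, rng.uniform(0.05, 2.0), size=t.size)
        if rng.random() < 0.5:  # inject a deterministic excursion sometimes
            i0 = rng.integers(0, t.size - 8)
            v[i0 : i0 + rng.integers(1, 8)] += rng.uniform(-8, 8)
        w = Waveform(time_ms=t, voltage_uv=v, level_db=50.0)
        b = baseline_stats(w)
        k = rng.uniform(1.0, 3.0)
        m = int(rng.integers(1, 6))
        ours = bool(detect_response(w, b, k=k, min_run=m))
        oracle = _brute_force_detect(w, b.mean, b.sd, (1.4, 5.0), k, m)
        agree += ours == oracle
    return {"agreement": agree / n, "n": n}


# -- 2/3. threshold recovery and false-positive control ---------------------


def threshold_recovery(seed: int = 0, n: int = 200) -> dict:
    """Recovery of known thresholds drawn from {20..60} dB under the default
    noise model, plus exactness in the noiseless limit."""
    rng = np.random.default_rng(seed)
    within = exact_noiseless = 0
    for i in range(n):
        truth = float(rng.choice([20, 30, 40, 50, 60]))
        cfg = ABRSimConfig(true_threshold_db=truth, seed=int(rng.integers(2**31 - 1)))
        series, _ = simulate_abr_series(cfg)
        est = estimate_threshold(series)
        if not est.censored and abs(est.threshold_db - truth) <= 10.0:
            within += 1
        cfg0 = dataclasses.replace(cfg, noise_sd_uv=0.0)
        series0, _ = simulate_abr_series(cfg0)
        est0 = estimate_threshold(series0)
        if not est0.censored and est0.threshold_db == truth:
            exact_noiseless += 1
    return {
        "within_one_step": within / n,
        "noiseless_exact": exact_noiseless / n,
        "n": n,
    }


def false_positive_censoring(seed: int = 0, n: int = 200) -> dict:
    """Fraction of all-noise series correctly censored at the top level."""
    rng = np.random.default_rng(seed)
    censored = 0
    for _ in range(n):
        cfg = ABRSimConfig(
            true_threshold_db=100.0,
            amplitude_growth_uv_per_db=0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        series, _ = simulate_abr_series(cfg)
        censored += estimate_threshold(series).censored
    return {"censored": censored / n, "n": n}


# -- 4. segmentation exactness ----------------------------------------------


def segmentation_exactness(seed: int = 0, n_frames: int = 100) -> dict:
    """Count conservation and area accuracy on non-touching synthetic disks.

    Frames use circular buttons with drawn radius >= 2 µm so the drawn area
    is an analytic truth; measured areas come from the pixel counts of the
    segmented components matched to ground truth by nearest centroid.
    """
    rng = np.random.default_rng(seed)
    exact = 0
    max_rel_err = 0.0
    for _ in range(n_frames):
        cfg = CochleaSimConfig(
            circular_buttons=True,
            size_profile=dataclasses.replace(
                CochleaSimConfig().size_profile,
                peak_area_um2=20.0,
                floor_area_um2=16.0,
                area_sd_um2=2.0,
                min_area_um2=float(np.pi * 4.0),  # radius >= 2 µm
            ),
            button_density_per_10k_um2=30.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        frame, truth = simulate_cochlea_image(cfg, 11.3)
        segs = segment_buttons(frame, threshold=150.0, area_limits_um2=(0.5, 200.0))
        if len(segs) == truth.n_buttons:
            exact += 1
        for b in truth.buttons:
            cy, cx = b["center_px"]
            seg = min(
                segs,
                key=lambda s: (s.centroid[0] - cy) ** 2 + (s.centroid[1] - cx) ** 2,
            )
            rel = abs(seg.area_um2 - b["area_um2"]) / b["area_um2"]
            max_rel_err = max(max_rel_err, rel)

    # a single 5x5-pixel square at 0.2 µm pitch must measure exactly 1 µm²
    img = np.full((50, 50), 220, dtype=np.uint8)
    img[10:15, 20:25] = 60
    sq = segment_buttons(ImageFrame(pixels=img), threshold=128)
    square_area = sq[0].area_um2 if len(sq) == 1 else float("nan")
    return {
        "count_exact": exact / n_frames,
        "disk_area_max_rel_err": max_rel_err,
        "square_5x5_area_um2": square_area,
        "n": n_frames,
    }


# -- 5. normalised-OD identity ----------------------------------------------


def normalization_identity(seed: int = 0) -> dict:
    """Self-normalisation: the field's own pixel ODs must z-score to mean 0,
    SD 1; a button at the field mean scores 0, at mean + 2 SD scores 2."""
    rng = np.random.default_rng(seed)
    img = rng.integers(40, 240, size=(200, 200), dtype=np.uint8)
    frame = ImageFrame(pixels=np.asarray(img, dtype=np.uint8))
    cal = default_calibration()
    fs = field_od_stats(frame, cal)
    z = np.array([normalized_od(od, fs) for od in cal(frame.pixels.ravel().astype(float))])
    return {
        "mean_abs": abs(float(np.mean(z))),
        "sd_err": abs(float(np.std(z)) - 1.0),
        "at_mean": normalized_od(fs.mean_od, fs),
        "at_mean_plus_2sd": normalized_od(fs.mean_od + 2 * fs.sd_od, fs),
    }


# -- 6. place map -----------------------------------------------------------


def place_map_checks(seed: int = 0, n: int = 1000) -> dict:
    """Round-trip identity of the map and its inverse, frame ordering along
    the trace, and scale invariance of frequency assignment."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, size=n)
    rt = np.abs(frequency_to_place(place_to_frequency(x, RAT_MAP), RAT_MAP) - x)
    # a gently curved digitised trace, ~9.4 mm long
    s = np.linspace(0, 1, 400)
    pts = np.column_stack([9000 * s, 1500 * np.sin(2 * np.pi * s)])
    trace = SpiralTrace(pts)
    frames = locate_frequency_frames(trace, ANALYSIS_FREQUENCIES_KHZ, RAT_MAP)
    arcs = [fr.arc_position_um for fr in frames]
    ordered = all(a < b for a, b in zip(arcs, arcs[1:]))
    trace2 = SpiralTrace(pts * 2.0)
    frames2 = locate_frequency_frames(trace2, ANALYSIS_FREQUENCIES_KHZ, RAT_MAP)
    scale_err = max(
        abs(f2.arc_position_um - 2.0 * f1.arc_position_um)
        for f1, f2 in zip(frames, frames2)
    )
    return {
        "roundtrip_max_err": float(rt.max()),
        "frames_ordered": bool(ordered),
        "scale_invariance_err_um": float(scale_err),
        "n": n,
    }


# -- 7. cochleotopic profile recovery ---------------------------------------


def profile_peak_recovery(seed: int = 0, n_cochleae: int = 100) -> dict:
    """Fraction of simulated sham cochleae whose measured mean-area argmax
    over the six frequency regions falls at 11.3 kHz."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cochleae):
        cfg = CochleaSimConfig(seed=int(rng.integers(2**31 - 1)))
        means = []
        for f in ANALYSIS_FREQUENCIES_KHZ:
            frame, _ = simulate_cochlea_image(cfg, f, seed=int(rng.integers(2**31 - 1)))
            segs = segment_buttons(frame, threshold=150.0)
            means.append(np.mean([s.area_um2 for s in segs]) if segs else -np.inf)
        hits += ANALYSIS_FREQUENCIES_KHZ[int(np.argmax(means))] == 11.3
    return {"peak_at_11p3": hits / n_cochleae, "n": n_cochleae}


# -- 8. statistics oracles --------------------------------------------------


def _mw_enumeration_oracle(a, b) -> float:
    """Two-sided exact Mann-Whitney p by brute-force enumeration of all
    placements of sample a among the pooled values."""
    pooled = np.concatenate([a, b])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    us = []
    for comb in itertools.combinations(range(n), n_a):
        u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2
        us.append(u)
    us = np.asarray(us)
    tol = 1e-9
    return min(1.0, 2.0 * min(np.mean(us <= u_obs + tol), np.mean(us >= u_obs - tol)))


def _friedman_rank_oracle(data) -> float:
    """Friedman statistic from first principles: rank each block by sorting
    with explicit midrank ties, then apply the tie-corrected quotient."""
    n, k = data.shape
    R = np.zeros_like(data, dtype=float)
    for i in range(n):
        row = data[i]
        order = np.argsort(row, kind="mergesort")
        ranks = np.empty(k)
        j = 0
        while j < k:
            j2 = j
            while j2 + 1 < k and row[order[j2 + 1]] == row[order[j]]:
                j2 += 1
            ranks[order[j : j2 + 1]] = (j + j2) / 2.0 + 1.0
            j = j2 + 1
        R[i] = ranks
    rj = R.sum(axis=0)
    denom = (R**2).sum() - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:
        return 0.0
    return float((k - 1) * ((rj - n * (k + 1) / 2.0) ** 2).sum() / denom)


def _gh_montecarlo_p(q_obs: float, k: int, df: float, n_draws: int, rng) -> float:
    """Monte-Carlo studentized-range tail probability: draws of
    (max-min of k standard normals) / sqrt(chi2_df / df)."""
    block = 200_000
    exceed = total = 0
    while total < n_draws:
        m = min(block, n_draws - total)
        z = rng.standard_normal((m, k))
        rng_range = z.max(axis=1) - z.min(axis=1)
        s = np.sqrt(rng.chisquare(df, size=m) / df)
        exceed += int(np.sum(rng_range / s >= q_obs))
        total += m
    return exceed / total


def stats_oracles(seed: int = 0, mc_draws: int = 1_000_000) -> dict:
    """Exactness of the statistical battery against independent oracles."""
    rng = np.random.default_rng(seed)

    # Mann-Whitney: canonical example and random small samples
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    mw_u0 = res.statistic
    mw_p = res.p_value
    mw_agree = 0
    n_mw = 60
    for _ in range(n_mw):
        na, nb = rng.integers(2, 9), rng.integers(2, 9)
        a = rng.integers(0, 6, size=na).astype(float)
        b = rng.integers(0, 6, size=nb).astype(float)
        ours = mann_whitney(a, b, mode="exact").p_value
        oracle = _mw_enumeration_oracle(a, b)
        mw_agree += abs(ours - oracle) < 1e-12
    # Friedman vs rank oracle on random tables (with ties)
    fr_max = 0.0
    for _ in range(100):
        n, k = rng.integers(3, 10), rng.integers(3, 7)
        data = rng.integers(0, 5, size=(n, k)).astype(float)
        ours, _, _ = friedman_statistic(data)
        fr_max = max(fr_max, abs(ours - _friedman_rank_oracle(data)))
    # two-group ANOVA F == t^2
    a = rng.normal(0, 1, 8)
    b = rng.normal(0.5, 1, 11)
    fres = anova_oneway_posthoc({"a": a, "b": b}, posthoc="bonferroni")
    t = sps.ttest_ind(a, b).statistic
    f_vs_t2 = abs(fres.statistic - t**2)
    # Games-Howell vs Monte-Carlo studentized range
    groups = {
        "g1": rng.normal(0.0, 1.0, 9),
        "g2": rng.normal(0.8, 2.0, 7),
        "g3": rng.normal(0.3, 0.5, 12),
    }
    gh = anova_oneway_posthoc(groups, posthoc="games_howell").posthoc
    gh_err = 0.0
    for _, row in gh.iterrows():
        p_mc = _gh_montecarlo_p(row["statistic"], len(groups), row["df"], mc_draws, rng)
        gh_err = max(gh_err, abs(row["p_adj"] - p_mc))
    return {
        "mw_u_123_456": float(mw_u0),
        "mw_p_123_456": float(mw_p),
        "mw_exact_oracle_agreement": mw_agree / n_mw,
        "friedman_oracle_max_abs_diff": fr_max,
        "anova_f_minus_t2": float(f_vs_t2),
        "games_howell_mc_max_abs_diff": float(gh_err),
        "mc_draws": mc_draws,
    }


# -- 9. null calibration ----------------------------------------------------


def null_calibration(seed: int = 0, reps: int = 1000) -> dict:
    """Empirical type-I error of each test under its own simulated null."""
    rng = np.random.default_rng(seed)
    from .stats import anova_twoway

    rej = {"friedman": 0, "mann_whitney": 0, "anova_oneway": 0, "anova_twoway": 0, "pearson": 0}
    for _ in range(reps):
        # Friedman: 6 subjects x 6 timepoints, exchangeable normal
        data = rng.normal(size=(6, 6))
        _, df, p = friedman_statistic(data)
        rej["friedman"] += p < 0.05
        # Mann-Whitney exact, n = 6 + 6
        p = mann_whitney(rng.normal(size=6), rng.normal(size=6)).p_value
        rej["mann_whitney"] += p < 0.05
        # one-way ANOVA, 3 groups of 6
        p = anova_oneway_posthoc(
            {g: rng.normal(size=6) for g in "abc"}, posthoc="bonferroni"
        ).p_value
        rej["anova_oneway"] += p < 0.05
        # Pearson, n = 30
        p = sps.pearsonr(rng.normal(size=30), rng.normal(size=30)).pvalue
        rej["pearson"] += p < 0.05
    # two-way ANOVA null is costlier; same rep count, vectorised data draw
    for _ in range(reps):
        df2 = pd.DataFrame(
            {
                "y": rng.normal(size=36),
                "a": np.repeat(["g1", "g2", "g3"], 12),
                "b": np.tile(np.repeat(["f1", "f2"], 6), 3),
            }
        )
        p = anova_twoway(df2, "y", "a", "b").p_value
        rej["anova_twoway"] += p < 0.05
    out = {k: v / reps for k, v in rej.items()}
    out["mc_se"] = float(np.sqrt(0.05 * 0.95 / reps))
    out["n"] = reps
    return out


# -- 10. end-to-end qualitative reproduction --------------------------------


def end_to_end_reproduction(seed: int = 0, reps: int = 50, n_per_group: int = 6) -> dict:
    """Does the full pipeline reproduce the study's qualitative pattern?

    Per replicate study: (a) the trauma group's day-13 threshold elevation is
    significant in the Friedman post hoc, (b) the stimulated-then-traumatised
    group's day-13 contrast is not, and (c) the day-26 mean normalised OD is
    higher under prior stimulation than under trauma alone.
    """
    rng = np.random.default_rng(seed)
    ok = at_sig = esat_ns = od_order = 0
    for _ in range(reps):
        cfg = PipelineConfig(
            design=StudyDesign(n_per_group=n_per_group, seed=0),
            seed=int(rng.integers(2**31 - 1)),
        )
        bundle = run_pipeline(cfg)
        ph_at = bundle.stat_details["friedman_AT"].posthoc
        p_at = float(ph_at.loc[ph_at["level_b"] == 13, "p_adj"].iloc[0])
        ph_es = bundle.stat_details["friedman_ES_AT"].posthoc
        p_es = float(ph_es.loc[ph_es["level_b"] == 13, "p_adj"].iloc[0])
        btn = bundle.buttons
        od_at = btn.loc[btn["condition"] == "AT+14d", "norm_od"].mean()
        od_es = btn.loc[btn["condition"] == "ES_AT+14d", "norm_od"].mean()
        a, b, c = p_at < 0.05, p_es >= 0.05, od_es > od_at
        at_sig += a
        esat_ns += b
        od_order += c
        ok += a and b and c
    return {
        "all_conditions": ok / reps,
        "at_day13_significant": at_sig / reps,
        "esat_day13_nonsignificant": esat_ns / reps,
        "day26_od_order": od_order / reps,
        "n": reps,
    }
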