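"""Stage orchestration: synthetic runs and the consolidated report.

Each stage generates its synthetic cohort under the configured study
conditions, runs the corresponding analysis, writes its tabular artifacts
(CSV) plus a JSON report section into the run directory, and returns the
section.  ``run_all`` + ``consolidate`` produce one report with a row per
figure-level quantity (n, mean, SEM), Welch's t for two-group comparisons
and paired t for within-experiment pre/post contrasts.

Determinism: the run seed fans out to one fixed substream per stage, and
report JSON is serialized with sorted keys, so identical configurations
produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import census as cen
from . import clustering as clu
from . import ephys as eph
from . import lfp as lf
from . import morphology as mor
from . import puncta as pun
from . import synth
from .config import STAGES
from .stats import group_summary, paired_t, welch_t

logger = logging.getLogger(__name__)

__all__ = ["run_stage", "run_all", "consolidate", "STAGES"]

_STAGE_STREAM = {name: i for i, name in enumerate(STAGES)}


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(seed).spawn(len(STAGES))[_STAGE_STREAM[stage]]
    return int(ss.generate_state(1)[0] % (2**31))


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Stages

def _stage_morpho(cfg: dict, out: Path, seed: int) -> dict:
    p = cfg["morpho"]
    trees, labels = synth.gen_cohort_trees(p["n_per_class"], seed=seed)
    idx_cfg = mor.IndexConfig(prominence_frac=p["prominence_frac"], d0_um=p["d0_um"])
    rows, sholl_rows = [], []
    for i, (tree, lab) in enumerate(zip(trees, labels)):
        apical = mor.extract_apical(tree)
        f = mor.lri_ori(apical, idx_cfg)
        rows.append(
            {"cell_id": f"cell{i:03d}", "lri": f.lri, "ori": f.ori,
             "first_bif_um": f.first_bifurcation_um,
             "total_apical_um": f.total_apical_length_um,
             "n_bifurcations": f.bifurcation_count,
             "defined": f.defined, "true_class": "complex" if lab == 0 else "simple"}
        )
        prof = mor.sholl(apical, p["sholl_step_um"])
        for r, n in zip(prof.radii, prof.intersections):
            sholl_rows.append(
                {"cell_id": f"cell{i:03d}", "radius_um": float(r),
                 "n_intersections": int(n)}
            )
    feats = pd.DataFrame(rows).set_index("cell_id")
    pd.DataFrame(sholl_rows).to_csv(out / "sholl.csv", index=False)
    feats.to_csv(out / "morpho_features.csv")

    usable = feats[feats.defined]
    excluded = [
        {"cell_id": cid, "rule": "undefined LRI/ORI (unbranched tree)"}
        for cid in feats.index[~feats.defined]
    ]
    res = clu.kmeans(usable[["lri", "ori"]], 2, seed=seed, n_init=p["kmeans_n_init"])
    truth = (usable["true_class"] == "simple").astype(int).to_numpy()
    purity = float(max((res.labels == truth).mean(), (res.labels != truth).mean()))

    fb_c = usable.loc[usable.true_class == "complex", "first_bif_um"]
    fb_s = usable.loc[usable.true_class == "simple", "first_bif_um"]
    t, pval = welch_t(fb_c, fb_s)

    sholl_df = pd.DataFrame(sholl_rows).merge(
        feats[["true_class"]], left_on="cell_id", right_index=True
    )
    prof_c = (
        sholl_df[sholl_df.true_class == "complex"]
        .groupby("radius_um")["n_intersections"].mean()
    )
    return {
        "kmeans_label_purity": purity,
        "cluster_centers_lri_ori": res.centers.tolist(),
        "wss": res.wss,
        "first_bif_um": {
            "complex": group_summary(fb_c),
            "simple": group_summary(fb_s),
            "welch_t": t, "p": pval,
        },
        "sholl_complex_peak": {
            "count": float(prof_c.max()),
            "radius_um": float(prof_c.idxmax()),
        },
        "excluded": excluded,
    }


def _stage_cluster(cfg: dict, out: Path, seed: int) -> dict:
    p = cfg["cluster"]
    df, truth = synth.gen_physiology(p["n_per_class"], seed=seed)
    df.to_csv(out / "physiology_features.csv")
    pca = clu.zscore_pca(df, n_components=p["n_components"])
    res = clu.kmeans(pca.scores, 2, seed=seed, n_init=p["kmeans_n_init"])
    pca.scores.assign(cluster=res.labels).to_csv(out / "physiology_scores.csv")
    conc = clu.concordance(truth, res.labels)
    elbow = clu.elbow_wss(pca.scores, p["elbow_k_max"], seed=seed)
    return {
        "pca_explained_variance_ratio": pca.explained_variance_ratio.tolist(),
        "agreement_with_truth": conc.agreement,
        "contingency": conc.table.to_dict(),
        "wss_curve": [[int(k), float(w)] for k, w in elbow],
        "excluded": [
            {"cell_id": str(c), "rule": "missing clustering feature"}
            for c in pca.dropped_rows
        ],
    }


def _stage_ephys(cfg: dict, out: Path, seed: int) -> dict:
    p = cfg["ephys"]
    rng = np.random.default_rng(seed)

    sweep = synth.gen_rc_sag_sweep(rin_MOhm=p["rin_MOhm"], sag_index=p["sag_index"])
    rin_meas = eph.input_resistance(sweep)
    sag_meas = eph.sag_index(sweep)
    spikes = eph.spike_train_features(synth.gen_spike_sweep())

    washin_rows, pct_by_class, excluded = [], {}, []
    for cls, factor in p["washin_factors"].items():
        pcts = []
        for i in range(p["washin_n_cells"]):
            series = synth.gen_washin(
                drug_factor=factor, event_cv=p["event_cv"],
                seed=int(rng.integers(2**31)), drug_label="conotoxin",
            )
            pct = eph.washin_percent_of_baseline(series)
            included = eph.washin_inclusion(series)
            cell = f"{cls}{i:02d}"
            washin_rows.append(
                {"cell_id": cell, "class": cls, "percent_of_baseline": pct,
                 "included": included}
            )
            # the >=30%-reduction rule gates drug-efficacy QC; flagged cells
            # are logged but the toxin group summaries keep every cell
            pcts.append(pct)
            if not included:
                excluded.append(
                    {"cell_id": cell, "rule": "wash-in reduced IPSC by < 30% (flag only)"}
                )
        pct_by_class[cls] = pcts
    pd.DataFrame(washin_rows).to_csv(out / "washin.csv", index=False)
    t_w, p_w = welch_t(pct_by_class["complex"], pct_by_class["simple"])

    ie_rows, ie_by_class = [], {}
    for cls, mean_ratio in p["ie_ratio_means"].items():
        vals = []
        for i in range(p["ie_n_cells"]):
            epsc = max(40.0, float(rng.normal(100.0, 15.0)))
            # mean-corrected lognormal: E[ratio] = mean_ratio exactly
            ratio = float(rng.lognormal(np.log(mean_ratio) - 0.3**2 / 2, 0.3))
            mono = float(rng.uniform(50.0, 120.0))
            r = eph.ie_ratio(epsc, mono + ratio * epsc, mono)
            vals.append(r.ie_ratio)
            ie_rows.append({"cell_id": f"{cls}{i:02d}", "class": cls,
                            "ie_ratio": r.ie_ratio})
        ie_by_class[cls] = vals
    pd.DataFrame(ie_rows).to_csv(out / "ie_ratio.csv", index=False)
    t_ie, p_ie = welch_t(ie_by_class["complex"], ie_by_class["simple"])

    return {
        "intrinsic_recovery": {
            "rin_MOhm": {"true": p["rin_MOhm"], "measured": rin_meas},
            "sag_index": {"true": p["sag_index"], "measured": sag_meas},
            "spike_threshold_mV": spikes.spike_threshold_mV,
            "adaptation_ratio": spikes.adaptation_ratio,
        },
        "washin_percent_of_baseline": {
            cls: group_summary(v) for cls, v in pct_by_class.items()
        } | {"welch_t": t_w, "p": p_w},
        "ie_ratio": {cls: group_summary(v) for cls, v in ie_by_class.items()}
        | {"welch_t": t_ie, "p": p_ie},
        "excluded": excluded,
    }


def _stage_puncta(cfg: dict, out: Path, seed: int) -> dict:
    p = cfg["puncta"]
    rng = np.random.default_rng(seed)
    rows, section = [], {}
    for stain, bias in p["biases"].items():
        ratios = []
        for i in range(p["n_scenes"]):
            scene = synth.gen_scene(
                bias=bias, puncta_rate_per_soma=p["puncta_rate_per_soma"],
                seed=int(rng.integers(2**31)),
            )
            res = pun.quantify_scene(scene)
            ratios.append(res.bias_ratio)
            rows.append({"stain": stain, "scene": i, "bias_ratio": res.bias_ratio,
                         "total_pos": res.total_pos, "total_neg": res.total_neg})
        section[stain] = group_summary(ratios) | {"true_bias": bias}
    pd.DataFrame(rows).to_csv(out / "innervation_bias.csv", index=False)
    section["excluded"] = []
    return section


def _stage_lfp(cfg: dict, out: Path, seed: int) -> dict:
    p = cfg["lfp"]
    rng = np.random.default_rng(seed)
    band = tuple(p["gamma_band_hz"])
    section, rows = {}, []
    for gt in cfg["genotypes"]:
        peak_f, norm_p, lags, xmax = [], [], [], []
        pre_vals, post_vals = [], []
        for i in range(p["n_experiments"]):
            exp_id = f"{gt}{i:02d}"
            pre, post = synth.gen_lfp(
                f0_hz=p["f0_hz"][gt], lag_ms=p["lag_ms"][gt],
                drug_power_factor=p["drug_power_factor"][gt],
                duration_s=p["duration_s"], snr=p["snr"],
                seed=int(rng.integers(2**31)), experiment_id=exp_id,
            )
            fs = pre.sampling_rate_hz
            d_pre = lf.preprocess(pre.channel_deep, fs)
            s_pre = lf.preprocess(pre.channel_superficial, fs)
            d_post = lf.preprocess(post.channel_deep, fs)
            sp_pre = lf.power_spectrum(d_pre, fs, band_hz=band, experiment_id=exp_id)
            sp_post = lf.power_spectrum(d_post, fs, band_hz=band, experiment_id=exp_id)
            xc = lf.xcorr_windowed(d_pre, s_pre, fs, max_lag_ms=p["max_lag_ms"])
            peak_f.append(sp_pre.peak_freq_hz)
            norm_p.append(lf.normalized_peak_power(sp_pre, sp_post))
            lags.append(xc.lag_at_max_ms)
            xmax.append(xc.max_value)
            pre_vals.append(sp_pre.peak_power_vrms)
            post_vals.append(sp_post.peak_power_vrms)
            rows.append({"experiment": exp_id, "genotype": gt,
                         "peak_freq_hz": sp_pre.peak_freq_hz,
                         "norm_peak_power": norm_p[-1],
                         "xcorr_max": xc.max_value, "lag_ms": xc.lag_at_max_ms})
        t_pp, p_pp = paired_t(pre_vals, post_vals)
        section[gt] = {
            "peak_freq_hz": group_summary(peak_f),
            "norm_peak_power": group_summary(norm_p) | {"paired_t": t_pp, "p": p_pp},
            "lag_ms": group_summary(lags),
            "xcorr_max": group_summary(xmax),
        }
    pd.DataFrame(rows).to_csv(out / "lfp_summary.csv", index=False)
    section["excluded"] = []
    return section


def _stage_census(cfg: dict, out: Path, seed: int) -> dict:
    p = cfg["census"]
    rng = np.random.default_rng(seed)
    section, hist_rows = {}, []
    for gt in cfg["genotypes"]:
        cells, rois, truth = synth.gen_census(
            p_marker=tuple(p["p_marker"][gt]),
            n_cells_per_band=tuple(p["n_cells_per_band"]),
            seed=int(rng.integers(2**31)),
        )
        frac = cen.band_marker_fraction(cells, rois, "calbindin")
        edges, values = cen.position_histogram(
            cells.loc[cells.calbindin, "depth_pcl_um"], bin_um=p["bin_um"]
        )
        for e, v in zip(edges[:-1], values):
            hist_rows.append({"genotype": gt, "bin_left_um": float(e),
                              "fraction": float(v)})
        section[gt] = {
            "calbindin_fraction": {
                "deep": frac["deep"], "superficial": frac["superficial"],
                "true_deep": truth["p_deep"], "true_superficial": truth["p_superficial"],
            },
        }
    # birth-dating colocalization at the latest timepoint
    n, prob = p["coloc_n"], p["coloc_p"]
    marked = [f"n{i}" for i in range(n)]
    costained = [m for m in marked if rng.random() < prob]
    section["colocalization_fraction"] = {
        "value": cen.colocalization_fraction(marked, costained),
        "true_p": prob, "n": n,
    }
    pd.DataFrame(hist_rows).to_csv(out / "census_histograms.csv", index=False)
    section["excluded"] = []
    return section


_STAGE_FN = {
    "morpho": _stage_morpho,
    "cluster": _stage_cluster,
    "ephys": _stage_ephys,
    "puncta": _stage_puncta,
    "lfp": _stage_lfp,
    "census": _stage_census,
}


def run_stage(stage: str, cfg: dict, out_dir) -> dict:
    """Run one pipeline stage into ``out_dir``; returns its report section."""
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(_STAGE_FN)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = _stage_seed(cfg["seed"], stage)
    logger.info("running stage %s (substream seed %d)", stage, seed)
    section = _STAGE_FN[stage](cfg, out, seed)
    for exc in section.get("excluded", []):
        logger.info("excluded %s: %s", exc.get("cell_id", "?"), exc.get("rule", "?"))
    section["parameters"] = cfg[stage]
    section["seed"] = cfg["seed"]
    _write_json(section, out / f"report_{stage}.json")
    return section


def run_all(cfg: dict, out_dir) -> dict:
    """Run every stage and write the consolidated report."""
    out = Path(out_dir)
    report = {stage: run_stage(stage, cfg, out) for stage in STAGES}
    _write_json(report, out / "report.json")
    consolidate(out)
    return report


def consolidate(run_dir) -> pd.DataFrame:
    """Collect figure-level quantities from a run directory into one table.

    One row per (stage, quantity, group) with n, mean and SEM where the
    section provides them; partial runs are flagged, not fatal.
    """
    run = Path(run_dir)
    rows = []
    for stage in STAGES:
        path = run / f"report_{stage}.json"
        if not path.exists():
            rows.append({"stage": stage, "quantity": "(missing)", "group": "",
                         "n": None, "mean": None, "sem": None})
            continue
        section = json.loads(path.read_text())

        def walk(obj, trail):
            if isinstance(obj, dict):
                if {"n", "mean", "sem"} <= set(obj):
                    rows.append({"stage": stage, "quantity": ".".join(trail[:-1]) or trail[-1],
                                 "group": trail[-1], "n": obj["n"],
                                 "mean": obj["mean"], "sem": obj["sem"]})
                else:
                    for k, v in obj.items():
                        if k not in ("parameters", "excluded"):
                            walk(v, trail + [k])
            elif isinstance(obj, (int, float)) and trail[-1] != "seed":
                rows.append({"stage": stage, "quantity": ".".join(trail[:-1]),
                             "group": trail[-1], "n": None,
                             "mean": float(obj), "sem": None})

        walk(section, [])
    df = pd.DataFrame(rows)
    df.to_csv(run / "report_summary.csv", index=False)
    return df
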