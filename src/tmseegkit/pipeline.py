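"""End-to-end pipeline runner: schedule -> (synth or load) -> TEP/GMFP ->
TANOVA -> TFR/regression -> microstates.

Every output table is CSV with a metadata header line (package version,
config hash, seeds); metadata files are JSON.  Reruns with the same config
and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from .data_model import average_epochs, baseline_correct
from .microstates import (backfit, canonical_templates, grand_mean_templates,
                          gmfp_peaks, modified_kmeans, ms_parameters,
                          ms_rm_anova, sort_templates)
from .stim_schedule import TACSParams, TBSParams, build_schedule, summarize
from .synth_data import (CohortConfig, RestingConfig, synth_resting_cohort,
                         synth_tep_cohort)
from .tanova import MapEnsemble, normalize_gmfp, tanova_series
from .tep_gmfp import bin_time_series, gmfp, per_bin_rm_anova
from .tfr import (DEFAULT_ROIS, change_score_regression, db_normalize,
                  morlet_decompose, roi_power, three_way_rm_anova, WaveletSpec)

log = logging.getLogger("tmseegkit")

_DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "results",
    "stages": {"schedule": True, "synth": True, "tep": True, "tanova": True,
               "tfr": True, "microstates": True},
    "schedule": {},  # TACSParams/TBSParams overrides: {"tacs": {...}, "tbs": {...}}
    "synth": {"n_subjects": 8, "n_trials": 6, "srate": 500.0},
    "resting": {"n_subjects": 8, "duration_s": 20.0, "srate": 250.0},
    "tep": {"baseline_ms": [-40.0, -2.0], "bin_width_ms": 20.0,
            "bin_range_ms": [-20.0, 400.0], "from_ms": 40.0,
            "intensity": "sub"},
    "tanova": {"n_perm": 250, "alpha": 0.05},
    "tfr": {"baseline_ms": [-400.0, -200.0]},
    "microstates": {"k": 4, "restarts": 5},
}


def merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(_DEFAULT_CONFIG))
    if not user:
        return cfg
    for key, val in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            for k2, v2 in val.items():
                if key in ("stages",) and k2 not in cfg[key]:
                    raise ValueError(f"unknown stage {k2!r}")
                cfg[key][k2] = v2
        else:
            cfg[key] = val
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: str, cfg: dict) -> None:
    header = (f"# tmseegkit v{__version__} config={_config_hash(cfg)} "
              f"seed={cfg['seed']}\n")
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10g")


def _write_json(obj, path: str, cfg: dict) -> None:
    payload = {"meta": {"version": __version__,
                        "config": _config_hash(cfg), "seed": cfg["seed"]},
               "result": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def run_pipeline(user_config: dict | None = None,
                 out_dir: str | None = None) -> dict:
    """Execute the configured stages; returns a bundle of results."""
    cfg = merge_config(user_config)
    out = out_dir or cfg["out_dir"]
    os.makedirs(out, exist_ok=True)
    seed = int(cfg["seed"])
    bundle: dict = {}
    stages = cfg["stages"]

    def stage(name):
        enabled = stages.get(name, False)
        log.info("stage %-12s %s", name, "run" if enabled else "skipped")
        return enabled

    try:
        if stage("schedule"):
            tacs = TACSParams(**cfg["schedule"].get("tacs", {}))
            tbs = TBSParams(**cfg["schedule"].get("tbs", {}))
            for mode in ("active", "sham"):
                sched = build_schedule(tacs, tbs, mode)
                _write_csv(sched.table(), os.path.join(out, f"schedule_{mode}.csv"),
                           cfg)
                _write_json(summarize(sched),
                            os.path.join(out, f"schedule_{mode}.json"), cfg)
                bundle[f"schedule_{mode}"] = sched

        dataset = None
        if stage("synth"):
            sy = dict(cfg["synth"])
            sy.setdefault("seed", seed)
            dataset = synth_tep_cohort(CohortConfig(**sy))
            _write_json(dataset.truth, os.path.join(out, "synth_truth.json"),
                        cfg)
            bundle["dataset"] = dataset

        binned = evoked_cells = None
        if stage("tep"):
            if dataset is None:
                raise RuntimeError(
                    "tep stage requires the synth stage (or loaded data); "
                    "enable stages.synth"
                )
            tep_cfg = cfg["tep"]
            intensity = tep_cfg["intensity"]
            binned, evoked_cells = {}, {}
            gmfp_rows = []
            for (s, c, t, inten), ep in dataset.epochs.items():
                if inten != intensity:
                    continue
                ev = average_epochs(
                    baseline_correct(ep, tuple(tep_cfg["baseline_ms"])))
                g = gmfp(ev)
                evoked_cells[(s, c, t)] = ev
                binned[(s, c, t)] = bin_time_series(
                    g, tep_cfg["bin_width_ms"], tuple(tep_cfg["bin_range_ms"]))
                for tm, val in zip(g.times_ms, g.values):
                    gmfp_rows.append({"subject": s, "session": c, "time": t,
                                      "t_ms": tm, "gmfp": val})
            _write_csv(pd.DataFrame(gmfp_rows),
                       os.path.join(out, "gmfp.csv"), cfg)
            table = per_bin_rm_anova(binned, from_ms=tep_cfg["from_ms"])
            _write_csv(table, os.path.join(out, "gmfp_bin_anova.csv"), cfg)
            bundle["gmfp_bin_anova"] = table

        if stage("tanova"):
            if evoked_cells is None:
                raise RuntimeError(
                    "tanova stage requires the tep stage; enable stages.tep"
                )
            tv = cfg["tanova"]
            subjects = sorted({k[0] for k in evoked_cells})
            tep_cfg = cfg["tep"]
            maps = []
            ref = None
            for s in subjects:
                block = []
                for t in ("pre", "post"):
                    row = []
                    for c in ("active", "sham"):
                        ev = evoked_cells[(s, c, t)]
                        bs = bin_time_series(ev, tep_cfg["bin_width_ms"],
                                             tuple(tep_cfg["bin_range_ms"]))
                        ref = bs
                        row.append(bs.bin_means.T)  # bins x channels
                    block.append(row)
                maps.append(block)
            ens = MapEnsemble(np.asarray(maps), ref.bin_centers_ms)
            res = tanova_series(normalize_gmfp(ens), n_perm=tv["n_perm"],
                                seed=seed, alpha=tv["alpha"])
            pdf = pd.DataFrame({"t_ms": res.times_ms,
                                **{f"p_{e}": res.p_series[e]
                                   for e in res.p_series}})
            _write_csv(pdf, os.path.join(out, "tanova_p.csv"), cfg)
            _write_json({"duration_threshold_ms": res.duration_threshold_ms,
                         "significant_periods": res.significant_periods,
                         "n_perm": res.n_perm},
                        os.path.join(out, "tanova_periods.json"), cfg)
            bundle["tanova"] = res

        if stage("tfr"):
            if dataset is None:
                raise RuntimeError(
                    "tfr stage requires the synth stage; enable stages.synth"
                )
            spec = WaveletSpec(f_max=min(70.0, 0.4 * cfg["synth"]["srate"]))
            rows = []
            for (s, c, t, inten), ep in dataset.epochs.items():
                tfr_db = db_normalize(
                    morlet_decompose(ep, spec),
                    tuple(cfg["tfr"]["baseline_ms"]))
                for band, roi in DEFAULT_ROIS.items():
                    rows.append({"subject": s, "session": c, "time": t,
                                 "intensity": inten, "band": band,
                                 "db": roi_power(tfr_db, roi,
                                                 dataset.montage.names)})
            roi_df = pd.DataFrame(rows)
            _write_csv(roi_df, os.path.join(out, "roi_power.csv"), cfg)
            anova_rows, reg_rows = [], []
            subjects = sorted(roi_df["subject"].unique())
            for band in DEFAULT_ROIS:
                sub = roi_df[roi_df["band"] == band]
                y = np.empty((len(subjects), 2, 2, 2))
                for si, s in enumerate(subjects):
                    for ti, t in enumerate(("pre", "post")):
                        for ci, c in enumerate(("active", "sham")):
                            for ii, inten in enumerate(("sub", "supra")):
                                v = sub[(sub.subject == s) & (sub.time == t)
                                        & (sub.session == c)
                                        & (sub.intensity == inten)]["db"]
                                y[si, ti, ci, ii] = float(v.iloc[0])
                at = three_way_rm_anova(y)
                at.insert(0, "band", band)
                anova_rows.append(at)
                for ii, inten in enumerate(("sub", "supra")):
                    pre = y[:, 0, :, ii].ravel()
                    post = y[:, 1, :, ii].ravel()
                    cond = np.array([c for _ in subjects
                                     for c in ("active", "sham")])
                    fit = change_score_regression(pre, post, cond)
                    for row in fit.summary_rows():
                        row.update({"band": band, "intensity": inten,
                                    "model_F": fit.model_F,
                                    "df": fit.df_resid})
                        reg_rows.append(row)
            _write_csv(pd.concat(anova_rows, ignore_index=True),
                       os.path.join(out, "tfr_anova.csv"), cfg)
            _write_csv(pd.DataFrame(reg_rows),
                       os.path.join(out, "tfr_regression.csv"), cfg)
            bundle["tfr_anova"] = pd.concat(anova_rows, ignore_index=True)

        if stage("microstates"):
            ms_cfg = cfg["microstates"]
            rc = dict(cfg["resting"])
            rc.setdefault("seed", seed)
            resting = synth_resting_cohort(RestingConfig(**rc))
            models = {}
            for key, (data, _) in resting.recordings.items():
                peaks = gmfp_peaks(data, resting.srate)
                models[key] = modified_kmeans(peaks, k=ms_cfg["k"],
                                              restarts=ms_cfg["restarts"],
                                              seed=seed)
            grand = grand_mean_templates(list(models.values()))
            grand = sort_templates(grand, canonical_templates(resting.montage))
            params = {}
            for key, (data, _) in resting.recordings.items():
                seq = backfit(data, grand, resting.srate)
                params[key] = ms_parameters(seq)
            table = ms_rm_anova(params)
            _write_csv(table, os.path.join(out, "microstate_anova.csv"), cfg)
            tmpl = pd.DataFrame(grand.templates.T,
                                columns=list(grand.labels))
            tmpl.insert(0, "channel", list(resting.montage.names))
            _write_csv(tmpl, os.path.join(out, "microstate_templates.csv"),
                       cfg)
            _write_json({"shared_variance": grand.shared_variance},
                        os.path.join(out, "microstate_meta.json"), cfg)
            bundle["microstate_anova"] = table
    except Exception as err:
        log.error("pipeline aborted: %s", err)
        raise
    return bundle
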