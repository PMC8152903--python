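"""End-to-end orchestration: simulate -> preprocess -> decode -> stats -> report.

Three layers:

* participant-level helpers (`preprocess_epochs`, `decode_participant`) and
  study-level decoding (`decode_study`) that return in-memory results;
* named study suites used for validation of the whole pipeline against the
  generator's ground truth: chance calibration (`chance_calibration`),
  family-wise error rate of the cluster permutation test over repeated null
  studies (`fwer_suite`), the identity/expression crossover recovery
  (`crossover_recovery`) and previous-trial reactivation recovery
  (`reactivation_recovery`);
* `run_study`, which writes a TSV/JSON report bundle for a full synthetic
  study (accuracy time courses with cluster annotations, period confusion
  matrices, cross-dimension series, temporal generalization matrices,
  previous-trial series, and the behavioral t / Bayes-factor report).

All randomness descends from one master seed through a fixed splitting
rule, so every artifact is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decode as _decode
from . import preprocess as _pre
from . import stats as _stats
from . import synth as _synth
from .core import (ConfigError, DecodeConfig, EpochSet, collapse_dimension,
                   derive_seed, exclude_trials, relabel_previous_trial)
from .synth import NoiseParams, SynthConfig

__all__ = ["StudyConfig", "preprocess_epochs", "decode_study",
           "chance_calibration", "fwer_suite", "crossover_recovery",
           "reactivation_recovery", "null_study_config", "crossover_study_config",
           "reactivation_study_config", "run_study"]

PERCEPTION_MS = (0.0, 500.0)
MAINTENANCE_MS = (500.0, 1500.0)


# ---------------------------------------------------------------------------
# participant- and study-level decoding


def preprocess_epochs(epochs: EpochSet, config: DecodeConfig,
                      baseline: bool = True) -> EpochSet:
    """Low-pass filter and (when the epoch has a pre-stimulus part)
    baseline-correct over [max(t_start, -500), 0) ms."""
    out = _pre.lowpass_filter(epochs, config.lowpass_hz)
    if baseline and out.t_start_ms < 0:
        out = _pre.baseline_correct(out, (max(out.t_start_ms, -500.0), 0.0))
    return out


def _labels_for(epochs: EpochSet, dimension: str):
    """Class labels (and the epoch subset) for a decoding dimension."""
    if dimension in ("identity", "expression"):
        return epochs, collapse_dimension(epochs.labels, dimension)
    if dimension in ("previous-identity", "previous-expression"):
        target = dimension.split("-", 1)[1]
        prev, positions = relabel_previous_trial(epochs.labels, target)
        return epochs.subset(positions), prev
    raise ConfigError(f"unknown decoding dimension: {dimension!r}")


def decode_participant(epochs: EpochSet, dimension: str, config: DecodeConfig,
                       seed: int, mode: str = "timecourse"):
    ep, labels = _labels_for(epochs, dimension)
    if mode == "timecourse":
        return _decode.decode_timecourse(ep, labels, config, seed=seed)
    if mode == "crosstime":
        windowed = _pre.window_average(ep, config.window_ms)
        return _decode.decode_crosstime(windowed, labels, config, seed=seed)
    if mode == "crossdim":
        control = "expression" if dimension == "identity" else "identity"
        return _decode.decode_crossdim(ep, labels,
                                       collapse_dimension(ep.labels, control), config)
    raise ConfigError(f"unknown decoding mode: {mode!r}")


def decode_study(synth_cfg: SynthConfig, decode_cfg: DecodeConfig,
                 dimension: str = "identity", seed: int = 0,
                 apply_preprocess: bool = True, mode: str = "timecourse") -> dict:
    """Simulate every participant and decode one dimension.

    Returns stores / accuracy series per participant plus the time axis.
    """
    stores, series, times = [], [], None
    for p, (pid, ep) in enumerate(_synth.simulate_study(synth_cfg, seed)):
        if apply_preprocess:
            ep = preprocess_epochs(ep, decode_cfg)
        if ep.labels.is_post_test.any():
            ep = exclude_trials(ep, drop_post_test=True)
        out = decode_participant(ep, dimension, decode_cfg,
                                 seed=derive_seed(seed, p, _DIM_CODE[dimension]),
                                 mode=mode)
        if mode == "crosstime":
            series.append(out)
            times = out.window_times
        else:
            s, st = out
            stores.append(st)
            series.append(s)
            times = s.times
    return {"stores": stores, "series": series, "times": times,
            "participant_ids": [f"sub-{i + 1:02d}" for i in range(synth_cfg.n_participants)]}


_DIM_CODE = {"identity": 1, "expression": 2,
             "previous-identity": 3, "previous-expression": 4}


# ---------------------------------------------------------------------------
# named validation suites (the study conditions for calibration / recovery)


def null_study_config(n_participants: int = 8, n_trials: int = 160,
                      phi: float = 0.5, seed: int = 0) -> SynthConfig:
    """Zero-signal study: AR(1) noise only (no alpha component), reduced
    epoch [0, 400) ms = 100 post-onset time points."""
    return dataclasses.replace(
        SynthConfig(),
        n_participants=n_participants, n_trials=n_trials,
        epoch_ms=(0.0, 400.0),
        identity_gain=0.0, expression_gain=0.0, reactivation_gain=0.0,
        noise=NoiseParams(sd_uv=8.0, ar_phi=phi, alpha_amp_uv=0.0),
        rng_seed=seed,
    )


def crossover_study_config(n_participants: int = 22, fs: float = 125.0,
                           seed: int = 0) -> SynthConfig:
    """Default-envelope study: transient identity coding, sustained
    expression coding, generative crossover at ~500 ms.  Runs at the
    emulated study's sample size (22 participants, 640 trials); the only
    desk-scale concession is the 125-Hz time grid."""
    return dataclasses.replace(SynthConfig(), n_participants=n_participants,
                               fs=fs, rng_seed=seed)


REACTIVATION_RHO = 0.8  # uV; canonical "reactivation on" gain for recovery


def reactivation_study_config(rho: float, n_participants: int = 22,
                              fs: float = 125.0, seed: int = 0) -> SynthConfig:
    """Previous-trial reactivation study over a shortened [-200, 800) ms
    epoch (the reactivation bump lies within [60, 660] ms post-onset).

    Current-trial gains are zeroed: the no-repeat design constraint makes
    previous-trial labels anti-correlated with current-trial labels, so any
    current-trial class signal leaks (at -1/3 of its gain, with inverted
    pattern) into previous-trial group means.  Isolating the reactivation
    component is what makes the rho = 0 condition a true negative control.
    """
    return dataclasses.replace(SynthConfig(), n_participants=n_participants,
                               fs=fs, epoch_ms=(-200.0, 800.0),
                               segment_edges_ms=(0.0, 200.0, 500.0),
                               identity_gain=0.0, expression_gain=0.0,
                               reactivation_gain=rho, rng_seed=seed)


def chance_calibration(seed: int = 0, n_participants: int = 10,
                       decode_cfg: DecodeConfig | None = None) -> dict:
    """Grand-mean decoding accuracy on zero-signal epochs.

    The decoder runs directly on the simulated epochs (no filtering: the
    calibration isolates the decoding engine itself) over 100 post-onset
    time points; with no class signal the grand mean must sit at chance.
    """
    decode_cfg = decode_cfg or DecodeConfig()
    cfg = null_study_config(n_participants=n_participants, seed=seed)
    res = decode_study(cfg, decode_cfg, "identity", seed=seed, apply_preprocess=False)
    post = res["times"] >= 0
    per_tp = np.stack([st.accuracy()[post] for st in res["stores"]])
    n_total = sum(st.n_attempts for st in res["stores"]) * int(post.sum())
    return {
        "grand_mean": float(per_tp.mean()),
        "chance": 0.25,
        "n_attempts_total": n_total,
        "binomial_se": float(np.sqrt(0.25 * 0.75 / n_total)),
        "n_participants": n_participants,
        "n_timepoints": int(post.sum()),
    }


def fwer_suite(n_studies: int = 200, seed: int = 0, n_participants: int = 8,
               n_perm: int = 200, phi: float = 0.5,
               decode_cfg: DecodeConfig | None = None,
               cluster_alpha: float = 0.05) -> dict:
    """Family-wise false-positive rate of the vs-chance cluster permutation
    test over repeated zero-signal studies.

    Each study: simulate n_participants with AR(1) noise only, decode the
    identity dimension (5 subsampling iterations -- the error rate of the
    permutation test does not depend on the iteration count), run the
    cluster test with ``n_perm`` permutations, and record whether any
    cluster reached p < cluster_alpha.
    """
    decode_cfg = decode_cfg or DecodeConfig(n_iterations=5)
    flags = np.zeros(n_studies, dtype=bool)
    for s in range(n_studies):
        master = derive_seed(seed, 101, s)
        cfg = null_study_config(n_participants=n_participants, phi=phi, seed=master)
        res = decode_study(cfg, decode_cfg, "identity", seed=master,
                           apply_preprocess=False)
        test = _stats.vs_chance_cluster_test(
            res["stores"], res["times"], n_perm=n_perm,
            seed=derive_seed(master, 77), smooth_points=decode_cfg.smooth_points)
        flags[s] = any(c.p < cluster_alpha for c in test["clusters"].clusters)
    frac = float(flags.mean())
    return {
        "fraction_significant": frac,
        "n_studies": n_studies,
        "alpha": cluster_alpha,
        "mc_se": float(np.sqrt(cluster_alpha * (1 - cluster_alpha) / n_studies)),
    }


def _decode_study_shared(cfg: SynthConfig, decode_cfg: DecodeConfig,
                         dimensions, seed: int) -> dict:
    """Simulate each participant once, preprocess once, decode every
    requested dimension on the same epochs."""
    out = {dim: {"stores": [], "times": None} for dim in dimensions}
    for p, (pid, ep) in enumerate(_synth.simulate_study(cfg, seed)):
        ep = preprocess_epochs(ep, decode_cfg)
        for dim in dimensions:
            _, st = decode_participant(ep, dim, decode_cfg,
                                       seed=derive_seed(seed, p, _DIM_CODE[dim]))
            out[dim]["stores"].append(st)
            out[dim]["times"] = st.times
    return out


def crossover_recovery(seed: int = 0, n_participants: int = 32,
                       n_perm: int = 200,
                       decode_cfg: DecodeConfig | None = None) -> dict:
    """Recover the identity/expression temporal dissociation.

    Decodes both dimensions on the default crossover generator and runs the
    paired condition-swap cluster test; the generative signal difference is
    positive (identity > expression) throughout [0, 500) ms and negative
    throughout (500, 1500) ms, so recovered difference clusters must respect
    that boundary.
    """
    decode_cfg = decode_cfg or DecodeConfig()
    cfg = crossover_study_config(n_participants=n_participants, seed=seed)
    res = _decode_study_shared(cfg, decode_cfg, ("identity", "expression"), seed)
    acc_id = _stats.accuracy_matrix(res["identity"]["stores"], decode_cfg.smooth_points)
    acc_ex = _stats.accuracy_matrix(res["expression"]["stores"], decode_cfg.smooth_points)
    times = res["identity"]["times"]
    diff = _stats.condition_diff_cluster_test(
        acc_id, acc_ex, times, n_perm=n_perm, seed=derive_seed(seed, 88))
    sig = [c for c in diff["clusters"].clusters if c.p < 0.05]
    return {
        "clusters": diff["clusters"],
        "identity_gt_expression": [c for c in sig if c.mass > 0],
        "expression_gt_identity": [c for c in sig if c.mass < 0],
        "acc_identity": acc_id,
        "acc_expression": acc_ex,
        "times": times,
    }


def reactivation_recovery(rho: float, seed: int = 0, n_participants: int = 32,
                          n_perm: int = 200,
                          decode_cfg: DecodeConfig | None = None) -> dict:
    """Decode the previous trial's identity; with reactivation gain rho > 0
    the pattern re-emerges after the current stimulus onset, with rho = 0
    there is nothing to find."""
    decode_cfg = decode_cfg or DecodeConfig()
    cfg = reactivation_study_config(rho, n_participants=n_participants, seed=seed)
    res = _decode_study_shared(cfg, decode_cfg, ("previous-identity",), seed)
    stores = res["previous-identity"]["stores"]
    times = res["previous-identity"]["times"]
    test = _stats.vs_chance_cluster_test(
        stores, times, n_perm=n_perm, seed=derive_seed(seed, 66),
        smooth_points=decode_cfg.smooth_points)
    acc = test["accuracy"]
    pre = times < 0
    return {
        "clusters": test["clusters"],
        "significant": [c for c in test["clusters"].clusters if c.p < 0.05],
        "pre_onset_mean": float(acc[:, pre].mean()),
        "accuracy": acc,
        "times": times,
    }


# ---------------------------------------------------------------------------
# full report bundle


@dataclass
class StudyConfig:
    """Everything a full synthetic study needs, echoed into every output."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    decode: DecodeConfig = field(default_factory=DecodeConfig)
    n_perm: int = 1000
    point_alpha: float = 0.05
    cluster_alpha: float = 0.05
    seed: int = 0
    include_confusion: bool = True
    include_crossdim: bool = True
    include_crosstime: bool = True
    include_previous: bool = True
    include_behavior: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "synth" in d:
            s = dict(d["synth"])
            for key in ("identity_envelope", "expression_envelope", "reactivation_envelope"):
                if key in s and isinstance(s[key], dict):
                    s[key] = _synth.EnvelopeParams(**s[key])
            if "noise" in s and isinstance(s["noise"], dict):
                s["noise"] = NoiseParams(**s["noise"])
            for key in ("epoch_ms", "segment_edges_ms"):
                if key in s:
                    s[key] = tuple(s[key])
            d["synth"] = SynthConfig(**s)
        if "decode" in d and isinstance(d["decode"], dict):
            d["decode"] = DecodeConfig(**d["decode"])
        return cls(**d)


def _decode_study_cached(cache_dir: Path, key: str, synth_cfg: SynthConfig,
                         decode_cfg: DecodeConfig, dim: str, seed: int,
                         mode: str = "timecourse") -> dict:
    """decode_study with prediction stores cached on disk, so a re-run of
    the same configuration restarts from intermediates instead of
    re-simulating and re-training."""
    from .core import AccuracySeries, PredictionStore
    from .preprocess import smooth_values

    path = cache_dir / f"{key}.npz"
    if path.exists():
        with np.load(path) as z:
            times = z["times"]
            n = int(z["n_participants"])
            stores = [PredictionStore(
                predicted=z[f"pred_{i}"], true=z[f"true_{i}"], times=times,
                n_classes=int(z["n_classes"]), n_iterations=int(z[f"nit_{i}"]),
                n_folds=int(z[f"nf_{i}"])) for i in range(n)]
        series = [AccuracySeries(
            values=smooth_values(st.accuracy(), decode_cfg.smooth_points),
            times=times, n_attempts=st.n_attempts) for st in stores]
        return {"stores": stores, "series": series, "times": times,
                "participant_ids": [f"sub-{i + 1:02d}" for i in range(n)]}
    res = decode_study(synth_cfg, decode_cfg, dim, seed=seed, mode=mode)
    cache_dir.mkdir(parents=True, exist_ok=True)
    payload = {"times": res["times"],
               "n_participants": len(res["stores"]),
               "n_classes": res["stores"][0].n_classes}
    for i, st in enumerate(res["stores"]):
        payload[f"pred_{i}"] = st.predicted
        payload[f"true_{i}"] = st.true
        payload[f"nit_{i}"] = st.n_iterations
        payload[f"nf_{i}"] = st.n_folds
    np.savez(path, **payload)
    return res


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def _acc_frame(acc: np.ndarray, times: np.ndarray, pids) -> pd.DataFrame:
    df = pd.DataFrame(acc.T, columns=pids)
    df.insert(0, "time_ms", times)
    return df


def _cluster_json(clusters) -> dict:
    return {
        "tail": clusters.tail,
        "point_alpha": clusters.point_alpha,
        "cluster_alpha": clusters.cluster_alpha,
        "df": clusters.df,
        "threshold": clusters.threshold,
        "clusters": [c.to_dict() for c in clusters.clusters],
    }


def run_study(config: StudyConfig, out_dir) -> dict:
    """Run the complete synthetic study and write the report bundle.

    Deterministic given the master seed: re-running with the same config
    produces byte-identical files.  Returns the in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_begin = time.time()
    seed = config.seed
    log_lines = []

    def log(stage: str, detail: str, t0: float) -> None:
        log_lines.append(f"{stage}\t{detail}\telapsed_s={time.time() - t0:.2f}")

    provenance = {"config": config.to_dict(), "config_hash": config.config_hash(),
                  "seed": seed}
    _write_json(out / "config.json", provenance)
    results: dict = {"config": config}
    pids = [f"sub-{i + 1:02d}" for i in range(config.synth.n_participants)]

    cache_dir = out / "cache"

    for dim in ("identity", "expression"):
        t0 = time.time()
        res = _decode_study_cached(cache_dir, f"{dim}_{config.config_hash()}",
                                   config.synth, config.decode, dim, seed)
        test = _stats.vs_chance_cluster_test(
            res["stores"], res["times"], n_perm=config.n_perm,
            seed=derive_seed(seed, 11, _DIM_CODE[dim]),
            smooth_points=config.decode.smooth_points,
            point_alpha=config.point_alpha, cluster_alpha=config.cluster_alpha)
        results[dim] = {"decode": res, "test": test}
        _write_tsv(out / f"accuracy_{dim}.tsv",
                   _acc_frame(test["accuracy"], res["times"], pids))
        _write_json(out / f"clusters_{dim}.json",
                    {**provenance, **_cluster_json(test["clusters"])})
        log("decode+stats", dim, t0)

        if config.include_confusion:
            t0 = time.time()
            periods = [p for p in (PERCEPTION_MS, MAINTENANCE_MS)
                       if p[0] < res["times"][-1]]
            mats = []
            for st in res["stores"]:
                mats.append([m.matrix for m in _decode.confusion_by_period(st, periods)])
            for j, period in enumerate(periods):
                mean_mat = np.mean([m[j] for m in mats], axis=0)
                df = pd.DataFrame(mean_mat,
                                  columns=[f"pred_{c}" for c in range(1, 5)])
                df.insert(0, "true", np.arange(1, 5))
                _write_tsv(out / f"confusion_{dim}_{int(period[0])}_{int(period[1])}.tsv", df)
            log("confusion", dim, t0)

    t0 = time.time()
    diff = _stats.condition_diff_cluster_test(
        results["identity"]["test"]["accuracy"],
        results["expression"]["test"]["accuracy"],
        results["identity"]["decode"]["times"], n_perm=config.n_perm,
        seed=derive_seed(seed, 12), point_alpha=config.point_alpha,
        cluster_alpha=config.cluster_alpha)
    results["condition_diff"] = diff
    _write_json(out / "clusters_identity_vs_expression.json",
                {**provenance, **_cluster_json(diff["clusters"])})
    log("condition-diff", "identity-vs-expression", t0)

    if config.include_crossdim:
        for dim in ("identity", "expression"):
            t0 = time.time()
            res = _decode_study_cached(
                cache_dir, f"crossdim_{dim}_{config.config_hash()}",
                config.synth, config.decode, dim, seed, mode="crossdim")
            test = _stats.vs_chance_cluster_test(
                res["stores"], res["times"], n_perm=config.n_perm,
                seed=derive_seed(seed, 13, _DIM_CODE[dim]),
                smooth_points=config.decode.smooth_points,
                point_alpha=config.point_alpha, cluster_alpha=config.cluster_alpha)
            results[f"crossdim_{dim}"] = {"decode": res, "test": test}
            _write_tsv(out / f"crossdim_accuracy_{dim}.tsv",
                       _acc_frame(test["accuracy"], res["times"], pids))
            _write_json(out / f"crossdim_clusters_{dim}.json",
                        {**provenance, **_cluster_json(test["clusters"])})
            log("crossdim", dim, t0)

    if config.include_crosstime:
        for dim in ("identity", "expression"):
            t0 = time.time()
            res = decode_study(config.synth, config.decode, dim, seed=seed,
                               mode="crosstime")
            mean_gm = np.mean([g.accuracy for g in res["series"]], axis=0)
            results[f"crosstime_{dim}"] = {"matrices": res["series"], "mean": mean_gm}
            df = pd.DataFrame(mean_gm,
                              columns=[f"test_{int(t)}" for t in res["times"]])
            df.insert(0, "train_ms", res["times"])
            _write_tsv(out / f"generalization_{dim}.tsv", df)
            log("crosstime", dim, t0)

    if config.include_previous:
        for dim in ("previous-identity", "previous-expression"):
            t0 = time.time()
            res = _decode_study_cached(
                cache_dir, f"{dim}_{config.config_hash()}",
                config.synth, config.decode, dim, seed)
            test = _stats.vs_chance_cluster_test(
                res["stores"], res["times"], n_perm=config.n_perm,
                seed=derive_seed(seed, 14, _DIM_CODE[dim]),
                smooth_points=config.decode.smooth_points,
                point_alpha=config.point_alpha, cluster_alpha=config.cluster_alpha)
            results[dim] = {"decode": res, "test": test}
            tag = dim.replace("-", "_")
            _write_tsv(out / f"accuracy_{tag}.tsv",
                       _acc_frame(test["accuracy"], res["times"], pids))
            _write_json(out / f"clusters_{tag}.json",
                        {**provenance, **_cluster_json(test["clusters"])})
            log("previous-trial", dim, t0)

    if config.include_behavior:
        t0 = time.time()
        behavior = _synth.simulate_behavior(config.synth, seed)
        tstat, df_, p = _stats.one_sample_t_test(behavior[:, 0] - behavior[:, 1],
                                                 0.0, tail="two")
        bf01 = _stats.jzs_bf01(tstat, behavior.shape[0])
        results["behavior"] = {"t": tstat, "df": df_, "p": p, "bf01": bf01,
                               "mean_identity": float(behavior[:, 0].mean()),
                               "mean_expression": float(behavior[:, 1].mean())}
        _write_json(out / "behavior.json", {**provenance, **results["behavior"]})
        log("behavior", f"t={tstat:.3f}", t0)

    log_lines.append(f"total\t-\telapsed_s={time.time() - t_begin:.2f}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
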