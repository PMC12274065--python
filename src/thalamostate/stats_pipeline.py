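"""Group/state statistics and the end-to-end synthetic pipeline.

Inferential layer over the per-unit firing metrics: rank correlation between
an ordered consciousness scale (walk < wake < REM < NREM) and firing rate,
Levene's test for homogeneity of variance between genotypes, Holm step-down
correction for families of nonparametric comparisons, and a seeded 2-D UMAP
embedding of the (tonic rate, burst spike rate, burst event rate) feature
space. ``run_pipeline`` chains synthesis, activity scoring, spike analytics
and statistics into one reproducible run driven by a single seed.
"""

from __future__ import annotations

import configparser
import math
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss

from . import __version__
from .io_formats import (
    EpochSet,
    write_epochs,
    write_motion,
    write_results,
    write_spikes,
)
from .activity_analysis import (
    classify_states,
    filter_accelerometer,
    instantaneous_activity,
    lom_metrics,
    normalize_index,
    windowed_index,
)
from .spike_analysis import detect_bursts, state_firing_metrics, zscore_vs_wake
from .synthetic import (
    MotionEpisode,
    MotionGenParams,
    default_ko_params,
    default_wt_params,
    gen_motion_trace,
    gen_spike_train,
    gen_state_schedule,
)

__all__ = [
    "STATE_ORDER",
    "state_correlation",
    "variance_homogeneity",
    "group_compare_holm",
    "state_space_embedding",
    "run_pipeline",
]

#: Consciousness-ordered state codes (1 = most awake) used for rank
#: correlation between brain state and firing.
STATE_ORDER: dict[str, int] = {"walk": 1, "wake": 2, "REM": 3, "NREM": 4}

FEATURE_COLUMNS = ["tonic_rate_hz", "burst_spike_rate_hz", "burst_event_rate_per_min"]


def state_correlation(
    metrics: pd.DataFrame,
    order: dict[str, int] | None = None,
    rate_col: str = "total_rate_hz",
    method: str = "spearman",
) -> tuple[float, float]:
    """Rank correlation between the ordered brain-state code and firing rate.

    Rows are unit-by-state observations; states absent from ``order`` are
    dropped. Returns (rho, two-sided p); a constant rate column yields
    (NaN, NaN).
    """
    order = order or STATE_ORDER
    df = metrics[metrics["state"].isin(order)].copy()
    if len(df) < 3 or df["state"].nunique() < 2:
        raise ValueError("need >= 3 observations spanning >= 2 states")
    codes = df["state"].map(order).to_numpy(float)
    rates = df[rate_col].to_numpy(float)
    if np.ptp(rates) == 0:
        return math.nan, math.nan
    if method == "spearman":
        rho, p = ss.spearmanr(codes, rates)
    elif method == "pearson":
        rho, p = ss.pearsonr(codes, rates)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


def variance_homogeneity(
    a: Sequence[float], b: Sequence[float], center: str = "mean"
) -> tuple[float, float]:
    """Two-sample Levene test (classic mean-centered form by default)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    stat, p = ss.levene(a, b, center=center)
    return float(stat), float(p)


def group_compare_holm(
    pvalues: Sequence[float] | None = None,
    sample_pairs: Sequence[tuple[Sequence[float], Sequence[float]]] | None = None,
    alpha: float = 0.05,
    paired: bool = False,
) -> pd.DataFrame:
    """Holm step-down decisions over a family of comparisons.

    Either raw p-values or sample pairs may be given; pairs are tested with
    the two-sided rank-sum test (Wilcoxon signed-rank when ``paired``).
    Returns a DataFrame with the raw p, Holm-adjusted p, and reject flag;
    decisions are monotone in p.
    """
    from statsmodels.stats.multitest import multipletests

    if (pvalues is None) == (sample_pairs is None):
        raise ValueError("provide exactly one of pvalues or sample_pairs")
    if sample_pairs is not None:
        pvalues = []
        for x, y in sample_pairs:
            if paired:
                pvalues.append(ss.wilcoxon(x, y).pvalue)
            else:
                pvalues.append(ss.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    p = np.asarray(pvalues, float)
    if p.size < 1:
        raise ValueError("need at least one comparison")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return pd.DataFrame({"p": p, "p_holm": p_adj, "reject": reject})


def state_space_embedding(
    features: pd.DataFrame,
    seed: int,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """Seeded 2-D UMAP embedding of standardized firing features.

    ``features`` must carry the three firing-feature columns without missing
    values and at least 10 rows; metadata columns (unit, state, genotype) are
    carried through to the returned frame alongside ``umap1``/``umap2``.
    """
    import umap  # deferred: heavy import

    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature matrix lacks column(s) {missing}")
    X = features[FEATURE_COLUMNS].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 rows to embed")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, X.shape[0] - 1),
        min_dist=min_dist,
        random_state=int(seed) % (2**31),
    )
    coords = reducer.fit_transform(Xs)
    out = features.copy().reset_index(drop=True)
    out["umap1"] = coords[:, 0]
    out["umap2"] = coords[:, 1]
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "run": {"seed": "0", "out_dir": "results"},
    "synth": {
        "genotype": "WT",
        "n_units": "8",
        "schedule_total_s": "3600",
        "state_menu": "wake,NREM,REM",
        "motion_total_s": "2400",
        "baseline_s": "600",
        "injection_s": "600",
        "lom_episodes": "900:180,1500:120",
        "sample_rate_hz": "100",
    },
    "activity": {
        "lom_threshold": "0.25",
        "nonwalk_min_s": "60",
        "lom_min_s": "30",
        "horizon_s": "3600",
    },
    "spikes": {
        "isi_max_ms": "10",
        "silence_min_ms": "50",
        "min_spikes": "2",
        "zscore_bin_s": "10",
        "zscore_target": "NREM",
    },
    "stats": {"embed": "true", "alpha": "0.05"},
}


def _load_config(config: str | Path | dict | None) -> configparser.ConfigParser:
    cp = configparser.ConfigParser()
    cp.read_dict(_DEFAULT_CONFIG)
    if config is None:
        return cp
    if isinstance(config, dict):
        cp.read_dict(config)
    else:
        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(path)
        cp.read(path)
    return cp


def _parse_episodes(text: str) -> list[MotionEpisode]:
    out = []
    text = text.strip()
    if not text:
        return out
    for item in text.split(","):
        onset, dur = item.split(":")
        out.append(MotionEpisode(float(onset), float(dur)))
    return out


@dataclass
class _Log:
    lines: list[str]

    def add(self, msg: str) -> None:
        self.lines.append(msg)
        print(msg, file=sys.stderr)


def run_pipeline(config: str | Path | dict | None, out_dir: str | Path | None = None) -> Path:
    """Run synth -> activity -> spikes -> stats and write a results directory.

    Every stochastic stage is seeded from the single ``[run] seed`` key, so a
    repeated run writes byte-identical numeric outputs. Outputs: the
    synthesized inputs (spikes/epochs/motion/truth), per-window states and
    episodes, LOM metrics, per-unit state metrics and Z-scores, group
    statistics, the embedding, and a run log echoing the configuration.
    """
    cp = _load_config(config)
    seed = cp.getint("run", "seed")
    out = Path(out_dir or cp.get("run", "out_dir"))
    out.mkdir(parents=True, exist_ok=True)
    log = _Log([f"thalamostate {__version__}", f"seed {seed}"])
    ss_root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss_root.spawn(4)]
    log.add(f"stage seeds: {seeds}")

    try:
        # --- synth ---------------------------------------------------------
        genotype = cp.get("synth", "genotype")
        n_units = cp.getint("synth", "n_units")
        menu = [m.strip() for m in cp.get("synth", "state_menu").split(",")]
        total_s = cp.getfloat("synth", "schedule_total_s")
        schedule = gen_state_schedule(seeds[0], total_s, menu)
        params = default_ko_params() if genotype == "KO" else default_wt_params()
        trains, truths = [], []
        for u in range(n_units):
            tr, truth = gen_spike_train(
                seeds[0] + 1 + u, schedule, params, genotype=genotype,
                unit_id=f"{genotype.lower()}{u:02d}", p2v_width_us=350.0,
            )
            trains.append(tr)
            truths.append(truth)
        mot_params = MotionGenParams(
            total_s=cp.getfloat("synth", "motion_total_s"),
            baseline_duration_s=cp.getfloat("synth", "baseline_s"),
            episodes=_parse_episodes(cp.get("synth", "lom_episodes")),
        )
        motion, mtruth = gen_motion_trace(
            seeds[1], mot_params, sample_rate_hz=cp.getfloat("synth", "sample_rate_hz")
        )
        write_spikes(trains, out / "spikes.tsv")
        write_epochs(schedule, out / "epochs.tsv")
        write_motion(motion, out / "motion.csv")
        truth_df = pd.DataFrame(
            {
                "unit_id": [t.unit_id for t in trains],
                "n_true_bursts": [t2.n_bursts for t2 in truths],
                "n_tonic": [t2.n_tonic_spikes for t2 in truths],
            }
        )
        write_results(truth_df, out / "truth.tsv")
        log.add(f"synth: {n_units} {genotype} units, {len(schedule)} epochs")

        # --- activity ------------------------------------------------------
        injection_s = cp.getfloat("synth", "injection_s")
        filtered = filter_accelerometer(motion)
        act = instantaneous_activity(filtered)
        series = windowed_index(act, motion.sample_rate_hz, t0_s=motion.t0_s)
        series = normalize_index(series, (0.0, cp.getfloat("synth", "baseline_s")))
        states = classify_states(
            series,
            injection_s,
            lom_threshold=cp.getfloat("activity", "lom_threshold"),
            nonwalk_min_s=cp.getfloat("activity", "nonwalk_min_s"),
            lom_min_s=cp.getfloat("activity", "lom_min_s"),
        )
        metrics = lom_metrics(
            states, injection_s, horizon_s=cp.getfloat("activity", "horizon_s")
        )
        write_results(states.episodes, out / "episodes.tsv")
        write_results(metrics, out / "metrics.tsv")
        log.add(
            f"activity: {len(states.episodes_of('LOM'))} LOM episodes, "
            f"total {metrics.total_LOM_s:g} s"
        )

        # --- spikes --------------------------------------------------------
        burst_rows = []
        metric_frames = []
        z_rows = []
        target_lab = cp.get("spikes", "zscore_target")
        wake_iv = schedule.intervals("wake")
        target_iv = schedule.intervals(target_lab)
        for tr in trains:
            bursts = detect_bursts(
                tr,
                isi_max_ms=cp.getfloat("spikes", "isi_max_ms"),
                silence_min_ms=cp.getfloat("spikes", "silence_min_ms"),
                min_spikes=cp.getint("spikes", "min_spikes"),
            )
            bf = bursts.to_frame()
            bf.insert(0, "unit_id", tr.unit_id)
            burst_rows.append(bf)
            metric_frames.append(state_firing_metrics(tr, bursts, schedule))
            if len(wake_iv) and len(target_iv):
                wake_es = EpochSet(
                    wake_iv[:, 0], wake_iv[:, 1], ["wake"] * len(wake_iv)
                )
                targ_es = EpochSet(
                    target_iv[:, 0], target_iv[:, 1], [target_lab] * len(target_iv)
                )
                zc = zscore_vs_wake(
                    tr, wake_es, targ_es, bin_s=cp.getfloat("spikes", "zscore_bin_s")
                )
                z_rows.append(
                    {
                        "unit_id": tr.unit_id,
                        "target_state": target_lab,
                        "z": zc.z,
                        "label": zc.label,
                    }
                )
        bursts_df = pd.concat(burst_rows, ignore_index=True)
        if bursts_df.empty:
            bursts_df = pd.DataFrame(
                columns=["unit_id", "onset_s", "n_spikes", "duration_s"]
            )
        # an all-header file still records that detection ran
        bursts_df.to_csv(out / "bursts.tsv", sep="\t", index=False, float_format="%.6g")
        state_metrics = pd.concat(metric_frames, ignore_index=True)
        write_results(state_metrics, out / "state_metrics.tsv")
        if z_rows:
            write_results(pd.DataFrame(z_rows), out / "zscores.tsv")
        log.add(f"spikes: {int(bursts_df.shape[0])} detected bursts")

        # --- stats ---------------------------------------------------------
        stats_rows = []
        try:
            rho, p = state_correlation(state_metrics)
            stats_rows.append(
                {"test": "spearman_state_vs_rate", "statistic": rho, "p": p}
            )
        except ValueError as exc:
            log.add(f"stats: state correlation skipped ({exc})")
        nrem = state_metrics[state_metrics["state"] == "NREM"]["total_rate_hz"]
        wake = state_metrics[state_metrics["state"] == "wake"]["total_rate_hz"]
        if len(nrem) >= 2 and len(wake) >= 2:
            stat, p = variance_homogeneity(wake, nrem)
            stats_rows.append(
                {"test": "levene_wake_vs_nrem", "statistic": stat, "p": p}
            )
            holm = group_compare_holm(sample_pairs=[(wake, nrem)])
            stats_rows.append(
                {
                    "test": "ranksum_wake_vs_nrem_holm",
                    "statistic": float(holm["p_holm"].iloc[0]),
                    "p": float(holm["p"].iloc[0]),
                }
            )
        if stats_rows:
            write_results(pd.DataFrame(stats_rows), out / "stats.tsv")
        if cp.getboolean("stats", "embed") and len(state_metrics) >= 10:
            feat = state_metrics[["unit_id", "state"] + FEATURE_COLUMNS].copy()
            emb = state_space_embedding(feat, seeds[3])
            write_results(emb, out / "embedding.tsv")
            log.add(f"stats: embedded {len(emb)} unit-state rows")
    except Exception as exc:
        log.add(f"FAILED: {type(exc).__name__}: {exc}")
        (out / "log.txt").write_text("\n".join(log.lines) + "\n")
        raise

    log.add("done")
    cfg_echo = [
        f"{sec}.{key} = {val}"
        for sec in cp.sections()
        for key, val in cp.items(sec)
    ]
    (out / "log.txt").write_text("\n".join(log.lines + ["", "# config"] + cfg_echo) + "\n")
    return out
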