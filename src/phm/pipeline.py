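"""End-to-end orchestration: simulate → preprocess → fuse/window → pattern
calls → pattern-specific features → optimize → semi-supervised train →
evaluate, from one serializable configuration.

The corpus is split subject-wise (whole recordings go to train or test); the
labeled fraction applies within the training windows, the remaining training
windows participating as unlabeled data in the manifold regularizer.
Kinematic and static windows are featurized by their respective extractors
and the two tables are concatenated row-wise (zero-filled across the other
pattern's block) with a pattern indicator column before optimization.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import (
    SensorConfig,
    generate_recording,
    pad_schedule,
    gotov_schedule,
    PAD_PROFILES,
    GOTOV_PROFILES,
)
from .preprocessing import preprocess
from .fusion import fuse_streams, make_windows, Window
from .patterns import DEFAULT_TAU, decide_pattern, recording_stats
from .features import (
    TemplateBank,
    kinematic_features,
    static_features,
)
from .optimize import (
    fit_qda,
    qda_transform,
    fit_ofnda,
    ofnda_transform,
)
from .manifold import (
    GraphSpec,
    fit_rls,
    fit_laprls,
    fit_nystrom_laprls,
    predict,
    evaluate,
    EvaluationReport,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage's tunables in one round-trippable document."""

    # corpus
    profile: str = "pad"  # pad | gotov
    n_recordings: int = 20
    seconds: float = 70.0
    seed: int = 0
    subject_jitter: float = 0.1
    # preprocessing
    still_interval: tuple[float, float] = (0.0, 5.0)
    beta: float = 0.1
    wavelet: str = "db4"
    wavelet_level: int = 3
    bessel_order: int = 4
    # fusion / windowing
    window_seconds: float = 2.0
    overlap: float = 0.5
    min_label_purity: float = 0.8
    exclude_impure_train: bool = True
    # pattern decision
    tau: float = DEFAULT_TAU
    max_degree: int = 6
    # features
    dtw_downsample: int = 4
    msst_iterations: int = 3
    n_bands: int = 8
    hmrf_states: int = 2
    hmrf_beta: float = 1.0
    # optimization
    optimizer: str = "qda"  # qda | ofnda
    qda_shrinkage: float = 0.1
    ofnda_fuzzifier: float = 2.0
    # classification
    algorithm: str = "laprls"  # rls | laprls | nystrom
    labeled_fraction: float = 0.5
    test_fraction: float = 0.25
    gamma_a: float = 1e-5
    gamma_i: float = 1e-2
    graph_k: int = 7
    nystrom_fraction: float = 0.25
    pcg_tol: float = 1e-8

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = yaml.safe_dump(_plain(asdict(self)), sort_keys=True)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text) or {}
        if "still_interval" in data:
            data["still_interval"] = tuple(data["still_interval"])
        return cls(**data)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Corpus construction
# ---------------------------------------------------------------------------

@dataclass
class CorpusWindow:
    """One window plus its provenance inside the corpus."""

    recording: int
    window: Window
    pattern: str
    score: float
    true_regime: str


def build_corpus(config: PipelineConfig) -> list[CorpusWindow]:
    """Generate, preprocess, fuse, window and pattern-call every recording."""
    if config.profile == "pad":
        schedule, profiles = pad_schedule(config.seconds), PAD_PROFILES
    elif config.profile == "gotov":
        schedule, profiles = gotov_schedule(config.seconds), GOTOV_PROFILES
    else:
        raise ValueError(f"unknown profile {config.profile!r}")

    out: list[CorpusWindow] = []
    for rec_i in range(config.n_recordings):
        rec_seed = config.seed * 10_000 + rec_i
        imu, phy, truth = generate_recording(
            schedule, SensorConfig(), seed=rec_seed, profiles=profiles,
            subject_jitter=config.subject_jitter,
        )
        imu_c, phy_f, _orient, _cal = preprocess(
            imu, phy,
            still_interval=config.still_interval,
            beta=config.beta,
            wavelet=config.wavelet,
            level=config.wavelet_level,
            bessel_order=config.bessel_order,
        )
        fus = fuse_streams(imu_c, phy_f)
        stats = recording_stats(fus)
        for w in make_windows(fus, config.window_seconds, config.overlap):
            call = decide_pattern(w, stats, tau=config.tau, max_degree=config.max_degree)
            out.append(
                CorpusWindow(
                    recording=rec_i,
                    window=w,
                    pattern=call.pattern,
                    score=call.score,
                    true_regime=truth.schedule.regime_of(w.label),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def featurize(
    corpus: list[CorpusWindow],
    bank: TemplateBank,
    config: PipelineConfig,
    rate: float,
    static_cache: dict | None = None,
) -> pd.DataFrame:
    """One row per window: pattern indicator + zero-filled feature blocks."""
    kin_names: list[str] | None = None
    stat_names: list[str] | None = None
    rows = []
    for idx, cw in enumerate(corpus):
        if cw.pattern == "kinematic":
            fv = kinematic_features(cw.window, bank)
            kin_names = kin_names or fv.names
            rows.append((idx, "kinematic", fv.values))
        else:
            if static_cache is not None and idx in static_cache:
                fv = static_cache[idx]
            else:
                fv = static_features(
                    cw.window, rate,
                    msst_iterations=config.msst_iterations,
                    n_bands=config.n_bands,
                    n_states=config.hmrf_states,
                    beta=config.hmrf_beta,
                )
                if static_cache is not None:
                    static_cache[idx] = fv
            stat_names = stat_names or fv.names
            rows.append((idx, "static", fv.values))
    kin_names = kin_names or []
    stat_names = stat_names or []
    cols = ["pattern_ind"] + kin_names + stat_names
    table = np.zeros((len(rows), len(cols)))
    for r, (idx, pat, vals) in enumerate(rows):
        if pat == "kinematic":
            table[r, 0] = 1.0
            table[r, 1 : 1 + len(kin_names)] = vals
        else:
            table[r, 1 + len(kin_names) :] = vals
    df = pd.DataFrame(table, columns=cols)
    df.insert(0, "window_index", [idx for idx, _, _ in rows])
    return df


def _standardize(train: np.ndarray, full: np.ndarray) -> np.ndarray:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (full - mu) / sd


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    report: EvaluationReport
    pattern_agreement: float
    n_windows: int
    n_test: int
    config: PipelineConfig
    predictions: pd.DataFrame = field(repr=False, default=None)


def _split_recordings(config: PipelineConfig, rng: np.random.Generator):
    n = config.n_recordings
    n_test = max(1, int(round(config.test_fraction * n)))
    perm = rng.permutation(n)
    return set(perm[n_test:].tolist()), set(perm[:n_test].tolist())


def _choose_labeled(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Seeded labeled subset containing at least one window per class."""
    n = len(labels)
    n_lab = max(1, int(round(fraction * n)))
    chosen = set(rng.choice(n, size=n_lab, replace=False).tolist())
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if not chosen & set(members.tolist()):
            chosen.add(int(members[rng.integers(len(members))]))
    mask = np.zeros(n, bool)
    mask[list(chosen)] = True
    return mask


def run(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    corpus: list[CorpusWindow] | None = None,
    static_cache: dict | None = None,
) -> RunResult:
    """Execute the full pipeline and evaluate on held-out recordings."""
    if config.optimizer not in ("qda", "ofnda"):
        raise ValueError(f"unknown optimizer {config.optimizer!r}")
    if config.algorithm not in ("rls", "laprls", "nystrom"):
        raise ValueError(f"unknown algorithm {config.algorithm!r}")
    rng = np.random.default_rng(config.seed + 777)
    corpus = corpus if corpus is not None else build_corpus(config)
    rate = corpus[0].window.data.shape[0] / config.window_seconds

    labels_all = np.array([cw.window.label for cw in corpus])
    rec_of = np.array([cw.recording for cw in corpus])
    train_recs, test_recs = _split_recordings(config, rng)
    train_mask = np.isin(rec_of, list(train_recs))
    test_mask = ~train_mask

    pure = np.array(
        [cw.window.label_purity >= config.min_label_purity for cw in corpus]
    )
    trainable = train_mask & (pure if config.exclude_impure_train else True)

    train_idx = np.flatnonzero(trainable)
    labeled_local = _choose_labeled(
        labels_all[train_idx], config.labeled_fraction, rng
    )
    labeled_mask = np.zeros(len(corpus), bool)
    labeled_mask[train_idx[labeled_local]] = True

    # template bank from labeled kinematic training windows
    kin_labeled = [
        corpus[i].window
        for i in np.flatnonzero(labeled_mask)
        if corpus[i].pattern == "kinematic"
    ]
    if not kin_labeled:
        raise RuntimeError("no labeled kinematic windows to build the template bank")
    bank = TemplateBank.fit(kin_labeled, downsample=config.dtw_downsample)

    feats = featurize(corpus, bank, config, rate, static_cache=static_cache)
    Xraw = feats.drop(columns=["window_index"]).to_numpy()
    X = _standardize(Xraw[trainable], Xraw)

    # optimization branch (fitted on labeled training windows only)
    y_lab = labels_all[labeled_mask]
    if config.optimizer == "qda":
        opt = fit_qda(X[labeled_mask], y_lab, config.qda_shrinkage)
        Xopt = qda_transform(opt, X)
    elif config.optimizer == "ofnda":
        opt = fit_ofnda(X[labeled_mask], y_lab, p=config.ofnda_fuzzifier)
        Xopt = ofnda_transform(opt, X)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    unlabeled_mask = trainable & ~labeled_mask
    X_l, X_u = Xopt[labeled_mask], Xopt[unlabeled_mask]
    spec = GraphSpec(k=config.graph_k)
    if config.algorithm == "rls":
        model = fit_rls(X_l, y_lab, config.gamma_a)
    elif config.algorithm == "laprls":
        model = fit_laprls(X_l, y_lab, X_u, config.gamma_a, config.gamma_i, spec=spec)
    elif config.algorithm == "nystrom":
        n_pool = len(X_l) + len(X_u)
        m = max(1, int(round(config.nystrom_fraction * n_pool)))
        model = fit_nystrom_laprls(
            X_l, y_lab, X_u, m=m, gamma_a=config.gamma_a, gamma_i=config.gamma_i,
            spec=spec, pcg_tol=config.pcg_tol, seed=config.seed,
        )
    else:
        raise ValueError(f"unknown algorithm {config.algorithm!r}")

    pred, scores = predict(model, Xopt[test_mask])
    report = evaluate(
        pred, labels_all[test_mask], scores, score_classes=model.classes
    )
    agreement = float(
        np.mean([(cw.pattern == cw.true_regime) for cw in corpus])
    )
    pred_df = pd.DataFrame(
        {
            "recording": rec_of[test_mask],
            "start": [corpus[i].window.start for i in np.flatnonzero(test_mask)],
            "true": labels_all[test_mask],
            "predicted": pred,
        }
    )
    result = RunResult(
        report, agreement, len(corpus), int(test_mask.sum()), config, pred_df
    )
    if outdir is not None:
        _write_artifacts(Path(outdir), config, feats, corpus, result)
    return result


def _write_artifacts(outdir, config, feats, corpus, result):
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    feats.to_csv(outdir / "features.csv", index=False)
    calls = pd.DataFrame(
        {
            "recording": [cw.recording for cw in corpus],
            "window_start": [cw.window.start for cw in corpus],
            "label": [cw.window.label for cw in corpus],
            "pattern": [cw.pattern for cw in corpus],
            "score": [cw.score for cw in corpus],
            "true_regime": [cw.true_regime for cw in corpus],
        }
    )
    calls.to_csv(outdir / "pattern_calls.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(result.report.to_dict(), indent=2))
    result.predictions.to_csv(outdir / "predictions.csv", index=False)
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "seed": config.seed,
        "n_windows": result.n_windows,
        "n_test": result.n_test,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Labeled-fraction sweep
# ---------------------------------------------------------------------------

def sweep_labeled_fraction(
    config: PipelineConfig,
    fractions: list[float],
    seeds: list[int],
    algorithms: list[str] = ("laprls",),
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Mean ± SD of RMSE and accuracy per (fraction, algorithm) over seeds.

    The corpus and the static feature block are computed once per seed and
    shared across fractions/algorithms (only labeled-set–dependent stages
    are refit).
    """
    if any(not (0 < f < 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1)")
    records = []
    for seed in seeds:
        cfg_seed = _replace(config, seed=seed)
        corpus = build_corpus(cfg_seed)
        static_cache: dict = {}
        for frac in fractions:
            for algo in algorithms:
                cfg = _replace(cfg_seed, labeled_fraction=frac, algorithm=algo)
                try:
                    res = run(cfg, corpus=corpus, static_cache=static_cache)
                except RuntimeError as exc:
                    log.warning(
                        "skipping fraction %.2f seed %d (%s)", frac, seed, exc
                    )
                    continue
                records.append(
                    {
                        "fraction": frac,
                        "algorithm": algo,
                        "seed": seed,
                        "rmse": res.report.rmse,
                        "accuracy": res.report.accuracy,
                        "macro_f1": res.report.macro_f1,
                    }
                )
    df = pd.DataFrame(records)
    summary = (
        df.groupby(["fraction", "algorithm"])
        .agg(
            rmse_mean=("rmse", "mean"),
            rmse_sd=("rmse", "std"),
            acc_mean=("accuracy", "mean"),
            acc_sd=("accuracy", "std"),
            n_seeds=("seed", "count"),
        )
        .reset_index()
    )
    if out_csv is not None:
        summary.to_csv(out_csv, index=False)
    return summary


def _replace(config: PipelineConfig, **kw) -> PipelineConfig:
    d = asdict(config)
    d.update(kw)
    d["still_interval"] = tuple(d["still_interval"])
    return PipelineConfig(**d)


def plot_sweep(summary: pd.DataFrame, path: str | Path) -> None:
    """RMSE-vs-labeled-fraction curves, one line per algorithm."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for algo, grp in summary.groupby("algorithm"):
        ax.errorbar(grp["fraction"], grp["rmse_mean"], yerr=grp["rmse_sd"],
                    marker="o", capsize=3, label=algo)
    ax.set_xlabel("labeled fraction")
    ax.set_ylabel("RMSE (scores vs ±1 targets)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
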