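"""End-to-end orchestration: cohort -> behavior -> connectivity ->
graph metrics -> NBS -> PCR, from a single config.

Stages exchange long/tidy tables keyed on (subject, session, band,
node), written as CSV next to a JSON run manifest that records the
config hash, derived seeds, per-stage row counts and a result summary.
Every stochastic stage derives its seed deterministically from the
global seed, so identical config + seed reproduces identical artifacts
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import connectivity as con
from . import graph_metrics as gm
from . import nbs as nbs_mod
from . import stats as st
from . import synthetic as syn

logger = logging.getLogger(__name__)


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Route package logs to stderr and optionally a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunConfig:
    """Everything one run needs.

    ``mode`` is ``"synthetic"`` (generate a cohort) or ``"files"`` (read
    EEG trials and behavior traces from ``input_dir``).  The synthetic
    block plants a session effect of ``effect_size`` (change in coupling
    strength, post minus pre) on ``effect_edges`` in ``effect_band``,
    and — when ``latent_gain > 0`` — ties a per-subject-session latent
    state to both theta-band coupling on ``theta_edges`` and tracking
    noise, creating the metric/performance association the stats stage
    is meant to recover.
    """

    mode: str = "synthetic"
    out_dir: str = "runs/demo"
    seed: int = 0
    # cohort / recording geometry
    n_subjects: int = 6
    n_trials: int = 2
    trial_duration: float = 12.0
    fs: float = 512.0
    # connectivity
    window_length: float = 4.0
    stride: float = 2.0
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")
    preprocess: bool = True
    pool_trials: bool = True
    percolation: bool = True
    # synthetic structure
    effect_edges: tuple[tuple[str, str], ...] = (
        ("AF4", "FC4"), ("FC4", "C4"), ("C4", "CP4"), ("CP4", "O2"),
    )
    effect_band: str = "beta"
    effect_size: float = 0.0
    base_strength: float = 0.35
    noise_sd: float = 1.0
    theta_edges: tuple[tuple[str, str], ...] = (
        ("CPz", "Pz"), ("Pz", "O1"), ("CP3", "CPz"),
    )
    theta_base_strength: float = 0.4
    latent_gain: float = 0.0
    # behavior
    behavior_difficulty: str = "hard"
    behavior_duration: float = 60.0
    behavior_noise_pre: float = 25.0
    behavior_noise_post: float = 12.0
    behavior_lag: float = 0.08
    # NBS
    nbs_T: float = 2.75
    nbs_k: int = 1000
    nbs_alpha: float = 0.05
    nbs_tail: str = "decrease"
    # stats
    stats_band: str = "theta"
    stats_alpha: float = 0.05
    # files mode
    input_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        # YAML lists arrive as lists; normalize to tuples for hashing.
        cfg.bands = tuple(cfg.bands)
        cfg.effect_edges = tuple(tuple(e) for e in cfg.effect_edges)
        cfg.theta_edges = tuple(tuple(e) for e in cfg.theta_edges)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = list(self.bands)
        d["effect_edges"] = [list(e) for e in self.effect_edges]
        d["theta_edges"] = [list(e) for e in self.theta_edges]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage 1: cohort (synthetic generation or file loading)
# ---------------------------------------------------------------------------

def _subject_ids(n: int) -> list[str]:
    return [f"s{u + 1:02d}" for u in range(n)]


def _generate_cohort(
    cfg: RunConfig, rng: np.random.Generator
) -> tuple[list[con.EEGRecording], pd.DataFrame]:
    """Synthetic EEG trials and behavior trial traces for the cohort."""
    recordings: list[con.EEGRecording] = []
    beh_rows = []
    for sid in _subject_ids(cfg.n_subjects):
        for session in ("pre", "post"):
            z = float(rng.standard_normal()) if cfg.latent_gain > 0 else 0.0
            theta_strength = float(
                np.clip(
                    cfg.theta_base_strength + cfg.latent_gain * z, 0.02, 0.95
                )
            )
            effect_strength = cfg.base_strength
            if session == "post":
                effect_strength = float(
                    np.clip(cfg.base_strength + cfg.effect_size, 0.0, 1.0)
                )
            specs = [
                syn.CouplingSpec(
                    pair=e, band=cfg.effect_band,
                    phase_lag=np.pi / 2, strength=effect_strength,
                )
                for e in cfg.effect_edges
            ] + [
                syn.CouplingSpec(
                    pair=e, band="theta",
                    phase_lag=np.pi / 2, strength=theta_strength,
                )
                for e in cfg.theta_edges
            ]
            base_noise = (
                cfg.behavior_noise_pre if session == "pre"
                else cfg.behavior_noise_post
            )
            track_noise = base_noise * float(np.exp(-1.2 * z))
            for trial in range(cfg.n_trials):
                recordings.append(
                    syn.gen_coupled_eeg(
                        specs,
                        n_channels=16,
                        fs=cfg.fs,
                        duration=cfg.trial_duration,
                        noise_sd=cfg.noise_sd,
                        seed=int(rng.integers(2 ** 31)),
                        subject=sid,
                        session=session,
                        trial=trial,
                    )
                )
                for hand in ("left", "right"):
                    track = beh.generate_track(
                        cfg.behavior_difficulty,
                        duration=cfg.behavior_duration,
                        seed=int(rng.integers(2 ** 31)),
                    )
                    cursor = syn.gen_tracker(
                        track,
                        lag=cfg.behavior_lag,
                        noise_sd=track_noise,
                        seed=int(rng.integers(2 ** 31)),
                    )
                    beh_rows.append(
                        {
                            "subject": sid,
                            "session": session,
                            "trial": trial,
                            "hand": hand,
                            "r": beh.performance_r(cursor, track.trace),
                        }
                    )
    return recordings, pd.DataFrame(beh_rows)


def _load_cohort(cfg: RunConfig) -> tuple[list[con.EEGRecording], pd.DataFrame]:
    """files mode: EEG sidecar pairs under <input_dir>/eeg and one
    behavior.csv with per-sample cursor/track traces."""
    if cfg.input_dir is None:
        raise ValueError("files mode requires input_dir")
    root = Path(cfg.input_dir)
    eeg_dir = root / "eeg"
    sidecars = sorted(eeg_dir.glob("*.json"))
    if not sidecars:
        raise ValueError(f"no EEG sidecars found under {eeg_dir}")
    recordings = [con.read_eeg_csv(p) for p in sidecars]
    beh_path = root / "behavior.csv"
    if not beh_path.exists():
        raise ValueError(f"missing behavior traces: {beh_path}")
    traces = pd.read_csv(beh_path)
    needed = {"subject", "session", "trial", "hand", "cursor_x", "track_x"}
    if not needed.issubset(traces.columns):
        raise ValueError(f"behavior.csv needs columns {sorted(needed)}")
    rows = []
    for (sid, session, trial, hand), g in traces.groupby(
        ["subject", "session", "trial", "hand"], sort=True
    ):
        rows.append(
            {
                "subject": sid,
                "session": session,
                "trial": trial,
                "hand": hand,
                "r": beh.performance_r(
                    g["cursor_x"].to_numpy(), g["track_x"].to_numpy()
                ),
            }
        )
    return recordings, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage 3: connectivity
# ---------------------------------------------------------------------------

def _estimate_connectivity(
    recordings: Sequence[con.EEGRecording], cfg: RunConfig
) -> list[con.ConnectivityMatrix]:
    groups: dict[tuple[str, str], list[con.EEGRecording]] = {}
    for rec in recordings:
        groups.setdefault((rec.subject, rec.session), []).append(rec)
    mats: list[con.ConnectivityMatrix] = []
    for (sid, session), recs in sorted(groups.items()):
        processed = [con.preprocess(r) if cfg.preprocess else r for r in recs]
        wsets = [
            con.sliding_windows(r, cfg.window_length, cfg.stride)
            for r in processed
        ]
        if cfg.pool_trials:
            pooled = con.pool_windows(wsets)
            for band in cfg.bands:
                mats.append(con.ciplv(pooled, band, subject=sid, session=session))
        else:
            for band in cfg.bands:
                per_trial = [
                    con.ciplv(ws, band, subject=sid, session=session)
                    for ws in wsets
                ]
                mats.append(con.average_matrices(per_trial))
    return mats


# ---------------------------------------------------------------------------
# Stage 6: stats
# ---------------------------------------------------------------------------

def _stats_stage(
    node_metrics: pd.DataFrame,
    bimanual: pd.DataFrame,
    cfg: RunConfig,
) -> tuple[dict, pd.DataFrame | None]:
    band_metrics = node_metrics[node_metrics["band"] == cfg.stats_band]
    if band_metrics.empty:
        raise ValueError(f"no node metrics for band {cfg.stats_band!r}")
    wide = band_metrics.pivot_table(
        index=["subject", "session"], columns="node", values="closeness"
    ).reset_index()
    merged = wide.merge(bimanual, on=["subject", "session"], how="inner")
    if len(merged) < len(wide):
        raise ValueError("behavior and node metrics cover different cohorts")
    node_cols = [c for c in wide.columns if c not in ("subject", "session")]
    controls = pd.DataFrame(
        {
            "session": merged["session"].astype("category"),
            "participant": merged["subject"].astype("category"),
        }
    )
    screening = st.screen_nodes(
        merged[node_cols], merged["pc1"], controls=controls,
        alpha=cfg.stats_alpha,
    )
    selected = screening.loc[screening["significant"], "node"].tolist()
    summary: dict = {
        "band": cfg.stats_band,
        "n_observations": int(len(merged)),
        "screened_nodes": len(node_cols),
        "selected_nodes": selected,
        "max_abs_rho": float(screening["rho"].abs().max()),
        "top_node": str(
            screening.loc[screening["rho"].abs().idxmax(), "node"]
        ),
    }
    if not selected:
        summary["note"] = (
            "no node survived Bonferroni screening; PCR not fitted"
        )
        return summary, screening
    if len(selected) >= 2:
        summary["vif"] = {
            k: (None if np.isinf(v) else float(v))
            for k, v in st.vif(merged[selected]).items()
        }
    model = st.pcr_with_loocv(
        merged[selected], merged["pc1"], controls=controls
    )
    summary["pcr"] = {
        "selected_nodes": list(model.selected_nodes),
        "loadings": [float(v) for v in model.loadings],
        "explained_variance": model.explained_variance,
        "beta0": model.beta0,
        "beta1": model.beta1,
        "beta0_se": model.beta0_se,
        "r2": model.r2,
        "loocv_r2": model.loocv_r2,
        "loocv_rmse": model.loocv_rmse,
    }
    return summary, screening


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False)
    return len(df)


def run(cfg: RunConfig) -> dict:
    """Execute all stages and write artifacts + manifest to out_dir.

    Returns the manifest dict.  A stage failure raises with the stage
    name attached, leaving earlier artifacts in place.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    nbs_seed = int(rng.integers(2 ** 31))
    stages: list[dict] = []
    summary: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
            return result
        return wrap

    # 1 — cohort
    @stage("cohort")
    def cohort():
        if cfg.mode == "synthetic":
            return _generate_cohort(cfg, rng)
        if cfg.mode == "files":
            return _load_cohort(cfg)
        raise ValueError(f"unknown mode {cfg.mode!r}")

    recordings, hand_scores = cohort
    stages.append(
        {
            "name": "cohort",
            "n_recordings": len(recordings),
            "n_behavior_trials": int(len(hand_scores)),
        }
    )

    # 2 — behavior
    @stage("behavior")
    def behavior_stage():
        _write_csv(hand_scores, out / "hand_scores.csv")
        means = beh.session_scores(hand_scores)
        _write_csv(means, out / "session_scores.csv")
        bim = beh.bimanual_pca(means)
        _write_csv(bim, out / "bimanual.csv")
        return means, bim

    session_means, bimanual = behavior_stage
    stages.append(
        {
            "name": "behavior",
            "rows": int(len(session_means)),
            "explained_variance": float(bimanual["explained_variance"].iloc[0]),
        }
    )
    summary["behavior"] = {
        "explained_variance": float(bimanual["explained_variance"].iloc[0]),
        "mean_score_pre": float(
            session_means.loc[session_means["session"] == "pre", "r"].mean()
        ),
        "mean_score_post": float(
            session_means.loc[session_means["session"] == "post", "r"].mean()
        ),
    }

    # 3 — connectivity
    @stage("connectivity")
    def connectivity_stage():
        mats = _estimate_connectivity(recordings, cfg)
        frame = con.connectivity_to_frame(mats)
        _write_csv(frame, out / "connectivity.csv")
        np.savez(
            out / "connectivity.npz",
            **{
                f"{m.subject}_{m.session}_{m.band}": m.values
                for m in mats
            },
        )
        return mats

    matrices = connectivity_stage
    stages.append({"name": "connectivity", "n_matrices": len(matrices)})

    # 4 — graph metrics
    @stage("graph_metrics")
    def graph_stage():
        table = gm.node_closeness_table(matrices, percolation=cfg.percolation)
        _write_csv(table, out / "node_metrics.csv")
        return table

    node_metrics = graph_stage
    stages.append({"name": "graph_metrics", "rows": int(len(node_metrics))})

    # 5 — NBS
    @stage("nbs")
    def nbs_stage():
        by_band = {}
        subjects = sorted({m.subject for m in matrices})
        for band in cfg.bands:
            pre = [
                next(
                    m for m in matrices
                    if m.subject == s and m.session == "pre" and m.band == band
                )
                for s in subjects
            ]
            post = [
                next(
                    m for m in matrices
                    if m.subject == s and m.session == "post" and m.band == band
                )
                for s in subjects
            ]
            res = nbs_mod.nbs_test(
                pre, post,
                nbs_mod.NBSConfig(
                    T=cfg.nbs_T, k=cfg.nbs_k, alpha=cfg.nbs_alpha,
                    tail=cfg.nbs_tail, seed=nbs_seed,
                ),
            )
            payload = nbs_mod.result_to_dict(res)
            (out / f"nbs_{band}.json").write_text(
                json.dumps(payload, indent=1, sort_keys=True)
            )
            by_band[band] = payload
        return by_band

    nbs_results = nbs_stage
    stages.append({"name": "nbs", "bands": list(cfg.bands)})
    summary["nbs"] = {
        band: {
            "any_significant": payload["any_significant"],
            "n_components": len(payload["components"]),
            "significant_extents": [
                c["extent"] for c in payload["components"] if c["significant"]
            ],
        }
        for band, payload in nbs_results.items()
    }

    # 6 — stats
    @stage("stats")
    def stats_stage():
        stats_summary, screening = _stats_stage(node_metrics, bimanual, cfg)
        if screening is not None:
            _write_csv(screening, out / f"correlations_{cfg.stats_band}.csv")
        (out / f"pcr_{cfg.stats_band}.json").write_text(
            json.dumps(stats_summary, indent=1, sort_keys=True)
        )
        return stats_summary

    summary["stats"] = stats_stage
    stages.append({"name": "stats", "band": cfg.stats_band})

    from . import __version__

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "derived_seeds": {"nbs": nbs_seed},
        "version": __version__,
        "stages": stages,
        "summary": summary,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    logger.info("run complete: %d stages -> %s", len(stages), out)
    return manifest
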